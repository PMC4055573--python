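"""Synthetic data under an isolation-with-migration coalescent model.

The generator emulates the validation design of the scan: two in-group
populations A and B (two haploid samples each) plus an optional outgroup,
with unidirectional migration from B into A (forward in time) at scaled
rate ``m`` during a bounded window, recombination along a 100 kb sequence,
and Jukes-Cantor sequence evolution on each local genealogy.

Times are in coalescent units (one unit = 2N generations; a pair of
lineages in one population coalesces at rate 1 per unit).  Defaults are
anchored on consensus estimates for *Mus musculus* / *M. spretus*: an
in-group divergence of 1.5 Mya at 2 generations per year with Ne = 50,000
gives ``t_split_ab = 30``; ``theta`` (4N*mu per bp) follows the commonly
cited 4.5e-9 substitutions/site/year at 2 generations/year (about 1.35%
in-group sequence divergence), and ``rho`` corresponds to 0.56 cM/Mb.

Recombination uses the sequentially-independent-segments approximation:
Poisson breakpoints along the sequence and an independent genealogy per
segment.  Every segment also carries a conservative per-site truth label
(:func:`label_migration_lower_bound`): a clade of exactly one A lineage
plus one or more B lineages whose root falls inside the migration window
can only arise through migration, so the labelled fraction is a sound
lower bound on the true fraction of migrant-affected sites, and is
identically false when m = 0.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from . import substitution as sub, trees
from .io import SiteAlignment
from .trees import Node, RootedTree

_MAX_EVENTS = 10 ** 6


@dataclass
class SimConfig:
    """Study conditions for the isolation-with-migration generator."""

    n_a: int = 2
    n_b: int = 2
    n_out: int = 0
    t_split_ab: float = 30.0
    t_split_outgroup: float = 60.0
    migration_rate: float = 0.5       # per A lineage per unit, backwards
    t_mig_start: float = 0.0
    t_mig_end: float = 0.25
    recombination_rate: float = 5.6e-4  # breakpoints per bp (0.56 cM/Mb)
    theta: float = 4.5e-4               # 4N*mu per bp
    length: int = 100_000
    seed: int = 0
    replicates: int = 20

    def __post_init__(self):
        if not (0 <= self.t_mig_start < self.t_mig_end
                <= self.t_split_ab < self.t_split_outgroup):
            raise ValueError(
                "need 0 <= t_mig_start < t_mig_end <= t_split_ab "
                "< t_split_outgroup")
        if self.migration_rate < 0 or self.length < 1:
            raise ValueError("migration_rate must be >= 0 and length >= 1")

    @property
    def sample_labels(self) -> list[str]:
        return ([f"a{i+1}" for i in range(self.n_a)]
                + [f"b{i+1}" for i in range(self.n_b)]
                + [f"o{i+1}" for i in range(self.n_out)])

    @property
    def allele_map(self) -> dict[str, str]:
        out = {f"a{i+1}": "A" for i in range(self.n_a)}
        out.update({f"b{i+1}": "B" for i in range(self.n_b)})
        out.update({f"o{i+1}": "O" for i in range(self.n_out)})
        return out


@dataclass
class Segment:
    start: int
    end: int
    genealogy: RootedTree      # coalescent units; node.tag = time
    migrant: bool


@dataclass
class SimReplicate:
    config: SimConfig
    segments: list[Segment]
    alignment: SiteAlignment
    truth: np.ndarray          # (L,) bool, per-site migration lower bound

    @property
    def truth_fraction(self) -> float:
        return float(self.truth.mean())


# ----------------------------------------------------------------------
# structured coalescent
# ----------------------------------------------------------------------

def simulate_genealogy(config: SimConfig,
                       rng: np.random.Generator) -> RootedTree:
    """One draw from the structured coalescent with isolation and a
    bounded migration window.  Node ``tag`` carries the event time."""
    lineages: dict[int, str] = {}
    nodes: dict[int, Node] = {}
    for i, label in enumerate(config.sample_labels):
        nodes[i] = Node(label=label, tag=0.0)
        lineages[i] = config.allele_map[label]
    next_id = len(nodes)

    boundaries = sorted({config.t_mig_start, config.t_mig_end,
                         config.t_split_ab, config.t_split_outgroup})
    t = 0.0
    events = 0
    while len(lineages) > 1:
        events += 1
        if events > _MAX_EVENTS:
            raise RuntimeError("event cap exceeded")
        pops: dict[str, list[int]] = {}
        for lid, pop in lineages.items():
            pops.setdefault(pop, []).append(lid)
        mig_on = config.t_mig_start <= t < config.t_mig_end
        rates: list[tuple[float, str, str]] = []
        for pop, members in pops.items():
            k = len(members)
            if k >= 2:
                rates.append((k * (k - 1) / 2.0, "coal", pop))
        if mig_on and config.migration_rate > 0 and "A" in pops:
            rates.append((len(pops["A"]) * config.migration_rate,
                          "mig", "A"))
        total = sum(r for r, _, _ in rates)
        nxt = next((b for b in boundaries if b > t), math.inf)
        if total == 0.0:
            t = nxt
        else:
            wait = rng.exponential(1.0 / total)
            if t + wait >= nxt:
                t = nxt
            else:
                t += wait
                u = rng.random() * total
                acc = 0.0
                for r, kind, pop in rates:
                    acc += r
                    if u < acc:
                        break
                if kind == "mig":
                    lid = pops["A"][rng.integers(len(pops["A"]))]
                    lineages[lid] = "B"
                else:
                    members = pops[pop]
                    i, j = rng.choice(len(members), size=2, replace=False)
                    a, b = members[i], members[j]
                    parent = Node(tag=t, children=[nodes[a], nodes[b]])
                    nodes[a].length = t - nodes[a].tag
                    nodes[b].length = t - nodes[b].tag
                    del nodes[a], nodes[b], lineages[a], lineages[b]
                    nodes[next_id] = parent
                    lineages[next_id] = pop
                    next_id += 1
                continue
        # hit a boundary: apply population merges
        if t >= config.t_split_ab:
            for lid, pop in list(lineages.items()):
                if pop == "A":
                    lineages[lid] = "B"
        if t >= config.t_split_outgroup:
            for lid, pop in list(lineages.items()):
                if pop == "O":
                    lineages[lid] = "B"

    (root_id,) = lineages
    root = nodes[root_id]
    root.length = 0.0
    return RootedTree(root, trees.COALESCENT)


def label_migration_lower_bound(genealogy: RootedTree,
                                config: SimConfig) -> bool:
    """Conservative migration evidence: some clade of exactly one A sample
    and >= 1 B samples (no outgroup) coalesces strictly within the
    migration window (t_mig_start, t_mig_end).

    Sound: under pure isolation no A lineage can coalesce with a B
    lineage before t_split_ab, let alone inside the window, so the label
    is identically false when m = 0.  Conservative: a migrant lineage
    that coalesces only after the window closes is not counted, so the
    labelled site fraction is a lower bound on the migrant-affected
    fraction."""
    for node in genealogy.postorder():
        if node.is_leaf():
            continue
        labels = [l.label for l in _leaves_under(node)]
        n_a = sum(l.startswith("a") for l in labels)
        n_b = sum(l.startswith("b") for l in labels)
        n_o = len(labels) - n_a - n_b
        if n_a == 1 and n_b >= 1 and n_o == 0 and \
                config.t_mig_start < node.tag < config.t_mig_end:
            return True
    return False


def _leaves_under(node: Node) -> list[Node]:
    return [n for n in trees._postorder(node) if n.is_leaf()]


# ----------------------------------------------------------------------
# sequence evolution
# ----------------------------------------------------------------------

def _evolve_jc(genealogy: RootedTree, theta: float, n_sites: int,
               labels: list[str], rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor evolution; branch lengths are (theta/2) * coalescent
    time.  Returns (n_labels, n_sites) IUPAC codes."""
    base_codes = np.array([sub.CODE_OF[b] for b in sub.BASES],
                          dtype=np.uint8)
    order = {lab: i for i, lab in enumerate(labels)}
    out = np.empty((len(labels), n_sites), dtype=np.uint8)

    def walk(node: Node, states: np.ndarray):
        if node.is_leaf():
            out[order[node.label]] = base_codes[states]
            return
        for child in node.children:
            b = 0.5 * theta * child.length
            p_change = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
            states_child = states.copy()
            hit = rng.random(n_sites) < p_change
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                states_child[hit] = (states_child[hit] + shift) % 4
            walk(child, states_child)

    root_states = rng.integers(0, 4, size=n_sites)
    walk(genealogy.root, root_states)
    return out


# ----------------------------------------------------------------------
# replicates
# ----------------------------------------------------------------------

def segment_boundaries(length: int, rho: float,
                       rng: np.random.Generator) -> list[tuple[int, int]]:
    """Partition [0, length) at Poisson(rho * length) breakpoints."""
    n_breaks = rng.poisson(rho * length) if rho > 0 else 0
    n_breaks = min(n_breaks, length - 1)
    if n_breaks:
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_breaks,
                                  replace=False))
    else:
        cuts = np.array([], dtype=int)
    edges = np.concatenate([[0], cuts, [length]])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def simulate_replicate(config: SimConfig,
                       seed: int | None = None) -> SimReplicate:
    """One replicate: segments, alignment and per-site truth track."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = config.sample_labels
    segments: list[Segment] = []
    codes = np.empty((len(labels), config.length), dtype=np.uint8)
    truth = np.zeros(config.length, dtype=bool)
    for start, end in segment_boundaries(
            config.length, config.recombination_rate, rng):
        genealogy = simulate_genealogy(config, rng)
        migrant = label_migration_lower_bound(genealogy, config)
        codes[:, start:end] = _evolve_jc(genealogy, config.theta,
                                         end - start, labels, rng)
        truth[start:end] = migrant
        segments.append(Segment(start, end, genealogy, migrant))
    alignment = SiteAlignment(list(labels), codes)
    return SimReplicate(config, segments, alignment, truth)


def simulate_study(config: SimConfig) -> list[SimReplicate]:
    """The replicate set for one condition; replicate i uses seed
    ``config.seed + i`` so conditions are reproducible one by one."""
    return [simulate_replicate(config, seed=config.seed + i)
            for i in range(config.replicates)]


# ----------------------------------------------------------------------
# ms-format interchange
# ----------------------------------------------------------------------

_MS_LINE = re.compile(r"^\[(\d+)\](.+;)\s*$")


def write_ms_trees(replicate: SimReplicate) -> str:
    """Segment genealogies in ms -T style: ``[length]newick`` lines."""
    lines = []
    for seg in replicate.segments:
        newick = seg.genealogy.newick()
        lines.append(f"[{seg.end - seg.start}]{newick}")
    return "\n".join(lines) + "\n"


def read_ms_output(text: str) -> list[tuple[int, RootedTree]]:
    """Parse ms-style tree lines into (segment length, genealogy) pairs.

    Lines that are not tree lines (``ms`` echoes its command line, seeds
    and ``//`` separators) are skipped; malformed tree lines raise with
    their line number.
    """
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or not line.startswith("["):
            continue
        match = _MS_LINE.match(line)
        if not match:
            raise ValueError(f"malformed ms tree line {lineno}: {line!r}")
        length = int(match.group(1))
        try:
            tree = trees.parse_newick(match.group(2), trees.COALESCENT)
        except trees.TreeError as exc:
            raise ValueError(
                f"malformed newick on line {lineno}: {exc}") from exc
        times = tree.node_times()
        for node in tree.postorder():
            node.tag = times[id(node)]
        out.append((length, tree))
    return out


def segments_from_ms(text: str, config: SimConfig) -> list[Segment]:
    """Turn parsed ms output into labelled segments."""
    parsed = read_ms_output(text)
    segments = []
    pos = 0
    for length, tree in parsed:
        segments.append(Segment(
            pos, pos + length, tree,
            label_migration_lower_bound(tree, config)))
        pos += length
    return segments


# ----------------------------------------------------------------------
# text exports
# ----------------------------------------------------------------------

def write_truth_bed(replicate: SimReplicate, path,
                    chrom: str = "sim") -> None:
    from .io import write_bed
    runs = []
    t = replicate.truth
    edges = np.flatnonzero(np.diff(np.concatenate([[0], t.view(np.int8),
                                                   [0]])))
    for a, b in zip(edges[::2], edges[1::2]):
        runs.append((int(a), int(b), "migrant"))
    write_bed(runs, path, chrom=chrom)


def write_segments_tsv(replicate: SimReplicate, path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tmigrant\tnewick\n")
        for seg in replicate.segments:
            fh.write(f"{seg.start}\t{seg.end}\t{int(seg.migrant)}\t"
                     f"{seg.genealogy.newick()}\n")
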
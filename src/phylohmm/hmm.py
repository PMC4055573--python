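"""The phylo-HMM coupling parental species trees with gene genealogies.

Hidden states are pairs (parental class, rooted gene-tree topology), plus a
silent start state at index 0.  For K parental classes and M rooted
topologies on the sampled alleles the model has 1 + K*M states; the
three-species one-allele case gives 7 states, the two-species
two-alleles-each case used for empirical scans gives 31.

Transitions.  With class-switching probability ``gamma`` (split uniformly
across the K-1 other classes), congruent-state genealogy-switch factor
``s1`` and incongruent-state factor ``s2``, and P̃_c the class-normalised
coalescent topology probabilities:

* within class, i != j:  (1-gamma) * s(g_i) * P̃_c(g_j)
* across classes:        gamma/(K-1) * P̃_c'(g_j)
* diagonal:              the remainder, so each row sums to exactly 1
* from the start state:  P(g | T_c) normalised over all non-start states

``s(g_i)`` is s1 if g_i is congruent with its parental tree, s2 otherwise.
Incomplete lineage sorting enters through P̃_c (computed exactly under the
multispecies coalescent), introgression through the class structure.

Emissions are pruning-algorithm likelihoods of alignment columns on the
state's genealogy under GTR.  Because the model is time-reversible, states
whose genealogies differ only in root placement are emission-equivalent, so
branch lengths are shared in blocks keyed by the unrooted topology
(``share="unrooted"``, the default) or kept per rooted topology
(``share="rooted"``).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _kernels, coalescent, substitution as sub, trees
from .io import SiteAlignment
from .network import ParentalForest
from .trees import RootedTree


class ModelError(ValueError):
    pass


class ParameterInfeasibleError(ModelError):
    """gamma/s1/s2 values that would make a diagonal entry negative."""


@dataclass
class HmmParams:
    """Transition parameters: class switch gamma, genealogy-switch factors
    s1 (out of congruent states) and s2 (out of incongruent states)."""

    gamma: float
    s1: float
    s2: float

    def __post_init__(self):
        for name in ("gamma", "s1", "s2"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ModelError(f"{name}={v} outside [0, 1)")

    def copy(self) -> "HmmParams":
        return HmmParams(self.gamma, self.s1, self.s2)


@dataclass
class GeneTreeState:
    class_index: int
    topology: RootedTree
    topology_index: int
    block_key: str
    congruent: bool
    introgressed: bool

    @property
    def key(self) -> str:
        return self.topology.topology_key()


class BranchBlock:
    """A shared branch-length parameter block.

    ``tree`` is the emission tree (unrooted form or rooted topology) whose
    edge nodes carry the block's scalars; ``edges`` lists those nodes in a
    deterministic order keyed by their leaf-set bipartitions.
    """

    def __init__(self, key: str, tree: RootedTree):
        self.key = key
        self.tree = tree
        self.edges = trees.ordered_edges(tree)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def get_vector(self) -> np.ndarray:
        return np.array([e.length for e in self.edges])

    def set_vector(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.edges),):
            raise ModelError(f"block {self.key!r} expects "
                             f"{len(self.edges)} lengths")
        for e, v in zip(self.edges, values):
            e.length = float(v)


class HmmModel:
    """Full model: parental forest, states, transition and emission
    machinery."""

    def __init__(self, forest: ParentalForest, gtr: sub.GtrParams,
                 params: HmmParams, share: str = "unrooted",
                 init_branch_length: float = 0.05):
        if share not in ("unrooted", "rooted", "unrooted_class"):
            raise ModelError(f"share must be 'unrooted', 'rooted' or "
                             f"'unrooted_class', got {share!r}")
        self.forest = forest
        self.gtr = gtr
        self.params = params
        self.share = share
        if forest.n_classes == 1:
            self.params = HmmParams(0.0, params.s1, params.s2)

        self.alleles = forest.alleles
        self.topologies = trees.enumerate_rooted_topologies(self.alleles)
        self.n_topologies = len(self.topologies)
        self.n_classes = forest.n_classes

        self.blocks: dict[str, BranchBlock] = {}

        def make_block(top: RootedTree, class_index: int) -> str:
            if share == "rooted":
                form, key = trees.tag_clades(top.copy()), \
                    top.topology_key()
            else:
                form = trees.unrooted_form(top)
                key = form.topology_key()
                if share == "unrooted_class":
                    key = f"class{class_index}:{key}"
            if key not in self.blocks:
                block = BranchBlock(key, form)
                block.set_vector(np.full(block.n_edges,
                                         init_branch_length))
                self.blocks[key] = block
            return key

        self.states: list[GeneTreeState] = []
        for c in range(self.n_classes):
            congruent_seen = 0
            for m, top in enumerate(self.topologies):
                cong = trees.is_congruent(top, forest.parental_trees[c],
                                          forest.allele_map)
                congruent_seen += cong
                self.states.append(GeneTreeState(
                    class_index=c, topology=top, topology_index=m,
                    block_key=make_block(top, c), congruent=cong,
                    introgressed=c in forest.introgressed_class_indices))
            if congruent_seen != 1:
                raise ModelError(
                    f"class {c}: expected exactly one congruent topology, "
                    f"found {congruent_seen}")

        self._tables: np.ndarray | None = None  # (K, M) raw MSC probs

    # -- counts --------------------------------------------------------
    @property
    def n_states(self) -> int:
        """Total state count including the start state."""
        return 1 + len(self.states)

    @property
    def introgressed_mask(self) -> np.ndarray:
        return np.array([s.introgressed for s in self.states])

    @property
    def congruent_mask(self) -> np.ndarray:
        return np.array([s.congruent for s in self.states])

    # -- coalescent topology probabilities -----------------------------
    def invalidate_tables(self) -> None:
        self._tables = None

    def topology_tables(self) -> np.ndarray:
        """(K, M) matrix of P(topology | parental tree) per class."""
        if self._tables is None:
            rows = []
            for c, ptree in enumerate(self.forest.parental_trees):
                tab = coalescent.topology_probability_table(
                    ptree, self.forest.allele_map, self.topologies)
                row = np.array([tab[t.topology_key()]
                                for t in self.topologies])
                if np.any(np.isnan(row)):
                    raise ArithmeticError(
                        f"NaN topology probability in class {c}")
                rows.append(row)
            self._tables = np.vstack(rows)
        return self._tables

    def normalized_tables(self) -> np.ndarray:
        tables = self.topology_tables()
        return tables / tables.sum(axis=1, keepdims=True)

    # -- transition structure ------------------------------------------
    def transition_matrix(self) -> np.ndarray:
        """(1+KM) x (1+KM) row-stochastic matrix; row/column 0 is the
        start state (no incoming transitions)."""
        k, m = self.n_classes, self.n_topologies
        gamma, s1, s2 = (self.params.gamma, self.params.s1,
                         self.params.s2)
        ptil = self.normalized_tables()  # (K, M)
        n = k * m
        t = np.zeros((1 + n, 1 + n))

        # start row: normalised gene-tree probability over all states
        raw = self.topology_tables().reshape(-1)
        t[0, 1:] = raw / raw.sum()

        gamma_split = gamma / (k - 1) if k > 1 else 0.0
        cong = self.congruent_mask
        for c in range(k):
            rows = slice(1 + c * m, 1 + (c + 1) * m)
            s_of = np.where(cong[c * m:(c + 1) * m], s1, s2)
            block = (1.0 - gamma) * s_of[:, None] * ptil[c][None, :]
            np.fill_diagonal(block, 0.0)
            t[rows, rows] = block
            for c2 in range(k):
                if c2 == c:
                    continue
                cols = slice(1 + c2 * m, 1 + (c2 + 1) * m)
                t[rows, cols] = gamma_split * ptil[c2][None, :]
        off = t[1:, 1:].sum(axis=1)
        diag = 1.0 - off
        if np.any(diag < -1e-12):
            bad = int(np.argmin(diag))
            raise ParameterInfeasibleError(
                f"negative diagonal remainder {diag[bad]:.3e} at state "
                f"{1 + bad} for gamma={gamma}, s1={s1}, s2={s2}")
        idx = np.arange(1, 1 + n)
        t[idx, idx] = np.clip(diag, 0.0, None)
        return t

    def initial_distribution(self) -> np.ndarray:
        """Distribution over non-start states after leaving the start."""
        return self.transition_matrix()[0, 1:]

    # -- emissions -----------------------------------------------------
    def pattern_data(self, alignment: SiteAlignment
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Distinct column patterns and per-site pattern indices.

        Patterns have shape (n_patterns, n_alleles), columns ordered as
        ``self.alleles``.
        """
        missing = set(self.alleles) - set(alignment.labels)
        if missing:
            raise ModelError(f"alignment lacks rows for alleles "
                             f"{sorted(missing)}")
        rows = [alignment.labels.index(a) for a in self.alleles]
        cols = alignment.codes[rows].T  # (L, n_alleles)
        patterns, inverse = np.unique(cols, axis=0, return_inverse=True)
        return patterns, inverse.astype(np.int64)

    def block_log_likelihoods(self, patterns: np.ndarray
                              ) -> dict[str, np.ndarray]:
        return {key: sub.column_log_likelihoods(
                    block.tree, self.gtr, patterns, self.alleles)
                for key, block in self.blocks.items()}

    def emission_matrix(self, patterns: np.ndarray,
                        block_ll: dict[str, np.ndarray] | None = None
                        ) -> np.ndarray:
        """(KM, n_patterns) linear emission probabilities per state."""
        if block_ll is None:
            block_ll = self.block_log_likelihoods(patterns)
        emis = np.empty((len(self.states), patterns.shape[0]))
        for i, state in enumerate(self.states):
            emis[i] = np.exp(block_ll[state.block_key])
        return emis

    # -- copying / serialisation ---------------------------------------
    def copy(self) -> "HmmModel":
        clone = HmmModel(self.forest, self.gtr.copy(), self.params.copy(),
                         share=self.share)
        for key, block in self.blocks.items():
            clone.blocks[key].set_vector(block.get_vector())
        # parental trees may have been modified in place: deep-copy them
        clone.forest = ParentalForest(
            [t.copy() for t in self.forest.parental_trees],
            dict(self.forest.allele_map),
            self.forest.introgressed_class_indices)
        clone.invalidate_tables()
        return clone

    def to_json(self) -> dict:
        return {
            "format": "phylohmm-model",
            "version": 1,
            "share": self.share,
            "parental_trees": [t.newick()
                               for t in self.forest.parental_trees],
            "allele_map": self.forest.allele_map,
            "introgressed_class_indices":
                sorted(self.forest.introgressed_class_indices),
            "hmm": {"gamma": self.params.gamma, "s1": self.params.s1,
                    "s2": self.params.s2},
            "gtr": {"freqs": self.gtr.freqs.tolist(),
                    "exch": self.gtr.exch.tolist()},
            "blocks": {key: block.get_vector().tolist()
                       for key, block in self.blocks.items()},
        }

    @classmethod
    def from_json(cls, data: dict) -> "HmmModel":
        forest = ParentalForest(
            [trees.parse_newick(s, trees.COALESCENT)
             for s in data["parental_trees"]],
            dict(data["allele_map"]),
            frozenset(data["introgressed_class_indices"]))
        gtr = sub.GtrParams(np.array(data["gtr"]["freqs"]),
                            np.array(data["gtr"]["exch"]))
        params = HmmParams(**data["hmm"])
        model = cls(forest, gtr, params, share=data["share"])
        for key, values in data["blocks"].items():
            if key not in model.blocks:
                raise ModelError(f"serialised block {key!r} does not match "
                                 "the model structure")
            model.blocks[key].set_vector(np.array(values))
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "HmmModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


# ----------------------------------------------------------------------
# decoding
# ----------------------------------------------------------------------

@dataclass
class DecodingResult:
    """Posterior decoding output; state indices include the start state at
    0, so ``posterior[:, j]`` corresponds to full state index ``j + 1``."""

    log_likelihood: float
    log_likelihood_backward: float
    posterior: np.ndarray          # (L, KM)
    viterbi_path: np.ndarray | None = None   # full state indices (>= 1)
    viterbi_log_probability: float | None = None


def _prepare(model: HmmModel, alignment: SiteAlignment):
    patterns, pat_idx = model.pattern_data(alignment)
    emis = model.emission_matrix(patterns)
    t = model.transition_matrix()
    return t[0, 1:].copy(), t[1:, 1:].copy(), emis, pat_idx


def _check_finite(ll: float, pat_idx, emis):
    if not np.isfinite(ll):
        dead = np.flatnonzero(emis[:, pat_idx].sum(axis=0) <= 0.0)
        col = int(dead[0]) if dead.size else -1
        raise ModelError(f"impossible observation: all-zero emission at "
                         f"column {col}")


def log_likelihood(model: HmmModel, alignment: SiteAlignment) -> float:
    pi, trans, emis, pat_idx = _prepare(model, alignment)
    ll = _kernels.forward_ll(pi, trans, emis, pat_idx)
    _check_finite(ll, pat_idx, emis)
    return float(ll)


def forward_backward(model: HmmModel, alignment: SiteAlignment
                     ) -> DecodingResult:
    pi, trans, emis, pat_idx = _prepare(model, alignment)
    alpha, scales, ll = _kernels.forward_pass(pi, trans, emis, pat_idx)
    _check_finite(ll, pat_idx, emis)
    beta = _kernels.backward_pass(trans, emis, pat_idx, scales)
    llb = _kernels.backward_ll(pi, trans, emis, pat_idx)
    posterior = alpha * beta
    posterior /= posterior.sum(axis=1, keepdims=True)
    return DecodingResult(float(ll), float(llb), posterior)


def viterbi(model: HmmModel, alignment: SiteAlignment) -> np.ndarray:
    """Most probable full-state path (values index ``model.states`` + 1)."""
    pi, trans, emis, pat_idx = _prepare(model, alignment)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_t = np.log(trans)
        log_e = np.log(emis)
    path, score = _kernels.viterbi_path(log_pi, log_t, log_e, pat_idx)
    if not np.isfinite(score):
        _check_finite(-np.inf, pat_idx, emis)
    return path + 1


def viterbi_with_score(model: HmmModel, alignment: SiteAlignment
                       ) -> tuple[np.ndarray, float]:
    pi, trans, emis, pat_idx = _prepare(model, alignment)
    with np.errstate(divide="ignore"):
        path, score = _kernels.viterbi_path(
            np.log(pi), np.log(trans), np.log(emis), pat_idx)
    return path + 1, float(score)


def introgression_posterior(decoding: DecodingResult,
                            model: HmmModel) -> np.ndarray:
    """Per-site probability of being in any introgressed-class state."""
    return decoding.posterior[:, model.introgressed_mask].sum(axis=1)


# ----------------------------------------------------------------------
# sampling (used by the parameter-recovery experiments)
# ----------------------------------------------------------------------

def sample(model: HmmModel, n_sites: int, rng: np.random.Generator
           ) -> tuple[np.ndarray, SiteAlignment]:
    """Draw a state path and an alignment from the model.

    Returns (full-state path, alignment with rows ordered as
    ``model.alleles``).
    """
    t = model.transition_matrix()
    pi, trans = t[0, 1:], t[1:, 1:]
    n = len(model.states)
    path = np.empty(n_sites, dtype=np.int64)
    path[0] = rng.choice(n, p=pi)
    for i in range(1, n_sites):
        path[i] = rng.choice(n, p=trans[path[i - 1]])

    codes = np.empty((len(model.alleles), n_sites), dtype=np.uint8)
    for key, block in model.blocks.items():
        sites = np.flatnonzero(
            np.array([model.states[s].block_key for s in path]) == key)
        if sites.size == 0:
            continue
        codes[:, sites] = _simulate_columns(block.tree, model.gtr,
                                            sites.size, model.alleles, rng)
    aln = SiteAlignment(list(model.alleles), codes)
    return path + 1, aln


def _simulate_columns(tree: RootedTree, gtr: sub.GtrParams, n: int,
                      leaf_order: list[str], rng) -> np.ndarray:
    base_codes = np.array([sub.CODE_OF[b] for b in sub.BASES],
                          dtype=np.uint8)
    out = np.empty((len(leaf_order), n), dtype=np.uint8)
    order = {lab: i for i, lab in enumerate(leaf_order)}

    def walk(node, states):
        if node.is_leaf():
            out[order[node.label]] = base_codes[states]
            return
        for child in node.children:
            p = gtr.transition_matrix(child.length)
            cum = p.cumsum(axis=1)
            u = rng.random(n)
            child_states = (u[:, None] > cum[states]).sum(axis=1)
            walk(child, child_states)

    root_states = rng.choice(4, size=n, p=gtr.freqs)
    walk(tree.root, root_states)
    return out
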
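"""End-to-end scan orchestration and the built-in validation experiments.

``scan`` is the user-facing pipeline: build a model for an alignment and a
parental forest, initialise it from the data (empirical base composition,
distance-based gene-tree branch lengths), fit the free parameters by
coordinate ascent, decode, and call regions.

The experiment functions reproduce the package's validation designs on
synthetic data: an isolation/migration grid compared against the
truth-track lower bound, GTR recovery on Jukes-Cantor data, and
transition-parameter recovery on data sampled from a known 7-state model.
Problem sizes (replicate counts, fitted parameter groups) are deliberately
desk-scale; see docs/methods.md.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import fit as fitmod, hmm, regions as regmod, simulate as simmod
from . import substitution as sub, trees
from .io import SiteAlignment
from .network import ParentalForest


# ----------------------------------------------------------------------
# data-driven initialisation
# ----------------------------------------------------------------------

def empirical_gtr(alignment: SiteAlignment,
                  floor: float = 1e-3) -> sub.GtrParams:
    """GTR initialised at the empirical base composition with all
    exchangeabilities 1 (a Jukes-Cantor-shaped starting point)."""
    counts = np.zeros(4)
    for b, code in enumerate(sub.encode(sub.BASES)):
        counts[b] = (alignment.codes == code).sum()
    counts = np.maximum(counts, floor * counts.sum() / 4 + 1.0)
    return sub.GtrParams(counts / counts.sum(), np.ones(6))


def jc_corrected_distances(alignment: SiteAlignment,
                           labels: list[str]) -> np.ndarray:
    """Pairwise Jukes-Cantor-corrected distances, ignoring ambiguous
    sites."""
    acgt = sub.encode(sub.BASES)
    idx = [alignment.labels.index(l) for l in labels]
    codes = alignment.codes[idx]
    plain = np.isin(codes, acgt)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = plain[i] & plain[j]
            p = float((codes[i][ok] != codes[j][ok]).mean()) if ok.any() \
                else 0.0
            p = min(p, 0.74)
            dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0
            d[i, j] = d[j, i] = dist
    return d


def initialize_blocks_from_distances(model: hmm.HmmModel,
                                     alignment: SiteAlignment,
                                     min_length: float = 1e-5) -> None:
    """Set each shared branch-length block from additive-distance
    estimates (three-point / four-point formulas); a crude but serviceable
    starting point for the coordinate ascent."""
    labels = model.alleles
    d = jc_corrected_distances(alignment, labels)
    pos = {lab: i for i, lab in enumerate(labels)}

    def dist(x, y):
        return d[pos[x], pos[y]]

    lo, hi = fitmod.BOUNDS["block"]

    for block in model.blocks.values():
        leaves = sorted({lab for e in block.edges for lab in e.tag})
        values = {}
        if len(leaves) == 2:
            x, y = leaves
            values[frozenset([x])] = dist(x, y)
            values[frozenset([y])] = dist(x, y) / 2.0
        elif len(leaves) == 3:
            for x in leaves:
                y, z = [l for l in leaves if l != x]
                values[frozenset([x])] = 0.5 * (dist(x, y) + dist(x, z)
                                                - dist(y, z))
        elif len(leaves) == 4:
            internal = next((e.tag for e in block.edges
                             if len(e.tag) == 2), None)
            if internal is None:
                pair = (leaves[0], leaves[1])
            else:
                pair = tuple(sorted(internal))
            z, w = pair
            x, y = [l for l in leaves if l not in pair]
            for u, v in ((x, y), (y, x), (z, w), (w, z)):
                far = [l for l in leaves if l not in (u, v)]
                values[frozenset([u])] = 0.5 * (
                    dist(u, v)
                    + 0.5 * (dist(u, far[0]) + dist(u, far[1]))
                    - 0.5 * (dist(v, far[0]) + dist(v, far[1])))
            cross = 0.25 * (dist(x, z) + dist(x, w) + dist(y, z)
                            + dist(y, w))
            values[frozenset(pair)] = (cross - 0.5 * dist(x, y)
                                       - 0.5 * dist(z, w))
        mean_d = d[np.triu_indices_from(d, 1)].mean() if d.size else 0.01
        for edge in block.edges:
            v = values.get(edge.tag, mean_d / 2.0)
            edge.length = float(min(max(v, min_length), hi))


def initialize_introgressed_blocks(model: hmm.HmmModel,
                                   alignment: SiteAlignment,
                                   recipient_species: str,
                                   nu: float | None = None) -> None:
    """Hypothesis-informed starting lengths for introgressed-class blocks.

    Uses the two parental divergence times carried by the forest (t_bg for
    the background class, t_intro for the introgressed class) and a clock
    rate ``nu`` (substitutions per site per coalescent unit of *path*
    length, estimated from mean cross-species distance / 2 t_bg).  Each
    mixed-topology block of an introgressed class is committed to one
    recipient allele playing the migrant: its edge is set short
    (nu * t_intro) together with its in-split donor partner, the other
    recipient allele long (2 nu t_bg), donor edges at nu.  This makes
    migrant segments of either phase prefer *some* introgressed-class
    state from the first iteration onward; only applies to the
    two-species, two-alleles-each configuration, otherwise the
    distance-based init is kept.
    """
    forest = model.forest
    if not forest.introgressed_class_indices:
        return
    background = min(set(range(forest.n_classes))
                     - set(forest.introgressed_class_indices))
    times_bg = forest.parental_trees[background].node_times()
    t_bg = times_bg[id(forest.parental_trees[background].root)]
    species_alleles: dict[str, list[str]] = {}
    for a, s in forest.allele_map.items():
        species_alleles.setdefault(s, []).append(a)
    if len(species_alleles) != 2 or recipient_species not in \
            species_alleles:
        return
    donor_species = next(s for s in species_alleles
                         if s != recipient_species)
    recip = sorted(species_alleles[recipient_species])
    donor = sorted(species_alleles[donor_species])
    if len(recip) != 2 or len(donor) != 2:
        return
    if nu is None:
        d = jc_corrected_distances(alignment, model.alleles)
        pos = {lab: i for i, lab in enumerate(model.alleles)}
        cross = [d[pos[r], pos[x]] for r in recip for x in donor]
        nu = max(float(np.mean(cross)) / (2.0 * t_bg), 1e-8)

    lo, hi = fitmod.BOUNDS["block"]

    def clamp(v):
        return float(min(max(v, lo), hi))

    for c in forest.introgressed_class_indices:
        tree_c = forest.parental_trees[c]
        t_intro = tree_c.node_times()[id(tree_c.root)]
        prefix = f"class{c}:"
        for key, block in model.blocks.items():
            if model.share == "unrooted_class" and \
                    not key.startswith(prefix):
                continue
            internal = next((e for e in block.edges
                             if len(e.tag) == 2), None)
            if internal is None:
                continue
            side = set(internal.tag)
            # migrant allele: recip[0] unless this split pairs recip[1]
            # with the first donor allele
            if {recip[1], donor[0]} in (side,
                                        set(model.alleles) - side):
                migrant = recip[1]
            else:
                migrant = recip[0]
            other_recip = recip[1] if migrant == recip[0] else recip[0]
            for e in block.edges:
                if len(e.tag) == 2:
                    e.length = clamp(nu * 0.3)
                elif next(iter(e.tag)) == migrant:
                    e.length = clamp(nu * max(t_intro, 1e-3))
                elif next(iter(e.tag)) == other_recip:
                    e.length = clamp(2.0 * nu * t_bg)
                else:  # donor allele
                    e.length = clamp(nu * 0.75)


def heuristic_model(alignment: SiteAlignment, forest: ParentalForest,
                    params: hmm.HmmParams | None = None,
                    share: str = "unrooted_class",
                    recipient_species: str | None = None
                    ) -> hmm.HmmModel:
    """Build a model initialised from the data (and, for introgressed
    classes, from the network hypothesis when the recipient species is
    named)."""
    params = params or hmm.HmmParams(0.05, 0.1, 0.1)
    model = hmm.HmmModel(forest, empirical_gtr(alignment), params,
                         share=share)
    initialize_blocks_from_distances(model, alignment)
    if recipient_species is not None:
        initialize_introgressed_blocks(model, alignment,
                                       recipient_species)
    return model


# ----------------------------------------------------------------------
# the scan pipeline
# ----------------------------------------------------------------------

@dataclass
class ScanResult:
    model: hmm.HmmModel
    fit_report: fitmod.FitReport
    decoding: hmm.DecodingResult
    viterbi_path: np.ndarray
    track: np.ndarray
    regions: list[regmod.IntrogressionRegion]
    summary: regmod.ScanSummary


DEFAULT_SCAN_FIT = fitmod.FitConfig(
    free_groups=("hmm", "gtr", "blocks"), restarts=1, max_rounds=3,
    brent_maxiter=12, tolerance=1e-3)


def scan(alignment: SiteAlignment, forest: ParentalForest,
         fit_config: fitmod.FitConfig | None = None,
         threshold: float = 0.9, min_sites: int = 2,
         merge_gap: int = 0, model: hmm.HmmModel | None = None,
         share: str = "unrooted_class",
         recipient_species: str | None = None) -> ScanResult:
    """Fit, decode and annotate one alignment.

    The parental trees (the network hypothesis) are treated as fixed
    unless ``fit_config.free_groups`` includes ``"parental"``: with
    identical class topologies the introgressed class is distinguished
    from the background class only through its divergence time, and
    letting it drift to the background value makes the class posterior
    uninformative.
    """
    if model is None:
        model = heuristic_model(alignment, forest, share=share,
                                recipient_species=recipient_species)
    config = fit_config or DEFAULT_SCAN_FIT
    fitted, report = fitmod.fit(model, alignment, config)
    decoding = hmm.forward_backward(fitted, alignment)
    path = hmm.viterbi(fitted, alignment)
    track = hmm.introgression_posterior(decoding, fitted)
    positions = alignment.positions
    regions = regmod.call_regions(track, positions=positions,
                                  threshold=threshold,
                                  min_sites=min_sites,
                                  merge_gap=merge_gap,
                                  chromosome=alignment.chrom)
    summary = regmod.summarize(fitted, decoding, regions,
                               viterbi_path=path, threshold=threshold)
    return ScanResult(fitted, report, decoding, path, track, regions,
                      summary)


# ----------------------------------------------------------------------
# validation experiments
# ----------------------------------------------------------------------

def simulation_forest(config: simmod.SimConfig) -> ParentalForest:
    """The two-parental-tree hypothesis matching the generator: class 0 is
    vertical descent (divergence at the A-B split), class 1 introgressive
    descent (divergence inside the migration window)."""
    t_bg = config.t_split_ab
    t_intro = max(0.5 * (config.t_mig_start + config.t_mig_end), 1e-2)
    ingroup = [lab for lab, sp in config.allele_map.items()
               if sp in ("A", "B")]
    background = trees.parse_newick(f"(A:{t_bg},B:{t_bg});",
                                    trees.COALESCENT)
    introgressed = trees.parse_newick(f"(A:{t_intro},B:{t_intro});",
                                      trees.COALESCENT)
    allele_map = {a: config.allele_map[a] for a in ingroup}
    return ParentalForest([background, introgressed], allele_map, {1})


def grid_fit(model: hmm.HmmModel, alignment: SiteAlignment
             ) -> tuple[hmm.HmmModel, fitmod.FitReport]:
    """The scaled-down two-phase fit used in the migration grid: one
    sweep over the introgressed-class branch-length blocks, then two
    sweeps over gamma/s1/s2 (log-scale Brent, so the class-switch
    probability can resolve to its often-tiny ML value)."""
    intro = model.forest.introgressed_class_indices
    keys = tuple(k for k in model.blocks
                 if any(k.startswith(f"class{c}:") for c in intro))
    phase1 = fitmod.FitConfig(
        free_groups=("blocks",), block_keys=keys or None, restarts=1,
        max_rounds=1, brent_maxiter=10, brent_xatol=1e-4,
        tolerance=1e-3)
    model, _ = fitmod.fit(model, alignment, phase1)
    phase2 = fitmod.FitConfig(
        free_groups=("hmm",), restarts=1, max_rounds=2,
        brent_maxiter=20, brent_xatol=0.01, tolerance=1e-3)
    return fitmod.fit(model, alignment, phase2)


@dataclass
class GridRow:
    migration_rate: float
    t_mig_end: float
    replicate: int
    inferred_percent: float
    bound_percent: float
    n_regions: int
    gamma_hat: float


def migration_experiment(seed: int = 0,
                         migration_rates=(0.0, 0.5, 2.0),
                         windows=((0.0, 0.25),),
                         n_replicates: int = 20,
                         length: int = 100_000,
                         threshold: float = 0.9) -> list[GridRow]:
    """The migration grid: per replicate, the inferred percentage of
    introgressed sites (posterior > threshold) and the truth-track lower
    bound."""
    rows: list[GridRow] = []
    for w_i, (t0, t1) in enumerate(windows):
        for m_i, m in enumerate(migration_rates):
            base_seed = seed + 10_000 * w_i + 1_000 * m_i
            config = simmod.SimConfig(
                migration_rate=m, t_mig_start=t0, t_mig_end=t1,
                length=length, seed=base_seed, replicates=n_replicates)
            forest = simulation_forest(config)
            for rep in range(n_replicates):
                replicate = simmod.simulate_replicate(
                    config, seed=base_seed + rep)
                aln = replicate.alignment.subset(
                    sorted(forest.allele_map))
                model = heuristic_model(
                    aln, forest,
                    params=hmm.HmmParams(0.01, 0.01, 0.05),
                    recipient_species="A")
                fitted, _report = grid_fit(model, aln)
                decoding = hmm.forward_backward(fitted, aln)
                track = hmm.introgression_posterior(decoding, fitted)
                regions = regmod.call_regions(track,
                                              threshold=threshold)
                inferred = 100.0 * float((track > threshold).mean())
                rows.append(GridRow(
                    migration_rate=m, t_mig_end=t1, replicate=rep,
                    inferred_percent=inferred,
                    bound_percent=100.0 * replicate.truth_fraction,
                    n_regions=len(regions),
                    gamma_hat=fitted.params.gamma))
    return rows


GTR_FIT = fitmod.FitConfig(
    free_groups=("hmm", "gtr", "blocks"), restarts=1, max_rounds=2,
    brent_maxiter=10, tolerance=1e-3)


def gtr_recovery_experiment(seed: int = 0, n_replicates: int = 5,
                            length: int = 100_000,
                            migration_rate: float = 0.5
                            ) -> np.ndarray:
    """Fit the full model (including GTR frequencies) to Jukes-Cantor
    replicates; returns the (n_replicates, 4) fitted stationary
    frequencies."""
    config = simmod.SimConfig(migration_rate=migration_rate,
                              length=length, seed=seed,
                              replicates=n_replicates)
    forest = simulation_forest(config)
    freqs = []
    for rep in range(n_replicates):
        replicate = simmod.simulate_replicate(config, seed=seed + rep)
        aln = replicate.alignment.subset(sorted(forest.allele_map))
        result = scan(aln, forest, fit_config=GTR_FIT,
                      recipient_species="A")
        freqs.append(result.model.gtr.freqs.copy())
    return np.array(freqs)


# -- 7-state transition-parameter recovery -----------------------------

def seven_state_model(gamma: float = 0.05, s1: float = 0.1,
                      s2: float = 0.3,
                      internal_branch: float = 1.0,
                      leaf_sub: float = 0.05,
                      internal_sub: float = 0.15,
                      far_sub: float = 0.20) -> hmm.HmmModel:
    """The three-species simple-case model with per-rooted-topology branch
    lengths (cherry leaves short, the far leaf long), so that genealogy
    states are emission-distinguishable."""
    am = {"a": "A", "b": "B", "c": "C"}
    t = internal_branch
    forest = ParentalForest(
        [trees.parse_newick(f"((A:1,B:1):{t},C:{1 + t});",
                            trees.COALESCENT),
         trees.parse_newick(f"((B:1,C:1):{t},A:{1 + t});",
                            trees.COALESCENT)],
        am, {1})
    model = hmm.HmmModel(forest, sub.GtrParams.jukes_cantor(),
                         hmm.HmmParams(gamma, s1, s2), share="rooted")
    for block in model.blocks.values():
        internal = next(e for e in block.edges if len(e.tag) > 1)
        for e in block.edges:
            if len(e.tag) > 1:
                e.length = internal_sub
            elif e.tag <= internal.tag:
                e.length = leaf_sub
            else:
                e.length = far_sub
    return model


@dataclass
class RecoveryRow:
    replicate: int
    gamma_hat: float
    s1_hat: float
    s2_hat: float
    restart_spread: float   # max |ll_r - ll_best| across restarts


def transition_recovery_experiment(seed: int = 0,
                                   n_replicates: int = 20,
                                   length: int = 10_000,
                                   gamma: float = 0.05,
                                   s1: float = 0.1,
                                   s2: float = 0.3,
                                   restarts: int = 3
                                   ) -> list[RecoveryRow]:
    """Sample alignments from a known 7-state model and re-fit gamma, s1
    and s2 (structural parameters held at truth)."""
    truth = seven_state_model(gamma=gamma, s1=s1, s2=s2)
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        _path, aln = hmm.sample(truth, length, rng)
        start = truth.copy()
        config = fitmod.FitConfig(free_groups=("hmm",),
                                  restarts=restarts, seed=seed + rep,
                                  max_rounds=50, tolerance=1e-6)
        fitted, report = fitmod.fit(start, aln, config)
        best = max(report.restart_logliks)
        spread = max(best - ll for ll in report.restart_logliks)
        rows.append(RecoveryRow(
            replicate=rep, gamma_hat=fitted.params.gamma,
            s1_hat=fitted.params.s1, s2_hat=fitted.params.s2,
            restart_spread=spread))
    return rows
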
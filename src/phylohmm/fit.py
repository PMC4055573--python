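"""Maximum-likelihood training by coordinate ascent with Brent's method.

Every free parameter is exposed as a bounded scalar: the HMM transition
parameters gamma/s1/s2, five free GTR exchangeabilities (GT is the
reference), three stick-breaking coordinates for the stationary
frequencies, parental-tree branch lengths (coalescent units; one block per
class, restricted to edges that can influence the coalescent topology
probabilities), and gene-tree branch lengths (substitution units; one
shared block per topologically distinct genealogy).  Each round sweeps the
scalars in a fixed order and optimises each on its profile log-likelihood
with Brent's bounded univariate method; the coalescent topology tables and
the transition matrix are functions of other parameters and are recomputed,
never optimised directly.

Caching: moving a transition or parental scalar leaves the emission matrix
untouched; moving a gene-tree branch length recomputes only its block's
pattern likelihoods; moving a GTR scalar recomputes all blocks.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import _kernels, substitution as sub, trees
from .hmm import HmmModel, ModelError
from .io import SiteAlignment

logger = logging.getLogger("phylohmm")

BOUNDS = {
    "hmm": (1e-6, 1.0 - 1e-6),
    "gtr_stick": (1e-6, 1.0 - 1e-6),
    "gtr_exch": (1e-3, 100.0),
    "block": (1e-6, 10.0),
    "parental": (1e-3, 20.0),
}

GROUP_ORDER = ("hmm", "gtr", "parental", "blocks")


@dataclass
class ScalarSpec:
    """One bounded free scalar of the model.

    ``log10`` scalars are optimised on a log scale (used for the HMM
    switching probabilities, whose maximum-likelihood values can sit many
    orders of magnitude below 1); bounds are stored on the natural scale.
    """

    group: str        # hmm | gtr | parental | blocks
    kind: str         # hmm | gtr_stick | gtr_exch | parental | block
    name: str
    index: tuple      # addressing within its structure
    bounds: tuple[float, float]
    log10: bool = False

    @property
    def opt_bounds(self) -> tuple[float, float]:
        if self.log10:
            return (math.log10(self.bounds[0]),
                    math.log10(self.bounds[1]))
        return self.bounds

    def to_opt(self, v: float) -> float:
        return math.log10(v) if self.log10 else v

    def from_opt(self, v: float) -> float:
        return 10.0 ** v if self.log10 else v


@dataclass
class FitConfig:
    tolerance: float = 1e-6
    max_rounds: int = 100
    restarts: int = 3
    seed: int = 0
    free_groups: tuple[str, ...] = GROUP_ORDER
    block_keys: tuple[str, ...] | None = None  # restrict "blocks" group
    brent_maxiter: int = 40
    brent_xatol: float = 1e-6


@dataclass
class FitReport:
    log_likelihood: float
    rounds: int
    trace: list[float]
    converged: bool
    flat: bool
    restart_logliks: list[float]
    config: FitConfig
    n_evaluations: int = 0


# ----------------------------------------------------------------------
# parameter packing
# ----------------------------------------------------------------------

def _freqs_to_sticks(freqs: np.ndarray) -> np.ndarray:
    v0 = freqs[0]
    v1 = freqs[1] / (1 - freqs[0])
    v2 = freqs[2] / (1 - freqs[0] - freqs[1])
    return np.array([v0, v1, v2])


def _sticks_to_freqs(sticks: np.ndarray) -> np.ndarray:
    v0, v1, v2 = sticks
    fa = v0
    fc = (1 - v0) * v1
    fg = (1 - v0 - fc) * v2
    ft = 1 - fa - fc - fg
    return np.array([fa, fc, fg, ft])


def _parental_free_edges(model: HmmModel, class_index: int):
    """Edges of a parental tree whose lengths can affect the topology
    probabilities: internal edges, plus leaf edges of species with at
    least two sampled alleles."""
    tree = model.forest.parental_trees[class_index]
    trees.tag_clades(tree)
    counts: dict[str, int] = {}
    for sp in model.forest.allele_map.values():
        counts[sp] = counts.get(sp, 0) + 1
    edges = []
    for node in trees.ordered_edges(tree):
        if node.is_leaf():
            if counts.get(node.label, 0) >= 2:
                edges.append(node)
        else:
            edges.append(node)
    return edges


def parameter_specs(model: HmmModel, free_groups=GROUP_ORDER,
                    block_keys=None) -> list[ScalarSpec]:
    specs: list[ScalarSpec] = []
    if "hmm" in free_groups:
        for name in ("gamma", "s1", "s2"):
            if name == "gamma" and model.n_classes == 1:
                continue
            specs.append(ScalarSpec("hmm", "hmm", name, (name,),
                                    BOUNDS["hmm"], log10=True))
    if "gtr" in free_groups:
        for i in range(3):
            specs.append(ScalarSpec("gtr", "gtr_stick", f"freq_stick{i}",
                                    (i,), BOUNDS["gtr_stick"]))
        for i, pair in enumerate(("AC", "AG", "AT", "CG", "CT")):
            specs.append(ScalarSpec("gtr", "gtr_exch", f"exch_{pair}",
                                    (i,), BOUNDS["gtr_exch"]))
    if "parental" in free_groups:
        for c in range(model.n_classes):
            for k, _edge in enumerate(_parental_free_edges(model, c)):
                specs.append(ScalarSpec("parental", "parental",
                                        f"parental{c}_edge{k}", (c, k),
                                        BOUNDS["parental"]))
    if "blocks" in free_groups:
        keys = sorted(model.blocks) if block_keys is None else \
            [k for k in sorted(model.blocks) if k in block_keys]
        for key in keys:
            for k in range(model.blocks[key].n_edges):
                specs.append(ScalarSpec("blocks", "block",
                                        f"block[{key}]_edge{k}", (key, k),
                                        BOUNDS["block"]))
    return specs


def pack_parameters(model: HmmModel,
                    free_groups=GROUP_ORDER
                    ) -> tuple[np.ndarray, list[ScalarSpec]]:
    specs = parameter_specs(model, free_groups)
    values = np.array([_get_scalar(model, s) for s in specs])
    return values, specs


def unpack_parameters(values: np.ndarray, specs: list[ScalarSpec],
                      model: HmmModel) -> HmmModel:
    """Write scalars back into the model (clamping to bounds with a
    warning) and invalidate derived tables."""
    for v, spec in zip(values, specs):
        lo, hi = spec.bounds
        if not lo <= v <= hi:
            logger.warning("clamping %s=%g to [%g, %g]", spec.name, v,
                           lo, hi)
            v = min(max(v, lo), hi)
        _set_scalar(model, spec, v)
    model.invalidate_tables()
    model.gtr._eig = None
    return model


def _get_scalar(model: HmmModel, spec: ScalarSpec) -> float:
    if spec.kind == "hmm":
        return getattr(model.params, spec.index[0])
    if spec.kind == "gtr_stick":
        return _freqs_to_sticks(model.gtr.freqs)[spec.index[0]]
    if spec.kind == "gtr_exch":
        return model.gtr.exch[spec.index[0]] / model.gtr.exch[5]
    if spec.kind == "parental":
        c, k = spec.index
        return _parental_free_edges(model, c)[k].length
    if spec.kind == "block":
        key, k = spec.index
        return model.blocks[key].edges[k].length
    raise AssertionError(spec.kind)


def _set_scalar(model: HmmModel, spec: ScalarSpec, value: float) -> None:
    if spec.kind == "hmm":
        setattr(model.params, spec.index[0], float(value))
    elif spec.kind == "gtr_stick":
        sticks = _freqs_to_sticks(model.gtr.freqs)
        sticks[spec.index[0]] = value
        model.gtr.freqs = _sticks_to_freqs(sticks)
        model.gtr._eig = None
    elif spec.kind == "gtr_exch":
        model.gtr.exch = model.gtr.exch.copy()
        model.gtr.exch[spec.index[0]] = value * model.gtr.exch[5]
        model.gtr._eig = None
    elif spec.kind == "parental":
        c, k = spec.index
        _parental_free_edges(model, c)[k].length = float(value)
        model.invalidate_tables()
    elif spec.kind == "block":
        key, k = spec.index
        model.blocks[key].edges[k].length = float(value)
    else:
        raise AssertionError(spec.kind)


# ----------------------------------------------------------------------
# cached likelihood workspace
# ----------------------------------------------------------------------

class Workspace:
    """Model + alignment with incremental emission/transition caches."""

    def __init__(self, model: HmmModel, alignment: SiteAlignment):
        self.model = model
        self.patterns, self.pat_idx = model.pattern_data(alignment)
        self.block_ll = model.block_log_likelihoods(self.patterns)
        self._emis = model.emission_matrix(self.patterns, self.block_ll)
        self._trans = model.transition_matrix()
        self.n_evaluations = 0

    # -- cache refreshes ----------------------------------------------
    def _refresh_block(self, key: str) -> None:
        block = self.model.blocks[key]
        self.block_ll[key] = sub.column_log_likelihoods(
            block.tree, self.model.gtr, self.patterns, self.model.alleles)
        ll = np.exp(self.block_ll[key])
        for i, state in enumerate(self.model.states):
            if state.block_key == key:
                self._emis[i] = ll

    def _refresh_all_blocks(self) -> None:
        for key in self.model.blocks:
            self._refresh_block(key)

    def _refresh_transition(self) -> None:
        self._trans = self.model.transition_matrix()

    def apply(self, spec: ScalarSpec, value: float) -> None:
        _set_scalar(self.model, spec, value)
        if spec.kind == "hmm":
            self._refresh_transition()
        elif spec.kind in ("gtr_stick", "gtr_exch"):
            self._refresh_all_blocks()
        elif spec.kind == "parental":
            self._refresh_transition()
        elif spec.kind == "block":
            self._refresh_block(spec.index[0])

    def log_likelihood(self) -> float:
        self.n_evaluations += 1
        return float(_kernels.forward_ll(
            self._trans[0, 1:].copy(), self._trans[1:, 1:], self._emis,
            self.pat_idx))


def profile_objective(workspace: Workspace, spec: ScalarSpec,
                      value: float) -> float:
    """Profile log-likelihood of one scalar, other parameters fixed."""
    workspace.apply(spec, value)
    return workspace.log_likelihood()


# ----------------------------------------------------------------------
# the fit itself
# ----------------------------------------------------------------------

def fit(model: HmmModel, alignment: SiteAlignment,
        config: FitConfig | None = None) -> tuple[HmmModel, FitReport]:
    """Coordinate-ascent ML fit; returns (best model copy, report).

    Restart 0 starts from the supplied model; further restarts draw the
    free scalars uniformly from their bounds with seeds derived from
    ``config.seed``.  The best final likelihood wins.
    """
    config = config or FitConfig()
    specs = parameter_specs(model, config.free_groups,
                            config.block_keys)
    if not specs:
        raise ModelError("no free parameters selected")
    rng = np.random.default_rng(config.seed)

    best: tuple[float, HmmModel, FitReport] | None = None
    restart_lls: list[float] = []
    for restart in range(max(1, config.restarts)):
        work_model = model.copy()
        if restart > 0:
            draw = np.array([s.from_opt(rng.uniform(*s.opt_bounds))
                             for s in specs])
            unpack_parameters(draw, specs, work_model)
        result = _ascend(work_model, alignment, specs, config)
        if result is None:
            continue
        ll, fitted, report = result
        restart_lls.append(ll)
        if best is None or ll > best[0]:
            best = (ll, fitted, report)

    if best is None:
        raise ModelError("no restart produced a finite log-likelihood")
    ll, fitted, report = best
    report.restart_logliks = restart_lls
    return fitted, report


def _ascend(model: HmmModel, alignment: SiteAlignment,
            specs: list[ScalarSpec], config: FitConfig):
    ws = Workspace(model, alignment)
    cur = ws.log_likelihood()
    if not np.isfinite(cur):
        return None
    trace = [cur]
    converged = False
    flat = False
    rounds = 0
    for rounds in range(1, config.max_rounds + 1):
        round_start = cur
        moved = 0
        for spec in specs:
            cur_value = _get_scalar(model, spec)

            def objective(v, spec=spec):
                return -profile_objective(ws, spec, spec.from_opt(v))

            res = minimize_scalar(
                objective, bounds=spec.opt_bounds, method="bounded",
                options={"xatol": config.brent_xatol,
                         "maxiter": config.brent_maxiter})
            cand_value, cand_ll = spec.from_opt(float(res.x)), \
                -float(res.fun)
            if cand_ll > cur + 1e-10:
                ws.apply(spec, cand_value)
                cur = cand_ll
                moved += 1
            else:
                ws.apply(spec, cur_value)
        trace.append(cur)
        if moved == 0 and cur - round_start < 1e-9 and rounds == 1:
            # nothing improved on the very first sweep: check flatness
            flat = _looks_flat(ws, specs, cur)
        if cur - round_start < config.tolerance:
            converged = True
            break
    report = FitReport(
        log_likelihood=cur, rounds=rounds, trace=trace,
        converged=converged, flat=flat, restart_logliks=[],
        config=config, n_evaluations=ws.n_evaluations)
    if flat:
        logger.warning("all parameter profiles are flat; the data carry "
                       "no information about the free parameters")
    return cur, model, report


def _looks_flat(ws: Workspace, specs: list[ScalarSpec],
                cur: float) -> bool:
    """True if every free scalar's profile is constant (e.g. an all-missing
    alignment)."""
    for spec in specs:
        cur_value = _get_scalar(ws.model, spec)
        lo, hi = spec.bounds
        lls = []
        for v in (lo, 0.5 * (lo + hi), hi):
            lls.append(profile_objective(ws, spec, v))
        ws.apply(spec, cur_value)
        if max(lls) - min(lls) > 1e-9 or abs(max(lls) - cur) > 1e-9:
            return False
    return True
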
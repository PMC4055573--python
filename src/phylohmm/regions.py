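"""Turning decodings into genome annotations and summary statistics.

Regions are maximal runs of sites whose introgression posterior exceeds a
threshold; runs separated by at most ``merge_gap`` sites are merged and
runs spanning fewer than ``min_sites`` sites are dropped.  When genomic
coordinates accompany the sites (SNP-array style) regions are reported in
genomic bp from the first to the last qualifying site, 0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm import DecodingResult, HmmModel, introgression_posterior


@dataclass
class IntrogressionRegion:
    start: int                 # 0-based half-open, genomic if available
    end: int
    site_start: int            # site-index span (always available)
    site_end: int
    mean_posterior: float
    min_posterior: float
    site_count: int
    chromosome: str | None = None
    state_class: int | None = None


@dataclass
class ScanSummary:
    percent_sites_posterior: float
    percent_sites_viterbi: float | None
    gamma_readback: float
    per_topology_posterior: dict[str, float]
    n_regions: int
    threshold: float

    def to_text(self) -> str:
        lines = [
            f"percent sites introgressed (posterior rule): "
            f"{self.percent_sites_posterior:.4f}",
            f"percent sites introgressed (viterbi rule): "
            + (f"{self.percent_sites_viterbi:.4f}"
               if self.percent_sites_viterbi is not None else "n/a"),
            f"gamma read-back from transition matrix: "
            f"{self.gamma_readback:.6g}",
            f"regions called (posterior > {self.threshold}): "
            f"{self.n_regions}",
            "posterior mass per gene-tree topology:",
        ]
        for key, mass in sorted(self.per_topology_posterior.items(),
                                key=lambda kv: -kv[1]):
            lines.append(f"  {key}\t{mass:.4f}")
        return "\n".join(lines) + "\n"


def call_regions(track: np.ndarray,
                 positions: np.ndarray | None = None,
                 threshold: float = 0.9,
                 min_sites: int = 2,
                 merge_gap: int = 0,
                 chromosome: str | None = None
                 ) -> list[IntrogressionRegion]:
    """Deterministic run-length region calling on a posterior track."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    track = np.asarray(track, dtype=float)
    if positions is not None and len(positions) != len(track):
        raise ValueError("positions length must match the track")
    above = track > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(
        [[0], above.view(np.int8), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))  # site-index half-open runs

    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    out = []
    for a, b in merged:
        if b - a < min_sites:
            continue
        if positions is not None:
            start, end = int(positions[a]), int(positions[b - 1]) + 1
        else:
            start, end = int(a), int(b)
        window = track[a:b]
        out.append(IntrogressionRegion(
            start=start, end=end, site_start=int(a), site_end=int(b),
            mean_posterior=float(window.mean()),
            min_posterior=float(window.min()),
            site_count=int(b - a), chromosome=chromosome))
    return out


def gamma_readback(model: HmmModel) -> float:
    """Average, over non-introgressed states, of the summed transition
    probability into introgressed-class states.  Under this package's
    transition parameterisation the value equals the model's gamma
    exactly; computing it from the matrix mirrors how it would be read off
    a fitted model."""
    t = model.transition_matrix()
    intro = model.introgressed_mask
    if not intro.any() or intro.all():
        return 0.0
    rows = t[1:, 1:][~intro][:, intro]
    return float(rows.sum(axis=1).mean())


def summarize(model: HmmModel, decoding: DecodingResult,
              regions: list[IntrogressionRegion],
              viterbi_path: np.ndarray | None = None,
              threshold: float = 0.9) -> ScanSummary:
    track = introgression_posterior(decoding, model)
    pct_post = 100.0 * float((track > threshold).mean())
    pct_vit = None
    if viterbi_path is not None:
        intro = model.introgressed_mask
        pct_vit = 100.0 * float(intro[viterbi_path - 1].mean())
    per_topology: dict[str, float] = {}
    for i, state in enumerate(model.states):
        key = state.key
        per_topology[key] = per_topology.get(key, 0.0) + float(
            decoding.posterior[:, i].mean())
    return ScanSummary(
        percent_sites_posterior=pct_post,
        percent_sites_viterbi=pct_vit,
        gamma_readback=gamma_readback(model),
        per_topology_posterior=per_topology,
        n_regions=len(regions),
        threshold=threshold)


def missing_data_mask(alignment_codes: np.ndarray,
                      n_code: int) -> np.ndarray:
    """Sites where every row is missing; reported separately, never
    interpolated."""
    return (alignment_codes == n_code).all(axis=0)
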
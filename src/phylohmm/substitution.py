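"""GTR substitution model and pruning likelihoods for alignment columns.

The general time-reversible model is parameterised by stationary base
frequencies pi (A,C,G,T) and six exchangeabilities (AC,AG,AT,CG,CT,GT; GT
serves as the reference and is fixed to 1 during fitting).  The rate matrix
is normalised to one expected substitution per site per unit branch length,
so gene-tree branch lengths are identifiable as expected substitutions per
site.

Column likelihoods are computed with the pruning algorithm, vectorised over
the distinct site patterns of an alignment.  IUPAC ambiguity codes and gaps
are marginalised: an ambiguous leaf contributes partial likelihood 1 for
every compatible base, so an all-missing column has likelihood exactly 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import Node, RootedTree

BASES = "ACGT"
PAIR_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

# IUPAC nucleotide codes -> compatibility masks over (A, C, G, T)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}
CODE_OF = {sym: i for i, sym in enumerate(IUPAC)}
N_CODE = CODE_OF["N"]
MASKS = np.zeros((len(IUPAC), 4))
for sym, bases in IUPAC.items():
    for b in bases:
        MASKS[CODE_OF[sym], BASES.index(b)] = 1.0


class AlphabetError(ValueError):
    """A symbol outside the IUPAC nucleotide alphabet."""


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes; raises on non-IUPAC."""
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        try:
            out[i] = CODE_OF[ch]
        except KeyError:
            raise AlphabetError(
                f"non-IUPAC symbol {ch!r} at position {i}") from None
    return out


def decode(codes: np.ndarray) -> str:
    symbols = list(IUPAC)
    return "".join(symbols[c] for c in codes)


@dataclass
class GtrParams:
    """Stationary frequencies + exchangeabilities, with mean rate 1."""

    freqs: np.ndarray
    exch: np.ndarray
    normalize: bool = True

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.exch = np.asarray(self.exch, dtype=float)
        if self.freqs.shape != (4,) or self.exch.shape != (6,):
            raise ValueError("freqs must have shape (4,), exch (6,)")
        if np.any(self.freqs <= 0) or abs(self.freqs.sum() - 1) > 1e-12:
            raise ValueError("frequencies must be positive and sum to 1")
        if np.any(self.exch <= 0):
            raise ValueError("exchangeabilities must be positive")
        self._eig = None

    @classmethod
    def jukes_cantor(cls) -> "GtrParams":
        return cls(np.full(4, 0.25), np.ones(6))

    def rate_matrix(self) -> np.ndarray:
        q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.exch, _PAIRS):
            q[i, j] = rate * self.freqs[j]
            q[j, i] = rate * self.freqs[i]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        if self.normalize:
            mean_rate = -(self.freqs * np.diag(q)).sum()
            q /= mean_rate
        return q

    def _eigensystem(self):
        if self._eig is None:
            q = self.rate_matrix()
            sqrt_pi = np.sqrt(self.freqs)
            sym = q * sqrt_pi[:, None] / sqrt_pi[None, :]
            lam, u = np.linalg.eigh((sym + sym.T) / 2)
            left = u.T * sqrt_pi[None, :]
            right = u / sqrt_pi[:, None]
            self._eig = (lam, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), computed from the symmetric eigensystem."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        lam, right, left = self._eigensystem()
        p = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def copy(self) -> "GtrParams":
        return GtrParams(self.freqs.copy(), self.exch.copy(), self.normalize)


def column_log_likelihoods(tree: RootedTree, gtr: GtrParams,
                           patterns: np.ndarray,
                           leaf_order: list[str]) -> np.ndarray:
    """log-likelihood of each site pattern on ``tree`` under ``gtr``.

    ``patterns`` has shape (n_patterns, n_leaves) of IUPAC codes, columns
    ordered as ``leaf_order``.  Branch lengths are expected substitutions
    per site; the root may be multifurcating (unrooted-form trees).
    """
    patterns = np.asarray(patterns)
    col_of = {label: k for k, label in enumerate(leaf_order)}

    def partial(node: Node) -> np.ndarray:
        if node.is_leaf():
            try:
                k = col_of[node.label]
            except KeyError:
                raise ValueError(f"leaf {node.label!r} missing from the "
                                 "alignment rows") from None
            return MASKS[patterns[:, k]]
        out = None
        for child in node.children:
            p_child = partial(child) @ gtr.transition_matrix(child.length).T
            out = p_child if out is None else out * p_child
        return out

    like = partial(tree.root) @ gtr.freqs
    with np.errstate(divide="ignore"):
        return np.log(like)
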
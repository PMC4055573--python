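"""Alignment container and readers/writers for the formats the tool touches.

Alignments are stored column-major-friendly as a (rows x sites) matrix of
IUPAC codes (:class:`SiteAlignment`).  Supported inputs: FASTA and relaxed
PHYLIP (via Biopython) and a phased-haplotype TSV dialect with per-site
genomic coordinates (header ``chrom  pos  <hap1> <hap2> ...``, positions
1-based), emulating SNP-array haplotype tables.  Outputs are plain text:
FASTA, TSV tracks, BED (0-based half-open) and JSON model files.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from . import substitution as sub

logger = logging.getLogger("phylohmm")


class AlignmentError(ValueError):
    pass


@dataclass
class SiteAlignment:
    """One haploid sequence per row; columns are sites.

    ``positions`` (0-based genomic coordinates, strictly increasing) and
    ``chrom`` are optional and carried through to region reports.
    """

    labels: list[str]
    codes: np.ndarray  # (n_rows, n_sites) uint8 IUPAC codes
    chrom: str | None = None
    positions: np.ndarray | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.labels):
            raise AlignmentError("codes must be (n_rows, n_sites) with one "
                                 "row per label")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != (self.codes.shape[1],):
                raise AlignmentError("positions length must match the "
                                     "number of sites")
            if np.any(np.diff(self.positions) <= 0):
                raise AlignmentError("positions must be strictly "
                                     "increasing")

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, items: list[tuple[str, str]],
                       chrom=None, positions=None) -> "SiteAlignment":
        labels, rows = [], []
        length = None
        for label, seq in items:
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"row {label!r} has length {len(seq)}, expected "
                    f"{length}")
            labels.append(label)
            rows.append(_encode_lenient(seq, label))
        return cls(labels, np.vstack(rows), chrom=chrom,
                   positions=positions)

    def sequences(self) -> list[tuple[str, str]]:
        return [(lab, sub.decode(row))
                for lab, row in zip(self.labels, self.codes)]

    def subset(self, labels: list[str]) -> "SiteAlignment":
        idx = [self.labels.index(l) for l in labels]
        return SiteAlignment(list(labels), self.codes[idx],
                             chrom=self.chrom, positions=self.positions)


def _encode_lenient(seq: str, label: str) -> np.ndarray:
    """Encode, coercing unknown symbols to N with a logged count."""
    seq = seq.upper()
    unknown = sum(ch not in sub.CODE_OF for ch in seq)
    if unknown:
        logger.warning("row %s: %d unknown symbols coded as N",
                       label, unknown)
        seq = "".join(ch if ch in sub.CODE_OF else "N" for ch in seq)
    return sub.encode(seq)


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------

def read_alignment(path, format: str = "fasta") -> SiteAlignment:
    """Read ``fasta``, ``phylip`` or ``haplotype-tsv`` into a
    :class:`SiteAlignment`."""
    path = Path(path)
    if format == "fasta":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
        if not records:
            raise AlignmentError(f"no sequences found in {path}")
        return SiteAlignment.from_sequences(records)
    if format == "phylip":
        aln = AlignIO.read(path, "phylip-relaxed")
        return SiteAlignment.from_sequences(
            [(r.id, str(r.seq)) for r in aln])
    if format == "haplotype-tsv":
        return read_haplotype_tsv(path)
    raise ValueError(f"unknown alignment format {format!r}")


def read_haplotype_tsv(path) -> SiteAlignment:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[:2] != ["chrom", "pos"]:
        raise AlignmentError(
            "haplotype TSV must start with columns 'chrom' and 'pos'")
    hap_cols = cols[2:]
    if not hap_cols:
        raise AlignmentError("haplotype TSV has no haplotype columns")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise AlignmentError("haplotype TSV must cover a single chromosome")
    positions = df["pos"].astype(np.int64).to_numpy() - 1  # 1-based input
    rows = []
    for col in hap_cols:
        seq = "".join(df[col].to_numpy())
        rows.append(_encode_lenient(seq, col))
    return SiteAlignment(hap_cols, np.vstack(rows), chrom=str(chroms[0]),
                         positions=positions)


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------

def write_fasta(alignment: SiteAlignment, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for label, seq in alignment.sequences():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_haplotype_tsv(alignment: SiteAlignment, path) -> None:
    positions = alignment.positions
    if positions is None:
        positions = np.arange(alignment.n_sites, dtype=np.int64)
    chrom = alignment.chrom or "chr"
    seqs = dict(alignment.sequences())
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(alignment.labels) + "\n")
        for j in range(alignment.n_sites):
            bases = "\t".join(seqs[l][j] for l in alignment.labels)
            fh.write(f"{chrom}\t{positions[j] + 1}\t{bases}\n")


def write_bed(intervals, path, chrom="region") -> None:
    """Write (start, end[, name]) intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in intervals:
            start, end = row[0], row[1]
            name = row[2] if len(row) > 2 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
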
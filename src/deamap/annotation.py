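"""Gene models decomposed into stranded interval features.

All coordinates are 0-based half-open on the genomic forward strand.
Each gene carries one or more isoforms (ordered exon blocks); the first
isoform of a gene is its *primary* isoform and defines the gene-level
decomposition into 5'UTR / exon / intron / 3'UTR intervals used for
background-rate classes, window construction and cluster shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: feature kinds, in the order they appear along a + strand transcript
FEATURE_KINDS = ("five_utr", "exon", "intron", "three_utr")

#: kinds treated as exonic when assigning a shuffling host feature
EXONIC_KINDS = ("five_utr", "exon", "three_utr")


@dataclass
class FeatureAnnotation:
    """Transcript models plus their interval decomposition.

    Attributes
    ----------
    genes : DataFrame with columns gene_id, chrom, start0, end0, strand.
    isoforms : DataFrame with columns isoform_id, gene_id, chrom, strand,
        exon_starts, exon_ends (comma-joined int strings, sorted ascending;
        exon blocks include UTR sequence).
    features : DataFrame with columns chrom, start0, end0, strand, gene_id,
        kind (one of FEATURE_KINDS); the decomposition of every gene's
        primary isoform. Features of one gene are disjoint and cover the
        gene span.
    """

    genes: pd.DataFrame
    isoforms: pd.DataFrame
    features: pd.DataFrame
    _iso_cache: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------
    def gene_strand(self, gene_id: str) -> str:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(f"unknown gene {gene_id!r}")
        return row["strand"].iloc[0]

    def isoform_blocks(self, isoform_id: str) -> np.ndarray:
        """Exon blocks of an isoform as an (n, 2) array of [start, end)."""
        if isoform_id not in self._iso_cache:
            row = self.isoforms.loc[self.isoforms["isoform_id"] == isoform_id]
            if row.empty:
                raise KeyError(f"unknown isoform {isoform_id!r}")
            starts = np.array([int(x) for x in row["exon_starts"].iloc[0].split(",")])
            ends = np.array([int(x) for x in row["exon_ends"].iloc[0].split(",")])
            self._iso_cache[isoform_id] = np.column_stack([starts, ends])
        return self._iso_cache[isoform_id]

    def isoform_strand(self, isoform_id: str) -> str:
        row = self.isoforms.loc[self.isoforms["isoform_id"] == isoform_id]
        if row.empty:
            raise KeyError(f"unknown isoform {isoform_id!r}")
        return row["strand"].iloc[0]

    # ------------------------------------------------------------------
    def feature_at(self, chrom: str, pos: int, strand: str) -> pd.Series | None:
        """The primary-isoform feature containing ``pos`` (or None)."""
        f = self.features
        m = (
            (f["chrom"] == chrom)
            & (f["strand"] == strand)
            & (f["start0"] <= pos)
            & (pos < f["end0"])
        )
        hit = f.loc[m]
        if hit.empty:
            return None
        return hit.iloc[0]

    def sorted_features(self) -> pd.DataFrame:
        return self.features.sort_values(
            ["chrom", "start0", "end0", "kind"], kind="mergesort"
        ).reset_index(drop=True)

    def equivalent(self, other: "FeatureAnnotation") -> bool:
        """Same interval sets (used by round-trip tests)."""
        a = self.sorted_features()[["chrom", "start0", "end0", "strand", "gene_id", "kind"]]
        b = other.sorted_features()[["chrom", "start0", "end0", "strand", "gene_id", "kind"]]
        return a.reset_index(drop=True).equals(b.reset_index(drop=True))


def features_from_blocks(
    gene_id: str,
    chrom: str,
    strand: str,
    blocks: np.ndarray,
    utr5_len: int,
    utr3_len: int,
) -> list[dict]:
    """Decompose exon blocks (+ UTR lengths at the transcript ends) into
    five_utr/exon/intron/three_utr feature rows.

    ``utr5_len``/``utr3_len`` are measured in transcript orientation: the
    5'UTR occupies the first ``utr5_len`` nt of the first transcribed exon
    block. On the minus strand the first transcribed block is the rightmost
    genomic block.
    """
    blocks = np.asarray(blocks)
    if blocks.ndim != 2 or (blocks[:, 1] <= blocks[:, 0]).any():
        raise ValueError("exon blocks must be non-empty [start, end) pairs")
    rows: list[dict] = []

    def add(kind: str, s: int, e: int) -> None:
        if e > s:
            rows.append(
                dict(chrom=chrom, start0=int(s), end0=int(e), strand=strand,
                     gene_id=gene_id, kind=kind)
            )

    # introns: gaps between consecutive blocks
    for (s0, e0), (s1, e1) in zip(blocks[:-1], blocks[1:]):
        add("intron", e0, s1)

    exonic = [list(map(int, b)) for b in blocks]
    if strand == "+":
        first, last = exonic[0], exonic[-1]
        add("five_utr", first[0], first[0] + utr5_len)
        first[0] += utr5_len
        add("three_utr", last[1] - utr3_len, last[1])
        last[1] -= utr3_len
    else:
        first, last = exonic[-1], exonic[0]
        add("five_utr", first[1] - utr5_len, first[1])
        first[1] -= utr5_len
        add("three_utr", last[0], last[0] + utr3_len)
        last[0] += utr3_len
    for s, e in exonic:
        add("exon", s, e)
    return rows
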
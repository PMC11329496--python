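"""Readers and writers for the on-disk formats.

Internal coordinates are 0-based half-open everywhere; GTF (1-based,
inclusive) is converted at this boundary. BED is 0-based half-open and
passes through unchanged. Strand is mandatory on every interval record:
unstranded input is rejected rather than guessed.
"""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import FeatureAnnotation

SITE_COLUMNS = ["chrom", "pos0", "strand", "ref_count", "alt_count"]
READ_COLUMNS = [
    "read_id", "isoform_id", "mapped", "secondary", "supplementary",
    "quality", "strand", "edited_C", "total_C", "edit_positions",
]
BED_COLUMNS = ["chrom", "start0", "end0", "name", "score", "strand"]

_FLOAT_FMT = "%.6g"


# ----------------------------------------------------------------- FASTA
def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seq, 80) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


# ------------------------------------------------------------------- GTF
def write_gtf(annotation: FeatureAnnotation, path: str | Path) -> None:
    """Emit gene/transcript/exon/UTR records (1-based, inclusive).

    Exon records cover the full exon blocks (UTR included, as is
    conventional); UTR records mark the untranslated ends.
    """
    lines: list[str] = []

    def rec(chrom, source, kind, s0, e0, strand, attrs) -> None:
        attr = " ".join(f'{k} "{v}";' for k, v in attrs)
        lines.append(
            f"{chrom}\tdeamap\t{kind}\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t{attr}"
        )

    for g in annotation.genes.itertuples():
        rec(g.chrom, "deamap", "gene", g.start0, g.end0, g.strand,
            [("gene_id", g.gene_id)])
        isoforms = annotation.isoforms[annotation.isoforms["gene_id"] == g.gene_id]
        for iso in isoforms.itertuples():
            blocks = annotation.isoform_blocks(iso.isoform_id)
            rec(g.chrom, "deamap", "transcript", blocks[0, 0], blocks[-1, 1],
                g.strand, [("gene_id", g.gene_id), ("transcript_id", iso.isoform_id)])
            for s, e in blocks:
                rec(g.chrom, "deamap", "exon", s, e, g.strand,
                    [("gene_id", g.gene_id), ("transcript_id", iso.isoform_id)])
        utrs = annotation.features[
            (annotation.features["gene_id"] == g.gene_id)
            & (annotation.features["kind"].isin(["five_utr", "three_utr"]))
        ]
        primary = isoforms["isoform_id"].iloc[0]
        for u in utrs.itertuples():
            rec(g.chrom, "deamap", "UTR", u.start0, u.end0, g.strand,
                [("gene_id", g.gene_id), ("transcript_id", primary)])
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> FeatureAnnotation:
    """Parse a GTF into a :class:`FeatureAnnotation`.

    Introns are derived as gaps between consecutive exons of each
    transcript; exon blocks minus UTR spans give the ``exon`` features of
    the primary (first listed) isoform of each gene.
    """
    genes: list[dict] = []
    iso_exons: dict[str, list[tuple[int, int]]] = {}
    iso_meta: dict[str, dict] = {}
    utrs: dict[str, list[tuple[int, int]]] = {}
    gene_isoforms: dict[str, list[str]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}")
            chrom, _src, kind, s1, e1, _score, strand, _frame, attrs = parts
            if strand not in "+-":
                raise ValueError(f"{path}: missing strand on line {lineno}")
            try:
                start0, end0 = int(s1) - 1, int(e1)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}") from exc
            a = _parse_attrs(attrs)
            if kind == "gene":
                genes.append(dict(gene_id=a["gene_id"], chrom=chrom,
                                  start0=start0, end0=end0, strand=strand))
            elif kind == "transcript":
                tid = a["transcript_id"]
                iso_meta[tid] = dict(gene_id=a["gene_id"], chrom=chrom, strand=strand)
                gene_isoforms.setdefault(a["gene_id"], []).append(tid)
                iso_exons.setdefault(tid, [])
            elif kind == "exon":
                iso_exons.setdefault(a["transcript_id"], []).append((start0, end0))
            elif kind == "UTR":
                utrs.setdefault(a["gene_id"], []).append((start0, end0))

    genes_df = pd.DataFrame(genes)
    iso_rows = []
    for gid, tids in gene_isoforms.items():
        for tid in tids:
            blocks = sorted(iso_exons[tid])
            meta = iso_meta[tid]
            iso_rows.append(dict(
                isoform_id=tid, gene_id=gid, chrom=meta["chrom"],
                strand=meta["strand"],
                exon_starts=",".join(str(s) for s, _ in blocks),
                exon_ends=",".join(str(e) for _, e in blocks),
            ))
    isoforms_df = pd.DataFrame(iso_rows)

    feat_rows: list[dict] = []
    for g in genes_df.itertuples():
        primary = gene_isoforms[g.gene_id][0]
        blocks = sorted(iso_exons[primary])
        for (s0, e0), (s1, e1) in zip(blocks[:-1], blocks[1:]):
            if s1 > e0:
                feat_rows.append(dict(chrom=g.chrom, start0=e0, end0=s1,
                                      strand=g.strand, gene_id=g.gene_id,
                                      kind="intron"))
        gene_utrs = sorted(utrs.get(g.gene_id, []))
        # first transcribed UTR is the 5' one
        labelled: list[tuple[int, int, str]] = []
        if gene_utrs:
            ordered = gene_utrs if g.strand == "+" else gene_utrs[::-1]
            names = ["five_utr", "three_utr"]
            if len(ordered) == 1:
                # single UTR: 5' if at transcript start, else 3'
                u = ordered[0]
                at_start = (g.strand == "+" and u[0] == blocks[0][0]) or (
                    g.strand == "-" and u[1] == blocks[-1][1])
                labelled = [(u[0], u[1], "five_utr" if at_start else "three_utr")]
            else:
                labelled = [(u[0], u[1], nm) for u, nm in zip(ordered, names)]
        for s, e, nm in labelled:
            feat_rows.append(dict(chrom=g.chrom, start0=s, end0=e,
                                  strand=g.strand, gene_id=g.gene_id, kind=nm))
        utr_spans = [(s, e) for s, e, _ in labelled]
        for s, e in blocks:
            cur = [(s, e)]
            for us, ue in utr_spans:
                nxt = []
                for cs, ce in cur:
                    if ue <= cs or us >= ce:
                        nxt.append((cs, ce))
                    else:
                        if cs < us:
                            nxt.append((cs, us))
                        if ue < ce:
                            nxt.append((ue, ce))
                cur = nxt
            for cs, ce in cur:
                feat_rows.append(dict(chrom=g.chrom, start0=cs, end0=ce,
                                      strand=g.strand, gene_id=g.gene_id,
                                      kind="exon"))
    features_df = pd.DataFrame(feat_rows)
    return FeatureAnnotation(genes=genes_df, isoforms=isoforms_df,
                             features=features_df)


# ------------------------------------------------------------------- BED
def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 into a DataFrame (chrom, start0, end0, name, score, strand)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: BED line {lineno} lacks a strand field")
            if parts[5] not in "+-":
                raise ValueError(f"{path}: BED line {lineno} has no strand")
            rows.append(dict(chrom=parts[0], start0=int(parts[1]),
                             end0=int(parts[2]), name=parts[3],
                             score=float(parts[4]) if parts[4] != "." else 0.0,
                             strand=parts[5]))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(intervals: pd.DataFrame, path: str | Path,
              extra_columns: list[str] | None = None) -> None:
    """Write BED6(+extra), sorted by chrom then start."""
    df = intervals.copy()
    if "name" not in df:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    if "score" not in df:
        df["score"] = 0.0
    df = df.sort_values(["chrom", "start0", "end0"], kind="mergesort")
    cols = BED_COLUMNS + (extra_columns or [])
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            d = row._asdict()
            fields = [str(d["chrom"]), str(int(d["start0"])), str(int(d["end0"])),
                      str(d["name"]), _FLOAT_FMT % float(d["score"]), d["strand"]]
            for c in (extra_columns or []):
                v = d[c]
                fields.append(_FLOAT_FMT % v if isinstance(v, float) else str(v))
            fh.write("\t".join(fields) + "\n")


# ------------------------------------------------------------------- TSV
def write_site_counts(counts: pd.DataFrame, path: str | Path) -> None:
    df = counts[SITE_COLUMNS].sort_values(["chrom", "pos0"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_site_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing site-count columns {sorted(missing)}")
    return df


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    df = reads[READ_COLUMNS].copy()
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_reads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"edit_positions": str}, keep_default_na=False)
    for col in ("mapped", "secondary", "supplementary"):
        df[col] = df[col].astype(bool)
    return df


def parse_edit_positions(value: str) -> np.ndarray:
    """Comma-joined genomic positions of the edited Cs of one read."""
    if not value or value in (".", "nan"):
        return np.empty(0, dtype=int)
    return np.array([int(x) for x in value.split(",")], dtype=int)
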
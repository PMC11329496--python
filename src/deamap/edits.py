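"""C-to-U edit-site calling from per-site count evidence.

A candidate edit site is a transcribed sense-strand C position (genomic C
on + genes, genomic G on - genes) with at least one read supporting the
converted base (T on +, A on -). Each candidate receives a confidence
score in [0, 1]: the posterior probability, under a Jeffreys Beta(1/2, 1/2)
prior with binomial likelihood, that the site's true conversion rate
exceeds the background rate ``p_bg``. The score is coverage-aware and
monotone in the counts; it is this package's own definition, not a
re-derivation of any published caller's internal formula.

Sites are then filtered with the experiment's thresholds: confidence above
0.5, edit fraction below 0.8 (near-fixed fractions mark SNPs rather than
enzymatic editing), and exclusion of known SNP positions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EDIT_SITE_COLUMNS = ["chrom", "pos0", "strand", "ref_count", "alt_count",
                     "edit_fraction", "score"]


# ----------------------------------------------------------------- pileup
def pileup_counts(sam_path: str | Path, genome: dict[str, str],
                  annotation) -> pd.DataFrame:
    """Per-site ref/alt counts from aligned reads.

    Only positions that are C on the annotated gene's sense strand are
    counted; a mismatch counts as edited only when it is C→T on a + gene
    or G→A on a - gene. Reads aligned to the strand opposite the gene are
    excluded. Positions outside annotated genes are ignored (their gene
    strand is unknown); this is logged once per contig.
    """
    import pysam

    genes = annotation.genes
    counts: dict[tuple[str, int, str], list[int]] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            chrom = read.reference_name
            if chrom not in genome:
                raise ValueError(f"read {read.query_name} maps to unknown "
                                 f"contig {chrom!r}")
            read_strand = "-" if read.is_reverse else "+"
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos >= len(genome[chrom]):
                    raise ValueError(
                        f"position {rpos} beyond end of contig {chrom}")
                g = genes[(genes["chrom"] == chrom)
                          & (genes["start0"] <= rpos)
                          & (rpos < genes["end0"])]
                if g.empty:
                    continue
                gene_strand = g["strand"].iloc[0]
                if read_strand != gene_strand:
                    continue
                ref_base = genome[chrom][rpos].upper()
                sense_ref = "C" if gene_strand == "+" else "G"
                edited_base = "T" if gene_strand == "+" else "A"
                if ref_base != sense_ref:
                    continue
                obs = seq[qpos].upper()
                key = (chrom, rpos, gene_strand)
                slot = counts.setdefault(key, [0, 0])
                if obs == ref_base:
                    slot[0] += 1
                elif obs == edited_base:
                    slot[1] += 1
                # other mismatches are ignored
    rows = [dict(chrom=c, pos0=p, strand=s, ref_count=r, alt_count=a)
            for (c, p, s), (r, a) in sorted(counts.items()) if r + a > 0]
    return pd.DataFrame(rows, columns=["chrom", "pos0", "strand",
                                       "ref_count", "alt_count"])


# ---------------------------------------------------------------- scoring
def score_edit_site(alt_count, ref_count, p_bg: float):
    """Posterior P(edit rate > p_bg) with a Jeffreys prior.

    Vectorised over ``alt_count``/``ref_count``. Requires alt+ref > 0 and
    0 < p_bg < 1.
    """
    if not (0.0 < p_bg < 1.0):
        raise ValueError(f"p_bg must lie in (0, 1), got {p_bg}")
    alt = np.asarray(alt_count, dtype=float)
    ref = np.asarray(ref_count, dtype=float)
    if np.any(alt + ref <= 0):
        raise ValueError("scoring requires at least one covering read")
    return stats.beta.sf(p_bg, alt + 0.5, ref + 0.5)


def global_edit_fraction(count_tables: list[pd.DataFrame]) -> float:
    """Pooled edited fraction across tables; background-rate estimator."""
    alt = sum(int(t["alt_count"].sum()) for t in count_tables)
    total = sum(int((t["alt_count"] + t["ref_count"]).sum()) for t in count_tables)
    if total == 0:
        raise ValueError("no covered sites in background tables")
    return alt / total


def call_edit_sites(counts: pd.DataFrame, p_bg: float) -> pd.DataFrame:
    """Score every covered position with >= 1 converted read.

    Zero-conversion positions carry no edit evidence and are not emitted
    as candidate sites (they still count as covered background elsewhere).
    """
    covered = counts[(counts["ref_count"] + counts["alt_count"]) > 0]
    cand = covered[covered["alt_count"] > 0].copy()
    total = cand["alt_count"] + cand["ref_count"]
    cand["edit_fraction"] = cand["alt_count"] / total
    cand["score"] = score_edit_site(cand["alt_count"].to_numpy(),
                                    cand["ref_count"].to_numpy(), p_bg)
    return cand.reset_index(drop=True)[EDIT_SITE_COLUMNS]


# --------------------------------------------------------------- filtering
def filter_edit_sites(sites: pd.DataFrame,
                      snp_positions: pd.DataFrame | None = None,
                      score_min: float = 0.5,
                      fraction_max: float = 0.8) -> pd.DataFrame:
    """Retain sites with score > score_min, fraction < fraction_max and
    position not in the known-SNP list. Both comparisons are exclusive.

    ``snp_positions`` may be None, a DataFrame with chrom/pos0 columns, or
    a BED-style DataFrame with chrom/start0 (single-base intervals).
    """
    keep = (sites["score"] > score_min) & (sites["edit_fraction"] < fraction_max)
    if snp_positions is not None and len(snp_positions):
        pos_col = "pos0" if "pos0" in snp_positions else "start0"
        snp_keys = set(zip(snp_positions["chrom"], snp_positions[pos_col]))
        keep &= np.array([
            (c, p) not in snp_keys
            for c, p in zip(sites["chrom"], sites["pos0"])], dtype=bool)
    out = sites[keep].reset_index(drop=True)
    logger.info("filter_edit_sites: %d of %d sites retained", len(out), len(sites))
    return out
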
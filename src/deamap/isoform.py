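"""Isoform-resolved edit quantification from long reads.

The unit statistic is editsC: for one isoform in one sample, the number
of edited-C calls divided by the number of C calls, summed over reads and
restricted to C positions within the isoform's exons and UTRs. Reads are
first filtered on mapping/quality/strand criteria; recurrent edit
positions present in every replicate of every sample (putative SNPs) and
annotated SNPs are removed before quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import parse_edit_positions

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["isoform_id", "sample", "read_count", "total_C_calls",
                   "edited_C_calls", "editsC", "mean_edit_fraction"]


# --------------------------------------------------------------- filtering
def filter_long_reads(reads: pd.DataFrame, annotation=None,
                      min_quality: float = 20.0) -> pd.DataFrame:
    """Retain mapped, primary, non-supplementary reads with quality >=
    ``min_quality`` aligned to their isoform's annotated strand.

    When ``annotation`` is None the read's own strand column is compared
    against the majority strand of its isoform within the table.
    """
    keep = (reads["mapped"]
            & ~reads["secondary"]
            & ~reads["supplementary"]
            & (reads["quality"] >= min_quality))
    if annotation is not None:
        iso_strand = reads["isoform_id"].map(
            annotation.isoforms.set_index("isoform_id")["strand"])
    else:
        iso_strand = reads.groupby("isoform_id")["strand"].transform(
            lambda s: s.mode().iloc[0])
    keep &= reads["strand"] == iso_strand
    out = reads[keep].reset_index(drop=True)
    logger.info("filter_long_reads: %d of %d reads retained",
                len(out), len(reads))
    return out


def remove_putative_snps(edit_tables: dict[str, pd.DataFrame],
                         known_snps: pd.DataFrame | None = None,
                         ) -> dict[str, pd.DataFrame]:
    """Strip recurrent and annotated SNP positions from all read tables.

    ``edit_tables`` maps sample names (every replicate of every condition,
    controls included) to read tables. An edit position observed (>= 1
    edited read) in *all* tables is a putative SNP and is removed from the
    per-read edit lists everywhere; positions in ``known_snps`` (chrom is
    ignored: positions are genome-wide unique in these toy references;
    pass pos0 or BED start0) are removed afterwards.
    """
    if len(edit_tables) < 2:
        raise ValueError("need at least two samples to detect recurrent edits")
    per_table_positions = []
    for name, table in edit_tables.items():
        pos = set()
        for value in table["edit_positions"]:
            pos.update(parse_edit_positions(value).tolist())
        per_table_positions.append(pos)
    recurrent = set.intersection(*per_table_positions)
    drop = set(recurrent)
    if known_snps is not None and len(known_snps):
        col = "pos0" if "pos0" in known_snps else "start0"
        drop |= set(int(p) for p in known_snps[col])
    logger.info("remove_putative_snps: %d recurrent + %d annotated positions",
                len(recurrent), len(drop) - len(recurrent))

    out = {}
    for name, table in edit_tables.items():
        table = table.copy()
        new_lists = []
        new_counts = []
        for value in table["edit_positions"]:
            pos = [p for p in parse_edit_positions(value).tolist()
                   if p not in drop]
            new_lists.append(",".join(map(str, pos)))
            new_counts.append(len(pos))
        table["edit_positions"] = new_lists
        table["edited_C"] = new_counts
        out[name] = table
    return out


# ------------------------------------------------------------------ editsC
def compute_editsC(isoform_id: str, reads: pd.DataFrame, annotation,
                   sample: str = "") -> pd.Series:
    """Aggregate editsC for one isoform from its (filtered) reads.

    editsC = sum(edited_C) / sum(total_C) over reads. A 0/0 aggregate is
    emitted with NaN editsC rather than dropped.
    """
    if not (annotation.isoforms["isoform_id"] == isoform_id).any():
        raise KeyError(f"isoform {isoform_id!r} not in annotation")
    sub = reads[reads["isoform_id"] == isoform_id]
    total = int(sub["total_C"].sum())
    edited = int(sub["edited_C"].sum())
    frac = sub["edited_C"] / sub["total_C"].replace(0, np.nan)
    return pd.Series(dict(
        isoform_id=isoform_id, sample=sample, read_count=len(sub),
        total_C_calls=total, edited_C_calls=edited,
        editsC=(edited / total if total else np.nan),
        mean_edit_fraction=float(frac.mean()) if len(sub) else np.nan))


def editsC_profiles(reads_by_sample: dict[str, pd.DataFrame],
                    annotation) -> pd.DataFrame:
    """Per-isoform per-sample editsC table over all annotated isoforms."""
    rows = []
    for sample, reads in reads_by_sample.items():
        for isoform_id in annotation.isoforms["isoform_id"]:
            rows.append(compute_editsC(isoform_id, reads, annotation,
                                       sample=sample))
    return pd.DataFrame(rows)[PROFILE_COLUMNS]


# --------------------------------------------------------------- selection
@dataclass(frozen=True)
class IsoformFilter:
    min_coverage: int = 20
    min_edit_fraction: float = 0.02
    coverage_rule: str = "min"  # "min" over replicates, or "mean"


def filter_isoforms(profiles: pd.DataFrame, case_samples: list[str],
                    params: IsoformFilter = IsoformFilter()) -> pd.DataFrame:
    """Coverage and signal filters applied across replicates.

    Retains isoforms whose read count meets ``min_coverage`` in every
    replicate (or on average, per ``coverage_rule``) and whose mean editsC
    across the case replicates reaches ``min_edit_fraction``.
    """
    cov = profiles.pivot_table(index="isoform_id", columns="sample",
                               values="read_count", aggfunc="sum")
    agg = cov.min(axis=1) if params.coverage_rule == "min" else cov.mean(axis=1)
    enough_cov = agg >= params.min_coverage
    case = profiles[profiles["sample"].isin(case_samples)]
    case_mean = case.groupby("isoform_id")["editsC"].mean()
    signal = case_mean >= params.min_edit_fraction
    ok = enough_cov & signal.reindex(enough_cov.index).fillna(False)
    kept = set(ok[ok].index)
    out = profiles[profiles["isoform_id"].isin(kept)].reset_index(drop=True)
    logger.info("filter_isoforms: %d of %d isoforms retained",
                len(kept), profiles["isoform_id"].nunique())
    return out


def select_confident_isoforms(case_profiles: pd.DataFrame,
                              control_profiles: pd.DataFrame,
                              k_std: float = 1.5) -> pd.DataFrame:
    """Case-elevated isoforms from an OLS fit of case on control editsC.

    Mean editsC per isoform is computed for each condition, case is
    regressed on control (with intercept) across isoforms, and isoforms
    with a residual exceeding ``k_std`` sample standard deviations of the
    residuals are selected (one-sided: the goal is case-specific signal).
    """
    case_mean = case_profiles.groupby("isoform_id")["editsC"].mean()
    control_mean = control_profiles.groupby("isoform_id")["editsC"].mean()
    merged = pd.concat([case_mean.rename("case"),
                        control_mean.rename("control")], axis=1).dropna()
    if len(merged) < 3:
        raise ValueError("need at least three matched isoforms for the fit")
    x = merged["control"].to_numpy()
    y = merged["case"].to_numpy()
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ coef
    sd = residuals.std(ddof=1)
    # the absolute floor keeps float rounding on a perfect fit from
    # producing selections out of residuals of order machine epsilon
    selected = (residuals > k_std * sd) & (residuals > 1e-9)
    return pd.DataFrame(dict(
        isoform_id=merged.index, case_editsC=y, control_editsC=x,
        fitted=design @ coef, residual=residuals, selected=selected,
    )).reset_index(drop=True)
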
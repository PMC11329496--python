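"""Edit-cluster detection: Poisson window statistics with BH-FDR.

Fixed-length windows are slid along every annotated feature (5'UTR, exon,
intron, 3'UTR) that contains at least one filtered edit site. For each
window the number of edit sites k is compared against a Poisson null with
expectation lambda = p_bg(class) * (covered C positions in the window),
where p_bg(class) is the per-region-class density of passing edit sites
among covered Cs. Window p-values are Benjamini-Hochberg adjusted across
all windows of the run; significant same-strand windows closer than the
merge distance are fused, and each merged cluster is trimmed to the span
of the outermost edit sites it contains.

Site-count (rather than read-count) statistics decouple cluster
significance from coverage inflation at poorly covered positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CLUSTER_COLUMNS = ["chrom", "start0", "end0", "strand", "n_edit_sites",
                   "p_value", "q_value", "score"]

#: floor for the Poisson expectation in windows with no covered C
LAM_FLOOR = 1e-6

REGION_CLASSES = ("five_utr", "exon", "intron", "three_utr")


@dataclass(frozen=True)
class ClusterModel:
    window_len: int = 50
    window_step: int = 10
    fdr_threshold: float = 0.1
    merge_distance: int = 15
    p_bg: dict | None = None  # region class -> rate; None = estimate

    def validate(self) -> None:
        if self.window_step > self.window_len:
            raise ValueError("window_step must be <= window_len")
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be >= 0")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must lie in (0, 1)")


# -------------------------------------------------------------- primitives
def poisson_tail(k, lam):
    """P(X >= k) for X ~ Poisson(lam), via the survival function."""
    k = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lam must be positive")
    if np.any(k < 0) or np.any(np.asarray(k, dtype=float) % 1 != 0):
        raise ValueError("k must be a non-negative integer")
    return stats.poisson.sf(k - 1, lam_arr)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    return q


# ------------------------------------------------------------- background
def estimate_background_rate(sites: pd.DataFrame, counts: pd.DataFrame,
                             annotation) -> dict[str, float]:
    """Passing-edit-site density among covered Cs, per region class.

    Classes with covered Cs but no sites get their own (zero-numerator)
    rate floor-ed later by the lambda floor; classes with no coverage at
    all inherit the global rate.
    """
    covered = counts[(counts["ref_count"] + counts["alt_count"]) > 0]
    if covered.empty:
        raise ValueError("no covered C positions anywhere")
    cls_sites = _assign_class(sites, annotation)
    cls_cov = _assign_class(covered, annotation)
    n_sites = cls_sites.value_counts()
    n_cov = cls_cov.value_counts()
    global_rate = len(cls_sites.dropna()) / max(len(cls_cov.dropna()), 1)
    rates = {}
    for cls in REGION_CLASSES:
        cov = int(n_cov.get(cls, 0))
        if cov == 0:
            rates[cls] = global_rate
        else:
            rates[cls] = int(n_sites.get(cls, 0)) / cov
    return rates


def _assign_class(table: pd.DataFrame, annotation) -> pd.Series:
    """Region class of each position (NaN outside annotated features)."""
    feats = annotation.features
    out = pd.Series(np.nan, index=table.index, dtype=object)
    for chrom, sub in table.groupby("chrom", sort=False):
        f = feats[feats["chrom"] == chrom]
        if f.empty:
            continue
        starts = f["start0"].to_numpy()
        ends = f["end0"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        kinds = f["kind"].to_numpy()[order]
        fstrand = f["strand"].to_numpy()[order]
        pos = sub["pos0"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)]) & (
            sub["strand"].to_numpy() == fstrand[np.clip(idx, 0, None)])
        vals = np.where(ok, kinds[np.clip(idx, 0, None)], None)
        out.loc[sub.index] = vals
    return out


# ---------------------------------------------------------------- calling
def call_edit_clusters(sites: pd.DataFrame, counts: pd.DataFrame,
                       annotation, model: ClusterModel) -> pd.DataFrame:
    """Windows -> Poisson p -> BH q -> threshold -> merge -> trim."""
    model.validate()
    if sites.empty:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    p_bg = model.p_bg or estimate_background_rate(sites, counts, annotation)

    covered = counts[(counts["ref_count"] + counts["alt_count"]) > 0]
    win_rows = []
    feats = annotation.features
    for chrom, strand in sites.groupby(["chrom", "strand"], sort=False).groups:
        s_pos = np.sort(sites.loc[(sites["chrom"] == chrom)
                                  & (sites["strand"] == strand),
                                  "pos0"].to_numpy())
        c_pos = np.sort(covered.loc[(covered["chrom"] == chrom)
                                    & (covered["strand"] == strand),
                                    "pos0"].to_numpy())
        f = feats[(feats["chrom"] == chrom) & (feats["strand"] == strand)]
        for feat in f.itertuples():
            lo = np.searchsorted(s_pos, feat.start0)
            hi = np.searchsorted(s_pos, feat.end0)
            if hi == lo:
                continue  # feature holds no edit site
            length = feat.end0 - feat.start0
            n_win = max(1, -(-(length - model.window_len) // model.window_step) + 1) \
                if length > model.window_len else 1
            starts = feat.start0 + model.window_step * np.arange(n_win)
            ends = np.minimum(starts + model.window_len, feat.end0)
            k = np.searchsorted(s_pos, ends) - np.searchsorted(s_pos, starts)
            keep = k > 0
            if not keep.any():
                continue
            starts, ends, k = starts[keep], ends[keep], k[keep]
            n_c = np.searchsorted(c_pos, ends) - np.searchsorted(c_pos, starts)
            lam = np.maximum(p_bg[feat.kind] * n_c, LAM_FLOOR)
            p = poisson_tail(k, lam)
            for s, e, kk, pp in zip(starts, ends, k, p):
                win_rows.append((chrom, int(s), int(e), strand, int(kk),
                                 float(pp)))
    if not win_rows:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    win = pd.DataFrame(win_rows, columns=["chrom", "start0", "end0", "strand",
                                          "k", "p_value"])
    win["q_value"] = bh_fdr(win["p_value"].to_numpy())
    sig = win[win["q_value"] < model.fdr_threshold]
    if sig.empty:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    return _merge_and_trim(sig, sites, model)


def _merge_and_trim(sig: pd.DataFrame, sites: pd.DataFrame,
                    model: ClusterModel) -> pd.DataFrame:
    out = []
    sig = sig.sort_values(["chrom", "strand", "start0", "end0"],
                          kind="mergesort")
    for (chrom, strand), grp in sig.groupby(["chrom", "strand"], sort=False):
        s_pos = np.sort(sites.loc[(sites["chrom"] == chrom)
                                  & (sites["strand"] == strand),
                                  "pos0"].to_numpy())
        cur_s = cur_e = None
        cur_p = cur_q = np.inf
        for row in grp.itertuples():
            if cur_s is None:
                cur_s, cur_e = row.start0, row.end0
                cur_p, cur_q = row.p_value, row.q_value
            elif row.start0 - cur_e <= model.merge_distance:
                cur_e = max(cur_e, row.end0)
                cur_p = min(cur_p, row.p_value)
                cur_q = min(cur_q, row.q_value)
            else:
                out.append(_trim(chrom, strand, cur_s, cur_e, cur_p, cur_q,
                                 s_pos))
                cur_s, cur_e = row.start0, row.end0
                cur_p, cur_q = row.p_value, row.q_value
        if cur_s is not None:
            out.append(_trim(chrom, strand, cur_s, cur_e, cur_p, cur_q, s_pos))
    clusters = pd.DataFrame([r for r in out if r is not None],
                            columns=CLUSTER_COLUMNS)
    return clusters.sort_values(["chrom", "start0", "end0"],
                                kind="mergesort").reset_index(drop=True)


def _trim(chrom, strand, start, end, p, q, s_pos):
    lo = np.searchsorted(s_pos, start)
    hi = np.searchsorted(s_pos, end)
    if hi == lo:  # merged span without sites cannot occur, but be safe
        return None
    first, last = int(s_pos[lo]), int(s_pos[hi - 1])
    with np.errstate(divide="ignore"):
        score = float(-np.log10(q)) if q > 0 else 300.0
    return dict(chrom=chrom, start0=first, end0=last + 1, strand=strand,
                n_edit_sites=int(hi - lo), p_value=float(p),
                q_value=float(q), score=score)
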
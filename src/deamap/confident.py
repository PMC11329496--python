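"""Confident clusters: strand-aware replicate intersection and control
subtraction.

``intersect_replicates`` keeps the clusters of the first (anchor)
replicate that overlap, by at least 1 nt on the same strand, at least one
cluster in every other replicate — the successive -wa/-u/-s semantics of
interval intersection. ``subtract_control`` then removes whole anchor
clusters that overlap any control cluster (whole-interval removal, never
trimming: downstream statistics count clusters, and trimming would
fabricate cluster fragments). The result is therefore always a subset of
the anchor replicate's clusters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _overlaps_any(queries: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: >=1 nt same-strand overlap with any subject."""
    hit = np.zeros(len(queries), dtype=bool)
    if subjects.empty or queries.empty:
        return hit
    for (chrom, strand), sub in subjects.groupby(["chrom", "strand"], sort=False):
        mask = (queries["chrom"] == chrom) & (queries["strand"] == strand)
        if not mask.any():
            continue
        # merge subject intervals, then test span membership
        iv = sub[["start0", "end0"]].sort_values("start0").to_numpy()
        merged = [list(iv[0])]
        for s, e in iv[1:]:
            if s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        ms = np.array([m[0] for m in merged])
        me = np.array([m[1] for m in merged])
        qs = queries.loc[mask, "start0"].to_numpy()
        qe = queries.loc[mask, "end0"].to_numpy()
        # overlap iff some merged interval starts before query end and
        # ends after query start
        idx = np.searchsorted(ms, qe, side="left") - 1
        ok = (idx >= 0) & (me[np.clip(idx, 0, None)] > qs)
        hit[np.flatnonzero(mask.to_numpy())] = ok
    return hit


def intersect_replicates(replicate_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Anchor clusters overlapping >=1 cluster in every other replicate.

    The first listed set anchors the intersection; the choice of anchor
    can change the result, so it is logged.
    """
    if len(replicate_sets) < 2:
        raise ValueError("need at least two replicate cluster sets")
    anchor = replicate_sets[0].reset_index(drop=True)
    keep = np.ones(len(anchor), dtype=bool)
    for other in replicate_sets[1:]:
        keep &= _overlaps_any(anchor, other)
    out = anchor[keep].reset_index(drop=True)
    logger.info(
        "intersect_replicates: anchor=first of %d sets; %d of %d anchor "
        "clusters kept (result depends on anchor choice)",
        len(replicate_sets), len(out), len(anchor))
    return out


def subtract_control(clusters: pd.DataFrame,
                     control_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Drop whole clusters with >=1 nt same-strand overlap with any control."""
    clusters = clusters.reset_index(drop=True)
    keep = np.ones(len(clusters), dtype=bool)
    for control in control_sets:
        keep &= ~_overlaps_any(clusters, control)
    out = clusters[keep].reset_index(drop=True)
    logger.info("subtract_control: %d of %d clusters retained",
                len(out), len(clusters))
    return out
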
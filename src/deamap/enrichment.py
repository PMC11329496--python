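"""Binding-specificity statistics for cluster sets.

Covers motif scanning on gene sense strands, the motif-containing
fraction of a cluster set, within-feature random shuffling of clusters
(length- and strand-preserving), permutation Z-scores and fold
enrichment, signed nearest-target distances in transcript orientation,
same-strand peak-overlap fractions, and an edit-radius estimator that
finds the distance beyond which case and control distance distributions
become indistinguishable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import EXONIC_KINDS
from .confident import _overlaps_any
from .simulate import revcomp, rna_to_dna

logger = logging.getLogger(__name__)

#: sentinel Z when the permuted fractions have zero spread
Z_UNDEFINED = float("nan")


@dataclass(frozen=True)
class PermutationSummary:
    observed_fraction: float
    permuted_fractions: tuple
    z_score: float
    enrichment: float
    n_perm: int
    seed: int | None = None


# -------------------------------------------------------------- motif scan
def scan_motif(genome: dict[str, str], annotation, motif: str) -> pd.DataFrame:
    """All occurrences of an RNA k-mer on gene sense strands.

    For + genes the DNA equivalent is matched directly on the forward
    genomic sequence; for - genes its reverse complement is matched (the
    sense-strand RNA then reads the motif). Occurrences outside annotated
    genes are ignored. Overlapping occurrences are all reported.
    """
    dna = rna_to_dna(motif)
    k = len(dna)
    rows = []
    for g in annotation.genes.itertuples():
        target = dna if g.strand == "+" else revcomp(dna)
        seq = genome[g.chrom][g.start0:g.end0].upper()
        for m in re.finditer(f"(?={re.escape(target)})", seq):
            s = g.start0 + m.start()
            rows.append(dict(chrom=g.chrom, start0=s, end0=s + k,
                             strand=g.strand, gene_id=g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start0", "end0", "strand",
                                       "gene_id"])


def motif_fraction(clusters: pd.DataFrame, hits: pd.DataFrame) -> float:
    """Fraction of clusters with >=1 nt same-strand overlap with a hit."""
    if clusters.empty:
        raise ValueError("motif fraction undefined for an empty cluster set")
    if hits.empty:
        return 0.0
    return float(_overlaps_any(clusters.reset_index(drop=True), hits).mean())


def overlap_fraction(clusters: pd.DataFrame, peaks: pd.DataFrame) -> float:
    """Fraction of clusters overlapping any same-strand reference peak."""
    if clusters.empty:
        raise ValueError("overlap fraction undefined for an empty cluster set")
    return float(_overlaps_any(clusters.reset_index(drop=True), peaks).mean())


# -------------------------------------------------------------- shuffling
def _host_features(clusters: pd.DataFrame, annotation) -> pd.DataFrame:
    """Host feature (exonic vs intron span containing the midpoint).

    UTRs count as exonic: contiguous runs of exonic features are *not*
    fused (features are disjoint per gene), so the host is simply the
    feature interval containing the cluster midpoint.
    """
    feats = annotation.features
    rows = []
    for i, c in enumerate(clusters.itertuples()):
        mid = (c.start0 + c.end0) // 2
        f = feats[(feats["chrom"] == c.chrom) & (feats["strand"] == c.strand)
                  & (feats["start0"] <= mid) & (mid < feats["end0"])]
        if f.empty:
            raise ValueError(
                f"cluster {c.chrom}:{c.start0}-{c.end0}({c.strand}) midpoint "
                "lies outside every annotated feature")
        # fuse adjacent exonic features (UTR+exon) into one host span
        row = f.iloc[0]
        start, end = int(row["start0"]), int(row["end0"])
        if row["kind"] in EXONIC_KINDS:
            gf = feats[(feats["gene_id"] == row["gene_id"])
                       & (feats["kind"].isin(EXONIC_KINDS))].sort_values("start0")
            for r in gf.itertuples():
                if r.start0 == end:
                    end = r.end0
                if r.end0 == start:
                    start = r.start0
        rows.append(dict(idx=i, host_start=start, host_end=end))
    return pd.DataFrame(rows)


def shuffle_clusters(clusters: pd.DataFrame, annotation, n_perm: int = 20,
                     seed: int | None = None) -> list[pd.DataFrame]:
    """Length- and strand-preserving random placement within host features.

    Each permutation redraws every cluster's start uniformly among the
    offsets at which it still fits inside its host feature (the exon or
    intron containing its midpoint; UTRs are exonic). Clusters longer than
    their host are clamped to the host span.
    """
    clusters = clusters.reset_index(drop=True)
    hosts = _host_features(clusters, annotation)
    rng = np.random.default_rng(seed)
    lengths = (clusters["end0"] - clusters["start0"]).to_numpy()
    out = []
    for _ in range(n_perm):
        starts = np.empty(len(clusters), dtype=int)
        ends = np.empty(len(clusters), dtype=int)
        for h in hosts.itertuples():
            length = lengths[h.idx]
            lo, hi = h.host_start, h.host_end
            if length >= hi - lo:
                starts[h.idx], ends[h.idx] = lo, hi
            else:
                s = int(rng.integers(lo, hi - length + 1))
                starts[h.idx], ends[h.idx] = s, s + length
        perm = clusters.copy()
        perm["start0"] = starts
        perm["end0"] = ends
        out.append(perm)
    return out


def permutation_enrichment(observed_fraction: float,
                           permuted_fractions,
                           seed: int | None = None) -> PermutationSummary:
    """Z-score and fold enrichment of an observed fraction vs permutations.

    Uses the sample (n-1) standard deviation. A zero permutation spread
    yields a NaN Z (logged); a zero permutation mean with a positive
    observation yields infinite enrichment (logged).
    """
    perm = np.asarray(list(permuted_fractions), dtype=float)
    if perm.size < 2:
        raise ValueError("need at least two permuted fractions")
    mean = perm.mean()
    sd = 0.0 if np.all(perm == perm[0]) else perm.std(ddof=1)
    if sd == 0.0:
        z = Z_UNDEFINED
        logger.warning("permutation sd is zero; Z undefined")
    else:
        z = (observed_fraction - mean) / sd
    if mean == 0.0:
        enrichment = float("inf") if observed_fraction > 0 else 0.0
        if observed_fraction > 0:
            logger.warning("permutation mean is zero; enrichment infinite")
    else:
        enrichment = observed_fraction / mean
    return PermutationSummary(observed_fraction=float(observed_fraction),
                              permuted_fractions=tuple(perm),
                              z_score=float(z), enrichment=float(enrichment),
                              n_perm=int(perm.size), seed=seed)


def motif_enrichment(clusters: pd.DataFrame, hits: pd.DataFrame, annotation,
                     n_perm: int = 20, seed: int | None = None,
                     fraction_of=motif_fraction) -> PermutationSummary:
    """Observed vs within-feature-shuffled fraction, in one call."""
    observed = fraction_of(clusters, hits)
    perms = shuffle_clusters(clusters, annotation, n_perm=n_perm, seed=seed)
    fracs = [fraction_of(p, hits) for p in perms]
    return permutation_enrichment(observed, fracs, seed=seed)


# -------------------------------------------------------------- distances
def nearest_feature_distance(clusters: pd.DataFrame,
                             targets: pd.DataFrame) -> np.ndarray:
    """Signed midpoint-to-midpoint distance to the nearest same-strand target.

    Positive means downstream in transcript orientation (the sign is
    flipped on - strand); ties in absolute distance break toward the
    negative (upstream) side. Clusters with no same-strand target on their
    chromosome get NaN.
    """
    if targets.empty:
        raise ValueError("target set is empty")
    out = np.full(len(clusters), np.nan)
    t_mid = ((targets["start0"] + targets["end0"]) // 2).to_numpy()
    for i, c in enumerate(clusters.reset_index(drop=True).itertuples()):
        mask = ((targets["chrom"] == c.chrom)
                & (targets["strand"] == c.strand)).to_numpy()
        if not mask.any():
            continue
        mid = (c.start0 + c.end0) // 2
        d = t_mid[mask] - mid
        if c.strand == "-":
            d = -d
        order = np.lexsort((d, np.abs(d)))  # min |d|, ties -> negative first
        out[i] = d[order[0]]
    return out


# ------------------------------------------------------------- edit radius
def edit_radius(case_distances, control_distances, grid_max: int = 1000,
                epsilon: float = 0.1, min_tail: int = 20) -> int:
    """Distance beyond which case and control distances are alike.

    The case sample is modelled as the control's distance distribution
    plus an excess of short distances contributed by directed editing.
    Beyond the true edit radius the two samples, *conditioned on exceeding
    a threshold d*, follow the same distribution; below it the case tail
    still carries excess short-distance mass. The estimator therefore
    returns the smallest d on [0, grid_max] from which onward the
    Kolmogorov-Smirnov distance between the renormalised tail CDFs stays
    within ``epsilon``. Thresholds where either tail holds fewer than
    ``min_tail`` observations are treated as converged (no case signal
    left to compare); an exhausted grid returns ``grid_max``.
    """
    case = np.abs(np.asarray(case_distances, dtype=float))
    ctrl = np.abs(np.asarray(control_distances, dtype=float))
    case = case[~np.isnan(case)]
    ctrl = ctrl[~np.isnan(ctrl)]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both distance samples must be non-empty")
    grid = np.arange(grid_max + 1)
    # tail counts: number of |d| strictly greater than each grid point
    case_sorted = np.sort(case)
    ctrl_sorted = np.sort(ctrl)
    case_tail = case.size - np.searchsorted(case_sorted, grid, side="right")
    ctrl_tail = ctrl.size - np.searchsorted(ctrl_sorted, grid, side="right")

    ok = np.zeros(grid_max + 1, dtype=bool)
    for d in grid:
        if case_tail[d] < min_tail or ctrl_tail[d] < min_tail:
            ok[d] = True
            continue
        # renormalised tail survival on d..grid_max; allow the two-sample
        # KS sampling noise (99% quantile) on top of epsilon so thin tails
        # are not declared divergent by chance
        sc = case_tail[d:] / case_tail[d]
        st = ctrl_tail[d:] / ctrl_tail[d]
        noise = 1.63 * np.sqrt(1.0 / case_tail[d] + 1.0 / ctrl_tail[d])
        ok[d] = np.max(np.abs(sc - st)) <= max(epsilon, noise)
    # smallest d with ok everywhere from d onward
    converged = np.flip(np.logical_and.accumulate(np.flip(ok)))
    idx = np.flatnonzero(converged)
    return int(idx[0]) if idx.size else int(grid_max)
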
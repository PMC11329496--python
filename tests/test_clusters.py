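"""Poisson tails, BH-FDR and window clustering against brute force."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from deamap.annotation import FeatureAnnotation
from deamap.clusters import (LAM_FLOOR, ClusterModel, bh_fdr,
                             call_edit_clusters, estimate_background_rate,
                             poisson_tail)


# ------------------------------------------------------------ poisson tail
def pmf_tail_oracle(k, lam):
    """Direct Poisson pmf summation (upper tail, term-by-term)."""
    total = 0.0
    i = k
    while True:
        term = math.exp(-lam + i * math.log(lam) - math.lgamma(i + 1))
        total += term
        if i > lam and term < 1e-18:
            break
        i += 1
        if i > k + 2000:
            break
    return min(total, 1.0)


def test_poisson_tail_certain_event():
    assert poisson_tail(0, 2.5) == 1.0


def test_poisson_tail_closed_form():
    assert poisson_tail(1, 1.0) == pytest.approx(1 - math.exp(-1), abs=1e-14)


def test_poisson_tail_matches_pmf_summation_grid():
    lams = [0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0]
    for lam in lams:
        for k in range(0, 101):
            assert poisson_tail(k, lam) == pytest.approx(
                pmf_tail_oracle(k, lam), abs=1e-10)


def test_poisson_tail_rejects_bad_inputs():
    with pytest.raises(ValueError):
        poisson_tail(1, 0.0)
    with pytest.raises(ValueError):
        poisson_tail(-1, 1.0)


# ----------------------------------------------------------------- BH-FDR
def bh_oracle(p):
    """Textbook step-up definition with cumulative-minimum enforcement."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * n / rank_from_top)
        adjusted[idx] = running
    return adjusted


def test_bh_single_and_textbook_example():
    assert bh_fdr([0.01]) == pytest.approx([0.01])
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
        [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_oracle_on_many_random_vectors(rng):
    for _ in range(1000):
        n = int(rng.integers(1, 1001))
        p = rng.random(n)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)


@given(st.lists(st.floats(0, 1), min_size=2, max_size=30),
       st.randoms(use_true_random=False))
def test_bh_is_order_equivariant(p, pyrandom):
    perm = list(range(len(p)))
    pyrandom.shuffle(perm)
    q = bh_fdr(p)
    q_perm = bh_fdr([p[i] for i in perm])
    np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# ------------------------------------------------------- background rates
def _flat_annotation(rows):
    feats = pd.DataFrame(rows)
    genes = feats.groupby("gene_id").agg(
        chrom=("chrom", "first"), start0=("start0", "min"),
        end0=("end0", "max"), strand=("strand", "first")).reset_index()
    return FeatureAnnotation(genes=genes, isoforms=pd.DataFrame(),
                             features=feats)


@pytest.fixture
def intron_annotation():
    return _flat_annotation([
        dict(chrom="chr1", start0=0, end0=10000, strand="+", gene_id="g1",
             kind="intron"),
        dict(chrom="chr1", start0=10000, end0=10400, strand="+", gene_id="g1",
             kind="exon"),
    ])


def test_background_rate_is_site_density(intron_annotation, rng):
    pos = np.sort(rng.choice(10000, size=10000, replace=False))[:10000]
    counts = pd.DataFrame(dict(chrom="chr1", pos0=np.arange(10000),
                               strand="+", ref_count=10, alt_count=0))
    sites = pd.DataFrame(dict(chrom="chr1", pos0=pos[:10], strand="+",
                              ref_count=9, alt_count=1,
                              edit_fraction=0.1, score=0.9))
    rates = estimate_background_rate(sites, counts, intron_annotation)
    assert rates["intron"] == pytest.approx(10 / 10000)
    # exon class has no coverage -> inherits global rate
    assert rates["exon"] == pytest.approx(10 / 10000)


def test_background_rate_requires_coverage(intron_annotation):
    empty = pd.DataFrame(dict(chrom=[], pos0=[], strand=[], ref_count=[],
                              alt_count=[]))
    with pytest.raises(ValueError):
        estimate_background_rate(empty, empty, intron_annotation)


# -------------------------------------------------------------- clustering
def brute_force_clusters(sites, counts, annotation, model, p_bg):
    """Exhaustive re-implementation of the window/merge/trim contract."""
    windows = []
    covered = counts[(counts["ref_count"] + counts["alt_count"]) > 0]
    for f in annotation.features.itertuples():
        spos = sorted(sites[(sites["chrom"] == f.chrom)
                            & (sites["strand"] == f.strand)
                            & (sites["pos0"] >= f.start0)
                            & (sites["pos0"] < f.end0)]["pos0"])
        if not spos:
            continue
        start = f.start0
        starts = [start]
        while starts[-1] + model.window_len < f.end0:
            starts.append(starts[-1] + model.window_step)
        for s in starts:
            e = min(s + model.window_len, f.end0)
            k = sum(1 for p in spos if s <= p < e)
            if k == 0:
                continue
            ncov = ((covered["chrom"] == f.chrom)
                    & (covered["strand"] == f.strand)
                    & (covered["pos0"] >= s) & (covered["pos0"] < e)).sum()
            lam = max(p_bg[f.kind] * ncov, LAM_FLOOR)
            windows.append(dict(chrom=f.chrom, strand=f.strand, start0=s,
                                end0=e, k=k, lam=lam))
    if not windows:
        return []
    p = [pmf_tail_oracle(w["k"], w["lam"]) for w in windows]
    q = bh_oracle(p)
    sig = [dict(**w, p=pp, q=qq) for w, pp, qq in zip(windows, p, q)
           if qq < model.fdr_threshold]
    sig.sort(key=lambda w: (w["chrom"], w["strand"], w["start0"], w["end0"]))
    merged = []
    for w in sig:
        if (merged and merged[-1]["chrom"] == w["chrom"]
                and merged[-1]["strand"] == w["strand"]
                and w["start0"] - merged[-1]["end0"] <= model.merge_distance):
            merged[-1]["end0"] = max(merged[-1]["end0"], w["end0"])
            merged[-1]["p"] = min(merged[-1]["p"], w["p"])
            merged[-1]["q"] = min(merged[-1]["q"], w["q"])
        else:
            merged.append(dict(w))
    out = []
    for m in merged:
        inside = sorted(sites[(sites["chrom"] == m["chrom"])
                              & (sites["strand"] == m["strand"])
                              & (sites["pos0"] >= m["start0"])
                              & (sites["pos0"] < m["end0"])]["pos0"])
        out.append(dict(chrom=m["chrom"], start0=inside[0],
                        end0=inside[-1] + 1, strand=m["strand"],
                        n=len(inside), p=m["p"], q=m["q"]))
    out.sort(key=lambda c: (c["chrom"], c["start0"], c["end0"]))
    return out


def _mk_sites(positions, chrom="chr1", strand="+"):
    return pd.DataFrame(dict(chrom=chrom, pos0=list(positions),
                             strand=strand, ref_count=45, alt_count=5,
                             edit_fraction=0.1, score=0.99))


def _mk_counts(n, chrom="chr1", strand="+"):
    return pd.DataFrame(dict(chrom=chrom, pos0=np.arange(n), strand=strand,
                             ref_count=50, alt_count=0))


def test_dense_sites_form_one_cluster(intron_annotation):
    sites = _mk_sites([5000, 5007, 5013, 5021, 5029])
    counts = _mk_counts(10000)
    model = ClusterModel()
    p_bg = {"intron": 0.001, "exon": 0.001, "five_utr": 0.001,
            "three_utr": 0.001}
    clusters = call_edit_clusters(sites, counts, intron_annotation,
                                  ClusterModel(p_bg=p_bg))
    assert len(clusters) == 1
    c = clusters.iloc[0]
    assert (c["start0"], c["end0"]) == (5000, 5030)
    assert c["n_edit_sites"] == 5
    # manual Poisson + BH for the winning window
    oracle = brute_force_clusters(sites, counts, intron_annotation, model,
                                  p_bg)
    assert c["p_value"] == pytest.approx(oracle[0]["p"], rel=1e-9)
    assert c["q_value"] == pytest.approx(oracle[0]["q"], rel=1e-9)


@pytest.mark.parametrize("gap,expect_merged", [(10, 1), (20, 2)])
def test_merge_distance_boundary(gap, expect_merged):
    """Significant windows separated by `gap` nt merge iff gap <= 15."""
    annotation = _flat_annotation([
        dict(chrom="chr1", start0=3000, end0=3020, strand="+", gene_id="g1",
             kind="intron"),
        dict(chrom="chr1", start0=3020 + gap, end0=3040 + gap, strand="+",
             gene_id="g1", kind="intron"),
    ])
    left = [3000 + 2 * i for i in range(10)]
    right = [3020 + gap + 2 * i for i in range(10)]
    sites = _mk_sites(left + right)
    counts = _mk_counts(10000)
    p_bg = {k: 0.0005 for k in ("intron", "exon", "five_utr", "three_utr")}
    model = ClusterModel(window_len=20, window_step=20, p_bg=p_bg)
    clusters = call_edit_clusters(sites, counts, annotation, model)
    assert len(clusters) == expect_merged
    oracle = brute_force_clusters(sites, counts, annotation, model, p_bg)
    assert [(c["start0"], c["end0"]) for c in oracle] == \
        list(zip(clusters["start0"], clusters["end0"]))


def test_empty_site_set_gives_empty_output(intron_annotation):
    empty = _mk_sites([]).iloc[:0]
    out = call_edit_clusters(empty, _mk_counts(100), intron_annotation,
                             ClusterModel())
    assert out.empty


def test_clusters_match_brute_force_on_random_fixture(intron_annotation, rng):
    """<=200 random sites: implementation vs exhaustive windows."""
    positions = np.sort(rng.choice(10000, size=180, replace=False))
    sites = _mk_sites(positions)
    counts = _mk_counts(10400)
    p_bg = {k: 0.004 for k in ("intron", "exon", "five_utr", "three_utr")}
    model = ClusterModel(p_bg=p_bg)
    clusters = call_edit_clusters(sites, counts, intron_annotation, model)
    oracle = brute_force_clusters(sites, counts, intron_annotation, model,
                                  p_bg)
    assert len(clusters) == len(oracle)
    for got, exp in zip(clusters.itertuples(), oracle):
        assert (got.start0, got.end0, got.n_edit_sites) == \
            (exp["start0"], exp["end0"], exp["n"])
        assert got.q_value == pytest.approx(exp["q"], rel=1e-9)


def test_clusters_are_disjoint_same_strand(intron_annotation, rng):
    positions = np.sort(rng.choice(8000, size=150, replace=False))
    sites = _mk_sites(positions)
    counts = _mk_counts(10400)
    p_bg = {k: 0.003 for k in ("intron", "exon", "five_utr", "three_utr")}
    clusters = call_edit_clusters(sites, counts, intron_annotation,
                                  ClusterModel(p_bg=p_bg))
    c = clusters.sort_values("start0")
    assert (c["start0"].to_numpy()[1:] >= c["end0"].to_numpy()[:-1]).all()
    assert (c["q_value"] <= 1).all() and (c["q_value"] >= 0).all()
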
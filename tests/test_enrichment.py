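"""Motif scanning, shuffling, permutation statistics, distances, radius."""

import math
import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deamap.enrichment import (edit_radius, motif_fraction,
                               nearest_feature_distance, overlap_fraction,
                               permutation_enrichment, scan_motif,
                               shuffle_clusters)
from deamap.simulate import revcomp

from conftest import intervals


# -------------------------------------------------------------- motif scan
def test_scan_finds_direct_occurrence_in_plus_gene(tiny_reference,
                                                   tiny_config):
    hits = scan_motif(tiny_reference.genome, tiny_reference.annotation,
                      tiny_config.motif)
    truth = tiny_reference.truth.bound_motifs
    truth_keys = set(zip(truth["chrom"], truth["start0"], truth["strand"]))
    hit_keys = set(zip(hits["chrom"], hits["start0"], hits["strand"]))
    assert truth_keys <= hit_keys


def test_scan_matches_regex_on_sense_strand_sequences(tiny_reference,
                                                      tiny_config):
    """Independent oracle: extract each gene's sense sequence, regex it."""
    dna = tiny_config.motif.replace("U", "T")
    expected = 0
    for g in tiny_reference.annotation.genes.itertuples():
        seq = tiny_reference.genome[g.chrom][g.start0:g.end0]
        sense = seq if g.strand == "+" else revcomp(seq)
        expected += len(re.findall(f"(?={dna})", sense))
    hits = scan_motif(tiny_reference.genome, tiny_reference.annotation,
                      tiny_config.motif)
    assert len(hits) == expected


def test_scan_rejects_bad_alphabet(tiny_reference):
    with pytest.raises(ValueError):
        scan_motif(tiny_reference.genome, tiny_reference.annotation, "UGXAUG")


def test_scan_minus_strand_motif():
    genome = {"c": "A" * 30 + "CATGCA" + "A" * 30}
    ann = type("A", (), {})()
    ann.genes = pd.DataFrame(dict(gene_id=["g"], chrom=["c"], start0=[0],
                                  end0=[66], strand=["-"]))
    hits = scan_motif(genome, ann, "UGCAUG")
    assert len(hits) == 1
    assert (hits["start0"].iloc[0], hits["strand"].iloc[0]) == (30, "-")


# ---------------------------------------------------------- motif fraction
def test_motif_fraction_saturated_and_empty():
    clusters = intervals([("c", 100, 150, "+"), ("c", 300, 360, "+")])
    hits_on = intervals([("c", 120, 126, "+"), ("c", 310, 316, "+")])
    assert motif_fraction(clusters, hits_on) == 1.0
    assert motif_fraction(clusters, hits_on.iloc[:0]) == 0.0
    with pytest.raises(ValueError):
        motif_fraction(clusters.iloc[:0], hits_on)


def test_motif_fraction_hand_count():
    clusters = intervals([
        ("c", 0, 10, "+"),    # hit inside
        ("c", 20, 30, "+"),   # hit on wrong strand
        ("c", 40, 50, "+"),   # 1-nt overlap at end
        ("c", 60, 70, "+"),   # no hit
        ("c", 80, 90, "-"),   # hit on -
    ])
    hits = intervals([("c", 4, 10, "+"), ("c", 22, 28, "-"),
                      ("c", 49, 55, "+"), ("c", 81, 87, "-")])
    assert motif_fraction(clusters, hits) == pytest.approx(3 / 5)


def test_overlap_fraction_identity_and_disjoint():
    clusters = intervals([("c", 0, 10, "+"), ("c", 50, 60, "-")])
    assert overlap_fraction(clusters, clusters.copy()) == 1.0
    other = intervals([("chrX", 0, 100, "+")])
    assert overlap_fraction(clusters, other) == 0.0


# ---------------------------------------------------------------- shuffling
def test_shuffle_preserves_length_strand_and_host(tiny_reference):
    feats = tiny_reference.annotation.features
    introns = feats[feats["kind"] == "intron"].head(6)
    clusters = pd.DataFrame(dict(
        chrom=introns["chrom"].to_numpy(),
        start0=(introns["start0"] + 5).to_numpy(),
        end0=(introns["start0"] + 45).to_numpy(),
        strand=introns["strand"].to_numpy()))
    perms = shuffle_clusters(clusters, tiny_reference.annotation,
                             n_perm=20, seed=5)
    assert len(perms) == 20
    for perm in perms:
        assert ((perm["end0"] - perm["start0"])
                == (clusters["end0"] - clusters["start0"])).all()
        assert (perm["strand"] == clusters["strand"]).all()
        for orig, new in zip(introns.itertuples(), perm.itertuples()):
            assert orig.start0 <= new.start0
            assert new.end0 <= orig.end0


def test_shuffle_clamps_cluster_spanning_whole_feature(tiny_reference):
    feats = tiny_reference.annotation.features
    intron = feats[feats["kind"] == "intron"].iloc[0]
    clusters = pd.DataFrame([dict(chrom=intron["chrom"],
                                  start0=intron["start0"],
                                  end0=intron["end0"],
                                  strand=intron["strand"])])
    perms = shuffle_clusters(clusters, tiny_reference.annotation,
                             n_perm=20, seed=1)
    for perm in perms:
        assert perm["start0"].iloc[0] == intron["start0"]
        assert perm["end0"].iloc[0] == intron["end0"]


def test_shuffle_outside_annotation_raises(tiny_reference):
    far = pd.DataFrame([dict(chrom="chr9", start0=10, end0=60, strand="+")])
    with pytest.raises(ValueError, match="outside"):
        shuffle_clusters(far, tiny_reference.annotation, n_perm=2, seed=0)


def test_shuffle_start_positions_are_uniform(tiny_reference):
    """Chi-square on the permuted starts of one cluster over many draws."""
    feats = tiny_reference.annotation.features
    intron = feats[(feats["kind"] == "intron")
                   & (feats["end0"] - feats["start0"] >= 200)].iloc[0]
    lo, hi = int(intron["start0"]), int(intron["end0"])
    length = 30
    clusters = pd.DataFrame([dict(chrom=intron["chrom"], start0=lo + 50,
                                  end0=lo + 50 + length,
                                  strand=intron["strand"])])
    perms = shuffle_clusters(clusters, tiny_reference.annotation,
                             n_perm=10000, seed=42)
    starts = np.array([p["start0"].iloc[0] for p in perms])
    n_offsets = hi - length - lo + 1
    assert starts.min() >= lo and starts.max() <= hi - length
    n_bins = 10
    edges = np.linspace(lo, hi - length + 1, n_bins + 1)
    observed, _ = np.histogram(starts, bins=edges)
    expected = len(starts) * np.diff(edges) / n_offsets
    chi2 = ((observed - expected) ** 2 / expected).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=n_bins - 1)


# ---------------------------------------------------------- permutation z
def test_permutation_null_identity():
    s = permutation_enrichment(0.2, [0.1, 0.2, 0.3])
    assert s.z_score == pytest.approx(0.0, abs=1e-12)
    assert s.enrichment == pytest.approx(1.0)


def test_permutation_zero_spread_gives_nan_z():
    s = permutation_enrichment(0.10, [0.025] * 20)
    assert math.isnan(s.z_score)
    assert s.enrichment == pytest.approx(4.0)


def test_permutation_zero_mean_gives_infinite_enrichment():
    s = permutation_enrichment(0.4, [0.0] * 5)
    assert math.isinf(s.enrichment)


def test_permutation_matches_hand_formula(rng):
    perm = rng.random(20) * 0.2
    s = permutation_enrichment(0.4, perm)
    assert s.z_score == pytest.approx(
        (0.4 - perm.mean()) / perm.std(ddof=1))
    assert s.enrichment == pytest.approx(0.4 / perm.mean())
    with pytest.raises(ValueError):
        permutation_enrichment(0.4, [0.1])


# ----------------------------------------------------------------- distance
def test_distance_concentric_is_zero():
    clusters = intervals([("c", 100, 110, "+")])
    targets = intervals([("c", 102, 108, "+")])
    assert nearest_feature_distance(clusters, targets)[0] == 0


def test_distance_sign_flips_on_minus_strand():
    clusters = intervals([("c", 100, 110, "-")])
    targets = intervals([("c", 200, 210, "-")])  # 100 nt to the right
    assert nearest_feature_distance(clusters, targets)[0] == -100


def test_distance_ties_break_upstream():
    clusters = intervals([("c", 100, 110, "+")])
    targets = intervals([("c", 55, 65, "+"), ("c", 145, 155, "+")])
    assert nearest_feature_distance(clusters, targets)[0] == -45


def test_distance_matches_exhaustive_scan(rng):
    clusters = intervals([("c", int(s), int(s) + 10, "+")
                          for s in rng.integers(0, 2000, size=5)])
    targets = intervals([("c", int(s), int(s) + 6,
                          "+" if rng.random() < 0.7 else "-")
                         for s in rng.integers(0, 2000, size=7)])
    got = nearest_feature_distance(clusters, targets)
    for i, c in enumerate(clusters.itertuples()):
        cm = (c.start0 + c.end0) // 2
        best = None
        for t in targets.itertuples():
            if t.strand != c.strand:
                continue
            d = (t.start0 + t.end0) // 2 - cm
            if best is None or abs(d) < abs(best) or (
                    abs(d) == abs(best) and d < best):
                best = d
        if best is None:
            assert np.isnan(got[i])
        else:
            assert got[i] == best


# -------------------------------------------------------------- edit radius
def test_edit_radius_identical_samples_is_zero(rng):
    d = rng.integers(0, 800, size=500)
    assert edit_radius(d, d.copy()) == 0


def test_edit_radius_short_case_vs_broad_control(rng):
    case = rng.uniform(0, 50, size=600)
    ctrl = rng.uniform(0, 1000, size=600)
    est = edit_radius(case, ctrl, grid_max=1000)
    assert est <= 60


def test_edit_radius_recovers_mixture_boundary(rng):
    """Case = control + excess below 200; boundary must be found."""
    background = rng.uniform(0, 1000, size=2000)
    excess = rng.uniform(0, 200, size=3000)
    case = np.concatenate([background, excess])
    ctrl = rng.uniform(0, 1000, size=3000)
    est = edit_radius(case, ctrl, grid_max=1000)
    assert 150 <= est <= 250


def test_edit_radius_requires_samples():
    with pytest.raises(ValueError):
        edit_radius([], [1.0])
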
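"""End-to-end study runners on the synthetic experiments.

Three studies exercise the full method, each a pure function of a seed:

* the cluster study: short-read site counts for case / enzyme-only /
  buffer-only in triplicate, through edit calling, Poisson cluster
  detection, replicate intersection and buffer subtraction, and the
  motif-enrichment permutation statistics plus edit-radius estimation;
* the null-FDR study: buffer-only-only simulations across seeds, counting
  false confident clusters;
* the isoform study: long reads for case and enzyme-only in duplicate,
  through read filtering, recurrent/annotated SNP removal, editsC
  quantification, isoform filtering and confident-isoform selection.

The problem sizes here (about 1 Mb of genes for the cluster study, about
200 genes of long reads) are the package's desk-scale study conditions;
the statistics they feed are size-free (rates, fractions, Z-scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import confident as cf
from . import edits, enrichment, isoform
from .clusters import ClusterModel, call_edit_clusters
from .simulate import Reference, SimConfig, generate_reference, \
    simulate_long_reads, simulate_site_counts

#: truth label: an isoform counts as bound when at least this fraction of
#: its exonic Cs lies within the edit radius of a bound motif
BOUND_ISOFORM_MIN_FRACTION = 0.15


def cluster_study_config(seed: int = 0) -> SimConfig:
    """Short-read study: intronic binding sites, triplicate conditions."""
    return SimConfig(seed=seed)


def isoform_study_config(seed: int = 0, bound: bool = True) -> SimConfig:
    """Long-read study: exonic binding, duplicate case/enzyme samples.

    ``bound=False`` yields the matched pure-null experiment (no bound
    motifs) used to calibrate the selection rate.
    """
    return SimConfig(
        seed=seed, n_genes=200, exons_per_gene=(3, 4), exon_len=(150, 250),
        intron_len=(300, 800), utr_len=(100, 150), gene_gap=(150, 300),
        n_bound_motifs=20 if bound else 0, motif_regions="exon",
        n_replicates=2, n_snps=30, alt_isoform_fraction=0.25,
        lr_violation_fraction=0.02)


def null_study_config(seed: int = 0) -> SimConfig:
    """Small buffer-only universe for the false-discovery study."""
    return SimConfig(seed=seed, n_genes=30, intron_len=(800, 2000),
                     n_bound_motifs=0, n_snps=10)


# ------------------------------------------------------------------ helpers
def sites_as_intervals(sites: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(dict(chrom=sites["chrom"], start0=sites["pos0"],
                             end0=sites["pos0"] + 1, strand=sites["strand"]))


def recovery_fraction(truth_motifs: pd.DataFrame, clusters: pd.DataFrame,
                      max_distance: int = 200) -> float:
    """Fraction of truth motifs within ``max_distance`` nt (edge-to-edge)
    of a same-strand cluster."""
    if truth_motifs.empty:
        raise ValueError("no truth motifs")
    widened = clusters.copy()
    widened["start0"] = (clusters["start0"] - max_distance).clip(lower=0)
    widened["end0"] = clusters["end0"] + max_distance
    return float(cf._overlaps_any(truth_motifs.reset_index(drop=True),
                                  widened).mean())


# ------------------------------------------------------------ cluster study
@dataclass
class ClusterStudyResult:
    config: SimConfig
    reference: Reference
    counts: dict = field(default_factory=dict)       # (condition, rep) -> counts
    sites: dict = field(default_factory=dict)        # (condition, rep) -> filtered sites
    clusters: dict = field(default_factory=dict)     # (condition, rep) -> clusters
    confident: dict = field(default_factory=dict)    # condition -> confident set
    p_bg_score: float = float("nan")
    case_motif: enrichment.PermutationSummary | None = None
    enzyme_motif: enrichment.PermutationSummary | None = None
    recovery: float = float("nan")
    precision: dict = field(default_factory=dict)    # set name -> precision
    edit_radius_estimate: int = -1


def run_cluster_study(seed: int = 0, config: SimConfig | None = None,
                      model: ClusterModel | None = None,
                      n_perm: int = 20) -> ClusterStudyResult:
    config = config or cluster_study_config(seed)
    if config.seed != seed:
        config = config.with_seed(seed)
    model = model or ClusterModel()
    reference = generate_reference(config)
    res = ClusterStudyResult(config=config, reference=reference)
    truth = reference.truth

    buffer_counts = [simulate_site_counts(reference, config, "buffer_only", r)
                     for r in range(config.n_replicates)]
    res.p_bg_score = edits.global_edit_fraction(buffer_counts)

    for condition in ("case", "enzyme_only", "buffer_only"):
        for rep in range(config.n_replicates):
            counts = (buffer_counts[rep] if condition == "buffer_only" else
                      simulate_site_counts(reference, config, condition, rep))
            called = edits.call_edit_sites(counts, res.p_bg_score)
            filtered = edits.filter_edit_sites(called, truth.snps)
            res.counts[(condition, rep)] = counts
            res.sites[(condition, rep)] = filtered
            res.clusters[(condition, rep)] = call_edit_clusters(
                filtered, counts, reference.annotation, model)

    buffer_sets = [res.clusters[("buffer_only", r)]
                   for r in range(config.n_replicates)]
    for condition in ("case", "enzyme_only"):
        reps = [res.clusters[(condition, r)]
                for r in range(config.n_replicates)]
        res.confident[condition] = cf.subtract_control(
            cf.intersect_replicates(reps), buffer_sets)
    res.confident["buffer_only"] = cf.intersect_replicates(buffer_sets) \
        if all(len(b) for b in buffer_sets) else buffer_sets[0].iloc[:0]

    # enrichment statistics
    hits = enrichment.scan_motif(reference.genome, reference.annotation,
                                 config.motif)
    case_conf = res.confident["case"]
    if len(case_conf):
        res.case_motif = enrichment.motif_enrichment(
            case_conf, hits, reference.annotation, n_perm=n_perm, seed=seed)
        res.recovery = recovery_fraction(truth.bound_motifs, case_conf,
                                         max_distance=config.edit_radius)
    enz_conf = res.confident["enzyme_only"]
    if len(enz_conf):
        res.enzyme_motif = enrichment.motif_enrichment(
            enz_conf, hits, reference.annotation, n_perm=n_perm, seed=seed + 1)

    # precision: fraction of clusters within the edit radius of a truth motif
    for name, cset in [("replicate0", res.clusters[("case", 0)]),
                       ("confident", case_conf)]:
        if len(cset) and len(truth.bound_motifs):
            res.precision[name] = recovery_fraction(
                cset, truth.bound_motifs, max_distance=config.edit_radius)

    # edit radius: case edit sites inside confident clusters vs enzyme sites
    if len(case_conf):
        case_site_iv = sites_as_intervals(res.sites[("case", 0)])
        in_cluster = cf._overlaps_any(case_site_iv, case_conf)
        enz_sites = pd.concat([res.sites[("enzyme_only", r)]
                               for r in range(config.n_replicates)])
        case_d = enrichment.nearest_feature_distance(
            case_site_iv[in_cluster], truth.bound_motifs)
        ctrl_d = enrichment.nearest_feature_distance(
            sites_as_intervals(enz_sites), truth.bound_motifs)
        res.edit_radius_estimate = enrichment.edit_radius(case_d, ctrl_d)
    return res


# --------------------------------------------------------------- null study
def run_null_fdr_study(seed: int = 0, n_seeds: int = 10,
                       model: ClusterModel | None = None) -> list[int]:
    """Confident-cluster counts from buffer-only triplicates, per seed.

    Everything called here is a false discovery; with BH at FDR 0.1 the
    probability of *any* rejection in a null run is bounded near the FDR
    level, and three-way intersection shrinks it further.
    """
    model = model or ClusterModel()
    counts_out = []
    for i in range(n_seeds):
        config = null_study_config(seed + i)
        reference = generate_reference(config)
        tables = [simulate_site_counts(reference, config, "buffer_only", r)
                  for r in range(config.n_replicates)]
        p_bg = edits.global_edit_fraction(tables)
        cluster_sets = []
        for counts in tables:
            called = edits.call_edit_sites(counts, p_bg)
            filtered = edits.filter_edit_sites(called, reference.truth.snps)
            cluster_sets.append(call_edit_clusters(
                filtered, counts, reference.annotation, model))
        if any(len(c) == 0 for c in cluster_sets):
            counts_out.append(0)
        else:
            counts_out.append(len(cf.intersect_replicates(cluster_sets)))
    return counts_out


# ------------------------------------------------------------ isoform study
@dataclass
class IsoformStudyResult:
    config: SimConfig
    reference: Reference
    profiles: pd.DataFrame
    filtered_profiles: pd.DataFrame
    selection: pd.DataFrame
    sensitivity: float
    selection_rate: float
    replicate_pearson: float
    n_bound_truth: int


def run_isoform_study(seed: int = 0,
                      config: SimConfig | None = None) -> IsoformStudyResult:
    config = config or isoform_study_config(seed)
    if config.seed != seed:
        config = config.with_seed(seed)
    reference = generate_reference(config)
    annotation = reference.annotation
    truth = reference.truth

    samples = {}
    case_samples, control_samples = [], []
    for condition in ("case", "enzyme_only", "buffer_only"):
        for rep in range(config.n_replicates):
            name = f"{condition}_rep{rep}"
            reads = simulate_long_reads(reference, config, condition, rep)
            samples[name] = isoform.filter_long_reads(reads, annotation)
            if condition == "case":
                case_samples.append(name)
            elif condition == "enzyme_only":
                control_samples.append(name)
    # buffer-only replicates join the recurrent-edit detection (a position
    # edited even without enzyme marks a variant, not editing) but carry
    # no editsC profile of interest
    samples = isoform.remove_putative_snps(samples, truth.snps)
    samples = {k: v for k, v in samples.items()
               if not k.startswith("buffer_only")}
    profiles = isoform.editsC_profiles(samples, annotation)
    filtered = isoform.filter_isoforms(profiles, case_samples)
    selection = isoform.select_confident_isoforms(
        filtered[filtered["sample"].isin(case_samples)],
        filtered[filtered["sample"].isin(control_samples)])

    bound_ids = set(truth.isoform_stats.loc[
        truth.isoform_stats["bound_fraction"] >= BOUND_ISOFORM_MIN_FRACTION,
        "isoform_id"])
    selected_ids = set(selection.loc[selection["selected"], "isoform_id"])
    sensitivity = (len(selected_ids & bound_ids) / len(bound_ids)
                   if bound_ids else float("nan"))
    selection_rate = float(selection["selected"].mean())

    case_pivot = profiles[profiles["sample"].isin(case_samples)].pivot_table(
        index="isoform_id", columns="sample", values="editsC").dropna()
    replicate_pearson = float(np.corrcoef(
        case_pivot.iloc[:, 0], case_pivot.iloc[:, 1])[0, 1]) \
        if case_pivot.shape[0] > 2 and case_pivot.shape[1] >= 2 else float("nan")

    return IsoformStudyResult(
        config=config, reference=reference, profiles=profiles,
        filtered_profiles=filtered, selection=selection,
        sensitivity=sensitivity, selection_rate=selection_rate,
        replicate_pearson=replicate_pearson, n_bound_truth=len(bound_ids))
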
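"""File-level pipeline orchestration.

``PipelineConfig`` names the input files (genome, annotation, per-
condition/replicate site-count tables, SNP list, optional long-read
tables and reference peaks) and the thresholds of every stage; it can be
loaded from / saved to YAML. ``run_pipeline`` executes edit calling,
cluster calling per replicate, confident-cluster derivation, motif
enrichment and (when long reads are present) isoform editsC, writing each
stage's output under ``outdir``. All floating-point output is formatted,
and all tables sorted, so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import confident as cf
from . import edits, enrichment, io as dio, isoform
from .clusters import ClusterModel, call_edit_clusters

logger = logging.getLogger(__name__)

CASE, ENZYME, BUFFER = "case", "enzyme_only", "buffer_only"


@dataclass
class PipelineConfig:
    genome: str = ""
    annotation: str = ""
    snps: str = ""
    sites: dict = field(default_factory=dict)   # condition -> [tsv, ...]
    reads: dict = field(default_factory=dict)   # condition -> [tsv, ...]
    peaks: str = ""
    outdir: str = "deamap_out"
    motif: str = "UGCAUG"
    score_min: float = 0.5
    fraction_max: float = 0.8
    p_bg_score: float = 0.005   # used only when no buffer tables are given
    window_len: int = 50
    window_step: int = 10
    fdr: float = 0.1
    merge_distance: int = 15
    n_perm: int = 20
    min_coverage: int = 20
    min_edit_fraction: float = 0.02
    k_std: float = 1.5
    anchor_replicate: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def cluster_model(self) -> ClusterModel:
        return ClusterModel(window_len=self.window_len,
                            window_step=self.window_step,
                            fdr_threshold=self.fdr,
                            merge_distance=self.merge_distance)


def _reorder(paths: list, anchor: int) -> list:
    return [paths[anchor]] + [p for i, p in enumerate(paths) if i != anchor]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every applicable stage; returns a result dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = dio.read_fasta(config.genome)
    annotation = dio.read_gtf(config.annotation)
    snps = dio.read_bed(config.snps) if config.snps else None
    results: dict = {"stage_counts": {}}

    def stage(name, value):
        results["stage_counts"][name] = value
        logger.info("stage %s: %s", name, value)

    # background rate for scoring
    buffer_tables = [dio.read_site_counts(p)
                     for p in config.sites.get(BUFFER, [])]
    p_bg = (edits.global_edit_fraction(buffer_tables) if buffer_tables
            else config.p_bg_score)
    results["p_bg_score"] = p_bg
    logger.info("scoring background rate: %.6g (%s)", p_bg,
                "buffer-only estimate" if buffer_tables else "config constant")

    model = config.cluster_model()
    cluster_sets: dict[str, list[pd.DataFrame]] = {}
    for condition, paths in sorted(config.sites.items()):
        cluster_sets[condition] = []
        for rep, path in enumerate(paths):
            counts = dio.read_site_counts(path)
            called = edits.call_edit_sites(counts, p_bg)
            filtered = edits.filter_edit_sites(
                called, snps, score_min=config.score_min,
                fraction_max=config.fraction_max)
            site_path = out / f"edit_sites_{condition}_rep{rep}.tsv"
            filtered.to_csv(site_path, sep="\t", index=False,
                            float_format="%.6g")
            clusters = call_edit_clusters(filtered, counts, annotation, model)
            bed = clusters.assign(
                name=[f"{condition}_rep{rep}_c{i}" for i in range(len(clusters))])
            dio.write_bed(bed, out / f"clusters_{condition}_rep{rep}.bed",
                          extra_columns=["p_value", "q_value"])
            cluster_sets[condition].append(clusters)
            stage(f"sites_{condition}_rep{rep}", len(filtered))
            stage(f"clusters_{condition}_rep{rep}", len(clusters))

    # confident clusters: intersect case replicates, subtract buffer sets
    buffer_sets = cluster_sets.get(BUFFER, [])
    for condition in (CASE, ENZYME):
        reps = cluster_sets.get(condition, [])
        if len(reps) < 2:
            continue
        reps = _reorder(reps, config.anchor_replicate)
        logger.info("anchor replicate for %s: %d", condition,
                    config.anchor_replicate)
        conf = cf.intersect_replicates(reps)
        if buffer_sets:
            conf = cf.subtract_control(conf, buffer_sets)
        results[f"confident_{condition}"] = conf
        bed = conf.assign(name=[f"{condition}_conf{i}" for i in range(len(conf))])
        dio.write_bed(bed, out / f"confident_{condition}.bed",
                      extra_columns=["p_value", "q_value"])
        stage(f"confident_{condition}", len(conf))

    # enrichment on case confident clusters
    conf = results.get(f"confident_{CASE}")
    if conf is not None and len(conf):
        hits = enrichment.scan_motif(genome, annotation, config.motif)
        summary = enrichment.motif_enrichment(conf, hits, annotation,
                                              n_perm=config.n_perm,
                                              seed=config.seed)
        rows = [dict(statistic="motif_fraction",
                     observed=summary.observed_fraction,
                     perm_mean=float(pd.Series(summary.permuted_fractions).mean()),
                     perm_sd=float(pd.Series(summary.permuted_fractions).std(ddof=1)),
                     z=summary.z_score, enrichment=summary.enrichment,
                     n_perm=summary.n_perm)]
        if config.peaks:
            peaks = dio.read_bed(config.peaks)
            obs = enrichment.overlap_fraction(conf, peaks)
            perms = enrichment.shuffle_clusters(conf, annotation,
                                                n_perm=config.n_perm,
                                                seed=config.seed + 1)
            fr = [enrichment.overlap_fraction(p, peaks) for p in perms]
            s2 = enrichment.permutation_enrichment(obs, fr)
            rows.append(dict(statistic="peak_overlap", observed=obs,
                             perm_mean=float(pd.Series(fr).mean()),
                             perm_sd=float(pd.Series(fr).std(ddof=1)),
                             z=s2.z_score, enrichment=s2.enrichment,
                             n_perm=s2.n_perm))
            dist = enrichment.nearest_feature_distance(conf, peaks)
            pd.DataFrame({"distance": dist}).to_csv(
                out / "peak_distances.tsv", sep="\t", index=False,
                float_format="%.6g")
        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        dist = enrichment.nearest_feature_distance(conf, hits)
        pd.DataFrame({"distance": dist}).to_csv(
            out / "motif_distances.tsv", sep="\t", index=False,
            float_format="%.6g")
        results["enrichment"] = rows

    # isoform stage
    if config.reads:
        samples, case_names, control_names = {}, [], []
        for condition, paths in sorted(config.reads.items()):
            for rep, path in enumerate(paths):
                name = f"{condition}_rep{rep}"
                samples[name] = isoform.filter_long_reads(
                    dio.read_reads(path), annotation)
                if condition == CASE:
                    case_names.append(name)
                elif condition == ENZYME:
                    control_names.append(name)
        # every condition (buffer included) joins recurrent-edit detection;
        # only case and enzyme-only samples are profiled
        samples = isoform.remove_putative_snps(samples, snps)
        samples = {k: v for k, v in samples.items()
                   if k.rsplit("_rep", 1)[0] in (CASE, ENZYME)}
        profiles = isoform.editsC_profiles(samples, annotation)
        profiles.to_csv(out / "editsC.tsv", sep="\t", index=False,
                        float_format="%.6g")
        stage("isoform_profiles", profiles["isoform_id"].nunique())
        filt = isoform.filter_isoforms(
            profiles, case_names,
            isoform.IsoformFilter(min_coverage=config.min_coverage,
                                  min_edit_fraction=config.min_edit_fraction))
        stage("isoforms_passing_filters", filt["isoform_id"].nunique())
        if control_names and filt["isoform_id"].nunique() >= 3:
            sel = isoform.select_confident_isoforms(
                filt[filt["sample"].isin(case_names)],
                filt[filt["sample"].isin(control_names)], k_std=config.k_std)
            sel.to_csv(out / "isoform_selection.tsv", sep="\t", index=False,
                       float_format="%.6g")
            results["isoform_selection"] = sel
            stage("isoforms_selected", int(sel["selected"].sum()))

    pd.Series(results["stage_counts"]).to_csv(out / "stage_counts.tsv",
                                              sep="\t", header=False)
    return results
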
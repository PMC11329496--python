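"""Seeded synthetic transcriptomes with antibody-directed editing.

The generator emulates the data a directed-deaminase profiling experiment
produces: stranded toy genes on a small genome, a set of *bound* motif
occurrences where a tethered cytidine deaminase elevates C-to-U conversion
within a fixed edit radius, uniform background conversion elsewhere
(enzyme-present background, and a lower buffer-only artifact rate), planted
SNP positions that read as near-fixed apparent edits in every condition,
replicate structure, and isoform-resolved long reads.

Everything is a pure function of ``SimConfig.seed``; per-table generators
derive their streams from (seed, condition, replicate) so each table is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import io as dio
from .annotation import EXONIC_KINDS, FeatureAnnotation, features_from_blocks

CONDITIONS = ("case", "enzyme_only", "buffer_only")
_CONDITION_CODE = {c: i for i, c in enumerate(CONDITIONS)}

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def rna_to_dna(motif: str) -> str:
    motif = motif.upper().replace("U", "T")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} is not over the RNA alphabet")
    return motif


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic editing experiment.

    Rates are per-read probabilities that a covered sense-strand C reads as
    T. ``p_bound`` applies in the case condition at C sites within
    ``edit_radius`` nt of a bound motif; ``p_bg_enzyme`` is the free-enzyme
    background (case and enzyme-only), ``p_bg_buffer`` the no-enzyme
    artifact rate. SNPs present an apparent edit fraction of at least
    ``snp_fraction`` in every condition and replicate.
    """

    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (200, 300)
    intron_len: tuple[int, int] = (2000, 6000)
    utr_len: tuple[int, int] = (150, 250)
    gene_gap: tuple[int, int] = (200, 500)
    n_chromosomes: int = 2
    n_bound_motifs: int = 30
    motif: str = "UGCAUG"
    motif_regions: str = "intron"  # "intron" | "exon" | "any"
    edit_radius: int = 200
    p_bound: float = 0.05
    p_bg_enzyme: float = 0.002
    p_bg_buffer: float = 0.0005
    coverage_mean: float = 50.0
    n_replicates: int = 3
    n_snps: int = 50
    snp_fraction: float = 0.9
    # long-read layer
    alt_isoform_fraction: float = 0.0
    lr_reads_per_isoform: int = 24
    lr_p_bound: float = 0.25
    lr_baseline_median: float = 0.03
    lr_baseline_sigma: float = 0.25
    lr_violation_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_bg_buffer <= self.p_bg_enzyme < self.p_bound <= 1.0):
            raise ValueError("require 0 <= p_bg_buffer <= p_bg_enzyme < p_bound <= 1")
        if self.edit_radius < 0:
            raise ValueError("edit_radius must be >= 0")
        for name in ("exons_per_gene", "exon_len", "intron_len", "utr_len", "gene_gap"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.snp_fraction < 0.8:
            raise ValueError("snp_fraction below 0.8 would evade the SNP filter")
        if self.motif_regions not in ("intron", "exon", "any"):
            raise ValueError("motif_regions must be intron/exon/any")
        rna_to_dna(self.motif)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Ground truth of one generated reference.

    ``sites`` lists every transcribed sense-strand C position with its
    gene, distance to the gene's bound motif (-1 when the gene has none),
    the bound mask at the configured edit radius, and the SNP mask.
    """

    bound_motifs: pd.DataFrame
    snps: pd.DataFrame
    sites: pd.DataFrame
    isoform_stats: pd.DataFrame = field(default_factory=pd.DataFrame)


class Reference(NamedTuple):
    genome: dict[str, str]
    annotation: FeatureAnnotation
    truth: SimTruth


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


# ----------------------------------------------------------------- layout
def _draw(rng: np.random.Generator, rng_range: tuple[int, int]) -> int:
    return int(rng.integers(rng_range[0], rng_range[1] + 1))


def generate_reference(config: SimConfig) -> Reference:
    """Build genome, annotation and truth for one synthetic experiment."""
    config.validate()
    rng = _rng(config, 0)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: 0 for c in chrom_names}
    gene_rows, iso_rows, feat_rows = [], [], []

    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_chromosomes]
        strand = "+" if (gi // config.n_chromosomes) % 2 == 0 else "-"
        gene_id = f"g{gi:04d}"
        n_ex = _draw(rng, config.exons_per_gene)
        exon_lens = [_draw(rng, config.exon_len) for _ in range(n_ex)]
        intron_lens = [_draw(rng, config.intron_len) for _ in range(n_ex - 1)]
        utr5, utr3 = _draw(rng, config.utr_len), _draw(rng, config.utr_len)
        # UTRs extend the terminal exon blocks
        if strand == "+":
            exon_lens[0] += utr5
            exon_lens[-1] += utr3
        else:
            exon_lens[-1] += utr5
            exon_lens[0] += utr3
        start = cursors[chrom] + _draw(rng, config.gene_gap)
        blocks = []
        pos = start
        for i, el in enumerate(exon_lens):
            blocks.append((pos, pos + el))
            pos += el
            if i < n_ex - 1:
                pos += intron_lens[i]
        end = pos
        cursors[chrom] = end
        gene_rows.append(dict(gene_id=gene_id, chrom=chrom, start0=start,
                              end0=end, strand=strand))
        blocks_arr = np.array(blocks)
        iso_rows.append(dict(
            isoform_id=f"{gene_id}.t1", gene_id=gene_id, chrom=chrom,
            strand=strand,
            exon_starts=",".join(str(s) for s, _ in blocks),
            exon_ends=",".join(str(e) for _, e in blocks)))
        feat_rows.extend(features_from_blocks(gene_id, chrom, strand,
                                              blocks_arr, utr5, utr3))

    genes = pd.DataFrame(gene_rows)
    features = pd.DataFrame(feat_rows)

    # alternative isoforms: skip one internal exon of eligible genes
    eligible = [i for i, r in enumerate(iso_rows)
                if len(r["exon_starts"].split(",")) >= 3]
    n_alt = int(round(config.alt_isoform_fraction * len(eligible)))
    alt_rows = []
    if n_alt:
        chosen = rng.choice(len(eligible), size=n_alt, replace=False)
        for idx in sorted(chosen):
            g = gene_rows[eligible[idx]]
            base = iso_rows[eligible[idx]]
            starts = base["exon_starts"].split(",")
            ends = base["exon_ends"].split(",")
            skip = int(rng.integers(1, len(starts) - 1))
            alt_rows.append(dict(
                isoform_id=f"{g['gene_id']}.t2", gene_id=g["gene_id"],
                chrom=g["chrom"], strand=g["strand"],
                exon_starts=",".join(s for i, s in enumerate(starts) if i != skip),
                exon_ends=",".join(e for i, e in enumerate(ends) if i != skip)))
    isoforms = pd.DataFrame(iso_rows + alt_rows)
    annotation = FeatureAnnotation(genes=genes, isoforms=isoforms,
                                   features=features)

    # sequence
    genome = {}
    for chrom in chrom_names:
        length = cursors[chrom] + _draw(rng, config.gene_gap)
        genome[chrom] = rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                                   size=length).tobytes().decode()

    motif_dna = rna_to_dna(config.motif)
    truth = _plant_truth(genome, annotation, config, motif_dna, rng)
    return Reference(genome=genome, annotation=annotation, truth=truth)


def _plant_truth(genome, annotation, config, motif_dna, rng) -> SimTruth:
    mlen = len(motif_dna)
    kinds = {"intron": ("intron",), "exon": EXONIC_KINDS,
             "any": ("intron",) + EXONIC_KINDS}[config.motif_regions]
    feats = annotation.features
    eligible = feats[(feats["kind"].isin(kinds))
                     & (feats["end0"] - feats["start0"] >= mlen + 10)]
    genes_with = eligible["gene_id"].unique()
    if config.n_bound_motifs > len(genes_with):
        raise ValueError(
            f"cannot place {config.n_bound_motifs} bound motifs: only "
            f"{len(genes_with)} genes have an eligible {config.motif_regions} "
            "feature (one bound motif per gene)")
    motif_rows = []
    if config.n_bound_motifs:
        chosen_genes = rng.choice(np.sort(genes_with),
                                  size=config.n_bound_motifs, replace=False)
        seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
        for mi, gid in enumerate(sorted(chosen_genes)):
            gf = eligible[eligible["gene_id"] == gid]
            # widest eligible feature hosts the motif
            widths = gf["end0"] - gf["start0"]
            f = gf.loc[widths.idxmax()]
            start = int(rng.integers(f["start0"] + 2, f["end0"] - mlen - 2))
            planted = motif_dna if f["strand"] == "+" else revcomp(motif_dna)
            seqs[f["chrom"]][start:start + mlen] = planted.encode()
            motif_rows.append(dict(chrom=f["chrom"], start0=start,
                                   end0=start + mlen, strand=f["strand"],
                                   gene_id=gid, name=f"m{mi:03d}"))
        for c in genome:
            genome[c] = seqs[c].decode()
    bound_motifs = pd.DataFrame(
        motif_rows, columns=["chrom", "start0", "end0", "strand", "gene_id", "name"])

    snps = _plant_snps(genome, annotation, config, bound_motifs, rng)
    sites = _site_table(genome, annotation, config, bound_motifs, snps)
    iso_stats = _isoform_stats(genome, annotation, config, sites, rng)
    return SimTruth(bound_motifs=bound_motifs, snps=snps, sites=sites,
                    isoform_stats=iso_stats)


def _plant_snps(genome, annotation, config, bound_motifs, rng) -> pd.DataFrame:
    rows, used = [], set()
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    genes = annotation.genes
    guard = 0
    while len(rows) < config.n_snps:
        guard += 1
        if guard > 100 * max(config.n_snps, 1) + 1000:
            raise ValueError("could not place SNPs without motif overlap")
        g = genes.iloc[int(rng.integers(len(genes)))]
        pos = int(rng.integers(g["start0"], g["end0"]))
        key = (g["chrom"], pos)
        if key in used:
            continue
        in_motif = (
            (bound_motifs["chrom"] == g["chrom"])
            & (bound_motifs["start0"] - 1 <= pos)
            & (pos < bound_motifs["end0"] + 1)).any() if len(bound_motifs) else False
        if in_motif:
            continue
        base = b"C" if g["strand"] == "+" else b"G"
        seqs[g["chrom"]][pos:pos + 1] = base
        used.add(key)
        rows.append(dict(chrom=g["chrom"], pos0=pos, strand=g["strand"],
                         gene_id=g["gene_id"]))
    for c in genome:
        genome[c] = seqs[c].decode()
    return pd.DataFrame(rows, columns=["chrom", "pos0", "strand", "gene_id"])


def _site_table(genome, annotation, config, bound_motifs, snps) -> pd.DataFrame:
    """Every transcribed sense-strand C position, with truth columns."""
    frames = []
    motif_by_gene = {r.gene_id: (r.start0, r.end0)
                     for r in bound_motifs.itertuples()}
    for g in annotation.genes.itertuples():
        seq = np.frombuffer(genome[g.chrom][g.start0:g.end0].encode(), dtype="S1")
        sense_c = seq == (b"C" if g.strand == "+" else b"G")
        pos = np.nonzero(sense_c)[0] + g.start0
        if pos.size == 0:
            continue
        if g.gene_id in motif_by_gene:
            ms, me = motif_by_gene[g.gene_id]
            dist = np.maximum(0, np.maximum(ms - pos, pos - (me - 1)))
        else:
            dist = np.full(pos.size, -1)
        frames.append(pd.DataFrame(dict(
            chrom=g.chrom, pos0=pos, strand=g.strand, gene_id=g.gene_id,
            motif_distance=dist)))
    sites = pd.concat(frames, ignore_index=True)
    sites["bound"] = (sites["motif_distance"] >= 0) & (
        sites["motif_distance"] <= config.edit_radius)
    snp_keys = set(zip(snps["chrom"], snps["pos0"]))
    sites["is_snp"] = [
        (c, p) in snp_keys for c, p in zip(sites["chrom"], sites["pos0"])]
    return sites


def _isoform_stats(genome, annotation, config, sites, rng) -> pd.DataFrame:
    """Per-isoform exonic C census, bound fraction and baseline edit rate.

    The per-isoform baseline (log-normal around ``lr_baseline_median``)
    models transcript-to-transcript variation in background deamination and
    is shared across conditions and replicates, which is what makes
    case-versus-control regression of editsC meaningful.
    """
    site_idx = {(c, p): i for i, (c, p) in
                enumerate(zip(sites["chrom"], sites["pos0"]))}
    bound = sites["bound"].to_numpy()
    is_snp = sites["is_snp"].to_numpy()
    rows = []
    for iso in annotation.isoforms.itertuples():
        blocks = annotation.isoform_blocks(iso.isoform_id)
        want = b"C" if iso.strand == "+" else b"G"
        positions = []
        for s, e in blocks:
            seq = np.frombuffer(genome[iso.chrom][s:e].encode(), dtype="S1")
            positions.append(np.nonzero(seq == want)[0] + s)
        pos = np.concatenate(positions) if positions else np.empty(0, dtype=int)
        idx = np.array([site_idx[(iso.chrom, p)] for p in pos], dtype=int)
        n_c = len(pos)
        n_bound = int(bound[idx].sum()) if n_c else 0
        baseline = config.lr_baseline_median * float(
            np.exp(rng.normal(0.0, config.lr_baseline_sigma)))
        rows.append(dict(
            isoform_id=iso.isoform_id, gene_id=iso.gene_id, n_exonic_C=n_c,
            n_bound_C=n_bound,
            bound_fraction=(n_bound / n_c if n_c else 0.0),
            n_snp_C=int(is_snp[idx].sum()) if n_c else 0,
            baseline=baseline,
            positions=",".join(map(str, pos))))
    return pd.DataFrame(rows)


# --------------------------------------------------------------- counts
def simulate_site_counts(reference: Reference, config: SimConfig,
                         condition: str, replicate: int) -> pd.DataFrame:
    """Per-site coverage/edit counts for one condition and replicate.

    Coverage is per-site independent Poisson(``coverage_mean``); edited
    reads are Binomial(coverage, p_site). Sites with zero coverage are not
    emitted. SNP positions show ``ceil(coverage * snp_fraction)`` edited
    reads in every condition, guaranteeing an apparent fraction at or above
    ``snp_fraction``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if not (0 <= replicate < config.n_replicates):
        raise ValueError(f"replicate {replicate} out of range")
    rng = _rng(config, 1, _CONDITION_CODE[condition], replicate)
    sites = reference.truth.sites
    n = len(sites)
    if condition == "case":
        p = np.where(sites["bound"], config.p_bound, config.p_bg_enzyme)
    elif condition == "enzyme_only":
        p = np.full(n, config.p_bg_enzyme)
    else:
        p = np.full(n, config.p_bg_buffer)
    coverage = rng.poisson(config.coverage_mean, size=n)
    edited = rng.binomial(coverage, p)
    snp = sites["is_snp"].to_numpy()
    edited[snp] = np.ceil(coverage[snp] * config.snp_fraction).astype(int)
    keep = coverage > 0
    return pd.DataFrame(dict(
        chrom=sites["chrom"].to_numpy()[keep],
        pos0=sites["pos0"].to_numpy()[keep],
        strand=sites["strand"].to_numpy()[keep],
        ref_count=(coverage - edited)[keep],
        alt_count=edited[keep]))


# ------------------------------------------------------------ long reads
def simulate_long_reads(reference: Reference, config: SimConfig,
                        condition: str, replicate: int) -> pd.DataFrame:
    """Isoform-assigned long reads with per-C edit calls.

    Each read spans its whole isoform (exons and UTRs). Per-C conversion
    probability is the isoform baseline, replaced by ``lr_p_bound`` at
    bound Cs in the case condition and by ``p_bg_buffer`` throughout in the
    buffer-only condition; SNP Cs convert with ``snp_fraction`` everywhere.
    A fraction ``lr_violation_fraction`` of reads per isoform is planted
    with each disqualifying property (quality < 20, unmapped, secondary,
    supplementary, wrong strand) to exercise the read filters.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if not (0 <= replicate < config.n_replicates):
        raise ValueError(f"replicate {replicate} out of range")
    rng = _rng(config, 2, _CONDITION_CODE[condition], replicate)
    truth = reference.truth
    bound = truth.sites["bound"].to_numpy()
    is_snp = truth.sites["is_snp"].to_numpy()
    site_idx = {(c, p): i for i, (c, p) in
                enumerate(zip(truth.sites["chrom"], truth.sites["pos0"]))}

    iso_meta = reference.annotation.isoforms.set_index("isoform_id")
    rows = []
    for iso in truth.isoform_stats.itertuples():
        pos = dio.parse_edit_positions(iso.positions)
        chrom = iso_meta.at[iso.isoform_id, "chrom"]
        strand = iso_meta.at[iso.isoform_id, "strand"]
        idx = (np.array([site_idx[(chrom, p)] for p in pos], dtype=int)
               if len(pos) else np.empty(0, dtype=int))
        if condition == "case":
            p_vec = np.where(bound[idx], config.lr_p_bound, iso.baseline)
        elif condition == "enzyme_only":
            p_vec = np.full(len(pos), iso.baseline)
        else:
            p_vec = np.full(len(pos), config.p_bg_buffer)
        p_vec = np.where(is_snp[idx], config.snp_fraction, p_vec)

        n_reads = config.lr_reads_per_isoform
        calls = rng.random((n_reads, len(pos))) < p_vec
        quality = np.clip(rng.normal(30.0, 3.0, size=n_reads), 20.5, None)
        mapped = np.ones(n_reads, dtype=bool)
        secondary = np.zeros(n_reads, dtype=bool)
        supplementary = np.zeros(n_reads, dtype=bool)
        strands = np.full(n_reads, strand)
        n_bad = int(round(config.lr_violation_fraction * n_reads))
        cursor = 0
        for prop in range(5):
            sel = slice(cursor, cursor + n_bad)
            if prop == 0:
                quality[sel] = 10.0
            elif prop == 1:
                mapped[sel] = False
            elif prop == 2:
                secondary[sel] = True
            elif prop == 3:
                supplementary[sel] = True
            else:
                strands[sel] = "-" if strand == "+" else "+"
            cursor += n_bad
        for ri in range(n_reads):
            edited_pos = pos[calls[ri]]
            rows.append(dict(
                read_id=f"{iso.isoform_id}.{condition}.r{replicate}.{ri}",
                isoform_id=iso.isoform_id,
                mapped=bool(mapped[ri]), secondary=bool(secondary[ri]),
                supplementary=bool(supplementary[ri]),
                quality=round(float(quality[ri]), 2), strand=strands[ri],
                edited_C=int(calls[ri].sum()), total_C=len(pos),
                edit_positions=",".join(map(str, edited_pos))))
    return pd.DataFrame(rows, columns=dio.READ_COLUMNS)


# ---------------------------------------------------------------- bundle
def write_fixture_bundle(reference: Reference, config: SimConfig,
                         directory: str | Path,
                         include_long_reads: bool = False) -> dict[str, Path]:
    """Write the complete synthetic dataset to ``directory``.

    Emits genome FASTA, annotation GTF, truth BEDs (bound motifs, SNPs) and
    per-condition/replicate site-count TSVs (plus long-read TSVs when
    requested). Everything round-trips through :mod:`deamap.io`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = directory / "genome.fa"
    dio.write_fasta(reference.genome, paths["genome"])
    paths["annotation"] = directory / "annotation.gtf"
    dio.write_gtf(reference.annotation, paths["annotation"])

    motifs = reference.truth.bound_motifs.copy()
    paths["truth_motifs"] = directory / "truth_motifs.bed"
    dio.write_bed(motifs.assign(score=0.0), paths["truth_motifs"])
    snps = reference.truth.snps
    snp_iv = pd.DataFrame(dict(chrom=snps["chrom"], start0=snps["pos0"],
                               end0=snps["pos0"] + 1,
                               name=[f"snp{i}" for i in range(len(snps))],
                               score=0.0, strand=snps["strand"]))
    paths["truth_snps"] = directory / "truth_snps.bed"
    dio.write_bed(snp_iv, paths["truth_snps"])

    for condition in CONDITIONS:
        for rep in range(config.n_replicates):
            key = f"sites_{condition}_rep{rep}"
            paths[key] = directory / f"{key}.tsv"
            dio.write_site_counts(
                simulate_site_counts(reference, config, condition, rep),
                paths[key])
            if include_long_reads:
                key = f"reads_{condition}_rep{rep}"
                paths[key] = directory / f"{key}.tsv"
                dio.write_reads(
                    simulate_long_reads(reference, config, condition, rep),
                    paths[key])
    return paths
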
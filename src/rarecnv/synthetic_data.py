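"""Seeded synthetic cohorts with known ground truth.

Generates case/control rosters with QC metrics, background rare CNVs,
locus-specific enrichment with a chosen control frequency and odds
ratio, planted common (>= 1%) CNV groups, planted QC-outlier samples, a
toy gene annotation, and Log R Ratio matrices with carrier intensity
shifts.  Every pipeline stage can therefore run against data whose
truth is recorded, with byte-identical output for a fixed seed.

The defaults mirror the study regime the package targets: 2591 cases
against 8842 controls, rare background CNVs of 10 kb-2 Mb, and
locus-level carrier frequencies in the 0.01-0.3% range with odds ratios
of a few.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cnv_data import (
    DELETION,
    DUPLICATION,
    CnvCall,
    GeneModel,
    LocusDef,
    SampleRecord,
    write_cnv_table,
    write_fam,
    write_gene_models,
    write_locus_table,
)
from .locus_association import case_frequency_from_or, odds_ratio as table_odds_ratio
from .qc_filtering import LrrMatrix


@dataclass(frozen=True)
class LocusSpec:
    """Planted enrichment at one locus: control frequency and odds ratio."""

    locus: LocusDef
    control_freq: float
    odds_ratio: float

    def __post_init__(self):
        if not (0 <= self.control_freq < 1):
            raise ValueError(f"{self.locus.name}: control_freq must be in [0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.locus.name}: odds_ratio must be > 0")

    @property
    def case_freq(self) -> float:
        f = case_frequency_from_or(self.control_freq, self.odds_ratio)
        if f > 1:
            raise ValueError(f"{self.locus.name}: implied case frequency > 1")
        return f


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``background_rate`` is the mean number of rare background CNVs per
    sample (Poisson); sizes are log-uniform over ``size_range`` (bp) and
    positions uniform on the toy genome.  ``del_shift``/``dup_shift``
    are the Log R Ratio offsets of carrier probes against noise of s.d.
    ``lrr_noise_sd`` — typical Illumina-array magnitudes.
    """

    n_cases: int = 2591
    n_controls: int = 8842
    background_rate: float = 3.0
    size_range: tuple[int, int] = (10_000, 2_000_000)
    locus_specs: tuple[LocusSpec, ...] = ()
    n_chroms: int = 2
    chrom_length_bp: int = 50_000_000
    gene_count: int = 200
    exons_per_gene: int = 10
    n_common_cnvs: int = 0
    common_freq: float = 0.02
    n_outliers: int = 0
    lrr_noise_sd: float = 0.15
    del_shift: float = -0.45
    dup_shift: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not (self.del_shift < 0 < self.dup_shift):
            raise ValueError("need del_shift < 0 < dup_shift")
        if not (0 < self.common_freq <= 1):
            raise ValueError("common_freq must be in (0, 1]")
        lo, hi = self.size_range
        if not (0 < lo < hi):
            raise ValueError("size_range must be increasing and positive")
        for spec in self.locus_specs:
            spec.case_freq  # raises if the implied case frequency is invalid


@dataclass
class GroundTruth:
    """What was planted: the answer key for every downstream stage."""

    locus_carriers: dict[str, set[str]] = field(default_factory=dict)
    outlier_samples: set[str] = field(default_factory=set)
    common_groups: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "locus_carriers": {k: sorted(v) for k, v in self.locus_carriers.items()},
            "outlier_samples": sorted(self.outlier_samples),
            "common_groups": [
                {**g, "samples": sorted(g["samples"])} for g in self.common_groups
            ],
        }, indent=1, sort_keys=True)


@dataclass
class SimulatedCohort:
    roster: list[SampleRecord]
    calls: list[CnvCall]
    genes: list[GeneModel]
    truth: GroundTruth
    config: SimConfig


def toy_genes(config: SimConfig) -> list[GeneModel]:
    """Deterministic toy annotation: genes evenly spaced on each chromosome.

    Each gene spans 30 kb with ``exons_per_gene`` 2-kb exons evenly
    spread across the span, alternating strand.
    """
    genes = []
    per_chrom = config.gene_count // config.n_chroms
    span = 30_000
    exon_len = 2_000
    for ci in range(config.n_chroms):
        chrom = str(ci + 1)
        spacing = (config.chrom_length_bp - 2 * span) // max(per_chrom, 1)
        for gi in range(per_chrom):
            tx_start = span + gi * spacing + 1
            step = (span - exon_len) // max(config.exons_per_gene - 1, 1)
            exons = tuple(
                (tx_start + k * step, tx_start + k * step + exon_len - 1)
                for k in range(config.exons_per_gene)
            )
            genes.append(GeneModel(
                gene_name=f"G{ci * per_chrom + gi + 1:04d}",
                chrom=chrom,
                strand="+" if gi % 2 == 0 else "-",
                tx_start_bp=tx_start,
                tx_end_bp=exons[-1][1],
                exons=exons,
            ))
    return genes


def simulate_cohort(config: SimConfig, seed: int | None = None) -> SimulatedCohort:
    """Draw a full synthetic cohort; identical seed gives identical output."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = GroundTruth()

    n_total = config.n_cases + config.n_controls
    ids = [f"case{i + 1:05d}" for i in range(config.n_cases)] + \
          [f"ctrl{i + 1:05d}" for i in range(config.n_controls)]
    phenotypes = ["case"] * config.n_cases + ["control"] * config.n_controls
    cohorts = ["cases"] * config.n_cases + ["controls"] * config.n_controls

    calls: list[CnvCall] = []

    # background rare CNVs
    bg_counts = rng.poisson(config.background_rate, size=n_total)
    lo, hi = config.size_range
    for i, k in enumerate(bg_counts):
        for _ in range(k):
            size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            chrom = str(rng.integers(1, config.n_chroms + 1))
            start = int(rng.integers(1, max(config.chrom_length_bp - size, 2)))
            cnv_type = DELETION if rng.random() < 0.5 else DUPLICATION
            calls.append(CnvCall(
                sample_id=ids[i], chrom=chrom,
                start_bp=start, end_bp=start + size - 1,
                cnv_type=cnv_type,
                n_probes=max(1, size // 2500),
                confidence=float(np.round(rng.uniform(10, 100), 1)),
            ))

    # planted common CNV groups (identical event shared by >= common_freq of samples)
    for g in range(config.n_common_cnvs):
        size = 100_000
        chrom = str(g % config.n_chroms + 1)
        start = int(rng.integers(1, config.chrom_length_bp - size))
        cnv_type = DELETION if g % 2 == 0 else DUPLICATION
        n_carriers = int(np.ceil(config.common_freq * n_total))
        members = rng.choice(n_total, size=n_carriers, replace=False)
        for i in members:
            calls.append(CnvCall(
                sample_id=ids[i], chrom=chrom,
                start_bp=start, end_bp=start + size - 1,
                cnv_type=cnv_type, n_probes=size // 2500,
            ))
        truth.common_groups.append({
            "chrom": chrom, "start_bp": start, "end_bp": start + size - 1,
            "cnv_type": cnv_type, "samples": {ids[i] for i in members},
        })

    # locus-specific enrichment
    for spec in config.locus_specs:
        f_case, f_ctrl = spec.case_freq, spec.control_freq
        carriers: set[str] = set()
        draws = rng.random(n_total)
        for i in range(n_total):
            f = f_case if phenotypes[i] == "case" else f_ctrl
            if draws[i] < f:
                carriers.add(ids[i])
                calls.append(CnvCall(
                    sample_id=ids[i], chrom=spec.locus.chrom,
                    start_bp=spec.locus.start_bp, end_bp=spec.locus.end_bp,
                    cnv_type=spec.locus.cnv_type,
                    n_probes=spec.locus.length_bp // 2500,
                ))
        truth.locus_carriers[spec.locus.name] = carriers

    # per-sample QC metrics, with planted outliers
    lrr_sd = rng.normal(0.12, 0.012, size=n_total)
    baf_drift = rng.normal(0.002, 0.0004, size=n_total)
    wave = rng.normal(0.0, 0.01, size=n_total)
    if config.n_outliers:
        outlier_idx = rng.choice(n_total, size=config.n_outliers, replace=False)
        lrr_sd[outlier_idx] = 0.6  # far outside median +/- 3 IQR
        truth.outlier_samples = {ids[i] for i in outlier_idx}
    per_sample_calls = {sid: 0 for sid in ids}
    for c in calls:
        per_sample_calls[c.sample_id] += 1
    roster = [
        SampleRecord(
            sample_id=ids[i], phenotype=phenotypes[i], cohort=cohorts[i],
            qc_metrics={
                "lrr_sd": float(lrr_sd[i]),
                "baf_drift": float(baf_drift[i]),
                "wave_factor": float(wave[i]),
                "cnv_count": float(per_sample_calls[ids[i]]),
            },
        )
        for i in range(n_total)
    ]

    calls.sort(key=lambda c: (c.chrom, c.start_bp, c.end_bp, c.sample_id, c.cnv_type))
    return SimulatedCohort(roster=roster, calls=calls, genes=toy_genes(config),
                           truth=truth, config=config)


def simulate_lrr(
    region: tuple[str, int, int],
    sample_ids: Sequence[str],
    carriers: Mapping[str, str],
    config: SimConfig,
    n_probes: int = 40,
    seed: int | None = None,
) -> LrrMatrix:
    """Log R Ratio matrix over a region with carrier probes shifted.

    ``carriers`` maps sample id to ``del``/``dup``; their probes inside
    the region are offset by ``del_shift``/``dup_shift`` on top of
    N(0, lrr_noise_sd) noise shared by everyone.
    """
    chrom, start, end = region
    if n_probes < 1 or end - start + 1 < n_probes:
        raise ValueError("region too small for the requested probe count")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    positions = np.linspace(start, end, n_probes).astype(np.int64)
    positions = np.unique(positions)
    values = rng.normal(0.0, config.lrr_noise_sd, size=(len(positions), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        if sid in carriers:
            shift = config.del_shift if carriers[sid] == DELETION else config.dup_shift
            values[:, j] += shift
    return LrrMatrix(
        chroms=[chrom] * len(positions),
        positions=positions,
        sample_ids=list(sample_ids),
        values=values,
    )


def published_locus_specs(min_or: float = 1.0) -> list[LocusSpec]:
    """Locus specs taken from the bundled published carrier counts.

    Control frequency is the published pooled control rate; the odds
    ratio is the published-count OR where defined, else ``min_or``.
    """
    from .cnv_data import bundled_locus_counts, bundled_sz_loci
    from .cnv_data import ContingencyTable

    counts = bundled_locus_counts().set_index("locus")
    specs = []
    for locus in bundled_sz_loci():
        row = counts.loc[locus.name]
        table = ContingencyTable(
            a=int(row.bd_carriers), b=int(row.bd_total - row.bd_carriers),
            c=int(row.control_carriers),
            d=int(row.control_total - row.control_carriers),
        )
        orr = table_odds_ratio(table)
        specs.append(LocusSpec(
            locus=locus,
            control_freq=row.control_carriers / row.control_total,
            odds_ratio=orr if orr is not None else min_or,
        ))
    return specs


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Emit the cohort as PLINK .cnv/.fam, BED, refFlat and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cnv": outdir / "sim.cnv",
        "fam": outdir / "sim.fam",
        "bed": outdir / "sim_calls.bed",
        "refflat": outdir / "sim_genes.refflat",
        "truth": outdir / "ground_truth.json",
    }
    write_cnv_table(cohort.calls, paths["cnv"], format="plink_cnv")
    write_cnv_table(cohort.calls, paths["bed"], format="bed")
    write_fam(cohort.roster, paths["fam"])
    write_gene_models(cohort.genes, paths["refflat"])
    paths["truth"].write_text(cohort.truth.to_json() + "\n")
    if cohort.config.locus_specs:
        paths["loci"] = outdir / "sim_loci.tsv"
        write_locus_table([s.locus for s in cohort.config.locus_specs],
                          paths["loci"], units="bp")
    return paths
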
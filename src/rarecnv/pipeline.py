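"""Pipeline orchestration: configuration, stage running and report rendering.

Stages run in the fixed order qc -> locus -> gene -> burden.  Each stage
writes a machine-readable TSV plus a JSON metrics sidecar; a manifest
records the configuration hash, seed and package version so a run is
fully reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .burden_analysis import BurdenModel, DEFAULT_N_PERM
from .cnv_data import bundled_sz_loci, read_cnv_table, read_fam, read_gene_models, read_locus_table
from .gene_scan import GeneScanModel
from .locus_association import CohortCounts, LocusAssociationResults, LocusAssociationModel
from .qc_filtering import (
    QcConfig,
    exclude_outlier_samples,
    filter_autosomal,
    filter_by_frequency,
    filter_by_probes,
    write_qc_report,
)

log = logging.getLogger("rarecnv")

STAGES = ("qc", "locus", "gene", "burden")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly to YAML."""

    cnv_path: str
    fam_path: str
    out_dir: str
    locus_path: str | None = None  # None -> bundled 15-locus table
    locus_units: str = "bp"
    gene_path: str | None = None
    gene_format: str = "refflat"
    cnv_format: str = "plink_cnv"
    qc: QcConfig = field(default_factory=QcConfig)
    min_locus_coverage: float = 0.5
    n_regions: int = 120
    alpha: float = 0.05
    gene_min_size_bp: int = 10_000
    burden_groups: tuple[str, str] = ("case", "control")
    burden_group_by: str = "phenotype"
    burden_exclude_loci: bool = False
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self._as_dict(), sort_keys=True))

    def _as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qc"] = dataclasses.asdict(self.qc)
        d["burden_groups"] = list(self.burden_groups)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        qc = QcConfig(**raw.pop("qc", {}))
        raw["burden_groups"] = tuple(raw.get("burden_groups", ("case", "control")))
        return cls(qc=qc, **raw)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self._as_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _sidecar(path: Path, metrics: Mapping) -> None:
    path.with_suffix(".json").write_text(json.dumps(metrics, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES) -> dict:
    """Run the requested stages in fixed order; returns the run manifest.

    A failing stage marks the manifest ``failed`` and later stages are
    skipped; artifacts written so far are listed as partial.
    """
    logging.basicConfig(level=config.log_level)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "status": "ok",
        "artifacts": [],
    }

    calls = read_cnv_table(config.cnv_path, format=config.cnv_format)
    roster = read_fam(config.fam_path)
    loci = (read_locus_table(config.locus_path, units=config.locus_units)
            if config.locus_path else bundled_sz_loci())
    log.info("loaded %d calls, %d samples, %d loci", len(calls), len(roster), len(loci))

    def emit(name: str, write, metrics: Mapping) -> None:
        path = outdir / name
        write(path)
        _sidecar(path, metrics)
        manifest["artifacts"] += [str(path), str(path.with_suffix(".json"))]

    try:
        for stage in stages:
            if stage == "qc":
                n0 = len(calls)
                if config.qc.autosomes_only:
                    calls = filter_autosomal(calls)
                n_auto = len(calls)
                calls = filter_by_probes(calls, config.qc.min_probes)
                n_probes = len(calls)
                calls = filter_by_frequency(
                    calls, roster, config.qc.freq_threshold, config.qc.overlap_fraction
                )
                log.info("qc: %d calls in, %d autosomal, %d probe-filtered, %d rare",
                         n0, n_auto, n_probes, len(calls))
                excluded = []
                if all(s.qc_metrics for s in roster):
                    kept, excluded = exclude_outlier_samples(roster, config.qc.outlier_k)
                    drop = {s.sample_id for s, _ in excluded}
                    roster = kept
                    calls = [c for c in calls if c.sample_id not in drop]
                    log.info("qc: excluded %d outlier samples", len(excluded))
                else:
                    kept = roster
                    log.info("qc: roster carries no QC metrics; "
                             "outlier exclusion skipped")
                from .cnv_data import write_cnv_table

                emit("qc_calls.cnv",
                     lambda p: write_cnv_table(calls, p),
                     {"calls_in": n0, "autosomal": n_auto,
                      "probe_filtered": n_probes, "rare": len(calls),
                      "samples_excluded": len(excluded), "samples_kept": len(roster)})
                if excluded or all(s.qc_metrics for s in roster):
                    emit("qc_samples.tsv",
                         lambda p: write_qc_report(excluded, kept, p),
                         {"excluded": len(excluded)})
            elif stage == "locus":
                res = LocusAssociationModel(
                    calls, roster, loci,
                    min_locus_coverage=config.min_locus_coverage,
                    n_regions=config.n_regions, alpha=config.alpha,
                ).fit()
                emit("locus_association.tsv", res.to_tsv,
                     {"n_loci": len(res.results),
                      "threshold": res.threshold,
                      "n_genomewide": sum(r.significant_genomewide for r in res)})
            elif stage == "gene":
                if config.gene_path is None:
                    log.info("gene: no gene model file configured; stage skipped")
                    continue
                genes = read_gene_models(config.gene_path, format=config.gene_format)
                res = GeneScanModel(
                    calls, roster, genes, excluded_loci=loci,
                    min_size_bp=config.gene_min_size_bp,
                    min_locus_coverage=config.min_locus_coverage,
                ).fit()
                emit("gene_scan.tsv", res.to_tsv,
                     {"n_genes": len(genes), "n_nominal": len(res.nominal),
                      "n_regions": res.n_regions,
                      "n_genewide": len(res.genomewide)})
            elif stage == "burden":
                res = BurdenModel(
                    calls, roster,
                    groups=config.burden_groups, group_by=config.burden_group_by,
                    exclude_loci=loci if config.burden_exclude_loci else (),
                    min_locus_coverage=config.min_locus_coverage,
                ).fit(n_perm=config.n_perm, seed=config.seed)
                emit("burden.tsv", res.to_tsv,
                     {"n_perm": config.n_perm, "seed": config.seed,
                      "p_values": {f"{r.stratum[0]}_{r.cnv_type}": r.p_perm
                                   for r in res}})
    except Exception as exc:  # stage failure: flag, keep partial artifacts
        log.error("stage %r failed: %s", stage, exc)
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def render_table1(
    results: LocusAssociationResults | Sequence,
    cohort_blocks: Mapping[str, Mapping[str, CohortCounts]] | None = None,
    loci: Sequence | None = None,
) -> str:
    """Human-readable locus table: per-cohort %(n/N), OR (CI), p.

    ``cohort_blocks`` maps cohort name -> {locus name -> CohortCounts};
    an empty block is dropped with a warning.  Percentages are shown to
    2 significant figures; the machine TSV keeps full precision.
    """
    rows = list(results)
    blocks = dict(cohort_blocks or {})
    for name in [n for n, b in blocks.items() if not b]:
        log.warning("cohort block %r is empty; column omitted", name)
        del blocks[name]
    positions = {l.name: f"chr{l.chrom}:{l.start_bp / 1e6:.2f}-{l.end_bp / 1e6:.2f}"
                 for l in (loci or [])}

    def pct(n: int, total: int) -> str:
        return f"{100 * n / total:.2g}% ({n}/{total})" if total else "NA"

    header = ["locus", "position"] + list(blocks) + \
             ["cases %(n/N)", "controls %(n/N)", "OR (95% CI)", "P-value"]
    out = ["\t".join(header)]
    for r in rows:
        t = r.table
        cells = [r.locus, positions.get(r.locus, "")]
        for name in blocks:
            cc = blocks[name].get(r.locus)
            cells.append(pct(cc.carriers, cc.total) if cc else "")
        orci = (f"{r.odds_ratio:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
                if r.odds_ratio is not None else "NA")
        cells += [pct(t.a, t.n_cases), pct(t.c, t.n_controls), orci,
                  f"{r.p_value:.2g}"]
        out.append("\t".join(cells))
    return "\n".join(out) + "\n"


def render_table2(results) -> str:
    """Human-readable burden table mirroring the machine TSV."""
    rows = list(results)
    if not rows:
        return "stratum\ttype\n"
    ga, gb = rows[0].group_a, rows[0].group_b
    from .burden_analysis import stratum_label

    out = ["\t".join(["size range", "CNV type", f"{ga} freq (n)",
                      f"{gb} freq (n)", "P-value"])]
    for r in rows:
        out.append("\t".join([
            stratum_label(r.stratum), r.cnv_type,
            f"{r.rate_a_pct:.2g}% ({r.count_a})",
            f"{r.rate_b_pct:.2g}% ({r.count_b})",
            f"{r.p_perm:.2g}",
        ]))
    return "\n".join(out) + "\n"
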
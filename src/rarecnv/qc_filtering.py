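"""Sample- and call-level quality control.

Four stages: robust outlier-sample exclusion per cohort, population
frequency filtering by reciprocal overlap (rare means <1% by default),
size filtering with a strict-lower/inclusive-upper convention, and a
median Z-score intensity check that validates a call against the Log R
Ratio distribution of all samples over the call's probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .cnv_data import AUTOSOMES, DELETION, DUPLICATION, CnvCall, SampleRecord

MIN_COHORT_SIZE = 8  # robust statistics need a handful of samples


@dataclass
class QcConfig:
    """Thresholds for the QC stage.

    outlier_k
        half-width of the per-cohort acceptance band in IQR units
        (median +/- k*IQR).
    freq_threshold
        population frequency at or above which a CNV is considered
        common and removed (default 1%).
    overlap_fraction
        reciprocal overlap fraction used to group CNVs when estimating
        their population frequency (default 0.5).
    min_probes
        minimum supporting array probes per call; calls without probe
        annotation are kept.
    zscore_threshold
        |z| needed for the median Z-score intensity validation.
    autosomes_only
        drop chrX/chrY calls before analysis.
    """

    outlier_k: float = 3.0
    freq_threshold: float = 0.01
    overlap_fraction: float = 0.5
    min_probes: int = 10
    zscore_threshold: float = 2.0
    autosomes_only: bool = True

    def __post_init__(self):
        if not (0 < self.freq_threshold <= 1):
            raise ValueError("freq_threshold must be in (0, 1]")
        if not (0 < self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.outlier_k <= 0 or self.zscore_threshold <= 0:
            raise ValueError("outlier_k and zscore_threshold must be > 0")
        if self.min_probes < 0:
            raise ValueError("min_probes must be >= 0")


@dataclass
class LrrMatrix:
    """Per-probe Log R Ratios for a set of samples.

    ``values`` has one row per probe (positions ascending within each
    chromosome) and one column per sample.
    """

    chroms: Sequence[str]
    positions: np.ndarray
    sample_ids: Sequence[str]
    values: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.positions), len(self.sample_ids)):
            raise ValueError("LRR matrix dimensions inconsistent")
        if len(self.chroms) != len(self.positions):
            raise ValueError("one chromosome label per probe required")
        for chrom in set(self.chroms):
            pos = self.positions[[c == chrom for c in self.chroms]]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"probe positions not strictly increasing on {chrom}")

    def probe_mask(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        on_chrom = np.array([c == chrom for c in self.chroms])
        return on_chrom & (self.positions >= start_bp) & (self.positions <= end_bp)


@dataclass(frozen=True)
class ZscoreResult:
    validated: bool
    z: float | None
    reason: str | None = None


def exclude_outlier_samples(
    roster: Sequence[SampleRecord], k: float = 3.0
) -> tuple[list[SampleRecord], list[tuple[SampleRecord, list[str]]]]:
    """Exclude samples that are QC outliers within their own cohort.

    A sample is excluded iff any metric falls outside
    [median - k*IQR, median + k*IQR] of that metric in its cohort.  With a
    degenerate (zero-IQR) metric, any value different from the median is
    an outlier.  Returns ``(kept, excluded)`` with per-sample reasons.
    """
    cohorts: dict[str, list[SampleRecord]] = {}
    for s in roster:
        if not s.qc_metrics:
            raise ValueError(f"sample {s.sample_id} has no QC metrics")
        cohorts.setdefault(s.cohort, []).append(s)

    kept: list[SampleRecord] = []
    excluded: list[tuple[SampleRecord, list[str]]] = []
    for cohort, members in cohorts.items():
        if len(members) < MIN_COHORT_SIZE:
            raise ValueError(
                f"cohort {cohort!r} has {len(members)} samples; "
                f">= {MIN_COHORT_SIZE} required for outlier detection"
            )
        metrics = sorted({m for s in members for m in s.qc_metrics})
        bounds = {}
        for m in metrics:
            vals = np.array([float(s.qc_metrics[m]) for s in members])
            med = np.median(vals)
            q75, q25 = np.percentile(vals, [75, 25])
            iqr = q75 - q25
            bounds[m] = (med - k * iqr, med + k * iqr)
        for s in members:
            reasons = [
                m for m in metrics
                if not (bounds[m][0] <= float(s.qc_metrics[m]) <= bounds[m][1])
            ]
            if reasons:
                excluded.append((s, reasons))
            else:
                kept.append(s)
    return kept, excluded


def reciprocal_overlap(call_a: CnvCall, call_b: CnvCall) -> float:
    """Smaller of the two mutual overlap fractions (0 when disjoint)."""
    if call_a.chrom != call_b.chrom:
        return 0.0
    ov = call_a.overlap_bp(call_b.start_bp, call_b.end_bp)
    return min(ov / call_a.length_bp, ov / call_b.length_bp)


def call_frequencies(
    calls: Sequence[CnvCall],
    roster: Sequence[SampleRecord],
    overlap_fraction: float = 0.5,
) -> np.ndarray:
    """Population frequency of each call.

    A call's frequency is the number of distinct samples (cases and
    controls pooled) carrying a same-type call that reciprocally overlaps
    it by at least ``overlap_fraction``, divided by the roster size.  The
    call's own carrier always counts, so frequencies are >= 1/N.
    """
    if not roster:
        raise ValueError("empty roster")
    n = len(roster)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for idx, c in enumerate(calls):
        trees.setdefault((c.chrom, c.cnv_type), IntervalTree()).addi(
            c.start_bp, c.end_bp + 1, idx
        )
    freqs = np.empty(len(calls))
    for i, c in enumerate(calls):
        carriers = {c.sample_id}
        tree = trees[(c.chrom, c.cnv_type)]
        for hit in tree.overlap(c.start_bp, c.end_bp + 1):
            other = calls[hit.data]
            if reciprocal_overlap(c, other) >= overlap_fraction:
                carriers.add(other.sample_id)
        freqs[i] = len(carriers) / n
    return freqs


def filter_by_frequency(
    calls: Sequence[CnvCall],
    roster: Sequence[SampleRecord],
    threshold: float = 0.01,
    overlap_fraction: float = 0.5,
) -> list[CnvCall]:
    """Keep rare calls: those with population frequency < ``threshold``.

    Frequencies are computed on the full input call set before any
    removal, so the operation is order-independent and idempotent.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    freqs = call_frequencies(calls, roster, overlap_fraction)
    return [c for c, f in zip(calls, freqs) if f < threshold]


def filter_by_size(
    calls: Iterable[CnvCall], min_bp: int, max_bp: int | None = None
) -> list[CnvCall]:
    """Keep calls with ``min_bp < length_bp <= max_bp`` (max may be None).

    The strict-lower/inclusive-upper convention makes adjacent strata
    such as (500 kb, 1 Mb] and (1 Mb, inf) a partition.
    """
    if min_bp < 0 or (max_bp is not None and max_bp <= min_bp):
        raise ValueError("need 0 <= min_bp < max_bp")
    return [
        c for c in calls
        if c.length_bp > min_bp and (max_bp is None or c.length_bp <= max_bp)
    ]


def filter_by_probes(calls: Iterable[CnvCall], min_probes: int) -> list[CnvCall]:
    """Drop calls annotated with fewer than ``min_probes`` supporting probes."""
    return [c for c in calls if c.n_probes is None or c.n_probes >= min_probes]


def filter_autosomal(calls: Iterable[CnvCall]) -> list[CnvCall]:
    return [c for c in calls if c.chrom in AUTOSOMES]


def median_zscore_validate(
    call: CnvCall, lrr: LrrMatrix, threshold: float = 2.0
) -> ZscoreResult:
    """Median Z-score intensity validation of a single call.

    Each sample's median LRR over the probes inside the call interval is
    computed; the carrier's median is standardised against the mean and
    s.d. of all samples' medians.  A deletion validates at z <= -threshold,
    a duplication at z >= +threshold.  Adding a constant to the whole
    matrix leaves z unchanged.
    """
    if len(lrr.sample_ids) < MIN_COHORT_SIZE:
        raise ValueError(f"need >= {MIN_COHORT_SIZE} samples for z-score validation")
    try:
        col = list(lrr.sample_ids).index(call.sample_id)
    except ValueError:
        raise ValueError(f"sample {call.sample_id} not in LRR matrix") from None
    mask = lrr.probe_mask(call.chrom, call.start_bp, call.end_bp)
    if not mask.any():
        return ZscoreResult(False, None, "no probe support")
    medians = np.median(lrr.values[mask, :], axis=0)
    sd = medians.std(ddof=1)
    z = 0.0 if sd == 0 else float((medians[col] - medians.mean()) / sd)
    if call.cnv_type == DELETION:
        ok = z <= -threshold
    else:
        ok = z >= threshold
    return ZscoreResult(ok, z, None if ok else "z-score below threshold")


def write_qc_report(
    excluded: Sequence[tuple[SampleRecord, list[str]]],
    kept: Sequence[SampleRecord],
    path,
) -> None:
    """TSV report: one row per sample with metrics, excluded flag, reasons."""
    rows = [(s, False, []) for s in kept] + [(s, True, r) for s, r in excluded]
    metrics = sorted({m for s, _, _ in rows for m in (s.qc_metrics or {})})
    with Path(path).open("w") as fh:
        fh.write("sample_id\tcohort\t" + "\t".join(metrics) + "\texcluded\treasons\n")
        for s, flag, reasons in sorted(rows, key=lambda r: (r[0].cohort, r[0].sample_id)):
            vals = "\t".join(f"{float((s.qc_metrics or {}).get(m, float('nan'))):g}"
                             for m in metrics)
            fh.write(f"{s.sample_id}\t{s.cohort}\t{vals}\t{int(flag)}\t{','.join(reasons)}\n")
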
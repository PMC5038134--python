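"""Case-control association at predefined recurrent-CNV loci.

A sample is a carrier at a locus when it has a CNV call of the locus's
type covering at least half the locus (configurable).  Carrier counts,
optionally pooled over several cohorts, enter a two-sided Fisher's exact
test; effect sizes are odds ratios with Woolf (log-OR normal) confidence
intervals.  Genome-wide significance uses a Bonferroni correction over
the ~120 genomic regions prone to recurrent CNVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cnv_data import CnvCall, ContingencyTable, LocusDef, SampleRecord

DEFAULT_N_RECURRENT_REGIONS = 120


@dataclass(frozen=True)
class CohortCounts:
    """Carrier count and sample total for one cohort at one locus."""

    cohort: str
    carriers: int
    total: int

    def __post_init__(self):
        if not (0 <= self.carriers <= self.total):
            raise ValueError(f"{self.cohort}: need 0 <= carriers <= total")


@dataclass(frozen=True)
class AssociationResult:
    """Association statistics for one locus (one Table-style row)."""

    locus: str
    table: ContingencyTable
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float
    significant_genomewide: bool

    @property
    def case_freq(self) -> float:
        return self.table.a / self.table.n_cases if self.table.n_cases else float("nan")

    @property
    def control_freq(self) -> float:
        return self.table.c / self.table.n_controls if self.table.n_controls else float("nan")


def match_call_to_locus(
    call: CnvCall, locus: LocusDef, min_locus_coverage: float = 0.5
) -> bool:
    """Does this call count as a hit at this locus?

    Requires identical CNV type and an overlap of at least
    ``min_locus_coverage`` of the locus length.
    """
    if call.chrom != locus.chrom or call.cnv_type != locus.cnv_type:
        return False
    ov = call.overlap_bp(locus.start_bp, locus.end_bp)
    return ov >= min_locus_coverage * locus.length_bp


def count_carriers(
    calls: Sequence[CnvCall],
    roster: Sequence[SampleRecord],
    locus: LocusDef,
    min_locus_coverage: float = 0.5,
) -> ContingencyTable:
    """2x2 carrier table at a locus; a sample counts once however many calls."""
    phenotype = {s.sample_id: s.phenotype for s in roster}
    case_carriers: set[str] = set()
    control_carriers: set[str] = set()
    for call in calls:
        if call.sample_id not in phenotype:
            raise ValueError(f"call sample {call.sample_id!r} missing from roster")
        if match_call_to_locus(call, locus, min_locus_coverage):
            (case_carriers if phenotype[call.sample_id] == "case"
             else control_carriers).add(call.sample_id)
    n1 = sum(1 for s in roster if s.phenotype == "case")
    n2 = len(roster) - n1
    a, c = len(case_carriers), len(control_carriers)
    return ContingencyTable(a=a, b=n1 - a, c=c, d=n2 - c)


def pool_counts(per_cohort: Sequence[CohortCounts]) -> CohortCounts:
    """Pool carrier counts over non-overlapping cohorts by summation."""
    return CohortCounts(
        cohort="+".join(c.cohort for c in per_cohort) or "pooled",
        carriers=sum(c.carriers for c in per_cohort),
        total=sum(c.total for c in per_cohort),
    )


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p ("minlike": sum of tables no more likely).

    A zero margin means the table carries no information; p = 1.
    """
    if table.a + table.c == 0 or table.b + table.d == 0 \
            or table.n_cases == 0 or table.n_controls == 0:
        return 1.0
    p = stats.fisher_exact(table.as_array(), alternative="two-sided")[1]
    return float(min(1.0, p))


def odds_ratio(table: ContingencyTable) -> float | None:
    """Sample odds ratio (a*d)/(b*c); None (reported NA) on any zero cell."""
    if table.has_zero_cell:
        return None
    return (table.a * table.d) / (table.b * table.c)


def woolf_ci(table: ContingencyTable, level: float = 0.95) -> tuple[float, float] | None:
    """Woolf confidence interval: exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d))."""
    orr = odds_ratio(table)
    if orr is None:
        return None
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    return math.exp(math.log(orr) - z * se), math.exp(math.log(orr) + z * se)


def genomewide_threshold(
    n_regions: int = DEFAULT_N_RECURRENT_REGIONS, alpha: float = 0.05
) -> float:
    """Bonferroni threshold alpha / n_regions (unrounded)."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    return alpha / n_regions


def case_frequency_from_or(control_freq: float, odds_ratio: float) -> float:
    """Case carrier frequency implied by a control frequency and an OR."""
    if not (0 <= control_freq < 1):
        raise ValueError("control_freq must be in [0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    odds = control_freq / (1 - control_freq) * odds_ratio
    return odds / (1 + odds)


def power_two_proportion(
    control_freq: float,
    odds_ratio: float,
    n_case: int,
    n_control: int,
    alpha: float = 0.05,
) -> float:
    """Normal-approximation power of the two-sided two-proportion test.

    The case frequency is implied by the control frequency and the odds
    ratio.  At OR = 1 the power equals alpha; power increases with the
    sample sizes and with |ln OR|.
    """
    if not (0 < control_freq < 1):
        raise ValueError("control_freq must be in (0, 1)")
    p1 = control_freq
    p2 = case_frequency_from_or(p1, odds_ratio)
    se = math.sqrt(p1 * (1 - p1) / n_control + p2 * (1 - p2) / n_case)
    delta = abs(p2 - p1) / se
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(delta - z) + stats.norm.cdf(-delta - z))


def associate(
    table: ContingencyTable,
    locus_name: str,
    threshold: float | None = None,
    ci_level: float = 0.95,
) -> AssociationResult:
    """Full association summary for one locus from its 2x2 table."""
    if threshold is None:
        threshold = genomewide_threshold()
    p = fisher_exact_two_sided(table)
    orr = odds_ratio(table)
    ci = woolf_ci(table, ci_level)
    return AssociationResult(
        locus=locus_name,
        table=table,
        odds_ratio=orr,
        ci_low=ci[0] if ci else None,
        ci_high=ci[1] if ci else None,
        p_value=p,
        significant_genomewide=p < threshold,
    )


class LocusAssociationModel:
    """Carrier-count association at predefined loci.

    Built either from per-sample CNV calls plus a phenotype roster, or
    (``from_counts``) from already-pooled carrier counts per locus.
    ``fit()`` returns a :class:`LocusAssociationResults`.
    """

    def __init__(
        self,
        calls: Sequence[CnvCall],
        roster: Sequence[SampleRecord],
        loci: Sequence[LocusDef],
        min_locus_coverage: float = 0.5,
        n_regions: int = DEFAULT_N_RECURRENT_REGIONS,
        alpha: float = 0.05,
        ci_level: float = 0.95,
    ):
        if not loci:
            raise ValueError("no loci supplied")
        self.calls = list(calls)
        self.roster = list(roster)
        self.loci = list(loci)
        self.min_locus_coverage = min_locus_coverage
        self.n_regions = n_regions
        self.alpha = alpha
        self.ci_level = ci_level
        self._tables: dict[str, ContingencyTable] | None = None

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, tuple[Sequence[CohortCounts], Sequence[CohortCounts]]],
        n_regions: int = DEFAULT_N_RECURRENT_REGIONS,
        alpha: float = 0.05,
        ci_level: float = 0.95,
    ) -> "LocusAssociationModel":
        """Build from pooled counts: locus -> (case cohorts, control cohorts)."""
        model = cls.__new__(cls)
        model.calls, model.roster, model.loci = [], [], []
        model.min_locus_coverage = 0.5
        model.n_regions, model.alpha, model.ci_level = n_regions, alpha, ci_level
        tables = {}
        for locus, (case_counts, control_counts) in counts.items():
            case = pool_counts(list(case_counts))
            ctrl = pool_counts(list(control_counts))
            tables[locus] = ContingencyTable(
                a=case.carriers, b=case.total - case.carriers,
                c=ctrl.carriers, d=ctrl.total - ctrl.carriers,
            )
        model._tables = tables
        return model

    def fit(self) -> "LocusAssociationResults":
        threshold = genomewide_threshold(self.n_regions, self.alpha)
        if self._tables is None:
            self._tables = {
                locus.name: count_carriers(
                    self.calls, self.roster, locus, self.min_locus_coverage
                )
                for locus in self.loci
            }
        results = [
            associate(tbl, name, threshold, self.ci_level)
            for name, tbl in self._tables.items()
        ]
        return LocusAssociationResults(results, threshold=threshold, model=self)


class LocusAssociationResults:
    """Per-locus association results with a Table-style summary."""

    def __init__(self, results: Sequence[AssociationResult], threshold: float,
                 model: LocusAssociationModel | None = None):
        self.results = list(results)
        self.threshold = threshold
        self.model = model

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, locus: str) -> AssociationResult:
        for r in self.results:
            if r.locus == locus:
                return r
        raise KeyError(locus)

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.results:
            t = r.table
            rows.append({
                "locus": r.locus,
                "case_carriers": t.a, "case_total": t.n_cases,
                "control_carriers": t.c, "control_total": t.n_controls,
                "case_freq_pct": 100 * r.case_freq,
                "control_freq_pct": 100 * r.control_freq,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "p_value": r.p_value,
                "significant_genomewide": r.significant_genomewide,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Locus association (two-sided Fisher exact; "
            f"genome-wide threshold {self.threshold:.3g})",
            f"{'locus':<22}{'case n/N':>16}{'control n/N':>16}"
            f"{'OR':>8}{'95% CI':>18}{'p':>10}  gw",
        ]
        for r in sorted(self.results, key=lambda r: r.p_value):
            t = r.table
            orr = f"{r.odds_ratio:.2f}" if r.odds_ratio is not None else "NA"
            ci = (f"({r.ci_low:.2f}-{r.ci_high:.2f})"
                  if r.ci_low is not None else "NA")
            flag = "*" if r.significant_genomewide else ""
            lines.append(
                f"{r.locus:<22}{f'{t.a}/{t.n_cases}':>16}"
                f"{f'{t.c}/{t.n_controls}':>16}{orr:>8}{ci:>18}"
                f"{r.p_value:>10.2g}  {flag}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
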
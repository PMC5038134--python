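"""Genome-wide scan for genes enriched in exon-disrupting CNVs.

Every gene is tested for an excess of case samples carrying a CNV that
overlaps at least one basepair of at least one exon, with deletions and
duplications analysed separately (two-sided Fisher's exact test).  Calls
at known recurrent loci can be excluded, and nominally significant genes
are collapsed into regions by proximity so that one multi-gene CNV is
not read as many independent signals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .cnv_data import CNV_TYPES, CnvCall, ContingencyTable, GeneModel, LocusDef, SampleRecord, chrom_sort_key
from .locus_association import fisher_exact_two_sided, match_call_to_locus

GENEWIDE_ALPHA = 2.5e-6  # 0.05 Bonferroni-corrected for ~20 000 genes


@dataclass(frozen=True)
class GeneScanRow:
    """Carrier counts and Fisher p for one gene and one CNV type."""

    gene_name: str
    cnv_type: str
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int
    p_value: float
    region_id: str | None = None

    @property
    def table(self) -> ContingencyTable:
        return ContingencyTable(
            a=self.case_carriers,
            b=self.case_total - self.case_carriers,
            c=self.control_carriers,
            d=self.control_total - self.control_carriers,
        )


def exonic_hit(call: CnvCall, gene: GeneModel) -> bool:
    """True iff the call overlaps >= 1 bp of >= 1 exon of the gene."""
    if call.chrom != gene.chrom:
        return False
    if call.end_bp < gene.tx_start_bp or call.start_bp > gene.tx_end_bp:
        return False
    return any(call.overlap_bp(s, e) > 0 for s, e in gene.exons)


def scan_genes(
    calls: Sequence[CnvCall],
    roster: Sequence[SampleRecord],
    genes: Sequence[GeneModel],
    excluded_loci: Sequence[LocusDef] = (),
    min_size_bp: int = 10_000,
    min_locus_coverage: float = 0.5,
) -> list[GeneScanRow]:
    """Count exon-disrupting carriers per gene x CNV type and test each.

    Calls of length <= ``min_size_bp`` are dropped, as are calls matching
    any excluded locus under the locus-association rule.  Carriers are
    counted as distinct samples.  Rows (one per gene and CNV type,
    including genes with no carriers) are sorted by ascending p, then
    gene name and type for determinism.
    """
    if not genes:
        raise ValueError("empty gene set")
    phenotype = {s.sample_id: s.phenotype for s in roster}
    n_case = sum(1 for s in roster if s.phenotype == "case")
    n_control = len(roster) - n_case

    usable = [c for c in calls if c.length_bp > min_size_bp]
    if excluded_loci:
        usable = [
            c for c in usable
            if not any(match_call_to_locus(c, l, min_locus_coverage)
                       for l in excluded_loci)
        ]

    # exon interval tree per chromosome -> gene indices
    trees: dict[str, IntervalTree] = {}
    for gi, g in enumerate(genes):
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e + 1, gi)

    carriers: dict[tuple[int, str], set[str]] = {}
    for c in usable:
        if c.sample_id not in phenotype:
            raise ValueError(f"call sample {c.sample_id!r} missing from roster")
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(c.start_bp, c.end_bp + 1):
            carriers.setdefault((hit.data, c.cnv_type), set()).add(c.sample_id)

    rows: list[GeneScanRow] = []
    for gi, g in enumerate(genes):
        for cnv_type in CNV_TYPES:
            hit_samples = carriers.get((gi, cnv_type), set())
            a = sum(1 for s in hit_samples if phenotype[s] == "case")
            c_ = len(hit_samples) - a
            table = ContingencyTable(a=a, b=n_case - a, c=c_, d=n_control - c_)
            rows.append(GeneScanRow(
                gene_name=g.gene_name,
                cnv_type=cnv_type,
                case_carriers=a,
                case_total=n_case,
                control_carriers=c_,
                control_total=n_control,
                p_value=fisher_exact_two_sided(table),
            ))
    rows.sort(key=lambda r: (r.p_value, r.gene_name, r.cnv_type))
    return rows


def collapse_regions(
    rows: Sequence[GeneScanRow],
    genes: Mapping[str, GeneModel],
    max_gap_bp: int = 1_000_000,
) -> list[GeneScanRow]:
    """Assign region ids: same-type genes within ``max_gap_bp`` share one.

    Genes of one CNV type on one chromosome whose transcript intervals
    lie within ``max_gap_bp`` of each other (transitively) form a region.
    Implemented as a sorted sweep per (chromosome, type); equivalent to
    connected components of the gene-proximity graph.
    """
    groups: dict[tuple[str, str], list[GeneScanRow]] = {}
    for r in rows:
        g = genes[r.gene_name]
        groups.setdefault((g.chrom, r.cnv_type), []).append(r)

    out: list[GeneScanRow] = []
    for (chrom, cnv_type), members in sorted(
        groups.items(), key=lambda kv: (chrom_sort_key(kv[0][0]), kv[0][1])
    ):
        members.sort(key=lambda r: (genes[r.gene_name].tx_start_bp, r.gene_name))
        region_no = 0
        reach = None  # rightmost transcript end of the open region
        for r in members:
            g = genes[r.gene_name]
            if reach is None or g.tx_start_bp > reach + max_gap_bp:
                region_no += 1
                reach = g.tx_end_bp
            else:
                reach = max(reach, g.tx_end_bp)
            out.append(replace(r, region_id=f"{cnv_type}_chr{chrom}_r{region_no}"))
    out.sort(key=lambda r: (r.p_value, r.gene_name, r.cnv_type))
    return out


class GeneScanModel:
    """Genome-wide exon-disruption scan as a fit-able model object."""

    def __init__(
        self,
        calls: Sequence[CnvCall],
        roster: Sequence[SampleRecord],
        genes: Sequence[GeneModel],
        excluded_loci: Sequence[LocusDef] = (),
        min_size_bp: int = 10_000,
        min_locus_coverage: float = 0.5,
        genewide_alpha: float = GENEWIDE_ALPHA,
    ):
        self.calls = list(calls)
        self.roster = list(roster)
        self.genes = list(genes)
        self.excluded_loci = list(excluded_loci)
        self.min_size_bp = min_size_bp
        self.min_locus_coverage = min_locus_coverage
        self.genewide_alpha = genewide_alpha

    def fit(self, nominal_alpha: float = 0.05) -> "GeneScanResults":
        rows = scan_genes(
            self.calls, self.roster, self.genes,
            self.excluded_loci, self.min_size_bp, self.min_locus_coverage,
        )
        gene_map = {g.gene_name: g for g in self.genes}
        nominal = [r for r in rows if r.p_value < nominal_alpha]
        collapsed = {
            (r.gene_name, r.cnv_type): r.region_id
            for r in collapse_regions(nominal, gene_map)
        }
        rows = [
            replace(r, region_id=collapsed.get((r.gene_name, r.cnv_type)))
            for r in rows
        ]
        return GeneScanResults(rows, gene_map, nominal_alpha, self.genewide_alpha)


class GeneScanResults:
    """Ranked gene-level results with region grouping of nominal hits."""

    def __init__(self, rows, genes, nominal_alpha, genewide_alpha):
        self.rows: list[GeneScanRow] = list(rows)
        self.genes = genes
        self.nominal_alpha = nominal_alpha
        self.genewide_alpha = genewide_alpha

    def __iter__(self):
        return iter(self.rows)

    @property
    def nominal(self) -> list[GeneScanRow]:
        return [r for r in self.rows if r.p_value < self.nominal_alpha]

    @property
    def genomewide(self) -> list[GeneScanRow]:
        return [r for r in self.rows if r.p_value < self.genewide_alpha]

    @property
    def n_regions(self) -> int:
        return len({r.region_id for r in self.nominal})

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{
            "gene": r.gene_name,
            "cnv_type": r.cnv_type,
            "case_carriers": r.case_carriers,
            "case_total": r.case_total,
            "control_carriers": r.control_carriers,
            "control_total": r.control_total,
            "p_value": r.p_value,
            "region_id": r.region_id,
            "significant_genewide": r.p_value < self.genewide_alpha,
        } for r in self.rows])

    def summary(self, top: int = 10) -> str:
        lines = [
            f"Gene scan: {len(self.nominal)} gene/type pairs nominal at "
            f"p<{self.nominal_alpha:g} in {self.n_regions} regions; "
            f"{len(self.genomewide)} gene-wide significant "
            f"(p<{self.genewide_alpha:g})",
            f"{'gene':<14}{'type':<6}{'case n/N':>12}{'control n/N':>14}"
            f"{'p':>10}  region",
        ]
        for r in self.rows[:top]:
            lines.append(
                f"{r.gene_name:<14}{r.cnv_type:<6}"
                f"{f'{r.case_carriers}/{r.case_total}':>12}"
                f"{f'{r.control_carriers}/{r.control_total}':>14}"
                f"{r.p_value:>10.2g}  {r.region_id or ''}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
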
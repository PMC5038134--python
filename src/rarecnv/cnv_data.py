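"""Domain types and file I/O for rare-CNV case-control analysis.

Coordinates are 1-based inclusive throughout (the PLINK convention);
BED-style half-open coordinates are converted at the I/O boundary.
Chromosome labels are normalised by stripping any leading ``chr`` and
mapping the PLINK numeric codes 23/24 to X/Y.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DELETION = "del"
DUPLICATION = "dup"
CNV_TYPES = (DELETION, DUPLICATION)

AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROM_ORDER = AUTOSOMES + ("X", "Y")

_TYPE_TOKENS = {
    "del": DELETION,
    "deletion": DELETION,
    "dup": DUPLICATION,
    "duplication": DUPLICATION,
}

# copy-number classes: 0/1 are deletions, 3/4 duplications; 2 is reference
_CN_TO_TYPE = {0: DELETION, 1: DELETION, 3: DUPLICATION, 4: DUPLICATION}


class ParseError(ValueError):
    """Raised when an input file does not parse under the declared dialect."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def normalize_chrom(label: str | int) -> str:
    """Normalise a chromosome label to ``1``..``22``, ``X`` or ``Y``."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s == "23":
        s = "X"
    elif s == "24":
        s = "Y"
    if s not in CHROM_ORDER:
        raise ValueError(f"unrecognised chromosome label: {label!r}")
    return s


def chrom_sort_key(chrom: str) -> int:
    return CHROM_ORDER.index(chrom)


def parse_cnv_type(token: str | int) -> str:
    """Map a type token or integer copy number to ``del``/``dup``."""
    s = str(token).strip().lower()
    if s in _TYPE_TOKENS:
        return _TYPE_TOKENS[s]
    try:
        cn = int(s)
    except ValueError:
        raise ValueError(f"unknown CNV type token: {token!r}") from None
    if cn not in _CN_TO_TYPE:
        raise ValueError(f"copy number {cn} is not a CNV (expected 0, 1, 3 or 4)")
    return _CN_TO_TYPE[cn]


@dataclass(frozen=True)
class CnvCall:
    """A single CNV event called in one sample.

    ``start_bp``/``end_bp`` are 1-based inclusive; ``length_bp`` is
    ``end - start + 1``. ``copy_number`` (0-4), ``n_probes`` and
    ``confidence`` are optional call-quality annotations.
    """

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    cnv_type: str
    copy_number: int | None = None
    n_probes: int | None = None
    confidence: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"CNV {self.sample_id} {self.chrom}:{self.start_bp}-{self.end_bp}: "
                "start > end"
            )
        if self.start_bp < 1:
            raise ValueError("positions are 1-based; start_bp must be >= 1")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be one of {CNV_TYPES}, got {self.cnv_type!r}")
        if self.copy_number is not None:
            implied = _CN_TO_TYPE.get(self.copy_number)
            if implied is None:
                raise ValueError(f"copy_number {self.copy_number} out of range 0-4 (non-2)")
            if implied != self.cnv_type:
                raise ValueError(
                    f"copy_number {self.copy_number} inconsistent with type {self.cnv_type}"
                )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def overlap_bp(self, start_bp: int, end_bp: int) -> int:
        """Overlap length (bp) with another 1-based inclusive interval."""
        return max(0, min(self.end_bp, end_bp) - max(self.start_bp, start_bp) + 1)


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual: phenotype, source cohort and QC metrics."""

    sample_id: str
    phenotype: str  # "case" or "control"
    cohort: str = "default"
    qc_metrics: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.phenotype not in ("case", "control"):
            raise ValueError(f"phenotype must be 'case' or 'control', got {self.phenotype!r}")


@dataclass(frozen=True)
class LocusDef:
    """A predefined recurrent-CNV region with its expected CNV type."""

    name: str
    chrom: str
    start_bp: int
    end_bp: int
    cnv_type: str

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start_bp > self.end_bp:
            raise ValueError(f"locus {self.name}: empty interval")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"locus {self.name}: bad cnv_type {self.cnv_type!r}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of 1-based inclusive intervals, merging book-ended neighbours."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure; the unit of the genome-wide scan.

    Exons are stored union-merged (non-overlapping, sorted), so a gene
    built from several transcripts carries the per-basepair union of
    their exons.
    """

    gene_name: str
    chrom: str
    strand: str
    tx_start_bp: int
    tx_end_bp: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_name}: strand must be + or -")
        merged = _merge_intervals(self.exons)
        for s, e in merged:
            if s > e:
                raise ValueError(f"gene {self.gene_name}: empty exon ({s}, {e})")
            if s < self.tx_start_bp or e > self.tx_end_bp:
                raise ValueError(
                    f"gene {self.gene_name}: exon ({s}, {e}) outside transcript bounds"
                )
        object.__setattr__(self, "exons", merged)

    def merged_with(self, other: "GeneModel") -> "GeneModel":
        """Exon-union merge of two transcript records sharing a gene symbol."""
        if (self.gene_name, self.chrom) != (other.gene_name, other.chrom):
            raise ValueError("can only merge transcripts of one gene on one chromosome")
        return GeneModel(
            gene_name=self.gene_name,
            chrom=self.chrom,
            strand=self.strand,
            tx_start_bp=min(self.tx_start_bp, other.tx_start_bp),
            tx_end_bp=max(self.tx_end_bp, other.tx_end_bp),
            exons=self.exons + other.exons,
        )


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 carrier/non-carrier by case/control table.

    ``a`` case carriers, ``b`` case non-carriers, ``c`` control carriers,
    ``d`` control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("contingency cells must be non-negative integers")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PLINK_CNV_HEADER = ("FID", "IID", "CHR", "BP1", "BP2", "TYPE", "SCORE", "SITES")


def read_cnv_table(path, format: str = "plink_cnv") -> list[CnvCall]:
    """Read CNV calls from a PLINK ``.cnv`` file or a BED file.

    PLINK columns are FID IID CHR BP1 BP2 TYPE SCORE SITES, with TYPE the
    integer copy number; a header line is detected and skipped.  BED input
    (0-based half-open) may carry a sample id in column 4 and a del/dup
    token in column 5; a bare BED3 line is read as a deletion with sample
    id ``NA``.
    """
    path = Path(path)
    calls: list[CnvCall] = []
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if format == "plink_cnv":
                if tuple(f.upper() for f in fields[: len(_PLINK_CNV_HEADER)]) == _PLINK_CNV_HEADER:
                    continue
                if len(fields) < 6:
                    raise ParseError(path, line_no, f"expected >= 6 columns, got {len(fields)}")
                try:
                    cn = int(fields[5])
                    call = CnvCall(
                        sample_id=fields[1],
                        chrom=fields[2],
                        start_bp=int(fields[3]),
                        end_bp=int(fields[4]),
                        cnv_type=parse_cnv_type(cn),
                        copy_number=cn,
                        confidence=float(fields[6]) if len(fields) > 6 else None,
                        n_probes=int(fields[7]) if len(fields) > 7 else None,
                    )
                except (ValueError, IndexError) as exc:
                    raise ParseError(path, line_no, str(exc)) from exc
            elif format == "bed":
                if len(fields) < 3:
                    raise ParseError(path, line_no, "BED needs >= 3 columns")
                try:
                    call = CnvCall(
                        sample_id=fields[3] if len(fields) > 3 else "NA",
                        chrom=fields[0],
                        start_bp=int(fields[1]) + 1,  # half-open -> 1-based inclusive
                        end_bp=int(fields[2]),
                        cnv_type=parse_cnv_type(fields[4]) if len(fields) > 4 else DELETION,
                    )
                except ValueError as exc:
                    raise ParseError(path, line_no, str(exc)) from exc
            else:
                raise ValueError(f"unknown CNV table format: {format!r}")
            calls.append(call)
    return calls


def write_cnv_table(calls: Sequence[CnvCall], path, format: str = "plink_cnv") -> None:
    path = Path(path)
    order = sorted(
        range(len(calls)),
        key=lambda i: (chrom_sort_key(calls[i].chrom), calls[i].start_bp, calls[i].end_bp,
                       calls[i].sample_id),
    )
    with path.open("w") as fh:
        if format == "plink_cnv":
            fh.write("FID IID CHR BP1 BP2 TYPE SCORE SITES\n")
            for i in order:
                c = calls[i]
                cn = c.copy_number if c.copy_number is not None else (1 if c.cnv_type == DELETION else 3)
                score = c.confidence if c.confidence is not None else 0
                sites = c.n_probes if c.n_probes is not None else 0
                fh.write(f"{c.sample_id} {c.sample_id} {c.chrom} {c.start_bp} {c.end_bp} "
                         f"{cn} {score:g} {sites}\n")
        elif format == "bed":
            for i in order:
                c = calls[i]
                fh.write(f"{c.chrom}\t{c.start_bp - 1}\t{c.end_bp}\t{c.sample_id}\t{c.cnv_type}\n")
        else:
            raise ValueError(f"unknown CNV table format: {format!r}")


def read_fam(path, cohort_from_fid: bool = True) -> list[SampleRecord]:
    """Read a PLINK ``.fam`` roster (PHE 1=control, 2=case).

    The FID column doubles as the cohort label when ``cohort_from_fid``.
    """
    path = Path(path)
    roster: list[SampleRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(path, line_no, f"expected 6 columns, got {len(fields)}")
            phe = fields[5]
            if phe == "2":
                phenotype = "case"
            elif phe == "1":
                phenotype = "control"
            else:
                raise ParseError(path, line_no, f"phenotype must be 1 or 2, got {phe!r}")
            sid = fields[1]
            if sid in seen:
                raise ParseError(path, line_no, f"duplicate sample id {sid!r}")
            seen.add(sid)
            roster.append(SampleRecord(
                sample_id=sid,
                phenotype=phenotype,
                cohort=fields[0] if cohort_from_fid else "default",
            ))
    return roster


def write_fam(roster: Sequence[SampleRecord], path) -> None:
    with Path(path).open("w") as fh:
        for s in roster:
            phe = 2 if s.phenotype == "case" else 1
            fh.write(f"{s.cohort} {s.sample_id} 0 0 0 {phe}\n")


def read_locus_table(path, units: str = "mb") -> list[LocusDef]:
    """Read a locus definition TSV with columns name/chrom/start/end/type.

    ``units`` is ``mb`` (values multiplied by 1e6 and rounded to integer bp)
    or ``bp``.
    """
    if units not in ("mb", "bp"):
        raise ValueError("units must be 'mb' or 'bp'")
    path = Path(path)
    loci: list[LocusDef] = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        required = {"name", "chrom", "start", "end", "type"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ParseError(path, 1, f"locus table missing columns: {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                if units == "mb":
                    start = round(float(row["start"]) * 1e6)
                    end = round(float(row["end"]) * 1e6)
                else:
                    start = int(row["start"])
                    end = int(row["end"])
                loci.append(LocusDef(
                    name=row["name"],
                    chrom=row["chrom"],
                    start_bp=start,
                    end_bp=end,
                    cnv_type=_TYPE_TOKENS.get(row["type"].strip().lower())
                    or _fail_type(row["type"]),
                ))
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc)) from exc
    return loci


def _fail_type(token: str):
    raise ValueError(f"unknown cnv_type token: {token!r}")


def _merge_gene_records(records: Iterable[GeneModel]) -> list[GeneModel]:
    by_key: dict[tuple[str, str], GeneModel] = {}
    for g in records:
        key = (g.gene_name, g.chrom)
        by_key[key] = by_key[key].merged_with(g) if key in by_key else g
    return sorted(by_key.values(),
                  key=lambda g: (chrom_sort_key(g.chrom), g.tx_start_bp, g.gene_name))


def read_gene_models(path, format: str = "refflat") -> list[GeneModel]:
    """Read gene models from refFlat or BED12, merging transcripts by symbol.

    Both formats use 0-based half-open exon coordinates on disk; internal
    coordinates are 1-based inclusive.  Transcripts sharing a gene symbol
    on one chromosome are collapsed to the union of their exons.
    """
    path = Path(path)
    records: list[GeneModel] = []
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if format == "refflat":
                    # geneName txName chrom strand txStart txEnd cdsStart cdsEnd
                    # exonCount exonStarts exonEnds
                    if len(f) < 11:
                        raise ValueError(f"refFlat needs 11 columns, got {len(f)}")
                    starts = [int(x) + 1 for x in f[9].rstrip(",").split(",")]
                    ends = [int(x) for x in f[10].rstrip(",").split(",")]
                    records.append(GeneModel(
                        gene_name=f[0], chrom=f[2], strand=f[3],
                        tx_start_bp=int(f[4]) + 1, tx_end_bp=int(f[5]),
                        exons=tuple(zip(starts, ends)),
                    ))
                elif format == "bed12":
                    if len(f) < 12:
                        raise ValueError(f"BED12 needs 12 columns, got {len(f)}")
                    chrom_start = int(f[1])
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                    if len(sizes) != int(f[9]) or len(offsets) != int(f[9]):
                        raise ValueError("blockCount inconsistent with block lists")
                    exons = tuple(
                        (chrom_start + off + 1, chrom_start + off + size)
                        for off, size in zip(offsets, sizes)
                    )
                    records.append(GeneModel(
                        gene_name=f[3], chrom=f[0], strand=f[5],
                        tx_start_bp=chrom_start + 1, tx_end_bp=int(f[2]),
                        exons=exons,
                    ))
                else:
                    raise ValueError(f"unknown gene model format: {format!r}")
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc)) from exc
    return _merge_gene_records(records)


def write_gene_models(genes: Sequence[GeneModel], path, format: str = "refflat") -> None:
    if format != "refflat":
        raise ValueError("only refFlat output is supported")
    with Path(path).open("w") as fh:
        for g in genes:
            starts = ",".join(str(s - 1) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write("\t".join([
                g.gene_name, g.gene_name, g.chrom, g.strand,
                str(g.tx_start_bp - 1), str(g.tx_end_bp),
                str(g.tx_start_bp - 1), str(g.tx_end_bp),
                str(len(g.exons)), starts, ends,
            ]) + "\n")


def write_locus_table(loci: Sequence[LocusDef], path, units: str = "bp") -> None:
    with Path(path).open("w") as fh:
        fh.write("name\tchrom\tstart\tend\ttype\n")
        for l in loci:
            if units == "mb":
                fh.write(f"{l.name}\t{l.chrom}\t{l.start_bp / 1e6:g}\t{l.end_bp / 1e6:g}\t{l.cnv_type}\n")
            else:
                fh.write(f"{l.name}\t{l.chrom}\t{l.start_bp}\t{l.end_bp}\t{l.cnv_type}\n")


# ---------------------------------------------------------------------------
# bundled reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    from importlib.resources import files

    return Path(str(files("rarecnv").joinpath("data", name)))


def bundled_sz_loci() -> list[LocusDef]:
    """The 15 recurrent CNV loci previously implicated in schizophrenia.

    hg19 coordinates as published (Mb, truncated to 10 kb resolution).
    """
    return read_locus_table(_data_path("sz_loci_hg19.tsv"), units="mb")


def bundled_locus_counts():
    """Published pooled carrier counts at the 15 loci.

    Returns a pandas DataFrame with per-locus bipolar-disorder (BDRN-only
    and all-sources-combined) and control carrier counts and totals.
    """
    import pandas as pd

    return pd.read_csv(_data_path("table1_counts.tsv"), sep="\t")
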
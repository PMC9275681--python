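"""Readers/writers for on-disk formats and the packaged regulon fixture.

Coordinate conventions: all in-memory intervals are 0-based half-open.
GFF3 is emitted/parsed 1-based inclusive; BED is 0-based half-open. The
conversion happens only in this module.

The packaged fixture ``data/cenkr_regulon.tsv`` mirrors the published
CenKR regulon table for *Rhodobacter sphaeroides*: 31 transcriptional
units with a TGA-N8-TGA-family binding motif, per-strain ChIP
fold-enrichments, per-strain log2 fold changes with BH FDRs, and the
assigned regulatory role.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "IntegrityError",
    "GenomicInterval",
    "Peak",
    "DifferentialExpressionRecord",
    "TranscriptionalUnit",
    "RegulonFixtureEntry",
    "read_peak_table",
    "write_peak_table",
    "read_de_table",
    "write_de_table",
    "read_genome",
    "write_genome",
    "read_annotations",
    "write_annotations",
    "load_regulon_fixture",
    "fixture_de_records",
]

#: Strains of the study, in decreasing order of two-component-system activity.
DEFAULT_STRAINS = ("D56E", "WT", "dcenK", "D56A")

#: Activity class of each non-WT strain comparison (mutant vs WT).
DEFAULT_STRAIN_CLASSES = {"D56E": "hyper", "dcenK": "low", "D56A": "low"}

FIXTURE_SHA256 = "39c1a3273c29b3bde8b623bc84cc5435fd2d3bd7491591f1e0f53ea62e9eaf67"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


class IntegrityError(RuntimeError):
    """The packaged fixture does not match its recorded checksum."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A located stretch of a replicon, 0-based half-open."""

    replicon: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.replicon:
            raise ValidationError("replicon id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.replicon}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.replicon == other.replicon
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """One ChIP peak from one replicate of one strain.

    ``fold_enrichment`` is IP over input DNA; ``center`` defaults to the
    midpoint of the interval when the caller does not give one.
    """

    interval: GenomicInterval
    fold_enrichment: float
    strain: str
    replicate: str
    name: str = ""
    center: int = -1

    def __post_init__(self) -> None:
        if self.center < 0:
            object.__setattr__(self, "center", self.interval.center)
        if not self.interval.contains(self.center):
            raise ValidationError(
                f"peak center {self.center} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if not self.fold_enrichment > 0:
            raise ValidationError("fold_enrichment must be positive")

    @property
    def replicon(self) -> str:
        return self.interval.replicon


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    """Per-gene log2 fold change for one strain comparison (mutant vs WT).

    ``fdr is None`` encodes a "tested, not significant" cell (printed
    "n.s." in the source table) and is deliberately distinct from a
    large numeric FDR.
    """

    gene: str
    comparison: str
    log2fc: float | None
    fdr: float | None

    def __post_init__(self) -> None:
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(
                f"fdr {self.fdr} for {self.gene}/{self.comparison} outside [0, 1]"
            )

    @property
    def significant(self) -> bool:
        return self.fdr is not None


@dataclass
class TranscriptionalUnit:
    """An operon: TSS, strand, promoter elements and member genes.

    ``minus35`` / ``minus10`` are absolute genomic intervals of the core
    promoter hexamers; either may be None when unannotated. ``tss`` is a
    0-based genomic position of the first transcribed base. ``genes``
    maps locus id -> absolute CDS interval, in transcription order.
    """

    tu_id: str
    interval: GenomicInterval
    tss: int | None
    genes: dict[str, GenomicInterval] = field(default_factory=dict)
    minus35: GenomicInterval | None = None
    minus10: GenomicInterval | None = None

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def replicon(self) -> str:
        return self.interval.replicon

    @property
    def lead_gene(self) -> str | None:
        return next(iter(self.genes), None)

    @property
    def translation_start(self) -> int | None:
        """Genomic position of the first CDS base of the lead gene."""
        lead = self.lead_gene
        if lead is None:
            return None
        g = self.genes[lead]
        return g.start if self.strand == "+" else g.end - 1

    def to_relative(self, pos: int) -> int:
        """Signed position relative to the TSS, negative = upstream."""
        if self.tss is None:
            raise ValidationError(f"TU {self.tu_id} has no annotated TSS")
        return pos - self.tss if self.strand == "+" else self.tss - pos


@dataclass(frozen=True)
class RegulonFixtureEntry:
    """One row of the packaged 31-entry regulon table."""

    locus_id: str
    gene_name: str
    annotation: str
    replicon: str
    peak_center: int
    shared_peak: bool
    chip_enrichment: Mapping[str, float]  # strain -> fold enrichment; absent = no signal
    motif_seq: str
    log2fc: Mapping[str, tuple[float, float]]  # comparison -> (lfc, fdr); absent = n.s.
    role: str
    category: str
    tm_domain: bool
    signal_peptide: bool
    essential: bool

    def __post_init__(self) -> None:
        if len(self.motif_seq) != 15 or set(self.motif_seq) - set("ACGT"):
            raise ValidationError(f"{self.locus_id}: motif must be a 15-mer over ACGT")
        if self.role not in {"+", "-"}:
            raise ValidationError(f"{self.locus_id}: role must be + or -")
        if self.category not in {"envelope_extracytoplasmic", "cytoplasmic"}:
            raise ValidationError(f"{self.locus_id}: bad category {self.category!r}")


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = ["replicon", "start", "end", "name", "fold_enrichment", "strain", "replicate"]


def read_peak_table(path: str | Path, dialect: str = "tsv") -> list[Peak]:
    """Read a peak table (``tsv`` with named columns, or ``bed6``).

    BED6 carries the enrichment in the score column; strain/replicate are
    then parsed from a name of the form ``<strain>:<replicate>:<label>``
    (missing parts default to empty strings). Malformed rows raise with
    the 1-based line number.
    """
    path = Path(path)
    if dialect not in {"tsv", "bed6"}:
        raise FormatError(f"unknown peak dialect {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "tsv":
        if not lines:
            raise FormatError(f"{path}: empty file, expected a header")
        header = lines[0].split("\t")
        missing = [c for c in _PEAK_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        idx = {c: header.index(c) for c in header}
        body = lines[1:]
    else:
        body = lines
    for lineno, line in enumerate(body, start=2 if dialect == "tsv" else 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if dialect == "tsv":
                replicon = fields[idx["replicon"]]
                start, end = int(fields[idx["start"]]), int(fields[idx["end"]])
                name = fields[idx["name"]]
                enrich = float(fields[idx["fold_enrichment"]])
                strain = fields[idx["strain"]]
                replicate = fields[idx["replicate"]]
                center = (
                    int(fields[idx["center"]])
                    if "center" in idx and fields[idx["center"]] not in ("", ".")
                    else -1
                )
            else:
                if len(fields) < 6:
                    raise FormatError("BED6 requires 6 columns")
                replicon, start, end, name, score, _strand = fields[:6]
                start, end = int(start), int(end)
                enrich = float(score)
                parts = (name.split(":") + ["", ""])[:3]
                strain, replicate = parts[0], parts[1]
                center = -1
            interval = GenomicInterval(replicon, start, end)
            peaks.append(
                Peak(interval, enrich, strain, replicate, name=name, center=center)
            )
        except (ValidationError, FormatError, ValueError, IndexError) as exc:
            kind = ValidationError if isinstance(exc, ValidationError) else FormatError
            raise kind(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peak_table(peaks: Iterable[Peak], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_PEAK_COLUMNS + ["center"]) + "\n")
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.interval.replicon,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name,
                        f"{p.fold_enrichment:g}",
                        p.strain,
                        p.replicate,
                        str(p.center),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

_NS_TOKENS = {"n.s.", "ns", "na", ""}


def _parse_fdr(token: str, where: str) -> float | None:
    token = token.strip()
    if token.lower() in _NS_TOKENS:
        return None
    value = float(token)
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{where}: fdr {value} outside [0, 1]")
    return value


def read_de_table(path: str | Path) -> list[DifferentialExpressionRecord]:
    """Read a TSV with columns gene, comparison, log2fc, fdr.

    Blank or "n.s." fdr cells become the not-significant sentinel
    (``fdr=None``); the log2fc cell may then also be blank/"n.s.".
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene", "comparison", "log2fc", "fdr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path}:{i}"
        fdr = _parse_fdr(row.fdr, where)
        lfc_token = row.log2fc.strip()
        lfc = None if lfc_token.lower() in _NS_TOKENS else float(lfc_token)
        records.append(DifferentialExpressionRecord(row.gene, row.comparison, lfc, fdr))
    return records


def write_de_table(
    records: Iterable[DifferentialExpressionRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcomparison\tlog2fc\tfdr\n")
        for r in records:
            lfc = "n.s." if r.log2fc is None else f"{r.log2fc:.6g}"
            fdr = "n.s." if r.fdr is None else f"{r.fdr:.6g}"
            fh.write(f"{r.gene}\t{r.comparison}\t{lfc}\t{fdr}\n")


# ---------------------------------------------------------------------------
# Genome FASTA
# ---------------------------------------------------------------------------


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA into an ordered {replicon: sequence} map."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 annotations (transcriptional units with TSS / promoter elements)
# ---------------------------------------------------------------------------


def write_annotations(tus: Sequence[TranscriptionalUnit], path: str | Path) -> None:
    """Emit TUs as GFF3: a transcript feature with TSS, promoter-element
    and CDS children. 1-based inclusive on disk."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tu in tus:
            s = tu.strand
            fh.write(
                f"{tu.replicon}\tcenreg\ttranscript\t{tu.interval.start + 1}\t"
                f"{tu.interval.end}\t.\t{s}\t.\tID={tu.tu_id}\n"
            )
            if tu.tss is not None:
                fh.write(
                    f"{tu.replicon}\tcenreg\tTSS\t{tu.tss + 1}\t{tu.tss + 1}\t.\t{s}\t.\t"
                    f"ID={tu.tu_id}.tss;Parent={tu.tu_id}\n"
                )
            for kind, iv in (("minus_35_signal", tu.minus35), ("minus_10_signal", tu.minus10)):
                if iv is not None:
                    fh.write(
                        f"{tu.replicon}\tcenreg\t{kind}\t{iv.start + 1}\t{iv.end}\t.\t{s}\t.\t"
                        f"ID={tu.tu_id}.{kind};Parent={tu.tu_id}\n"
                    )
            for gene_id, iv in tu.genes.items():
                fh.write(
                    f"{tu.replicon}\tcenreg\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{s}\t.\t"
                    f"ID={gene_id};Parent={tu.tu_id};locus_tag={gene_id}\n"
                )


def read_annotations(path: str | Path) -> list[TranscriptionalUnit]:
    """Parse TU annotations written by :func:`write_annotations` (or any
    GFF3 using the same feature types) via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    tus: list[TranscriptionalUnit] = []
    for feat in db.features_of_type("transcript", order_by=("seqid", "start")):
        interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        tu = TranscriptionalUnit(feat.id, interval, tss=None)
        for child in db.children(feat, order_by="start"):
            ivc = GenomicInterval(child.seqid, child.start - 1, child.end, child.strand)
            if child.featuretype == "TSS":
                tu.tss = child.start - 1
            elif child.featuretype == "minus_35_signal":
                tu.minus35 = ivc
            elif child.featuretype == "minus_10_signal":
                tu.minus10 = ivc
            elif child.featuretype == "CDS":
                locus = child.attributes.get("locus_tag", [child.id])[0]
                tu.genes[locus] = ivc
        if tu.strand == "-":  # transcription order = descending coordinate
            tu.genes = dict(
                sorted(tu.genes.items(), key=lambda kv: -kv[1].start)
            )
        tus.append(tu)
    return tus


# ---------------------------------------------------------------------------
# Packaged regulon fixture
# ---------------------------------------------------------------------------


def _fixture_path() -> Path:
    return Path(resources.files("cenreg") / "data" / "cenkr_regulon.tsv")


def load_regulon_fixture(path: str | Path | None = None, check_integrity: bool = True) -> list[RegulonFixtureEntry]:
    """Load the packaged 31-entry regulon table.

    Raises :class:`IntegrityError` when the packaged file's checksum does
    not match the recorded value (only for the packaged copy).
    """
    packaged = path is None
    path = _fixture_path() if packaged else Path(path)
    raw = path.read_bytes()
    if packaged and check_integrity:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != FIXTURE_SHA256:
            raise IntegrityError(
                f"fixture checksum mismatch: {digest} != {FIXTURE_SHA256}"
            )
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        enrich = {}
        for strain in DEFAULT_STRAINS:
            token = getattr(row, f"enrich_{strain}")
            if token != "--":
                enrich[strain] = float(token)
        lfc: dict[str, tuple[float, float]] = {}
        for comp in ("D56E", "dcenK", "D56A"):
            fdr = _parse_fdr(getattr(row, f"fdr_{comp}"), row.locus_id)
            if fdr is not None:
                lfc[comp] = (float(getattr(row, f"lfc_{comp}")), fdr)
        entries.append(
            RegulonFixtureEntry(
                locus_id=row.locus_id,
                gene_name=row.gene_name,
                annotation=row.annotation,
                replicon=row.replicon,
                peak_center=int(row.peak_center),
                shared_peak=row.shared_peak == "Y",
                chip_enrichment=enrich,
                motif_seq=row.motif_seq,
                log2fc=lfc,
                role=row.role,
                category=row.category,
                tm_domain=row.tm_domain == "Y",
                signal_peptide=row.signal_peptide == "Y",
                essential=row.essential == "Y",
            )
        )
    if len(entries) != 31:
        raise IntegrityError(f"expected 31 fixture entries, found {len(entries)}")
    return entries


def fixture_de_records(
    entries: Sequence[RegulonFixtureEntry] | None = None,
) -> list[DifferentialExpressionRecord]:
    """Expand fixture rows into per-comparison DE records (n.s. cells
    become the not-significant sentinel)."""
    if entries is None:
        entries = load_regulon_fixture()
    records = []
    for e in entries:
        for comp in ("D56E", "dcenK", "D56A"):
            if comp in e.log2fc:
                lfc, fdr = e.log2fc[comp]
                records.append(DifferentialExpressionRecord(e.locus_id, comp, lfc, fdr))
            else:
                records.append(DifferentialExpressionRecord(e.locus_id, comp, None, None))
    return records
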
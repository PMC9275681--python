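"""Assembly of the direct regulon: intersect upstream-classified ChIP
consensus peaks with opposing-expression transcriptional units, assign
activation/repression roles from the strain DE evidence, and classify
the regulatory mechanism from binding-site position relative to the
core promoter.

Role logic mirrors the published table: increased transcript in the
hyperactive strain (or, when the hyperactive comparison is not
significant, the negated agreed sign of the low-activity strains) means
positive regulation. Mechanism follows the observed promoter geometry:
sites wholly upstream of the -35 hexamer are activation-consistent,
sites overlapping the -35 .. TSS span are repression-consistent; a
role/mechanism disagreement is logged as a warning, never an exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .expression import GeneCall, TUExpressionSummary, detect_opposing
from .io_formats import (
    DEFAULT_STRAIN_CLASSES,
    RegulonFixtureEntry,
    TranscriptionalUnit,
    ValidationError,
    fixture_de_records,
    load_regulon_fixture,
)
from .motif import MotifSite
from .peaks import ConsensusPeak, PeakAssignment

__all__ = [
    "Candidate",
    "RegulonEntry",
    "intersect_candidates",
    "assign_role",
    "classify_mechanism",
    "build_regulon_table",
    "regulon_to_dataframe",
    "replay_fixture_roles",
]

logger = logging.getLogger(__name__)

_DIRECTION_TO_ROLE = {"up": "+", "down": "-"}


@dataclass(frozen=True)
class Candidate:
    tu_id: str
    summary: TUExpressionSummary
    assignment: PeakAssignment

    @property
    def peak(self) -> ConsensusPeak:
        return self.assignment.peak


@dataclass
class RegulonEntry:
    tu_id: str
    lead_gene: str
    peak: ConsensusPeak
    assignment: PeakAssignment
    site: MotifSite | None
    role: str  # "+", "-" or "unassigned"
    mechanism: str  # activation_consistent | repression_consistent | unclassified
    mixed_direction: bool = False
    gene_calls: tuple[GeneCall, ...] = ()
    annotations: Mapping[str, object] = field(default_factory=dict)


def intersect_candidates(
    assignments: Sequence[PeakAssignment],
    tu_summaries: Sequence[TUExpressionSummary],
) -> list[Candidate]:
    """TUs with >=1 upstream-classified peak AND an opposing expression
    pattern. Each candidate keeps its best-supported peak (max support,
    ties broken by max mean WT enrichment, then smallest |distance to
    TSS|)."""
    summaries = {s.tu_id: s for s in tu_summaries}
    by_tu: dict[str, list[PeakAssignment]] = {}
    for a in assignments:
        if a.classification == "upstream" and a.tu_id is not None:
            by_tu.setdefault(a.tu_id, []).append(a)
    candidates = []
    for tu_id, hits in sorted(by_tu.items()):
        summary = summaries.get(tu_id)
        if summary is None or not summary.any_opposing:
            continue
        best = max(
            hits,
            key=lambda a: (
                a.peak.support,
                a.peak.per_strain_enrichment.get("WT", float("-inf")),
                -abs(a.distance_to_tss),
            ),
        )
        candidates.append(Candidate(tu_id, summary, best))
    return candidates


def assign_role(
    summary: TUExpressionSummary, gene_calls: Mapping[str, GeneCall] | None = None
) -> tuple[str, bool]:
    """Regulatory role from member-gene directions.

    Returns (role, mixed). Disagreeing member directions resolve to the
    member with the smallest hyper-strain FDR (already the summary's
    ``direction_hyper``) and set the mixed flag.
    """
    directions = set()
    if gene_calls:
        directions = {
            gene_calls[g].direction_hyper
            for g in summary.member_genes
            if g in gene_calls and gene_calls[g].direction_hyper != "none"
        }
    if summary.direction_hyper == "none":
        return "unassigned", False
    mixed = len(directions) > 1
    if mixed:
        logger.warning(
            "TU %s members disagree in direction; using smallest hyper-strain FDR",
            summary.tu_id,
        )
    return _DIRECTION_TO_ROLE[summary.direction_hyper], mixed


def classify_mechanism(
    site: MotifSite | None,
    tu: TranscriptionalUnit,
    site_interval=None,
) -> str:
    """Mechanism class from site position in the TU's promoter frame.

    The site span is taken from ``site.position_vs_tss`` (TSS-relative
    center) or an absolute ``site_interval``. Wholly upstream of the -35
    element start -> activation_consistent; overlapping the [-35 start,
    TSS] span -> repression_consistent; entirely downstream of the TSS
    -> unclassified. Unannotated promoter elements fall back to the
    default -35 placement at [-35, -30].
    """
    if site is None:
        return "unclassified"
    if site_interval is not None:
        if site_interval.replicon != tu.replicon:
            raise ValidationError(
                f"site on {site_interval.replicon} but TU {tu.tu_id} on {tu.replicon}"
            )
        rel = sorted(
            (tu.to_relative(site_interval.start), tu.to_relative(site_interval.end - 1))
        )
        rel_lo, rel_hi = rel
    elif site.position_vs_tss is not None:
        half = len(site.site_seq) // 2
        rel_lo = site.position_vs_tss - half
        rel_hi = site.position_vs_tss + (len(site.site_seq) - 1 - half)
    else:
        return "unclassified"
    if tu.minus35 is not None:
        m35_start = min(
            tu.to_relative(tu.minus35.start), tu.to_relative(tu.minus35.end - 1)
        )
    else:
        m35_start = -35
    if rel_hi < m35_start:
        return "activation_consistent"
    if rel_lo <= 0 and rel_hi >= m35_start:
        return "repression_consistent"
    return "unclassified"


def build_regulon_table(
    candidates: Sequence[Candidate],
    sites: Mapping[str, MotifSite | None],
    tus: Mapping[str, TranscriptionalUnit],
    gene_calls: Mapping[str, GeneCall] | None = None,
    annotations: Mapping[str, Mapping[str, object]] | None = None,
) -> tuple[list[RegulonEntry], list[RegulonEntry], list[str]]:
    """Assemble (core, expanded, warnings).

    The core regulon keeps candidates with motif support (the published
    31-vs-59 distinction); the expanded output keeps all candidates.
    Role-vs-mechanism disagreement is recorded as a warning only.
    """
    entries: list[RegulonEntry] = []
    warnings_log: list[str] = []
    for cand in candidates:
        tu = tus.get(cand.tu_id)
        site = sites.get(cand.tu_id)
        role, mixed = assign_role(cand.summary, gene_calls)
        mechanism = classify_mechanism(site, tu) if tu is not None else "unclassified"
        if role == "+" and mechanism == "repression_consistent":
            warnings_log.append(
                f"{cand.tu_id}: activating role with repression-consistent site geometry"
            )
        if role == "-" and mechanism == "activation_consistent":
            warnings_log.append(
                f"{cand.tu_id}: repressing role with activation-consistent site geometry"
            )
        lead = (
            tu.lead_gene
            if tu is not None and tu.lead_gene
            else (cand.summary.member_genes[0] if cand.summary.member_genes else cand.tu_id)
        )
        calls = tuple(
            gene_calls[g] for g in cand.summary.member_genes if gene_calls and g in gene_calls
        )
        entries.append(
            RegulonEntry(
                tu_id=cand.tu_id,
                lead_gene=lead,
                peak=cand.peak,
                assignment=cand.assignment,
                site=site,
                role=role,
                mechanism=mechanism,
                mixed_direction=mixed,
                gene_calls=calls,
                annotations=(annotations or {}).get(cand.tu_id, {}),
            )
        )

    def sort_key(e: RegulonEntry):
        return (
            str(e.annotations.get("category", "")),
            e.peak.replicon,
            e.peak.center,
        )

    entries.sort(key=sort_key)
    core = [e for e in entries if e.site is not None]
    return core, entries, warnings_log


def regulon_to_dataframe(entries: Sequence[RegulonEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append(
            {
                "tu_id": e.tu_id,
                "lead_gene": e.lead_gene,
                "replicon": e.peak.replicon,
                "peak_center": e.peak.center,
                "support": e.peak.support,
                "distance_to_tss": e.assignment.distance_to_tss,
                "shared_peak": e.assignment.shared,
                "site_seq": e.site.site_seq if e.site else "",
                "site_score": round(e.site.score, 4) if e.site else "",
                "role": e.role,
                "mechanism": e.mechanism,
                "mixed_direction": e.mixed_direction,
                **{f"enrich_{s}": round(v, 3) for s, v in e.peak.per_strain_enrichment.items()},
                **{k: v for k, v in e.annotations.items()},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixture replay
# ---------------------------------------------------------------------------


def replay_fixture_roles(
    entries: Sequence[RegulonFixtureEntry] | None = None,
    strain_classes: Mapping[str, str] = DEFAULT_STRAIN_CLASSES,
) -> dict[str, str]:
    """Recompute the regulatory-role column of the packaged regulon table
    from its per-strain DE evidence alone; returns locus -> role."""
    if entries is None:
        entries = load_regulon_fixture()
    roles: dict[str, str] = {}
    records = fixture_de_records(entries)
    by_gene: dict[str, list] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    for e in entries:
        _, direction, _ = detect_opposing(by_gene[e.locus_id], strain_classes)
        roles[e.locus_id] = _DIRECTION_TO_ROLE.get(direction, "unassigned")
    return roles
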
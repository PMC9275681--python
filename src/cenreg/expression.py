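"""Differential-expression thresholds and the opposing-pattern criterion.

The study's gene-level filter: |log2FC| > 0.5 (strict) and FDR < 0.05
(strict) in at least two strain comparisons. Its signature of direct
regulation is an *opposing* pattern — up in the hyperactive strain
(D56E) and down in low-activity strains (dcenK / D56A), or vice versa.
Genes significant only in low-activity strains still qualify when those
calls agree in sign (the hyper direction is then inferred by negation);
low-activity calls that contradict each other make the gene ambiguous.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import (  # noqa: F401  (re-exported domain types)
    DEFAULT_STRAIN_CLASSES,
    DifferentialExpressionRecord,
    TranscriptionalUnit,
    ValidationError,
)

__all__ = [
    "GeneCall",
    "TUExpressionSummary",
    "filter_degs",
    "detect_opposing",
    "call_genes",
    "aggregate_to_tus",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneCall:
    gene: str
    is_deg: bool
    n_significant_strains: int
    opposing: bool
    direction_hyper: str  # "up", "down" or "none"
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.opposing and self.direction_hyper == "none":
            raise ValidationError(f"{self.gene}: opposing call without a direction")


@dataclass(frozen=True)
class TUExpressionSummary:
    tu_id: str
    member_genes: tuple[str, ...]
    any_opposing: bool
    direction_hyper: str
    representative_gene: str
    representative_log2fc: Mapping[str, float]  # comparison -> log2FC


def _group_by_gene(
    records: Iterable[DifferentialExpressionRecord],
) -> dict[str, list[DifferentialExpressionRecord]]:
    seen: set[tuple[str, str]] = set()
    grouped: dict[str, list[DifferentialExpressionRecord]] = defaultdict(list)
    for r in records:
        key = (r.gene, r.comparison)
        if key in seen:
            raise ValidationError(f"duplicate record for gene {r.gene}, comparison {r.comparison}")
        seen.add(key)
        grouped[r.gene].append(r)
    return grouped


def _counts_as_deg(
    r: DifferentialExpressionRecord, lfc_threshold: float, fdr_threshold: float
) -> bool:
    return (
        r.fdr is not None
        and r.fdr < fdr_threshold
        and r.log2fc is not None
        and abs(r.log2fc) > lfc_threshold
    )


def detect_opposing(
    records: Sequence[DifferentialExpressionRecord],
    strain_classes: Mapping[str, str] = DEFAULT_STRAIN_CLASSES,
    fdr_threshold: float = 0.05,
) -> tuple[bool, str, bool]:
    """Opposing-pattern call for one gene's records.

    Returns (opposing, direction_hyper, ambiguous). Significance here is
    FDR-only (a sub-threshold fold change still carries its sign, as in
    the published table). Order of input records is irrelevant.
    """

    def sign(x: float | None) -> int:
        if x is None or x == 0:
            return 0
        return 1 if x > 0 else -1

    hyper_sig = []
    low_sig = []
    for r in records:
        if r.fdr is None or r.fdr >= fdr_threshold or r.log2fc is None:
            continue
        klass = strain_classes.get(r.comparison)
        if klass == "hyper":
            hyper_sig.append(r)
        elif klass == "low":
            low_sig.append(r)

    hyper_signs = {sign(r.log2fc) for r in hyper_sig} - {0}
    low_signs = {sign(r.log2fc) for r in low_sig} - {0}

    ambiguous = len(low_signs) > 1
    if hyper_signs:
        # smallest-FDR hyper call carries the direction
        best = min(hyper_sig, key=lambda r: r.fdr)
        direction = "up" if sign(best.log2fc) > 0 else "down"
        hyper_sign = sign(best.log2fc)
    elif len(low_signs) == 1:
        direction = "up" if next(iter(low_signs)) < 0 else "down"
        hyper_sign = -next(iter(low_signs))
    else:
        return False, "none", ambiguous

    if ambiguous:
        return False, direction, True
    # (c) no significant low call may share the hyper sign
    if any(s == hyper_sign for s in low_signs):
        return False, direction, False
    # (a) significant hyper + opposite-sign significant low, or
    # (b) low-only calls agreeing in sign
    opposing = (bool(hyper_signs) and bool(low_signs)) or (
        not hyper_signs and len(low_signs) == 1
    )
    return opposing, direction, False


def filter_degs(
    records: Iterable[DifferentialExpressionRecord],
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    min_strains: int = 2,
) -> list[GeneCall]:
    """DEG status only (opposing fields left unset); see :func:`call_genes`."""
    return call_genes(
        records,
        strain_classes={},
        lfc_threshold=lfc_threshold,
        fdr_threshold=fdr_threshold,
        min_strains=min_strains,
    )


def call_genes(
    records: Iterable[DifferentialExpressionRecord],
    strain_classes: Mapping[str, str] = DEFAULT_STRAIN_CLASSES,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    min_strains: int = 2,
) -> list[GeneCall]:
    """Per-gene DEG and opposing-pattern calls.

    A strain comparison counts toward DEG status iff the FDR is present
    and < fdr_threshold and |log2FC| > lfc_threshold, both strict. DEG
    status (>= min_strains counting comparisons) and opposing status are
    computed independently.
    """
    if lfc_threshold < 0 or not (0 < fdr_threshold <= 1):
        raise ValidationError("thresholds must be positive")
    if min_strains < 1:
        raise ValidationError("min_strains must be >= 1")
    calls = []
    for gene, recs in _group_by_gene(records).items():
        n_sig = sum(_counts_as_deg(r, lfc_threshold, fdr_threshold) for r in recs)
        opposing, direction, ambiguous = (
            detect_opposing(recs, strain_classes, fdr_threshold)
            if strain_classes
            else (False, "none", False)
        )
        calls.append(
            GeneCall(gene, n_sig >= min_strains, n_sig, opposing, direction, ambiguous)
        )
    return calls


def aggregate_to_tus(
    gene_calls: Sequence[GeneCall],
    operon_map: Mapping[str, str] | Sequence[TranscriptionalUnit],
    records: Iterable[DifferentialExpressionRecord] = (),
    strain_classes: Mapping[str, str] = DEFAULT_STRAIN_CLASSES,
) -> list[TUExpressionSummary]:
    """Roll gene calls up to transcriptional units.

    ``operon_map`` maps gene -> tu_id (or is a TU list, from which the
    map is built; a gene appearing in two TUs is an annotation error).
    Genes absent from the map become logged singleton TUs. The
    representative gene of a TU is the member with the smallest
    hyper-strain FDR; its log2FCs are reported per comparison.
    """
    if not isinstance(operon_map, Mapping):
        built: dict[str, str] = {}
        for tu in operon_map:
            for g in tu.genes:
                if g in built:
                    raise ValidationError(f"gene {g} belongs to two TUs ({built[g]}, {tu.tu_id})")
                built[g] = tu.tu_id
        operon_map = built

    recs_by_gene: dict[str, list[DifferentialExpressionRecord]] = defaultdict(list)
    for r in records:
        recs_by_gene[r.gene].append(r)

    hyper_strains = {s for s, k in strain_classes.items() if k == "hyper"}

    def hyper_fdr(gene: str) -> float:
        fdrs = [
            r.fdr
            for r in recs_by_gene.get(gene, [])
            if r.comparison in hyper_strains and r.fdr is not None
        ]
        return min(fdrs) if fdrs else float("inf")

    members: dict[str, list[GeneCall]] = defaultdict(list)
    for call in gene_calls:
        tu_id = operon_map.get(call.gene)
        if tu_id is None:
            tu_id = call.gene
            logger.info("gene %s not in operon map; treated as singleton TU", call.gene)
        members[tu_id].append(call)

    summaries = []
    for tu_id, calls in members.items():
        genes = tuple(c.gene for c in calls)
        rep = min(genes, key=lambda g: (hyper_fdr(g), g))
        rep_lfc = {
            r.comparison: r.log2fc
            for r in recs_by_gene.get(rep, [])
            if r.log2fc is not None
        }
        opposing_calls = [c for c in calls if c.opposing]
        directed = opposing_calls or [c for c in calls if c.direction_hyper != "none"]
        direction = (
            min(directed, key=lambda c: (hyper_fdr(c.gene), c.gene)).direction_hyper
            if directed
            else "none"
        )
        summaries.append(
            TUExpressionSummary(
                tu_id=tu_id,
                member_genes=genes,
                any_opposing=bool(opposing_calls),
                direction_hyper=direction,
                representative_gene=rep,
                representative_log2fc=rep_lfc,
            )
        )
    return summaries
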
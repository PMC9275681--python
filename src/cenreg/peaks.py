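"""Replicate-concordance filtering of ChIP peaks and TSS-proximity
assignment of consensus peaks to transcriptional units.

The published filter keeps binding sites "present in three or more
biological replicates" and near mapped TSSs; peaks in intragenic
regions or between convergent coding regions are dropped. The
concordance rule here is center-distance single linkage (the overlap
criterion itself is not stated in the source analysis), with support
counted over distinct (strain, replicate) experiments pooled across
strains — a site is one site, while per-strain enrichment is averaged
separately and left missing for strains with no member peaks.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import (  # noqa: F401  (re-exported domain types)
    GenomicInterval,
    Peak,
    TranscriptionalUnit,
    ValidationError,
)

__all__ = [
    "Peak",
    "ConsensusPeak",
    "PeakAssignment",
    "cluster_replicate_peaks",
    "filter_by_support",
    "assign_to_tss",
]


@dataclass(frozen=True)
class ConsensusPeak:
    """A replicate-concordant binding site."""

    replicon: str
    center: int
    support: int  # distinct (strain, replicate) experiments
    per_strain_enrichment: Mapping[str, float]
    member_peaks: tuple[Peak, ...]

    @property
    def mean_enrichment(self) -> float:
        vals = list(self.per_strain_enrichment.values())
        return sum(vals) / len(vals)


@dataclass(frozen=True)
class PeakAssignment:
    """A consensus peak placed relative to one TU's TSS.

    ``distance_to_tss`` is signed in the TU's frame (negative =
    upstream). Only ``classification == "upstream"`` assignments
    propagate to the regulon stage. ``shared`` marks peaks assigned to
    more than one TU (divergent or tandem promoters).
    """

    peak: ConsensusPeak
    tu_id: str | None
    distance_to_tss: int | None
    classification: str  # upstream | intragenic | convergent_intergenic | orphan
    shared: bool = False


def cluster_replicate_peaks(
    peaks: Sequence[Peak], max_center_distance: int = 100
) -> list[ConsensusPeak]:
    """Single-linkage clustering of peak centers within a distance cutoff.

    Deterministic under input permutation: peaks are first sorted by
    (replicon, center, strain, replicate). On a line, single linkage
    reduces to chaining peaks whose adjacent centers are within the
    cutoff. The consensus center is the (lower) median of member
    centers.
    """
    if max_center_distance < 0:
        raise ValidationError("max_center_distance must be >= 0")
    ordered = sorted(
        peaks, key=lambda p: (p.replicon, p.center, p.strain, p.replicate, p.name)
    )
    consensus: list[ConsensusPeak] = []
    cluster: list[Peak] = []

    def flush() -> None:
        if not cluster:
            return
        centers = [p.center for p in cluster]
        center = int(statistics.median_low(centers))
        support = len({(p.strain, p.replicate) for p in cluster})
        by_strain: dict[str, list[float]] = {}
        for p in cluster:
            by_strain.setdefault(p.strain, []).append(p.fold_enrichment)
        enrich = {s: sum(v) / len(v) for s, v in sorted(by_strain.items())}
        consensus.append(
            ConsensusPeak(cluster[0].replicon, center, support, enrich, tuple(cluster))
        )

    for p in ordered:
        if cluster and (
            p.replicon != cluster[-1].replicon
            or p.center - cluster[-1].center > max_center_distance
        ):
            flush()
            cluster = []
        cluster.append(p)
    flush()
    return consensus


def filter_by_support(
    consensus: Sequence[ConsensusPeak], min_replicates: int = 3
) -> list[ConsensusPeak]:
    """Keep consensus peaks supported by >= min_replicates distinct
    biological replicates."""
    if min_replicates < 1:
        raise ValidationError("min_replicates must be >= 1")
    return [c for c in consensus if c.support >= min_replicates]


def _flanking_tus(
    tus: Sequence[TranscriptionalUnit], replicon: str, center: int
) -> tuple[TranscriptionalUnit | None, TranscriptionalUnit | None]:
    left = right = None
    for tu in tus:
        if tu.replicon != replicon:
            continue
        if tu.interval.end <= center:
            if left is None or tu.interval.end > left.interval.end:
                left = tu
        elif tu.interval.start > center:
            if right is None or tu.interval.start < right.interval.start:
                right = tu
    return left, right


def assign_to_tss(
    consensus: Sequence[ConsensusPeak],
    tus: Sequence[TranscriptionalUnit],
    window_upstream: int = 300,
    window_downstream: int = 100,
) -> list[PeakAssignment]:
    """Assign each consensus peak to every TU whose TSS it lies near.

    A peak is ``upstream`` for a TU when its center falls within
    ``window_upstream`` bp upstream through ``window_downstream`` bp
    downstream of the TSS in the TU's frame. Multi-assignment is allowed
    and flagged shared. Unassigned peaks are classified ``intragenic``
    (center inside an annotated CDS), ``convergent_intergenic`` (between
    TUs pointing toward each other), or ``orphan``.
    """
    if window_upstream < 0 or window_downstream < 0:
        raise ValidationError("assignment windows must be >= 0")
    for tu in tus:
        if tu.tss is None:
            raise ValidationError(f"TU {tu.tu_id} lacks an annotated TSS")

    assignments: list[PeakAssignment] = []
    for peak in consensus:
        hits: list[tuple[str, int]] = []
        for tu in tus:
            if tu.replicon != peak.replicon:
                continue
            rel = tu.to_relative(peak.center)
            if -window_upstream <= rel <= window_downstream:
                hits.append((tu.tu_id, rel))
        if hits:
            shared = len(hits) > 1
            for tu_id, rel in hits:
                assignments.append(
                    PeakAssignment(peak, tu_id, rel, "upstream", shared=shared)
                )
            continue
        in_cds = any(
            iv.contains(peak.center)
            for tu in tus
            if tu.replicon == peak.replicon
            for iv in tu.genes.values()
        )
        if in_cds:
            assignments.append(PeakAssignment(peak, None, None, "intragenic"))
            continue
        left, right = _flanking_tus(tus, peak.replicon, peak.center)
        if (
            left is not None
            and right is not None
            and left.strand == "+"
            and right.strand == "-"
        ):
            assignments.append(PeakAssignment(peak, None, None, "convergent_intergenic"))
        else:
            assignments.append(PeakAssignment(peak, None, None, "orphan"))
    return assignments
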
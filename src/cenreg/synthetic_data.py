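"""Seeded generator of genomes, planted binding sites, ChIP peak tables and
differential-expression tables with known truth.

The generator emulates the study design around the CenKR two-component
system: four strains spanning an activity gradient (phosphomimetic
``D56E`` > ``WT`` > kinase deletion ``dcenK`` ~ non-phosphorylatable
``D56A``), replicated ChIP peaks whose detection probability grows with
the strain's mean fold-enrichment, planted TGA-N8-TGA direct-repeat
sites upstream of target operons (upstream of the -35 hexamer for
activated targets, on top of the promoter for repressed ones), and
summary-level RNA-seq effects with opposing signs between the
hyperactive and low-activity strains. Differential expression is
simulated at the (log2FC, p, FDR) summary level; the pipeline consumes
DE tables, so read-count simulation is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import (
    DEFAULT_STRAIN_CLASSES,
    DEFAULT_STRAINS,
    DifferentialExpressionRecord,
    GenomicInterval,
    Peak,
    TranscriptionalUnit,
)

__all__ = [
    "SimulationConfig",
    "TruthEntry",
    "TruthTable",
    "benjamini_hochberg",
    "simulate_genome_and_annotations",
    "plant_sites",
    "simulate_peaks",
    "simulate_de",
    "simulate_all",
    "SimulatedDataset",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the published conditions where stated: the strain set
    and its activity classes, enrichment means anchored to the tolQ row
    of the regulon table (4.5 / 3.2 / 1.6 / 1.6), GC content of the
    organism (~0.68), a >=0.5 log2FC / <0.05 FDR effect-size regime, and
    a ~30% rate of "n.s." low-activity cells. Replicate count (4) is a
    choice consistent with a >=3-replicate concordance filter.
    """

    seed: int = 0
    n_tus: int = 60
    n_direct_targets: int = 40
    frac_repressed: float = 0.3
    genome_length: int | None = None  # None = auto-sized to fit n_tus
    gc_content: float = 0.68
    strains: tuple[str, ...] = DEFAULT_STRAINS
    strain_classes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STRAIN_CLASSES)
    )
    n_replicates: int = 4
    peak_fpr: float = 2.0  # expected false peaks per replicon per replicate
    enrichment_means: Mapping[str, float] = field(
        default_factory=lambda: {"D56E": 4.5, "WT": 3.2, "dcenK": 1.6, "D56A": 1.6}
    )
    enrichment_sd: float = 0.25  # sd of log fold-enrichment
    detection_power: float | None = None  # overrides the enrichment-derived power
    jitter_sd: float = 10.0  # bp sd of peak-center jitter
    peak_width: int = 200
    lfc_effect_mean: float = 2.0
    lfc_effect_sd: float = 0.3
    low_effect_scale: float = 0.5  # |effect| in low-activity strains, relative to hyper
    null_lfc_sd: float = 0.2
    ns_frac: float = 0.3  # fraction of low-activity cells masked to "no effect"
    n_genes_per_tu: tuple[int, int] = (1, 3)
    upstream_length: int = 300
    utr_length: int = 40
    gene_length: int = 500
    intergenic_gap: int = 150

    def __post_init__(self) -> None:
        if self.n_direct_targets > self.n_tus:
            raise ConfigurationError("n_direct_targets must be <= n_tus")
        if not (0.0 < self.gc_content < 1.0):
            raise ConfigurationError("gc_content must be in (0, 1)")
        if not (0.0 <= self.frac_repressed <= 1.0):
            raise ConfigurationError("frac_repressed must be in [0, 1]")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.upstream_length < 200:
            raise ConfigurationError("upstream_length must be >= 200")
        lo, hi = self.n_genes_per_tu
        if not (1 <= lo <= hi):
            raise ConfigurationError("n_genes_per_tu must be a 1-based (lo, hi) range")

    # -- derived quantities -------------------------------------------------

    def detection_probability(self, strain: str) -> float:
        """Per-replicate probability that a true site yields a peak.

        Monotone in the strain's mean fold-enrichment:
        ``1 - exp(-0.75 * (mean - 1))``, clipped to [0, 1]; a mean of 1
        (no enrichment over input) gives zero power. An explicit
        ``detection_power`` overrides this for all strains.
        """
        if self.detection_power is not None:
            return float(np.clip(self.detection_power, 0.0, 1.0))
        mean = float(self.enrichment_means.get(strain, 1.0))
        return float(np.clip(1.0 - math.exp(-0.75 * (mean - 1.0)), 0.0, 1.0))

    @property
    def comparisons(self) -> tuple[str, ...]:
        """Mutant strains compared against WT, in strain order."""
        return tuple(s for s in self.strains if s != "WT")


@dataclass
class TruthEntry:
    tu_id: str
    is_direct_target: bool
    role: str  # "+", "-" or "" for non-targets
    genes: tuple[str, ...]
    site: GenomicInterval | None = None  # planted site, strand = TU strand
    site_seq: str | None = None  # coding-strand orientation
    rel_center: int | None = None  # site center relative to TSS (negative = upstream)
    planted_effect: dict[str, float] = field(default_factory=dict)  # comparison -> mu


@dataclass
class TruthTable:
    config: SimulationConfig
    replicon_lengths: dict[str, int]
    entries: list[TruthEntry]
    gene_effects: dict[tuple[str, str], float] = field(default_factory=dict)

    def direct_targets(self) -> list[TruthEntry]:
        return [e for e in self.entries if e.is_direct_target]

    def by_tu(self) -> dict[str, TruthEntry]:
        return {e.tu_id: e for e in self.entries}


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Rank-based step-up FDR adjustment: fdr_i = min_{j>=i}(p_(j) * m / j)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Genome and annotation synthesis
# ---------------------------------------------------------------------------


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=length, p=probs)


def simulate_genome_and_annotations(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptionalUnit]]:
    """Generate an i.i.d. background genome with tiled transcriptional units.

    Every TU gets an intergenic upstream region (>= 200 bp), a TSS, and
    -35 / -10 promoter hexamers at [-35, -30] and [-12, -7] relative to
    the TSS. TU strands are drawn at random; blocks are laid out in
    coordinate order on a single replicon.
    """
    rng = _rng(cfg, 1)
    strands = rng.choice(["+", "-"], size=cfg.n_tus) if cfg.n_tus else np.array([])
    n_genes = (
        rng.integers(cfg.n_genes_per_tu[0], cfg.n_genes_per_tu[1] + 1, size=cfg.n_tus)
        if cfg.n_tus
        else np.array([], dtype=int)
    )
    gap = 20  # intra-operon spacer between CDSs

    tus: list[TranscriptionalUnit] = []
    cursor = cfg.intergenic_gap
    for i in range(cfg.n_tus):
        k = int(n_genes[i])
        tx_len = cfg.utr_length + k * cfg.gene_length + (k - 1) * gap
        block = cfg.upstream_length + tx_len
        start = cursor
        strand = str(strands[i])
        tu_id = f"TU{i:04d}"
        if strand == "+":
            tss = start + cfg.upstream_length
            interval = GenomicInterval("chr1", tss, tss + tx_len, "+")
            minus35 = GenomicInterval("chr1", tss - 35, tss - 29, "+")
            minus10 = GenomicInterval("chr1", tss - 12, tss - 6, "+")
            genes = {}
            g = tss + cfg.utr_length
            for j in range(k):
                genes[f"{tu_id}g{j}"] = GenomicInterval("chr1", g, g + cfg.gene_length, "+")
                g += cfg.gene_length + gap
        else:
            tss = start + tx_len - 1
            interval = GenomicInterval("chr1", start, tss + 1, "-")
            minus35 = GenomicInterval("chr1", tss + 30, tss + 36, "-")
            minus10 = GenomicInterval("chr1", tss + 7, tss + 13, "-")
            genes = {}
            e = tss + 1 - cfg.utr_length
            for j in range(k):
                genes[f"{tu_id}g{j}"] = GenomicInterval("chr1", e - cfg.gene_length, e, "-")
                e -= cfg.gene_length + gap
        tus.append(
            TranscriptionalUnit(tu_id, interval, tss, genes, minus35, minus10)
        )
        cursor = start + block + cfg.intergenic_gap

    required = cursor + cfg.intergenic_gap
    length = cfg.genome_length if cfg.genome_length is not None else required
    if length < required:
        raise ConfigurationError(
            f"genome_length {length} too short for {cfg.n_tus} TUs (need {required})"
        )
    seq = _random_sequence(rng, length, cfg.gc_content)
    genome = {"chr1": "".join(_BASES[seq])}
    return genome, tus


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------

SITE_WIDTH = 15


def _sample_site(rng: np.random.Generator, gc: float) -> str:
    """A 15-mer direct repeat: T[GC]A - N8 - T[GC]A - N (background Ns)."""
    bg = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    def half() -> str:
        return "T" + ("G" if rng.random() < 0.5 else "C") + "A"

    middle = "".join(_BASES[rng.choice(4, size=8, p=bg)])
    flank = str(_BASES[rng.choice(4, p=bg)])
    return half() + middle + half() + flank


def plant_sites(
    genome: Mapping[str, str],
    tus: Sequence[TranscriptionalUnit],
    cfg: SimulationConfig,
) -> tuple[dict[str, str], TruthTable]:
    """Write direct-repeat sites into upstream regions of target TUs.

    Activated targets get a site wholly upstream of the -35 element
    (center drawn in [-75, -45] relative to the TSS); repressed targets
    get a site overlapping the promoter/TSS span (center in [-28, -10]).
    """
    rng = _rng(cfg, 2)
    if cfg.n_direct_targets > len(tus):
        raise ConfigurationError("more direct targets than TUs")
    order = rng.permutation(len(tus))
    target_idx = sorted(order[: cfg.n_direct_targets].tolist())
    n_rep = int(round(cfg.frac_repressed * cfg.n_direct_targets))
    repressed = set(rng.choice(target_idx, size=n_rep, replace=False).tolist()) if n_rep else set()

    mutable = {name: list(seq) for name, seq in genome.items()}
    entries: list[TruthEntry] = []
    for i, tu in enumerate(tus):
        genes = tuple(tu.genes)
        if i not in set(target_idx):
            entries.append(TruthEntry(tu.tu_id, False, "", genes))
            continue
        role = "-" if i in repressed else "+"
        site_seq = _sample_site(rng, cfg.gc_content)
        half = SITE_WIDTH // 2
        if role == "+":
            c = int(rng.integers(-75, -44))  # end = c+7 <= -37, upstream of -35
        else:
            c = int(rng.integers(-28, -9))  # overlaps [-35, 0]
        if tu.strand == "+":
            g_start = tu.tss + c - half
            written = site_seq
        else:
            g_start = tu.tss - c - half
            written = revcomp(site_seq)
        g_end = g_start + SITE_WIDTH
        site = GenomicInterval(tu.replicon, g_start, g_end, tu.strand)
        for gene_iv in tu.genes.values():
            if site.overlaps(gene_iv):
                raise ConfigurationError(
                    f"planted site for {tu.tu_id} overlaps a coding region"
                )
        mutable[tu.replicon][g_start:g_end] = list(written)
        entries.append(
            TruthEntry(tu.tu_id, True, role, genes, site, site_seq, c)
        )

    planted = {name: "".join(chars) for name, chars in mutable.items()}
    truth = TruthTable(
        config=cfg,
        replicon_lengths={name: len(seq) for name, seq in planted.items()},
        entries=entries,
    )
    return planted, truth


# ---------------------------------------------------------------------------
# ChIP peak simulation
# ---------------------------------------------------------------------------


def simulate_peaks(
    truth: TruthTable, cfg: SimulationConfig | None = None
) -> dict[tuple[str, str], list[Peak]]:
    """Per strain x replicate peak tables.

    Every true site yields a peak per replicate with the strain's
    detection probability; centers are jittered Normal(0, jitter_sd);
    enrichments are lognormal around the strain mean; false peaks arrive
    Poisson(peak_fpr) per replicon per replicate, uniformly placed. All
    randomness for true sites is drawn up-front in a fixed order so that
    runs with different enrichment means share detection draws (coupling
    under a shared seed).
    """
    cfg = cfg or truth.config
    rng = _rng(cfg, 3)
    sites = [e for e in truth.direct_targets() if e.site is not None]
    n_sites, n_strains, n_reps = len(sites), len(cfg.strains), cfg.n_replicates

    u = rng.random((n_sites, n_strains, n_reps))
    jitter = rng.normal(0.0, cfg.jitter_sd, size=(n_sites, n_strains, n_reps))
    log_e = rng.normal(0.0, 1.0, size=(n_sites, n_strains, n_reps))

    half_w = cfg.peak_width // 2
    out: dict[tuple[str, str], list[Peak]] = {}
    for si, strain in enumerate(cfg.strains):
        power = cfg.detection_probability(strain)
        mean = float(cfg.enrichment_means.get(strain, 1.0))
        # lognormal parameterized so the arithmetic mean equals the strain mean
        mu = math.log(max(mean, 1e-9)) - cfg.enrichment_sd**2 / 2
        for ri in range(n_reps):
            rep = f"rep{ri + 1}"
            peaks: list[Peak] = []
            for ki, entry in enumerate(sites):
                if u[ki, si, ri] >= power:
                    continue
                center = int(entry.site.center + round(jitter[ki, si, ri]))
                enrich = math.exp(mu + cfg.enrichment_sd * log_e[ki, si, ri])
                iv = GenomicInterval(
                    entry.site.replicon, max(0, center - half_w), center + half_w
                )
                peaks.append(
                    Peak(iv, enrich, strain, rep, name=f"{strain}:{rep}:{entry.tu_id}",
                         center=center)
                )
            for replicon, length in truth.replicon_lengths.items():
                n_false = rng.poisson(cfg.peak_fpr)
                for _ in range(n_false):
                    center = int(rng.integers(half_w, max(length - half_w, half_w + 1)))
                    enrich = math.exp(mu + cfg.enrichment_sd * rng.normal())
                    iv = GenomicInterval(replicon, center - half_w, center + half_w)
                    peaks.append(
                        Peak(iv, enrich, strain, rep, name=f"{strain}:{rep}:fp", center=center)
                    )
            out[(strain, rep)] = peaks
    return out


# ---------------------------------------------------------------------------
# Differential-expression simulation
# ---------------------------------------------------------------------------


def simulate_de(
    truth: TruthTable, cfg: SimulationConfig | None = None
) -> dict[str, list[DifferentialExpressionRecord]]:
    """Summary-level DE tables, one per strain comparison (mutant vs WT).

    Direct-target genes receive the planted effect (sign per role,
    negated and scaled in low-activity strains, masked to zero with
    probability ``ns_frac`` per low-activity cell); all other genes are
    null. Two-sided z-test p-values against the null sd, BH-adjusted
    within each comparison.
    """
    cfg = cfg or truth.config
    rng = _rng(cfg, 4)
    genes: list[str] = [g for e in truth.entries for g in e.genes]
    gene_entry = {g: e for e in truth.entries for g in e.genes}

    out: dict[str, list[DifferentialExpressionRecord]] = {}
    for comp in cfg.comparisons:
        klass = cfg.strain_classes.get(comp, "low")
        mus = np.zeros(len(genes))
        for gi, g in enumerate(genes):
            e = gene_entry[g]
            if not e.is_direct_target:
                continue
            sign = 1.0 if e.role == "+" else -1.0
            if klass == "hyper":
                mu = sign * cfg.lfc_effect_mean
            else:
                mu = -sign * cfg.lfc_effect_mean * cfg.low_effect_scale
                if rng.random() < cfg.ns_frac:
                    mu = 0.0
            mus[gi] = mu
            truth.gene_effects[(g, comp)] = mu
            e.planted_effect.setdefault(comp, sign * cfg.lfc_effect_mean if klass == "hyper" else -sign * cfg.lfc_effect_mean * cfg.low_effect_scale)
        noise_sd = np.where(mus != 0.0, cfg.lfc_effect_sd, cfg.null_lfc_sd)
        lfc = mus + rng.normal(0.0, 1.0, size=len(genes)) * noise_sd
        pvals = 2.0 * stats.norm.sf(np.abs(lfc) / cfg.null_lfc_sd)
        fdrs = benjamini_hochberg(pvals)
        out[comp] = [
            DifferentialExpressionRecord(g, comp, float(lfc[gi]), float(fdrs[gi]))
            for gi, g in enumerate(genes)
        ]
    return out


# ---------------------------------------------------------------------------
# Planted-motif sequence sets (for exercising the discovery engine)
# ---------------------------------------------------------------------------


def simulate_motif_dataset(
    n_sequences: int = 20,
    seq_length: int = 200,
    width: int = 14,
    n_with_site: int = 18,
    seed: int = 11,
    sharpness: float = 0.95,
    gc: float = 0.5,
) -> tuple[dict[str, str], dict[str, int | None], np.ndarray]:
    """Random sequences with a sharp-PWM motif planted in a subset.

    The generator PWM puts ``sharpness`` probability on a random
    consensus base per column, the rest split evenly. Returns
    (sequences, planted offset per sequence or None, generator PWM).
    """
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=width)
    pwm = np.full((4, width), (1 - sharpness) / 3)
    pwm[consensus, np.arange(width)] = sharpness
    bg = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    sequences: dict[str, str] = {}
    offsets: dict[str, int | None] = {}
    with_site = set(rng.choice(n_sequences, size=n_with_site, replace=False).tolist())
    for i in range(n_sequences):
        seq = list(_BASES[rng.choice(4, size=seq_length, p=bg)])
        name = f"seq{i:02d}"
        if i in with_site:
            off = int(rng.integers(0, seq_length - width + 1))
            site = [
                _BASES[rng.choice(4, p=pwm[:, j])] for j in range(width)
            ]
            seq[off : off + width] = site
            offsets[name] = off
        else:
            offsets[name] = None
        sequences[name] = "".join(seq)
    return sequences, offsets, pwm


# ---------------------------------------------------------------------------
# One-call convenience
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    tus: list[TranscriptionalUnit]
    truth: TruthTable
    peaks: dict[tuple[str, str], list[Peak]]
    de: dict[str, list[DifferentialExpressionRecord]]

    def all_peaks(self) -> list[Peak]:
        return [p for plist in self.peaks.values() for p in plist]

    def all_de_records(self) -> list[DifferentialExpressionRecord]:
        return [r for rlist in self.de.values() for r in rlist]


def simulate_all(cfg: SimulationConfig) -> SimulatedDataset:
    genome, tus = simulate_genome_and_annotations(cfg)
    genome, truth = plant_sites(genome, tus, cfg)
    peaks = simulate_peaks(truth, cfg)
    de = simulate_de(truth, cfg)
    return SimulatedDataset(cfg, genome, tus, truth, peaks, de)
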
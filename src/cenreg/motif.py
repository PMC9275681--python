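"""Position weight matrices, log-odds scanning, ZOOPS-EM motif discovery,
direct-repeat matching, and cross-species conservation reports.

The scanner is a PatSer-style log-odds scorer in bits,
``score = sum_j log2(p[b_j][j] / q[b_j])``; the discovery routine is a
MEME-style expectation-maximization over the ZOOPS model (zero or one
motif occurrence per sequence, latent presence/offset/strand) with
multi-width model selection by information content x expected site
count. MEME's classic objective and E-value statistics are deliberately
not reproduced; this stand-in objective is documented in the methods
note.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .io_formats import ValidationError

__all__ = [
    "PWM",
    "MotifSite",
    "DiscoveryResult",
    "DegenerateInputError",
    "revcomp",
    "background_from_sequences",
    "build_pwm",
    "scan",
    "best_site_per_sequence",
    "discover_zoops",
    "match_direct_repeat",
    "extract_upstream",
    "conservation_report",
    "write_meme",
    "read_meme",
]

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNSW", "TGCAYRMKVBHDNSW")


class DegenerateInputError(ValueError):
    """Discovery input carries no usable sequence variation."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; any IUPAC-ambiguous base -> 4 (scores 0 bits)."""
    arr = np.fromiter((_IDX.get(b, 4) for b in seq.upper()), dtype=np.int8, count=len(seq))
    return arr


def background_from_sequences(sequences: Iterable[str]) -> np.ndarray:
    """0th-order background from a sequence set, both strands pooled
    (hence strand-symmetric: q[A]=q[T], q[C]=q[G])."""
    counts = np.zeros(4)
    for seq in sequences:
        enc = encode(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    if counts.sum() == 0:
        raise DegenerateInputError("no unambiguous bases in sequence set")
    counts = counts + counts[::-1]  # pool with the complementary strand
    return counts / counts.sum()


@dataclass(frozen=True)
class PWM:
    """Probability + log-odds representation of a binding motif.

    ``probs[b][j] = (counts[b][j] + kappa * q[b]) / (n_sites + kappa)``
    with pseudocount kappa split by background proportions.
    """

    probs: np.ndarray  # (4, W)
    background: np.ndarray  # (4,)
    pseudocount: float = 1.0
    n_sites: int = 0
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        q = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "background", q)
        if p.ndim != 2 or p.shape[0] != 4:
            raise ValidationError("probs must be a 4 x W matrix")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-9):
            raise ValidationError("PWM columns must each sum to 1")
        if not np.isclose(q.sum(), 1.0, atol=1e-9):
            raise ValidationError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """(5, W) log2(p/q) with a zero row for ambiguous bases."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background[:, None])
        return np.vstack([lo, np.zeros(self.width)])

    @property
    def information_content(self) -> float:
        """Total IC in bits, sum_j sum_b p log2(p/q); non-negative."""
        return float(np.sum(self.column_ic))

    @property
    def column_ic(self) -> np.ndarray:
        p, q = self.probs, self.background[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / q), 0.0)
        return terms.sum(axis=0)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:4].max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.probs[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
            self.n_sites,
        )


@dataclass(frozen=True)
class MotifSite:
    """One scored motif occurrence within a scanned sequence.

    ``offset`` is 0-based on the forward coordinates of the scanned
    window; for strand "-", ``site_seq`` is the reverse complement of
    the covered window (motif orientation).
    """

    source_seq_id: str
    offset: int
    strand: str
    site_seq: str
    score: float
    position_vs_tss: int | None = None


def build_pwm(
    sites: Sequence[str],
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> PWM:
    """Count matrix -> probability matrix with background-split pseudocount."""
    if not sites:
        raise ValidationError("at least one site is required")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValidationError("sites must have uniform length")
    for s in sites:
        for j, b in enumerate(s.upper()):
            if b not in _IDX:
                raise ValidationError(f"non-ACGT character {b!r} at position {j} of {s!r}")
    q = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    counts = np.zeros((4, width))
    for s in sites:
        for j, b in enumerate(s.upper()):
            counts[_IDX[b], j] += 1
    n = len(sites)
    probs = (counts + pseudocount * q[:, None]) / (n + pseudocount)
    return PWM(probs, q, pseudocount, n, counts)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _window_scores(lo: np.ndarray, enc: np.ndarray, width: int) -> np.ndarray:
    """Score every offset of an encoded sequence against a (5, W) log-odds
    matrix; O(W) vectorized passes."""
    m = enc.size - width + 1
    scores = np.zeros(m)
    for k in range(width):
        scores += lo[enc[k : k + m], k]
    return scores


def scan(
    pwm: PWM,
    sequence: str,
    both_strands: bool = True,
    threshold: float = 0.0,
    seq_id: str = "",
) -> list[MotifSite]:
    """All offsets scoring >= threshold bits, sorted by descending score,
    then ascending offset, then strand (+ first). A sequence shorter than
    the motif yields an empty result with a warning."""
    W = pwm.width
    if len(sequence) < W:
        warnings.warn(
            f"sequence {seq_id or '<unnamed>'} shorter than motif width {W}; no sites"
        )
        return []
    enc = encode(sequence)
    hits: list[MotifSite] = []
    fwd = _window_scores(pwm.log_odds, enc, W)
    strands = [("+", fwd)]
    if both_strands:
        rc_lo = np.vstack([pwm.log_odds[:4][::-1, ::-1], np.zeros(W)])
        strands.append(("-", _window_scores(rc_lo, enc, W)))
    for strand, scores in strands:
        for off in np.nonzero(scores >= threshold)[0]:
            window = sequence[off : off + W].upper()
            site_seq = window if strand == "+" else revcomp(window)
            hits.append(MotifSite(seq_id, int(off), strand, site_seq, float(scores[off])))
    hits.sort(key=lambda h: (-h.score, h.offset, h.strand != "+"))
    return hits


def best_site_per_sequence(
    pwm: PWM, sequences: Mapping[str, str], both_strands: bool = True
) -> dict[str, MotifSite]:
    """The single top-scoring site per sequence (ties: smallest offset,
    then + strand), ignoring any threshold."""
    out: dict[str, MotifSite] = {}
    for seq_id, seq in sequences.items():
        hits = scan(pwm, seq, both_strands=both_strands, threshold=-np.inf, seq_id=seq_id)
        if hits:
            out[seq_id] = hits[0]
    return out


# ---------------------------------------------------------------------------
# ZOOPS-EM discovery
# ---------------------------------------------------------------------------


@dataclass
class DiscoveryResult:
    pwm: PWM
    sites: dict[str, MotifSite | None]
    objective: float
    n_sequences_with_site: int
    width: int
    gamma: float
    log_likelihood: float
    log_likelihood_trajectory: list[float] = field(default_factory=list)


def _zoops_loglik(
    encs: list[np.ndarray],
    width: int,
    q: np.ndarray,
    use_revcomp: bool,
    theta: np.ndarray,
    gamma: float,
) -> float:
    """Observed-data ZOOPS log-likelihood (relative to the background
    model) for a fixed parameter set; used to screen seed candidates."""
    tiny = 1e-300
    lo_nat = np.log(np.maximum(theta, tiny)) - np.log(np.maximum(q, tiny))[:, None]
    lo = np.vstack([lo_nat, np.zeros(width)])
    lo_rc = np.vstack([lo_nat[::-1, ::-1], np.zeros(width)])
    n_strands = 2 if use_revcomp else 1
    ll = 0.0
    for enc in encs:
        m = enc.size - width + 1
        llo = _window_scores(lo, enc, width)
        if use_revcomp:
            llo = np.concatenate([llo, _window_scores(lo_rc, enc, width)])
        site_log = np.log(gamma) - np.log(n_strands * m) + llo
        ll += logsumexp(np.concatenate([[np.log1p(-gamma)], site_log]))
    return float(ll)


def _zoops_em_single(
    encs: list[np.ndarray],
    width: int,
    q: np.ndarray,
    use_revcomp: bool,
    theta0: np.ndarray,
    gamma0: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, float, list[float]]:
    """One EM run. Returns (theta, gamma, loglik, trajectory); the
    observed-data log-likelihood is asserted non-decreasing every
    iteration (pure maximum-likelihood M-step, so the EM guarantee
    applies exactly)."""
    comp_encs = [np.where(e < 4, 3 - e, 4) for e in encs]
    n_strands = 2 if use_revcomp else 1
    theta, gamma = theta0.copy(), gamma0
    trajectory: list[float] = []
    prev_ll = -np.inf
    tiny = 1e-300

    for _ in range(max_iter):
        log_theta = np.log(np.maximum(theta, tiny))
        log_q = np.log(np.maximum(q, tiny))
        lo = np.vstack([log_theta - log_q[:, None], np.zeros(width)])
        lo_rc = np.vstack([(log_theta - log_q[:, None])[::-1, ::-1], np.zeros(width)])

        new_counts = np.zeros((5, width))
        gamma_sum = 0.0
        ll = 0.0
        for enc, cenc in zip(encs, comp_encs):
            m = enc.size - width + 1
            llo_f = _window_scores(lo, enc, width)
            parts = [llo_f]
            if use_revcomp:
                parts.append(_window_scores(lo_rc, enc, width))
            llo = np.concatenate(parts)  # (S*m,)
            site_log = np.log(gamma) - np.log(n_strands * m) + llo
            log_f = logsumexp(np.concatenate([[np.log1p(-gamma)], site_log]))
            ll += log_f
            resp = np.exp(site_log - log_f)
            z_site = resp.sum()
            gamma_sum += z_site
            r_f = resp[:m]
            for k in range(width):
                np.add.at(new_counts[:, k], enc[k : k + m], r_f)
            if use_revcomp:
                r_r = resp[m:]
                for k in range(width):
                    np.add.at(new_counts[:, k], cenc[width - 1 - k : width - 1 - k + m], r_r)

        trajectory.append(ll)
        if ll + 1e-9 * max(1.0, abs(ll)) < prev_ll:
            raise AssertionError(f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        converged = abs(ll - prev_ll) < tol
        prev_ll = ll

        counts4 = new_counts[:4]
        col_tot = counts4.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(col_tot > 0, counts4 / np.maximum(col_tot, tiny), q[:, None])
        gamma = float(np.clip(gamma_sum / len(encs), 1e-6, 1.0 - 1e-6))
        if converged:
            break
    return theta, gamma, prev_ll, trajectory


def _zoops_assign_sites(
    seq_ids: list[str],
    seqs: list[str],
    encs: list[np.ndarray],
    width: int,
    q: np.ndarray,
    use_revcomp: bool,
    theta: np.ndarray,
    gamma: float,
) -> tuple[dict[str, MotifSite | None], float]:
    """Hard per-sequence site calls from the converged model; a site is
    present when the posterior site probability exceeds 1/2."""
    tiny = 1e-300
    log_theta = np.log(np.maximum(theta, tiny))
    log_q = np.log(np.maximum(q, tiny))
    lo_nat = log_theta - log_q[:, None]
    lo = np.vstack([lo_nat, np.zeros(width)])
    lo_rc = np.vstack([lo_nat[::-1, ::-1], np.zeros(width)])
    n_strands = 2 if use_revcomp else 1
    expected_sites = 0.0
    sites: dict[str, MotifSite | None] = {}
    for seq_id, seq, enc in zip(seq_ids, seqs, encs):
        m = enc.size - width + 1
        llo_f = _window_scores(lo, enc, width)
        llo = np.concatenate(
            [llo_f, _window_scores(lo_rc, enc, width)] if use_revcomp else [llo_f]
        )
        site_log = np.log(gamma) - np.log(n_strands * m) + llo
        log_f = logsumexp(np.concatenate([[np.log1p(-gamma)], site_log]))
        p_site = float(np.exp(logsumexp(site_log) - log_f))
        expected_sites += p_site
        if p_site <= 0.5:
            sites[seq_id] = None
            continue
        best = int(np.argmax(llo))  # ties resolve to + strand, smaller offset
        strand = "+" if best < m else "-"
        off = best if best < m else best - m
        window = seq[off : off + width].upper()
        site_seq = window if strand == "+" else revcomp(window)
        score_bits = float(llo[best] / np.log(2))
        sites[seq_id] = MotifSite(seq_id, off, strand, site_seq, score_bits)
    return sites, expected_sites


def discover_zoops(
    sequences: Mapping[str, str] | Sequence[str],
    w_min: int = 10,
    w_max: int = 20,
    revcomp_search: bool = True,
    n_restarts: int = 5,
    seed: int = 0,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> DiscoveryResult:
    """ZOOPS-EM motif discovery across widths w_min..w_max.

    Per width, EM runs from ``n_restarts`` seeded subsequence
    initializations; the best restart (by log-likelihood) competes
    across widths on objective = IC_bits x expected site count.
    Deterministic given the seed.
    """
    if isinstance(sequences, Mapping):
        seq_ids, seqs = list(sequences.keys()), [sequences[k] for k in sequences]
    else:
        seq_ids, seqs = [f"seq{i}" for i in range(len(sequences))], list(sequences)
    if len(seqs) < 2:
        raise ValidationError("ZOOPS discovery requires at least 2 sequences")
    if min(len(s) for s in seqs) < w_max:
        raise ValidationError(f"every sequence must be at least w_max={w_max} long")
    encs = [encode(s) for s in seqs]
    distinct = set()
    for e in encs:
        distinct.update(np.unique(e[e < 4]).tolist())
    if len(distinct) < 2:
        raise DegenerateInputError("sequences carry a single-letter alphabet")
    q = (
        background_from_sequences(seqs)
        if background is None
        else np.asarray(background, dtype=float)
    )
    rng = np.random.default_rng(seed)

    def seed_theta(width: int, i: int, off: int) -> np.ndarray:
        theta0 = np.tile(q[:, None], (1, width)) * 0.5
        for k, b in enumerate(encs[i][off : off + width]):
            if b < 4:
                theta0[b, k] += 0.5
        return theta0 / theta0.sum(axis=0)

    best: DiscoveryResult | None = None
    for width in range(w_min, w_max + 1):
        # MEME-style starts: screen random subsequence seeds with a
        # one-E-step likelihood, then run EM from the most promising.
        n_screen = max(30, 10 * n_restarts)
        seen: set[tuple[int, int]] = set()
        scored: list[tuple[float, int, int]] = []
        for _ in range(n_screen):
            i = int(rng.integers(len(seqs)))
            off = int(rng.integers(len(seqs[i]) - width + 1))
            if (i, off) in seen:
                continue
            seen.add((i, off))
            ll1 = _zoops_loglik(
                encs, width, q, revcomp_search, seed_theta(width, i, off), 0.5
            )
            scored.append((ll1, i, off))
        scored.sort(key=lambda t: -t[0])
        best_ll, best_model = -np.inf, None
        for _, i, off in scored[:n_restarts]:
            theta, gamma, ll, traj = _zoops_em_single(
                encs, width, q, revcomp_search, seed_theta(width, i, off), 0.5, max_iter, tol
            )
            if ll > best_ll:
                best_ll, best_model = ll, (theta, gamma, traj)
        theta, gamma, traj = best_model
        sites, expected = _zoops_assign_sites(
            seq_ids, seqs, encs, width, q, revcomp_search, theta, gamma
        )
        em_pwm = PWM(theta, q, 0.0, int(round(expected)))
        objective = em_pwm.information_content * expected
        hard = [s.site_seq for s in sites.values() if s is not None and set(s.site_seq) <= set(ALPHABET)]
        pwm = build_pwm(hard, q, pseudocount) if hard else em_pwm
        result = DiscoveryResult(
            pwm=pwm,
            sites=sites,
            objective=objective,
            n_sequences_with_site=sum(s is not None for s in sites.values()),
            width=width,
            gamma=gamma,
            log_likelihood=best_ll,
            log_likelihood_trajectory=traj,
        )
        if best is None or result.objective > best.objective:
            best = result
    return best


# ---------------------------------------------------------------------------
# Direct-repeat matching
# ---------------------------------------------------------------------------


def match_direct_repeat(
    window: str,
    half_site: str = "TGA",
    gap: int = 8,
    max_mismatch: int = 2,
) -> list[tuple[int, int]]:
    """Offsets where half_site - N_gap - half_site matches with at most
    ``max_mismatch`` total mismatches; returns (offset, n_mismatches)."""
    if set(half_site.upper()) - set(ALPHABET):
        raise ValidationError("half_site must be over ACGT")
    if gap < 0:
        raise ValidationError("gap must be >= 0")
    window = window.upper()
    h = half_site.upper()
    span = 2 * len(h) + gap
    out = []
    for off in range(len(window) - span + 1):
        mm = sum(a != b for a, b in zip(window[off : off + len(h)], h))
        second = window[off + len(h) + gap : off + span]
        mm += sum(a != b for a, b in zip(second, h))
        if mm <= max_mismatch:
            out.append((off, mm))
    return out


# ---------------------------------------------------------------------------
# Upstream extraction and conservation
# ---------------------------------------------------------------------------


def extract_upstream(
    genome: Mapping[str, str],
    tus: Sequence,
    length: int = 200,
    anchor: str = "translation_start",
) -> dict[str, str]:
    """Strand-aware upstream windows in coding-strand orientation.

    ``anchor`` is "translation_start" (first CDS base of the lead gene)
    or "tss". Windows truncated at replicon ends emit a warning.
    """
    if length <= 0:
        raise ValidationError("length must be positive")
    if anchor not in {"translation_start", "tss"}:
        raise ValidationError(f"unknown anchor {anchor!r}")
    out: dict[str, str] = {}
    for tu in tus:
        pos = tu.translation_start if anchor == "translation_start" else tu.tss
        if pos is None:
            raise ValidationError(f"TU {tu.tu_id} lacks anchor {anchor}")
        seq = genome[tu.replicon]
        if tu.strand == "+":
            start = pos - length
            if start < 0:
                warnings.warn(f"{tu.tu_id}: upstream window truncated at replicon start")
                start = 0
            out[tu.tu_id] = seq[start:pos]
        else:
            end = pos + 1 + length
            if end > len(seq):
                warnings.warn(f"{tu.tu_id}: upstream window truncated at replicon end")
                end = len(seq)
            out[tu.tu_id] = revcomp(seq[pos + 1 : end])
    return out


def conservation_report(
    pwm: PWM,
    species_upstream_sets: Mapping[str, Mapping[str, str]],
    half_site: str = "TGA",
    gap: int = 8,
    max_mismatch: int = 2,
    pseudocount: float = 1.0,
):
    """Cross-species binding-site conservation.

    For each species: retain the single best-scoring site per upstream
    sequence, build a species PWM from the retained sites, and summarize
    half-site conservation by direct-repeat matching. Returns
    (summary DataFrame, {species: PWM}, {species: {seq_id: MotifSite}}).
    """
    import pandas as pd

    rows = []
    species_pwms: dict[str, PWM] = {}
    species_sites: dict[str, dict[str, MotifSite]] = {}
    for species, seqs in species_upstream_sets.items():
        if not seqs:
            warnings.warn(f"species {species!r}: empty upstream set, skipped")
            continue
        sites = best_site_per_sequence(pwm, seqs)
        species_sites[species] = sites
        retained = [s.site_seq for s in sites.values() if set(s.site_seq) <= set(ALPHABET)]
        sp_pwm = build_pwm(retained, pwm.background, pseudocount) if retained else None
        if sp_pwm is not None:
            species_pwms[species] = sp_pwm
        n_repeat = sum(
            bool(match_direct_repeat(s.site_seq, half_site, gap, max_mismatch))
            for s in sites.values()
        )
        scores = [s.score for s in sites.values()]
        rows.append(
            {
                "species": species,
                "n_sequences": len(seqs),
                "n_sites": len(sites),
                "mean_score": float(np.mean(scores)) if scores else float("nan"),
                "consensus": sp_pwm.consensus if sp_pwm else "",
                "frac_direct_repeat": n_repeat / len(sites) if sites else float("nan"),
            }
        )
    return pd.DataFrame(rows), species_pwms, species_sites


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------


def write_meme(pwm: PWM, path, name: str = "motif_1") -> None:
    q = pwm.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {q[0]:.6f} C {q[1]:.6f} G {q[2]:.6f} T {q[3]:.6f}\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {pwm.n_sites} E= 0\n"
        )
        for j in range(pwm.width):
            fh.write(" " + " ".join(f"{pwm.probs[b, j]:.6f}" for b in range(4)) + "\n")


def read_meme(path) -> PWM:
    background = np.full(4, 0.25)
    probs_rows: list[list[float]] = []
    n_sites = 0
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    expecting_bg = expecting_rows = False
    width = 0
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("Background letter frequencies"):
            expecting_bg = True
            continue
        if expecting_bg and stripped:
            tokens = stripped.split()
            background = np.array([float(tokens[i]) for i in (1, 3, 5, 7)])
            expecting_bg = False
            continue
        if stripped.startswith("letter-probability matrix"):
            tokens = stripped.replace("=", " = ").split()
            width = int(tokens[tokens.index("w") + 2])
            if "nsites" in tokens:
                n_sites = int(float(tokens[tokens.index("nsites") + 2]))
            expecting_rows = True
            continue
        if expecting_rows and stripped:
            probs_rows.append([float(x) for x in stripped.split()])
            if len(probs_rows) == width:
                expecting_rows = False
    if not probs_rows:
        raise ValidationError(f"{path}: no letter-probability matrix found")
    probs = np.array(probs_rows).T
    probs = probs / probs.sum(axis=0)  # renormalize printed rounding
    return PWM(probs, background, n_sites=n_sites)
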
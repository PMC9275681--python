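"""PWM construction, log-odds scanning, ZOOPS-EM discovery,
direct-repeat matching, upstream extraction and conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cenreg.io_formats import GenomicInterval, TranscriptionalUnit, ValidationError, load_regulon_fixture
from cenreg.motif import (
    ALPHABET,
    DegenerateInputError,
    PWM,
    background_from_sequences,
    best_site_per_sequence,
    build_pwm,
    conservation_report,
    discover_zoops,
    extract_upstream,
    match_direct_repeat,
    read_meme,
    revcomp,
    scan,
    write_meme,
)
from cenreg.synthetic_data import simulate_motif_dataset

_IDX = {b: i for i, b in enumerate(ALPHABET)}


def naive_scan_scores(pwm, seq):
    """Brute-force per-offset oracle: explicit nested loops, no shared
    code with the scanner."""
    W = pwm.width
    out = {}
    for strand in ("+", "-"):
        scores = []
        for off in range(len(seq) - W + 1):
            window = seq[off : off + W].upper()
            if strand == "-":
                window = revcomp(window)
            s = 0.0
            for j, b in enumerate(window):
                if b in _IDX:
                    s += math.log2(pwm.probs[_IDX[b], j] / pwm.background[_IDX[b]])
            scores.append(s)
        out[strand] = scores
    return out


def random_pwm(rng, width):
    sites = [
        "".join(rng.choice(list(ALPHABET), size=width)) for _ in range(rng.integers(2, 8))
    ]
    q = rng.dirichlet([5, 5, 5, 5])
    return build_pwm(sites, q, pseudocount=1.0)


class TestBuildPWM:
    def test_single_site_zero_pseudocount_gives_indicators(self):
        pwm = build_pwm(["ACGT"], pseudocount=0.0)
        assert np.allclose(pwm.probs, np.eye(4))

    def test_hand_computed_probability(self):
        pwm = build_pwm(["AA", "AC"], pseudocount=1.0)
        assert pwm.probs[0, 0] == pytest.approx((2 + 0.25) / 3)
        assert pwm.probs[1, 1] == pytest.approx((1 + 0.25) / 3)

    def test_columns_normalized_and_ic_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pwm = random_pwm(rng, int(rng.integers(4, 16)))
            assert np.allclose(pwm.probs.sum(axis=0), 1.0, atol=1e-9)
            assert pwm.information_content >= 0
            assert np.all(pwm.column_ic >= -1e-12)

    def test_ic_zero_iff_probs_equal_background(self):
        q = np.array([0.16, 0.34, 0.34, 0.16])
        flat = PWM(np.tile(q[:, None], (1, 5)), q)
        assert flat.information_content == pytest.approx(0.0, abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError, match="uniform length"):
            build_pwm(["ACG", "ACGT"])

    def test_non_acgt_named_with_position(self):
        with pytest.raises(ValidationError, match="position 2"):
            build_pwm(["ACNT"])

    def test_fixture_pwm_has_positive_ic_everywhere(self):
        motifs = [e.motif_seq for e in load_regulon_fixture()]
        q = background_from_sequences(motifs)
        pwm = build_pwm(motifs, q, pseudocount=1.0)
        assert pwm.width == 15 and pwm.n_sites == 31
        assert np.all(pwm.column_ic > 0)


class TestScan:
    def test_consensus_scores_maximum_at_offset_zero(self):
        pwm = build_pwm(["TGACGCAGATGTGTT"] * 3, pseudocount=0.5)
        hits = scan(pwm, pwm.consensus, threshold=-np.inf)
        top = hits[0]
        assert top.offset == 0 and top.strand == "+"
        assert top.score == pytest.approx(pwm.max_score)

    def test_flat_pwm_scores_zero_everywhere(self):
        q = np.full(4, 0.25)
        pwm = PWM(np.tile(q[:, None], (1, 2)), q)
        hits = scan(pwm, "ACGTACGT", threshold=-np.inf)
        assert hits and all(h.score == pytest.approx(0.0) for h in hits)

    def test_hit_count_and_oracle_agreement_on_random_kb(self):
        rng = np.random.default_rng(42)
        pwm = random_pwm(rng, 10)
        seq = "".join(rng.choice(list(ALPHABET), size=1000))
        hits = scan(pwm, seq, threshold=-np.inf)
        L, W = len(seq), pwm.width
        assert len(hits) == 2 * (L - W + 1)
        oracle = naive_scan_scores(pwm, seq)
        for h in hits:
            assert h.score == pytest.approx(oracle[h.strand][h.offset], abs=1e-9)

    def test_short_sequence_warns_and_returns_empty(self):
        pwm = build_pwm(["ACGTACGT"])
        with pytest.warns(UserWarning, match="shorter than motif"):
            assert scan(pwm, "ACG") == []

    def test_ambiguous_bases_contribute_zero_bits(self):
        pwm = build_pwm(["AAAA", "AAAA"], pseudocount=1.0)
        (a,) = [h for h in scan(pwm, "AANA", threshold=-np.inf) if h.strand == "+"]
        per_base = math.log2(pwm.probs[0, 0] / 0.25)
        assert a.score == pytest.approx(3 * per_base, abs=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=12, max_size=120),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_scanner_equals_oracle_property(self, seq, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, int(rng.integers(3, 12)))
        if len(seq) < pwm.width:
            return
        oracle = naive_scan_scores(pwm, seq)
        for h in scan(pwm, seq, threshold=-np.inf):
            assert h.score == pytest.approx(oracle[h.strand][h.offset], abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, 8)
        seq = "".join(rng.choice(list(ALPHABET), size=60))
        fwd = {(h.offset, h.strand): h.score for h in scan(pwm, seq, threshold=-np.inf)}
        mirrored = {}
        L, W = len(seq), pwm.width
        for h in scan(pwm, revcomp(seq), threshold=-np.inf):
            mirrored[(L - W - h.offset, "+" if h.strand == "-" else "-")] = h.score
        assert set(fwd) == set(mirrored)
        for k in fwd:
            assert fwd[k] == pytest.approx(mirrored[k], abs=1e-9)

    def test_cross_check_against_biopython_pssm(self):
        """Independent oracle: Bio.motifs PSSM with matching pseudocount
        and background reproduces the forward-strand scores."""
        from Bio import motifs as bio_motifs
        from Bio.Seq import Seq

        instances = [e.motif_seq for e in load_regulon_fixture()]
        q = background_from_sequences(instances)
        pwm = build_pwm(instances, q, pseudocount=1.0)

        m = bio_motifs.create([Seq(s) for s in instances])
        background = dict(zip("ACGT", q))
        pssm = m.counts.normalize(
            pseudocounts={b: 1.0 * q[i] for i, b in enumerate("ACGT")}
        ).log_odds(background)
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list(ALPHABET), size=400))
        expected = pssm.calculate(Seq(seq))
        ours = {h.offset: h.score for h in scan(pwm, seq, both_strands=False, threshold=-np.inf)}
        for off, value in enumerate(expected):
            assert ours[off] == pytest.approx(float(value), abs=1e-4)


class TestBestSite:
    def test_planted_consensus_is_best(self):
        rng = np.random.default_rng(1)
        pwm = build_pwm(["TGACGCAGATGTGAT"] * 4, pseudocount=0.5)
        bg = "".join(rng.choice(list(ALPHABET), size=200))
        seq = bg[:80] + pwm.consensus + bg[80:]
        best = best_site_per_sequence(pwm, {"s": seq})["s"]
        assert best.offset == 80 and best.site_seq == pwm.consensus

    def test_palindromic_top_site_takes_plus_strand(self):
        pwm = build_pwm(["ACGT", "ACGT"], pseudocount=0.0)  # revcomp(ACGT) == ACGT
        best = best_site_per_sequence(pwm, {"s": "GGACGTGG"})["s"]
        assert best.strand == "+"

    def test_agrees_with_full_scan_max(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(rng, 9)
        for i in range(50):
            seq = "".join(rng.choice(list(ALPHABET), size=150))
            best = best_site_per_sequence(pwm, {"s": seq})["s"]
            top = scan(pwm, seq, threshold=-np.inf)[0]
            assert (best.offset, best.strand, best.score) == (
                top.offset,
                top.strand,
                top.score,
            )


class TestZOOPSDiscovery:
    def test_exact_planted_14mer_recovered_noise_free(self):
        rng = np.random.default_rng(0)
        planted = "TGACGCAGATGTGA"
        seqs = {}
        for i in range(6):
            bg = "".join(rng.choice(list(ALPHABET), size=120))
            off = 15 + 15 * i
            seqs[f"s{i}"] = bg[:off] + planted + bg[off:]
        res = discover_zoops(seqs, w_min=14, w_max=14, n_restarts=8, seed=0)
        assert res.pwm.consensus in (planted, revcomp(planted))
        assert res.n_sequences_with_site == 6

    def test_loglik_monotone_within_restart(self):
        seqs, _, _ = simulate_motif_dataset(n_sequences=10, n_with_site=9, seed=2)
        res = discover_zoops(seqs, w_min=14, w_max=14, n_restarts=2, seed=2)
        traj = res.log_likelihood_trajectory
        assert len(traj) >= 2
        assert all(b >= a - 1e-9 * max(1, abs(a)) for a, b in zip(traj, traj[1:]))

    def test_deterministic_given_seed(self):
        seqs, _, _ = simulate_motif_dataset(n_sequences=8, n_with_site=7, seed=3)
        r1 = discover_zoops(seqs, w_min=12, w_max=13, n_restarts=2, seed=9)
        r2 = discover_zoops(seqs, w_min=12, w_max=13, n_restarts=2, seed=9)
        assert np.array_equal(r1.pwm.probs, r2.pwm.probs)
        assert r1.width == r2.width and r1.objective == r2.objective
        assert {k: (v.offset, v.strand) if v else None for k, v in r1.sites.items()} == {
            k: (v.offset, v.strand) if v else None for k, v in r2.sites.items()
        }

    def test_width_selection_brackets_planted_width(self):
        seqs, _, _ = simulate_motif_dataset(n_sequences=12, n_with_site=12, seed=4)
        res = discover_zoops(seqs, w_min=13, w_max=15, n_restarts=3, seed=4)
        assert 13 <= res.width <= 15

    def test_single_letter_sequences_rejected(self):
        with pytest.raises(DegenerateInputError):
            discover_zoops({"a": "A" * 30, "b": "A" * 30}, w_min=10, w_max=10)

    def test_too_few_or_too_short_sequences_rejected(self):
        with pytest.raises(ValidationError):
            discover_zoops({"a": "ACGT" * 10}, w_min=10, w_max=10)
        with pytest.raises(ValidationError):
            discover_zoops({"a": "ACGTACGT", "b": "ACGTACGT"}, w_min=10, w_max=10)


class TestDirectRepeat:
    def test_rsp1834_site_matches_with_zero_mismatches(self):
        assert match_direct_repeat("TGACGCAGCTGTGAA") == [(0, 0)]

    def test_rsp0847_site_needs_two_mismatches(self):
        matches = match_direct_repeat("ACACGAGCGCGTGAG")
        assert (0, 2) in matches

    def test_no_t_sequence_has_no_strict_match(self):
        assert match_direct_repeat("GCAGCAGCAGCAGCA", max_mismatch=0) == []

    def test_fixture_motifs_are_degenerate_direct_repeats(self):
        """Most of the 31 published motifs carry the repeat within 2
        mismatches; all do within 3 (e.g. TCACGCAATCGCAAC needs 3)."""
        entries = load_regulon_fixture()
        within2 = sum(bool(match_direct_repeat(e.motif_seq)) for e in entries)
        assert within2 >= 28
        for e in entries:
            assert match_direct_repeat(e.motif_seq, max_mismatch=3), e.motif_seq


class TestExtractUpstream:
    def _genome(self, n=6000, seed=0):
        rng = np.random.default_rng(seed)
        return {"chr1": "".join(rng.choice(list(ALPHABET), size=n))}

    def _tu(self, tu_id, strand, tss, gene_start, gene_end):
        tu = TranscriptionalUnit(
            tu_id,
            GenomicInterval("chr1", min(tss, gene_start), max(tss + 1, gene_end), strand),
            tss,
        )
        tu.genes["g"] = GenomicInterval("chr1", gene_start, gene_end, strand)
        return tu

    def test_plus_strand_window(self):
        genome = self._genome()
        tu = self._tu("p", "+", 950, 1000, 1600)
        out = extract_upstream(genome, [tu], 200)
        assert out["p"] == genome["chr1"][800:1000]

    def test_minus_strand_window_is_revcomp(self):
        genome = self._genome()
        tu = self._tu("m", "-", 5050, 4400, 5000)
        out = extract_upstream(genome, [tu], 200)
        # translation start = base 4999; upstream = [5000, 5200) revcomp'd
        from Bio.Seq import Seq

        assert out["m"] == str(Seq(genome["chr1"][5000:5200]).reverse_complement())

    def test_truncation_at_replicon_start_warns(self):
        genome = self._genome()
        tu = self._tu("t", "+", 40, 50, 500)
        with pytest.warns(UserWarning, match="truncated"):
            out = extract_upstream(genome, [tu], 200)
        assert out["t"] == genome["chr1"][:50]

    def test_tss_anchor(self):
        genome = self._genome()
        tu = self._tu("p", "+", 950, 1000, 1600)
        out = extract_upstream(genome, [tu], 100, anchor="tss")
        assert out["p"] == genome["chr1"][850:950]


class TestConservation:
    @staticmethod
    def fixture_pwm():
        motifs = [e.motif_seq for e in load_regulon_fixture()]
        return build_pwm(motifs, background_from_sequences(motifs))

    def test_self_consistency_on_training_like_set(self):
        pwm = self.fixture_pwm()
        rng = np.random.default_rng(0)
        seqs = {}
        for i, e in enumerate(load_regulon_fixture()):
            bg = "".join(rng.choice(list(ALPHABET), size=300))
            seqs[f"s{i}"] = bg[:100] + e.motif_seq + bg[115:]
        table, pwms, _ = conservation_report(pwm, {"self": seqs})
        assert pwms["self"].consensus == pwm.consensus

    def test_mutated_conserved_sites_recovered(self):
        """Synthetic species at 5%/bp mutation: >=90% of retained best
        sites overlap the planted positions."""
        pwm = self.fixture_pwm()
        rng = np.random.default_rng(3)
        seqs, plants = {}, {}
        for i in range(6):
            site = list(pwm.consensus)  # conserved sites resemble the consensus
            for j in range(len(site)):
                if rng.random() < 0.05:
                    site[j] = str(rng.choice(list(ALPHABET)))
            bg = "".join(rng.choice(list(ALPHABET), size=300))
            off = int(rng.integers(0, 285))
            seqs[f"s{i}"] = bg[:off] + "".join(site) + bg[off + 15 :]
            plants[f"s{i}"] = off
        _, _, sites = conservation_report(pwm, {"sp": seqs})
        n_overlap = sum(
            abs(sites["sp"][k].offset - plants[k]) <= 7 for k in plants
        )
        assert n_overlap / len(plants) >= 0.9

    def test_background_species_scores_below_planted_species(self):
        pwm = self.fixture_pwm()
        rng = np.random.default_rng(4)
        planted, empty = {}, {}
        motifs = [e.motif_seq for e in load_regulon_fixture()]
        for i in range(6):
            bg = "".join(rng.choice(list(ALPHABET), size=300))
            planted[f"p{i}"] = bg[:140] + motifs[i] + bg[155:]
            empty[f"e{i}"] = "".join(rng.choice(list(ALPHABET), size=300))
        table, _, _ = conservation_report(pwm, {"planted": planted, "background": empty})
        scores = dict(zip(table.species, table.mean_score))
        assert scores["background"] < scores["planted"]

    def test_empty_species_skipped_with_warning(self):
        pwm = self.fixture_pwm()
        with pytest.warns(UserWarning, match="empty"):
            table, _, _ = conservation_report(pwm, {"none": {}})
        assert table.empty


class TestMemeFormat:
    def test_round_trip(self, tmp_path):
        motifs = [e.motif_seq for e in load_regulon_fixture()]
        pwm = build_pwm(motifs, background_from_sequences(motifs))
        path = tmp_path / "m.meme"
        write_meme(pwm, path)
        back = read_meme(path)
        assert back.width == pwm.width and back.n_sites == 31
        assert np.allclose(back.probs, pwm.probs, atol=1e-4)
        assert np.allclose(back.background, pwm.background, atol=1e-6)

    def test_biopython_parses_our_minimal_format(self, tmp_path):
        from Bio import motifs as bio_motifs

        pwm = build_pwm(["ACGTACGTAC", "ACGAACGTAC"], pseudocount=1.0)
        path = tmp_path / "m.meme"
        write_meme(pwm, path, name="x")
        with open(path) as fh:
            (record,) = bio_motifs.parse(fh, "minimal")
        assert record.length == 10
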
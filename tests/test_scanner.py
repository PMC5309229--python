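"""Log-odds scoring, the discretized null distribution, and scanning."""

import itertools

import numpy as np
import pytest

from pprchip.code import PWMatrix
from pprchip.errors import UsageError
from pprchip.scanner import (
    EPSILON,
    BackgroundModel,
    ScoreDistribution,
    SequenceRecord,
    log_odds_matrix,
    logodds_score,
    scan,
)

UNIFORM = BackgroundModel.uniform()


def _rc(seq: str) -> str:
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    return "".join(comp[b] for b in reversed(seq))


def _brute_pvalues(pwm, background):
    """Exhaustive null: p-value of every window by full enumeration."""
    lo = log_odds_matrix(pwm, background)
    bga = background.array()
    L = len(pwm)
    scores, probs = [], []
    for w in itertools.product(range(4), repeat=L):
        scores.append(lo[np.arange(L), list(w)].sum())
        probs.append(np.prod(bga[list(w)]))
    scores, probs = np.array(scores), np.array(probs)
    return scores, np.array(
        [probs[scores >= s - 1e-9].sum() for s in scores]
    )


class TestLogOdds:
    def test_pwm_equal_to_background_scores_zero(self):
        pwm = PWMatrix(probs=np.full((6, 4), 0.25))
        assert logodds_score(pwm, UNIFORM, "ACGUAC") == pytest.approx(0.0)

    def test_near_deterministic_row(self):
        pwm = PWMatrix(probs=np.array([[1 - 3 * EPSILON, EPSILON, EPSILON, EPSILON]]))
        score = logodds_score(pwm, UNIFORM, "A")
        assert score == pytest.approx(np.log2((1 - 3 * EPSILON) / 0.25), abs=1e-9)
        assert score == pytest.approx(1.999, abs=1e-3)

    def test_consensus_window_scores_rowwise_maximum(self, sharp_pwm):
        score = logodds_score(sharp_pwm, UNIFORM, "UGAC")
        lo = log_odds_matrix(sharp_pwm, UNIFORM)
        assert score == pytest.approx(lo.max(axis=1).sum())

    def test_length_mismatch_rejected(self, sharp_pwm):
        with pytest.raises(UsageError):
            logodds_score(sharp_pwm, UNIFORM, "UGACC")


class TestScoreDistribution:
    def test_deterministic_single_row_top_pvalue_quarter(self):
        pwm = PWMatrix(probs=np.array([[1.0, 0, 0, 0]]))
        dist = ScoreDistribution(pwm, UNIFORM)
        top = logodds_score(pwm, UNIFORM, "A")
        assert dist.pvalue(top) == pytest.approx(0.25)

    def test_uniform_pwm_everything_has_pvalue_one(self):
        pwm = PWMatrix(probs=np.full((3, 4), 0.25))
        dist = ScoreDistribution(pwm, UNIFORM)
        assert dist.pvalue(0.0) == 1.0

    @pytest.mark.parametrize("length,seed,conc,bg", [
        (2, 0, 1.0, UNIFORM),
        (3, 1, 0.5, UNIFORM),
        (4, 2, 2.0, BackgroundModel((0.3, 0.2, 0.3, 0.2))),
        (5, 3, 1.0, UNIFORM),
        (6, 4, 0.5, BackgroundModel((0.4, 0.1, 0.1, 0.4))),
    ])
    def test_dp_matches_exhaustive_enumeration(
        self, random_pwm_factory, length, seed, conc, bg
    ):
        """DP p-values equal brute-force enumeration within 1e-3."""
        pwm = random_pwm_factory(length, seed, conc)
        dist = ScoreDistribution(pwm, bg, n_bins=10_000)
        scores, truth = _brute_pvalues(pwm, bg)
        dp = np.array([dist.pvalue(s) for s in scores])
        assert np.max(np.abs(dp - truth)) <= 1e-3

    def test_pvalue_non_increasing_in_score(self, random_pwm_factory):
        pwm = random_pwm_factory(4, 7)
        dist = ScoreDistribution(pwm, UNIFORM)
        grid = np.linspace(-20, 20, 200)
        ps = [dist.pvalue(s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert dist.pvalue(-1e9) == 1.0

    def test_too_few_bins_rejected(self, sharp_pwm):
        with pytest.raises(UsageError):
            ScoreDistribution(sharp_pwm, UNIFORM, n_bins=10)


class TestScan:
    def test_planted_consensus_is_the_only_hit(self, sharp_pwm):
        rng = np.random.default_rng(5)
        bases = list(rng.choice(list("ACGU"), size=200))
        # make sure no accidental consensus occurrence, then plant one
        seq_str = "".join(bases).replace("UGAC", "UGAG")
        planted = 101
        seq_str = seq_str[:planted - 1] + "UGAC" + seq_str[planted + 3:]
        hits = scan(sharp_pwm, SequenceRecord("s", seq_str), p_threshold=0.01)
        assert [(h.start, h.end) for h in hits] == [(planted, planted + 3)]
        assert hits[0].p_value == pytest.approx(0.25 ** 4, rel=1e-6)

    def test_uniform_pwm_threshold_boundary(self):
        """All windows carry p = 1: none pass 0.5, all pass 1.0."""
        pwm = PWMatrix(probs=np.full((3, 4), 0.25))
        seq = SequenceRecord("s", "ACGUACGUAC")
        assert scan(pwm, seq, p_threshold=0.5) == []
        assert len(scan(pwm, seq, p_threshold=1.0)) == seq.length - len(pwm) + 1

    def test_lowering_threshold_never_adds_hits(self, random_pwm_factory):
        pwm = random_pwm_factory(5, 11)
        rng = np.random.default_rng(12)
        seq = SequenceRecord("s", "".join(rng.choice(list("ACGU"), size=500)))
        loose = {(h.start, h.strand) for h in scan(pwm, seq, p_threshold=0.2)}
        tight = {(h.start, h.strand) for h in scan(pwm, seq, p_threshold=0.02)}
        assert tight <= loose

    def test_strand_symmetry(self, random_pwm_factory):
        """Scanning the reverse complement equals the minus-strand scan."""
        pwm = random_pwm_factory(4, 21)
        rng = np.random.default_rng(22)
        fwd = "".join(rng.choice(list("ACGU"), size=300))
        seq = SequenceRecord("s", fwd)
        rc_seq = SequenceRecord("s", _rc(fwd))
        minus = [h for h in scan(pwm, seq, p_threshold=0.1, strands="both")
                 if h.strand == "-"]
        given_rc = scan(pwm, rc_seq, p_threshold=0.1, strands="given")
        remapped = sorted(
            (seq.length - h.end + 1, seq.length - h.start + 1,
             round(h.score, 9), h.p_value)
            for h in given_rc
        )
        observed = sorted(
            (h.start, h.end, round(h.score, 9), h.p_value) for h in minus
        )
        assert observed == remapped

    def test_identical_inputs_identical_hits(self, random_pwm_factory):
        pwm = random_pwm_factory(5, 31)
        rng = np.random.default_rng(32)
        seq = SequenceRecord("s", "".join(rng.choice(list("ACGU"), size=400)))
        assert scan(pwm, seq, p_threshold=0.1) == scan(pwm, seq, p_threshold=0.1)

    def test_windows_containing_n_skipped(self, sharp_pwm):
        seq = SequenceRecord("s", "UGNC" * 5)
        assert scan(sharp_pwm, seq, p_threshold=1.0) == []

    def test_sequence_shorter_than_pwm_warns_empty(self, sharp_pwm, caplog):
        seq = SequenceRecord("s", "UG")
        assert scan(sharp_pwm, seq) == []
        assert any("shorter" in r.message for r in caplog.records)

    def test_circular_wraparound_site_found(self, sharp_pwm):
        """A site straddling the origin is reported with a wrapped end."""
        rng = np.random.default_rng(41)
        body = "".join(rng.choice(list("ACGU"), size=96)).replace("UGAC", "AAAA")
        # last two bases UG, first two AC: the site wraps 99,100,1,2
        seq_str = "AC" + body + "UG"
        assert len(seq_str) == 100
        seq = SequenceRecord("s", seq_str, circular=True)
        hits = scan(sharp_pwm, seq, p_threshold=0.01)
        assert any(h.start == 99 and h.end == 2 for h in hits)
        linear = scan(sharp_pwm, SequenceRecord("s", seq_str), p_threshold=0.01)
        assert not any(h.start == 99 for h in linear)
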
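import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnamesig import (
    MethylationSignature,
    SignatureScore,
    correlation_score,
    optimize_cutoff,
    random_signature_null,
    score_cohort,
    simulate_cohort,
    select_signature_cv,
    SimulationConfig,
)
from dnamesig.cohort_io import ValidationError
from dnamesig.scoring import NullDistribution, ScoreCutoff


def _sig(weights, probes=None):
    w = np.asarray(weights, dtype=float)
    probes = probes or [f"cg{i}" for i in range(len(w))]
    return MethylationSignature(probes, w, mean_pos=w * 0 + 0.6, mean_neg=0.6 - w)


def _pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


class TestCorrelationScore:
    def test_affine_transform_of_weights_scores_one(self):
        sig = _sig([0.30, -0.20, 0.10, -0.40, 0.25])
        profile = {p: 0.5 + 0.2 * w for p, w in zip(sig.probe_ids, sig.weights)}
        assert correlation_score(profile, sig).score == pytest.approx(1.0)

    def test_negative_affine_scores_minus_one(self):
        sig = _sig([0.30, -0.20, 0.10, -0.40, 0.25])
        profile = {p: 0.5 - 0.2 * w for p, w in zip(sig.probe_ids, sig.weights)}
        assert correlation_score(profile, sig).score == pytest.approx(-1.0)

    def test_matches_hand_pearson(self):
        weights = [0.30, -0.20, 0.10, -0.40, 0.25]
        betas = [0.71, 0.22, 0.55, 0.13, 0.64]
        sig = _sig(weights)
        profile = dict(zip(sig.probe_ids, betas))
        expected = _pearson_oracle(weights, betas)
        assert correlation_score(profile, sig).score == pytest.approx(expected, abs=1e-10)

    def test_low_coverage_leaves_sample_unscored(self):
        sig = _sig(np.linspace(-0.3, 0.3, 10).tolist()[:5] + [0.1, 0.2, -0.1, -0.2, 0.3])
        profile = {p: 0.5 for p in sig.probe_ids[:5]}  # 50% coverage
        sc = correlation_score(profile, sig, min_coverage=0.8)
        assert sc.score is None and sc.call == "unscored"

    def test_constant_profile_unscored(self):
        sig = _sig([0.1, 0.2, -0.3, 0.4])
        sc = correlation_score({p: 0.5 for p in sig.probe_ids}, sig)
        assert sc.score is None and sc.reason == "zero variance"

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(0.1, 0.9), b=st.floats(0.01, 0.4),
        seed=st.integers(0, 10_000),
    )
    def test_affine_rescaling_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=8) * 0.2
        w[w == 0] = 0.1
        sig = _sig(w)
        y = rng.uniform(0.05, 0.95, size=8)
        base = correlation_score(dict(zip(sig.probe_ids, y)), sig).score
        scaled = correlation_score(dict(zip(sig.probe_ids, np.clip(a + b * (y - 0.5), 0, 1))), sig).score
        if base is not None and scaled is not None:
            assert scaled == pytest.approx(base, abs=1e-8)


@pytest.fixture(scope="module")
def scored(planted_cohort):
    cohort, _ = planted_cohort
    sig = select_signature_cv(cohort, [50], folds=5, seed=1)
    return cohort, sig, score_cohort(cohort, sig)


class TestScoreCohort:
    def test_positive_centroid_scores_positive(self, scored):
        cohort, sig, scores = scored
        pos_scores = [s.score for s, m in zip(scores, cohort.marker_mask()) if m]
        assert np.mean(pos_scores) > 0

    def test_cutoff_minus_one_calls_everything_high(self, scored):
        cohort, sig, _ = scored
        scores = score_cohort(cohort, sig, ScoreCutoff(-1.0, 1.0, 1.0))
        assert all(s.call == "high" for s in scores if s.score is not None)

    def test_vectorized_matches_single_sample_api(self, scored):
        cohort, sig, scores = scored
        frame = cohort.beta.to_frame()
        for s in scores[:5]:
            solo = correlation_score(frame[s.sample_id].to_dict(), sig)
            assert solo.score == pytest.approx(s.score, abs=1e-12)

    def test_probe_dropout_keeps_well_separated_calls(self, scored, rng):
        cohort, sig, scores = scored
        cut = optimize_cutoff(scores, cohort.marker_mask())
        margin_ok = [
            s.sample_id for s in scores
            if s.score is not None and abs(s.score - cut.threshold) > 0.2
        ]
        keep = rng.choice(sig.size, size=int(sig.size * 0.9), replace=False)
        sub = MethylationSignature(
            [sig.probe_ids[i] for i in keep], sig.weights[keep],
            sig.mean_pos[keep], sig.mean_neg[keep],
        )
        before = {s.sample_id: s.call for s in score_cohort(cohort, sig, cut)}
        after = {s.sample_id: s.call for s in score_cohort(cohort, sub, cut)}
        assert all(before[sid] == after[sid] for sid in margin_ok)

    def test_platform_mismatch_raises(self, scored):
        cohort, sig, _ = scored
        foreign = MethylationSignature(
            [f"ch{i}" for i in range(sig.size - 1)] + [sig.probe_ids[0]],
            sig.weights, sig.mean_pos, sig.mean_neg,
        )
        with pytest.raises(ValidationError, match="platform mismatch"):
            score_cohort(cohort, foreign)

    def test_full_cohort_signature_auc_at_least_090(self, scored):
        from sklearn.metrics import roc_auc_score

        cohort, _, scores = scored
        y = cohort.marker_mask()
        assert roc_auc_score(y, [s.score for s in scores]) >= 0.9


def _brute_force_cutoff(scores, labels):
    """Try every threshold (all score values and +/-inf) exhaustively."""
    xs = [s for s in scores]
    best = None
    for thr in sorted(set(xs)) + [float("-inf"), float("inf")]:
        calls = [x >= thr for x in xs]
        sens = sum(c and l for c, l in zip(calls, labels)) / sum(labels)
        spec = sum((not c) and (not l) for c, l in zip(calls, labels)) / (
            len(labels) - sum(labels)
        )
        key = (min(sens, spec), sens + spec)
        if best is None or key > best:
            best = key
    return best


class TestOptimizeCutoff:
    def _scores(self, values):
        return [SignatureScore(f"S{i}", v, 10) for i, v in enumerate(values)]

    def test_perfect_separation(self):
        cut = optimize_cutoff(self._scores([0.9, 0.8, 0.1, 0.2]), [1, 1, 0, 0])
        assert cut.sensitivity == 1.0 and cut.specificity == 1.0

    def test_worked_overlapping_example(self):
        # positives 0.9, 0.8, 0.2; negatives 0.7, 0.1, 0.0: two thresholds tie
        # at min(sens, spec) = 2/3 and sens + spec = 5/3; the lower one wins
        cut = optimize_cutoff(self._scores([0.9, 0.8, 0.2, 0.7, 0.1, 0.0]), [1, 1, 1, 0, 0, 0])
        assert 0.1 < cut.threshold <= 0.2
        assert cut.sensitivity == pytest.approx(1.0)
        assert cut.specificity == pytest.approx(2 / 3)
        assert _brute_force_cutoff([0.9, 0.8, 0.2, 0.7, 0.1, 0.0],
                                   [True, True, True, False, False, False]) == (
            pytest.approx(2 / 3), pytest.approx(5 / 3))

    def test_single_class_raises(self):
        with pytest.raises(ValidationError, match="both"):
            optimize_cutoff(self._scores([0.1, 0.2]), [1, 1])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 100_000), n=st.integers(4, 50))
    def test_agrees_with_exhaustive_search(self, seed, n):
        rng = np.random.default_rng(seed)
        values = np.round(rng.normal(size=n), 2)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        cut = optimize_cutoff(self._scores(values), labels)
        achieved = (min(cut.sensitivity, cut.specificity), cut.sensitivity + cut.specificity)
        best = _brute_force_cutoff(list(values), list(labels))
        assert achieved == pytest.approx(best)


class TestRandomSignatureNull:
    def test_empirical_p_extremes(self):
        nd = NullDistribution(draws=np.array([1.0, 2.0, 3.0]), observed=5.0, seed=0)
        assert nd.empirical_p == pytest.approx(1 / 4)
        nd = NullDistribution(draws=np.array([5.0, 5.0, 5.0]), observed=5.0, seed=0)
        assert nd.empirical_p == 1.0

    def test_zero_draws_rejected(self, planted_cohort):
        cohort, _ = planted_cohort
        sig = select_signature_cv(cohort, [10], folds=5, seed=1)
        with pytest.raises(ValidationError, match="n_draws"):
            random_signature_null(cohort, sig, cohort, n_draws=0)

    def test_planted_survival_signal_beats_random_signatures(self):
        """A real signature predicts arm-specific survival better than random ones."""
        disc, _ = simulate_cohort(
            SimulationConfig(n_pos=35, n_neg=28, seed=61, population_seed=600)
        )
        val_cfg = SimulationConfig(
            n_pos=150, n_neg=150, seed=62, population_seed=600,
            treatment_probs={"carboplatin": 1.0, "cisplatin": 0.0, "none": 0.0},
            hr_marker_by_treatment={"carboplatin": 3.5, "cisplatin": 1.0, "none": 1.0},
        )
        val, _ = simulate_cohort(val_cfg)
        sig = select_signature_cv(disc, [25, 50], folds=5, seed=63)
        nd = random_signature_null(val, sig, disc, n_draws=200, seed=64)
        assert nd.empirical_p <= 0.05
        assert nd.n_draws == 200
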
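"""Camera benchmark intervals, agreement statistics, PR-AUC, effect sizes."""

import numpy as np
import pytest

from racewalk import (
    DomainError,
    InputError,
    StepLabel,
    VideoStepAnnotation,
    agreement_stats,
    benchmark_membership,
    benchmark_timing,
    detection_comparison,
    effect_sizes,
    fuzzy_agreement,
    hedges_g,
    pr_auc,
)
from racewalk.benchmark import es_label


class TestBenchmarkTiming:
    def test_worked_example(self):
        ann = VideoStepAnnotation(FNA=100, FNB=101, FNC=110, FND=111, FR=240)
        (b,), _ = benchmark_timing([ann], 30)
        assert b.LOGCB_max == pytest.approx(11 / 240)        # 45.83 ms
        assert b.LOGCB_min == pytest.approx(9 / 240)         # 37.5 ms
        assert b.LOGCB == pytest.approx(10 / 240)            # 41.67 ms

    def test_one_frame_flight(self):
        ann = VideoStepAnnotation(FNA=100, FNB=101, FNC=101, FND=102, FR=240)
        (b,), _ = benchmark_timing([ann], 30)
        assert b.LOGCB_min == 0.0
        assert b.LOGCB_max == pytest.approx(2 / 240)

    def test_no_flight_step(self):
        ann = VideoStepAnnotation(FNA=100, FNB=101, FNC=100, FND=101, FR=240, no_flight=True)
        (b,), _ = benchmark_timing([ann], 30)
        assert b.LOGCB == 0.0 and b.no_flight

    def test_interval_width_always_two_frames(self):
        rng = np.random.default_rng(2)
        anns = []
        for i in range(50):
            fna = int(rng.integers(0, 1000))
            span = int(rng.integers(2, 15))
            anns.append(
                VideoStepAnnotation(FNA=fna, FNB=fna + 1, FNC=fna + span - 1, FND=fna + span)
            )
        steps, _ = benchmark_timing(anns, 30)
        for b in steps:
            assert b.LOGCB_max - b.LOGCB_min == pytest.approx(2 / 240)

    def test_sequence_means(self):
        anns = [
            VideoStepAnnotation(FNA=100 * i, FNB=100 * i + 1, FNC=100 * i + 10, FND=100 * i + 11)
            for i in range(30)
        ]
        steps, seq = benchmark_timing(anns, 30)
        assert len(seq) == 1
        assert seq["LOGCB_S"].iloc[0] == pytest.approx(np.mean([b.LOGCB for b in steps]))

    def test_frame_invariant_violation_names_step(self):
        with pytest.raises(InputError, match="step 7"):
            VideoStepAnnotation(FNA=100, FNB=103, FNC=110, FND=111, step=7)


class TestBenchmarkMembership:
    @pytest.mark.parametrize("v,expected", [(0.030, 0.0), (0.050, 1.0), (0.045, 0.75)])
    def test_trapezoid(self, v, expected):
        assert benchmark_membership(v, 0.040, 200.0) == pytest.approx(expected)


class TestFuzzyAgreement:
    def test_identical_memberships(self):
        eta = np.array([0.0, 0.3, 0.7, 1.0])
        _, ac, wc, tau = fuzzy_agreement(eta, eta)
        assert (ac, wc, tau) == (4, 0, 1.0)

    def test_one_wrong_of_ten(self):
        eta = np.array([1.0] + [0.2] * 9)
        lam = np.array([0.0] + [0.2] * 9)
        _, ac, wc, tau = fuzzy_agreement(eta, lam)
        assert tau == pytest.approx(0.9)

    def test_boundary_half_is_wrong(self):
        _, ac, wc, _ = fuzzy_agreement([0.5], [0.0])
        assert (ac, wc) == (0, 1)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(4)
        eta, lam = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        assert fuzzy_agreement(eta, lam)[3] == fuzzy_agreement(lam, eta)[3]

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            fuzzy_agreement([0.1, 0.2], [0.1])


L, I, D = StepLabel.LEGAL, StepLabel.ILLEGAL, StepLabel.DOUBT


class TestAgreementStats:
    def test_perfect_prediction(self):
        truth = [L] * 7 + [I] * 3
        r = agreement_stats(truth, truth, "binary")
        assert r["accuracy"] == 1.0
        assert r["false_alarm"] == 0.0 and r["miss_alarm"] == 0.0

    def test_brute_force_counts(self):
        # 10 legal truth, 2 called illegal; 10 illegal truth, all called illegal
        truth = [L] * 10 + [I] * 10
        pred = [L] * 8 + [I] * 2 + [I] * 10
        r = agreement_stats(pred, truth, "binary")
        assert r["false_alarm"] == pytest.approx(0.2)
        assert r["miss_alarm"] == 0.0
        assert r["TPR"] == pytest.approx(0.8)
        assert r["FPR"] == 0.0
        assert r["accuracy"] == pytest.approx(0.9)
        assert r["false_alarm"] == pytest.approx(1 - r["TPR"])  # published relation
        assert r["miss_alarm"] == pytest.approx(r["FPR"])

    def test_all_predicted_legal(self):
        truth = [L] * 5 + [I] * 5
        pred = [L] * 10
        r = agreement_stats(pred, truth, "binary")
        assert r["miss_alarm"] == 1.0 and r["FPR"] == 1.0

    def test_empty_truth_class_is_nan(self):
        r = agreement_stats([L, L], [L, L], "binary")
        assert np.isnan(r["FPR"]) and np.isnan(r["miss_alarm"])

    def test_three_level_per_class(self):
        truth = [L, L, D, D, I, I]
        pred = [L, D, D, D, I, L]
        r = agreement_stats(pred, truth, "three_level")
        assert r["accuracy"] == pytest.approx(4 / 6)
        assert r["per_class"]["legal"]["TPR"] == pytest.approx(0.5)
        assert r["per_class"]["doubt"]["TPR"] == pytest.approx(1.0)
        assert r["per_class"]["doubt"]["PPV"] == pytest.approx(2 / 3)
        assert r["confusion_matrix"].sum() == 6

    def test_doubt_label_rejected_in_binary_mode(self):
        with pytest.raises(DomainError):
            agreement_stats([D], [L], "binary")


class TestPrAuc:
    def test_published_proposed_rows(self):
        # legal/doubt/illegal (TPR, PPV) points of the proposed classifier
        auc = pr_auc([(0.55, 1.00), (0.83, 0.21), (1.00, 0.86)])
        assert auc == pytest.approx(0.81, abs=0.005)

    def test_published_comparison_rows(self):
        auc = pr_auc([(0.19, 1.00), (0.83, 0.13), (1.00, 0.86)])
        assert auc == pytest.approx(0.64, abs=0.005)

    def test_perfect_classifier(self):
        assert pr_auc([(1.0, 1.0)]) == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            pr_auc([(1.2, 0.5)])


class TestDetectionComparison:
    def test_identical_flight_times(self):
        v = np.full(20, 0.045)
        r = detection_comparison(v, v)
        assert r["detection_rate"] == 1.0
        assert r["MD_mean"] == 0.0 and r["MD_sd"] == 0.0

    def test_false_logc_counted(self):
        r = detection_comparison([0.02, 0.03], [0.0, 0.03])
        assert r["false_logc"] == 1 and r["missed_logc"] == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            detection_comparison([0.1], [0.1, 0.2])


class TestEffectSizes:
    def test_identical_groups_trivial(self):
        g = hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert g == 0.0 and es_label(g) == "trivial"

    def test_unit_shift_large(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 400)
        y = rng.normal(1, 1, 400)
        g = hedges_g(y, x)
        assert g == pytest.approx(1.0, abs=0.1)
        assert es_label(g) in ("moderate", "large")  # g sits near the 1.0 cut

    def test_small_sample_correction_shrinks(self):
        x, y = [0.0, 1.0, 2.0], [2.0, 3.0, 4.0]
        g = hedges_g(x, y)
        uncorrected = (np.mean(x) - np.mean(y)) / 1.0  # pooled SD = 1
        j = 1 - 3 / (4 * 6 - 9)
        assert g == pytest.approx(uncorrected * j)

    def test_zero_pooled_sd_undefined(self):
        assert np.isnan(hedges_g([1.0, 1.0], [2.0, 2.0]))

    @pytest.mark.parametrize(
        "g,label",
        [(0.25, "trivial"), (0.3, "small"), (0.5, "moderate"), (0.99, "moderate"), (1.0, "large")],
    )
    def test_published_scale(self, g, label):
        assert es_label(g) == label

    def test_kappa_weights(self):
        rng = np.random.default_rng(9)
        gm = {k: rng.normal(0, 1, 30) for k in ("delta", "alpha", "gamma", "rho", "mu")}
        gn = {k: rng.normal(s, 1, 30) for s, k in zip((2, 1, 0.5, -1, 0.2), gm)}
        rep = effect_sizes(gm, gn)
        assert sum(rep.kappa.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in rep.kappa.values())

    def test_equal_effects_give_uniform_weights(self):
        gm = {k: np.array([0.0, 1.0, 2.0, 3.0]) for k in "abcde"}
        gn = {k: np.array([1.0, 2.0, 3.0, 4.0]) for k in "abcde"}
        rep = effect_sizes(gm, gn)
        assert all(v == pytest.approx(0.2) for v in rep.kappa.values())
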
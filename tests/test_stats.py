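"""Inferential layer: effect sizes, normality gating, reliability."""

import numpy as np
import pytest

from posturekit.errors import (
    IncompleteDesignError,
    InsufficientSampleError,
    InsufficientVarianceError,
    InvalidInputError,
    PairingError,
)
from posturekit.geometry import PostureProfile, RELIABILITY_PARAMS, PARAMETER_NAMES
from posturekit.stats import (
    MDC_FACTOR,
    cohens_d,
    compare_groups,
    height_correlations,
    holm_adjust,
    icc_3k,
    mdc95,
    normality_gate,
    pearson_with_relevance,
    reliability_table,
    sem_from_icc,
    session_centered_sd,
)

from _bruteforce import naive_icc_3k


class TestCohensD:
    @pytest.mark.parametrize(
        "ma,sa,mb,sb,expected,tol",
        [
            # published cluster-comparison rows: printed d recomputes from
            # the printed means +- SDs with the average-variance denominator
            (4.8, 2.6, 6.3, 3.4, 0.50, 0.005),
            (241.2, 14.1, 307.7, 23.4, 3.44, 0.005),
            (342.6, 19.4, 400.3, 22.2, 2.77, 0.005),
            (57.5, 7.0, 86.6, 10.7, 3.21, 0.02),
        ],
    )
    def test_reproduces_published_effect_sizes(self, ma, sa, mb, sb, expected, tol):
        assert cohens_d(ma, sa, mb, sb) == pytest.approx(expected, abs=tol)

    def test_zero_for_equal_means_and_antisymmetry(self):
        assert cohens_d(5.0, 1.0, 5.0, 2.0) == 0.0
        assert cohens_d(1.0, 2.0, 3.0, 4.0) == -cohens_d(3.0, 4.0, 1.0, 2.0)

    def test_invariant_under_common_affine_rescaling(self):
        d1 = cohens_d(10.0, 2.0, 13.0, 3.0)
        d2 = cohens_d(10 * 7 + 4, 2 * 7, 13 * 7 + 4, 3 * 7)
        assert d2 == pytest.approx(d1, rel=1e-12)

    def test_rejects_zero_sd(self):
        with pytest.raises(InvalidInputError):
            cohens_d(1.0, 0.0, 2.0, 1.0)


class TestSemMdc:
    @pytest.mark.parametrize(
        "sem,expected,tol",
        [(0.22, 0.61, 0.005), (0.81, 2.25, 0.005), (0.89, 2.47, 0.005), (0.0, 0.0, 1e-12)],
    )
    def test_mdc95_reproduces_published_values(self, sem, expected, tol):
        assert mdc95(sem) == pytest.approx(expected, abs=tol)

    def test_sem_closed_forms(self):
        assert sem_from_icc(1.0, 1.0) == 0.0
        assert sem_from_icc(2.5, 0.0) == 2.5
        assert sem_from_icc(0.9, 0.94) == pytest.approx(0.2205, abs=5e-5)

    def test_sem_rejects_out_of_range_icc(self):
        with pytest.raises(InvalidInputError):
            sem_from_icc(1.0, 1.2)
        with pytest.raises(InvalidInputError):
            mdc95(-0.1)

    def test_mdc_sem_ratio_is_conserved(self, rng):
        for _ in range(20):
            sem = rng.uniform(0.01, 5.0)
            assert mdc95(sem) / sem == pytest.approx(MDC_FACTOR, rel=1e-12)
        assert MDC_FACTOR == pytest.approx(1.96 * np.sqrt(2.0), rel=1e-15)
        assert MDC_FACTOR == pytest.approx(2.772, abs=1e-3)


class TestNormalityGate:
    def test_normal_samples_mostly_pass(self, rng):
        passes = sum(
            normality_gate(rng.normal(size=200))[2] for _ in range(100)
        )
        assert passes >= 90

    def test_exponential_samples_mostly_fail(self, rng):
        fails = sum(
            not normality_gate(rng.exponential(size=200))[2] for _ in range(100)
        )
        assert fails >= 95

    def test_degenerate_samples_raise(self):
        with pytest.raises(InsufficientVarianceError):
            normality_gate([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(InsufficientSampleError):
            normality_gate([1.0, 2.0])


class TestCompareGroups:
    def test_identical_samples_null(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_groups(x, x)
        assert res.p_value > 0.9
        assert res.cohens_d == 0.0

    def test_shifted_normals_detected_with_plausible_d(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 100)
            b = rng.normal(1, 1, 100)
            res = compare_groups(a, b)
            if res.p_value < 0.001 and 0.7 <= res.cohens_d <= 1.3:
                hits += 1
        assert hits >= 95

    def test_skewed_samples_use_mann_whitney(self, rng):
        a = rng.exponential(1.0, 150)
        b = rng.exponential(1.5, 150)
        assert compare_groups(a, b).test == "mann_whitney_u"

    def test_welch_flag(self, rng):
        a, b = rng.normal(0, 1, 50), rng.normal(0, 3, 50)
        assert compare_groups(a, b, welch=True).test == "welch_t"

    def test_constant_sample_raises(self):
        with pytest.raises(InsufficientVarianceError):
            compare_groups([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelations:
    def test_perfect_linear_relationship(self):
        x = np.arange(10.0)
        res = pearson_with_relevance(x, 2 * x)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.relevant

    def test_independent_noise_not_relevant(self, rng):
        ok = sum(
            abs(pearson_with_relevance(rng.normal(size=200), rng.normal(size=200)).pearson_r) < 0.2
            for _ in range(100)
        )
        assert ok >= 95

    def test_relevance_needs_both_p_and_r(self, rng):
        # strong negative correlation: significant but r < 0.45 -> not relevant
        x = np.arange(50.0)
        y = -x + rng.normal(0, 5, 50)
        res = pearson_with_relevance(x, y)
        assert res.p_value < 0.05 and not res.relevant

    def test_height_correlations_on_frame(self, rng):
        import pandas as pd

        n = 60
        h = rng.normal(170, 7, n)
        frame = pd.DataFrame({p: rng.normal(size=n) for p in PARAMETER_NAMES})
        frame["torso_vector"] = 1.5 * h + rng.normal(0, 5, n)
        res = height_correlations(frame, h)
        by_param = {r.pair[1]: r for r in res}
        assert by_param["torso_vector"].relevant
        assert not by_param["ear_line"].relevant


class TestIcc:
    def test_identical_sessions_give_one(self):
        m = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
        assert icc_3k(m) == pytest.approx(1.0)

    def test_constant_session_offset_gives_one(self):
        # consistency ICC ignores fixed session shifts
        m = np.array([[1, 2], [3, 4], [5, 6], [7, 8]], dtype=float)
        assert icc_3k(m) == pytest.approx(1.0)

    def test_matches_brute_force_and_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        for _ in range(5):
            m = rng.normal(0, 1, (8, 3)) + rng.normal(0, 2, (8, 1))
            assert icc_3k(m) == pytest.approx(naive_icc_3k(m), abs=1e-12)
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(8), 3),
                    "rater": np.tile(np.arange(3), 8),
                    "score": m.ravel(),
                }
            )
            ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
            # two-way mixed, consistency, average of k raters
            mask = ref.Type.isin(["ICC3k", "ICC(C,k)"])
            icc3k_ref = float(ref.loc[mask, "ICC"].iloc[0])
            assert icc_3k(m) == pytest.approx(icc3k_ref, abs=1e-9)

    def test_decreasing_in_error_variance(self, rng):
        subj = rng.normal(0, 1, (60, 1))
        prev = 1.1
        for sd in (0.1, 0.4, 0.8, 1.5):
            est = icc_3k(subj + rng.normal(0, sd, (60, 2)))
            assert est < prev
            prev = est

    def test_design_errors(self):
        with pytest.raises(InsufficientSampleError):
            icc_3k(np.ones((2, 2)))
        with pytest.raises(IncompleteDesignError):
            icc_3k(np.array([[1.0, np.nan], [2.0, 3.0], [4.0, 5.0]]))


def _profiles_from_matrix(mat, session):
    return [
        PostureProfile(
            subject_id=f"S{i}",
            session=session,
            values={p: float(row[j]) for j, p in enumerate(PARAMETER_NAMES)},
        )
        for i, row in enumerate(mat)
    ]


class TestReliabilityTable:
    def test_identical_sessions(self, rng):
        mat = rng.normal(10, 2, (6, len(PARAMETER_NAMES)))
        rows = reliability_table(
            _profiles_from_matrix(mat, 1), _profiles_from_matrix(mat, 2)
        )
        assert {r.parameter for r in rows} == set(RELIABILITY_PARAMS)
        for r in rows:
            assert r.icc_3k == pytest.approx(1.0)
            assert r.sem == pytest.approx(0.0, abs=1e-9)
            assert r.mdc95 == pytest.approx(0.0, abs=1e-9)

    def test_mdc_invariant_on_noisy_data(self, rng):
        m1 = rng.normal(10, 2, (20, len(PARAMETER_NAMES)))
        m2 = m1 + rng.normal(0, 0.5, m1.shape)
        rows = reliability_table(
            _profiles_from_matrix(m1, 1), _profiles_from_matrix(m2, 2)
        )
        j = PARAMETER_NAMES.index(rows[0].parameter)
        expected_sd = session_centered_sd(np.column_stack([m1[:, j], m2[:, j]]))
        for r in rows:
            assert r.mdc95 == pytest.approx(MDC_FACTOR * r.sem, rel=1e-12)
            assert 0.0 < r.icc_3k <= 1.0
        assert rows[0].sem == pytest.approx(
            expected_sd * np.sqrt(1 - rows[0].icc_3k), rel=1e-9
        )

    def test_unmatched_subjects_raise_with_orphans(self, rng):
        mat = rng.normal(10, 2, (5, len(PARAMETER_NAMES)))
        p1 = _profiles_from_matrix(mat, 1)
        p2 = _profiles_from_matrix(mat[:4], 2)
        with pytest.raises(PairingError) as exc:
            reliability_table(p1, p2)
        assert "S4" in exc.value.orphans

    def test_two_subjects_insufficient(self, rng):
        mat = rng.normal(10, 2, (2, len(PARAMETER_NAMES)))
        with pytest.raises(InsufficientSampleError):
            reliability_table(
                _profiles_from_matrix(mat, 1), _profiles_from_matrix(mat, 2)
            )


class TestHolm:
    def test_holm_monotone_and_bounded(self):
        p = np.array([0.001, 0.04, 0.03, 0.5])
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        assert adj[0] == pytest.approx(0.004)
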
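"""Method-agreement statistics: Bland-Altman, Pearson, ICC(2,k), cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgresp import (
    PairedRR,
    ReferenceRR,
    SimulationConfig,
    aggregate_reference,
    agreement_report,
    bland_altman,
    icc_avg,
    pearson,
    simulate_cohort,
    validate_cohort,
)


def _pairs(ref, est):
    return [PairedRR(str(i), r, e) for i, (r, e) in enumerate(zip(ref, est))]


class TestAggregateReference:
    def test_mean_of_three_counts(self):
        counts = [ReferenceRR(t, rr) for t, rr in ((0, 20), (900, 22), (1800, 24))]
        assert aggregate_reference(counts) == pytest.approx(22.0)

    def test_identical_counts(self):
        counts = [ReferenceRR(t, 18) for t in (0, 900, 1800)]
        assert aggregate_reference(counts) == pytest.approx(18.0)

    def test_two_counts_require_flag(self):
        counts = [ReferenceRR(0, 20), ReferenceRR(900, 22)]
        with pytest.raises(ValueError):
            aggregate_reference(counts)
        assert aggregate_reference(counts, allow_fewer=True) == pytest.approx(21.0)


class TestBlandAltman:
    def test_identity_gives_zero_band(self):
        bias, sd, lo, hi = bland_altman(_pairs([10, 15, 20], [10, 15, 20]))
        assert bias == lo == hi == 0.0

    def test_hand_computed_example(self):
        bias, sd, lo, hi = bland_altman(_pairs([10, 12, 14], [11, 12, 13]))
        assert bias == pytest.approx(0.0)
        assert sd == pytest.approx(1.0)
        assert (lo, hi) == (pytest.approx(-1.96), pytest.approx(1.96))

    def test_constant_offset(self):
        bias, sd, lo, hi = bland_altman(_pairs([10, 20, 30], [12, 22, 32]))
        assert bias == pytest.approx(2.0)
        assert hi - lo == pytest.approx(0.0)

    def test_single_pair_errors(self):
        with pytest.raises(ValueError):
            bland_altman(_pairs([10], [11]))

    @given(
        st.lists(
            st.tuples(
                st.floats(5, 60, allow_nan=False), st.floats(5, 60, allow_nan=False)
            ),
            min_size=2,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_under_role_swap(self, data):
        ref, est = zip(*data)
        b1, s1, lo1, hi1 = bland_altman(_pairs(ref, est))
        b2, s2, lo2, hi2 = bland_altman(_pairs(est, ref))
        assert b2 == pytest.approx(-b1, abs=1e-9)
        assert s2 == pytest.approx(s1, abs=1e-9)
        assert lo2 == pytest.approx(-hi1, abs=1e-9)
        assert hi2 == pytest.approx(-lo1, abs=1e-9)


class TestPearson:
    def test_perfect_and_inverse_correlation(self):
        assert pearson(_pairs([10, 20, 30], [10, 20, 30])) == pytest.approx(1.0)
        assert pearson(_pairs([10, 20, 30], [40, 30, 20])) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson(_pairs([1, 2, 3, 4], [2, 1, 4, 3])) == pytest.approx(0.6)

    def test_degenerate_side_named(self):
        with pytest.raises(ValueError, match="estimated"):
            pearson(_pairs([1, 2, 3], [5, 5, 5]))

    @given(
        a=st.floats(0.1, 5), b=st.floats(0, 10),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariance_under_positive_affine_maps(self, a, b, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(8, 40, size=12)
        est = ref + rng.normal(0, 2, size=12)
        r0 = pearson(_pairs(ref, est))
        r1 = pearson(_pairs(ref, a * est + b))
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestICC:
    def test_identical_columns_give_one(self):
        m = np.tile(np.arange(1.0, 9.0)[:, None], (1, 3))
        assert icc_avg(m) == pytest.approx(1.0)

    def test_six_by_two_anova_oracle(self):
        m = np.array([[1, 1], [2, 2], [3, 3], [4, 4], [5, 5], [6, 7]], dtype=float)
        # hand ANOVA: MSR = 97/12, MSC = MSE = 1/12 -> ICC(2,k) = 96/97
        assert icc_avg(m) == pytest.approx(96 / 97, abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(11)
        m = rng.standard_normal((200, 2))
        assert abs(icc_avg(m)) <= 0.15

    def test_matches_pingouin_two_way_random_average(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        subj = rng.uniform(10, 30, size=12)
        m = np.column_stack([subj + rng.normal(0, 1.5, 12), subj + rng.normal(0.5, 1.5, 12)])
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "score": m.ravel(),
            }
        )
        icc = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        sel = icc.Type.isin(["ICC2k", "ICC(A,k)"])  # label differs across versions
        expected = float(icc.loc[sel, "ICC"].iloc[0])
        assert icc_avg(m) == pytest.approx(expected, abs=1e-9)

    def test_small_or_missing_input_rejected(self):
        with pytest.raises(ValueError):
            icc_avg(np.ones((3, 2)))
        bad = np.ones((6, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_avg(bad)


class TestReportsAndCohorts:
    def test_report_internal_consistency(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(10, 30, 20)
        est = ref + rng.normal(0, 1, 20)
        rep = agreement_report(_pairs(ref, est))
        assert rep.loa_upper - rep.loa_lower == pytest.approx(2 * 1.96 * rep.sd_diff, abs=1e-9)
        assert -1 <= rep.pearson_r <= 1
        assert rep.icc_avg <= 1

    def test_perfect_estimates_give_perfect_report(self):
        cohort = simulate_cohort(
            6, (10, 30), (70, 100), SimulationConfig(duration_s=30.0), seed=9
        )
        pairs = _pairs(*([ [gt.rr_bpm for _, gt in cohort] ] * 2))
        rep = agreement_report(pairs)
        assert rep.bias == 0.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.icc_avg == pytest.approx(1.0)

    def test_validate_cohort_end_to_end(self, tmp_path):
        base = SimulationConfig(snr_db=25.0, duration_s=150.0)
        cohort = simulate_cohort(5, (10, 30), (70, 110), base, seed=21)
        rep = validate_cohort(
            [(rec, gt.rr_bpm) for rec, gt in cohort], plot_dir=tmp_path
        )
        assert rep.n == 5
        assert abs(rep.bias) < 1.0
        assert rep.pearson_r > 0.95
        assert (tmp_path / "scatter.svg").exists()
        assert (tmp_path / "bland_altman.svg").exists()

    def test_single_record_cohort_errors(self, clean_sim):
        rec, gt = clean_sim
        with pytest.raises(ValueError):
            validate_cohort([(rec, gt.rr_bpm)])
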
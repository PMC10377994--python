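"""ICC(A,1), classification bands, flagging and the study pipeline."""

import numpy as np
import pytest
from scipy.stats import f as f_dist

from ceph3d.errors import UndefinedICCError
from ceph3d.reliability import (FLAG_CI_BELOW, FLAG_ICC_BELOW, ICCResult,
                                RatingsMatrix, classify_icc, flag_result,
                                icc_a1, reliability_study)
from ceph3d.synthetic import NoiseModel, simulate_study


def oracle_icc_a1(x, alpha=0.05):
    """Independent from-scratch ICC(A,1) with CI: explicit two-way ANOVA
    sums of squares and the F/Satterthwaite interval, written with plain
    loops so it shares no code path with the implementation."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    msr = k * sum((x[i, :].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((x[i, j] - x[i, :].mean() - x[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    with np.errstate(all="ignore"):
        fj = msc / mse
        vn = (n - 1) * (k - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f_l = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_u = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return icc, lower, upper


class TestICC:
    def test_perfect_agreement_is_one(self):
        r = icc_a1(RatingsMatrix("q", [[1, 1], [2, 2], [3, 3]]))
        assert (r.icc, r.ci_low, r.ci_high) == (1.0, 1.0, 1.0)
        assert r.classification == "excellent" and not r.flags

    def test_matches_independent_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 13))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, k)) * rng.uniform(0.3, 5) + rng.normal(size=(1, k))
            mine = icc_a1(RatingsMatrix("q", x))
            icc, lo, hi = oracle_icc_a1(x)
            assert mine.icc == pytest.approx(icc, abs=1e-10)
            # edge cases: the implementation clips the CI to contain the
            # estimate, and degenerate draws make the oracle bounds nan
            if not mine.ci_note and np.isfinite(lo) and np.isfinite(hi):
                assert mine.ci_low == pytest.approx(lo, abs=1e-10)
                assert mine.ci_high == pytest.approx(min(hi, 1.0), abs=1e-10)

    def test_matches_pingouin_library(self, rng):
        """Library cross-check: pingouin's ICC(A,1) row (its CI is printed
        rounded to 2 decimals, hence the looser CI tolerance)."""
        import warnings

        import pandas as pd
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import pingouin as pg
            for _ in range(25):
                n, k = int(rng.integers(5, 12)), int(rng.integers(2, 4))
                x = rng.normal(size=(n, k)) + rng.normal(size=(1, k))
                mine = icc_a1(RatingsMatrix("q", x))
                df = pd.DataFrame({"subj": np.repeat(np.arange(n), k),
                                   "rater": np.tile(np.arange(k), n),
                                   "score": x.ravel()})
                table = pg.intraclass_corr(df, targets="subj", raters="rater",
                                           ratings="score")
                row = table[table["Type"] == "ICC(A,1)"].iloc[0]
                assert mine.icc == pytest.approx(row["ICC"], abs=1e-12)
                if not mine.ci_note:
                    assert mine.ci_low == pytest.approx(row["CI95"][0], abs=6e-3)
                    assert mine.ci_high == pytest.approx(
                        min(row["CI95"][1], 1.0), abs=6e-3)

    def test_rater_offset_lowers_absolute_agreement(self, rng):
        subjects = np.arange(8, dtype=float)[:, None]
        x = np.hstack([subjects, subjects + 3.0])  # constant inter-rater shift
        r = icc_a1(RatingsMatrix("q", x))
        assert r.icc < 1.0
        # consistency-type ICC ignores the offset entirely
        msr, msc, mse = r.ms_rows, r.ms_cols, r.ms_err
        icc_consistency = (msr - mse) / (msr + (2 - 1) * mse)
        assert r.icc < icc_consistency

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(10, 3))
        base = icc_a1(RatingsMatrix("q", x))
        moved = icc_a1(RatingsMatrix("q", 3.7 * x + 11.0))
        assert moved.icc == pytest.approx(base.icc, abs=1e-10)
        assert moved.ci_low == pytest.approx(base.ci_low, abs=1e-9)
        assert moved.ci_high == pytest.approx(base.ci_high, abs=1e-9)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedICCError, match="identical"):
            icc_a1(RatingsMatrix("q", np.full((5, 2), 3.0)))

    def test_negative_estimates_not_truncated(self, rng):
        # anti-correlated raters force a negative estimate
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        x = np.column_stack([a, a[::-1]])
        r = icc_a1(RatingsMatrix("q", x))
        assert r.icc < 0

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            RatingsMatrix("q", [[1, 2]])
        with pytest.raises(ValueError):
            RatingsMatrix("q", [[1, np.nan], [2, 3]])


class TestClassification:
    @pytest.mark.parametrize("icc, expected", [
        (0.38, "poor"), (0.49999, "poor"), (0.5, "moderate"), (0.66, "moderate"),
        (0.75, "moderate"), (0.7501, "good"), (0.9, "good"), (0.95, "excellent"),
        (-0.2, "poor"), (1.0, "excellent"),
    ])
    def test_bands(self, icc, expected):
        assert classify_icc(icc) == expected


class TestFlags:
    def _result(self, icc, lo, hi=1.0):
        return ICCResult("q", icc, lo, hi, 15, 2, 1.0, 0.1, 0.1)

    def test_good_icc_low_ci_is_condition2(self):
        assert self._result(0.94, 0.48).flags == {FLAG_CI_BELOW}

    def test_low_icc_is_condition1(self):
        assert self._result(0.66, 0.02).flags == {FLAG_ICC_BELOW}

    def test_solid_result_unflagged(self):
        assert self._result(0.95, 0.85).flags == set()

    def test_conditions_mutually_exclusive(self, rng):
        for _ in range(100):
            icc = rng.uniform(-0.5, 1.0)
            lo = icc - rng.uniform(0, 1)
            flags = flag_result(self._result(icc, lo))
            assert not ({FLAG_ICC_BELOW, FLAG_CI_BELOW} <= flags)


class TestStudy:
    def test_zero_noise_gives_unit_icc_everywhere(self):
        noise = NoiseModel(sigma_subject=2.0, sigma_examiner=0.0,
                           sigma_session=0.0, seed=5)
        manifest = simulate_study(3, noise)
        report = reliability_study(manifest, include_parameters=True)
        lm = report.landmark_table
        assert (lm["icc"] == 1.0).all() and (lm["flags"] == "").all()
        par = report.parameter_table
        non_airway = par[par["set"] != "airway"]
        assert (non_airway["icc"] == 1.0).all()
        assert par[par["set"] == "airway"]["note"].str.len().gt(0).all()

    def test_report_row_counts(self):
        noise = NoiseModel(seed=2)
        report = reliability_study(simulate_study(4, noise))
        # 127 landmark block rows (shared point listed twice) x 3 axes x 3 conditions
        assert len(report.landmark_table) == 127 * 3 * 3
        assert len(report.parameter_table) == 78 * 3

    def test_session_noise_drowns_subjects(self):
        noise = NoiseModel(sigma_subject=0.05, sigma_examiner=0.0,
                           sigma_session=5.0, seed=3)
        report = reliability_study(simulate_study(40, noise),
                                   include_parameters=False,
                                   landmark_filter=["n", "s"])
        intra = report.landmark_table.query("condition != 'inter'")
        # true ICC ~ 0.0001; single-cell estimates scatter ~ n^-1/2, so
        # check the pooled mean and a generous per-cell ceiling
        assert intra["icc"].mean() == pytest.approx(0.0, abs=0.15)
        assert (intra["icc"] < 0.6).all()

    def test_examiner_bias_hits_inter_not_intra(self):
        noise = NoiseModel(sigma_subject=1.0, sigma_examiner=2.0,
                           sigma_session=0.0, seed=4)
        report = reliability_study(simulate_study(25, noise),
                                   include_parameters=False,
                                   landmark_filter=["n"])
        tab = report.landmark_table
        intra = tab.query("condition != 'inter'")["icc"]
        inter = tab.query("condition == 'inter'")["icc"]
        assert (intra == 1.0).all()
        assert (inter < 1.0).all()

    def test_incomplete_subject_dropped(self):
        noise = NoiseModel(seed=6)
        manifest = simulate_study(4, noise)
        del manifest[("S002", "2", "2")]
        report = reliability_study(manifest, include_parameters=False,
                                   landmark_filter=["n"])
        assert report.n_subjects_used == 3
        assert report.n_subjects_dropped == 1

    def test_variance_components_recovered(self):
        """sigma_subject=2, sigma_session=1 gives a true intra-examiner ICC
        of 4/5; the estimate (pooled over landmark-axis cells, n=200
        subjects) must land within +-0.05."""
        noise = NoiseModel(sigma_subject=2.0, sigma_examiner=0.5,
                           sigma_session=1.0, seed=7)
        report = reliability_study(
            simulate_study(200, noise), include_parameters=False,
            landmark_filter=["n", "s", "ba", "gn", "me", "pg"])
        intra = report.landmark_table.query("condition != 'inter'")
        assert intra["icc"].mean() == pytest.approx(0.8, abs=0.05)
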
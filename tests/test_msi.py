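import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musuppress.core import (
    DegenerateInputError,
    IncompleteDesignError,
    InvalidInputError,
    MuSuppressError,
)
from musuppress.msi import (
    MSITable,
    compute_msi,
    median_split,
    msi_table_from_powers,
    msi_ttest_zero,
    rm_anova,
)
from musuppress.spectral import BandPower


class TestComputeMSI:
    def test_equal_powers_zero(self):
        assert compute_msi(3.3, 3.3) == 0.0

    def test_half_power_is_log_half(self):
        assert compute_msi(1.5, 3.0) == pytest.approx(np.log10(0.5), abs=1e-12)
        assert compute_msi(1.5, 3.0) == pytest.approx(-0.3010, abs=1e-4)

    def test_tenfold_is_plus_one(self):
        assert compute_msi(50.0, 5.0) == pytest.approx(1.0)

    def test_bandpower_objects_and_arrays(self):
        a = BandPower(np.array([1.0, 2.0]), (8, 13))
        b = BandPower(np.array([2.0, 2.0]), (8, 13))
        out = compute_msi(a, b)
        assert np.allclose(out, [np.log10(0.5), 0.0])

    def test_nonpositive_power_rejected(self):
        with pytest.raises(MuSuppressError):
            compute_msi(0.0, 1.0)
        with pytest.raises(MuSuppressError):
            compute_msi(1.0, -2.0)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    def test_antisymmetry(self, a, b):
        assert compute_msi(a, b) == pytest.approx(-compute_msi(b, a), abs=1e-12)


class TestTTestZero:
    def test_symmetric_values(self):
        values = [0.1, -0.1] * 8
        res = msi_ttest_zero(values)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == 15

    def test_closed_form_t(self, rng):
        x = rng.standard_normal(16) * 0.2 + 0.05
        res = msi_ttest_zero(x)
        m, s = x.mean(), x.std(ddof=1)
        assert res.t == pytest.approx(m / (s / np.sqrt(16)), rel=1e-12)
        assert res.d == pytest.approx(m / s, rel=1e-12)

    def test_p_matches_density_integration_oracle(self, rng):
        # independent oracle: integrate the t density numerically
        from math import gamma

        from scipy.integrate import quad

        x = rng.standard_normal(16) * 0.15 - 0.04
        res = msi_ttest_zero(x)
        df = res.df

        def t_pdf(u):
            c = gamma((df + 1) / 2) / (np.sqrt(df * np.pi) * gamma(df / 2))
            return c * (1 + u**2 / df) ** (-(df + 1) / 2)

        tail, _ = quad(t_pdf, abs(res.t), np.inf)
        assert res.p == pytest.approx(2 * tail, rel=1e-6)

    def test_ci_covers_mean(self, rng):
        x = rng.standard_normal(20) + 0.3
        res = msi_ttest_zero(x)
        assert res.ci[0] < x.mean() < res.ci[1]

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            msi_ttest_zero([0.5, 0.5, 0.5])
        with pytest.raises(InvalidInputError):
            msi_ttest_zero([0.5])


def _kron_projection_ss(arr: np.ndarray, effect_axes: tuple[int, ...]) -> float:
    """Independent sums-of-squares oracle: explicit Kronecker projection.

    For each axis, use the centering projection if the axis belongs to the
    effect and the averaging projection otherwise; the squared norm of the
    projected flattened data is the effect's SS.
    """
    mats = []
    for ax, size in enumerate(arr.shape):
        center = np.eye(size) - np.ones((size, size)) / size
        average = np.ones((size, size)) / size
        mats.append(center if ax in effect_axes else average)
    proj = mats[0]
    for m in mats[1:]:
        proj = np.kron(proj, m)
    y = arr.reshape(-1)
    return float(np.sum((proj @ y) ** 2))


class TestRMAnova:
    def test_df_for_three_level_factor_16_subjects(self, rng):
        arr = rng.standard_normal((16, 3))
        res = rm_anova(arr, ["condition"])
        row = res.iloc[0]
        assert (row.df1, row.df2) == (2, 30)

    def test_null_effect_f_is_zero(self, rng):
        # condition means exactly equal, nonzero subject and interaction noise
        subj = rng.standard_normal(16)
        noise = rng.standard_normal((16, 3))
        noise -= noise.mean(axis=0, keepdims=True)
        arr = subj[:, None] + noise
        res = rm_anova(arr, ["condition"])
        assert res.iloc[0].F == pytest.approx(0.0, abs=1e-12)
        assert res.iloc[0].ss_error > 0

    def test_all_effects_match_kron_projection_oracle(self, rng):
        arr = rng.standard_normal((16, 2, 3, 3))
        res = rm_anova(arr, ["session", "condition", "electrode"])
        axes = {"session": 1, "condition": 2, "electrode": 3}
        for _, row in res.iterrows():
            effect_axes = tuple(axes[f] for f in row.effect.split(" * "))
            ss = _kron_projection_ss(arr, effect_axes)
            ss_err = _kron_projection_ss(arr, (0,) + effect_axes)
            assert row.ss == pytest.approx(ss, rel=1e-8)
            assert row.ss_error == pytest.approx(ss_err, rel=1e-8)
            df1 = int(np.prod([arr.shape[ax] - 1 for ax in effect_axes]))
            df2 = df1 * 15
            f_ref = (ss / df1) / (ss_err / df2)
            assert row.F == pytest.approx(f_ref, rel=1e-8)

    def test_ss_conservation(self, rng):
        arr = rng.standard_normal((8, 2, 3))
        res = rm_anova(arr, ["a", "b"])
        ss_subject = _kron_projection_ss(arr, (0,))
        total = float(np.sum((arr - arr.mean()) ** 2))
        decomposed = res.ss.sum() + res.ss_error.sum() + ss_subject
        assert decomposed == pytest.approx(total, rel=1e-8)

    def test_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        arr = rng.standard_normal((10, 2, 3))
        rows = [
            {"subject": s, "a": f"a{i}", "b": f"b{j}", "msi": arr[s, i, j]}
            for s in range(10) for i in range(2) for j in range(3)
        ]
        df = pd.DataFrame(rows)
        mine = rm_anova(df, ["a", "b"])
        ref = AnovaRM(df, depvar="msi", subject="subject",
                      within=["a", "b"]).fit().anova_table
        for effect, ref_name in [("a", "a"), ("b", "b"), ("a * b", "a:b")]:
            f_mine = mine[mine.effect == effect].F.iloc[0]
            assert f_mine == pytest.approx(ref.loc[ref_name, "F Value"], rel=1e-8)

    def test_gg_epsilon_matches_pingouin(self, rng):
        import pingouin as pg

        arr = rng.standard_normal((12, 4)) + np.array([0.0, 0.1, 0.2, 0.0])
        arr[:, 0] *= 2.0  # induce a sphericity violation
        rows = [{"subject": s, "cond": f"c{j}", "msi": arr[s, j]}
                for s in range(12) for j in range(4)]
        df = pd.DataFrame(rows)
        mine = rm_anova(df, ["cond"]).iloc[0]
        ref = pg.rm_anova(data=df, dv="msi", within="cond", subject="subject",
                          correction=True)
        assert mine.F == pytest.approx(ref["F"].iloc[0], rel=1e-6)
        assert mine.eps_gg == pytest.approx(ref["eps"].iloc[0], rel=1e-6)
        assert mine.p_gg == pytest.approx(ref["p_GG_corr"].iloc[0], rel=1e-6)

    def test_epsilon_bounds(self, rng):
        arr = rng.standard_normal((9, 5))
        row = rm_anova(arr, ["f"]).iloc[0]
        assert 1.0 / 4 <= row.eps_gg <= 1.0

    def test_partial_eta_squared_definition(self, rng):
        arr = rng.standard_normal((8, 3))
        row = rm_anova(arr, ["f"]).iloc[0]
        assert row.np2 == pytest.approx(row.ss / (row.ss + row.ss_error))

    def test_missing_cells_rejected(self, rng):
        rows = [{"subject": s, "cond": f"c{j}", "msi": 0.1}
                for s in range(4) for j in range(3)]
        df = pd.DataFrame(rows).drop(index=0)
        with pytest.raises(IncompleteDesignError):
            rm_anova(df, ["cond"])


class TestMedianSplit:
    def test_one_to_sixteen(self):
        labels = median_split(np.arange(1.0, 17.0))
        assert list(labels[:8]) == ["suppresser"] * 8
        assert list(labels[8:]) == ["non-suppresser"] * 8

    def test_ties_at_median_equal_sizes(self):
        values = [1.0, 2.0, 2.0, 2.0, 2.0, 3.0]
        labels = median_split(values)
        assert (labels == "suppresser").sum() == 3
        # stable order: earlier tied entries fall in the lower half
        assert labels[1] == "suppresser" and labels[4] == "non-suppresser"

    def test_matches_sorting_oracle(self, rng):
        values = rng.standard_normal(16)
        labels = median_split(values)
        lower = set(np.argsort(values)[:8])
        for i in range(16):
            expected = "suppresser" if i in lower else "non-suppresser"
            assert labels[i] == expected

    def test_too_few_rejected(self):
        with pytest.raises(InvalidInputError):
            median_split([0.1])


class TestMSITable:
    def test_from_powers_and_subject_means(self):
        powers = {
            ("s0", "pre", "balls"): BandPower(np.array([2.0, 2.0]), (8, 13)),
            ("s0", "pre", "complex"): BandPower(np.array([1.0, 2.0]), (8, 13)),
        }
        table = msi_table_from_powers(powers, ["C3", "C4"], "balls")
        assert len(table.table) == 2
        means = table.subject_means("complex", "pre", ["C3"])
        assert means["s0"] == pytest.approx(np.log10(0.5))

    def test_missing_baseline_rejected(self):
        powers = {("s0", "pre", "complex"): BandPower(np.array([1.0]), (8, 13))}
        with pytest.raises(IncompleteDesignError):
            msi_table_from_powers(powers, ["C3"], "balls")

    def test_csv_round_trip(self, tmp_path):
        powers = {
            ("s0", "pre", "balls"): BandPower(np.array([2.0]), (8, 13)),
            ("s0", "pre", "social"): BandPower(np.array([1.0]), (8, 13)),
        }
        table = msi_table_from_powers(powers, ["C3"], "balls")
        path = tmp_path / "msi.csv"
        table.to_csv(path)
        back = MSITable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.table, table.table, check_dtype=False
        )
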
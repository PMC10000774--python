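"""Response-surface fitting, ANOVA decomposition and fit statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from chromaqbd.designs import Factor, full_factorial
from chromaqbd.rsm import (
    ResponseTable,
    anova_table,
    default_terms,
    fit_response_model,
    fit_statistics,
    predict,
)


def _toy_table(k=3, n_center=3, n_reps=1, seed=0, coefs=None, noise=0.0, rng=None):
    factors = [Factor(f"F{i}", -1.0, 1.0) for i in range(k)]  # natural == coded
    d = full_factorial(factors, n_center=n_center, n_replicates=n_reps, seed=seed)
    terms = default_terms(d.factor_names)
    X = np.column_stack(
        [np.ones(d.n_runs)]
        + [
            np.prod([d.coded[:, d.factor_names.index(p)] for p in t.split(":")], axis=0)
            for t in terms
        ]
    )
    if coefs is None:
        coefs = np.arange(1, X.shape[1] + 1, dtype=float)
    y = X @ coefs
    if noise > 0:
        y = y + noise * (rng or np.random.default_rng(0)).standard_normal(len(y))
    return ResponseTable(design=d, responses=pd.DataFrame({"Y": y})), coefs, terms


class TestFit:
    def test_perfect_fit_recovers_truth(self):
        table, coefs, _ = _toy_table()
        m = fit_response_model(table, "Y")
        np.testing.assert_allclose(m.coefficients.to_numpy(), coefs, atol=1e-10)
        resid = table.responses["Y"].to_numpy() - predict(
            m, table.design.to_frame()[table.design.factor_names]
        )
        assert np.sum(resid**2) < 1e-18

    def test_matches_normal_equations_oracle(self, rng):
        # 5-run non-orthogonal toy design, brute-force (X'X)^-1 X'y
        f = [Factor("A", -1, 1), Factor("B", -1, 1)]
        from chromaqbd.designs import DesignMatrix

        coded = np.array([[-1, -1], [1, -1], [-1, 1], [1, 1], [1, 1]], dtype=float)
        d = DesignMatrix(
            factors=f,
            coded=coded,
            is_center=np.zeros(5, bool),
            replicate=np.array([1, 1, 1, 1, 2]),
            run_order=np.arange(1, 6),
        )
        y = rng.standard_normal(5)
        table = ResponseTable(design=d, responses=pd.DataFrame({"Y": y}))
        m = fit_response_model(table, "Y", term_spec=["A", "B", "A:B"])
        X = np.column_stack([np.ones(5), coded[:, 0], coded[:, 1], coded[:, 0] * coded[:, 1]])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(m.coefficients.to_numpy(), beta, atol=1e-10)

    def test_intercept_is_mean_on_orthogonal_design(self, rng):
        table, _, _ = _toy_table(noise=1.0, rng=rng, n_center=0)
        m = fit_response_model(table, "Y")
        assert m.coefficients["Intercept"] == pytest.approx(
            table.responses["Y"].mean(), rel=1e-10
        )

    def test_rank_deficiency_names_terms(self):
        table, _, _ = _toy_table(n_center=0)
        with pytest.raises(ValueError, match="F0:F0"):
            fit_response_model(table, "Y", term_spec=["F0", "F0:F0"])


class TestAnova:
    def test_pure_error_zero_for_identical_replicates(self):
        table, _, _ = _toy_table(n_reps=2)  # replicate responses are identical
        m = anova_table(fit_response_model(table, "Y"), table)
        an = m.anova.set_index("source")
        assert an.loc["pure error", "SS"] == pytest.approx(0.0, abs=1e-18)

    def test_ss_additivity_on_random_tables(self, rng):
        for _ in range(20):
            table, _, _ = _toy_table(noise=rng.uniform(0.1, 5), rng=rng, n_reps=2)
            m = anova_table(fit_response_model(table, "Y"), table)
            an = m.anova.set_index("source")
            tot = an.loc["total", "SS"]
            assert abs(an.loc["model", "SS"] + an.loc["residual", "SS"] - tot) / tot < 1e-8
            assert (
                abs(an.loc["lack-of-fit", "SS"] + an.loc["pure error", "SS"] - an.loc["residual", "SS"])
                <= 1e-8 * tot
            )

    def test_p_value_matches_quadrature_oracle(self, rng):
        # hand-written F density integrated numerically
        table, _, _ = _toy_table(noise=1.0, rng=rng, n_reps=2)
        m = anova_table(fit_response_model(table, "Y"), table)
        an = m.anova.set_index("source")
        F_obs = float(an.loc["F0", "F"])
        d1, d2 = 1.0, float(an.loc["residual", "df"])

        def f_pdf(x):
            lg = (
                math.lgamma((d1 + d2) / 2)
                - math.lgamma(d1 / 2)
                - math.lgamma(d2 / 2)
                + (d1 / 2) * math.log(d1 / d2)
                + (d1 / 2 - 1) * math.log(x)
                - ((d1 + d2) / 2) * math.log(1 + d1 * x / d2)
            )
            return math.exp(lg)

        tail, _ = integrate.quad(f_pdf, F_obs, np.inf)
        assert float(an.loc["F0", "p"]) == pytest.approx(tail, abs=1e-6)

    def test_lack_of_fit_omitted_without_replicates(self):
        table, _, _ = _toy_table(n_center=0, n_reps=1)
        m = anova_table(fit_response_model(table, "Y"), table)
        assert not m.lack_of_fit_available
        assert "lack-of-fit" not in set(m.anova["source"])

    def test_curvature_row_with_center_points(self, rng):
        table, _, _ = _toy_table(n_center=3, noise=0.5, rng=rng)
        m = anova_table(fit_response_model(table, "Y"), table)
        assert "curvature" in set(m.anova["source"])


class TestFitStatistics:
    def test_perfect_fit(self):
        table, _, _ = _toy_table()
        m = anova_table(fit_response_model(table, "Y"), table)
        s = fit_statistics(m, table)
        assert s["R2"] == pytest.approx(1.0, abs=1e-12)
        assert s["CV_pct"] == pytest.approx(0.0, abs=1e-6)

    def test_adjusted_r2_not_above_r2(self, rng):
        table, _, _ = _toy_table(noise=2.0, rng=rng, n_reps=2)
        m = anova_table(fit_response_model(table, "Y"), table)
        s = fit_statistics(m, table)
        assert 0 <= s["R2"] <= 1
        assert s["adj_R2"] <= s["R2"] + 1e-12

    def test_constant_shift_moves_only_intercept(self, rng):
        table, _, _ = _toy_table(noise=1.0, rng=rng)
        m0 = fit_response_model(table, "Y")
        shifted = ResponseTable(
            design=table.design, responses=table.responses + 100.0
        )
        m1 = fit_response_model(shifted, "Y")
        assert m1.coefficients["Intercept"] - m0.coefficients["Intercept"] == pytest.approx(100.0, rel=1e-10)
        np.testing.assert_allclose(
            m1.coefficients.to_numpy()[1:], m0.coefficients.to_numpy()[1:], atol=1e-9
        )

    def test_row_permutation_invariance(self, rng):
        table, _, _ = _toy_table(noise=1.0, rng=rng, n_reps=2)
        perm = rng.permutation(table.design.n_runs)
        from chromaqbd.designs import DesignMatrix

        d = table.design
        d2 = DesignMatrix(
            factors=d.factors,
            coded=d.coded[perm],
            is_center=d.is_center[perm],
            replicate=d.replicate[perm],
            run_order=d.run_order[perm],
        )
        t2 = ResponseTable(design=d2, responses=table.responses.iloc[perm].reset_index(drop=True))
        s1 = fit_statistics(anova_table(fit_response_model(table, "Y"), table), table)
        s2 = fit_statistics(anova_table(fit_response_model(t2, "Y"), t2), t2)
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], rel=1e-9)


class TestPredict:
    def test_predict_at_design_points_of_perfect_fit(self):
        table, _, _ = _toy_table()
        m = fit_response_model(table, "Y")
        yhat = predict(m, table.design.to_frame()[table.design.factor_names])
        np.testing.assert_allclose(yhat, table.responses["Y"].to_numpy(), atol=1e-10)

    def test_predict_center_equals_intercept(self):
        table, _, _ = _toy_table(n_center=0)
        m = fit_response_model(table, "Y")
        mid = {f.name: [f.mid] for f in table.design.factors}
        assert predict(m, mid)[0] == pytest.approx(m.coefficients["Intercept"], rel=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        table, coefs, terms = _toy_table()
        m = fit_response_model(table, "Y")
        pts = rng.uniform(-1, 1, size=(20, 3))
        frame = pd.DataFrame(pts, columns=table.design.factor_names)
        # brute-force polynomial evaluation (natural == coded here)
        expected = np.full(20, coefs[0])
        for c, t in zip(coefs[1:], terms):
            expected += c * np.prod(
                [pts[:, table.design.factor_names.index(p)] for p in t.split(":")], axis=0
            )
        np.testing.assert_allclose(predict(m, frame), expected, atol=1e-10)

    def test_unknown_factor_rejected(self):
        table, _, _ = _toy_table()
        m = fit_response_model(table, "Y")
        with pytest.raises(KeyError):
            predict(m, {"bogus": [0.0], "F0": [0.0], "F1": [0.0], "F2": [0.0]})
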
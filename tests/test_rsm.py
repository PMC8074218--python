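"""Second-order response-surface regression and lack-of-fit ANOVA."""

import numpy as np
import pytest

import microenc as me
from microenc.rsm import quadratic_model_matrix, quadratic_terms


def normal_equations_fit(coded, y):
    """Independent oracle: explicit normal-equations solve of the quadratic."""
    X = quadratic_model_matrix(coded)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


@pytest.fixture(scope="module")
def ccd():
    return me.generate_ccd(me.quebracho_design_spec())


class TestFitQuadratic:
    def test_study_lc_linear_core_shell_coefficient(self, lc_fit):
        assert lc_fit.coef("core_shell") == pytest.approx(5.193, abs=0.02)
        assert lc_fit.marks[lc_fit.terms.index("core_shell")] == "***"

    def test_constant_response_gives_pure_intercept(self, ccd):
        fit = me.fit_quadratic(ccd, np.full(13, 7.5), "const")
        assert fit.coef("Intercept") == pytest.approx(7.5)
        assert np.allclose(fit.params[1:], 0.0, atol=1e-10)

    def test_noiseless_generate_then_fit_round_trip(self, ccd, rng):
        beta = rng.normal(size=6)
        y = quadratic_model_matrix(ccd.coded) @ beta
        fit = me.fit_quadratic(ccd, y, "synthetic")
        assert np.allclose(fit.params, beta, atol=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle_on_random_designs(self, rng):
        for _ in range(10):
            coded = rng.uniform(-1.5, 1.5, size=(12, 2))
            frame = {
                "run_id": np.arange(1, 13),
                "point_class": "factorial",
                "coded_a": coded[:, 0],
                "coded_b": coded[:, 1],
                "actual_a": coded[:, 0],
                "actual_b": coded[:, 1],
            }
            import pandas as pd

            table = me.DesignTable(pd.DataFrame(frame), ("a", "b"))
            y = rng.normal(size=12)
            fit = me.fit_quadratic(table, y)
            assert np.allclose(fit.params, normal_equations_fit(coded, y), atol=1e-10)

    def test_r2_adj_identity(self, lc_fit):
        n, p = lc_fit.nobs, len(lc_fit.terms)
        expect = 1 - (1 - lc_fit.r2) * (n - 1) / (n - p)
        assert lc_fit.r2_adj == pytest.approx(expect, abs=1e-12)

    def test_rank_deficient_design_names_aliased_terms(self):
        import pandas as pd

        coded = np.array([[x, x] for x in (-1.0, -0.5, 0.0, 0.5, 1.0, 0.25, -0.25, 0.75)])
        table = me.DesignTable(
            pd.DataFrame(
                {
                    "run_id": np.arange(1, 9),
                    "point_class": "factorial",
                    "coded_a": coded[:, 0],
                    "coded_b": coded[:, 1],
                    "actual_a": coded[:, 0],
                    "actual_b": coded[:, 1],
                }
            ),
            ("a", "b"),
        )
        with pytest.raises(np.linalg.LinAlgError, match="aliased"):
            me.fit_quadratic(table, np.arange(8.0))


class TestLackOfFit:
    def test_pure_error_df_from_center_replicates(self, lc_fit):
        # 13 runs, 9 distinct points -> 4 pure-error df; 9 - 6 terms -> 3 LOF df
        assert lc_fit.anova.rows["pure_error"][1] == 4
        assert lc_fit.anova.rows["lack_of_fit"][1] == 3

    def test_residual_ss_decomposes_exactly(self, lc_fit):
        ss_res = lc_fit.anova.rows["residual"][0]
        ss_lof = lc_fit.anova.rows["lack_of_fit"][0]
        ss_pe = lc_fit.anova.rows["pure_error"][0]
        assert ss_res == pytest.approx(ss_lof + ss_pe, abs=1e-10)
        assert ss_lof >= 0 and ss_pe >= 0

    def test_noiseless_quadratic_has_zero_lack_of_fit(self, ccd):
        beta = np.array([10.0, 2.0, -1.0, 0.5, -0.3, 0.2])
        y = quadratic_model_matrix(ccd.coded) @ beta
        fit = me.fit_quadratic(ccd, y)
        assert fit.anova.rows["lack_of_fit"][0] == pytest.approx(0.0, abs=1e-10)

    def test_no_replicates_reports_unavailable(self, rng):
        import pandas as pd

        coded = rng.uniform(-1, 1, size=(10, 2))
        table = me.DesignTable(
            pd.DataFrame(
                {
                    "run_id": np.arange(1, 11),
                    "point_class": "factorial",
                    "coded_a": coded[:, 0],
                    "coded_b": coded[:, 1],
                    "actual_a": coded[:, 0],
                    "actual_b": coded[:, 1],
                }
            ),
            ("a", "b"),
        )
        fit = me.fit_quadratic(table, rng.normal(size=10))
        assert fit.anova.f_lack_of_fit is None
        assert "unavailable" in fit.anova.status


class TestPredictAndGrid:
    def test_center_prediction_is_intercept(self, lc_fit):
        assert me.predict(lc_fit, [0.0, 0.0]) == pytest.approx(lc_fit.coef("Intercept"))
        assert me.predict(lc_fit, [0.0, 0.0]) == pytest.approx(12.292, abs=0.02)

    def test_prediction_matches_hand_polynomial(self, lc_fit):
        b = {t: lc_fit.coef(t) for t in lc_fit.terms}
        x1, x2 = 1.0, -1.0
        hand = (
            b["Intercept"] + b["core_shell"] * x1 + b["md_ga"] * x2
            + b["core_shell:md_ga"] * x1 * x2
            + b["core_shell^2"] * x1**2 + b["md_ga^2"] * x2**2
        )
        assert me.predict(lc_fit, [x1, x2]) == pytest.approx(hand, abs=1e-12)

    def test_dimension_mismatch(self, lc_fit):
        with pytest.raises(ValueError):
            me.predict(lc_fit, [0.0, 0.0, 0.0])

    def test_constant_fit_grid_uniform(self, ccd):
        fit = me.fit_quadratic(ccd, np.full(13, 3.0))
        grid = me.surface_grid(fit, resolution=2)
        assert len(grid) == 4
        assert np.allclose(grid["predicted"], 3.0)

    def test_lc_grid_argmax_at_high_core_low_md(self, lc_fit):
        grid = me.surface_grid(lc_fit, resolution=41)
        best = grid.loc[grid["predicted"].idxmax()]
        assert best["core_shell"] == pytest.approx(1.0)
        assert best["md_ga"] == pytest.approx(-1.0)

    def test_corrected_ey_surface_increases_along_md_ga(self, study_corrected):
        design, resp = study_corrected
        fit = me.fit_quadratic(design, resp["ey"].to_numpy(float), "ey")
        line = [me.predict(fit, [0.0, x2]) for x2 in np.linspace(-1, 1, 9)]
        assert np.all(np.diff(line) > 0)


class TestSignificanceMarks:
    @pytest.mark.parametrize(
        "p,mark", [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "")]
    )
    def test_star_thresholds(self, p, mark):
        assert me.significance_marks([p]) == [mark]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            me.significance_marks([1.5])


def test_term_ordering_generalizes_to_three_factors():
    terms = quadratic_terms(["a", "b", "c"])
    assert terms == [
        "Intercept", "a", "b", "c", "a:b", "a:c", "b:c", "a^2", "b^2", "c^2",
    ]
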
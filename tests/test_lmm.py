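"""Mixed-model ladder: specs, profiled deviance, AIC comparison, post hocs."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from erpfa.dataset import DatasetError
from erpfa.lmm import (
    LadderData,
    _profiled,
    build_ladder,
    compare_aic,
    fit_ladder,
    fit_lmm,
    posthoc_face_by_constraint,
    summarize_best,
)
from erpfa.simulate import simulate_trial_table

M5_FIXED = {
    "accent": 0.38,
    "constraint": 1.26,
    "face": 0.28,
    "accent:constraint": -0.28,
    "constraint:face": 0.2,
}


class TestLadderStructure:
    def test_eight_nested_models(self):
        ladder = build_ladder()
        assert [s.name for s in ladder] == [f"M{i}" for i in range(8)]
        assert ladder[0].terms == ()
        for lo, hi in zip(ladder, ladder[1:]):
            assert set(lo.terms) <= set(hi.terms)
            assert len(hi.terms) == len(lo.terms) + 1
        assert ladder[5].terms[-1] == "constraint:face"
        assert "(Constraint|Participant)" in ladder[0].formula
        assert "(1|Item)" in ladder[0].formula

    def test_design_matrices_nest(self):
        tab = simulate_trial_table(n_participants=3, trials_per_cell=1, seed=0)
        data = LadderData(tab)
        prev = None
        for spec in build_ladder():
            blocks = data.model_blocks(spec.terms)
            if prev is not None:
                assert blocks["names"][: len(prev)] == prev
            prev = blocks["names"]

    def test_sum_coding_is_plus_minus_one(self):
        tab = simulate_trial_table(n_participants=2, trials_per_cell=1, seed=0)
        X, names = (
            LadderData(tab).model_blocks(("accent", "constraint", "face"))["X"],
            None,
        )
        assert set(np.unique(X[:, 1:])) == {-1.0, 1.0}


class TestProfiledDeviance:
    def test_matches_dense_gls_oracle(self):
        """The sparse profiled deviance equals a dense marginal-likelihood
        evaluation with beta and sigma^2 profiled out by GLS."""
        tab = simulate_trial_table(
            n_participants=5, trials_per_cell=2, fixed=M5_FIXED, seed=3
        )
        data = LadderData(tab)
        blocks = data.model_blocks(build_ladder()[5].terms)
        for theta in ([0.3, 0.1, 0.2, 0.15], [1.0, 0.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0]):
            theta = np.asarray(theta)
            dev, beta, _, _ = _profiled(data, blocks, theta)
            lam = data.lambda_mat(theta)
            Z = data._Z.toarray()
            X, y, n = blocks["X"], data.y, data.n
            V = Z @ lam @ lam.T @ Z.T + np.eye(n)
            Vi = np.linalg.inv(V)
            bhat = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ bhat
            s2 = (r @ Vi @ r) / n
            dense = n * np.log(2 * np.pi * s2) + np.linalg.slogdet(V)[1] + n
            assert dev == pytest.approx(dense, abs=1e-8)
            assert np.abs(beta - bhat).max() <= 1e-10

    def test_matches_lme4_reference(self, tmp_path):
        """Deviance and fixed effects agree with lme4's ML fit (bobyqa)."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        tab = simulate_trial_table(
            n_participants=6, trials_per_cell=3, fixed=M5_FIXED, seed=3
        )
        fit = fit_lmm(tab, build_ladder()[5])
        csv = tmp_path / "trials.csv"
        tab.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv('{csv}')
                d$accent <- factor(d$accent, levels=c('L2','L1'))
                d$constraint <- factor(d$constraint, levels=c('HC','LC'))
                d$face <- factor(d$face, levels=c('Face','NoFace'))
                for (f in c('accent','constraint','face')) contrasts(d[[f]]) <- contr.sum(2)
                m <- lmer(amplitude ~ accent + constraint + face + accent:constraint +
                          constraint:face + (constraint|participant) + (1|item),
                          data=d, REML=FALSE,
                          control=lmerControl(optimizer='bobyqa',
                                              optCtrl=list(maxfun=100000)))
                cat(deviance(m), fixef(m), sep='\\n')
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        dev_r, beta_r = vals[0], np.array(vals[1:])
        assert fit.deviance == pytest.approx(dev_r, abs=2e-3)
        assert np.abs(fit.beta.to_numpy() - beta_r).max() <= 5e-3

    def test_refit_is_deterministic(self):
        tab = simulate_trial_table(n_participants=6, trials_per_cell=2,
                                   fixed=M5_FIXED, seed=9)
        f1 = fit_lmm(tab, build_ladder()[5])
        f2 = fit_lmm(tab, build_ladder()[5])
        assert f1.aic == f2.aic
        assert np.array_equal(f1.beta.to_numpy(), f2.beta.to_numpy())

    def test_aic_counts_variance_parameters(self):
        tab = simulate_trial_table(n_participants=5, trials_per_cell=2, seed=1)
        fit = fit_lmm(tab, build_ladder()[0])
        # intercept + 4 covariance parameters + residual
        assert fit.k_params == 1 + 4 + 1
        assert fit.aic == pytest.approx(fit.deviance + 2 * fit.k_params)

    def test_sign_invariance_of_sum_coding(self):
        """Relabeling which level is +1 flips the estimate's sign only."""
        tab = simulate_trial_table(n_participants=6, trials_per_cell=2,
                                   fixed={"constraint": 1.0}, seed=5)
        fit = fit_lmm(tab, build_ladder()[2])
        swapped = tab.copy()
        swapped["constraint"] = swapped["constraint"].map({"HC": "LC", "LC": "HC"})
        fit2 = fit_lmm(swapped, build_ladder()[2])
        est = fit.beta["Constraint[HC]"]
        est2 = fit2.beta["Constraint[HC]"]
        assert est == pytest.approx(-est2, abs=1e-4)


class TestCompareAic:
    def test_equal_aics_split_weight(self):
        out = compare_aic(aics=[100.0, 100.0])
        assert np.allclose(out["AICw"], 0.5)

    def test_delta_two_hand_computation(self):
        out = compare_aic(aics=[10.0, 12.0])
        # weights 1/(1+e^-1) and e^-1/(1+e^-1)
        assert out["AICw"].iloc[0] == pytest.approx(0.731, abs=5e-4)
        assert out["AICw"].iloc[1] == pytest.approx(0.269, abs=5e-4)

    def test_printed_comparison_column(self, reported_model_comparison):
        out = compare_aic(daics=reported_model_comparison["daic"].to_numpy())
        m4 = out["AICw"].iloc[4]
        assert round(float(m4), 2) == pytest.approx(0.15, abs=1e-9)
        np.testing.assert_allclose(
            out["AICw"], reported_model_comparison["aicw"], atol=0.005
        )
        assert out["AICw"].sum() == pytest.approx(1.0, abs=1e-6)
        assert out["dAIC"].min() == 0.0

    def test_needs_two_models(self):
        with pytest.raises(DatasetError):
            compare_aic(aics=[1.0])


class TestEstimation:
    def test_recovers_fixed_effects_within_3se(self):
        tab = simulate_trial_table(
            n_participants=24, trials_per_cell=12, fixed=M5_FIXED, seed=21
        )
        fit = fit_lmm(tab, build_ladder()[5])
        summ = summarize_best(fit).set_index("term")
        for term, truth in [
            ("Constraint[HC]", 1.26),
            ("Face[Face]", 0.28),
            ("Constraint[HC]*Face[Face]", 0.2),
        ]:
            row = summ.loc[term]
            assert abs(row["estimate"] - truth) <= 3 * row["se"]
            assert row["t_value"] == pytest.approx(
                row["estimate"] / row["se"], rel=1e-10
            )
            assert row["ci_high"] - row["ci_low"] == pytest.approx(
                2 * 1.96 * row["se"], rel=1e-10
            )

    def test_constraint_estimate_unbiased(self):
        """Bias of the Constraint effect < 5% of truth over repeated fits."""
        ests = []
        for seed in range(40):
            tab = simulate_trial_table(
                n_participants=12, trials_per_cell=4, fixed=M5_FIXED, seed=1000 + seed
            )
            fit = fit_lmm(tab, build_ladder()[5])
            ests.append(fit.beta["Constraint[HC]"])
        assert abs(np.mean(ests) - 1.26) <= 0.05 * 1.26

    def test_posthoc_contrast_weights_and_bonferroni(self):
        tab = simulate_trial_table(
            n_participants=10, trials_per_cell=4, fixed=M5_FIXED, seed=31
        )
        fit = fit_lmm(tab, build_ladder()[5])
        out = posthoc_face_by_constraint(fit).set_index("contrast")
        b = fit.beta
        expect_hc = 2 * b["Face[Face]"] + 2 * b["Constraint[HC]*Face[Face]"]
        expect_lc = 2 * b["Face[Face]"] - 2 * b["Constraint[HC]*Face[Face]"]
        assert out.loc["Face|HC", "estimate"] == pytest.approx(expect_hc, abs=1e-10)
        assert out.loc["Face|LC", "estimate"] == pytest.approx(expect_lc, abs=1e-10)
        assert (out["p_adj"] <= 1.0).all()
        assert np.allclose(out["p_adj"], np.minimum(1.0, 2 * out["p_raw"]))

    def test_posthoc_requires_interaction_term(self):
        tab = simulate_trial_table(n_participants=4, trials_per_cell=1, seed=0)
        fit = fit_lmm(tab, build_ladder()[3])
        with pytest.raises(DatasetError):
            posthoc_face_by_constraint(fit)

    def test_posthoc_type_one_error_near_nominal(self):
        """Null Face effects: raw-p rejections near 5% across simulations.

        Both the Face main effect and the interaction are zero, so each
        simple-effect contrast is null; the study's participant count keeps
        the normal approximation honest."""
        rej = 0
        n_sims = 500
        for seed in range(n_sims):
            tab = simulate_trial_table(
                n_participants=42,
                trials_per_cell=1,
                fixed={"constraint": 1.0},
                re_sd=(1.0, 0.4, 0.0, 0.4),
                seed=40_000 + seed,
            )
            fit = fit_lmm(tab, build_ladder()[5])
            out = posthoc_face_by_constraint(fit)
            rej += int(out["p_raw"].iloc[0] < 0.05)
        assert rej / n_sims == pytest.approx(0.05, abs=0.02)

    def test_injected_face_within_hc_only(self):
        """Face effect only under HC: first contrast fires, second does not."""
        hits = 0
        for seed in range(10):
            tab = simulate_trial_table(
                n_participants=30,
                trials_per_cell=10,
                fixed={"constraint": 1.0, "face": 0.3, "constraint:face": 0.3},
                resid_sd=3.0,
                seed=50_000 + seed,
            )
            fit = fit_lmm(tab, build_ladder()[5])
            out = posthoc_face_by_constraint(fit).set_index("contrast")
            if (
                out.loc["Face|HC", "p_adj"] < 0.05
                and out.loc["Face|LC", "p_adj"] > 0.05
            ):
                hits += 1
        assert hits >= 9

    def test_empty_and_degenerate_tables_rejected(self):
        with pytest.raises(DatasetError):
            LadderData(pd.DataFrame(columns=["participant", "item", "amplitude"]))
        tab = simulate_trial_table(n_participants=2, trials_per_cell=1, seed=0)
        tab.loc[0, "amplitude"] = np.inf
        with pytest.raises(DatasetError, match="finite"):
            LadderData(tab)


class TestWeightProperties:
    """Akaike-weight invariants over arbitrary AIC vectors."""

    def test_weights_normalized_and_order_equivariant(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, derandomize=True, deadline=None)
        @given(
            st.lists(
                st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
                min_size=2,
                max_size=10,
            )
        )
        def check(aics):
            out = compare_aic(aics=aics)
            assert out["dAIC"].min() == 0.0
            assert out["AICw"].sum() == pytest.approx(1.0, abs=1e-6)
            assert ((out["AICw"] >= 0) & (out["AICw"] <= 1)).all()
            # permuting the models permutes the weights identically
            perm = np.argsort(aics, kind="stable")[::-1]
            out2 = compare_aic(aics=np.asarray(aics)[perm])
            np.testing.assert_allclose(
                out2["AICw"].to_numpy(), out["AICw"].to_numpy()[perm], atol=1e-12
            )

        check()
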
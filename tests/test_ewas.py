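import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from smokesig import ewas
from smokesig.deconvolution import CellFractions
from smokesig.io_formats import BetaMatrix, SampleSheet, SHEET_COLUMNS
from smokesig.simulate import SimConfig, build_truth, simulate_dataset
from conftest import small_config


def _cohort(n_never=40, n_current=40, seed=0, tissue="buccal"):
    rng = np.random.default_rng(seed)
    n = n_never + n_current
    ids = [f"s{i}" for i in range(n)]
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ids,
                "tissue": tissue,
                "smoking_type": ["never"] * n_never + ["current"] * n_current,
                "age": rng.uniform(20, 70, n).round(1),
                "pack_years": 0.0,
                "duration_category": "NA",
                "sex": "F",
            }
        )
    )
    fractions = CellFractions(
        pd.DataFrame(
            {"immune": rng.beta(2, 6, n)}, index=pd.Index(ids, name="sample_id")
        ).assign(epithelial=lambda d: 1 - d["immune"])
    )
    return ids, sheet, fractions


def holm_brute_force(p):
    """Independent oracle: exhaustive step-down evaluation.

    The Holm-adjusted value of p_(i) is max_{j<=i} (m-j+1)·p_(j), capped at 1
    — derived here by literally walking the sorted sequence.
    """
    p = np.asarray(p, float)
    order = np.argsort(p, kind="stable")
    m = len(p)
    adj_sorted = []
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj_sorted.append(min(running, 1.0))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestFitCpg:
    def test_identical_groups_give_zero_effect_and_p_near_one(self):
        ids, sheet, fractions = _cohort(seed=1)
        beta_row = pd.Series(0.42, index=pd.Index(ids))
        effect, se, p = ewas.fit_cpg(beta_row, sheet, fractions)
        assert effect == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_statsmodels_ols(self):
        ids, sheet, fractions = _cohort(seed=2)
        rng = np.random.default_rng(3)
        y = rng.uniform(0.2, 0.8, len(ids))
        effect, se, p = ewas.fit_cpg(pd.Series(y, index=pd.Index(ids)), sheet, fractions)
        X = sm.add_constant(
            np.column_stack(
                [
                    (sheet.data["smoking_type"] == "current").astype(float),
                    sheet.data["age"],
                    fractions.immune_proportion.to_numpy(),
                ]
            )
        )
        fit = sm.OLS(y, X).fit()
        assert effect == pytest.approx(fit.params[1], abs=1e-10)
        assert se == pytest.approx(fit.bse[1], abs=1e-10)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_noiseless_effect_recovered_exactly(self):
        """Closed-form: when beta is an exact linear function of the design,
        OLS returns the constructed coefficients."""
        ids, sheet, fractions = _cohort(seed=4)
        cur = (sheet.data["smoking_type"] == "current").to_numpy(float)
        y = 0.6 - 0.15 * cur + 0.001 * sheet.data["age"].to_numpy() \
            - 0.2 * fractions.immune_proportion.to_numpy()
        effect, se, p = ewas.fit_cpg(pd.Series(y, index=pd.Index(ids)), sheet, fractions)
        assert effect == pytest.approx(-0.15, abs=1e-10)

    def test_orthogonal_noise_covariate_leaves_effect_unchanged(self):
        ids, sheet, fractions = _cohort(seed=5)
        rng = np.random.default_rng(6)
        y = rng.uniform(0.3, 0.7, len(ids))
        base_effect, _, _ = ewas.fit_cpg(pd.Series(y, index=pd.Index(ids)), sheet, fractions)
        X = np.column_stack(
            [
                np.ones(len(ids)),
                (sheet.data["smoking_type"] == "current").astype(float),
                sheet.data["age"],
                fractions.immune_proportion.to_numpy(),
            ]
        )
        noise = rng.normal(size=len(ids))
        # orthogonalize against the design so the estimate cannot move
        ortho = noise - X @ np.linalg.lstsq(X, noise, rcond=None)[0]
        extra = pd.DataFrame({"noise": ortho}, index=pd.Index(ids))
        effect, _, _ = ewas.fit_cpg(
            pd.Series(y, index=pd.Index(ids)), sheet, fractions, extra_covariates=extra
        )
        assert effect == pytest.approx(base_effect, abs=1e-10)

    def test_collinear_covariates_error_names_the_pair(self):
        ids, sheet, fractions = _cohort(seed=7)
        extra = pd.DataFrame(
            {"age_copy": sheet.data["age"].to_numpy()}, index=pd.Index(ids)
        )
        y = pd.Series(np.linspace(0.2, 0.8, len(ids)), index=pd.Index(ids))
        with pytest.raises(ewas.EwasError, match="age"):
            ewas.fit_cpg(y, sheet, fractions, extra_covariates=extra)

    def test_too_few_samples_per_group_rejected(self):
        ids, sheet, fractions = _cohort(n_never=5, n_current=40, seed=8)
        y = pd.Series(0.5, index=pd.Index(ids))
        with pytest.raises(ewas.EwasError, match=">= 10"):
            ewas.fit_cpg(y, sheet, fractions)

    def test_strong_immune_effect_in_blood_is_genomewide_significant(self):
        """Power check: an immune_hypoM CpG with effect -0.15 at n=400 clears
        the study's strictest genome-wide threshold in >= 99/100 replicates."""
        hits = 0
        for rep in range(100):
            cfg = SimConfig(
                n_cpgs=2,
                archetype_sizes={"immune_hypoM": 1, "null": 1},
                effect_size=0.15,
                n_samples={"blood": {"never": 200, "current": 200}},
                seed=1000 + rep,
            )
            truth = build_truth(cfg)
            beta, sheet, fractions = simulate_dataset(truth, cfg)["blood"]
            row = beta.data.iloc[0]
            _, _, p = ewas.fit_cpg(
                row, sheet, fractions, composition_covariate="lymphoid_proportion"
            )
            hits += p < 7.9e-8
        assert hits >= 99


class TestRunEwas:
    def test_vectorised_run_matches_per_row_fits(self, small_dataset):
        beta, sheet, fractions = small_dataset["cervical"]
        res = ewas.run_ewas(beta, sheet, fractions, "cervical", min_per_group=10)
        for cpg in beta.cpg_ids[::25]:
            effect, se, p = ewas.fit_cpg(beta.data.loc[cpg], sheet, fractions)
            assert res.table.loc[cpg, "effect"] == pytest.approx(effect, abs=1e-10)
            assert res.table.loc[cpg, "p"] == pytest.approx(p, abs=1e-10)

    def test_missing_betas_use_complete_cases(self, small_dataset):
        beta, sheet, fractions = small_dataset["buccal"]
        data = beta.data.copy()
        data.iloc[0, :5] = np.nan
        res = ewas.run_ewas(BetaMatrix(data), sheet, fractions, "buccal")
        assert res.table.iloc[0]["n"] == data.shape[1] - 5
        assert res.table.iloc[1]["n"] == data.shape[1]

    def test_constant_row_flagged_with_p_one(self, small_dataset):
        beta, sheet, fractions = small_dataset["buccal"]
        data = beta.data.copy()
        data.iloc[3] = 0.5
        res = ewas.run_ewas(BetaMatrix(data), sheet, fractions, "buccal")
        row = res.table.iloc[3]
        assert row["flag"] == "constant" and row["p"] == 1.0 and row["effect"] == 0.0

    def test_ex_smokers_excluded_from_discovery(self):
        cfg = small_config(
            seed=11,
            n_samples={"buccal": {"never": 30, "current": 30, "ex": 30}},
        )
        truth = build_truth(cfg)
        beta, sheet, fractions = simulate_dataset(truth, cfg)["buccal"]
        res = ewas.run_ewas(beta, sheet, fractions, "buccal")
        assert (res.table["n"] == 60).all()

    def test_null_simulation_type_one_error_and_inflation(self):
        cfg = SimConfig(
            n_cpgs=2000,
            archetype_sizes={"null": 2000},
            n_samples={"cervical": {"never": 100, "current": 100}},
            seed=21,
        )
        truth = build_truth(cfg)
        beta, sheet, fractions = simulate_dataset(truth, cfg)["cervical"]
        res = ewas.run_ewas(beta, sheet, fractions, "cervical")
        rate = (res.table["p"] < 0.05).mean()
        assert 0.05 - 0.015 < rate < 0.05 + 0.015
        assert 0.9 < res.lambda_gc < 1.1
        assert len(res.significant(0.05)) == 0


class TestHolm:
    def test_two_value_worked_example(self):
        np.testing.assert_allclose(ewas.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ewas.holm_adjust([0.3]), [0.3])

    def test_smallest_rejection_threshold_is_alpha_over_m(self):
        """The step-down start: only p < alpha/m can ever be rejected first.

        (With m tests at alpha=0.05 this is the genome-wide threshold the
        study quotes, e.g. 0.05/m ~ 7.9e-8 for m ~ 633k blood/buccal CpGs.)"""
        m = 100
        eps = 1e-12
        just_below = np.full(m, 0.5)
        just_below[0] = 0.05 / m - eps
        assert ewas.holm_adjust(just_below)[0] < 0.05
        just_above = np.full(m, 0.5)
        just_above[0] = 0.05 / m + 1e-6
        assert ewas.holm_adjust(just_above)[0] > 0.05

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, pvals):
        np.testing.assert_allclose(
            ewas.holm_adjust(pvals), holm_brute_force(pvals), atol=1e-12
        )

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = ewas.holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_nan_rejected(self):
        with pytest.raises(ewas.EwasError, match="NaN"):
            ewas.holm_adjust([0.1, np.nan])


class TestSignificantSites:
    def _result(self, tissue, sig_cpgs, all_cpgs):
        table = pd.DataFrame(
            {
                "effect": 0.1,
                "se": 0.01,
                "p": 0.5,
                "p_holm": [0.001 if c in sig_cpgs else 1.0 for c in all_cpgs],
                "n": 100,
                "flag": "",
            },
            index=pd.Index(all_cpgs, name="cpg_id"),
        )
        return ewas.EwasResult(table=table, tissue=tissue)

    def test_union_across_tissues(self):
        cpgs = ["cg1", "cg2", "cg3"]
        res = [
            self._result("buccal", {"cg1"}, cpgs),
            self._result("blood", {"cg2"}, cpgs),
        ]
        assert ewas.significant_sites(res) == ["cg1", "cg2"]

    def test_sex_chromosome_sites_dropped_with_annotation(self):
        cpgs = ["cg1", "cg2"]
        res = [self._result("buccal", {"cg1", "cg2"}, cpgs)]
        ann = pd.Series({"cg1": "chrX", "cg2": "chr5"})
        assert ewas.significant_sites(res, annotation=ann) == ["cg2"]

    def test_unannotated_sites_retained_with_warning(self):
        cpgs = ["cg1", "cg2"]
        res = [self._result("buccal", {"cg1", "cg2"}, cpgs)]
        ann = pd.Series({"cg1": "chrY"})
        with pytest.warns(UserWarning, match="missing from annotation"):
            kept = ewas.significant_sites(res, annotation=ann)
        assert kept == ["cg2"]
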
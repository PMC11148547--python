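import numpy as np
import pandas as pd
import pytest

from smokesig import cell_specific as cs
from smokesig.simulate import TISSUES, build_truth, simulate_dataset
from conftest import small_config


def _two_group_lines(f_never, f_current, never_fn, current_fn):
    f = np.concatenate([f_never, f_current])
    y = np.concatenate([never_fn(f_never), current_fn(f_current)])
    groups = np.array(["never"] * len(f_never) + ["current"] * len(f_current))
    return y, f, groups


F30 = np.linspace(0.05, 0.85, 30)


class TestFitGroupLines:
    def test_exact_line_recovered(self):
        y, f, g = _two_group_lines(F30, F30, lambda x: 0.8 - 0.2 * x, lambda x: 0.8 - 0.2 * x)
        lines = cs.fit_group_lines(y, f, g)
        assert lines["never"].intercept == pytest.approx(0.8, abs=1e-12)
        assert lines["never"].slope == pytest.approx(-0.2, abs=1e-12)
        assert lines["never"].resid_sd == pytest.approx(0.0, abs=1e-9)

    def test_constant_composition_rejected(self):
        y, f, g = _two_group_lines(
            np.full(30, 0.4), F30, lambda x: x, lambda x: x
        )
        with pytest.raises(cs.ExtrapolationError, match="too narrow"):
            cs.fit_group_lines(y, f, g)

    def test_small_group_rejected(self):
        y, f, g = _two_group_lines(F30[:5], F30, lambda x: x, lambda x: x)
        with pytest.raises(cs.ExtrapolationError, match="usable samples"):
            cs.fit_group_lines(y, f, g)

    def test_noisy_intercept_within_three_se_of_truth(self):
        rng = np.random.default_rng(12)
        f = rng.beta(3, 4, 300)
        y = 0.7 - 0.3 * f + rng.normal(0, 0.03, 300)
        lines = cs.fit_group_lines(y, f, np.repeat("never", 300))
        line = lines["never"]
        assert abs(line.intercept - 0.7) < 3 * line.se_at0


class TestDeltaBeta:
    def test_closed_form_worked_example(self):
        """never 0.8 - 0.2 f vs current 0.5 + 0.1 f: epithelial delta -0.30,
        immune delta (0.5+0.1) - (0.8-0.2) = 0.00."""
        y, f, g = _two_group_lines(F30, F30, lambda x: 0.8 - 0.2 * x, lambda x: 0.5 + 0.1 * x)
        assert cs.delta_beta(y, f, g, at=0) == pytest.approx(-0.3, abs=1e-12)
        assert cs.delta_beta(y, f, g, at=1) == pytest.approx(0.0, abs=1e-12)

    def test_identical_groups_give_zero_at_both_ends(self):
        rng = np.random.default_rng(1)
        y0 = 0.6 - 0.1 * F30 + rng.normal(0, 0.01, 30)
        y, f, g = _two_group_lines(F30, F30, lambda x: y0, lambda x: y0)
        assert cs.delta_beta(y, f, g, at=0) == pytest.approx(0.0, abs=1e-12)
        assert cs.delta_beta(y, f, g, at=1) == pytest.approx(0.0, abs=1e-12)

    def test_swapping_group_labels_negates_delta(self):
        rng = np.random.default_rng(2)
        y, f, g = _two_group_lines(
            F30,
            F30,
            lambda x: 0.7 - 0.2 * x + rng.normal(0, 0.02, len(x)),
            lambda x: 0.55 - 0.1 * x + rng.normal(0, 0.02, len(x)),
        )
        for at in (0, 1):
            d = cs.delta_beta(y, f, g, at=at)
            d_swapped = cs.delta_beta(y, f, g, at=at, case="never", control="current")
            assert d_swapped == pytest.approx(-d, abs=1e-12)

    def test_matches_independent_polyfit_oracle(self):
        rng = np.random.default_rng(3)
        y, f, g = _two_group_lines(
            rng.beta(2, 5, 40),
            rng.beta(2, 5, 40),
            lambda x: 0.75 - 0.25 * x + rng.normal(0, 0.03, len(x)),
            lambda x: 0.55 - 0.05 * x + rng.normal(0, 0.03, len(x)),
        )
        lines = {
            grp: np.polyfit(f[g == grp], y[g == grp], 1) for grp in ("never", "current")
        }
        for at in (0.0, 1.0):
            expected = np.polyval(lines["current"], at) - np.polyval(lines["never"], at)
            assert cs.delta_beta(y, f, g, at=at, spread_min=0.1) == pytest.approx(
                expected, abs=1e-10
            )

    def test_simulated_epithelial_effect_recovered_at_both_intercepts(self):
        cfg = small_config(seed=13, n_samples={t: {"never": 150, "current": 150} for t in TISSUES})
        truth = build_truth(cfg)
        beta, sheet, fractions = simulate_dataset(truth, cfg)["buccal"]
        hit = truth.archetype[truth.archetype == "epithelial_hypoM"].index[0]
        y = beta.data.loc[hit].to_numpy()
        f = fractions.data["immune"].to_numpy()
        g = sheet.data["smoking_type"].to_numpy()
        assert cs.delta_beta(y, f, g, at=0) == pytest.approx(-0.2, abs=0.03)
        assert cs.delta_beta(y, f, g, at=1) == pytest.approx(0.0, abs=0.05)


class TestBuildDeltaMatrix:
    def test_vectorised_matrix_matches_scalar_delta_beta(self, small_dataset):
        datasets = {t: small_dataset[t] for t in TISSUES}
        cpgs = list(datasets["buccal"][0].cpg_ids[:10])
        profile = cs.build_delta_matrix(datasets, cpgs, min_n=20, spread_min=0.1)
        beta, sheet, fractions = datasets["cervical"]
        for cpg in cpgs[:3]:
            d0 = cs.delta_beta(
                beta.data.loc[cpg].to_numpy(),
                fractions.data["immune"].to_numpy(),
                sheet.data["smoking_type"].to_numpy(),
                at=0,
                spread_min=0.1,
            )
            assert profile.values.loc[cpg, "epithelial_cervical"] == pytest.approx(d0, abs=1e-10)

    def test_blood_only_fills_lineage_columns_and_flags_rest(self, small_dataset):
        datasets = {"blood": small_dataset["blood"]}
        cpgs = list(small_dataset["blood"][0].cpg_ids[:5])
        profile = cs.build_delta_matrix(datasets, cpgs, spread_min=0.1)
        assert profile.values[["lymphoid_blood", "myeloid_blood"]].notna().all().all()
        assert (
            profile.values[
                ["epithelial_buccal", "immune_buccal", "epithelial_cervical", "immune_cervical"]
            ]
            .isna()
            .all()
            .all()
        )

    def test_sign_pattern_of_effect_cpgs_matches_archetype(self, default_truth, default_dataset):
        """The dominant component of each estimated profile carries the
        archetype's sign in nearly every non-null row."""
        datasets = {t: default_dataset[t] for t in TISSUES}
        nonnull = default_truth.archetype[default_truth.archetype != "null"].index
        profile = cs.build_delta_matrix(datasets, list(nonnull))
        true_mat = default_truth.delta_matrix().loc[nonnull]
        est = profile.values
        dominant = est.abs().to_numpy().argmax(axis=1)
        est_sign = np.sign(est.to_numpy()[np.arange(len(est)), dominant])
        true_sign = np.sign(true_mat.to_numpy()[np.arange(len(est)), dominant])
        assert (est_sign == true_sign).mean() >= 0.95

    def test_rmse_decreases_with_sample_size_and_meets_bound(self):
        """Parameter recovery across effect sizes: RMSE shrinks from n=100 to
        n=300 per tissue and is within 0.03 at n=300."""
        rmses = {}
        for n in (100, 300):
            cfg = small_config(
                seed=17,
                effect_size=0.1,
                n_samples={t: {"never": n // 2, "current": n // 2} for t in TISSUES},
            )
            truth = build_truth(cfg)
            data = simulate_dataset(truth, cfg)
            profile = cs.build_delta_matrix(
                {t: data[t] for t in TISSUES}, list(truth.cpg_ids)
            )
            err = profile.values - truth.delta_matrix()
            rmses[n] = float(np.sqrt((err**2).to_numpy().mean()))
        assert rmses[300] < rmses[100]
        assert rmses[300] <= 0.03

    def test_empty_cpg_list_rejected(self, small_dataset):
        with pytest.raises(cs.ExtrapolationError, match="empty"):
            cs.build_delta_matrix({"blood": small_dataset["blood"]}, [])


def test_roundtrip_clips_reported_values(tmp_path):
    idx = pd.Index(["cg1"], name="cpg_id")
    values = pd.DataFrame(
        [[-1.5, 0.2, 0.0, 0.0, np.nan, np.nan]], index=idx, columns=list(cs.DELTA_COLUMNS)
    )
    se = pd.DataFrame(
        [[0.1] * 6], index=idx, columns=list(cs.DELTA_COLUMNS)
    )
    profile = cs.DeltaBetaProfile(values=values, se=se)
    path = tmp_path / "delta.tsv"
    cs.write_delta_matrix(profile, path)
    back = cs.read_delta_matrix(path)
    assert back.values.loc["cg1", "epithelial_buccal"] == -1.0  # clipped on write
    assert profile.values.loc["cg1", "epithelial_buccal"] == -1.5  # retained in memory
    assert np.isnan(back.values.loc["cg1", "lymphoid_blood"])
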
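"""MMRM estimation, sensitivity ANCOVA, subgroup models, correlation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from csu_trial.efficacy_models import (
    ancova_with_imputation,
    build_longitudinal_dataset,
    correlate_biomarker_response,
    estimate_contrasts,
    fit_mmrm,
    fit_subgroup_mmrm,
    ls_means,
)


def simulate_long(
    rng,
    n_per_arm=60,
    effects=(0.0, -9.5),
    weeks=(1, 2, 3),
    sd=10.0,
    rho=0.6,
    countries=("X",),
    stratum_shift=None,
    stratum_p=0.5,
    include_stratum=None,
):
    """Multivariate-normal longitudinal data with compound-symmetric errors.

    ``effects`` are per-arm means at the last week, reached linearly over
    weeks.  Optional ``stratum_shift`` adds a per-arm extra effect for a
    binary stratum.  Returns rows compatible with fit_mmrm.
    """
    if include_stratum is None:
        include_stratum = stratum_shift is not None
    T = len(weeks)
    Sig = sd**2 * ((1 - rho) * np.eye(T) + rho * np.ones((T, T)))
    L = np.linalg.cholesky(Sig)
    frac = np.arange(1, T + 1) / T
    rows = []
    for a, eff in enumerate(effects):
        for i in range(n_per_arm):
            strat = bool(rng.random() < stratum_p)
            shift = stratum_shift[a] if (stratum_shift and strat) else 0.0
            mu = (eff + shift) * frac
            y = mu + L @ rng.standard_normal(T)
            country = countries[i % len(countries)]
            for t, w in enumerate(weeks):
                row = {"patient_id": f"a{a}p{i}", "arm": f"arm{a}",
                       "country": country, "week": w, "value": y[t]}
                if include_stratum:
                    row["stratum"] = "pos" if strat else "neg"
                rows.append(row)
    return pd.DataFrame(rows)


class TestMmrm:
    def test_single_visit_complete_data_equals_ols(self):
        """With one post-baseline visit, complete data and one country, the
        MMRM LS-mean difference equals the raw arm-mean difference."""
        rng = np.random.default_rng(0)
        d = simulate_long(rng, n_per_arm=25, weeks=(8,))
        fit = fit_mmrm(d, reference_arm="arm0", dof_method="residual")
        c = estimate_contrasts(fit, 8)[0]
        raw = (
            d.loc[d["arm"] == "arm1", "value"].mean()
            - d.loc[d["arm"] == "arm0", "value"].mean()
        )
        assert c.estimate == pytest.approx(raw, abs=1e-8)

    def test_contrast_recovery_with_missingness(self):
        """Mean estimated week-3 contrast over replicates recovers the true
        -9.5 within Monte Carlo error, with MAR missingness present."""
        rng = np.random.default_rng(1)
        ests = []
        for _ in range(40):
            d = simulate_long(rng, n_per_arm=50, effects=(0.0, -9.5))
            # drop ~20% of final visits at random (MCAR is MAR)
            last = d["week"] == 3
            drop = last & (rng.random(len(d)) < 0.2)
            d = d[~drop]
            fit = fit_mmrm(d, reference_arm="arm0", dof_method="residual")
            ests.append(estimate_contrasts(fit, 3)[0].estimate)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(-9.5, abs=3 * se + 0.2)

    def test_loglik_history_monotone(self):
        rng = np.random.default_rng(2)
        d = simulate_long(rng, n_per_arm=40)
        fit = fit_mmrm(d, reference_arm="arm0")
        hist = np.array(fit.loglik_history)
        assert np.all(np.diff(hist) >= -1e-6)

    def test_covariance_symmetric_psd(self):
        rng = np.random.default_rng(3)
        d = simulate_long(rng, n_per_arm=40)
        fit = fit_mmrm(d, reference_arm="arm0")
        S = fit.sigma.to_numpy()
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() > 0

    def test_country_adjustment_and_contrast_sign(self):
        rng = np.random.default_rng(4)
        d = simulate_long(
            rng, n_per_arm=80, effects=(0.0, -9.5), countries=("X", "Y", "Z")
        )
        fit = fit_mmrm(d, reference_arm="arm0", dof_method="residual")
        assert set(fit.countries) == {"X", "Y", "Z"}
        c = estimate_contrasts(fit, 3)[0]
        assert c.estimate < 0 and c.lower <= c.estimate <= c.upper

    def test_identical_arms_contrast_covers_zero(self):
        rng = np.random.default_rng(5)
        d = simulate_long(rng, n_per_arm=300, effects=(0.0, 0.0))
        fit = fit_mmrm(d, reference_arm="arm0", dof_method="residual")
        c = estimate_contrasts(fit, 3)[0]
        assert abs(c.estimate) < 2.5 * c.se
        assert c.lower < 0 < c.upper

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(6)
        ses = {}
        for n in (50, 800):
            d = simulate_long(rng, n_per_arm=n, weeks=(1, 2))
            fit = fit_mmrm(d, reference_arm="arm0", dof_method="residual")
            ses[n] = estimate_contrasts(fit, 2)[0].se
        assert ses[800] < ses[50]
        assert ses[50] / ses[800] == pytest.approx(4.0, rel=0.3)

    def test_visit_not_in_model_rejected(self):
        rng = np.random.default_rng(7)
        d = simulate_long(rng, n_per_arm=20)
        fit = fit_mmrm(d, reference_arm="arm0")
        with pytest.raises(ValueError, match="not in the fitted model"):
            estimate_contrasts(fit, 99)

    def test_empty_cell_design_rejected(self):
        rng = np.random.default_rng(8)
        d = simulate_long(rng, n_per_arm=20)
        d = d[~((d["arm"] == "arm1") & (d["week"] == 3))]
        with pytest.raises(ValueError, match="singular|cell"):
            fit_mmrm(d, reference_arm="arm0")

    def test_satterthwaite_dof_reasonable(self):
        """Satterthwaite dof for a between-arm contrast on complete data is
        close to the between-subject count n - #arms."""
        rng = np.random.default_rng(9)
        d = simulate_long(rng, n_per_arm=30, weeks=(1, 2))
        fit = fit_mmrm(d, reference_arm="arm0")
        c = estimate_contrasts(fit, 2, dof_method="satterthwaite")[0]
        assert 0.6 * 58 < c.dof < 1.4 * 58
        assert c.dof_method == "satterthwaite"

    def test_mar_dropout_mmrm_less_biased_than_complete_case(self):
        """When dropout depends on the previous visit's outcome (MAR), the
        MMRM final-visit contrast stays unbiased while the complete-case
        cross-sectional difference does not."""
        rng = np.random.default_rng(10)
        true = -8.0
        mmrm_est, cc_est = [], []
        for _ in range(60):
            d = simulate_long(
                rng, n_per_arm=60, effects=(0.0, true), weeks=(1, 2), rho=0.8
            )
            wide = d.pivot_table(index=["patient_id", "arm"], columns="week",
                                 values="value").reset_index()
            # worse (higher) week-1 outcomes drop before week 2
            p_drop = 0.85 * (wide[1] > wide[1].median())
            lost = rng.random(len(wide)) < p_drop
            keep_ids = set(wide.loc[~lost, "patient_id"])
            d2 = d[(d["week"] == 1) | d["patient_id"].isin(keep_ids)]
            fit = fit_mmrm(d2, reference_arm="arm0", dof_method="residual")
            mmrm_est.append(estimate_contrasts(fit, 2)[0].estimate)
            cc = wide[~lost]
            cc_est.append(
                cc.loc[cc["arm"] == "arm1", 2].mean()
                - cc.loc[cc["arm"] == "arm0", 2].mean()
            )
        assert abs(np.mean(mmrm_est) - true) < abs(np.mean(cc_est) - true)


class TestAncovaImputation:
    def _changes(self, series):
        rows = []
        for pid, vals in series.items():
            rows.append({"patient_id": pid, "week": 0, "uas7_change": 0.0,
                         "valid": True})
            for w, v in enumerate(vals, start=1):
                rows.append({"patient_id": pid, "week": w,
                             "uas7_change": v, "valid": v is not None})
        df = pd.DataFrame(rows)
        df["uas7_change"] = df["uas7_change"].astype(float)
        return df

    def _profiles(self, pids, arms):
        return pd.DataFrame(
            {"patient_id": pids, "arm": arms, "country": "X"}
        )

    def test_no_missing_locf_bocf_match_complete_case(self):
        rng = np.random.default_rng(11)
        pids = [f"P{i}" for i in range(40)]
        arms = ["placebo"] * 20 + ["active"] * 20
        series = {
            p: list(rng.normal(-5 if a == "placebo" else -12, 3, 8))
            for p, a in zip(pids, arms)
        }
        changes = self._changes(series)
        prof = self._profiles(pids, arms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            locf = ancova_with_imputation(changes, prof, "locf", reference_arm="placebo")
            bocf = ancova_with_imputation(changes, prof, "bocf", reference_arm="placebo")
        assert locf[0].estimate == pytest.approx(bocf[0].estimate, abs=1e-10)

    @pytest.mark.parametrize(
        "vals,locf_val,bocf_val",
        [
            ([-5.0, -12.0, None], -12.0, -12.0),  # last also best
            ([-12.0, -5.0, None], -5.0, -12.0),   # last vs most-negative
        ],
    )
    def test_imputation_rules(self, vals, locf_val, bocf_val):
        from csu_trial.efficacy_models import _impute_week8

        series = {"P1": vals + [None] * 5}
        changes = self._changes(series)
        locf = _impute_week8(changes, "locf")
        bocf = _impute_week8(changes, "bocf")
        assert locf["value"].iloc[0] == locf_val
        assert bocf["value"].iloc[0] == bocf_val

    def test_patient_without_postbaseline_excluded(self):
        from csu_trial.efficacy_models import _impute_week8

        changes = self._changes({"P1": [None] * 8, "P2": [-3.0] * 8})
        imp = _impute_week8(changes, "locf")
        assert list(imp["patient_id"]) == ["P2"]


class TestSubgroupMmrm:
    def test_collapsed_indicator_matches_plain_fit(self):
        rng = np.random.default_rng(12)
        d = simulate_long(rng, n_per_arm=30)
        d_one = d.assign(stratum="pos")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = fit_mmrm(d, reference_arm="arm0", dof_method="residual")
            sub = fit_subgroup_mmrm(d_one, reference_arm="arm0",
                                    dof_method="residual")
        c0 = estimate_contrasts(plain, 3)[0]
        c1 = estimate_contrasts(sub, 3)[0]
        assert c1.estimate == pytest.approx(c0.estimate, abs=1e-8)

    def test_stratum_specific_shift_recovered(self):
        """A -5-point extra effect in the marker-positive stratum shows up as
        the difference between the stratum contrasts."""
        rng = np.random.default_rng(13)
        diffs = []
        for _ in range(20):
            d = simulate_long(
                rng, n_per_arm=120, effects=(0.0, -6.0),
                stratum_shift=(0.0, -5.0),
            )
            fit = fit_subgroup_mmrm(d, reference_arm="arm0", dof_method="residual")
            cons = {c.label: c.estimate for c in estimate_contrasts(fit, 3)}
            pos = [v for k, v in cons.items() if "[pos]" in k][0]
            neg = [v for k, v in cons.items() if "[neg]" in k][0]
            diffs.append(pos - neg)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert np.mean(diffs) == pytest.approx(-5.0, abs=3 * se + 0.3)

    def test_no_shift_strata_agree(self):
        rng = np.random.default_rng(14)
        d = simulate_long(rng, n_per_arm=400, effects=(0.0, -6.0), include_stratum=True)
        fit = fit_subgroup_mmrm(d, reference_arm="arm0", dof_method="residual")
        cons = estimate_contrasts(fit, 3)
        ests = [c.estimate for c in cons]
        assert abs(ests[0] - ests[1]) < 3.0  # Monte Carlo agreement


class TestSpearman:
    def test_perfectly_monotone(self):
        rho, n = correlate_biomarker_response([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = correlate_biomarker_response([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_tied_pairs_match_hand_ranking(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        # hand-assigned average ranks for x (tie at 2.0 -> ranks 2.5, 2.5)
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0, 6.0])
        ry = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, n = correlate_biomarker_response(x, y)
        assert n == 6
        assert rho == pytest.approx(expected)

    def test_too_few_pairs_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            rho, n = correlate_biomarker_response([1, 2], [3, 4])
        assert np.isnan(rho) and n == 2


class TestBuildDataset:
    def test_patients_without_postbaseline_rows_absent(self, small_cohort):
        from csu_trial import endpoints as ep

        weekly = ep.derive_weekly_scores(small_cohort.diary, max_week=8)
        changes, _ = ep.change_from_baseline(weekly)
        data = build_longitudinal_dataset(changes, small_cohort.profiles)
        assert set(data.columns) >= {"patient_id", "arm", "country", "week", "value"}
        assert data["week"].between(1, 8).all()
        assert data["value"].notna().all()
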
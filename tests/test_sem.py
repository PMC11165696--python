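import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutsem import (
    MeasurementModel,
    NoFeasibleModelError,
    PruningCriteria,
    SemModel,
    SemSpec,
    build_moment_vector,
    fit_sem_dwls,
    generate_from_sem,
    polyserial_corr,
    prune_model,
)


def sem_dataset(lam=(0.8, 0.7, 0.6), gamma=0.55, n=2000, seed=0, threshold=0.0):
    lam = np.asarray(lam)
    x, y, xi = generate_from_sem(lam, gamma, 1 - lam**2, threshold, n, seed=seed)
    data = x.copy()
    data["depression"] = y
    return data, xi


class TestPolyserial:
    def test_independent_variables_give_near_zero(self, rng):
        x = rng.normal(size=5000)
        y = (rng.normal(size=5000) > 0.8).astype(int)
        rho, var = polyserial_corr(x, y)
        assert abs(rho) < 0.05
        assert var > 0

    def test_recovers_latent_correlation(self, rng):
        n = 5000
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n)
        rho, _ = polyserial_corr(z[:, 0], (z[:, 1] > 0).astype(int))
        assert rho == pytest.approx(0.6, abs=0.05)

    def test_median_split_stays_finite_near_clip(self, rng):
        x = rng.normal(size=500)
        y = (x > np.median(x)).astype(int)
        rho, var = polyserial_corr(x, y)
        assert np.isfinite(rho) and abs(rho) <= 0.999
        assert rho > 0.9

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            polyserial_corr(rng.normal(size=100), np.zeros(100))


class TestMomentVector:
    def test_pair_count_and_order(self):
        data, _ = sem_dataset(n=200, seed=1)
        s, w, n, pairs = build_moment_vector(data)
        assert len(s) == 6  # p* = 4 observed variables
        assert pairs[-1][1] == "depression"
        assert (w > 0).all()

    def test_matches_independent_pairwise_computation(self):
        data, _ = sem_dataset(n=500, seed=2)
        s, _, _, pairs = build_moment_vector(data)
        y = data["depression"].to_numpy()
        p = y.mean()
        tau = stats.norm.ppf(1 - p)
        for value, (a, b) in zip(s, pairs):
            if b == "depression":
                expected = (
                    np.corrcoef(data[a], y)[0, 1] * np.sqrt(p * (1 - p)) / stats.norm.pdf(tau)
                )
            else:
                expected = np.corrcoef(data[a], data[b])[0, 1]
            assert value == pytest.approx(np.clip(expected, -0.999, 0.999), abs=1e-9)

    def test_duplicated_column_detected(self):
        data, _ = sem_dataset(n=200, seed=3)
        data["Genus_001"] = data["Genus_000"]
        with pytest.raises(ValueError, match="duplicates"):
            build_moment_vector(data)

    def test_constant_column_named_in_error(self):
        data, _ = sem_dataset(n=200, seed=4)
        data["Genus_002"] = 1.0
        with pytest.raises(ValueError, match="Genus_002"):
            build_moment_vector(data)


class TestFitSemDwls:
    def test_df_counting_for_three_indicator_model(self):
        data, _ = sem_dataset(n=200, seed=5)
        spec = SemSpec(latents={"lv1": ["Genus_000", "Genus_001", "Genus_002"]})
        assert SemModel(data, spec).df_model == 2

    def test_parameter_recovery_light(self):
        errs = []
        for seed in range(5):
            data, _ = sem_dataset(seed=seed)
            spec = SemSpec(latents={"lv1": ["Genus_000", "Genus_001", "Genus_002"]})
            fit = fit_sem_dwls(spec, data)
            est = np.r_[fit.loadings.to_numpy(), fit.path_coefficients_raw["lv1"]]
            errs.append(np.abs(est - np.r_[0.8, 0.7, 0.6, 0.55]))
        assert np.mean(errs, axis=0).max() < 0.1

    def test_near_population_data_has_perfect_fit_indices(self):
        data, _ = sem_dataset(n=20000, seed=6)
        spec = SemSpec(latents={"lv1": ["Genus_000", "Genus_001", "Genus_002"]})
        fit = fit_sem_dwls(spec, data)
        assert fit.gfi > 0.999
        assert fit.rmsea < 0.03
        assert fit.agfi <= fit.gfi

    def test_sign_indeterminacy_resolved_canonically(self):
        data, _ = sem_dataset(seed=7)
        flipped = data.copy()
        for c in ("Genus_000", "Genus_001", "Genus_002"):
            flipped[c] = -flipped[c]
        spec = SemSpec(latents={"lv1": ["Genus_000", "Genus_001", "Genus_002"]})
        a = fit_sem_dwls(spec, data)
        b = fit_sem_dwls(spec, flipped)
        # same discrepancy, same canonical form (largest-|lambda| positive)
        assert a.fmin == pytest.approx(b.fmin, abs=1e-8)
        assert a.loadings.abs().idxmax() == b.loadings.abs().idxmax()
        assert a.loadings.max() > 0 and b.loadings.max() > 0

    def test_blind_scores_and_implied_psd(self):
        data, xi = sem_dataset(seed=8)
        spec = SemSpec(latents={"lv1": ["Genus_000", "Genus_001", "Genus_002"]})
        fit = fit_sem_dwls(spec, data)
        meas = fit.measurement_submodel()
        with_outcome = meas.factor_scores(data)
        without = meas.factor_scores(data.drop(columns="depression"))
        assert np.array_equal(with_outcome.to_numpy(), without.to_numpy())
        assert np.corrcoef(without["lv1"], xi)[0, 1] > 0.85
        eigvals = np.linalg.eigvalsh(fit.implied_corr().to_numpy())
        assert eigvals.min() > -1e-8

    def test_saturated_direct_model_allowed(self):
        data, _ = sem_dataset(n=300, seed=9)
        spec = SemSpec(direct=["Genus_000"])
        fit = fit_sem_dwls(spec, data)
        assert fit.df == 0
        assert fit.gfi == pytest.approx(1.0, abs=1e-6)
        assert fit.rmsea == 0.0
        assert np.isnan(fit.agfi)

    def test_too_few_samples_rejected(self):
        data, _ = sem_dataset(n=2000, seed=10)
        spec = SemSpec(latents={"lv1": ["Genus_000", "Genus_001", "Genus_002"]})
        with pytest.raises(ValueError):
            SemModel(data.iloc[:4], spec).fit()


class TestSpec:
    def test_candidate_assignment_and_demotion(self):
        spec = SemSpec.from_candidates(["A", "B"], ["C"])
        assert spec.latents == {"lv1": ["A", "B"]}
        assert spec.direct == ["C"]  # singleton latent demoted

    def test_duplicate_indicator_rejected(self):
        with pytest.raises(ValueError):
            SemSpec(latents={"lv1": ["A", "B"], "lv2": ["B", "C"]})

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            SemSpec()


class TestMeasurementModel:
    def test_single_indicator_passthrough_limits(self):
        meas = MeasurementModel(
            latents={"lv1": {"taxa": ["A"], "loadings": [1.0],
                             "residual_variances": [1e-10]}},
            latent_corr=[[1.0]],
            direct=["B"],
            means={"A": 2.0, "B": 0.0},
            sds={"A": 0.5, "B": 1.0},
        )
        clr = pd.DataFrame({"A": [2.5, 2.0], "B": [1.0, -1.0]})
        scores = meas.factor_scores(clr)
        # lambda = 1, theta -> 0: score equals the z-scored indicator
        assert scores["lv1"].to_numpy() == pytest.approx([1.0, 0.0], abs=1e-6)
        assert scores["B"].to_numpy() == pytest.approx([1.0, -1.0])
        # z = 0 shrinks to the prior mean
        assert meas.factor_scores(pd.DataFrame({"A": [2.0], "B": [0.0]}))[
            "lv1"
        ].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_serialisation(self):
        data, _ = sem_dataset(seed=11)
        spec = SemSpec(latents={"lv1": ["Genus_000", "Genus_001", "Genus_002"]})
        meas = fit_sem_dwls(spec, data).measurement_submodel()
        back = MeasurementModel.from_dict(meas.to_dict())
        assert back == meas

    def test_missing_taxon_named(self):
        data, _ = sem_dataset(seed=12)
        spec = SemSpec(latents={"lv1": ["Genus_000", "Genus_001", "Genus_002"]})
        meas = fit_sem_dwls(spec, data).measurement_submodel()
        with pytest.raises(ValueError, match="Genus_002"):
            meas.factor_scores(data[["Genus_000", "Genus_001"]])

    def test_refit_on_indicators_reproduces_loadings(self):
        data, _ = sem_dataset(n=4000, seed=13)
        spec = SemSpec(latents={"lv1": ["Genus_000", "Genus_001", "Genus_002"]})
        fit = fit_sem_dwls(spec, data)
        # refit measurement part against a fresh outcome-free criterion:
        # factor-analyse the indicator correlations alone
        z = (data.iloc[:, :3] - data.iloc[:, :3].mean()) / data.iloc[:, :3].std(ddof=0)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        # one-factor loadings from pairwise correlations (triad formulas)
        l0 = np.sqrt(corr[0, 1] * corr[0, 2] / corr[1, 2])
        l1 = np.sqrt(corr[0, 1] * corr[1, 2] / corr[0, 2])
        l2 = np.sqrt(corr[0, 2] * corr[1, 2] / corr[0, 1])
        assert fit.loadings.to_numpy() == pytest.approx([l0, l1, l2], abs=0.05)


class TestPruning:
    def _candidate_data(self, seed=0, n=800, noise_taxa=3):
        lam = np.array([0.8, 0.7, 0.6])
        data, _ = sem_dataset(lam=lam, gamma=0.8, n=n, seed=seed, threshold=1.0)
        rng = np.random.default_rng(seed + 1000)
        for j in range(noise_taxa):
            data[f"Noise_{j}"] = rng.normal(size=n)
        cols = [c for c in data.columns if c != "depression"] + ["depression"]
        return data[cols]

    def test_noise_latent_pruned_away(self):
        data = self._candidate_data()
        more = ["Genus_000", "Genus_001", "Genus_002"]
        less = ["Noise_0", "Noise_1", "Noise_2"]
        spec, fit, trace = prune_model((more, less), data)
        kept = set(spec.observed)
        assert {"Genus_000", "Genus_001", "Genus_002"} & kept
        assert fit.gfi >= 0.90 and fit.rmsea <= 0.08
        assert len(trace) > 1
        # the dominant path should involve the signal latent, not pure noise
        assert fit.max_abs_path > 0.3

    def test_single_candidate_becomes_direct_path(self):
        data = self._candidate_data(seed=3)
        spec, fit, _ = prune_model((["Genus_000"], []), data)
        assert spec.latents == {} and spec.direct == ["Genus_000"]
        assert fit.df == 0

    def test_impossible_criteria_raise_with_best_fit(self):
        data = self._candidate_data(seed=4, n=300)
        crit = PruningCriteria(gfi_min=1.0, rmsea_max=0.0)
        with pytest.raises(NoFeasibleModelError):
            prune_model((["Genus_000", "Genus_001"], ["Noise_0", "Noise_1"]), data,
                        criteria=crit)

    def test_exhaustive_agrees_on_feasibility(self):
        data = self._candidate_data(seed=5)
        more = ["Genus_000", "Genus_001", "Genus_002"]
        spec_g, fit_g, _ = prune_model((more, ["Noise_0"]), data)
        spec_e, fit_e, _ = prune_model((more, ["Noise_0"]), data, exhaustive=True)
        assert fit_e.max_abs_path >= fit_g.max_abs_path - 0.05

    def test_pruning_never_adds_indicators_and_is_reproducible(self):
        data = self._candidate_data(seed=6)
        more = ["Genus_000", "Genus_001", "Genus_002"]
        less = ["Noise_0", "Noise_1"]
        spec1, fit1, trace1 = prune_model((more, less), data)
        spec2, fit2, trace2 = prune_model((more, less), data)
        assert spec1.to_dict() == spec2.to_dict()
        assert trace1 == trace2
        assert len(spec1.observed) <= len(more) + len(less)
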
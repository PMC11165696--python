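"""Confirmatory SEM with a binary outcome, estimated by DWLS.

The structural model assumed by the pipeline: latent community factors
("positive-effect" lv1 and "negative-effect" lv2) underlie correlated
CLR-transformed genus abundances (indicators), and drive a probit-thresholded
latent liability y* whose sign determines the observed depression label.
Single-indicator latents are demoted to directly observed predictors wired
straight to the outcome.

Estimation is two-step categorical-SEM practice on the correlation metric:

1. Build the mixed sample moment vector s — Pearson correlations among the
   z-scored indicators and two-step polyserial correlations between each
   indicator and the binary outcome — with delta-method asymptotic variances w.
2. Minimise the diagonally weighted least-squares discrepancy
   F(theta) = sum_k (s_k - sigma_k(theta))^2 / w_k over loadings, structural
   paths and exogenous covariances.

Identification: latent variances are fixed at 1 and the indicators are
z-scored, so loadings are standardized and residual variances are derived as
theta_j = 1 - lambda_j^2. The structural disturbance of y* has unit variance
and paths are estimated on that raw scale (so simulation parameters are
recovered directly); standardized paths — the quantities displayed in path
diagrams and used as the pruning objective — divide by the implied SD of y*.
Fit is summarised by chi^2 = (n-1) F_min, GFI, AGFI and RMSEA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_EPS_RHO = 0.999
_W_FLOOR = 1e-6
_LAMBDA_BOUND = 0.995
_COV_BOUND = 0.99
_PATH_BOUND = 3.0


class ConvergenceError(RuntimeError):
    """DWLS optimisation failed to converge."""


class NoFeasibleModelError(RuntimeError):
    """Backward pruning found no model meeting the fit criteria."""

    def __init__(self, message: str, best_fit: "SemResults | None" = None):
        super().__init__(message)
        self.best_fit = best_fit


# ---------------------------------------------------------------------------
# model specification


@dataclass
class SemSpec:
    """Which taxa load on which latent, and which act as direct predictors.

    ``latents`` maps latent name -> ordered indicator taxa (each with >= 2
    indicators); ``direct`` lists observed predictors wired straight to the
    outcome. Use :meth:`from_candidates` to build the canonical two-latent
    starting model from effect-size screening lists (singleton latents are
    demoted to direct predictors automatically).
    """

    latents: dict[str, list[str]] = field(default_factory=dict)
    direct: list[str] = field(default_factory=list)
    outcome: str = "depression"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, taxa in self.latents.items():
            if len(taxa) < 2:
                raise ValueError(
                    f"latent {name!r} has {len(taxa)} indicator(s); "
                    "demote single indicators to direct predictors"
                )
            for t in taxa:
                if t in seen:
                    raise ValueError(f"indicator {t!r} appears twice")
                seen.add(t)
        for t in self.direct:
            if t in seen:
                raise ValueError(f"{t!r} is both an indicator and a direct predictor")
            seen.add(t)
        if not seen:
            raise ValueError("model has no predictors")

    @classmethod
    def from_candidates(
        cls,
        more: list[str],
        less: list[str],
        outcome: str = "depression",
        lv_more: str = "lv1",
        lv_less: str = "lv2",
    ) -> "SemSpec":
        """Initial model: more-abundant taxa on lv1, less-abundant on lv2."""
        latents: dict[str, list[str]] = {}
        direct: list[str] = []
        for name, taxa in ((lv_more, list(more)), (lv_less, list(less))):
            if len(taxa) >= 2:
                latents[name] = taxa
            elif len(taxa) == 1:
                direct.append(taxa[0])
        return cls(latents=latents, direct=direct, outcome=outcome)

    @property
    def observed(self) -> list[str]:
        """All observed predictor variables, indicators first."""
        out: list[str] = []
        for taxa in self.latents.values():
            out.extend(taxa)
        out.extend(self.direct)
        return out

    @property
    def n_free_params(self) -> int:
        n_lam = sum(len(t) for t in self.latents.values())
        n_lat = len(self.latents)
        n_dir = len(self.direct)
        n_psi = n_lat * (n_lat - 1) // 2
        n_phi = n_dir * n_lat
        n_phidd = n_dir * (n_dir - 1) // 2
        return n_lam + n_lat + n_dir + n_psi + n_phi + n_phidd

    def to_dict(self) -> dict:
        return {
            "latents": {k: list(v) for k, v in self.latents.items()},
            "direct": list(self.direct),
            "outcome": self.outcome,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SemSpec":
        return cls(latents=d["latents"], direct=d["direct"], outcome=d["outcome"])


# ---------------------------------------------------------------------------
# moment vector


def polyserial_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-step polyserial correlation of a continuous x with a binary y.

    Assumes y dichotomises a standard-normal latent at threshold
    tau = Phi^{-1}(1 - prevalence); then rho = r_pearson * sqrt(p(1-p)) /
    phi(tau), clipped away from +/-1. The asymptotic variance combines the
    Pearson-r variance and the prevalence uncertainty by the delta method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 20:
        raise ValueError("polyserial correlation needs n >= 20")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("binary variable has a single class")
    p = float(y.mean())
    tau = stats.norm.ppf(1 - p)
    a = np.sqrt(p * (1 - p)) / stats.norm.pdf(tau)
    r = float(np.corrcoef(x, y)[0, 1])
    rho = float(np.clip(r * a, -_EPS_RHO, _EPS_RHO))
    # delta method: var(r) ~ (1-r^2)^2/n; da/dp by central difference
    h = min(1e-4, p / 2, (1 - p) / 2)
    def _a(pp: float) -> float:
        return np.sqrt(pp * (1 - pp)) / stats.norm.pdf(stats.norm.ppf(1 - pp))
    dadp = (_a(p + h) - _a(p - h)) / (2 * h)
    var = (a**2) * (1 - r**2) ** 2 / n + (r * dadp) ** 2 * p * (1 - p) / n
    return rho, float(max(var, _W_FLOOR))


def build_moment_vector(
    data: pd.DataFrame, outcome: str = "depression"
) -> tuple[np.ndarray, np.ndarray, int, list[tuple[str, str]]]:
    """Non-redundant mixed correlations s with asymptotic variances w.

    ``data`` holds z-scored continuous indicators plus one binary outcome
    column. Pairs are ordered (i, j) with i < j in column order, outcome
    last. Pearson for continuous pairs, polyserial for continuous-outcome
    pairs; variances floored at 1e-6.

    The weights w are on the per-observation scale — the asymptotic variance
    of sqrt(n) * s_k — so that (n - 1) * F_min is chi-square distributed with
    the model's degrees of freedom under a correct model.
    """
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} missing")
    cont = [c for c in data.columns if c != outcome]
    y = data[outcome].to_numpy(dtype=float)
    x = data[cont].to_numpy(dtype=float)
    n = len(data)
    sds = x.std(axis=0, ddof=0)
    for name, sd in zip(cont, sds):
        if sd == 0:
            raise ValueError(f"column {name!r} is constant")
    variables = cont + [outcome]
    s, w, pairs = [], [], []
    corr = np.corrcoef(x, rowvar=False).reshape(len(cont), len(cont))
    for i in range(len(cont)):
        for j in range(i + 1, len(cont)):
            r = float(corr[i, j])
            if abs(r) > 0.9999:
                raise ValueError(f"columns {cont[i]!r} and {cont[j]!r} are duplicates (|r|=1)")
            s.append(r)
            w.append(max((1 - r**2) ** 2, _W_FLOOR))
            pairs.append((cont[i], cont[j]))
    for i, name in enumerate(cont):
        rho, var = polyserial_corr(x[:, i], y)
        s.append(rho)
        w.append(max(var * n, _W_FLOOR))
        pairs.append((name, outcome))
    assert len(s) == len(variables) * (len(variables) - 1) // 2
    return np.asarray(s), np.asarray(w), n, pairs


# ---------------------------------------------------------------------------
# parameterisation


class _ParamMap:
    """Flat parameter vector <-> structured model parameters."""

    def __init__(self, spec: SemSpec):
        self.spec = spec
        self.lat_names = list(spec.latents)
        self.ind_latent = {t: lv for lv, taxa in spec.latents.items() for t in taxa}
        self.slices: dict[str, slice] = {}
        k = 0
        n_lam = sum(len(t) for t in spec.latents.values())
        for name, size in (
            ("lam", n_lam),
            ("gamma", len(self.lat_names)),
            ("beta", len(spec.direct)),
            ("psi", len(self.lat_names) * (len(self.lat_names) - 1) // 2),
            ("phi", len(spec.direct) * len(self.lat_names)),
            ("phidd", len(spec.direct) * (len(spec.direct) - 1) // 2),
        ):
            self.slices[name] = slice(k, k + size)
            k += size
        self.n_params = k
        self.lam_index = {}
        pos = 0
        for lv, taxa in spec.latents.items():
            for t in taxa:
                self.lam_index[t] = pos
                pos += 1
        self._pair_plan: dict | None = None

    def prepare(self, pairs: list[tuple[str, str]]) -> None:
        """Precompute index arrays so implied moments evaluate vectorised."""
        spec = self.spec
        lat_pos = {name: i for i, name in enumerate(self.lat_names)}
        dir_pos = {name: i for i, name in enumerate(spec.direct)}
        kinds = {"ii": [], "id": [], "dd": [], "iy": [], "dy": []}
        for k, (a, b) in enumerate(pairs):
            if b == spec.outcome:
                if a in self.ind_latent:
                    kinds["iy"].append((k, self.lam_index[a], lat_pos[self.ind_latent[a]]))
                else:
                    kinds["dy"].append((k, dir_pos[a]))
            elif a in self.ind_latent and b in self.ind_latent:
                kinds["ii"].append(
                    (k, self.lam_index[a], self.lam_index[b],
                     lat_pos[self.ind_latent[a]], lat_pos[self.ind_latent[b]])
                )
            elif a in self.ind_latent:
                kinds["id"].append((k, self.lam_index[a], dir_pos[b],
                                    lat_pos[self.ind_latent[a]]))
            elif b in self.ind_latent:
                kinds["id"].append((k, self.lam_index[b], dir_pos[a],
                                    lat_pos[self.ind_latent[b]]))
            else:
                kinds["dd"].append((k, dir_pos[a], dir_pos[b]))
        widths = {"ii": 5, "id": 4, "dd": 3, "iy": 3, "dy": 2}
        self._pair_plan = {
            key: (
                np.asarray(val, dtype=np.intp)
                if val
                else np.zeros((0, widths[key]), dtype=np.intp)
            )
            for key, val in kinds.items()
        }
        self._n_pairs = len(pairs)

    def bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = []
        sizes = {k: v.stop - v.start for k, v in self.slices.items()}
        b += [(-_LAMBDA_BOUND, _LAMBDA_BOUND)] * sizes["lam"]
        b += [(-_PATH_BOUND, _PATH_BOUND)] * (sizes["gamma"] + sizes["beta"])
        b += [(-_COV_BOUND, _COV_BOUND)] * (sizes["psi"] + sizes["phi"] + sizes["phidd"])
        return b

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        return {k: theta[sl] for k, sl in self.slices.items()}

    def psi_matrix(self, psi_flat: np.ndarray) -> np.ndarray:
        L = len(self.lat_names)
        psi = np.eye(L)
        k = 0
        for i in range(L):
            for j in range(i + 1, L):
                psi[i, j] = psi[j, i] = psi_flat[k]
                k += 1
        return psi

    def phidd_matrix(self, phidd_flat: np.ndarray) -> np.ndarray:
        D = len(self.spec.direct)
        phidd = np.eye(D)
        k = 0
        for i in range(D):
            for j in range(i + 1, D):
                phidd[i, j] = phidd[j, i] = phidd_flat[k]
                k += 1
        return phidd


def _implied_moments(theta: np.ndarray, pm: _ParamMap, pairs: list[tuple[str, str]]) -> np.ndarray:
    if pm._pair_plan is None:
        pm.prepare(pairs)
    plan = pm._pair_plan
    p = pm.unpack(theta)
    spec = pm.spec
    lam, gamma, beta = p["lam"], p["gamma"], p["beta"]
    psi = pm.psi_matrix(p["psi"])
    phidd = pm.phidd_matrix(p["phidd"])
    L, D = len(pm.lat_names), len(spec.direct)
    phi = p["phi"].reshape(D, L) if D and L else np.zeros((D, L))

    # var(y*) with unit-variance structural disturbance
    var_y = 1.0 + (gamma @ psi @ gamma if L else 0.0)
    if D:
        var_y = var_y + beta @ phidd @ beta
        if L:
            var_y = var_y + 2.0 * gamma @ phi.T @ beta
    sd_y = np.sqrt(max(float(var_y), 1e-12))

    # cov of each latent / direct with y*
    cov_lat_y = psi @ gamma if L else np.zeros(0)
    if D and L:
        cov_lat_y = cov_lat_y + phi.T @ beta
    cov_dir_y = phidd @ beta if D else np.zeros(0)
    if D and L:
        cov_dir_y = cov_dir_y + phi @ gamma

    sigma = np.empty(pm._n_pairs)
    ii = plan["ii"]
    if len(ii):
        sigma[ii[:, 0]] = lam[ii[:, 1]] * lam[ii[:, 2]] * psi[ii[:, 3], ii[:, 4]]
    idp = plan["id"]
    if len(idp):
        sigma[idp[:, 0]] = lam[idp[:, 1]] * phi[idp[:, 2], idp[:, 3]]
    dd = plan["dd"]
    if len(dd):
        sigma[dd[:, 0]] = phidd[dd[:, 1], dd[:, 2]]
    iy = plan["iy"]
    if len(iy):
        sigma[iy[:, 0]] = lam[iy[:, 1]] * cov_lat_y[iy[:, 2]] / sd_y
    dy = plan["dy"]
    if len(dy):
        sigma[dy[:, 0]] = cov_dir_y[dy[:, 1]] / sd_y
    return sigma


def _start_values(pm: _ParamMap, s: np.ndarray, pairs: list[tuple[str, str]]) -> np.ndarray:
    """Spectral start: loadings from the leading eigenvector of each latent's
    indicator correlation block; paths from the outcome correlations."""
    spec = pm.spec
    corr = {}
    for (a, b), val in zip(pairs, s):
        corr[(a, b)] = corr[(b, a)] = val
    theta = np.zeros(pm.n_params)
    lam = theta[pm.slices["lam"]]
    for lv, taxa in spec.latents.items():
        k = len(taxa)
        block = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                block[i, j] = block[j, i] = corr[(taxa[i], taxa[j])]
        vals, vecs = np.linalg.eigh(block)
        lead = vecs[:, -1]
        # for R ~ lam lam' + Theta the leading eigenvector is ~ proportional
        # to lam; the eigenvalue overestimates ||lam||^2 slightly, fine for a start
        est = lead * np.sqrt(max(vals[-1], 0.2)) * np.sign(lead.sum() or 1.0)
        for i, t in enumerate(taxa):
            lam[pm.lam_index[t]] = np.clip(est[i], -0.9, 0.9)
    gamma = theta[pm.slices["gamma"]]
    for li, lv in enumerate(pm.lat_names):
        taxa = spec.latents[lv]
        rbar = np.mean([corr[(t, spec.outcome)] for t in taxa])
        lbar = np.mean([lam[pm.lam_index[t]] for t in taxa]) or 0.5
        gamma[li] = np.clip(rbar / lbar, -1.5, 1.5)
    beta = theta[pm.slices["beta"]]
    for di, d in enumerate(spec.direct):
        beta[di] = np.clip(corr[(d, spec.outcome)], -1.5, 1.5)
    # exogenous covariances start at rough sample analogues
    phi = theta[pm.slices["phi"]]
    k = 0
    for d in spec.direct:
        for lv in pm.lat_names:
            taxa = spec.latents[lv]
            lbar = np.mean([lam[pm.lam_index[t]] for t in taxa]) or 0.5
            phi[k] = np.clip(np.mean([corr[(d, t)] for t in taxa]) / lbar, -0.8, 0.8)
            k += 1
    phidd = theta[pm.slices["phidd"]]
    k = 0
    for i in range(len(spec.direct)):
        for j in range(i + 1, len(spec.direct)):
            phidd[k] = corr[(spec.direct[i], spec.direct[j])]
            k += 1
    return theta


# ---------------------------------------------------------------------------
# model / results


class SemModel:
    """Confirmatory SEM for a binary outcome, statsmodels-style.

    Parameters
    ----------
    data : DataFrame
        Samples x variables; must contain every indicator / direct taxon of
        ``spec`` (typically median CLR values) and the binary outcome column.
    spec : SemSpec
        Measurement and structural layout.

    ``fit()`` z-scores the indicators (recording the constants for later
    blinded scoring), builds the mixed moment vector and minimises the DWLS
    discrepancy.
    """

    def __init__(self, data: pd.DataFrame, spec: SemSpec):
        missing = [c for c in spec.observed + [spec.outcome] if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks columns: {missing}")
        self.spec = spec
        self.data = data
        y = data[spec.outcome].to_numpy(dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        self.endog = y
        self._pm = _ParamMap(spec)

    @property
    def df_model(self) -> int:
        p_star = len(self.spec.observed) + 1
        return p_star * (p_star - 1) // 2 - self.spec.n_free_params

    def fit(self, maxiter: int = 2000, gtol: float = 1e-8) -> "SemResults":
        spec, pm = self.spec, self._pm
        n = len(self.data)
        if n <= spec.n_free_params:
            raise ValueError("fewer samples than free parameters")
        if self.df_model < 0:
            raise ValueError(f"model has df={self.df_model}; under-identified")
        x = self.data[spec.observed].to_numpy(dtype=float)
        means = x.mean(axis=0)
        sds = x.std(axis=0, ddof=0)
        z = pd.DataFrame(
            (x - means) / sds, columns=spec.observed, index=self.data.index
        )
        z[spec.outcome] = self.endog
        s, w, n, pairs = build_moment_vector(z, outcome=spec.outcome)

        def objective(theta: np.ndarray) -> float:
            resid = s - _implied_moments(theta, pm, pairs)
            return float(np.sum(resid**2 / w))

        theta0 = _start_values(pm, s, pairs)
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=pm.bounds(),
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
        )
        if not res.success and res.fun > 1e-6:
            # one jittered restart before giving up
            rng = np.random.default_rng(0)
            res2 = optimize.minimize(
                objective,
                np.clip(theta0 + rng.normal(0, 0.05, size=theta0.shape), -0.9, 0.9),
                method="L-BFGS-B",
                bounds=pm.bounds(),
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
            )
            if res2.fun < res.fun:
                res = res2
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
        if not res.success and res.fun > 1e-4 and grad_norm > 1e-3:
            raise ConvergenceError(
                f"DWLS did not converge: {res.message} (|grad|_max={grad_norm:.2e})"
            )
        theta = self._canonical_sign(res.x)
        return SemResults(self, theta, s, w, pairs, float(objective(theta)), means, sds)

    def _canonical_sign(self, theta: np.ndarray) -> np.ndarray:
        """Resolve sign indeterminacy: largest-|loading| per latent positive."""
        pm = self._pm
        theta = theta.copy()
        p = pm.unpack(theta)
        L, D = len(pm.lat_names), len(self.spec.direct)
        phi = p["phi"].reshape(D, L) if D and L else None
        for li, lv in enumerate(pm.lat_names):
            idx = [pm.lam_index[t] for t in self.spec.latents[lv]]
            lams = p["lam"][idx]
            if lams[np.argmax(np.abs(lams))] < 0:
                p["lam"][idx] = -lams
                p["gamma"][li] = -p["gamma"][li]
                k = 0
                for i in range(L):
                    for j in range(i + 1, L):
                        if li in (i, j):
                            p["psi"][k] = -p["psi"][k]
                        k += 1
                if phi is not None:
                    phi[:, li] = -phi[:, li]
        if phi is not None:
            theta[pm.slices["phi"]] = phi.ravel()
        return theta


class SemResults:
    """Fitted SEM: parameters, fit indices, scoring and serialisation."""

    def __init__(
        self,
        model: SemModel,
        theta: np.ndarray,
        s: np.ndarray,
        w: np.ndarray,
        pairs: list[tuple[str, str]],
        fmin: float,
        means: np.ndarray,
        sds: np.ndarray,
    ):
        self.model = model
        self.spec = model.spec
        self.params = theta
        self._s, self._w, self._pairs = s, w, pairs
        self.fmin = fmin
        self.nobs = len(model.data)
        self.standardization = pd.DataFrame(
            {"mean": means, "sd": sds}, index=self.spec.observed
        )
        pm = model._pm
        p = pm.unpack(theta)
        self.loadings = pd.Series(
            {t: float(p["lam"][pm.lam_index[t]]) for lv in self.spec.latents for t in self.spec.latents[lv]},
            name="loading",
        )
        self.residual_variances = 1.0 - self.loadings**2
        self.residual_variances.name = "residual_variance"
        self._gamma = pd.Series(
            {lv: float(g) for lv, g in zip(pm.lat_names, p["gamma"])}, name="gamma"
        )
        self._beta = pd.Series(
            {d: float(b) for d, b in zip(self.spec.direct, p["beta"])}, name="beta"
        )
        self.latent_corr = pd.DataFrame(
            pm.psi_matrix(p["psi"]), index=pm.lat_names, columns=pm.lat_names
        )
        L, D = len(pm.lat_names), len(self.spec.direct)
        self.exo_corr = pd.DataFrame(
            p["phi"].reshape(D, L) if D and L else np.zeros((D, L)),
            index=self.spec.direct,
            columns=pm.lat_names,
        )
        self.direct_corr = pd.DataFrame(
            pm.phidd_matrix(p["phidd"]), index=self.spec.direct, columns=self.spec.direct
        )
        # implied sd of the latent response
        gam = p["gamma"]
        psi = pm.psi_matrix(p["psi"])
        bet = p["beta"]
        phidd = pm.phidd_matrix(p["phidd"])
        phi = p["phi"].reshape(D, L) if D and L else np.zeros((D, L))
        var_y = 1.0 + (gam @ psi @ gam if L else 0.0) + (bet @ phidd @ bet if D else 0.0)
        if D and L:
            var_y += 2.0 * gam @ phi.T @ bet
        self.sd_ystar = float(np.sqrt(max(var_y, 1e-12)))
        prev = float(model.endog.mean())
        self.threshold = float(stats.norm.ppf(1 - prev))

    # -- paths ------------------------------------------------------------
    @property
    def path_coefficients_raw(self) -> pd.Series:
        """Structural paths on the unit-disturbance scale of y*."""
        parts = [s for s in (self._gamma, self._beta) if len(s)]
        if not parts:
            return pd.Series(dtype=float, name="path_raw")
        return pd.concat(parts).rename("path_raw")

    @property
    def path_coefficients(self) -> pd.Series:
        """Standardized structural paths (per SD of the latent response)."""
        return (self.path_coefficients_raw / self.sd_ystar).rename("path_std")

    @property
    def max_abs_path(self) -> float:
        return float(self.path_coefficients.abs().max())

    # -- fit indices -------------------------------------------------------
    @property
    def at_bound(self) -> bool:
        """True when a structural path sits on the optimisation bound.

        A path pinned at the bound marks a degenerate solution (typically a
        latent with vanishing loadings absorbing the outcome correlations);
        pruning treats such fits as infeasible.
        """
        raw = self.path_coefficients_raw.abs()
        return bool(len(raw) and raw.max() >= _PATH_BOUND - 1e-6)

    @property
    def df(self) -> int:
        return self.model.df_model

    @property
    def chi2(self) -> float:
        return (self.nobs - 1) * self.fmin

    @property
    def gfi(self) -> float:
        f0 = float(np.sum(self._s**2 / self._w))
        return 1.0 - self.fmin / f0 if f0 > 0 else 1.0

    @property
    def agfi(self) -> float:
        if self.df == 0:
            return float("nan")  # undefined for saturated models
        m = len(self._s)
        return 1.0 - (m / self.df) * (1.0 - self.gfi)

    @property
    def rmsea(self) -> float:
        if self.df == 0:
            return 0.0  # saturated model reproduces the moments exactly
        return float(np.sqrt(max(self.chi2 - self.df, 0.0) / (self.df * (self.nobs - 1))))

    def implied_corr(self) -> pd.DataFrame:
        """Model-implied correlation matrix of the observed predictors + y*."""
        sigma = _implied_moments(self.params, self.model._pm, self._pairs)
        names = self.spec.observed + [self.spec.outcome]
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for (a, b), val in zip(self._pairs, sigma):
            mat.loc[a, b] = mat.loc[b, a] = val
        return mat

    # -- scoring -----------------------------------------------------------
    def measurement_submodel(self) -> "MeasurementModel":
        """Extract the measurement part for outcome-blinded factor scoring."""
        latents = {
            lv: {
                "taxa": list(taxa),
                "loadings": [float(self.loadings[t]) for t in taxa],
                "residual_variances": [float(self.residual_variances[t]) for t in taxa],
            }
            for lv, taxa in self.spec.latents.items()
        }
        return MeasurementModel(
            latents=latents,
            latent_corr=self.latent_corr.to_numpy().tolist(),
            direct=list(self.spec.direct),
            means={v: float(self.standardization.loc[v, "mean"]) for v in self.spec.observed},
            sds={v: float(self.standardization.loc[v, "sd"]) for v in self.spec.observed},
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Structural equation model (DWLS on mixed correlations)",
            f"  n = {self.nobs}, moments = {len(self._s)}, "
            f"free parameters = {self.spec.n_free_params}, df = {self.df}",
            f"  chi2 = {self.chi2:.3f}, GFI = {self.gfi:.3f}, "
            f"AGFI = {self.agfi:.3f}, RMSEA = {self.rmsea:.3f}",
            f"  outcome threshold tau = {self.threshold:.3f}",
            "  Loadings (standardized):",
        ]
        for lv, taxa in self.spec.latents.items():
            for t in taxa:
                lines.append(
                    f"    {lv} =~ {t}: lambda = {self.loadings[t]:+.3f}, "
                    f"theta = {self.residual_variances[t]:.3f}"
                )
        lines.append("  Structural paths (standardized | raw):")
        raw = self.path_coefficients_raw
        for name, val in self.path_coefficients.items():
            lines.append(f"    {name} -> {self.spec.outcome}: {val:+.3f} | {raw[name]:+.3f}")
        if len(self.latent_corr) > 1:
            lines.append(f"  Latent correlation: {self.latent_corr.iloc[0, 1]:+.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params": self.params.tolist(),
            "loadings": {k: float(v) for k, v in self.loadings.items()},
            "residual_variances": {k: float(v) for k, v in self.residual_variances.items()},
            "path_coefficients": {k: float(v) for k, v in self.path_coefficients.items()},
            "path_coefficients_raw": {
                k: float(v) for k, v in self.path_coefficients_raw.items()
            },
            "threshold": self.threshold,
            "fit": {
                "chi2": self.chi2,
                "df": self.df,
                "gfi": self.gfi,
                "agfi": None if self.df == 0 else self.agfi,
                "rmsea": self.rmsea,
                "fmin": self.fmin,
                "n": self.nobs,
            },
            "standardization": {
                v: {
                    "mean": float(self.standardization.loc[v, "mean"]),
                    "sd": float(self.standardization.loc[v, "sd"]),
                }
                for v in self.spec.observed
            },
        }


@dataclass
class MeasurementModel:
    """Measurement-only SEM used for depression-blinded factor scoring.

    Carries loadings, residual variances, latent correlations, direct-taxon
    pass-through names and the z-scoring constants — everything needed to
    score new samples, and nothing about the outcome.
    """

    latents: dict[str, dict]
    latent_corr: list[list[float]]
    direct: list[str]
    means: dict[str, float]
    sds: dict[str, float]

    @property
    def taxa(self) -> list[str]:
        out = [t for lv in self.latents.values() for t in lv["taxa"]]
        return out + list(self.direct)

    def factor_scores(self, clr: pd.DataFrame) -> pd.DataFrame:
        """Empirical-Bayes (posterior-mean) latent scores for each sample.

        Indicators are z-scored with the stored constants; scores are
        xi_hat = Psi Lambda' (Lambda Psi Lambda' + Theta)^{-1} z. Direct
        predictors pass through as their standardized values. Any outcome
        column in ``clr`` is ignored.
        """
        missing = [t for t in self.taxa if t not in clr.columns]
        if missing:
            raise ValueError(f"missing taxon columns: {missing}")
        cols = {}
        lat_names = list(self.latents)
        if lat_names:
            ind = [t for lv in lat_names for t in self.latents[lv]["taxa"]]
            z = np.column_stack(
                [(clr[t].to_numpy(float) - self.means[t]) / self.sds[t] for t in ind]
            )
            L = len(lat_names)
            lam = np.zeros((len(ind), L))
            theta = np.zeros(len(ind))
            pos = 0
            for li, lv in enumerate(lat_names):
                info = self.latents[lv]
                k = len(info["taxa"])
                lam[pos : pos + k, li] = info["loadings"]
                theta[pos : pos + k] = np.maximum(info["residual_variances"], 1e-8)
                pos += k
            psi = np.asarray(self.latent_corr)
            sigma = lam @ psi @ lam.T + np.diag(theta)
            weights = psi @ lam.T @ np.linalg.inv(sigma)  # (L, p)
            scores = z @ weights.T
            for li, lv in enumerate(lat_names):
                cols[lv] = scores[:, li]
        for d in self.direct:
            cols[d] = (clr[d].to_numpy(float) - self.means[d]) / self.sds[d]
        return pd.DataFrame(cols, index=clr.index)

    def score_reliability(self) -> dict[str, float]:
        """Theoretical correlation of each factor score with the true latent."""
        out = {}
        lat_names = list(self.latents)
        if not lat_names:
            return out
        ind = [t for lv in lat_names for t in self.latents[lv]["taxa"]]
        L = len(lat_names)
        lam = np.zeros((len(ind), L))
        theta = np.zeros(len(ind))
        pos = 0
        for li, lv in enumerate(lat_names):
            info = self.latents[lv]
            k = len(info["taxa"])
            lam[pos : pos + k, li] = info["loadings"]
            theta[pos : pos + k] = np.maximum(info["residual_variances"], 1e-8)
            pos += k
        psi = np.asarray(self.latent_corr)
        sigma = lam @ psi @ lam.T + np.diag(theta)
        # cov(score, latent) equals var(score) for posterior-mean scores
        acov = psi @ lam.T @ np.linalg.inv(sigma) @ lam @ psi
        for li, lv in enumerate(lat_names):
            out[lv] = float(acov[li, li] / np.sqrt(acov[li, li] * psi[li, li]))
        return out

    def to_dict(self) -> dict:
        return {
            "latents": self.latents,
            "latent_corr": self.latent_corr,
            "direct": list(self.direct),
            "means": self.means,
            "sds": self.sds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementModel":
        return cls(
            latents=d["latents"],
            latent_corr=d["latent_corr"],
            direct=list(d["direct"]),
            means=d["means"],
            sds=d["sds"],
        )


# ---------------------------------------------------------------------------
# spec-level convenience wrappers


def fit_sem_dwls(spec: SemSpec, data: pd.DataFrame) -> SemResults:
    """Fit ``spec`` to ``data`` by DWLS (see :class:`SemModel`)."""
    return SemModel(data, spec).fit()


def measurement_submodel(fit: SemResults) -> MeasurementModel:
    return fit.measurement_submodel()


def factor_scores(meas: MeasurementModel, clr: pd.DataFrame) -> pd.DataFrame:
    return meas.factor_scores(clr)


@dataclass
class PruningCriteria:
    """Feasibility thresholds for backward indicator elimination."""

    gfi_min: float = 0.90
    rmsea_max: float = 0.08


def _spec_without(spec: SemSpec, taxon: str) -> SemSpec | None:
    """Remove one indicator or direct predictor; demote singleton latents."""
    latents: dict[str, list[str]] = {}
    direct = [d for d in spec.direct if d != taxon]
    for lv, taxa in spec.latents.items():
        remaining = [t for t in taxa if t != taxon]
        if len(remaining) >= 2:
            latents[lv] = remaining
        elif len(remaining) == 1:
            direct.append(remaining[0])
    if not latents and not direct:
        return None
    return SemSpec(latents=latents, direct=direct, outcome=spec.outcome)


def _try_fit(spec: SemSpec, data: pd.DataFrame, criteria: PruningCriteria):
    model = SemModel(data, spec)
    if model.df_model < 0:
        return None, False, "under-identified"
    try:
        fit = model.fit()
    except (ConvergenceError, ValueError) as exc:
        return None, False, str(exc)
    feasible = (
        fit.gfi >= criteria.gfi_min
        and fit.rmsea <= criteria.rmsea_max
        and not fit.at_bound
    )
    return fit, feasible, "path at bound" if fit.at_bound else None


def prune_model(
    candidates: tuple[list[str], list[str]],
    data: pd.DataFrame,
    criteria: PruningCriteria | None = None,
    outcome: str = "depression",
    exhaustive: bool = False,
) -> tuple[SemSpec, SemResults, list[dict]]:
    """Backward-eliminate indicators to maximise the dominant structural path.

    Starts from the canonical two-latent model (more-abundant candidates on
    lv1, less-abundant on lv2; singletons demoted to direct predictors) and
    greedily removes one variable at a time. A move is feasible when the fit
    converges with GFI >= gfi_min and RMSEA <= rmsea_max; among feasible
    moves the one maximising the largest |standardized path coefficient| is
    taken, and the search stops when no move improves it. The full search
    trace is returned for audit.

    With ``exhaustive=True`` (intended for <= 10 candidates) every subset of
    the candidate taxa is fitted and the best feasible model returned.
    """
    criteria = criteria or PruningCriteria()
    more, less = candidates
    if not more and not less:
        raise ValueError("no candidate taxa to model")
    if exhaustive:
        return _prune_exhaustive(more, less, data, criteria, outcome)
    spec = SemSpec.from_candidates(more, less, outcome=outcome)
    trace: list[dict] = []
    current_fit, current_feasible, note = _try_fit(spec, data, criteria)
    best_infeasible = current_fit
    trace.append(_trace_entry("initial", spec, current_fit, current_feasible, note))
    while True:
        moves = []
        for taxon in spec.observed:
            cand_spec = _spec_without(spec, taxon)
            if cand_spec is None:
                continue
            fit, feasible, note = _try_fit(cand_spec, data, criteria)
            trace.append(_trace_entry(f"remove {taxon}", cand_spec, fit, feasible, note))
            if fit is not None:
                moves.append((cand_spec, fit, feasible))
                if best_infeasible is None or (
                    fit.gfi > getattr(best_infeasible, "gfi", -np.inf)
                ):
                    best_infeasible = fit
        feasible_moves = [(sp, f) for sp, f, ok in moves if ok]
        if feasible_moves:
            best_spec, best_fit = max(feasible_moves, key=lambda sf: sf[1].max_abs_path)
            if current_feasible and current_fit is not None and (
                best_fit.max_abs_path <= current_fit.max_abs_path
            ):
                break  # no feasible move improves the dominant path
            spec, current_fit, current_feasible = best_spec, best_fit, True
            trace.append(_trace_entry("accept", spec, current_fit, True, None))
            continue
        if current_feasible and current_fit is not None:
            break
        # keep searching downward through infeasible territory
        if not moves:
            raise NoFeasibleModelError(
                "no model of any size met the fit criteria", best_fit=best_infeasible
            )
        spec, current_fit, _ = max(moves, key=lambda sf: sf[1].gfi)
        current_feasible = False
        trace.append(_trace_entry("descend", spec, current_fit, False, None))
    if current_fit is None or not current_feasible:
        raise NoFeasibleModelError(
            "no model of any size met the fit criteria", best_fit=best_infeasible
        )
    return spec, current_fit, trace


def _prune_exhaustive(more, less, data, criteria, outcome):
    from itertools import combinations

    all_taxa = list(more) + list(less)
    if len(all_taxa) > 10:
        raise ValueError("exhaustive search limited to <= 10 candidates")
    best = None
    trace: list[dict] = []
    for r in range(len(all_taxa), 0, -1):
        for keep in combinations(all_taxa, r):
            sub_more = [t for t in more if t in keep]
            sub_less = [t for t in less if t in keep]
            if not sub_more and not sub_less:
                continue
            spec = SemSpec.from_candidates(sub_more, sub_less, outcome=outcome)
            fit, feasible, note = _try_fit(spec, data, criteria)
            trace.append(_trace_entry(f"subset {keep}", spec, fit, feasible, note))
            if feasible and (best is None or fit.max_abs_path > best[1].max_abs_path):
                best = (spec, fit)
    if best is None:
        raise NoFeasibleModelError("no subset met the fit criteria")
    return best[0], best[1], trace


def _trace_entry(step, spec, fit, feasible, note) -> dict:
    entry = {
        "step": step,
        "latents": {k: list(v) for k, v in spec.latents.items()},
        "direct": list(spec.direct),
        "feasible": bool(feasible),
    }
    if fit is not None:
        entry.update(
            gfi=round(fit.gfi, 6),
            agfi=None if fit.df == 0 else round(fit.agfi, 6),
            rmsea=round(fit.rmsea, 6),
            max_abs_path=round(fit.max_abs_path, 6),
            df=fit.df,
        )
    if note:
        entry["note"] = note
    return entry
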
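"""Synthetic cohorts with the statistical structure the pipeline assumes.

The study population this package emulates is a sex-stratified, heavily
imbalanced case/control cohort (33 depression / 246 control males,
35 / 384 females) of genus-level 16S profiles with post-rarefaction depths
spanning roughly 2,300-34,000 reads. Counts are drawn from a
Dirichlet-multinomial around a log-normal baseline composition; depression
cases receive additive shifts on the log-abundance of a small set of planted
genera *before* compositional closure, so the realised CLR effect size of a
planted genus is checked against the Monte-Carlo effect oracle rather than
assumed equal to the planted shift. Covariates (age, BMI, CES-D) mirror the
published group summaries; control CES-D is truncated below the screening
cutoff of 16.

A second generator draws data straight from a one-factor SEM with a
probit-thresholded binary outcome, for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

#: Table-1-style covariate summaries: sex -> group -> variable -> (mean, sd)
DEFAULT_COVARIATES: dict = {
    "male": {
        "depression": {"age": (41.5, 12.0), "bmi": (24.1, 4.4), "cesd": (25.1, 13.1)},
        "control": {"age": (42.7, 11.0), "bmi": (23.6, 3.1), "cesd": (6.2, 4.5)},
    },
    "female": {
        "depression": {"age": (41.3, 10.8), "bmi": (22.2, 4.0), "cesd": (24.4, 12.8)},
        "control": {"age": (41.2, 10.6), "bmi": (20.9, 2.5), "cesd": (6.5, 4.3)},
    },
}


@dataclass
class CohortConfig:
    """Everything needed to draw one synthetic cohort.

    ``planted_up`` / ``planted_down`` are lists of (taxon index, CLR shift)
    applied to case samples' log-abundances before closure (shifts in
    ``planted_down`` should be negative). Taxon indices double as abundance
    ranks: index 0 is the most abundant genus of the baseline profile.
    ``overdispersion`` is the total Dirichlet concentration: smaller values
    give noisier, more zero-inflated tables. ``latent_scale`` adds a shared
    per-sample community factor to each planted set's log-abundances (in
    cases and controls alike), inducing the within-group indicator
    correlations that the latent-variable model downstream assumes.
    """

    n_case_m: int = 33
    n_control_m: int = 246
    n_case_f: int = 35
    n_control_f: int = 384
    n_taxa: int = 120
    depth_range: tuple[int, int] = (2300, 34000)
    planted_up: list[tuple[int, float]] = field(default_factory=list)
    planted_down: list[tuple[int, float]] = field(default_factory=list)
    overdispersion: float = 50.0
    base_log_sd: float = 1.5
    latent_scale: float = 0.0
    n_flagged: int = 0
    n_unassigned: int = 0
    covariate_params: dict = field(default_factory=lambda: DEFAULT_COVARIATES)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case_m", "n_control_m", "n_case_f", "n_control_f", "n_taxa"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.depth_range[0] < 100 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must satisfy 100 <= min <= max")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        up = {i for i, _ in self.planted_up}
        down = {i for i, _ in self.planted_down}
        if up & down:
            raise ValueError(f"planted sets overlap: {sorted(up & down)}")
        for i, shift in self.planted_up + self.planted_down:
            if not 0 <= i < self.n_taxa:
                raise ValueError(f"planted taxon index {i} out of range [0, {self.n_taxa})")
            if not np.isfinite(shift):
                raise ValueError("planted CLR shifts must be finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depth_range"] = list(self.depth_range)
        d["planted_up"] = [[int(i), float(s)] for i, s in self.planted_up]
        d["planted_down"] = [[int(i), float(s)] for i, s in self.planted_down]
        return d


def _taxon_names(n: int) -> list[str]:
    return [f"Genus_{i:03d}" for i in range(n)]


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw (count table, sample metadata, screening roster) for one cohort.

    Counts: a log-normal baseline composition shared by all samples; case
    samples get the planted log-abundance shifts before closure; each sample
    is a Dirichlet-multinomial draw at a depth uniform in ``depth_range``.
    Optionally ``n_flagged`` participants failing one screening rule each and
    ``n_unassigned`` participants (illness without depression, or CES-D at or
    above the cutoff) are appended so the screening stage has work to do.
    Bit-identical output under a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    # sorted so that taxon index doubles as abundance rank: planted indices
    # then refer to reproducible abundance strata rather than a random genus
    base_log = np.sort(rng.normal(0.0, config.base_log_sd, size=config.n_taxa))[::-1]
    p_base = np.exp(base_log - base_log.max())
    p_base /= p_base.sum()
    shift = np.zeros(config.n_taxa)
    for i, s in config.planted_up + config.planted_down:
        shift[i] = s
    p_case = p_base * np.exp(shift)
    p_case /= p_case.sum()

    strata = [
        ("male", "depression", config.n_case_m),
        ("male", "control", config.n_control_m),
        ("female", "depression", config.n_case_f),
        ("female", "control", config.n_control_f),
    ]
    counts_rows, meta_rows, roster_rows = [], [], []
    sample_ids: list[str] = []
    idx = 0

    up_mask = np.zeros(config.n_taxa)
    down_mask = np.zeros(config.n_taxa)
    for i, _ in config.planted_up:
        up_mask[i] = 1.0
    for i, _ in config.planted_down:
        down_mask[i] = 1.0

    def _draw_samples(sex, group, n, comp, flags_fail=None, unassigned=False):
        nonlocal idx
        cov = config.covariate_params[sex][group if not unassigned else "control"]
        for _ in range(n):
            sid = f"S{idx:04d}"
            idx += 1
            sample_ids.append(sid)
            depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
            if config.latent_scale > 0:
                eta_up, eta_down = rng.normal(size=2)
                logp = np.log(comp) + config.latent_scale * (
                    eta_up * up_mask + eta_down * down_mask
                )
                p = np.exp(logp - logp.max())
                alpha = config.overdispersion * (p / p.sum())
            else:
                alpha = config.overdispersion * comp
            probs = rng.dirichlet(alpha)
            counts_rows.append(rng.multinomial(depth, probs))
            age = float(rng.normal(*cov["age"]))
            bmi = float(rng.normal(*cov["bmi"]))
            if group == "control" and not unassigned:
                cesd = float(_truncated_normal(rng, *cov["cesd"], 0, 15.999, 1)[0])
            elif group == "depression":
                cesd = float(np.clip(rng.normal(*cov["cesd"]), 0, 60))
            else:  # unassigned: healthy-looking but CES-D pushed past the cutoff
                cesd = float(_truncated_normal(rng, 20.0, 5.0, 16, 60, 1)[0])
            # unassigned participants fail the control rule through illness
            # or, when healthy, through their above-cutoff CES-D score
            other_illness = bool(unassigned and rng.uniform() < 0.5)
            roster_rows.append(
                {
                    "sample_id": sid,
                    "sex": sex,
                    "japanese": True,
                    "pregnant_lactating": False,
                    "enema": False,
                    "antibiotics_3mo": False,
                    "responded": True,
                    "depression": group == "depression" and not unassigned,
                    "other_illness": other_illness,
                    "age": round(age, 1),
                    "bmi": round(bmi, 1),
                    "cesd": round(cesd, 1),
                }
            )
            if flags_fail:
                roster_rows[-1][flags_fail[0]] = flags_fail[1]
            meta_rows.append(
                {
                    "sample_id": sid,
                    "sex": sex,
                    "group": "unassigned" if unassigned else group,
                    "age": roster_rows[-1]["age"],
                    "bmi": roster_rows[-1]["bmi"],
                    "cesd": roster_rows[-1]["cesd"],
                }
            )

    for sex, group, n in strata:
        comp = p_case if group == "depression" else p_base
        _draw_samples(sex, group, n, comp)
    fail_cycle = [
        ("japanese", False),
        ("pregnant_lactating", True),
        ("enema", True),
        ("antibiotics_3mo", True),
        ("responded", False),
    ]
    for j in range(config.n_flagged):
        sex = "female" if j % 2 else "male"
        _draw_samples(sex, "control", 1, p_base, flags_fail=fail_cycle[j % len(fail_cycle)])
        meta_rows[-1]["group"] = "excluded"
    for j in range(config.n_unassigned):
        sex = "female" if j % 2 else "male"
        _draw_samples(sex, "control", 1, p_base, unassigned=True)

    taxa = _taxon_names(config.n_taxa)
    counts = pd.DataFrame(np.asarray(counts_rows), index=sample_ids, columns=taxa)
    counts.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    roster = pd.DataFrame(roster_rows).set_index("sample_id")
    return counts, meta, roster


def generate_from_sem(
    loadings: np.ndarray,
    path_coefficient: float,
    residual_variances: np.ndarray,
    threshold: float,
    n: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Simulate one-factor SEM data with a probit-thresholded binary outcome.

    xi ~ N(0, 1); indicators x_j = lambda_j xi + e_j with e_j ~ N(0, theta_j);
    latent response y* = gamma xi + zeta with zeta ~ N(0, 1);
    y = 1 iff y* > threshold. Returns (indicators, y, true xi) so recovery
    experiments can correlate estimated factor scores with the truth.
    """
    lam = np.asarray(loadings, dtype=float)
    theta = np.asarray(residual_variances, dtype=float)
    if n < 10:
        raise ValueError("n < 10 is unidentifiable downstream")
    if np.any(theta < 0):
        raise ValueError("residual variances must be >= 0")
    if np.any(np.abs(lam) >= 2):
        raise ValueError("|loadings| must be < 2")
    if lam.shape != theta.shape:
        raise ValueError("loadings and residual variances must align")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    xi = rng.normal(size=n)
    eps = rng.normal(size=(n, len(lam))) * np.sqrt(theta)
    x = xi[:, None] * lam + eps
    zeta = rng.normal(size=n)
    y = (path_coefficient * xi + zeta > threshold).astype(int)
    cols = [f"Genus_{i:03d}" for i in range(len(lam))]
    return pd.DataFrame(x, columns=cols), y, xi


def study_config(seed: int = 0, sex: str = "female") -> CohortConfig:
    """Study-conditions cohort with five planted differential genera.

    Mirrors the female-stratum structure (3 more-abundant, 2 less-abundant
    genera at roughly 1:10 case:control imbalance). Planted log-abundance
    shifts were sized once, against the Monte-Carlo effect oracle, so the
    realised ALDEx2-style CLR effects land in the 0.25-0.45 band typical of
    real cohorts given the Dirichlet-multinomial dispersion used here; a
    shared community factor (latent_scale) correlates each planted set
    within groups, matching the latent-variable structure the downstream
    model assumes.
    """
    if sex == "female":
        n_case_m, n_control_m, n_case_f, n_control_f = 2, 10, 35, 384
    else:
        n_case_m, n_control_m, n_case_f, n_control_f = 33, 246, 2, 10
    return CohortConfig(
        n_case_m=n_case_m,
        n_control_m=n_control_m,
        n_case_f=n_case_f,
        n_control_f=n_control_f,
        n_taxa=120,
        planted_up=[(5, 0.5), (12, 0.6), (23, 0.7)],
        planted_down=[(31, -0.9), (44, -1.0)],
        latent_scale=0.7,
        seed=seed,
    )
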
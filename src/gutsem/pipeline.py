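"""End-to-end sex-stratified workflow: screening to deployable risk model.

``run_pipeline`` chains the stages in study order — participant screening,
coverage rarefaction, Dirichlet Monte-Carlo CLR, alpha/beta diversity
report, effect-size screening, SEM pruning, measurement-submodel extraction,
blinded factor scoring, SMOTE-balanced cross-validated logistic regression,
ROC — writing every intermediate artifact so each stage is auditable and
re-runnable on its own. A single master seed deterministically derives the
per-stage seeds; two runs with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .diversity import BetaDiversityReport, alpha_diversity, bray_curtis, nmds, permanova, permdisp
from .effects import classify_taxa, differential_abundance
from .preprocess import DEFAULT_SLOPE_MAX, coverage_rarefy, dirichlet_clr, median_clr
from .risk import LogisticRiskModel, estimate_risk
from .screening import apply_exclusions, assign_groups, compare_demographics
from .sem import PruningCriteria, SemResults, prune_model

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("rarefy", "clr", "permanova", "permdisp", "nmds", "effects", "cv", "final")


@dataclass
class PipelineConfig:
    """Knobs of the full workflow; defaults follow the study protocol."""

    counts_path: str = ""
    roster_path: str = ""
    out_dir: str = "gutsem_out"
    sex: str = "female"
    slope_max: float = DEFAULT_SLOPE_MAX
    n_instances: int = 128
    prior: float = 0.5
    effect_threshold: float = 0.2
    gfi_min: float = 0.90
    rmsea_max: float = 0.08
    folds: int = 10
    smote_k: int = 5
    smote_ratio: float = 1.0
    n_perm: int = 9999
    nmds_starts: int = 2
    nmds_max_iter: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "slope_max",
            "n_instances",
            "prior",
            "effect_threshold",
            "gfi_min",
            "rmsea_max",
            "folds",
            "smote_k",
            "smote_ratio",
            "n_perm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus where it was written."""

    out_dir: Path
    status: str
    audit: dict | None = None
    demographics: pd.DataFrame | None = None
    beta: BetaDiversityReport | None = None
    effects: pd.DataFrame | None = None
    selection: tuple[list[str], list[str]] | None = None
    sem_fit: SemResults | None = None
    risk: object | None = None


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return dict(zip(_STAGE_NAMES, children))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    config: PipelineConfig,
    counts: pd.DataFrame | None = None,
    roster: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the full workflow for one sex stratum.

    ``counts`` and ``roster`` may be passed in memory; otherwise they are
    read from the paths in ``config``. Artifacts land in ``config.out_dir``;
    a ``manifest.json`` completion marker is written only when the run
    finishes (or stops cleanly at the no-candidate-taxa exit).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    if counts is None:
        counts = gio.read_count_table(config.counts_path)
    if roster is None:
        roster = gio.read_metadata(config.roster_path)

    # -- screening ---------------------------------------------------------
    screened, audit = apply_exclusions(roster)
    meta = assign_groups(screened)
    for sex_name, sub in meta.groupby("sex"):
        audit.group_counts[str(sex_name)] = (
            sub["group"].value_counts().astype(int).to_dict()
        )
    gio.write_json(audit.to_dict(), out / "screening_audit.json")
    demographics = compare_demographics(meta)
    demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)
    stratum = meta[(meta["sex"] == config.sex) & meta["group"].isin(["depression", "control"])]
    if stratum.empty:
        raise ValueError(f"no screened samples in the {config.sex} stratum")
    labels = (stratum["group"] == "depression").astype(int)
    sub_counts = counts.loc[stratum.index]
    logger.info("screening: %d -> %d samples (%s stratum: %d)",
                len(roster), len(screened), config.sex, len(stratum))

    # -- rarefaction + CLR --------------------------------------------------
    rarefied, excluded = coverage_rarefy(sub_counts, config.slope_max, seed=seeds["rarefy"])
    gio.write_count_table(rarefied, out / "rarefied_counts.tsv")
    gio.write_json({"excluded_samples": excluded}, out / "rarefaction_exclusions.json")
    labels = labels.loc[rarefied.index]
    logger.info("rarefy: %d samples kept, %d excluded, %d genera",
                rarefied.shape[0], len(excluded), rarefied.shape[1])
    clr = dirichlet_clr(rarefied, config.n_instances, config.prior, seed=seeds["clr"])
    clr_median = median_clr(clr)

    # -- diversity report ---------------------------------------------------
    alpha = alpha_diversity(rarefied)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    dm = bray_curtis(rarefied)
    group_series = labels.map({1: "depression", 0: "control"})
    f_a, p_a = permanova(dm, group_series, n_perm=config.n_perm, seed=seeds["permanova"])
    f_d, p_d, disp = permdisp(dm, group_series, n_perm=config.n_perm, seed=seeds["permdisp"])
    coords, stress = nmds(
        dm,
        k_dims=2,
        seed=_seed_int(seeds["nmds"]),
        n_starts=config.nmds_starts,
        max_iter=config.nmds_max_iter,
        tol=1e-5,
    )
    coords.to_csv(out / "nmds_coordinates.tsv", sep="\t", index_label="sample_id")
    beta = BetaDiversityReport(f_a, p_a, f_d, p_d, disp.to_dict(), stress)
    gio.write_json(beta.to_dict(), out / "beta_diversity.json")
    logger.info("diversity: PERMANOVA p=%.4f, PERMDISP p=%.4f, NMDS stress=%.3f",
                p_a, p_d, stress)

    # -- differential abundance --------------------------------------------
    effects = differential_abundance(
        clr, labels, seed=_seed_int(seeds["effects"]), threshold=config.effect_threshold
    )
    effects.to_csv(out / "effect_sizes.tsv", sep="\t")
    more, less = classify_taxa(effects["effect"], threshold=config.effect_threshold)
    gio.write_json({"more_abundant": more, "less_abundant": less}, out / "taxon_selection.json")
    logger.info("effects: %d more-abundant, %d less-abundant taxa", len(more), len(less))
    result = PipelineResult(
        out_dir=out,
        status="",
        audit=audit.to_dict(),
        demographics=demographics,
        beta=beta,
        effects=effects,
        selection=(more, less),
    )
    if not more and not less:
        result.status = "no candidate taxa"
        gio.write_json({"status": result.status}, out / "manifest.json")
        logger.info("pipeline: no candidate taxa; stopping cleanly before SEM")
        return result

    # -- SEM ----------------------------------------------------------------
    sem_data = clr_median.copy()
    sem_data["depression"] = labels.to_numpy()
    spec, fit, trace = prune_model(
        (more, less),
        sem_data,
        criteria=PruningCriteria(gfi_min=config.gfi_min, rmsea_max=config.rmsea_max),
    )
    gio.write_json({"fit": fit.to_dict(), "trace": trace}, out / "sem_fit.json")
    logger.info("sem: %s; GFI=%.3f RMSEA=%.3f max|path|=%.3f",
                spec.to_dict(), fit.gfi, fit.rmsea, fit.max_abs_path)
    meas = fit.measurement_submodel()
    scores = meas.factor_scores(clr_median)
    scores.to_csv(out / "factor_scores.tsv", sep="\t", index_label="sample_id")

    # -- risk model ----------------------------------------------------------
    risk = LogisticRiskModel(scores, labels.to_numpy()).fit(
        folds=config.folds,
        seed=_seed_int(seeds["cv"]),
        smote_k=config.smote_k,
        smote_ratio=config.smote_ratio,
    )
    risk.roc.to_frame().to_csv(out / "roc_points.tsv", sep="\t", index=False)
    bundle = {"measurement_model": meas.to_dict(), "risk_model": risk.to_dict()}
    gio.write_model(bundle, out / "risk_model.json")
    logger.info("risk: pooled CV AUC=%.3f (resubstitution %.3f)",
                risk.cv_auc_pooled, risk.auc_resubstitution)

    result.sem_fit = fit
    result.risk = risk
    result.status = "complete"
    gio.write_json(
        {
            "status": "complete",
            "sex": config.sex,
            "n_samples": int(rarefied.shape[0]),
            "n_genera": int(rarefied.shape[1]),
            "selected_taxa": {"more": more, "less": less},
            "cv_auc_pooled": risk.cv_auc_pooled,
        },
        out / "manifest.json",
    )
    return result


def score_new_samples(model_path: str | Path, counts_path: str | Path,
                      config: PipelineConfig | None = None) -> pd.Series:
    """Score a new TSV count table with a persisted risk-model bundle."""
    from .risk import RiskResults
    from .sem import MeasurementModel

    config = config or PipelineConfig()
    bundle = gio.read_model(model_path)
    meas = MeasurementModel.from_dict(bundle["measurement_model"])
    risk = RiskResults.from_dict(bundle["risk_model"])
    counts = gio.read_count_table(counts_path)
    rarefied, _ = coverage_rarefy(counts, config.slope_max, seed=config.seed)
    clr = dirichlet_clr(rarefied, config.n_instances, config.prior, seed=config.seed)
    return estimate_risk(risk, meas, median_clr(clr))
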
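"""ALDEx2-style standardized effect sizes on Monte-Carlo CLR arrays.

For every genus, the effect size is the median between-group CLR difference
scaled by the larger within-group dispersion, computed inside each Dirichlet
Monte-Carlo instance and then medianed across instances. Being a
signal-to-noise ratio rather than a p-value, it is largely insensitive to the
severe case:control imbalance of the cohorts this pipeline targets. Genera
with |effect| above a threshold (0.2 by convention here) are classified as
more / less abundant in the case group and become SEM candidate indicators.

The per-group random pairing streams are seeded from the group *membership*
(sorted sample indices), which makes the estimate exactly antisymmetric under
swapping the group labels at the same master seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ClrArray

_DISP_FLOOR = 1e-12


def _group_rng(seed: int, members: np.ndarray, tag: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed), int(tag)] + [int(m) for m in np.sort(members)])
    return np.random.default_rng(ss)


def _gather(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """values (I, n_g, T) gathered along samples with idx (I, P) -> (I, P, T)."""
    return np.take_along_axis(values, idx[:, :, None], axis=1)


def aldex_effect(
    array: ClrArray,
    groups,
    seed: int = 0,
    n_pairs: int | None = None,
) -> pd.DataFrame:
    """Standardized per-genus effect of group membership on CLR abundance.

    Within each Monte-Carlo instance, ``n_pairs`` random case/control pairs
    give the between-group differences and random within-group pairs the
    dispersions; the instance effect is median(between) divided by the larger
    of the two median absolute within-group differences. The reported effect
    is the median over instances; the sign convention is case minus control
    (positive = more abundant in the case group).

    Parameters
    ----------
    array : ClrArray
        Monte-Carlo CLR stack, shape (n_instances, n_samples, n_taxa).
    groups : array-like of {0, 1}
        Binary labels aligned with the array's samples; 1 = case.
    n_pairs : int, optional
        Random pairings per instance; defaults to max(n_case, n_control).

    Returns
    -------
    DataFrame indexed by genus with columns ``effect``, ``diff_btw``
    (median between-group difference) and ``disp_win`` (median within-group
    dispersion).
    """
    labels = _as_binary(groups, array.sample_ids)
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    if len(idx1) < 2 or len(idx0) < 2:
        raise ValueError("both groups need at least two samples")
    v = array.values
    n_inst = v.shape[0]
    p = n_pairs or max(len(idx1), len(idx0))

    rng1 = _group_rng(seed, idx1, tag=1)
    rng0 = _group_rng(seed, idx0, tag=1)
    v1 = v[:, idx1, :]
    v0 = v[:, idx0, :]
    b1 = rng1.integers(len(idx1), size=(n_inst, p))
    w1a = rng1.integers(len(idx1), size=(n_inst, p))
    w1b = rng1.integers(len(idx1), size=(n_inst, p))
    b0 = rng0.integers(len(idx0), size=(n_inst, p))
    w0a = rng0.integers(len(idx0), size=(n_inst, p))
    w0b = rng0.integers(len(idx0), size=(n_inst, p))

    diff_btw = np.median(_gather(v1, b1) - _gather(v0, b0), axis=1)  # (I, T)
    disp1 = np.median(np.abs(_gather(v1, w1a) - _gather(v1, w1b)), axis=1)
    disp0 = np.median(np.abs(_gather(v0, w0a) - _gather(v0, w0b)), axis=1)
    disp = np.maximum(np.maximum(disp1, disp0), _DISP_FLOOR)
    effect_inst = diff_btw / disp
    return pd.DataFrame(
        {
            "effect": np.median(effect_inst, axis=0),
            "diff_btw": np.median(diff_btw, axis=0),
            "disp_win": np.median(disp, axis=0),
        },
        index=pd.Index(array.taxa, name="genus"),
    )


def _as_binary(groups, sample_ids) -> np.ndarray:
    if isinstance(groups, pd.Series):
        s = groups.copy()
        s.index = s.index.astype(str)
        groups = s.reindex([str(i) for i in sample_ids]).to_numpy()
    labels = np.asarray(groups)
    if labels.shape[0] != len(sample_ids):
        raise ValueError("labels do not align with samples")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    return labels.astype(int)


def wilcoxon_bh(array: ClrArray, groups) -> pd.DataFrame:
    """Expected Wilcoxon rank-sum p and Benjamini-Hochberg q per genus.

    A two-sided rank-sum test (normal approximation with tie correction) is
    run per genus inside every Monte-Carlo instance; BH correction is applied
    across genera within the instance; the expected p and q are the means
    over instances.
    """
    labels = _as_binary(groups, array.sample_ids)
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    if len(idx1) < 2 or len(idx0) < 2:
        raise ValueError("both groups need at least two samples")
    v = array.values
    res = stats.mannwhitneyu(
        v[:, idx1, :], v[:, idx0, :], axis=1, alternative="two-sided", method="asymptotic"
    )
    p = res.pvalue  # (I, T)
    q = stats.false_discovery_control(p, axis=1, method="bh")
    return pd.DataFrame(
        {"p_expected": p.mean(axis=0), "q_expected": q.mean(axis=0)},
        index=pd.Index(array.taxa, name="genus"),
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, q_(i) = min_{j>=i} p_(j) m / j."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


def classify_taxa(
    effects: pd.Series | pd.DataFrame, threshold: float = 0.2
) -> tuple[list[str], list[str]]:
    """Split genera into more / less abundant by strict effect threshold.

    Returns ``(more, less)`` genus-name lists ordered by |effect| descending;
    effects exactly at the threshold are neutral.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(effects, pd.DataFrame):
        effects = effects["effect"]
    order = effects.abs().sort_values(ascending=False, kind="stable").index
    eff = effects.loc[order]
    more = [str(g) for g in eff.index[eff > threshold]]
    less = [str(g) for g in eff.index[eff < -threshold]]
    return more, less


def differential_abundance(
    array: ClrArray, groups, seed: int = 0, threshold: float = 0.2
) -> pd.DataFrame:
    """Effect sizes, expected p/q and abundance class in one table."""
    out = aldex_effect(array, groups, seed=seed)
    out = out.join(wilcoxon_bh(array, groups))
    more, less = classify_taxa(out["effect"], threshold=threshold)
    cls = pd.Series("neutral", index=out.index, name="class")
    cls.loc[more] = "more"
    cls.loc[less] = "less"
    out["class"] = cls
    return out
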
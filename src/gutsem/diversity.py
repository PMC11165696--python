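"""Alpha-diversity indices and distance-based beta-diversity tests.

Shannon, Simpson and Pielou indices summarise within-sample richness and
evenness; Bray-Curtis dissimilarities between rarefied genus profiles feed
permutation tests for between-group location (PERMANOVA) and dispersion
(PERMDISP) differences, and a non-metric multidimensional scaling (NMDS)
ordination for visual export.

PERMANOVA/PERMDISP are implemented here rather than delegated so that the
permutation scheme, the add-one p-value estimator p = (1 + #{F* >= F}) /
(1 + n_perm) and the seeding are fully reproducible; the dispersion test uses
group centroids in principal-coordinate space (the reference R implementation
defaults to spatial medians — a documented divergence).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

logger = logging.getLogger(__name__)


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon (natural log), Simpson (1 - sum p^2) and Pielou.

    Pielou evenness is H / ln(S_obs) with S_obs the number of genera present;
    it is undefined (NaN) for single-genus samples.
    """
    counts = table.to_numpy(dtype=float)
    depths = counts.sum(axis=1)
    if np.any(depths == 0):
        bad = table.index[depths == 0].tolist()
        raise ValueError(f"empty samples have no diversity: {bad}")
    p = counts / depths[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    simpson = 1.0 - (p**2).sum(axis=1)
    s_obs = (counts > 0).sum(axis=1)
    pielou = np.where(s_obs > 1, shannon / np.log(np.maximum(s_obs, 2)), np.nan)
    return pd.DataFrame(
        {"shannon": shannon, "simpson": simpson, "pielou": pielou}, index=table.index
    )


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix on (rarefied) counts."""
    if table.shape[0] < 2:
        raise ValueError("need at least two samples")
    counts = table.to_numpy(dtype=float)
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("Bray-Curtis undefined for all-zero samples")
    condensed = pdist(counts, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in table.index])


def _align_groups(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        s = groups.copy()
        s.index = s.index.astype(str)
        groups = s.reindex(list(dm.ids)).to_numpy()
    groups = np.asarray(groups)
    if groups.shape[0] != dm.shape[0]:
        raise ValueError("groups do not align with the distance matrix")
    if pd.isna(groups).any():
        raise ValueError("missing group labels")
    return groups


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dm: DistanceMatrix | np.ndarray,
    groups,
    n_perm: int = 9999,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Permutational multivariate analysis of variance on a distance matrix.

    Returns the pseudo-F statistic from the partition of the squared
    distances and the add-one permutation p-value under random relabelling.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm))
    groups = _align_groups(dm, groups)
    codes, uniques = pd.factorize(groups)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs n >= 2")
    d2 = dm.data**2
    f_obs = _permanova_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, n_groups) >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return float(f_obs), float(p)


def _pcoa_axes(d2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes split into real and 'imaginary' parts.

    Gower-centers the squared distances and eigendecomposes; axes with
    negative eigenvalues (non-Euclidean part of e.g. Bray-Curtis) are kept
    separately — their squared contributions are *subtracted* from squared
    distances in the embedded space.
    """
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-8 * max(abs(vals).max(), 1.0)
    pos = vals > tol
    neg = vals < -tol
    coords_pos = vecs[:, pos] * np.sqrt(vals[pos])
    coords_neg = vecs[:, neg] * np.sqrt(-vals[neg])
    return coords_pos, coords_neg


def _dispersions(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    coords_pos, coords_neg = _pcoa_axes(d2)
    disp2 = np.empty(d2.shape[0])
    for g in range(n_groups):
        mask = codes == g
        cp = coords_pos[mask].mean(axis=0)
        cn = coords_neg[mask].mean(axis=0) if coords_neg.shape[1] else None
        val = ((coords_pos[mask] - cp) ** 2).sum(axis=1)
        if cn is not None:
            val = val - ((coords_neg[mask] - cn) ** 2).sum(axis=1)
        disp2[mask] = val
    if np.any(disp2 < 0):
        warnings.warn(
            "negative squared distances to centroid clamped to 0 "
            "(non-Euclidean axes dominate)",
            RuntimeWarning,
            stacklevel=3,
        )
        disp2 = np.clip(disp2, 0.0, None)
    return np.sqrt(disp2)


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = values.shape[0]
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        vals = values[codes == g]
        ss_between += len(vals) * (vals.mean() - grand) ** 2
        ss_within += ((vals - vals.mean()) ** 2).sum()
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permdisp(
    dm: DistanceMatrix | np.ndarray,
    groups,
    n_perm: int = 9999,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float, pd.Series]:
    """Test for homogeneity of multivariate group dispersions.

    Samples are embedded by principal coordinates (keeping negative-eigenvalue
    axes with the imaginary-part sign convention); each sample's dispersion is
    its distance to its group centroid in that space; a one-way ANOVA F on the
    dispersions is assessed by permuting the dispersion values' group labels.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm))
    groups = _align_groups(dm, groups)
    codes, uniques = pd.factorize(groups)
    n_groups = len(uniques)
    if n_groups < 2 or np.bincount(codes).min() < 2:
        raise ValueError("need >= 2 groups with n >= 2 each")
    disp = _dispersions(dm.data**2, codes, n_groups)
    f_obs = _anova_f(disp, codes, n_groups)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        if _anova_f(disp, rng.permutation(codes), n_groups) >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    mean_disp = pd.Series(
        {str(u): float(disp[codes == g].mean()) for g, u in enumerate(uniques)},
        name="mean_dispersion",
    )
    return float(f_obs), float(p), mean_disp


def nmds(
    dm: DistanceMatrix | np.ndarray,
    k_dims: int = 2,
    seed: int = 0,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS minimising Kruskal stress-1.

    Runs SMACOF with isotonic regression from ``n_starts`` random starts plus
    a principal-coordinates start and returns the best configuration.
    """
    if k_dims < 1:
        raise ValueError("k_dims must be >= 1")
    ids = None
    if isinstance(dm, DistanceMatrix):
        ids = list(dm.ids)
        d = dm.data
    else:
        d = np.asarray(dm, dtype=float)
    common = dict(
        n_components=k_dims,
        metric=False,
        dissimilarity="precomputed",
        max_iter=max_iter,
        eps=tol,
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mds = MDS(n_init=n_starts, random_state=seed, **common)
        coords = mds.fit_transform(d)
        stress = float(mds.stress_)
        # principal-coordinates start often beats random starts
        pos, _ = _pcoa_axes(d**2)
        if pos.shape[1] >= 1:
            init = np.zeros((d.shape[0], k_dims))
            take = min(k_dims, pos.shape[1])
            init[:, :take] = pos[:, ::-1][:, :take]  # largest eigenvalues first
            mds2 = MDS(n_init=1, random_state=seed, **common)
            coords2 = mds2.fit_transform(d, init=init)
            if mds2.stress_ < stress:
                coords, stress = coords2, float(mds2.stress_)
    out = pd.DataFrame(coords, columns=[f"NMDS{i + 1}" for i in range(k_dims)])
    if ids is not None:
        out.index = ids
    return out, stress


@dataclass
class BetaDiversityReport:
    """Bundle of the between-group beta-diversity comparison."""

    permanova_f: float
    permanova_p: float
    permdisp_f: float
    permdisp_p: float
    mean_dispersion: dict[str, float]
    nmds_stress: float

    def to_dict(self) -> dict:
        return {
            "permanova": {"F": self.permanova_f, "p": self.permanova_p},
            "permdisp": {
                "F": self.permdisp_f,
                "p": self.permdisp_p,
                "mean_dispersion": self.mean_dispersion,
            },
            "nmds_stress": self.nmds_stress,
        }
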
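"""Coverage-based rarefaction and Dirichlet Monte-Carlo CLR transformation.

Genus-level 16S count tables are compositional: only relative information
survives sequencing. The pipeline therefore (1) subsamples each sample down to
the smallest depth at which its rarefaction curve is nearly flat — i.e. the
expected number of *new* genera gained per additional read drops below a
coverage threshold — and (2) maps counts into an unconstrained Euclidean space
with the centered log-ratio (CLR) transform, propagating count uncertainty by
Monte-Carlo sampling from a Dirichlet posterior, as in ALDEx2-style analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: Coverage threshold on the rarefaction slope (expected new genera per
#: additional read) used by the study workflow.
DEFAULT_SLOPE_MAX = 0.002259329


def _log_choose(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    """log of the binomial coefficient C(n, k), -inf where k > n."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(k > n, -np.inf, out)


def expected_richness(counts: np.ndarray, n: int) -> float:
    """Expected number of genera observed in a random subsample of n reads.

    Hypergeometric expectation: E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n))
    where N is the sample depth and N_i the count of genus i. Computed with
    log-gamma arithmetic so it is stable at depths of tens of thousands.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    total = counts.sum()
    if n < 0 or n > total:
        raise ValueError(f"subsample depth {n} outside [0, {int(total)}]")
    log_absent = _log_choose(total - counts, n) - _log_choose(total, n)
    return float(np.sum(1.0 - np.exp(log_absent)))


def rarefaction_slope(counts: np.ndarray, n: int) -> float:
    """Expected new genera per additional read at subsample depth ``n``.

    Discrete forward difference of the expected-richness curve,
    E[S_{n+1}] - E[S_n]; non-increasing in ``n``.
    """
    counts = np.asarray(counts, dtype=float)
    depth = int(counts.sum())
    if not 1 <= n < depth:
        raise ValueError(f"need 1 <= n < depth ({depth}), got n={n}")
    return expected_richness(counts, n + 1) - expected_richness(counts, n)


def _coverage_depth(counts: np.ndarray, slope_max: float) -> int | None:
    """Smallest depth n with rarefaction slope <= slope_max, or None.

    Binary search; valid because the slope is non-increasing in n.
    """
    depth = int(np.asarray(counts).sum())
    if depth < 2:
        return None
    if rarefaction_slope(counts, depth - 1) > slope_max:
        return None
    lo, hi = 1, depth - 1  # slope(hi) <= slope_max already verified
    while lo < hi:
        mid = (lo + hi) // 2
        if rarefaction_slope(counts, mid) <= slope_max:
            hi = mid
        else:
            lo = mid + 1
    return lo


def coverage_rarefy(
    table: pd.DataFrame,
    slope_max: float = DEFAULT_SLOPE_MAX,
    seed: int | np.random.SeedSequence = 0,
    drop_empty_taxa: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Rarefy each sample to its coverage-matched depth.

    Each sample is subsampled without replacement (multivariate
    hypergeometric) to the smallest depth at which its rarefaction slope is
    at most ``slope_max``. Samples that never reach that coverage — their
    slope still exceeds the threshold one read short of full depth — are
    excluded and returned in the second element.

    The target depth per sample is a deterministic function of its counts;
    only the identity of the retained reads depends on ``seed``.
    """
    if slope_max <= 0:
        raise ValueError("slope_max must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(table.shape[0])
    rows = {}
    excluded: list[str] = []
    for (sample, counts), child in zip(table.iterrows(), children):
        vec = counts.to_numpy(dtype=np.int64)
        if vec.sum() == 0:
            excluded.append(sample)
            continue
        n_star = _coverage_depth(vec, slope_max)
        if n_star is None:
            excluded.append(sample)
            continue
        rng = np.random.default_rng(child)
        rows[sample] = rng.multivariate_hypergeometric(vec, n_star)
    if excluded:
        logger.info("coverage_rarefy: excluded %d under-covered samples", len(excluded))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.columns)
    if drop_empty_taxa and not out.empty:
        empty = out.columns[(out.sum(axis=0) == 0)]
        if len(empty):
            logger.info("coverage_rarefy: dropping %d all-zero genera", len(empty))
            out = out.drop(columns=empty)
    return out, excluded


@dataclass
class ClrArray:
    """Monte-Carlo stack of CLR-transformed compositions.

    ``values`` has shape (n_instances, n_samples, n_taxa); every
    instance-sample row sums to zero (the CLR identity).
    """

    values: np.ndarray
    sample_ids: list[str]
    taxa: list[str]
    prior: float
    seed: int | None = None

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    def median(self) -> pd.DataFrame:
        """Element-wise median across Monte-Carlo instances."""
        return pd.DataFrame(
            np.median(self.values, axis=0), index=self.sample_ids, columns=self.taxa
        )

    def save(self, path: str | Path) -> None:
        """Persist as a raw array file plus a JSON sidecar."""
        path = Path(path)
        np.save(path, self.values)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "shape": list(self.values.shape),
                    "sample_ids": list(self.sample_ids),
                    "taxa": list(self.taxa),
                    "prior": self.prior,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClrArray":
        path = Path(path)
        values = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(values, meta["sample_ids"], meta["taxa"], meta["prior"], meta["seed"])


def clr_transform(proportions: np.ndarray) -> np.ndarray:
    """Deterministic CLR of strictly positive compositions (rows)."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p <= 0):
        raise ValueError("CLR requires strictly positive proportions")
    logp = np.log(p)
    return logp - logp.mean(axis=-1, keepdims=True)


def dirichlet_clr(
    table: pd.DataFrame,
    n_instances: int = 128,
    prior: float = 0.5,
    seed: int | np.random.SeedSequence = 0,
) -> ClrArray:
    """Monte-Carlo CLR: per sample, CLR of draws from Dirichlet(counts + prior).

    The Dirichlet draw is realised through independent Gamma variates; the
    normalising constant cancels inside the CLR, so the Gammas are logged
    and row-centered directly.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if prior <= 0:
        raise ValueError("prior must be positive")
    counts = table.to_numpy(dtype=float)
    if np.any(counts.sum(axis=1) == 0):
        bad = table.index[counts.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero samples cannot be CLR-transformed: {bad}")
    n_samples, n_taxa = counts.shape
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    values = np.empty((n_instances, n_samples, n_taxa))
    alpha = counts + prior
    for s in range(n_samples):
        g = rng.standard_gamma(alpha[s], size=(n_instances, n_taxa))
        logg = np.log(g)
        values[:, s, :] = logg - logg.mean(axis=1, keepdims=True)
    seed_int = None
    if not isinstance(seed, np.random.SeedSequence):
        seed_int = int(seed)
    return ClrArray(values, list(table.index), list(table.columns), prior, seed_int)


def median_clr(array: ClrArray) -> pd.DataFrame:
    """Point summary of a :class:`ClrArray`: element-wise median."""
    return array.median()
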
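"""Participant screening, group assignment and demographic comparison.

The study design excludes participants by a fixed sequence of rules
(nationality, pregnancy/lactation, enema stool, recent antibiotics,
questionnaire non-response), assigns the remainder to a depression group
(self-reported physician-diagnosed depression) or a control group (no current
illness or treatment and a CES-D score strictly below the conventional
suspicion cutoff of 16), and compares age/BMI (Welch's t) and CES-D
(Wilcoxon rank-sum) between groups within each sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Exclusion rules in application order; a participant failing several rules
#: is attributed to the first failing one so the audit counts are well defined.
EXCLUSION_RULES = (
    "non_japanese",
    "pregnant_lactating",
    "enema",
    "antibiotics_3mo",
    "non_response",
)

#: Roster flag columns (True = fails the corresponding rule, except
#: ``japanese``/``responded`` where False fails).
FLAG_COLUMNS = ("japanese", "pregnant_lactating", "enema", "antibiotics_3mo", "responded")

CESD_CUTOFF = 16


@dataclass
class ScreeningAudit:
    """Removal counts per exclusion rule, in application order."""

    removed: dict[str, int]
    n_input: int
    n_remaining: int
    group_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.removed.values()) != self.n_input - self.n_remaining:
            raise ValueError("audit counts do not sum to the number removed")

    def to_dict(self) -> dict:
        return {
            "removed": dict(self.removed),
            "n_input": self.n_input,
            "n_remaining": self.n_remaining,
            "group_counts": self.group_counts,
        }


def _first_failing_rule(row: pd.Series) -> str | None:
    flags = {c: row.get(c) for c in FLAG_COLUMNS}
    if any(pd.isna(v) for v in flags.values()):
        return "non_response"  # a missing flag is treated as non-response
    checks = {
        "non_japanese": not bool(flags["japanese"]),
        "pregnant_lactating": bool(flags["pregnant_lactating"]),
        "enema": bool(flags["enema"]),
        "antibiotics_3mo": bool(flags["antibiotics_3mo"]),
        "non_response": not bool(flags["responded"]),
    }
    for rule in EXCLUSION_RULES:
        if checks[rule]:
            return rule
    return None


def apply_exclusions(roster: pd.DataFrame) -> tuple[pd.DataFrame, ScreeningAudit]:
    """Remove participants failing any exclusion rule.

    Each removed participant is counted once, under the first rule (in
    :data:`EXCLUSION_RULES` order) that it fails; a missing flag counts as
    questionnaire non-response.
    """
    missing = [c for c in FLAG_COLUMNS if c not in roster.columns]
    if missing:
        raise ValueError(f"roster lacks flag columns: {missing}")
    removed = {rule: 0 for rule in EXCLUSION_RULES}
    keep = np.ones(len(roster), dtype=bool)
    for i, (_, row) in enumerate(roster.iterrows()):
        rule = _first_failing_rule(row)
        if rule is not None:
            removed[rule] += 1
            keep[i] = False
    kept = roster.loc[keep].copy()
    audit = ScreeningAudit(removed=removed, n_input=len(roster), n_remaining=len(kept))
    return kept, audit


def assign_groups(roster: pd.DataFrame) -> pd.DataFrame:
    """Assign screened participants to depression / control / unassigned.

    Depression: self-reported physician-diagnosed depression. Control: no
    current illness or treatment AND CES-D strictly below 16 (a score of
    exactly 16 already flags suspicion of depression, so such participants
    stay unassigned). Everyone else is unassigned.
    """
    required = {"depression", "other_illness", "cesd", "sex"}
    missing = required - set(roster.columns)
    if missing:
        raise ValueError(f"roster lacks columns: {sorted(missing)}")
    group = np.where(
        roster["depression"].astype(bool),
        "depression",
        np.where(
            (~roster["other_illness"].astype(bool)) & (roster["cesd"] < CESD_CUTOFF),
            "control",
            "unassigned",
        ),
    )
    meta = roster.copy()
    meta["group"] = group
    return meta


def compare_demographics(meta: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD and p-values per sex for age, BMI and CES-D.

    Welch's unequal-variance t-test for age and BMI; two-sided Wilcoxon
    rank-sum for CES-D (exact enumeration when both groups have n <= 25 and
    no ties, normal approximation with tie correction otherwise). A group
    with fewer than two observations yields a missing p-value.
    """
    rows = []
    for sex, sub in meta.groupby("sex", sort=True):
        case = sub[sub["group"] == "depression"]
        ctrl = sub[sub["group"] == "control"]
        for var in ("age", "bmi", "cesd"):
            if var not in sub.columns:
                continue
            x = case[var].dropna().to_numpy(dtype=float)
            y = ctrl[var].dropna().to_numpy(dtype=float)
            p = np.nan
            if len(x) >= 2 and len(y) >= 2:
                if var == "cesd":
                    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
                    method = "exact" if (max(len(x), len(y)) <= 25 and not ties) else "asymptotic"
                    p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
                else:
                    if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
                        p = 1.0
                    else:
                        p = stats.ttest_ind(x, y, equal_var=False).pvalue
            rows.append(
                {
                    "sex": sex,
                    "variable": var,
                    "n_depression": len(x),
                    "n_control": len(y),
                    "mean_depression": x.mean() if len(x) else np.nan,
                    "sd_depression": x.std(ddof=1) if len(x) > 1 else np.nan,
                    "mean_control": y.mean() if len(y) else np.nan,
                    "sd_control": y.std(ddof=1) if len(y) > 1 else np.nan,
                    "p_value": float(p) if p == p else np.nan,
                }
            )
    return pd.DataFrame(rows)
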
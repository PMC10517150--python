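"""Multi-visit phenotype reconciliation, phenotype models, kinship pruning.

The self-reported balding pattern (1-4) is recorded at up to four visits.
Because the phenotype is progressive, a later visit reporting a lower
pattern than any earlier visit ("improvement") is implausible and triggers
the sanity rules below; otherwise the most recent pattern is used.

Four phenotype models are built from the reconciled patterns:

* continuous    - pattern 1-4 as a continuous response;
* all           - controls pattern 1 vs cases pattern 2-4;
* two_as_control- controls pattern 1-2 vs cases pattern 3-4;
* extreme       - supercontrols (pattern 1, age >= 60) vs severe cases
                  (pattern 4, age < 60); age is not a covariate here since
                  the model separates on age.

Relatives (kinship coefficient >= 0.0442, i.e. up to the third degree) are
pruned per model by iteratively removing the sample with the most related
partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EXCLUDED = "EXCLUDED"

MODELS = ("continuous", "all", "two_as_control", "extreme")

KINSHIP_THRESHOLD = 0.0442


@dataclass
class ReconciledPhenotype:
    """One sample's reconciled pattern and the model-specific ages.

    ``pattern`` is 1-4 or None when the sample is excluded (no plausible
    pattern).  ``case_age`` is the lowest age at which the selected pattern
    was recorded; ``control_age_p1`` / ``control_age_p12`` are the highest
    ages at which pattern 1 / pattern <= 2 were recorded, if any.
    """

    sample_id: str
    pattern: int | None
    case_age: float | None
    control_age_p1: float | None
    control_age_p12: float | None

    @property
    def excluded(self) -> bool:
        return self.pattern is None


def reconcile_visits(sample_id: str, visits: list[tuple[float, int]]) -> ReconciledPhenotype:
    """Reconcile one sample's (age, pattern) visits, ages strictly increasing.

    If no later visit reports a lower pattern than any earlier visit, the
    most recent pattern is selected.  On improvement: with exactly 2 visits
    and |difference| <= 1 the higher pattern is used; with 3 visits a pattern
    recorded exactly twice; with 4 visits a pattern recorded exactly three
    times; otherwise the sample is excluded.
    """
    if not visits:
        raise ValueError(f"sample {sample_id}: at least one visit required")
    if len(visits) > 4:
        raise ValueError(f"sample {sample_id}: more than 4 visits")
    ages = [a for a, _ in visits]
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ValueError(f"sample {sample_id}: visit ages must be strictly increasing")
    patterns = [p for _, p in visits]
    if any(p not in (1, 2, 3, 4) for p in patterns):
        raise ValueError(f"sample {sample_id}: pattern outside 1-4")

    improvement = any(patterns[j] < max(patterns[:j]) for j in range(1, len(patterns)))
    if not improvement:
        selected: int | None = patterns[-1]
    elif len(patterns) == 2:
        selected = max(patterns) if abs(patterns[0] - patterns[1]) <= 1 else None
    elif len(patterns) == 3:
        twice = [p for p in set(patterns) if patterns.count(p) == 2]
        selected = twice[0] if twice else None
    else:
        thrice = [p for p in set(patterns) if patterns.count(p) == 3]
        selected = thrice[0] if thrice else None

    case_age = None
    if selected is not None:
        case_age = min(a for a, p in visits if p == selected)
    age_p1 = [a for a, p in visits if p == 1]
    age_p12 = [a for a, p in visits if p <= 2]
    return ReconciledPhenotype(
        sample_id=sample_id,
        pattern=selected,
        case_age=case_age,
        control_age_p1=max(age_p1) if age_p1 else None,
        control_age_p12=max(age_p12) if age_p12 else None,
    )


def reconcile_all(visits: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`reconcile_visits` to a visit table; one row per sample.

    Visits are ordered by age within sample.  Excluded samples have NaN
    pattern.
    """
    rows = []
    for sid, grp in visits.groupby("sample_id", sort=True):
        grp = grp.sort_values("age")
        rec = reconcile_visits(str(sid), list(zip(grp["age"], grp["pattern"])))
        rows.append({
            "sample_id": rec.sample_id,
            "pattern": np.nan if rec.pattern is None else rec.pattern,
            "case_age": np.nan if rec.case_age is None else rec.case_age,
            "control_age_p1": np.nan if rec.control_age_p1 is None else rec.control_age_p1,
            "control_age_p12": np.nan if rec.control_age_p12 is None else rec.control_age_p12,
        })
    return pd.DataFrame(rows)


@dataclass
class PhenotypeDesign:
    """One phenotype model's response and roster.

    ``response`` is pattern 1-4 for the continuous model, {0, 1} otherwise.
    ``age`` is the model-appropriate covariate age (None for the extreme
    model, which separates on age by construction).
    """

    model: str
    sample_ids: list[str]
    response: np.ndarray
    age: np.ndarray | None

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "response": self.response})
        if self.age is not None:
            df["age"] = self.age
        return df


def assign_model(reconciled: pd.DataFrame, model: str, age_cut: float = 60.0) -> PhenotypeDesign:
    """Build a phenotype model from reconciled (non-excluded) samples.

    Cases carry ``case_age`` as the age covariate; controls carry the
    model-appropriate control age (pattern-1 age for all/continuous/extreme,
    pattern-<=2 age for two_as_control).  The extreme model keeps only
    pattern-4 cases younger than ``age_cut`` and pattern-1 controls at least
    ``age_cut`` old, and has no age covariate.
    """
    if model not in MODELS:
        raise ValueError(f"unknown phenotype model {model!r}; want one of {MODELS}")
    df = reconciled.dropna(subset=["pattern"]).copy()
    df["pattern"] = df["pattern"].astype(int)

    if model == "extreme":
        cases = df[(df["pattern"] == 4) & (df["case_age"] < age_cut)]
        controls = df[(df["pattern"] == 1) & (df["control_age_p1"] >= age_cut)]
        ids = cases["sample_id"].tolist() + controls["sample_id"].tolist()
        y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
        return PhenotypeDesign(model, ids, y, None)

    if model == "continuous":
        y = df["pattern"].to_numpy(float)
        age = np.where(df["pattern"] == 1, df["control_age_p1"], df["case_age"])
        return PhenotypeDesign(model, df["sample_id"].tolist(), y, age.astype(float))

    if model == "all":
        y = (df["pattern"] >= 2).to_numpy(float)
        age = np.where(df["pattern"] == 1, df["control_age_p1"], df["case_age"])
        return PhenotypeDesign(model, df["sample_id"].tolist(), y, age.astype(float))

    # two_as_control
    y = (df["pattern"] >= 3).to_numpy(float)
    age = np.where(df["pattern"] <= 2, df["control_age_p12"], df["case_age"])
    return PhenotypeDesign(model, df["sample_id"].tolist(), y, age.astype(float))


def prune_kinship(
    samples: list[str],
    pairs: list[tuple[str, str, float]],
    threshold: float = KINSHIP_THRESHOLD,
) -> set[str]:
    """Greedy kinship pruning: drop maximum-degree samples until edgeless.

    Builds the relatedness graph over pairs with coefficient >= threshold
    and iteratively removes a sample with the largest number of remaining
    related partners (ties broken toward the lexicographically smallest
    sample id, for determinism).  Returns the retained sample set.
    """
    sample_set = set(samples)
    adj: dict[str, set[str]] = {}
    for a, b, k in pairs:
        if a not in sample_set or b not in sample_set:
            raise ValueError(f"kinship pair ({a}, {b}) references unknown sample")
        if k >= threshold and a != b:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    removed: set[str] = set()
    while True:
        deg = {v: len(nb) for v, nb in adj.items() if nb}
        if not deg:
            break
        top = max(deg.values())
        victim = min(v for v, d in deg.items() if d == top)
        removed.add(victim)
        for nb in adj.pop(victim):
            adj[nb].discard(victim)
    return sample_set - removed
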
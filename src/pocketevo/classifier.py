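"""Rule-based classification into the three evolutionary scenarios.

Scenario 1 (pre-existing pocket): the pocket was present and under
purifying selection long before the ligand appeared — high pocket %ID
everywhere, pocket more conserved than the rest of the molecule, low
within-branch N, ω always well below 1, no positively selected pocket
sites.  The mammalian ligand most plausibly replaced an ancestral one
of similar binding properties.

Scenario 2 (progressive acquisition): the pocket does not resemble the
mammalian one before the ligand exists (%ID 0–30), identity rises once
the ligand is present, and ω exceeds 1 in at least one ligand-present
branch — the binding site was assembled under the ligand's influence.

Scenario 3 (reshuffling): pre-ligand branches show a divergent pocket
and elevated ω, ω is above 1 in the branch where the ligand appeared
and drops to strong purifying selection afterwards, and the
within-branch N is significantly higher before the ligand than after —
an ancestral pocket was reshaped when the present ligand arrived.

Criteria are evaluated in order S1, S2, S3; the first fully satisfied
scenario wins, otherwise the call is UNCLASSIFIED.  Every criterion's
outcome and supporting numbers are kept so borderline calls are
auditable.  An undefined (NaN) ω satisfies neither "ω < x" nor "ω > x".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .branches import BranchScheme
from .indexes import IndexTable


@dataclass
class Thresholds:
    """Decision thresholds of the scenario rules (defaults per the study)."""

    omega_positive: float = 1.0  # "> 1" = positive selection
    omega_low: float = 1.0  # "< 1" = purifying
    pocket_id_low_max: float = 30.0  # pre-ligand %ID ceiling for S2/S3 ("0 to 30%")
    pocket_id_high_min: float = 40.0  # S1 %ID floor ("minimum of 40 to 50%")
    n_low_max: float = 20.0  # "always low (inferior to 20)"
    alpha: float = 0.05
    n_contrast_alpha: float = 0.05
    trend_tol: float = 5.0  # slack (%ID points) for the increasing-trend test
    s3_terminal_min: float = 90.0  # "very high as it reaches the mammalian branch"

    def __post_init__(self) -> None:
        for name in ("omega_positive", "omega_low", "pocket_id_low_max",
                     "pocket_id_high_min", "n_low_max", "alpha", "n_contrast_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.pocket_id_low_max >= self.pocket_id_high_min:
            raise ValueError("pocket_id_low_max must be below pocket_id_high_min")


@dataclass
class Criterion:
    id: str
    description: str
    satisfied: bool
    values: dict = field(default_factory=dict)


@dataclass
class ScenarioCall:
    label: str  # S1 | S2 | S3 | UNCLASSIFIED
    criteria: list[Criterion]
    notes: str = ""

    def criterion(self, cid: str) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def to_json(self, path) -> None:
        doc = {
            "label": self.label,
            "notes": self.notes,
            "criteria": [
                {
                    "id": c.id,
                    "description": c.description,
                    "satisfied": bool(c.satisfied),
                    "values": _jsonable(c.values),
                }
                for c in self.criteria
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _lt(value: float, bound: float) -> bool:
    """NaN-safe strict less-than (NaN satisfies nothing)."""
    return not math.isnan(value) and value < bound


def _gt(value: float, bound: float) -> bool:
    return not math.isnan(value) and value > bound


def trend_increasing(values: list[float], tol: float) -> bool:
    """Noise-robust 'identity increases toward mammals' check.

    True when the terminal (mammalian-side) value is within ``tol`` of
    the maximum and above the first value.  Exact monotonicity is not
    required: group means of a ~25-residue pocket carry several points
    of sampling noise, which would break a strict check on genuinely
    increasing series.
    """
    vals = [v for v in values if not math.isnan(v)]
    if len(vals) != len(values) or not vals:
        return False
    if len(vals) == 1:
        return True
    return vals[-1] >= max(vals) - tol and vals[-1] > vals[0]


def classify(table: IndexTable, scheme: BranchScheme, th: Thresholds | None = None) -> ScenarioCall:
    """Apply the three-scenario decision rules to an index table."""
    th = th or Thresholds()
    df = table.table
    missing = [c for c in ("pct_id_pocket", "omega_pocket", "n_nonsyn", "direction") if c not in df]
    if missing:
        raise ValueError(f"malformed index table; missing columns {missing}")

    sampled = df[df["n_species"] > 0]
    pre = sampled[~sampled["ligand_present"].astype(bool)]
    post = sampled[sampled["ligand_present"].astype(bool)]
    if len(pre) < 2 or len(post) < 1:
        return ScenarioCall(
            label="UNCLASSIFIED",
            criteria=[],
            notes=(
                f"need >=2 pre-ligand and >=1 post-ligand sampled groups "
                f"(have {len(pre)} and {len(post)}); receptor cannot be distributed"
            ),
        )

    ligand_group = scheme.group_names[scheme.ligand_group_index]
    after = post[post.index != ligand_group]  # strictly after the appearance branch
    pocket_hits = table.positive_pocket_sites or []

    crit: list[Criterion] = []

    def add(cid, desc, ok, **values):
        crit.append(Criterion(cid, desc, bool(ok), values))
        return bool(ok)

    omega = sampled["omega_pocket"]
    pid = sampled["pct_id_pocket"]
    nn = sampled["n_nonsyn"]

    # ---- Scenario 1: pocket present and purifying throughout -------------
    s1 = add("S1a", "pocket omega below threshold in every branch",
             all(_lt(v, th.omega_low) for v in omega),
             omega=dict(omega))
    s1 &= add("S1b", "pocket %ID at or above the floor in every branch",
              all(not math.isnan(v) and v >= th.pocket_id_high_min for v in pid),
              pct_id_pocket=dict(pid), floor=th.pocket_id_high_min)
    s1 &= add("S1c", "pocket significantly more conserved than whole sequence in every branch",
              all(sampled["direction"] == "pocket-higher"),
              direction=dict(sampled["direction"]), p_value=dict(sampled["p_value"]))
    s1 &= add("S1d", "within-branch N low in every branch",
              all(v <= th.n_low_max for v in nn), n=dict(nn), max=th.n_low_max)
    s1 &= add("S1e", "no positively selected pocket site",
              len(pocket_hits) == 0, positive_pocket_sites=list(pocket_hits))
    if s1:
        return ScenarioCall(label="S1", criteria=crit)

    # ---- Scenario 2: progressive pocket acquisition -----------------------
    post_ids = [post.loc[g, "pct_id_pocket"] for g in post.index]
    s2 = add("S2a", "pre-ligand pocket %ID at or below the ceiling",
             all(not math.isnan(v) and v <= th.pocket_id_low_max for v in pre["pct_id_pocket"]),
             pre_pct_id=dict(pre["pct_id_pocket"]), ceiling=th.pocket_id_low_max)
    s2 &= add("S2b", "pocket %ID increases across ligand-present branches",
              trend_increasing(post_ids, th.trend_tol), post_pct_id=list(post_ids))
    s2 &= add("S2c", "omega above threshold in at least one ligand-present branch",
              any(_gt(v, th.omega_positive) for v in post["omega_pocket"]),
              post_omega=dict(post["omega_pocket"]))
    s2 &= add("S2d", "pocket never significantly more conserved than whole sequence",
              all(sampled["direction"] != "pocket-higher"),
              direction=dict(sampled["direction"]))
    s2 &= add("S2e", "within-branch N low in every branch",
              all(v <= th.n_low_max for v in nn), n=dict(nn), max=th.n_low_max)
    s2 &= add("S2f", "no positively selected pocket site",
              len(pocket_hits) == 0, positive_pocket_sites=list(pocket_hits))
    if s2:
        return ScenarioCall(label="S2", criteria=crit)

    # ---- Scenario 3: pocket reshuffled at ligand appearance ---------------
    s3 = add("S3a", "pre-ligand pocket %ID at or below the ceiling",
             all(not math.isnan(v) and v <= th.pocket_id_low_max for v in pre["pct_id_pocket"]),
             pre_pct_id=dict(pre["pct_id_pocket"]), ceiling=th.pocket_id_low_max)
    s3 &= add("S3b", "pocket %ID increases post-ligand and is very high in the terminal branch",
              trend_increasing(post_ids, th.trend_tol)
              and not math.isnan(post_ids[-1]) and post_ids[-1] >= th.s3_terminal_min,
              post_pct_id=list(post_ids), terminal_min=th.s3_terminal_min)
    s3 &= add("S3c", "omega below threshold in branches after the ligand appeared",
              all(_lt(v, th.omega_low) for v in after["omega_pocket"]),
              after_omega=dict(after["omega_pocket"]))
    s3 &= add("S3d", "omega above threshold in the ligand-appearance branch",
              ligand_group in post.index and _gt(post.loc[ligand_group, "omega_pocket"], th.omega_positive),
              appearance_group=ligand_group,
              appearance_omega=post.loc[ligand_group, "omega_pocket"] if ligand_group in post.index else float("nan"))
    pre_n = pre["n_nonsyn"].to_numpy(dtype=float)
    post_n = post["n_nonsyn"].to_numpy(dtype=float)
    if len(pre_n) >= 2 and len(post_n) >= 2 and (pre_n.std() > 0 or post_n.std() > 0):
        p_contrast = float(
            stats.ttest_ind(pre_n, post_n, equal_var=False, alternative="greater").pvalue
        )
    else:
        p_contrast = float("nan")
    s3 &= add("S3e", "within-branch N significantly higher pre-ligand than post-ligand",
              _lt(p_contrast, th.n_contrast_alpha),
              pre_n=list(pre_n), post_n=list(post_n), p=p_contrast)
    s3 &= add("S3f", "no positively selected pocket site",
              len(pocket_hits) == 0, positive_pocket_sites=list(pocket_hits))
    if s3:
        return ScenarioCall(label="S3", criteria=crit)

    return ScenarioCall(label="UNCLASSIFIED", criteria=crit,
                        notes="no scenario's full criteria set is satisfied")
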
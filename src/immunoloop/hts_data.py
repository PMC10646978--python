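"""Plate normalization, replicate merging, viability filtering, and the 12
functional goals over the 8 agonist-pathway combinations.

Readings arrive as long-format records (plate_id, well, molecule_id,
channel, agonist, raw_value).  Every well is normalized by the mean of the
same-plate positive controls for its (channel, agonist) pair, replicate
plates are averaged, and the standard error of the mean is propagated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

NFKB = "NFKB"
IRF = "IRF"
PATHWAYS = (NFKB, IRF)

LPS = "LPS"
MPLA = "MPLA"
CPG = "CpG"
CGAMP = "cGAMP"
NO_AGONIST = "NONE"
AGONISTS = (LPS, MPLA, CPG, CGAMP)

CONTROL_POSITIVE = "CONTROL_POSITIVE"
CONTROL_MODULATOR_ONLY = "CONTROL_MODULATOR_ONLY"

#: the six measured goal channels (pathway, agonist)
GOAL_CHANNELS = (
    (NFKB, LPS), (NFKB, MPLA), (NFKB, CPG),
    (IRF, LPS), (IRF, MPLA), (IRF, CGAMP),
)

#: the eight reporting combinations: six specialists + two generalists
GENERALIST = "generalist"
COMBINATIONS = GOAL_CHANNELS + ((NFKB, GENERALIST), (IRF, GENERALIST))

ENHANCE = "ENHANCE"
SUPPRESS = "SUPPRESS"

VIABILITY_THRESHOLD = 0.70


class NormalizationError(ValueError):
    """Positive controls missing or degenerate on a plate."""


class DataError(ValueError):
    """Profile data violates a precondition (e.g. nonpositive fold)."""


@dataclass(frozen=True)
class GoalSpec:
    """One of the 12 signed functional objectives."""

    goal_id: str
    pathway: str
    agonists: tuple[str, ...]
    direction: str

    @property
    def is_generalist(self) -> bool:
        return len(self.agonists) > 1

    @property
    def combination(self) -> tuple[str, str]:
        return (self.pathway, GENERALIST if self.is_generalist else self.agonists[0])


def all_goals() -> list[GoalSpec]:
    """The 12 goals: NF-κB {LPS,MPLA,CpG,generalist} x {enhance,suppress} plus
    IRF {LPS,MPLA,cGAMP,generalist} enhance-only."""
    goals = []
    for ag in (LPS, MPLA, CPG):
        for d in (ENHANCE, SUPPRESS):
            goals.append(GoalSpec(f"NFKB_{ag}_{d}", NFKB, (ag,), d))
    for d in (ENHANCE, SUPPRESS):
        goals.append(GoalSpec(f"NFKB_generalist_{d}", NFKB, (LPS, MPLA, CPG), d))
    for ag in (LPS, MPLA, CGAMP):
        goals.append(GoalSpec(f"IRF_{ag}_ENHANCE", IRF, (ag,), ENHANCE))
    goals.append(GoalSpec("IRF_generalist_ENHANCE", IRF, (LPS, MPLA, CGAMP), ENHANCE))
    assert len(goals) == 12
    return goals


def specialist_goals() -> list[GoalSpec]:
    return [g for g in all_goals() if not g.is_generalist]


@dataclass
class ModulationProfile:
    """Per-molecule fold change ± error per measured channel, plus viability."""

    molecule_id: str
    fold: dict = field(default_factory=dict)        # (pathway, agonist) -> mean fold
    fold_err: dict = field(default_factory=dict)    # matching standard errors
    confluency_scores: Optional[tuple[float, float]] = None
    viable: Optional[bool] = None                   # None = viability unknown
    incomplete: bool = False

    def has_channels(self, channels: Iterable[tuple[str, str]]) -> bool:
        return all(c in self.fold for c in channels)


def normalize_plate(readings: pd.DataFrame) -> pd.DataFrame:
    """Fold change per well: raw / mean(same plate+channel+agonist positive controls).

    Modulator-only wells (agonist == NONE) are normalized against the
    modulator-free wells of the same plate+channel marked CONTROL_POSITIVE
    with agonist NONE (resting cells) and flow through the same arithmetic.
    Returns a frame with columns plate_id, molecule_id, channel, agonist, fold.
    """
    req = {"plate_id", "molecule_id", "channel", "agonist", "raw_value"}
    missing = req - set(readings.columns)
    if missing:
        raise NormalizationError(f"missing reading columns: {sorted(missing)}")
    if (readings["raw_value"] < 0).any():
        raise DataError("negative raw_value encountered")

    out = []
    for (plate, channel, agonist), grp in readings.groupby(
            ["plate_id", "channel", "agonist"], sort=False):
        ctrl = grp[grp["molecule_id"] == CONTROL_POSITIVE]["raw_value"]
        if ctrl.empty or ctrl.mean() <= 0:
            raise NormalizationError(
                f"plate {plate!r}: no usable positive controls for "
                f"({channel}, {agonist})")
        denom = float(ctrl.mean())
        samples = grp[grp["molecule_id"] != CONTROL_POSITIVE]
        folds = samples["raw_value"].to_numpy(dtype=float) / denom
        out.append(pd.DataFrame({
            "plate_id": plate,
            "molecule_id": samples["molecule_id"].to_numpy(),
            "channel": channel,
            "agonist": agonist,
            "fold": folds,
        }))
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["plate_id", "molecule_id", "channel", "agonist", "fold"])


def replicate_sem(values: Sequence[float]) -> float:
    """Standard deviation of the mean: sample std / sqrt(n).  For n=2: |a-b|/2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 0.0
    return float(v.std(ddof=1) / math.sqrt(v.size))


def merge_replicates(folds: pd.DataFrame, n_replicates: int = 2,
                     strict: bool = True) -> list[ModulationProfile]:
    """Average replicate plate folds into per-molecule profiles with errors.

    ``folds`` is the output of :func:`normalize_plate` over all replicate
    plates.  Molecules with fewer than ``n_replicates`` measurements on any
    channel are flagged ``incomplete`` (and excluded from modeling upstream)
    rather than dropped.
    """
    profiles: dict[str, ModulationProfile] = {}
    for (mol, channel, agonist), grp in folds.groupby(
            ["molecule_id", "channel", "agonist"], sort=False):
        if mol == CONTROL_MODULATOR_ONLY:
            continue
        prof = profiles.setdefault(mol, ModulationProfile(molecule_id=mol))
        vals = grp["fold"].to_numpy(dtype=float)
        if strict and len(vals) != n_replicates:
            prof.incomplete = True
        prof.fold[(channel, agonist)] = float(vals.mean())
        prof.fold_err[(channel, agonist)] = replicate_sem(vals)
    return list(profiles.values())


def log2_fold(fold: float, fold_err: float = 0.0) -> tuple[float, float]:
    """log2 transform with delta-method error propagation: err/(fold*ln2)."""
    if fold <= 0:
        raise DataError(f"nonpositive fold change {fold}")
    return math.log2(fold), fold_err / (fold * math.log(2))


def apply_viability_filter(
        profiles: Iterable[ModulationProfile],
        confluency: dict[str, tuple[float, float]],
        threshold: float = VIABILITY_THRESHOLD,
) -> tuple[list[ModulationProfile], list[ModulationProfile]]:
    """Partition into (viable, non-viable).  viable <=> min(mask scores) > 0.70.

    Molecules with missing confluency data are marked viability-unknown
    (``viable is None``) and returned with the non-viable partition; nothing
    is deleted.
    """
    viable, nonviable = [], []
    for prof in profiles:
        scores = confluency.get(prof.molecule_id)
        prof.confluency_scores = scores
        if scores is None:
            prof.viable = None
            nonviable.append(prof)
            continue
        prof.viable = min(scores) > threshold
        (viable if prof.viable else nonviable).append(prof)
    return viable, nonviable


def goal_base(profile: ModulationProfile, goal: GoalSpec,
              aggregate: str = "arithmetic") -> float:
    """Fold (specialist) or mean fold over the goal's agonist set (generalist)."""
    missing = [a for a in goal.agonists if (goal.pathway, a) not in profile.fold]
    if missing:
        raise DataError(
            f"{profile.molecule_id}: missing folds for {goal.pathway} x {missing}")
    folds = [profile.fold[(goal.pathway, a)] for a in goal.agonists]
    if any(f <= 0 for f in folds):
        raise DataError(f"{profile.molecule_id}: nonpositive fold in {goal.goal_id}")
    if aggregate == "arithmetic":
        return float(np.mean(folds))
    if aggregate == "geometric":
        return float(np.exp(np.mean(np.log(folds))))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def goal_score(profile: ModulationProfile, goal: GoalSpec,
               aggregate: str = "arithmetic") -> float:
    """Signed log2 target: +log2(base) for ENHANCE, -log2(base) for SUPPRESS.

    Larger is always better for the optimizer.
    """
    score = math.log2(goal_base(profile, goal, aggregate))
    return score if goal.direction == ENHANCE else -score


def count_modulators(profiles: Iterable[ModulationProfile], threshold: float,
                     goals: Optional[Sequence[GoalSpec]] = None,
                     aggregate: str = "arithmetic") -> int:
    """Viable molecules with >= threshold-fold enhancement or <= 1/threshold
    suppression in at least one goal; each molecule counted once."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    goals = list(goals) if goals is not None else all_goals()
    count = 0
    for prof in profiles:
        if not prof.viable:
            continue
        for goal in goals:
            if not prof.has_channels((goal.pathway, a) for a in goal.agonists):
                continue
            base = goal_base(prof, goal, aggregate)
            if goal.direction == ENHANCE and base >= threshold:
                count += 1
                break
            if goal.direction == SUPPRESS and base <= 1.0 / threshold:
                count += 1
                break
    return count


def top_performers(profiles: Sequence[ModulationProfile], goal: GoalSpec,
                   k: int = 1, aggregate: str = "arithmetic"
                   ) -> tuple[ModulationProfile, float]:
    """The k-th best viable molecule under ``goal_score`` (1-based rank).

    Ties broken by molecule_id lexicographic order.  Returns the profile and
    its *fold* base (not the signed score).
    """
    ranked = sorted(
        ((goal_score(p, goal, aggregate), p) for p in profiles
         if p.viable and p.has_channels((goal.pathway, a) for a in goal.agonists)),
        key=lambda t: (-t[0], t[1].molecule_id))
    if k < 1 or k > len(ranked):
        raise IndexError(f"rank {k} outside 1..{len(ranked)} viable profiles")
    _, prof = ranked[k - 1]
    return prof, goal_base(prof, goal, aggregate)


# ---------------------------------------------------------------------------
# CSV interchange (the dialect the synthetic generator also emits)

def profiles_to_frame(profiles: Iterable[ModulationProfile]) -> pd.DataFrame:
    """Wide CSV layout: one row per molecule, fold/err per channel, viability."""
    rows = []
    for p in profiles:
        row: dict = {"id": p.molecule_id}
        for (path, ag) in GOAL_CHANNELS:
            key = f"{path}_{ag}"
            row[f"fold_{key}"] = p.fold.get((path, ag), np.nan)
            row[f"err_{key}"] = p.fold_err.get((path, ag), np.nan)
        if p.confluency_scores is not None:
            row["confluency_1"], row["confluency_2"] = p.confluency_scores
        else:
            row["confluency_1"] = row["confluency_2"] = np.nan
        row["viable"] = p.viable
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> list[ModulationProfile]:
    profiles = []
    for _, row in df.iterrows():
        p = ModulationProfile(molecule_id=str(row["id"]))
        for (path, ag) in GOAL_CHANNELS:
            key = f"{path}_{ag}"
            fold = row.get(f"fold_{key}", np.nan)
            if pd.notna(fold):
                p.fold[(path, ag)] = float(fold)
                err = row.get(f"err_{key}", 0.0)
                p.fold_err[(path, ag)] = float(err) if pd.notna(err) else 0.0
        c1, c2 = row.get("confluency_1", np.nan), row.get("confluency_2", np.nan)
        if pd.notna(c1) and pd.notna(c2):
            p.confluency_scores = (float(c1), float(c2))
            p.viable = min(p.confluency_scores) > VIABILITY_THRESHOLD
        profiles.append(p)
    return profiles
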
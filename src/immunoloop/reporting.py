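"""Campaign-level summary statistics recomputed from results CSVs.

Summaries are pure functions of the input files: identical inputs produce
identical reports.  The profile CSV dialect is the one written by
``hts_data.profiles_to_frame`` (optionally with ``smiles`` and ``round``
columns added).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from immunoloop import chemlib, hts_data
from immunoloop.hts_data import all_goals


class SchemaError(ValueError):
    """A results CSV is missing required columns."""


_REQUIRED = ["id"] + [f"fold_{p}_{a}" for p, a in hts_data.GOAL_CHANNELS]


@dataclass
class CampaignSummary:
    n_screened: int
    n_viable: int
    n_nonviable: int
    n_viability_unknown: int
    n_distinct_viable_merged: Optional[int]
    sampled_fraction: Optional[float]
    threshold_counts: dict               # {1.5: n, 2: n, 5: n, 10: n}
    top_k_folds: pd.DataFrame            # goal_id, k, molecule_id, fold
    novelty: Optional[dict] = None       # summary of max-Tanimoto-to-bootstrap
    n_retained_fragment_features: Optional[int] = None

    def to_dict(self) -> dict:
        d = {
            "n_screened": self.n_screened,
            "n_viable": self.n_viable,
            "n_nonviable": self.n_nonviable,
            "n_viability_unknown": self.n_viability_unknown,
            "n_distinct_viable_merged": self.n_distinct_viable_merged,
            "sampled_fraction": self.sampled_fraction,
            "threshold_counts": {str(k): v for k, v in self.threshold_counts.items()},
            "top_k_folds": self.top_k_folds.to_dict(orient="records"),
            "novelty": self.novelty,
            "n_retained_fragment_features": self.n_retained_fragment_features,
        }
        return d

    def to_markdown(self) -> str:
        lines = ["# Campaign summary", ""]
        lines.append(f"- screened: {self.n_screened}")
        lines.append(f"- viable: {self.n_viable}  non-viable: {self.n_nonviable}"
                     f"  unknown: {self.n_viability_unknown}")
        if self.n_distinct_viable_merged is not None:
            lines.append(f"- distinct viable after merge/dedup: "
                         f"{self.n_distinct_viable_merged}")
        if self.sampled_fraction is not None:
            lines.append(f"- sampled fraction of library: "
                         f"{100 * self.sampled_fraction:.2f}%")
        lines.append("")
        lines.append("| threshold | modulators |")
        lines.append("|---|---|")
        for k, v in self.threshold_counts.items():
            lines.append(f"| {k}x | {v} |")
        lines.append("")
        lines.append(self.top_k_folds.to_markdown(index=False))
        return "\n".join(lines)


def _load_profile_frame(paths: Sequence) -> pd.DataFrame:
    frames = []
    for p in paths:
        df = pd.read_csv(p)
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"{p}: missing columns {missing}")
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    return merged


def summarize_campaign(results: Sequence, bootstrap=None,
                       library_size: Optional[int] = None,
                       ks: Sequence[int] = (1, 5, 20),
                       thresholds: Sequence[float] = (1.5, 2.0, 5.0, 10.0),
                       aggregate: str = "arithmetic",
                       compute_fragment_filter: bool = False) -> CampaignSummary:
    """Deterministically recompute every summary statistic from profile CSVs.

    ``results`` is a list of per-round profile CSV paths; ``bootstrap`` an
    optional prior-screen CSV (same dialect, with a ``smiles`` column for
    novelty/dedup analysis).  Merged-distinct counting deduplicates by
    canonical SMILES when a ``smiles`` column is available, and applies the
    viability filter before counting.
    """
    df = _load_profile_frame(results)
    profiles = hts_data.profiles_from_frame(df)
    n_screened = len(profiles)
    n_viable = sum(1 for p in profiles if p.viable is True)
    n_nonviable = sum(1 for p in profiles if p.viable is False)
    n_unknown = n_screened - n_viable - n_nonviable

    goals = all_goals()
    counts = {t: hts_data.count_modulators(profiles, t, goals, aggregate)
              for t in thresholds}

    rows = []
    viable_profiles = [p for p in profiles if p.viable]
    for goal in goals:
        eligible = [p for p in viable_profiles
                    if p.has_channels((goal.pathway, a) for a in goal.agonists)]
        for k in ks:
            if k > len(eligible):
                continue
            prof, fold = hts_data.top_performers(eligible, goal, k, aggregate)
            rows.append({"goal_id": goal.goal_id, "k": k,
                         "molecule_id": prof.molecule_id,
                         "fold": fold})
    top_k = pd.DataFrame(rows)

    boot_df = None
    if bootstrap is not None:
        boot_df = pd.read_csv(bootstrap)

    n_distinct = None
    if "smiles" in df.columns:
        merged = df
        if boot_df is not None and "smiles" in boot_df.columns:
            merged = pd.concat([df, boot_df], ignore_index=True)
        viable_mask = merged[["confluency_1", "confluency_2"]].min(axis=1) > \
            hts_data.VIABILITY_THRESHOLD
        viable_smiles = merged.loc[viable_mask, "smiles"].dropna()
        canon = set()
        for smi in viable_smiles:
            try:
                canon.add(chemlib.canonical_smiles(smi))
            except chemlib.EncodingError:
                pass
        n_distinct = len(canon)

    sampled = n_screened / library_size if library_size else None

    novelty = None
    if (boot_df is not None and "smiles" in boot_df.columns
            and "smiles" in df.columns):
        strong_ids = set()
        by_id = {p.molecule_id: p for p in viable_profiles}
        for goal in goals:
            for p in viable_profiles:
                if not p.has_channels((goal.pathway, a) for a in goal.agonists):
                    continue
                base = hts_data.goal_base(p, goal, aggregate)
                if ((goal.direction == hts_data.ENHANCE and base >= 2.0)
                        or (goal.direction == hts_data.SUPPRESS and base <= 0.5)):
                    strong_ids.add(p.molecule_id)
        sub = df[df["id"].astype(str).isin(strong_ids)].dropna(subset=["smiles"])
        if len(sub) and len(boot_df):
            queries = [chemlib.Molecule.from_smiles(str(r["id"]), r["smiles"])
                       for _, r in sub.iterrows()]
            refs = [chemlib.Molecule.from_smiles(f"B{i}", s)
                    for i, s in enumerate(boot_df["smiles"].dropna())]
            sim = chemlib.nearest_training_similarity(queries, refs)
            q = sim["similarity"]
            novelty = {"n": int(len(q)), "min": float(q.min()),
                       "median": float(q.median()), "max": float(q.max()),
                       "frac_below_0.4": float((q < 0.4).mean())}

    n_features = None
    if compute_fragment_filter and "smiles" in df.columns:
        from immunoloop import design_rules
        frames = [df] if boot_df is None else [df, boot_df]
        merged = pd.concat(frames, ignore_index=True)
        viable_mask = merged[["confluency_1", "confluency_2"]].min(axis=1) > \
            hts_data.VIABILITY_THRESHOLD
        mols, seen = [], set()
        for i, row in merged[viable_mask].dropna(subset=["smiles"]).iterrows():
            try:
                canon = chemlib.canonical_smiles(row["smiles"])
            except chemlib.EncodingError:
                continue
            if canon in seen:
                continue
            seen.add(canon)
            mols.append(chemlib.Molecule(id=f"M{i}", smiles=canon,
                                         components=[canon],
                                         selfies_tokens=None))
        M = design_rules.featurize_fragments(mols)
        n_features = len(design_rules.filter_features(M).columns)

    return CampaignSummary(
        n_screened=n_screened, n_viable=n_viable, n_nonviable=n_nonviable,
        n_viability_unknown=n_unknown, n_distinct_viable_merged=n_distinct,
        sampled_fraction=sampled, threshold_counts=counts, top_k_folds=top_k,
        novelty=novelty, n_retained_fragment_features=n_features)
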
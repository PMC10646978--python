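"""Acquisition scoring, multi-objective Kriging-believer batch construction,
round orchestration, and the two convergence monitors.

The batch loop follows the screening protocol: each of the 12 goal models
nominates its top-EI untested, not-yet-selected candidate; the (<=12)
nominees, duplicates merged, are appended to *every* model with that model's
own posterior mean as a believed label; posteriors are updated by rank-1
Cholesky updates and the models polled again until the batch is full.
Believed labels never survive a round — models are always refitted from real
measurements only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from immunoloop import hts_data
from immunoloop.chemlib import CandidateLibrary, Molecule
from immunoloop.embedding import LatentSpace
from immunoloop.hts_data import GoalSpec, ModulationProfile, goal_score
from immunoloop.surrogate import (CandidatePosterior, GoalDataset, GprModel,
                                  _sqdist, cv_mae, fit_gpr)

logger = logging.getLogger(__name__)


class IntegrityError(RuntimeError):
    """Campaign state violates a data-integrity guard."""


# ---------------------------------------------------------------------------
# acquisition + convergence primitives

def expected_improvement(mean, var, f_star: float, xi: float = 0.0):
    """EI = (mu - f* - xi) Phi(u) + sigma phi(u), u = (mu - f* - xi)/sigma.

    At sigma = 0 this degenerates to max(0, mu - f* - xi).  Vectorized;
    NaN inputs are rejected.
    """
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.isnan(mean).any() or np.isnan(var).any():
        raise ValueError("NaN in EI inputs")
    if (var < 0).any():
        raise ValueError("negative variance in EI inputs")
    if xi < 0:
        raise ValueError("xi must be >= 0")
    sigma = np.sqrt(var)
    delta = mean - f_star - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(sigma > 0, delta / np.where(sigma > 0, sigma, 1.0), 0.0)
        ei = np.where(sigma > 0,
                      delta * norm.cdf(u) + sigma * norm.pdf(u),
                      np.maximum(delta, 0.0))
    return np.maximum(ei, 0.0)


def bhattacharyya_gaussian(mu1, var1, mu2, var2):
    """Closed-form Bhattacharyya distance between univariate Gaussians:

    D_B = (mu1-mu2)^2 / (4 (var1+var2)) + 0.5 ln((var1+var2) / (2 s1 s2)).
    """
    mu1, var1 = np.asarray(mu1, float), np.asarray(var1, float)
    mu2, var2 = np.asarray(mu2, float), np.asarray(var2, float)
    if (var1 <= 0).any() or (var2 <= 0).any():
        raise ValueError("variances must be positive")
    s = var1 + var2
    return 0.25 * (mu1 - mu2) ** 2 / s + 0.5 * np.log(s / (2.0 * np.sqrt(var1 * var2)))


# ---------------------------------------------------------------------------
# configuration / result types

@dataclass
class SelectionConfig:
    batch_size: int = 720
    ei_xi: float = 0.0
    believer_policy: str = "POSTERIOR_MEAN"
    seed: int = 0
    round_index: int = 0
    posterior_dtype: str = "float64"   # "float32" trades 1e-6 accuracy for speed

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.ei_xi < 0:
            raise ValueError("ei_xi must be >= 0")
        if self.believer_policy != "POSTERIOR_MEAN":
            raise ValueError(f"unknown believer policy {self.believer_policy!r}")


@dataclass
class AcquisitionBatch:
    round_index: int
    entries: list[dict]                    # molecule_id, source_goal, ei_value, believed_value
    selected_ids: list[str]                # ordered, de-duplicated
    complete: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


@dataclass
class StopSet:
    """Fixed random subset of untested candidates, drawn once and frozen."""

    ids: tuple[str, ...]
    seed: int
    embedding_hash: str = ""

    @classmethod
    def draw(cls, untested_ids: Sequence[str], size: int, seed: int,
             latent: Optional[LatentSpace] = None) -> "StopSet":
        pool = sorted(untested_ids)
        rng = np.random.default_rng(seed)
        size = min(size, len(pool))
        picks = rng.choice(len(pool), size=size, replace=False)
        return cls(ids=tuple(pool[i] for i in sorted(picks)), seed=seed,
                   embedding_hash=latent.content_hash() if latent else "")


@dataclass
class ConvergenceReport:
    round_index: int
    stabilizing: Optional[pd.DataFrame] = None   # goal_id, mean_db, se_db
    cv: Optional[pd.DataFrame] = None            # goal_id, mae, fold_std


def stabilizing_predictions(models_prev: dict, models_curr: dict,
                            stop: StopSet, latent: LatentSpace) -> pd.DataFrame:
    """Per-goal mean Bhattacharyya distance +/- standard error between the two
    rounds' posteriors over the stop set."""
    if stop.embedding_hash and stop.embedding_hash != latent.content_hash():
        raise IntegrityError("stop-set embedding hash mismatch")
    if set(models_prev) != set(models_curr):
        raise IntegrityError("goal sets differ between rounds")
    X = latent.subset(list(stop.ids))
    rows = []
    for goal_id in models_curr:
        p1 = models_prev[goal_id].predict(X)
        p2 = models_curr[goal_id].predict(X)
        db = bhattacharyya_gaussian(p1.mean, np.maximum(p1.var, 1e-12),
                                    p2.mean, np.maximum(p2.var, 1e-12))
        rows.append({"goal_id": goal_id, "mean_db": float(db.mean()),
                     "se_db": float(db.std() / math.sqrt(db.size))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kriging-believer batch construction

def kriging_believer_batch(models: dict, cand_ids: Sequence[str],
                           X_cand: np.ndarray, cfg: SelectionConfig,
                           f_star: Optional[dict] = None) -> AcquisitionBatch:
    """Select >= ``cfg.batch_size`` candidates by the multi-objective
    Kriging-believer loop over the given (untested) candidate pool.

    ``models`` maps goal_id -> conditioned :class:`GprModel`; ``f_star`` maps
    goal_id -> best *real* observed target (defaults to the max training
    label of each model — believed points never move it).
    """
    cand_ids = list(cand_ids)
    X_cand = np.atleast_2d(np.asarray(X_cand, dtype=float))
    m = len(cand_ids)
    if m != X_cand.shape[0]:
        raise ValueError("candidate ids and coordinates disagree")
    if f_star is None:
        f_star = {gid: float((mdl._y_std_units * mdl._y_std + mdl._y_mean).max())
                  for gid, mdl in models.items()}

    goal_order = list(models)
    # shared training set => one distance matrix for all posteriors
    shared_X = None
    D_shared = None
    if all(models[g].X is models[goal_order[0]].X for g in goal_order):
        shared_X = models[goal_order[0]].X
        D_shared = _sqdist(shared_X, X_cand)
    posteriors = {g: CandidatePosterior(models[g], X_cand, D_train_cand=D_shared,
                                        capacity=cfg.batch_size + 16,
                                        dtype=np.dtype(cfg.posterior_dtype))
                  for g in goal_order}
    cand_sqnorm = np.einsum("ij,ij->i", X_cand, X_cand)

    available = np.ones(m, dtype=bool)
    selected: list[str] = []
    sel_index: dict[str, int] = {}
    entries: list[dict] = []
    complete = True

    while len(selected) < cfg.batch_size:
        if not available.any():
            complete = False
            warnings.warn(
                f"candidate pool exhausted at {len(selected)} < "
                f"{cfg.batch_size}; returning partial batch")
            break
        sweep_nominees: dict[int, dict] = {}
        cached = {g: posteriors[g].posterior() for g in goal_order}
        for g in goal_order:
            pred = cached[g]
            ei = expected_improvement(pred.mean, pred.var, f_star[g], cfg.ei_xi)
            ei = np.where(available, ei, -np.inf)
            j = int(ei.argmax())
            if not np.isfinite(ei[j]):
                continue
            if j not in sweep_nominees:   # duplicates within a sweep merged
                sweep_nominees[j] = {
                    "molecule_id": cand_ids[j], "source_goal": g,
                    "ei_value": float(ei[j]),
                    "believed_value": float(pred.mean[j])}
        if not sweep_nominees:
            complete = False
            break
        for j, entry in sweep_nominees.items():
            available[j] = False
            sel_index[cand_ids[j]] = len(selected)
            selected.append(cand_ids[j])
            entries.append(entry)
            # squared distances from the nominee to all candidates, shared
            d_row = cand_sqnorm + cand_sqnorm[j] - 2.0 * (X_cand @ X_cand[j])
            np.maximum(d_row, 0.0, out=d_row)
            # every model believes its own posterior mean at the nominee
            for g in goal_order:
                believed = float(cached[g].mean[j])
                posteriors[g].add_believer(j, believed, d_row=d_row)

    return AcquisitionBatch(round_index=cfg.round_index, entries=entries,
                            selected_ids=selected, complete=complete)


# ---------------------------------------------------------------------------
# round orchestration

def build_goal_datasets(latent: LatentSpace,
                        profiles: dict[str, ModulationProfile],
                        goals: Sequence[GoalSpec],
                        aggregate: str = "arithmetic") -> dict[str, GoalDataset]:
    """One dataset per goal from all labeled, complete, embeddable profiles."""
    datasets = {}
    for goal in goals:
        ids, ys = [], []
        for mol_id, prof in profiles.items():
            if prof.incomplete or mol_id not in latent._index:
                continue
            if not prof.has_channels((goal.pathway, a) for a in goal.agonists):
                continue
            ids.append(mol_id)
            ys.append(goal_score(prof, goal, aggregate))
        X = latent.subset(ids)
        datasets[goal.goal_id] = GoalDataset(goal.goal_id, ids, X, np.asarray(ys))
    return datasets


@dataclass
class RoundResult:
    round_index: int
    batch: AcquisitionBatch
    convergence: ConvergenceReport
    models: dict = field(repr=False, default_factory=dict)


class Campaign:
    """Active-learning campaign: frozen embedding, accumulating real labels,
    per-round model refits and Kriging-believer batch selection.

    Convergence is reported, never auto-acted-on; the caller decides when to
    stop.
    """

    def __init__(self, library: CandidateLibrary, latent: LatentSpace,
                 goals: Optional[Sequence[GoalSpec]] = None,
                 batch_size: int = 720, ei_xi: float = 0.0, seed: int = 0,
                 hyper_strategy: str = "mll", n_restarts: int = 3,
                 refit_hyperparameters: bool = True,
                 stop_set_size: int = 1000,
                 compute_cv: bool = False,
                 aggregate: str = "arithmetic",
                 posterior_dtype: str = "float64"):
        self.library = library
        self.latent = latent
        self.latent_hash = latent.content_hash()
        self.goals = list(goals) if goals is not None else hts_data.all_goals()
        self.batch_size = batch_size
        self.ei_xi = ei_xi
        self.seed = seed
        self.hyper_strategy = hyper_strategy
        self.n_restarts = n_restarts
        self.refit_hyperparameters = refit_hyperparameters
        self.stop_set_size = stop_set_size
        self.compute_cv = compute_cv
        self.aggregate = aggregate
        self.posterior_dtype = posterior_dtype

        self.profiles: dict[str, ModulationProfile] = {}
        self.round_index = 0
        self.models: dict[str, GprModel] = {}
        self._models_prev: dict[str, GprModel] = {}
        self._frozen_hypers: dict[str, dict] = {}
        self.stop_set: Optional[StopSet] = None
        self.history: list[RoundResult] = []

    # -- label ingestion ----------------------------------------------------
    def ingest(self, profiles: Sequence[ModulationProfile]) -> None:
        """Register real measurements; believed labels are never stored."""
        for prof in profiles:
            self.profiles[prof.molecule_id] = prof
        self.library.mark_tested(
            [p.molecule_id for p in profiles if p.molecule_id in self.library])

    # -- model fitting ------------------------------------------------------
    def fit_models(self) -> dict[str, GprModel]:
        if self.latent.content_hash() != self.latent_hash:
            raise IntegrityError("latent embedding changed between rounds")
        datasets = build_goal_datasets(self.latent, self.profiles, self.goals,
                                       self.aggregate)
        models = {}
        for i, (goal_id, data) in enumerate(datasets.items()):
            if self.hyper_strategy == "mll" and (
                    self.refit_hyperparameters or goal_id not in self._frozen_hypers):
                model = fit_gpr(data, hyper_strategy="mll",
                                n_restarts=self.n_restarts,
                                seed=self.seed * 1000 + self.round_index * 17 + i)
                self._frozen_hypers[goal_id] = model.hyperparameters()
            else:
                model = fit_gpr(data, hyper_strategy="fixed",
                                fixed=self._frozen_hypers[goal_id])
            models[goal_id] = model
        return models

    def _audit_no_believers(self, models: dict[str, GprModel]) -> None:
        labeled = set(self.profiles)
        for goal_id, model in models.items():
            ghost = set(model.ids) - labeled
            if ghost:
                raise IntegrityError(
                    f"{goal_id}: believed/unknown ids in training set: "
                    f"{sorted(ghost)[:5]}")

    # -- the round ----------------------------------------------------------
    def run_round(self,
                  labeler: Optional[Callable[[list[Molecule]],
                                             Sequence[ModulationProfile]]] = None
                  ) -> RoundResult:
        """Refit on real labels, emit the next batch, report convergence;
        optionally label the batch via ``labeler`` (e.g. the synthetic HTS).
        """
        pending = self.library.tested_ids - set(self.profiles)
        if pending:
            raise IntegrityError(
                f"unlabeled prior selections: {sorted(pending)[:5]}")
        if not self.profiles:
            raise IntegrityError("no labeled bootstrap data ingested")

        self.round_index += 1
        models = self.fit_models()
        self._audit_no_believers(models)

        untested = sorted(self.library.untested_ids & set(self.latent._index))
        if self.stop_set is None:
            self.stop_set = StopSet.draw(untested, self.stop_set_size,
                                         seed=self.seed + 7919,
                                         latent=self.latent)

        report = ConvergenceReport(round_index=self.round_index)
        if self._models_prev:
            report.stabilizing = stabilizing_predictions(
                self._models_prev, models, self.stop_set, self.latent)
        if self.compute_cv:
            datasets = build_goal_datasets(self.latent, self.profiles,
                                           [g for g in self.goals
                                            if not g.is_generalist],
                                           self.aggregate)
            rows = []
            for goal_id, data in datasets.items():
                mae, spread = cv_mae(
                    data, seed=self.seed + self.round_index,
                    hyper_strategy="fixed",
                    fixed=self._frozen_hypers.get(goal_id)
                    or models[goal_id].hyperparameters())
                rows.append({"goal_id": goal_id, "mae": mae, "fold_std": spread})
            report.cv = pd.DataFrame(rows)

        cfg = SelectionConfig(batch_size=self.batch_size, ei_xi=self.ei_xi,
                              seed=self.seed, round_index=self.round_index,
                              posterior_dtype=self.posterior_dtype)
        X_cand = self.latent.subset(untested)
        batch = kriging_believer_batch(models, untested, X_cand, cfg)

        self.library.mark_tested(batch.selected_ids)
        self._models_prev = models
        self.models = models

        if labeler is not None:
            selected_mols = [self.library.get(i) for i in batch.selected_ids]
            self.ingest(labeler(selected_mols))

        result = RoundResult(self.round_index, batch, report, models)
        self.history.append(result)
        return result

    # -- reporting helpers --------------------------------------------------
    def best_observed(self, goal: GoalSpec) -> float:
        """Best real measured target for one goal (bootstrap included)."""
        scores = [goal_score(p, goal, self.aggregate) for p in self.profiles.values()
                  if not p.incomplete
                  and p.has_channels((goal.pathway, a) for a in goal.agonists)]
        if not scores:
            raise ValueError("no labeled data")
        return max(scores)
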
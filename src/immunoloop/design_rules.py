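"""Interpretable post hoc analysis: fragment featurization, feature
filtering, row normalization, and sparse LASSO models per agonist-pathway
combination.

The feature catalogue is the 85 ``fr_*`` substructure counters shipped with
RDKit, in their definition order; a glossary CSV can be exported with
:func:`export_glossary`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Fragments as _Fragments
from sklearn.linear_model import Lasso

from immunoloop.chemlib import Molecule

logger = logging.getLogger(__name__)

#: the 85 fragment-counter codes, fixed catalogue order (RDKit definition order)
FRAGMENT_CATALOGUE: list[str] = [name for name, _ in _Fragments.fns]
_FRAGMENT_FNS = dict(_Fragments.fns)

assert len(FRAGMENT_CATALOGUE) == 85


def fragment_counts(mol_or_smiles, fragments: Optional[Sequence[str]] = None
                    ) -> np.ndarray:
    """Counter vector for one molecule over ``fragments`` (default: all 85).

    Multi-component candidates are featurized as the single combined entity.
    """
    smiles = (mol_or_smiles.smiles if isinstance(mol_or_smiles, Molecule)
              else str(mol_or_smiles))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    names = FRAGMENT_CATALOGUE if fragments is None else list(fragments)
    return np.array([_FRAGMENT_FNS[n](mol) for n in names], dtype=np.int64)


@dataclass
class FragmentFeatureMatrix:
    """Molecules x fragment counters, with filter/normalization bookkeeping."""

    ids: list[str]
    counts: np.ndarray                       # (n, k) float (int pre-normalization)
    columns: list[str]
    retained_mask: Optional[np.ndarray] = None   # over the 85-column catalogue
    row_normalized: bool = False
    zero_rows: list[str] = field(default_factory=list)
    dropped_rows: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.ids), len(self.columns)):
            raise ValueError("matrix shape does not match ids/columns")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.ids, columns=self.columns)


def featurize_fragments(molecules: Sequence[Molecule]) -> FragmentFeatureMatrix:
    """One row per molecule over the fixed 85-counter catalogue.

    Unparseable molecules are dropped with a log entry (recorded in
    ``dropped_rows``), never silently.
    """
    ids, rows, dropped = [], [], []
    for m in molecules:
        try:
            rows.append(fragment_counts(m))
            ids.append(m.id)
        except ValueError as exc:
            dropped.append({"id": m.id, "reason": str(exc)})
            logger.warning("featurize_fragments: dropped %s (%s)", m.id, exc)
    if not rows:
        raise ValueError("no featurizable molecules")
    return FragmentFeatureMatrix(ids=ids, counts=np.stack(rows),
                                 columns=list(FRAGMENT_CATALOGUE),
                                 dropped_rows=dropped)


def filter_features(M: FragmentFeatureMatrix, rho_max: float = 0.95,
                    signed: bool = False) -> FragmentFeatureMatrix:
    """Drop zero-variance columns, then — scanning in catalogue order — any
    column whose Pearson correlation with a retained earlier column exceeds
    ``rho_max`` (|rho| by default; raw signed rho with ``signed=True``)."""
    if len(M.ids) < 2:
        raise ValueError("need >= 2 molecules to filter features")
    X = M.counts
    variances = X.var(axis=0)
    nonzero = variances > 0

    retained: list[int] = []
    for j in range(X.shape[1]):
        if not nonzero[j]:
            continue
        ok = True
        for i in retained:
            rho = np.corrcoef(X[:, i], X[:, j])[0, 1]
            stat = rho if signed else abs(rho)
            if stat > rho_max:
                ok = False
                break
        if ok:
            retained.append(j)

    mask = np.zeros(X.shape[1], dtype=bool)
    mask[retained] = True
    return FragmentFeatureMatrix(
        ids=list(M.ids), counts=X[:, mask],
        columns=[M.columns[j] for j in retained],
        retained_mask=mask, dropped_rows=list(M.dropped_rows))


def normalize_rows(M: FragmentFeatureMatrix) -> FragmentFeatureMatrix:
    """Each nonzero row divided by its Euclidean norm; zero rows untouched
    and flagged in ``zero_rows``."""
    norms = np.linalg.norm(M.counts, axis=1)
    zero = norms == 0
    scaled = M.counts / np.where(zero, 1.0, norms)[:, None]
    return FragmentFeatureMatrix(
        ids=list(M.ids), counts=scaled, columns=list(M.columns),
        retained_mask=M.retained_mask, row_normalized=True,
        zero_rows=[M.ids[i] for i in np.where(zero)[0]],
        dropped_rows=list(M.dropped_rows))


@dataclass
class LassoRuleModel:
    """Sparse fragment-coefficient model for one agonist-pathway combination.

    Sign convention: theta > 0 <=> enhancer-promoting, theta < 0 <=>
    suppressor-promoting (targets are log2-fold changes).
    """

    combination: str
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    cv_mae: float
    cv_curve: pd.DataFrame = field(repr=False, default=None)

    @property
    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.coefficients))


def default_lambda_grid(X: np.ndarray, y: np.ndarray, num: int = 50) -> np.ndarray:
    """50 log-spaced values spanning [1e-4 * lambda_max, lambda_max], where
    lambda_max is the smallest penalty giving the all-zero model."""
    n = X.shape[0]
    lam_max = float(np.abs(X.T @ (y - y.mean())).max() / n)
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max * 1e-4, lam_max, num=num)


def _id_keyed_folds(ids: Sequence[str], folds: int, seed: int) -> np.ndarray:
    """Seeded fold assignment keyed on sorted ids, so row order is irrelevant."""
    ids = np.asarray(ids, dtype=object)
    order = np.argsort(ids)
    rng = np.random.default_rng(seed)
    perm = order[rng.permutation(len(ids))]
    assign = np.empty(len(ids), dtype=int)
    assign[perm] = np.arange(len(ids)) % folds
    return assign


def fit_lasso_cv(M: FragmentFeatureMatrix, targets: np.ndarray,
                 combination: str = "", lambda_grid: Optional[np.ndarray] = None,
                 folds: int = 5, seed: int = 0,
                 column_standardize: bool = False) -> LassoRuleModel:
    """LASSO over a penalty grid with seeded 5-fold CV; the final model is
    refitted on all data at the CV-optimal penalty.

    ``column_standardize`` offers the textbook column-scaling convention for
    comparison with the default row-normalized input.
    """
    y = np.asarray(targets, dtype=float).ravel()
    X = M.counts
    if X.shape[0] != y.shape[0]:
        raise ValueError("|rows| != |targets|")
    if not np.isfinite(y).all():
        raise ValueError("non-finite targets")

    if column_standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    if np.allclose(y, y[0]):
        warnings.warn("degenerate all-equal targets: intercept-only model")
        return LassoRuleModel(combination, list(M.columns),
                              np.zeros(X.shape[1]), float(y[0]), np.inf, 0.0,
                              pd.DataFrame(columns=["lambda", "cv_error",
                                                    "cv_mae", "nonzero_count"]))

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    assign = _id_keyed_folds(M.ids, folds, seed)

    records = []
    for lam in np.sort(lambda_grid)[::-1]:
        errs, maes, nnz = [], [], []
        for f in range(folds):
            test = assign == f
            model = Lasso(alpha=lam, max_iter=50000, tol=1e-6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[~test], y[~test])
            pred = model.predict(X[test])
            errs.append(float(np.mean((pred - y[test]) ** 2)))
            maes.append(float(np.mean(np.abs(pred - y[test]))))
            nnz.append(int(np.count_nonzero(model.coef_)))
        records.append({"lambda": float(lam), "cv_error": float(np.mean(errs)),
                        "cv_mae": float(np.mean(maes)),
                        "nonzero_count": int(np.mean(nnz))})
    curve = pd.DataFrame(records)
    best = curve.loc[curve["cv_error"].idxmin()]

    final = Lasso(alpha=float(best["lambda"]), max_iter=200000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return LassoRuleModel(
        combination=combination, feature_names=list(M.columns),
        coefficients=np.asarray(final.coef_), intercept=float(final.intercept_),
        lambda_=float(best["lambda"]), cv_mae=float(best["cv_mae"]),
        cv_curve=curve)


def rank_coefficients(model: LassoRuleModel, top_n: Optional[int] = None
                      ) -> list[tuple[str, float]]:
    """Nonzero coefficients sorted by |theta| descending, ties by catalogue
    order; returns (fragment code, theta) pairs."""
    cat_rank = {name: i for i, name in enumerate(FRAGMENT_CATALOGUE)}
    entries = [(name, float(t)) for name, t in
               zip(model.feature_names, model.coefficients) if t != 0.0]
    entries.sort(key=lambda e: (-abs(e[1]), cat_rank.get(e[0], 10 ** 6)))
    return entries if top_n is None else entries[:top_n]


def export_glossary(path) -> pd.DataFrame:
    """Write the fragment-code glossary CSV (code + RDKit docstring)."""
    rows = [{"fragment_code": name,
             "description": (_FRAGMENT_FNS[name].__doc__ or "").strip()}
            for name in FRAGMENT_CATALOGUE]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
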
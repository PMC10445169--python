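"""Selection of class-predictive pathways by L1-penalized multinomial logistic regression.

PAS features are standardized (zero mean, unit variance) before the penalized
fit because the lasso penalty is scale-sensitive and PAS ranges vary with
pathway size.  The regression is the multinomial (softmax) formulation, not
one-vs-rest.  A pathway is "selected" when any of its per-class coefficients
exceeds 1e-8 in magnitude.

The regularization strength ``penalty`` is the lasso weight lambda (sklearn's
``C = 1 / lambda``).  ``penalty="auto"`` chooses lambda by stratified k-fold
cross-validated log-loss over a 30-point log-spaced grid, taking the sparsest
model within one standard error of the minimum (the glmnet ``lambda.1se``
convention), which guards against the mild over-selection of the plain
CV-minimum on small sample sizes.

CV log-loss is computed with predicted probabilities capped at 1 - 1e-2: on
small, well-separated folds the uncapped loss is dominated by confidence
rather than correctness and decreases without bound as the penalty weakens,
which would drag the chosen penalty to the grid boundary whenever the classes
are separable.  Capping bounds each observation's contribution, so the loss
curve flattens once a model classifies the folds confidently and the 1-SE
rule picks the sparsest such model.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .pas import PASMatrix

__all__ = ["SelectionResult", "select_pathways", "select_to_count", "write_selection"]

COEF_TOL = 1e-8
_PENALTY_GRID = np.logspace(-2, 2, 30)
_PROB_CAP = 1e-2  # cap predicted probabilities at 1 - _PROB_CAP in CV scoring


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a penalized pathway-selection fit."""

    selected_pathways: list[str]
    coefficients: pd.DataFrame  # pathway x class
    penalty: float
    class_labels: list[str]
    target_reached: bool = True
    cv_table: pd.DataFrame | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.selected_pathways)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.zeros_like(x)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - mu[nz]) / sd[nz]
    return out


def _fit(x: np.ndarray, y: np.ndarray, penalty: float, seed: int) -> LogisticRegression:
    model = LogisticRegression(
        l1_ratio=1.0,  # pure lasso penalty
        C=1.0 / penalty,
        solver="saga",
        max_iter=5_000,
        tol=1e-5,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(x, y)
    return model


def _path_fits(x: np.ndarray, y: np.ndarray, grid: np.ndarray, seed: int) -> list[LogisticRegression]:
    """Fit the whole penalty path with warm starts, strongest penalty first."""
    model = LogisticRegression(
        l1_ratio=1.0,
        solver="saga",
        max_iter=5_000,
        tol=1e-5,
        random_state=seed,
        warm_start=True,
    )
    fits: list[LogisticRegression] = [None] * len(grid)  # type: ignore[list-item]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in np.argsort(grid)[::-1]:  # descending lambda = ascending C
            model.C = 1.0 / grid[i]
            model.fit(x, y)
            fits[i] = copy.deepcopy(model)
    return fits


def _coefficient_frame(model: LogisticRegression, pathways: list[str]) -> pd.DataFrame:
    coef = model.coef_
    if coef.shape[0] == 1:  # binary fit: single contrast row
        cols = [f"{model.classes_[1]}"]
    else:
        cols = [str(c) for c in model.classes_]
    return pd.DataFrame(coef.T, index=pathways, columns=cols)


def _selected(coefs: pd.DataFrame) -> list[str]:
    mag = coefs.abs().max(axis=1)
    hit = mag[mag > COEF_TOL]
    # deterministic order: strongest coefficient first, names break ties
    order = sorted(hit.index, key=lambda p: (-hit[p], p))
    return order


def _validate_labels(labels: pd.Series, n_folds: int | None) -> None:
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("pathway selection needs at least two distinct class labels")
    if n_folds is not None and counts.min() < n_folds:
        raise ValidationError(
            f"smallest class has {counts.min()} samples, fewer than the {n_folds} "
            "cross-validation folds; reduce n_folds or supply an explicit penalty"
        )


def _cross_validate(
    x: np.ndarray, y: np.ndarray, seed: int, n_folds: int, grid: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """Mean CV log-loss per penalty; returns the 1-SE penalty and the CV table."""
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    classes = np.unique(y)
    losses = np.empty((len(grid), n_folds))
    for j, (train, test) in enumerate(cv.split(x, y)):
        fold_fits = _path_fits(x[train], y[train], grid, seed)
        for i, model in enumerate(fold_fits):
            prob = model.predict_proba(x[test])
            # folds can miss a class at tiny n; align columns to the full set
            full = np.zeros((prob.shape[0], len(classes)))
            for c_idx, c in enumerate(model.classes_):
                full[:, np.searchsorted(classes, c)] = prob[:, c_idx]
            full = np.clip(full, _PROB_CAP, 1.0 - _PROB_CAP)
            full /= full.sum(axis=1, keepdims=True)
            losses[i, j] = log_loss(y[test], full, labels=classes)
    mean = losses.mean(axis=1)
    se = losses.std(axis=1, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean))
    threshold = mean[best] + se[best]
    eligible = np.nonzero(mean <= threshold)[0]
    chosen = grid[eligible.max()]  # grid ascending in lambda: largest = sparsest
    table = pd.DataFrame({"penalty": grid, "cv_log_loss": mean, "cv_se": se})
    return float(chosen), table


def select_pathways(
    pas: PASMatrix,
    labels: pd.Series,
    penalty: float | str = "auto",
    seed: int = 0,
    n_folds: int = 5,
) -> SelectionResult:
    """Select pathways whose PAS are predictive of sample class.

    ``labels`` maps sample id to class; samples are aligned to the PAS matrix
    columns.  Returns the pathways with any nonzero coefficient, ordered by
    decreasing coefficient magnitude.
    """
    labels = labels.reindex(pas.sample_ids)
    if labels.isna().any():
        raise ValidationError(f"missing class labels for samples: {list(labels.index[labels.isna()])}")
    x = _standardize(pas.scores.to_numpy(dtype=float).T)
    y = labels.to_numpy(dtype=object)

    cv_table = None
    if penalty == "auto":
        _validate_labels(labels, n_folds)
        lam, cv_table = _cross_validate(x, y, seed, n_folds, _PENALTY_GRID)
    else:
        _validate_labels(labels, None)
        lam = float(penalty)
        if lam <= 0:
            raise ValidationError("penalty must be positive")

    model = _fit(x, y, lam, seed)
    coefs = _coefficient_frame(model, pas.pathway_names)
    return SelectionResult(
        selected_pathways=_selected(coefs),
        coefficients=coefs,
        penalty=lam,
        class_labels=[str(c) for c in model.classes_],
        cv_table=cv_table,
    )


def select_to_count(
    pas: PASMatrix,
    labels: pd.Series,
    target_count: int,
    seed: int = 0,
    max_iter: int = 50,
) -> SelectionResult:
    """Bisect the penalty until the selection reaches the largest size <= target_count.

    The lasso path is discrete, so an exact target can be unreachable; in that
    case the nearest size below is returned with ``target_reached=False``.
    """
    n_pathways = len(pas.pathway_names)
    if not 1 <= target_count <= n_pathways:
        raise ValidationError(f"target_count must be in [1, {n_pathways}]")
    labels = labels.reindex(pas.sample_ids)
    if labels.isna().any():
        raise ValidationError("missing class labels for some samples")
    _validate_labels(labels, None)
    x = _standardize(pas.scores.to_numpy(dtype=float).T)
    y = labels.to_numpy(dtype=object)

    def count_at(lam: float) -> tuple[int, LogisticRegression]:
        model = _fit(x, y, lam, seed)
        coefs = _coefficient_frame(model, pas.pathway_names)
        return len(_selected(coefs)), model

    lo, hi = 1e-6, 1e6  # lambda: lo dense, hi empty
    best: tuple[int, float, LogisticRegression] | None = None

    def consider(count: int, lam: float, model: LogisticRegression) -> None:
        nonlocal best
        if count <= target_count and (best is None or count > best[0] or (count == best[0] and lam > best[1])):
            best = (count, lam, model)

    c_lo, m_lo = count_at(lo)
    consider(c_lo, lo, m_lo)
    c_hi, m_hi = count_at(hi)
    consider(c_hi, hi, m_hi)
    if c_lo > target_count:
        for _ in range(max_iter):
            mid = float(np.sqrt(lo * hi))
            c, m = count_at(mid)
            consider(c, mid, m)
            if c == target_count:
                break
            if c > target_count:
                lo = mid
            else:
                hi = mid

    assert best is not None
    count, lam, model = best
    if count < target_count:
        warnings.warn(
            f"regularization path jumps over target {target_count}; achieved {count}",
            stacklevel=2,
        )
    coefs = _coefficient_frame(model, pas.pathway_names)
    return SelectionResult(
        selected_pathways=_selected(coefs),
        coefficients=coefs,
        penalty=lam,
        class_labels=[str(c) for c in model.classes_],
        target_reached=(count == target_count),
    )


def write_selection(result: SelectionResult, path) -> None:
    """Write pathway, per-class coefficients and selected flag as TSV."""
    out = result.coefficients.copy()
    out["selected"] = [p in set(result.selected_pathways) for p in out.index]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# penalty={result.penalty}\n")
        out.to_csv(fh, sep="\t", index_label="pathway")
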
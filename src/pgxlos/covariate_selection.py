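"""LASSO covariate screening ahead of the unpenalized ZTNB refit.

The adjusted model keeps the exposures of interest (PIP category and the
moderate-or-worse DDI flag) unconditionally and screens the remaining
candidate covariates with an L1-penalized regression of log(LOS) on
standardized predictors. The penalty weight is chosen by K-fold
cross-validation with the one-standard-error rule; covariates with any
nonzero indicator at the chosen weight (multi-level categoricals are
selected as a group) are carried, unioned with the forced set, into a
full unpenalized ZTNB refit from which all inference is taken. The
selection is treated as fixed at refit time; no post-selection
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .cohort_synth import build_design_matrix, design_column_groups
from .ztnb_model import ZtnbFit, fit_ztnb

__all__ = ["SelectionResult", "lasso_screen", "fit_adjusted_model"]

#: exposures that are never subject to exclusion
FORCED_EXPOSURES = ("pip_category", "ddi")


@dataclass
class SelectionResult:
    """Outcome of the covariate screen.

    ``selected_covariates`` is at the covariate (group) level and always
    contains ``always_keep``; ``selected_columns`` lists the design
    columns of those covariates. ``lambda_path`` is descending;
    ``chosen_lambda`` lies on it.
    """

    candidate_covariates: tuple[str, ...]
    selected_covariates: tuple[str, ...]
    selected_columns: tuple[str, ...]
    always_keep: tuple[str, ...]
    lambda_path: np.ndarray
    chosen_lambda: float
    cv_mean: np.ndarray
    cv_se: np.ndarray
    seed: int
    folds: int
    diagnostics: dict = field(default_factory=dict)


def lasso_screen(
    design: pd.DataFrame,
    y,
    always_keep: Sequence[str],
    seed: int,
    folds: int = 10,
    column_groups: Mapping[str, str] | None = None,
    n_lambdas: int = 100,
) -> SelectionResult:
    """Screen candidate design columns by a Gaussian LASSO on log(y).

    ``always_keep`` names covariates (groups) forced into the result and
    excluded from penalization; ``column_groups`` maps each design column
    to its covariate (identity when omitted). Deterministic given
    ``seed``, which fixes the cross-validation fold assignment.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 1):
        raise ValueError("LOS outcomes must be >= 1")
    n = design.shape[0]
    if n < folds:
        raise ValueError(f"{n} observations is fewer than {folds} folds")
    groups = dict(column_groups) if column_groups else {
        c: c for c in design.columns
    }
    always_keep = tuple(always_keep)
    keep_set = set(always_keep)
    candidate_cols = [c for c in design.columns if groups[c] not in keep_set]
    candidate_covs = tuple(dict.fromkeys(groups[c] for c in candidate_cols))
    target = np.log(y)

    if not candidate_cols:
        return SelectionResult(
            candidate_covariates=(), selected_covariates=always_keep,
            selected_columns=tuple(
                c for c in design.columns if groups[c] in keep_set
            ),
            always_keep=always_keep, lambda_path=np.array([]),
            chosen_lambda=float("nan"), cv_mean=np.array([]),
            cv_se=np.array([]), seed=seed, folds=folds,
            diagnostics={"note": "no candidates to screen"},
        )

    X = design[candidate_cols].to_numpy(dtype=float)
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Xs = (X - x_mean) / x_sd
    yc = target - target.mean()

    alphas, _, _ = lasso_path(Xs, yc, alphas=n_lambdas, eps=1e-3)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    mse = np.zeros((len(alphas), folds))
    for k, (tr, te) in enumerate(kf.split(Xs)):
        _, coefs, _ = lasso_path(Xs[tr], yc[tr], alphas=alphas)
        pred = Xs[te] @ coefs  # (n_te, n_alphas); both sides centered
        resid = pred - yc[te][:, None]
        mse[:, k] = np.mean(resid**2, axis=0)
    cv_mean = mse.mean(axis=1)
    cv_se = mse.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(cv_mean))
    threshold = cv_mean[best] + cv_se[best]
    # alphas descend; the 1-SE choice is the largest penalty within one SE
    chosen_idx = int(np.argmax(cv_mean <= threshold))
    chosen_lambda = float(alphas[chosen_idx])

    model = Lasso(alpha=chosen_lambda, max_iter=50_000)
    model.fit(Xs, yc)
    nonzero_cols = [
        c for c, b in zip(candidate_cols, model.coef_) if b != 0.0
    ]
    selected_groups = set(groups[c] for c in nonzero_cols)
    all_zero = not nonzero_cols

    selected_covs = tuple(
        g for g in dict.fromkeys(
            [groups[c] for c in design.columns]
        )
        if g in keep_set or g in selected_groups
    )
    selected_cols = tuple(
        c for c in design.columns if groups[c] in set(selected_covs)
    )
    diag = {"n_nonzero": len(nonzero_cols)}
    if all_zero:
        diag["note"] = "all candidate coefficients zero at chosen lambda"
    return SelectionResult(
        candidate_covariates=candidate_covs,
        selected_covariates=selected_covs,
        selected_columns=selected_cols,
        always_keep=always_keep,
        lambda_path=np.asarray(alphas),
        chosen_lambda=chosen_lambda,
        cv_mean=cv_mean,
        cv_se=cv_se,
        seed=seed,
        folds=folds,
        diagnostics=diag,
    )


def fit_adjusted_model(
    cohort: pd.DataFrame, selection: SelectionResult
) -> ZtnbFit:
    """Unpenalized ZTNB refit on the selected covariates.

    Inference comes entirely from this refit; the selection is treated
    as fixed. The forced exposures must be present in the selection.
    """
    missing = [k for k in selection.always_keep
               if k not in selection.selected_covariates]
    if missing:
        raise ValueError(
            f"selection is missing forced covariate(s): {missing}"
        )
    design = build_design_matrix(cohort, selection.selected_covariates)
    return fit_ztnb(design, cohort["los_days"].to_numpy())


def screen_and_fit(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    seed: int,
    always_keep: Sequence[str] = FORCED_EXPOSURES,
    folds: int = 10,
) -> tuple[SelectionResult, ZtnbFit]:
    """Convenience wrapper: build the candidate design, screen, refit."""
    design = build_design_matrix(cohort, candidates)
    groups = design_column_groups(candidates)
    selection = lasso_screen(
        design, cohort["los_days"].to_numpy(), always_keep=always_keep,
        seed=seed, folds=folds, column_groups=groups,
    )
    return selection, fit_adjusted_model(cohort, selection)
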
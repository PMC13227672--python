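"""Leave-one-batch-out (LOBO) validation of multi-kernel prediction.

Within each company that contributed at least three batches, each batch
serves once as the validation set while the company's remaining batches
form the training set.  The model is fitted by REML on training data
only; random animal effects for validation animals are predicted from
their kernel relationships to the training animals, and the prediction
score is the sum of the predicted random animal effects.  Observed
phenotypes are pre-adjusted with a kernel-free baseline model (fixed
effects plus random pen and litter); accuracy per fold is the Pearson
correlation between scores and adjusted phenotypes, aggregated as the
sample-size-weighted mean over folds.  For binary traits, a pooled AUC
is computed on the concatenated out-of-sample scores so each animal
contributes exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .kernels import RelationshipKernel
from .preprocess import build_fixed_design, pen_incidence
from .varcomp import (
    DegenerateTraitError,
    ModelSpec,
    VarCompFit,
    fit_reml,
    reml,
)

__all__ = [
    "FoldPlan",
    "CVResult",
    "plan_folds",
    "adjust_phenotypes",
    "predict_validation",
    "evaluate_fold",
    "pooled_auc",
    "run_cv",
]


class CrossValError(ValueError):
    pass


@dataclass
class FoldPlan:
    """One LOBO fold: a validation batch within an eligible company."""

    company: str
    validation_batch: str
    training_animals: list[str]
    validation_animals: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.training_animals) & set(self.validation_animals)
        if overlap:
            raise CrossValError(f"fold leaks animals: {sorted(overlap)[:5]}")
        if not self.training_animals or not self.validation_animals:
            raise CrossValError("fold has an empty training or validation set")


@dataclass
class CVResult:
    trait: str
    model: str
    per_fold: list[tuple[str, int, float]]  # (batch, n_validation, r)
    weighted_accuracy: float | None
    pooled_auc: float | None
    n_folds_converged: int
    fold_log: list[str] = field(default_factory=list)


def plan_folds(design: pd.DataFrame, min_batches: int = 3) -> list[FoldPlan]:
    """One fold per batch of every company with >= ``min_batches`` batches."""
    folds: list[FoldPlan] = []
    for company in sorted(design["company"].unique()):
        sub = design[design["company"] == company]
        batches = sorted(sub["batch"].unique())
        if len(batches) < min_batches:
            continue
        for batch in batches:
            folds.append(FoldPlan(
                company=company,
                validation_batch=batch,
                training_animals=list(
                    sub.loc[sub["batch"] != batch, "animal_id"]
                ),
                validation_animals=list(
                    sub.loc[sub["batch"] == batch, "animal_id"]
                ),
            ))
    if not folds:
        raise CrossValError(
            f"no company has at least {min_batches} batches; LOBO "
            "validation is not possible"
        )
    return folds


def _baseline_fit(y: pd.Series, design: pd.DataFrame,
                  fixed_terms: list[str]):
    """Kernel-free baseline: fixed effects + random pen and litter."""
    animals = [str(a) for a in y.index]
    design = design.set_index("animal_id").loc[animals].reset_index()
    X, xnames = build_fixed_design(design, fixed_terms)
    Zp = pen_incidence(design)
    Zl = pd.get_dummies(design["litter"].astype(str)).to_numpy(dtype=float)
    structures = {"pen": Zp @ Zp.T, "litter": Zl @ Zl.T}
    res = reml(y.to_numpy(dtype=float), X, structures)
    res.fixed_estimates.index = xnames
    return res, X, xnames, design


def adjust_phenotypes(
    y: pd.Series, design: pd.DataFrame, fixed_terms: list[str]
) -> pd.Series:
    """Corrected phenotypes: residuals of the kernel-free baseline model.

    Returns ``y`` minus the fitted fixed effects and minus the pen and
    litter BLUPs — the conditional residual of a mixed model with the
    trait's fixed effects and random pen/litter only.
    """
    res, X, _, _ = _baseline_fit(y, design, fixed_terms)
    if not res.converged:
        raise CrossValError("baseline adjustment model did not converge")
    fitted = X @ res.fixed_estimates.to_numpy()
    corrected = (
        y.to_numpy(dtype=float) - fitted - res.blup["pen"]
        - res.blup["litter"]
    )
    return pd.Series(corrected, index=y.index, name=y.name)


def predict_validation(
    fit: VarCompFit,
    kernels: dict[str, RelationshipKernel],
    fold: FoldPlan,
    ridge: float = 1e-8,
) -> pd.Series:
    """Out-of-fold prediction scores for validation animals.

    For each fitted kernel effect,
    ``u_val = K[val, train] (K[train, train] + ridge I)^-1 u_train`` —
    the conditional mean of the validation animals' effects given the
    training BLUPs, equivalent to solving the mixed-model equations
    with validation phenotypes absent.  The score is the sum over the
    fitted kernel effects.
    """
    train = fit.animal_ids
    val = fold.validation_animals
    scores = np.zeros(len(val))
    for name, u_train in fit.blup.items():
        if name in ("pen", "litter"):
            continue  # pen/litter levels of a held-out batch are unseen
        kern = _kernel_for_effect(name, kernels)
        known = set(kern.animal_ids)
        missing = [a for a in list(train) + list(val) if a not in known]
        if missing:
            raise CrossValError(
                f"kernel {name!r} lacks animals {missing[:5]}"
            )
        Ktt = kern.submatrix(train, train)
        Kvt = kern.submatrix(val, train)
        sol = np.linalg.solve(
            Ktt + ridge * np.eye(len(train)), u_train
        )
        scores = scores + Kvt @ sol
    return pd.Series(scores, index=val, name="score")


def _kernel_for_effect(
    name: str, kernels: dict[str, RelationshipKernel]
) -> RelationshipKernel:
    if name in kernels:
        return kernels[name]
    if name.startswith("mean(") and name.endswith(")"):
        from .kernels import combine_kernels

        parts = name[5:-1].split(",")
        missing = [p for p in parts if p not in kernels]
        if missing:
            raise CrossValError(f"no kernels for layers {missing}")
        ids = kernels[parts[0]].animal_ids
        return combine_kernels([kernels[p].reindex(ids) for p in parts])
    raise CrossValError(f"no kernel available for effect {name!r}")


def evaluate_fold(
    scores: pd.Series, corrected_y: pd.Series
) -> tuple[float, int]:
    """Pearson correlation between scores and adjusted phenotypes.

    Returns ``(r, n)``; ``r`` is NaN (fold flagged) when either vector
    has zero variance.
    """
    common = [a for a in scores.index if a in set(corrected_y.index)]
    if len(common) < 3:
        raise CrossValError("need >= 3 validation animals with both values")
    s = scores.loc[common].to_numpy(dtype=float)
    t = corrected_y.loc[common].to_numpy(dtype=float)
    if np.std(s) == 0 or np.std(t) == 0:
        return float("nan"), len(common)
    return float(np.corrcoef(s, t)[0, 1]), len(common)


def pooled_auc(scores: pd.Series, labels: pd.Series) -> float:
    """Rank-based AUC on pooled out-of-sample scores, ties counted 1/2."""
    labels = labels.loc[scores.index].to_numpy()
    uniq = np.unique(labels)
    if not np.array_equal(np.sort(uniq), [0, 1]):
        if uniq.size == 1:
            raise CrossValError(
                "pooled set contains only one class; AUC undefined"
            )
        raise CrossValError("labels must be binary 0/1")
    s = scores.to_numpy(dtype=float)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(auc)


def run_cv(
    trait: str,
    spec: ModelSpec,
    design: pd.DataFrame,
    kernels: dict[str, RelationshipKernel],
    y: pd.Series,
    min_batches: int = 3,
    adjust_mode: str = "per_fold",
    return_details: bool = False,
):
    """Full LOBO protocol for one trait/model combination.

    ``adjust_mode="per_fold"`` (default) estimates the baseline
    adjustment on each training fold and corrects validation phenotypes
    with the training-fold fixed-effect estimates (pen/litter BLUPs of
    unseen validation levels are zero).  ``adjust_mode="global"``
    adjusts once on all data before splitting, which risks mild
    leakage but matches a one-pass reading of the protocol.

    Batch is excluded from fold-level fixed effects because the
    validation batch is by construction unseen in training; its
    adjustment falls to the intercept.
    """
    if adjust_mode not in ("per_fold", "global"):
        raise CrossValError(f"unknown adjust_mode {adjust_mode!r}")
    folds = plan_folds(design, min_batches=min_batches)
    fixed_terms = [t for t in spec.fixed_terms if t != "batch"]
    fold_spec = ModelSpec(
        trait=spec.trait,
        kernel_set=spec.kernel_set,
        combined=spec.combined,
        fixed_terms=fixed_terms,
        include_pen=spec.include_pen,
        include_litter=spec.include_litter,
    )
    y = y.astype(float)
    binary = set(pd.unique(y.dropna())) <= {0.0, 1.0}

    if adjust_mode == "global":
        corrected_all = adjust_phenotypes(y, design, fixed_terms)

    per_fold: list[tuple[str, int, float]] = []
    log: list[str] = []
    pooled_scores: list[pd.Series] = []
    pooled_labels: list[pd.Series] = []
    details = []
    n_converged = 0
    for fold in folds:
        y_train = y.loc[fold.training_animals]
        y_val = y.loc[fold.validation_animals]
        try:
            fit = fit_reml(y_train, design, fold_spec, kernels)
        except DegenerateTraitError:
            log.append(f"{fold.validation_batch}: degenerate training trait")
            continue
        if not fit.converged:
            log.append(f"{fold.validation_batch}: REML did not converge")
            details.append((fold, fit, None, None))
            continue
        n_converged += 1
        if adjust_mode == "per_fold":
            base, Xb, xnames, _ = _baseline_fit(y_train, design, fixed_terms)
            dsub = (
                design.set_index("animal_id")
                .loc[fold.validation_animals]
                .reset_index()
            )
            Xv = _design_like(dsub, design, fixed_terms, xnames)
            corrected_val = pd.Series(
                y_val.to_numpy(dtype=float)
                - Xv @ base.fixed_estimates.to_numpy(),
                index=y_val.index,
            )
        else:
            corrected_val = corrected_all.loc[fold.validation_animals]
        scores = predict_validation(fit, kernels, fold)
        r, nv = evaluate_fold(scores, corrected_val)
        if np.isnan(r):
            log.append(
                f"{fold.validation_batch}: zero-variance fold, correlation "
                "undefined"
            )
        else:
            per_fold.append((fold.validation_batch, nv, r))
        pooled_scores.append(scores)
        pooled_labels.append(y_val)
        details.append((fold, fit, scores, corrected_val))

    weighted = None
    if per_fold:
        ns = np.array([n for _, n, _ in per_fold], dtype=float)
        rs = np.array([r for _, _, r in per_fold])
        weighted = float(np.sum(ns * rs) / np.sum(ns))
    auc = None
    if binary and pooled_scores:
        all_scores = pd.concat(pooled_scores)
        all_labels = pd.concat(pooled_labels)
        try:
            auc = pooled_auc(all_scores, all_labels)
        except CrossValError as exc:
            log.append(f"pooled AUC undefined: {exc}")
    result = CVResult(
        trait=trait,
        model=fold_spec.label,
        per_fold=per_fold,
        weighted_accuracy=weighted,
        pooled_auc=auc,
        n_folds_converged=n_converged,
        fold_log=log,
    )
    if return_details:
        return result, details
    return result


def _design_like(
    subset: pd.DataFrame,
    full_design: pd.DataFrame,
    fixed_terms: list[str],
    column_names: list[str],
) -> np.ndarray:
    """Design matrix for new animals matching training column layout.

    Factor levels unseen in training map to all-zero dummy columns
    (i.e., the reference/intercept); covariates are centered with the
    subset's own mean, matching how training covariates were centered.
    """
    cols = {}
    cols["intercept"] = np.ones(len(subset))
    for term in fixed_terms:
        col = subset[term]
        if col.dtype.kind in "OUSb" or isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            d = pd.get_dummies(col.astype(str), prefix=term)
            for c in d.columns:
                cols[c] = d[c].to_numpy(dtype=float)
        else:
            v = col.to_numpy(dtype=float)
            cols[term] = v - v.mean()
    X = np.zeros((len(subset), len(column_names)))
    for j, name in enumerate(column_names):
        if name in cols:
            X[:, j] = cols[name]
    return X


def weighted_accuracy(per_fold: list[tuple[str, int, float]]) -> float:
    """Recompute the sample-size-weighted mean correlation from folds."""
    if not per_fold:
        raise CrossValError("no folds with defined correlations")
    ns = np.array([n for _, n, _ in per_fold], dtype=float)
    rs = np.array([r for _, _, r in per_fold])
    return float(np.sum(ns * rs) / np.sum(ns))
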
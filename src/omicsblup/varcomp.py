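"""Multi-kernel linear mixed models: REML, BLUP and variance shares.

The phenotype model is

    y = 1*mu + X b + Z_pen p + Z_litter l + sum_k u_k + e

with one random animal effect ``u_k ~ N(0, K_k s2_k)`` per relationship
kernel (genomic and/or omics layers), random pen-within-batch and litter
effects ``p ~ N(0, I s2_p)``, ``l ~ N(0, I s2_l)``, and residual
``e ~ N(0, I s2_e)``.  Effects attached to different kernels are assumed
uncorrelated.  Alternatively, the kernel effects can be replaced by a
single effect ``u_c ~ N(0, C s2_c)`` with ``C`` the unweighted mean of
the selected kernels.

Variance components are estimated by average-information (AI) REML with
EM-style fallback steps and non-negativity enforced by an active set
(components are pinned at zero when the boundary is binding).  Binary
traits are fitted with the same linear model on 0/1 observations.

The proportion of phenotypic variance captured by the omics kernels is

    h2_omics_total = sum_k s2_k / (s2_pen + s2_litter + sum_k s2_k + s2_e)

with the per-kernel analog replacing the numerator by a single ``s2_k``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kernels import RelationshipKernel, combine_kernels
from .preprocess import build_fixed_design, pen_incidence

__all__ = [
    "ModelSpec",
    "VarCompFit",
    "VarianceReport",
    "RemlResult",
    "reml",
    "fit_reml",
    "variance_report",
    "enumerate_model_specs",
]

KERNEL_ORDER = ("G", "T", "P", "M")


class VarCompError(ValueError):
    pass


class DegenerateTraitError(VarCompError):
    """The phenotype vector has no variance."""


@dataclass
class ModelSpec:
    """One trait/model combination.

    ``kernel_set`` is an ordered subset of available kernel layers.
    With ``combined=True`` the selected kernels are averaged into one
    combined matrix fitted as a single random effect (requires >= 2
    kernels); otherwise each kernel gets its own variance component.
    """

    trait: str
    kernel_set: tuple[str, ...]
    combined: bool = False
    fixed_terms: list[str] = field(default_factory=lambda: ["entry_age"])
    include_pen: bool = True
    include_litter: bool = True

    def __post_init__(self) -> None:
        self.kernel_set = tuple(self.kernel_set)
        if not self.kernel_set:
            raise VarCompError("kernel_set must be nonempty")
        if self.combined and len(self.kernel_set) < 2:
            raise VarCompError("combined=True requires >= 2 kernels")

    @property
    def label(self) -> str:
        base = "".join(self.kernel_set)
        return f"{base}-mean" if self.combined else base


@dataclass
class RemlResult:
    """Raw output of the generic REML solver."""

    sigma2: dict[str, float]
    loglik_restricted: float
    converged: bool
    n_iterations: int
    loglik_trace: list[float]
    blup: dict[str, np.ndarray]
    fixed_estimates: pd.Series
    Py: np.ndarray
    pinned: list[str]


@dataclass
class VarCompFit:
    """REML estimates and BLUP solutions for one trait/model."""

    spec: ModelSpec
    sigma2: dict[str, float]
    loglik_restricted: float
    converged: bool
    n_iterations: int
    blup: dict[str, np.ndarray]
    fixed_estimates: pd.Series
    animal_ids: list[str]
    loglik_trace: list[float] = field(default_factory=list, repr=False)
    dropped_fixed_columns: list[str] = field(default_factory=list)


@dataclass
class VarianceReport:
    """Variance-share decomposition of a converged fit."""

    per_kernel_share: dict[str, float]
    total_omics_share: float
    pen_share: float
    litter_share: float
    residual_share: float


# ---------------------------------------------------------------------------
# generic AI-REML over named covariance structures
# ---------------------------------------------------------------------------

def reml(
    y: np.ndarray,
    X: np.ndarray,
    structures: dict[str, np.ndarray],
    max_iter: int = 200,
    tol_loglik: float = 1e-6,
    tol_param: float = 1e-4,
    init: dict[str, float] | None = None,
) -> RemlResult:
    """AI-REML for ``V = sum_i s2_i V_i + s2_e I``.

    ``structures`` maps effect names to n x n PSD covariance structures
    ``V_i`` (relationship kernels, or ``Z Z'`` for grouped effects); a
    ``"residual"`` identity term is always included.  Components are
    initialized at an equal split of the ordinary-least-squares residual
    variance.  Each iteration proposes an AI (Newton-with-average-
    information) step; steps that leave the feasible region or decrease
    the restricted likelihood are halved and, failing that, replaced by
    an EM-style fixed-point step, so the accepted restricted-likelihood
    trace is non-decreasing.  Components are pinned at zero when pushed
    to the boundary with a negative score, and released if the score
    turns positive.  Convergence requires both the restricted-loglik
    change below ``tol_loglik`` and the max relative component change
    below ``tol_param``; otherwise the fit is returned with
    ``converged=False`` rather than raising.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if np.var(y) == 0:
        raise DegenerateTraitError("phenotype vector has zero variance")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    px = X.shape[1]
    names = list(structures) + ["residual"]
    Vs = {k: np.asarray(v, dtype=float) for k, v in structures.items()}

    # equal-split initialization from the OLS residual variance
    bh, *_ = np.linalg.lstsq(X, y, rcond=None)
    vtot = float(np.sum((y - X @ bh) ** 2) / max(n - px, 1))
    if vtot <= 0:
        raise DegenerateTraitError("no residual variance after fixed effects")
    k_all = len(names)
    theta = {nm: vtot / k_all for nm in names}
    if init:
        theta.update({k: float(v) for k, v in init.items() if k in theta})
    floor = 1e-10 * vtot
    pinned: set[str] = set()

    def build_V(th):
        V = th["residual"] * np.eye(n)
        for nm, Vi in Vs.items():
            if th[nm] != 0.0:
                V += th[nm] * Vi
        return V

    def loglik_and_P(th):
        V = build_V(th)
        try:
            c, low = cho_factor(V, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        Vinv = cho_solve((c, low), np.eye(n), check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        A = Vinv @ X
        XtVX = X.T @ A
        try:
            cx, lowx = cho_factor(XtVX, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdetX = 2.0 * np.sum(np.log(np.diag(cx)))
        P = Vinv - A @ cho_solve((cx, lowx), A.T, check_finite=False)
        Py = P @ y
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))
        return ll, P, Py, Vinv, (cx, lowx), A

    state = loglik_and_P(theta)
    if state is None:
        raise VarCompError("initial covariance matrix is not positive definite")
    ll, P, Py, Vinv, xfac, A = state
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        free = [nm for nm in names if nm not in pinned]
        # scores and AI matrix on the free components
        tvecs = {}
        score = {}
        for nm in names:
            Vi_Py = Py if nm == "residual" else Vs[nm] @ Py
            tvecs[nm] = Vi_Py
            trPVi = (
                np.trace(P) if nm == "residual"
                else float(np.sum(P * Vs[nm]))
            )
            score[nm] = -0.5 * (trPVi - float(Py @ Vi_Py))
        # release pinned components whose score is positive
        for nm in list(pinned):
            if score[nm] > 0:
                pinned.discard(nm)
        free = [nm for nm in names if nm not in pinned]
        svec = np.array([score[nm] for nm in free])
        S = {nm: P @ tvecs[nm] for nm in free}
        AI = 0.5 * np.array(
            [[float(tvecs[a] @ S[b]) for b in free] for a in free]
        )

        accepted = False
        try:
            delta = np.linalg.solve(
                AI + 1e-12 * np.eye(len(free)) * max(np.trace(AI), 1.0),
                svec,
            )
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            step = 1.0
            for _ in range(20):
                cand = dict(theta)
                for j, nm in enumerate(free):
                    v = theta[nm] + step * delta[j]
                    if v < floor:
                        # approach the boundary geometrically rather than
                        # jumping to it; the residual keeps a positive floor
                        if theta[nm] > 2 * floor:
                            v = theta[nm] * 0.1
                        else:
                            v = floor if nm == "residual" else 0.0
                    cand[nm] = v
                st = loglik_and_P(cand)
                if st is not None and st[0] >= ll - 1e-12:
                    theta_new, new_state = cand, st
                    accepted = True
                    break
                step *= 0.5
        if not accepted:
            # EM-style fixed-point step: s2 <- s2 * (y'P Vi P y)/tr(P Vi)
            cand = dict(theta)
            for nm in free:
                trPVi = (
                    np.trace(P) if nm == "residual"
                    else float(np.sum(P * Vs[nm]))
                )
                quad = float(Py @ tvecs[nm])
                if trPVi > 0 and quad >= 0:
                    cand[nm] = max(theta[nm], floor) * quad / trPVi
                    if nm == "residual":
                        cand[nm] = max(cand[nm], floor)
            st = loglik_and_P(cand)
            if st is not None and st[0] >= ll - 1e-12:
                theta_new, new_state = cand, st
                accepted = True
        if not accepted:
            # stalled: no improving step exists within line-search
            # resolution, so we are at a maximum within tolerance
            converged = True
            break

        rel_change = max(
            abs(theta_new[nm] - theta[nm]) / max(theta[nm], floor, 1e-12)
            for nm in names
        )
        dll = new_state[0] - ll
        theta = theta_new
        ll, P, Py, Vinv, xfac, A = new_state
        trace.append(ll)
        # pin components stuck at the zero boundary with a negative score
        for nm in names:
            if nm == "residual":
                continue
            if theta[nm] <= floor:
                Vi_Py = Vs[nm] @ Py
                sc = -0.5 * (float(np.sum(P * Vs[nm])) - float(Py @ Vi_Py))
                if sc <= 0:
                    theta[nm] = 0.0
                    pinned.add(nm)
        if abs(dll) < tol_loglik and rel_change < tol_param:
            converged = True
            break

    beta = cho_solve(xfac, A.T @ y, check_finite=False)
    blup = {}
    for nm in names:
        if nm == "residual":
            continue
        blup[nm] = theta[nm] * (Vs[nm] @ Py)
    return RemlResult(
        sigma2={nm: float(theta[nm]) for nm in names},
        loglik_restricted=float(ll),
        converged=converged,
        n_iterations=it,
        loglik_trace=trace,
        blup=blup,
        fixed_estimates=pd.Series(beta),
        Py=Py,
        pinned=sorted(pinned),
    )


# ---------------------------------------------------------------------------
# trait-level fitting
# ---------------------------------------------------------------------------

def _grouped_structure(design: pd.DataFrame, column: str) -> np.ndarray:
    Z = pd.get_dummies(design[column].astype(str)).to_numpy(dtype=float)
    return Z @ Z.T


def fit_reml(
    y: pd.Series,
    design: pd.DataFrame,
    spec: ModelSpec,
    kernels: dict[str, RelationshipKernel],
    **reml_kwargs,
) -> VarCompFit:
    """Fit the multi-kernel mixed model for one trait by AI-REML.

    ``y`` is indexed by animal id; ``kernels`` maps layer tags to
    :class:`RelationshipKernel` objects covering (at least) those
    animals.  Pen is modeled as pen-within-batch.
    """
    animals = [str(a) for a in y.index]
    design = design.set_index("animal_id").loc[animals].reset_index()
    missing = [k for k in spec.kernel_set if k not in kernels]
    if missing:
        raise VarCompError(f"kernels not supplied for layers {missing}")

    X, xnames = build_fixed_design(design, spec.fixed_terms)
    structures: dict[str, np.ndarray] = {}
    layer_kernels = [kernels[k].reindex(animals) for k in spec.kernel_set]
    if spec.combined:
        C = combine_kernels(layer_kernels)
        structures[C.layer] = C.values
    else:
        for k, kern in zip(spec.kernel_set, layer_kernels):
            structures[k] = kern.values
    if spec.include_pen:
        Zp = pen_incidence(design)
        structures["pen"] = Zp @ Zp.T
    if spec.include_litter:
        structures["litter"] = _grouped_structure(design, "litter")

    res = reml(y.to_numpy(dtype=float), X, structures, **reml_kwargs)
    res.fixed_estimates.index = xnames
    return VarCompFit(
        spec=spec,
        sigma2=res.sigma2,
        loglik_restricted=res.loglik_restricted,
        converged=res.converged,
        n_iterations=res.n_iterations,
        blup=res.blup,
        fixed_estimates=res.fixed_estimates,
        animal_ids=animals,
        loglik_trace=res.loglik_trace,
    )


def variance_report(fit: VarCompFit) -> VarianceReport:
    """Variance shares: each component over the total phenotypic variance.

    The total is ``s2_pen + s2_litter + sum_k s2_omics_k + s2_e``; the
    omics total share replaces the numerator by the sum of kernel
    components, per-kernel shares by the single component.
    """
    if not fit.converged:
        warnings.warn(
            "variance_report on a non-converged fit; shares are from the "
            "last accepted iterate",
            stacklevel=2,
        )
    s2 = fit.sigma2
    kernel_names = [
        k for k in s2 if k not in ("pen", "litter", "residual")
    ]
    total = sum(s2.values())
    if total <= 0:
        raise VarCompError("all variance components are zero; shares undefined")
    per_kernel = {k: s2[k] / total for k in kernel_names}
    return VarianceReport(
        per_kernel_share=per_kernel,
        total_omics_share=sum(per_kernel.values()),
        pen_share=s2.get("pen", 0.0) / total,
        litter_share=s2.get("litter", 0.0) / total,
        residual_share=s2["residual"] / total,
    )


def enumerate_model_specs(
    kernel_layers: tuple[str, ...] = KERNEL_ORDER,
    combined_variants: bool = True,
    trait: str = "",
    **spec_kwargs,
) -> list[ModelSpec]:
    """All subset models of the available layers, plus combined variants.

    With the four layers G, T, P, M and ``combined_variants=True`` this
    yields 15 subset models (each layer a separate random effect) plus
    11 combined-mean variants (one per subset of size >= 2), i.e. 26
    model specifications, in deterministic order (by subset size, then
    layer order; separate-effect models first).
    """
    layers = tuple(kernel_layers)
    if not layers:
        raise VarCompError("kernel_layers must be nonempty")
    subsets = [
        combo
        for r in range(1, len(layers) + 1)
        for combo in itertools.combinations(layers, r)
    ]
    specs = [
        ModelSpec(trait=trait, kernel_set=s, combined=False, **spec_kwargs)
        for s in subsets
    ]
    if combined_variants:
        specs += [
            ModelSpec(trait=trait, kernel_set=s, combined=True, **spec_kwargs)
            for s in subsets
            if len(s) >= 2
        ]
    return specs
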
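"""Preprocessing of raw omics feature matrices and genotypes.

The end product for each omics layer is an :class:`OmicsMatrix`: an
animals x features matrix of residual feature values, adjusted for
technical and environmental structure by a per-feature mixed model and
standardized to column mean 0 / variance 1, ready for kernel
construction (``K = M M' / p``).

Layer-specific paths:

* transcriptome: TMM library-size normalization, counts-per-million,
  ``log2(CPM + 1)``, then residualization;
* metabolome: exclusion of metabolites with >= 20% missing values or
  sub-limit-of-detection status in > 20% of samples, median imputation
  of remaining missing cells, ``log2`` transform, then residualization;
* proteome: feature-wise K-nearest-neighbor imputation of
  missing-at-random cells, a masking-based validation of imputation
  accuracy with a mean-correlation > 0.4 retention rule, then
  residualization.

Genotypes pass three QC filters (SNP call rate > 0.90, individual call
rate > 0.90, minor allele frequency > 0.05) with per-SNP mean imputation
of surviving missing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

__all__ = [
    "FeatureModelSpec",
    "OmicsMatrix",
    "normalize_counts",
    "tmm_factors",
    "filter_metabolites",
    "knn_impute",
    "validate_imputation",
    "residualize_features",
    "qc_genotypes",
]

LAYERS = ("transcriptome", "proteome", "metabolome")

#: Default fixed-effect terms of the per-feature adjustment model by
#: layer.  Pen (nested in batch) is always a random effect.
LAYER_FIXED_TERMS = {
    "transcriptome": ["batch", "toy", "entry_age", "rin"],
    "proteome": ["batch", "entry_age"],
    "metabolome": ["batch", "entry_age"],
}


class PreprocessError(ValueError):
    pass


class LibrarySizeError(PreprocessError):
    """A sample has zero sequencing library size."""


@dataclass
class FeatureModelSpec:
    """Adjustment model for one omics layer.

    ``fixed_terms`` name columns of the cohort design table; columns of
    object/categorical dtype enter as factors, numeric columns as
    covariates.  ``random_pen`` adds a random pen-within-batch effect.
    """

    layer: str
    fixed_terms: list[str] | None = None
    random_pen: bool = True

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise PreprocessError(f"unknown layer {self.layer!r}")
        if self.fixed_terms is None:
            self.fixed_terms = list(LAYER_FIXED_TERMS[self.layer])


@dataclass
class OmicsMatrix:
    """Residual-standardized feature matrix for one omics layer.

    Columns have mean 0 and (population) variance 1 across the animals
    used in fitting, so the similarity kernel ``M M' / p`` has unit mean
    diagonal.
    """

    animal_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    layer: str
    report: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.animal_ids), len(self.feature_ids)):
            raise PreprocessError("OmicsMatrix shape mismatch")
        if np.isnan(self.values).any():
            raise PreprocessError("OmicsMatrix must be complete")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.animal_ids, columns=self.feature_ids
        )


# ---------------------------------------------------------------------------
# transcriptome: TMM + CPM + log2
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    weighted: bool = True,
    ref_animal: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors per animal.

    For each animal i vs the reference r, gene-wise log ratios
    ``M_g = log2((x_gi/N_i)/(x_gr/N_r))`` and average log intensities
    ``A_g`` are computed over genes expressed in both; the upper and
    lower ``logratio_trim`` (on M) and ``abs_trim`` (on A) quantiles are
    discarded and the factor is ``2**mean(M)`` over the remainder, using
    inverse asymptotic-variance weights when ``weighted``.  Factors are
    rescaled to have geometric mean 1.  The reference is the animal
    whose library size is closest to the 75th percentile of library
    sizes (unless given explicitly).
    """
    X = counts.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise PreprocessError("need at least 2 animals for TMM")
    if (X < 0).any():
        raise PreprocessError("counts must be nonnegative")
    lib = X.sum(axis=1)
    if (lib <= 0).any():
        bad = list(counts.index[lib <= 0])
        raise LibrarySizeError(f"zero library size for animals {bad}")

    if ref_animal is None:
        q75 = np.percentile(lib, 75)
        r = int(np.argmin(np.abs(lib - q75)))
    else:
        r = list(counts.index).index(ref_animal)

    factors = np.ones(X.shape[0])
    xr, Nr = X[r], lib[r]
    for i in range(X.shape[0]):
        if i == r:
            continue
        xi, Ni = X[i], lib[i]
        ok = (xi > 0) & (xr > 0)
        if ok.sum() == 0:
            continue
        fi, fr = xi[ok] / Ni, xr[ok] / Nr
        M = np.log2(fi / fr)
        A = 0.5 * (np.log2(fi) + np.log2(fr))
        # two-sided quantile trimming on both M and A
        keep = _trim_mask(M, logratio_trim) & _trim_mask(A, abs_trim)
        if keep.sum() == 0:
            continue
        if weighted:
            w = 1.0 / (
                (Ni - xi[ok]) / (Ni * xi[ok]) + (Nr - xr[ok]) / (Nr * xr[ok])
            )
            factors[i] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
        else:
            factors[i] = 2.0 ** np.mean(M[keep])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.index, name="tmm_factor")


def _trim_mask(v: np.ndarray, trim: float) -> np.ndarray:
    """Keep values whose rank lies strictly inside the trim quantiles."""
    n = v.size
    rank = np.argsort(np.argsort(v, kind="stable"), kind="stable") + 1
    lo = np.floor(n * trim) + 1
    hi = n + 1 - lo
    return (rank >= lo) & (rank <= hi)


def normalize_counts(counts: pd.DataFrame, **tmm_kwargs) -> pd.DataFrame:
    """TMM-normalized ``log2(CPM + 1)`` expression.

    CPM uses effective library sizes (raw library size x TMM factor).
    """
    counts = counts.astype(float)
    factors = tmm_factors(counts, **tmm_kwargs)
    eff_lib = counts.sum(axis=1) * factors
    cpm = counts.div(eff_lib, axis=0) * 1e6
    return np.log2(cpm + 1.0)


# ---------------------------------------------------------------------------
# metabolome: missing / sub-LOD filters + median imputation + log2
# ---------------------------------------------------------------------------

def filter_metabolites(
    values: pd.DataFrame,
    lod_mask: pd.DataFrame | None = None,
    missing_threshold: float = 0.20,
    lod_threshold: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter, median-impute and log2-transform metabolite concentrations.

    A metabolite is dropped when its generic-missing fraction is
    ``>= missing_threshold`` or its below-limit-of-detection fraction is
    ``> lod_threshold`` (note the different comparators).  Missing and
    sub-LOD cells of retained metabolites are imputed with the
    metabolite-specific median of observed values, then all values are
    log2-transformed.

    Parameters
    ----------
    values
        Animals x metabolites concentrations with NaN for cells that
        are missing *or* sub-LOD.
    lod_mask
        Boolean animals x metabolites mask flagging the sub-LOD cells
        (a subset of the NaN cells).  ``None`` means no sub-LOD cells.

    Returns
    -------
    (filtered, report)
        ``filtered``: complete log2 matrix of retained metabolites.
        ``report``: per-metabolite missing/LOD fractions and status.
    """
    n = values.shape[0]
    if lod_mask is None:
        lod_mask = pd.DataFrame(
            False, index=values.index, columns=values.columns
        )
    lod_mask = lod_mask.reindex_like(values).fillna(False).astype(bool)
    isna = values.isna()
    if (lod_mask & ~isna).any().any():
        raise PreprocessError("sub-LOD cells must be NaN in the value matrix")
    lod_frac = lod_mask.sum(axis=0) / n
    miss_frac = (isna & ~lod_mask).sum(axis=0) / n
    drop_missing = miss_frac >= missing_threshold
    drop_lod = lod_frac > lod_threshold
    all_missing = isna.all(axis=0)
    keep = ~(drop_missing | drop_lod | all_missing)

    report = pd.DataFrame({
        "feature_id": values.columns,
        "missing_fraction": miss_frac.to_numpy(),
        "lod_fraction": lod_frac.to_numpy(),
        "retained": keep.to_numpy(),
        "drop_reason": [
            "" if k else
            ("all_missing" if am else
             ("missing>=threshold" if dm else "lod>threshold"))
            for k, am, dm in zip(keep, all_missing, drop_missing)
        ],
    })
    kept = values.loc[:, keep].copy()
    medians = kept.median(axis=0, skipna=True)
    kept = kept.fillna(medians)
    if (kept <= 0).any().any():
        raise PreprocessError(
            "metabolite concentrations must be positive for log2 transform"
        )
    return np.log2(kept), report


# ---------------------------------------------------------------------------
# proteome: feature-wise KNN imputation + masking validation
# ---------------------------------------------------------------------------

def _feature_distances(X: np.ndarray) -> np.ndarray:
    """Pairwise feature distances on standardized values.

    Features are z-scored on their observed cells first, so the
    distance reflects profile similarity rather than abundance scale
    (for standardized features the squared distance is monotone in
    1 - correlation).  The root-*mean*-square over co-observed animals,
    rather than the plain Euclidean norm, keeps distances comparable
    across feature pairs with different numbers of co-observed animals.
    Pairs with no co-observed animals get distance +inf.
    """
    obs = ~np.isnan(X)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    X = (X - mu) / np.where(sd > 0, sd, 1.0)
    A = np.where(obs, X, 0.0)
    O = obs.astype(float)
    sq = (A ** 2).T @ O + O.T @ (A ** 2) - 2.0 * A.T @ A
    counts = O.T @ O
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(sq, 0.0) / counts)
    d[counts == 0] = np.inf
    np.fill_diagonal(d, np.inf)
    return d


def knn_impute(values: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Feature-wise K-nearest-neighbor imputation.

    Each missing cell (animal i, feature j) is filled with the
    unweighted mean, over the k features nearest to j that are observed
    at animal i, of the neighbor's value at i after aligning the
    neighbor to feature j's observed mean and SD.  Feature distances
    are RMS differences of z-scored values over co-observed animals.
    When fewer than k aligned neighbors are observed at a cell, the
    available ones are used; a cell with none falls back to the
    feature's observed mean.  ``k`` must be smaller than the candidate
    pool of other features.
    """
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    n_obs = obs.sum(axis=0)
    if not obs.any(axis=0).all():
        bad = list(values.columns[~obs.any(axis=0)])
        raise PreprocessError(f"features with no observed values: {bad}")
    if (n_obs < 2).any():
        bad = list(values.columns[n_obs < 2])
        raise PreprocessError(
            f"features need >= 2 observed values for mean/SD alignment: {bad}"
        )
    if k >= p:
        raise PreprocessError(
            f"k={k} is not smaller than the pool of {p - 1} candidate "
            "neighbor features"
        )
    if not obs.all():
        D = _feature_distances(X)
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        out = X.copy()
        for j in range(p):
            miss_rows = np.flatnonzero(~obs[:, j])
            if miss_rows.size == 0:
                continue
            order = np.argsort(D[:, j], kind="stable")
            order = order[np.isfinite(D[order, j])]
            for i in miss_rows:
                cand = order[obs[i, order]][:k]
                if cand.size == 0:
                    out[i, j] = mu[j]
                    continue
                aligned = mu[j] + (X[i, cand] - mu[cand]) / sd[cand] * sd[j]
                out[i, j] = aligned.mean()
        X = out
    return pd.DataFrame(X, index=values.index, columns=values.columns)


def validate_imputation(
    values: pd.DataFrame,
    n_masked_features: int = 100,
    n_repeats: int = 100,
    seed: int = 0,
    k: int = 10,
    mask_fraction: float = 0.5,
    accuracy_threshold: float = 0.4,
) -> tuple[pd.Series, list[str]]:
    """Masking-based validation of KNN imputation accuracy.

    Per repeat, ``n_masked_features`` features are drawn at random and a
    random ``mask_fraction`` of each one's observed cells is set to
    missing; the matrix is KNN-imputed and, per masked feature, the
    Pearson correlation between original and imputed values at the
    masked cells is recorded.  A feature's imputation accuracy is its
    mean correlation over the repeats in which it was masked; features
    with mean accuracy greater than ``accuracy_threshold`` are retained.

    A fraction of each feature's cells (rather than all of them) is
    masked so the held-out cells are genuinely out of sample for the
    feature-wise neighbor search: neighbors are chosen on the retained
    cells and evaluated on the masked ones, which keeps chance
    correlations from inflating the accuracy of uninformative features.

    Returns
    -------
    (accuracy, retained)
        ``accuracy``: per-feature mean correlation (NaN if a feature
        was never masked).  ``retained``: features with accuracy >
        ``accuracy_threshold``.
    """
    rng = np.random.default_rng(seed)
    p = values.shape[1]
    cols = list(values.columns)
    if n_masked_features > p:
        warnings.warn(
            f"fewer features ({p}) than n_masked_features "
            f"({n_masked_features}); masking all features each repeat",
            stacklevel=2,
        )
        n_masked_features = p
    sums = pd.Series(0.0, index=cols)
    counts = pd.Series(0, index=cols)
    X = values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    for _ in range(n_repeats):
        chosen = rng.choice(p, size=n_masked_features, replace=False)
        masked = values.copy()
        held: dict[int, np.ndarray] = {}
        for j in chosen:
            oi = np.flatnonzero(obs[:, j])
            m = max(1, int(round(mask_fraction * oi.size)))
            m = min(m, oi.size - 2)  # keep >=2 cells for alignment
            if m < 3:
                continue
            cells = rng.choice(oi, size=m, replace=False)
            held[j] = cells
            masked.iloc[cells, j] = np.nan
        imputed = knn_impute(masked, k=k)
        for j, cells in held.items():
            orig = X[cells, j]
            imp = imputed.iloc[cells, j].to_numpy()
            if np.std(orig) == 0 or np.std(imp) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(orig, imp)[0, 1])
            sums.iloc[j] += r
            counts.iloc[j] += 1
    with np.errstate(invalid="ignore"):
        accuracy = sums / counts.replace(0, np.nan)
    accuracy.name = "mean_imputation_accuracy"
    retained = [c for c in cols if accuracy[c] > accuracy_threshold]
    return accuracy, retained


# ---------------------------------------------------------------------------
# per-feature mixed-model residualization (all layers)
# ---------------------------------------------------------------------------

def build_fixed_design(
    design: pd.DataFrame, fixed_terms: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded factors + centered covariates.

    Object/categorical columns enter as factors (first level dropped);
    numeric columns as centered covariates.  Columns that are aliased
    (linearly dependent on earlier columns) are dropped, trailing-first,
    and reported in the returned name list only if kept.
    """
    blocks = [np.ones((len(design), 1))]
    names = ["intercept"]
    for term in fixed_terms:
        if term not in design.columns:
            raise PreprocessError(f"design table has no column {term!r}")
        col = design[term]
        if col.dtype.kind in "OUSb" or isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            dummies = pd.get_dummies(col.astype(str), prefix=term,
                                     drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns)
        else:
            v = col.to_numpy(dtype=float)
            blocks.append((v - v.mean())[:, None])
            names.append(term)
    X = np.hstack(blocks)
    return _drop_aliased(X, names)


def _drop_aliased(
    X: np.ndarray, names: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Drop trailing linearly dependent columns (rank-revealing sweep)."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    return X[:, keep], [names[j] for j in keep]


def pen_incidence(design: pd.DataFrame) -> np.ndarray:
    """Animals x pens 0/1 incidence for pen nested within batch."""
    labels = (
        design["batch"].astype(str) + "::" + design["pen"].astype(str)
    )
    return pd.get_dummies(labels).to_numpy(dtype=float)


def residualize_features(
    values: pd.DataFrame,
    spec: FeatureModelSpec,
    design: pd.DataFrame,
    ratio_grid: np.ndarray | None = None,
) -> OmicsMatrix:
    """Adjust features by a per-feature mixed model; standardize residuals.

    Per feature the model is ``y = mu + X b + Z_pen p + e`` with
    ``p ~ N(0, I s2_p)`` and ``e ~ N(0, I s2_e)``, fitted by REML over
    the variance ratio ``lambda = s2_p / s2_e`` on a bounded grid
    (profiled restricted likelihood, shared spectral decomposition of
    ``Z Z'`` across features).  Conditional residuals
    ``e_hat = y - X b_hat - Z p_hat`` are centered and divided by their
    population SD, yielding columns with mean 0 and variance exactly 1.

    Features whose residual variance collapses (exact linear functions
    of the design) are flagged degenerate and dropped.  The returned
    :class:`OmicsMatrix` carries a per-feature ``report`` with the
    fitted ratio, residual variance and status.
    """
    if values.isna().any().any():
        raise PreprocessError(
            "residualize_features requires a complete matrix; impute first"
        )
    design = design.set_index("animal_id").loc[values.index].reset_index()
    n = len(values)
    X, xnames = build_fixed_design(design, spec.fixed_terms)
    px = X.shape[1]
    if n - px < 3:
        raise PreprocessError("too few residual degrees of freedom")
    Y = values.to_numpy(dtype=float)

    if spec.random_pen:
        Z = pen_incidence(design)
        d, U = eigh(Z @ Z.T)
        d = np.maximum(d, 0.0)
    else:
        d = np.zeros(n)
        U = np.eye(n)

    if ratio_grid is None:
        ratio_grid = np.concatenate([[0.0], np.logspace(-3, 6, 91)])
    Yt = U.T @ Y
    Xt = U.T @ X

    best_ll = np.full(Y.shape[1], -np.inf)
    best_lam = np.zeros(Y.shape[1])
    if not spec.random_pen:
        ratio_grid = np.array([0.0])
    for lam in ratio_grid:
        w = 1.0 / (1.0 + lam * d)
        XtW = Xt * w[:, None]
        G = XtW.T @ Xt
        c, low = cho_factor(G)
        B = cho_solve((c, low), XtW.T @ Yt)          # px x f
        R = Yt - Xt @ B
        rss = np.einsum("i,ij,ij->j", w, R, R)
        sig2 = rss / (n - px)
        logdet_g = 2.0 * np.sum(np.log(np.diag(c)))
        ll = -0.5 * (
            (n - px) * (1.0 + np.log(2.0 * np.pi * np.maximum(sig2, 1e-300)))
            + np.sum(np.log1p(lam * d))
            + logdet_g
        )
        better = ll > best_ll
        best_lam = np.where(better, lam, best_lam)
        best_ll = np.where(better, ll, best_ll)

    # conditional residuals at the per-feature optimum:
    # e_hat = U diag(w) U' (y - X b_hat)  since I - lam*d*w = w
    resid = np.empty_like(Y)
    sig2_out = np.empty(Y.shape[1])
    for lam in np.unique(best_lam):
        cols = np.flatnonzero(best_lam == lam)
        w = 1.0 / (1.0 + lam * d)
        XtW = Xt * w[:, None]
        G = XtW.T @ Xt
        c, low = cho_factor(G)
        B = cho_solve((c, low), XtW.T @ Yt[:, cols])
        Rt = Yt[:, cols] - Xt @ B
        resid[:, cols] = U @ (Rt * w[:, None])
        sig2_out[cols] = (
            np.einsum("i,ij,ij->j", w, Rt, Rt) / (n - px)
        )

    feat_var = Y.var(axis=0, ddof=0)
    res_var = resid.var(axis=0, ddof=0)
    degenerate = res_var <= 1e-12 * np.maximum(feat_var, 1e-300)
    keep = ~degenerate
    if degenerate.any():
        warnings.warn(
            f"dropping {int(degenerate.sum())} degenerate feature(s) with "
            "zero residual variance",
            stacklevel=2,
        )
    M = resid[:, keep]
    M = M - M.mean(axis=0)
    M = M / M.std(axis=0, ddof=0)

    report = pd.DataFrame({
        "feature_id": values.columns,
        "pen_to_residual_ratio": best_lam,
        "residual_variance": sig2_out,
        "degenerate": degenerate,
    })
    return OmicsMatrix(
        animal_ids=[str(a) for a in values.index],
        feature_ids=[str(c) for c in values.columns[keep]],
        values=M,
        layer=spec.layer,
        report=report,
    )


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

class GenotypeQCError(PreprocessError):
    pass


def qc_genotypes(
    dosages: pd.DataFrame,
    maf_min: float = 0.05,
    snp_call_rate_min: float = 0.90,
    ind_call_rate_min: float = 0.90,
) -> tuple[pd.DataFrame, dict]:
    """Genotype QC: SNP call rate, then individual call rate, then MAF.

    All three thresholds are strict (``>``): a SNP with call rate
    exactly 0.90, an individual with call rate exactly 0.90, or a SNP
    with MAF exactly 0.05 is removed.  Filters are applied in one pass
    in the order SNP-rate -> individual-rate -> MAF; both call rates
    are computed on the input matrix, while MAF is computed on the
    call-rate-filtered matrix.  Remaining missing dosages are imputed
    with the per-SNP mean (2 x allele frequency).

    Returns the complete filtered matrix and a report dict.
    """
    X = dosages.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    snp_rate = obs.mean(axis=0)
    snp_keep = snp_rate > snp_call_rate_min

    ind_rate = obs.mean(axis=1)
    ind_keep = ind_rate > ind_call_rate_min

    X3 = X[np.ix_(ind_keep, snp_keep)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(X3, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf_keep = maf > maf_min

    kept = X3[:, maf_keep]
    if kept.shape[1] == 0:
        raise GenotypeQCError("all SNPs removed by QC filters")
    p_kept = np.nanmean(kept, axis=0) / 2.0
    fill = np.broadcast_to(2.0 * p_kept, kept.shape)
    kept = np.where(np.isnan(kept), fill, kept)

    out = pd.DataFrame(
        kept,
        index=dosages.index[ind_keep],
        columns=dosages.columns[snp_keep][maf_keep],
    )
    report = {
        "n_snps_in": int(X.shape[1]),
        "n_snps_fail_call_rate": int((~snp_keep).sum()),
        "n_snps_fail_maf": int((~maf_keep).sum()),
        "n_snps_out": int(out.shape[1]),
        "n_animals_in": int(X.shape[0]),
        "n_animals_removed": int((~ind_keep).sum()),
        "n_imputed_calls": int(np.isnan(X3[:, maf_keep]).sum()),
    }
    return out, report
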
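"""Relationship (similarity) kernels among animals.

Four kernel families are used for phenotype prediction:

* ``G`` — genomic relationship matrix (VanRaden method 1) computed
  separately within each source company and assembled block-diagonally,
  so that relationships are restricted to within-company comparisons.
* ``T`` / ``P`` / ``M`` — omics similarity matrices ``K = M M' / p``
  from column-standardized residual feature matrices (transcriptome,
  proteome, metabolome).
* combined kernels — unweighted elementwise means of selected layer
  kernels, fitted as a single random effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RelationshipKernel",
    "build_genomic_kernel",
    "build_omics_kernel",
    "combine_kernels",
    "stabilize_kernel",
]


class KernelError(ValueError):
    """Raised for structurally invalid kernel inputs."""


@dataclass
class RelationshipKernel:
    """A symmetric n x n animal-by-animal relationship matrix.

    Parameters
    ----------
    animal_ids
        Ordered animal identifiers (row/column order of ``values``).
    values
        Symmetric matrix of relationships on a unit-free scale.
    layer
        Tag: ``"G"``, ``"T"``, ``"P"``, ``"M"`` or a combination label
        such as ``"mean(G,T,M)"``.
    ridge_applied
        Amount added to the diagonal for numerical stabilization
        (0.0 if none).
    """

    animal_ids: list[str]
    values: np.ndarray
    layer: str
    ridge_applied: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise KernelError(
                f"kernel shape {self.values.shape} does not match "
                f"{n} animal ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10, rtol=0.0):
            raise KernelError("kernel matrix is not symmetric")
        # enforce exact symmetry so downstream factorizations are clean
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.animal_ids, columns=self.animal_ids
        )

    def reindex(self, animal_ids: list[str]) -> "RelationshipKernel":
        """Return the kernel restricted/reordered to ``animal_ids``."""
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            idx = np.array([pos[a] for a in animal_ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KernelError(f"animal {exc} missing from kernel") from exc
        return RelationshipKernel(
            animal_ids=list(animal_ids),
            values=self.values[np.ix_(idx, idx)],
            layer=self.layer,
            ridge_applied=self.ridge_applied,
            meta=dict(self.meta),
        )

    def submatrix(
        self, rows: list[str], cols: list[str]
    ) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        ri = np.array([pos[a] for a in rows])
        ci = np.array([pos[a] for a in cols])
        return self.values[np.ix_(ri, ci)]


def build_genomic_kernel(
    dosages: pd.DataFrame, company_labels: pd.Series
) -> RelationshipKernel:
    """Block-diagonal genomic relationship matrix (VanRaden method 1).

    For each company, ``G_c = W_c W_c' / (2 * sum_j p_j (1 - p_j))``
    with ``W_c`` the dosage matrix centered at twice the within-company
    allele frequency.  Blocks are placed on the diagonal by company;
    all cross-company entries are exactly zero, restricting genomic
    relationships to within-company comparisons.

    Parameters
    ----------
    dosages
        Animals x SNPs dosage matrix in {0, 1, 2}, complete (QC'd and
        imputed); index = animal ids.
    company_labels
        Company assignment per animal, indexed like ``dosages``.

    Notes
    -----
    SNPs that are monomorphic *within* a company contribute nothing to
    that block's numerator (their centered column is zero) and are
    excluded from the block's denominator.
    """
    if dosages.isna().any().any():
        raise KernelError("dosages must be complete (run qc_genotypes first)")
    company_labels = company_labels.reindex(dosages.index)
    if company_labels.isna().any():
        raise KernelError("every animal needs a company label")

    animals = list(dosages.index)
    n = len(animals)
    K = np.zeros((n, n))
    X = dosages.to_numpy(dtype=float)
    companies = company_labels.to_numpy()
    for comp in pd.unique(companies):
        idx = np.flatnonzero(companies == comp)
        if idx.size == 1:
            warnings.warn(
                f"company {comp!r} has a single animal; its genomic "
                "block is 1x1",
                stacklevel=2,
            )
        Xc = X[idx]
        p = Xc.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
        if denom <= 0:
            raise KernelError(
                f"company {comp!r} has no polymorphic SNPs; cannot build "
                "its genomic block"
            )
        W = Xc - 2.0 * p  # monomorphic columns center to exactly 0
        K[np.ix_(idx, idx)] = W @ W.T / denom
    return RelationshipKernel(
        animal_ids=animals,
        values=K,
        layer="G",
        meta={"n_snps": X.shape[1], "n_companies": len(pd.unique(companies))},
    )


def build_omics_kernel(M, layer: str | None = None) -> RelationshipKernel:
    """Omics similarity kernel ``K = M M' / p``.

    ``M`` is an :class:`~omicsblup.preprocess.OmicsMatrix` (or any
    object with ``animal_ids``, ``feature_ids``, ``values`` and
    ``layer``) holding the column-standardized residual features; ``p``
    is the number of features.  With population-variance (ddof=0)
    standardization the mean diagonal is exactly 1.
    """
    values = np.asarray(M.values, dtype=float)
    p = values.shape[1]
    if p == 0:
        raise KernelError("omics matrix has no features (p=0)")
    if np.isnan(values).any():
        raise KernelError("omics matrix must be complete")
    K = values @ values.T / p
    tag = layer if layer is not None else getattr(M, "layer", "omics")
    tag_letter = {"transcriptome": "T", "proteome": "P", "metabolome": "M"}.get(
        tag, tag
    )
    return RelationshipKernel(
        animal_ids=list(M.animal_ids),
        values=K,
        layer=tag_letter,
        meta={"p_features": p},
    )


def combine_kernels(kernels: list[RelationshipKernel]) -> RelationshipKernel:
    """Unweighted elementwise mean of kernels: ``C = (1/n_K) sum_k K_k``.

    All kernels must share the identical animal order; no silent
    realignment is performed.
    """
    if not kernels:
        raise KernelError("need at least one kernel to combine")
    ids = kernels[0].animal_ids
    for k in kernels[1:]:
        if list(k.animal_ids) != list(ids):
            raise KernelError(
                "kernels have different animal orders; reindex explicitly "
                "before combining"
            )
    C = np.mean([k.values for k in kernels], axis=0)
    label = "mean(" + ",".join(k.layer for k in kernels) + ")"
    return RelationshipKernel(
        animal_ids=list(ids),
        values=C,
        layer=label if len(kernels) > 1 else kernels[0].layer,
        meta={"components": [k.layer for k in kernels]},
    )


def stabilize_kernel(
    kernel: RelationshipKernel, epsilon: float = 1e-8
) -> RelationshipKernel:
    """Ensure the minimum eigenvalue is at least ``epsilon``.

    If ``min_eig < epsilon``, add ``epsilon - min_eig`` to the diagonal
    and record it in ``ridge_applied``; otherwise return the kernel
    unchanged.
    """
    K = kernel.values
    if not np.allclose(K, K.T, atol=1e-10, rtol=0.0):
        raise KernelError("cannot stabilize an asymmetric matrix")
    min_eig = float(np.linalg.eigvalsh(K)[0])
    if min_eig >= epsilon:
        return kernel
    ridge = epsilon - min_eig
    return RelationshipKernel(
        animal_ids=list(kernel.animal_ids),
        values=K + ridge * np.eye(K.shape[0]),
        layer=kernel.layer,
        ridge_applied=kernel.ridge_applied + ridge,
        meta=dict(kernel.meta),
    )
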
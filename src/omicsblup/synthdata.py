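"""Synthetic multi-omics pig cohorts with known ground truth.

The generator emulates a natural-disease-challenge cohort: batches of
weaned pigs enter the facility in sequence, each batch originating from
a single breeding company, with pens nested in batches and litters of
origin.  Per animal it produces:

* SNP dosages (unlinked loci, binomial given per-company allele
  frequencies with mild between-company drift);
* three blood omics layers (transcript counts, protein abundances with
  missing-at-random gaps, metabolite concentrations with
  below-limit-of-detection masking), each feature carrying a
  configurable genetically anchored variance share plus batch and pen
  shifts and independent noise;
* phenotypes drawn from the multi-kernel mixed model
  ``y = fixed + sum_k u_k + pen + litter + e`` with
  ``u_k ~ N(0, K_k s2_k)``, where the kernels ``K_k`` are built from
  the true (noise-inclusive but shift-free) feature signals and the
  block-diagonal within-company genomic relationship matrix; binary
  traits arise by thresholding the latent liability.

Because the realized random effects and the kernels used to draw them
are retained in :class:`CohortTruth`, every downstream stage (kernel
construction, REML, cross-validated prediction) can be tested against
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kernels import RelationshipKernel, build_genomic_kernel, stabilize_kernel

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "CohortTruth",
    "simulate_cohort",
    "inject_missingness",
    "table1_config",
]

LAYER_LETTER = {"transcriptome": "T", "proteome": "P", "metabolome": "M"}
RANDOM_TERMS = ("pen", "litter", "residual")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic cohort.

    ``true_varcomps`` maps each trait to its variance components on the
    phenotypic scale: kernel components keyed by layer letter ("G",
    "T", "P", "M") plus "pen", "litter" and "residual".  Binary traits
    are listed in ``binary_traits`` with their liability thresholds.
    ``genetic_anchor`` gives, per layer, the share of each feature's
    (shift-free) variance driven by genotype.
    """

    n_companies: int
    batches_per_company: list[int]
    animals_per_batch: int | list[int]
    pens_per_batch: int
    litters_per_batch: int
    n_snps: int
    maf_range: tuple[float, float]
    n_features_per_layer: dict[str, int]
    genetic_anchor: dict[str, float]
    true_varcomps: dict[str, dict[str, float]]
    binary_traits: dict[str, float] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_companies <= 0:
            raise SimulationError("n_companies must be positive")
        if len(self.batches_per_company) != self.n_companies:
            raise SimulationError(
                "batches_per_company must have one entry per company"
            )
        if any(b <= 0 for b in self.batches_per_company):
            raise SimulationError("batch counts must be positive")
        nb = self.n_batches
        if isinstance(self.animals_per_batch, int):
            if self.animals_per_batch <= 0:
                raise SimulationError("animals_per_batch must be positive")
        else:
            self.animals_per_batch = list(self.animals_per_batch)
            if len(self.animals_per_batch) != nb:
                raise SimulationError(
                    "animals_per_batch list must have one entry per batch"
                )
            if any(a <= 0 for a in self.animals_per_batch):
                raise SimulationError("batch sizes must be positive")
        if self.pens_per_batch <= 0 or self.litters_per_batch <= 0:
            raise SimulationError("pens/litters per batch must be positive")
        if self.n_snps <= 0:
            raise SimulationError("n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must lie within (0, 0.5]")
        for layer in self.n_features_per_layer:
            if layer not in LAYER_LETTER:
                raise SimulationError(f"unknown omics layer {layer!r}")
            if self.n_features_per_layer[layer] <= 0:
                raise SimulationError(f"{layer}: feature count must be positive")
        for layer, a in self.genetic_anchor.items():
            if layer not in self.n_features_per_layer:
                raise SimulationError(
                    f"genetic_anchor references unsimulated layer {layer!r}"
                )
            if not 0.0 <= a <= 1.0:
                raise SimulationError("genetic_anchor must lie in [0, 1]")
        letters = {"G"} | {
            LAYER_LETTER[layer] for layer in self.n_features_per_layer
        }
        for trait, comps in self.true_varcomps.items():
            for key, v in comps.items():
                if key not in letters and key not in RANDOM_TERMS:
                    raise SimulationError(
                        f"trait {trait!r}: variance component {key!r} "
                        "references a layer that is not simulated"
                    )
                if not np.isfinite(v) or v < 0:
                    raise SimulationError(
                        f"trait {trait!r}: component {key!r} must be a "
                        "finite nonnegative variance"
                    )
            if not np.isfinite(sum(comps.values())):
                raise SimulationError(f"trait {trait!r}: non-finite total")
        for trait in self.binary_traits:
            if trait not in self.true_varcomps:
                raise SimulationError(
                    f"binary trait {trait!r} has no variance components"
                )
        for layer, rate in self.missingness.items():
            if not 0.0 <= rate < 1.0:
                raise SimulationError("missingness rates must be in [0, 1)")

    @property
    def n_batches(self) -> int:
        return int(sum(self.batches_per_company))

    @property
    def n_animals(self) -> int:
        if isinstance(self.animals_per_batch, int):
            return self.n_batches * self.animals_per_batch
        return int(sum(self.animals_per_batch))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    kernels: dict[str, RelationshipKernel]
    random_effects: dict[str, dict[str, np.ndarray]]  # trait -> term -> n-vec
    liabilities: dict[str, np.ndarray]
    config: SimulationConfig


@dataclass
class SyntheticCohort:
    genotypes: pd.DataFrame
    design: pd.DataFrame
    raw_layers: dict[str, pd.DataFrame]
    lod_masks: dict[str, pd.DataFrame]
    phenotypes: pd.DataFrame
    truth: CohortTruth

    @property
    def animal_ids(self) -> list[str]:
        return list(self.design["animal_id"])


def inject_missingness(
    matrix: pd.DataFrame, rate: float, mode: str = "MAR", seed: int = 0
) -> pd.DataFrame:
    """Mask entries of a feature matrix.

    ``MAR`` masks cells uniformly at random across the whole matrix;
    ``LOD`` masks, per feature, the lowest-valued cells up to ``rate``
    (emulating below-limit-of-detection censoring).  The realized
    missing fraction is within rounding of the requested rate.
    """
    if not 0.0 <= rate < 1.0:
        raise SimulationError("missingness rate must be in [0, 1)")
    out = matrix.astype(float).copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n, p = out.shape
    if mode.upper() == "MAR":
        n_mask = int(round(rate * n * p))
        flat = rng.choice(n * p, size=n_mask, replace=False)
        vals = out.to_numpy()
        vals[np.unravel_index(flat, (n, p))] = np.nan
        out.iloc[:, :] = vals
    elif mode.upper() == "LOD":
        k = int(round(rate * n))
        vals = out.to_numpy()
        for j in range(p):
            order = np.argsort(vals[:, j], kind="stable")
            vals[order[:k], j] = np.nan
        out.iloc[:, :] = vals
    else:
        raise SimulationError(f"unknown missingness mode {mode!r}")
    return out


def _build_design(config: SimulationConfig, rng: np.random.Generator):
    rows = []
    company_names = [chr(ord("A") + i) for i in range(config.n_companies)]
    sizes = (
        [config.animals_per_batch] * config.n_batches
        if isinstance(config.animals_per_batch, int)
        else list(config.animals_per_batch)
    )
    batch_idx = 0
    animal = 0
    for comp, n_b in zip(company_names, config.batches_per_company):
        for _ in range(n_b):
            batch = f"B{batch_idx + 1:02d}"
            size = sizes[batch_idx]
            pens = [f"{batch}_P{j + 1}" for j in range(config.pens_per_batch)]
            litters = [
                f"{batch}_L{j + 1}" for j in range(config.litters_per_batch)
            ]
            litter_assign = rng.choice(len(litters), size=size)
            for i in range(size):
                rows.append({
                    "animal_id": f"A{animal + 1:04d}",
                    "company": comp,
                    "batch": batch,
                    "pen": pens[i % config.pens_per_batch],
                    "litter": litters[litter_assign[i]],
                })
                animal += 1
            batch_idx += 1
    design = pd.DataFrame(rows)
    n = len(design)
    design["entry_age"] = np.clip(
        np.round(rng.normal(27.0, 2.0, size=n)), 21, 33
    ).astype(int)
    # toy-enrichment status varies by pen; RIN is a sample-quality score
    pens = design["batch"].astype(str) + "::" + design["pen"].astype(str)
    toy_by_pen = {p: int(rng.integers(0, 2)) for p in pens.unique()}
    design["toy"] = pens.map(toy_by_pen).astype(str)
    design["rin"] = np.round(np.clip(rng.normal(8.0, 0.5, size=n), 5, 10), 2)
    return design


def _simulate_genotypes(
    config: SimulationConfig, design: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(design)
    lo, hi = config.maf_range
    base = rng.uniform(lo, hi, size=config.n_snps)
    companies = design["company"].to_numpy()
    X = np.empty((n, config.n_snps), dtype=np.int64)
    for comp in pd.unique(companies):
        idx = np.flatnonzero(companies == comp)
        p = np.clip(base + rng.normal(0.0, 0.03, size=config.n_snps),
                    0.01, 0.99)
        X[idx] = rng.binomial(2, p, size=(idx.size, config.n_snps))
    return pd.DataFrame(
        X,
        index=design["animal_id"],
        columns=[f"snp{j + 1}" for j in range(config.n_snps)],
    )


def _feature_signals(
    config: SimulationConfig,
    layer: str,
    genotypes: pd.DataFrame,
    design: pd.DataFrame,
    rng: np.random.Generator,
    snps_per_feature: int = 10,
    batch_shift_sd: float = 0.5,
    pen_shift_sd: float = 0.3,
    factor_share: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent feature signals: (core, observed) matrices.

    ``core`` is the genetically anchored signal plus non-genetic
    variation (unit variance); ``observed`` adds batch and pen shifts,
    which the downstream residualization is meant to remove.  The
    non-genetic part has co-expression-module structure: each feature
    belongs to one of ~p/25 modules whose members share a latent
    factor carrying ``factor_share`` of the non-genetic variance.
    Without such co-regulation, nearest-neighbor imputation (and its
    masking validation) would have nothing to work with.
    """
    n = len(design)
    p = config.n_features_per_layer[layer]
    a = config.genetic_anchor.get(layer, 0.0)
    W = genotypes.to_numpy(dtype=float)
    W = W - W.mean(axis=0)
    n_modules = max(4, p // 25)
    F = rng.standard_normal((n, n_modules))
    module = rng.integers(0, n_modules, size=p)
    core = np.empty((n, p))
    for j in range(p):
        eps = (
            np.sqrt(factor_share) * F[:, module[j]]
            + np.sqrt(1.0 - factor_share) * rng.standard_normal(n)
        )
        if a > 0:
            snps = rng.choice(W.shape[1], size=snps_per_feature, replace=False)
            wts = rng.standard_normal(snps_per_feature)
            g = W[:, snps] @ wts
            sd = g.std(ddof=0)
            g = g / sd if sd > 0 else g
            core[:, j] = np.sqrt(a) * g + np.sqrt(1.0 - a) * eps
        else:
            core[:, j] = eps
    batches = design["batch"].to_numpy()
    pens = (design["batch"].astype(str) + "::" + design["pen"]).to_numpy()
    observed = core.copy()
    for labels, sd in ((batches, batch_shift_sd), (pens, pen_shift_sd)):
        uniq, inv = np.unique(labels, return_inverse=True)
        shifts = rng.normal(0.0, sd, size=(uniq.size, p))
        observed = observed + shifts[inv]
    return core, observed


def _raw_layer(
    layer: str, observed: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Map latent signals to the raw measurement scale of the layer."""
    n, p = observed.shape
    if layer == "transcriptome":
        # exponentiate Gaussian signal into negative-binomial means
        log_mu = rng.normal(4.0, 1.5, size=p) + 0.5 * observed
        mu = np.exp(np.clip(log_mu, -10, 14))
        r = 10.0
        return rng.negative_binomial(r, r / (r + mu)).astype(float)
    if layer == "proteome":
        base = rng.normal(10.0, 2.0, size=p)
        return 2.0 ** (base + observed)
    if layer == "metabolome":
        base = rng.normal(5.0, 1.0, size=p)
        return 2.0 ** (base + observed)
    raise SimulationError(f"unknown layer {layer!r}")


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort under the configured generative model."""
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("design", "genotypes", "layers", "phenotypes", "missingness"),
            ss.spawn(5),
        )
    }
    design = _build_design(config, streams["design"])
    genotypes = _simulate_genotypes(config, design, streams["genotypes"])
    animals = list(design["animal_id"])
    n = len(animals)

    kernels: dict[str, RelationshipKernel] = {}
    kernels["G"] = stabilize_kernel(
        build_genomic_kernel(genotypes, design.set_index("animal_id")["company"])
    )
    raw_layers: dict[str, pd.DataFrame] = {}
    lod_masks: dict[str, pd.DataFrame] = {}
    layer_rng = streams["layers"]
    miss_seed_root = np.random.SeedSequence(config.seed + 1)
    miss_children = iter(miss_seed_root.spawn(len(config.n_features_per_layer)))
    for layer in ("transcriptome", "proteome", "metabolome"):
        if layer not in config.n_features_per_layer:
            continue
        core, observed = _feature_signals(config, layer, genotypes, design,
                                          layer_rng)
        Mc = core - core.mean(axis=0)
        sd = Mc.std(axis=0, ddof=0)
        Mc = Mc / np.where(sd > 0, sd, 1.0)
        K = Mc @ Mc.T / Mc.shape[1]
        kernels[LAYER_LETTER[layer]] = stabilize_kernel(RelationshipKernel(
            animal_ids=animals, values=K, layer=LAYER_LETTER[layer]
        ))
        raw = _raw_layer(layer, observed, layer_rng)
        prefix = {"transcriptome": "gene", "proteome": "prot",
                  "metabolome": "met"}[layer]
        df = pd.DataFrame(
            raw,
            index=animals,
            columns=[f"{prefix}{j + 1}" for j in range(raw.shape[1])],
        )
        df.index.name = "animal_id"
        rate = config.missingness.get(layer, 0.0)
        if rate > 0:
            mode = "LOD" if layer == "metabolome" else "MAR"
            seed_child = next(miss_children)
            df_missing = inject_missingness(
                df, rate, mode=mode,
                seed=int(seed_child.generate_state(1)[0] % (2 ** 31)),
            )
            if mode == "LOD":
                lod_masks[layer] = df_missing.isna()
            df = df_missing
        raw_layers[layer] = df

    # phenotypes under the multi-kernel mixed model
    prng = streams["phenotypes"]
    chol = {
        k: np.linalg.cholesky(
            kern.values + 1e-8 * np.eye(n)
        )
        for k, kern in kernels.items()
    }
    pens = (design["batch"].astype(str) + "::" + design["pen"]).to_numpy()
    litters = design["litter"].to_numpy()
    age = design["entry_age"].to_numpy(dtype=float)
    phen = {}
    random_effects: dict[str, dict[str, np.ndarray]] = {}
    liabilities: dict[str, np.ndarray] = {}
    for trait, comps in config.true_varcomps.items():
        effects: dict[str, np.ndarray] = {}
        total = sum(comps.values())
        for key, s2 in comps.items():
            if key in RANDOM_TERMS:
                continue
            effects[key] = (
                chol[key] @ prng.standard_normal(n) * np.sqrt(s2)
                if s2 > 0 else np.zeros(n)
            )
        for labels, key in ((pens, "pen"), (litters, "litter")):
            s2 = comps.get(key, 0.0)
            uniq, inv = np.unique(labels, return_inverse=True)
            effects[key] = (
                prng.normal(0.0, np.sqrt(s2), size=uniq.size)[inv]
                if s2 > 0 else np.zeros(n)
            )
        effects["residual"] = prng.normal(
            0.0, np.sqrt(comps.get("residual", 0.0)), size=n
        )
        liability = sum(effects.values())
        if trait in config.binary_traits:
            # no fixed-effect shifts on binary liabilities, so prevalence
            # follows the normal-threshold expectation exactly
            liabilities[trait] = liability
            phen[trait] = (liability > config.binary_traits[trait]).astype(int)
        else:
            # modest management effects: batch means add ~4% and entry age
            # ~1% of the configured phenotypic variance, so the sample
            # variance of a trait stays close to the component total
            uniq, inv = np.unique(design["batch"].to_numpy(),
                                  return_inverse=True)
            batch_fx = prng.normal(
                0.0, 0.2 * np.sqrt(total), size=uniq.size
            )[inv]
            age_sd = age.std(ddof=0)
            beta_age = 0.1 * np.sqrt(total) / age_sd if age_sd > 0 else 0.0
            phen[trait] = (
                batch_fx + beta_age * (age - age.mean()) + liability
            )
        random_effects[trait] = effects

    phenotypes = pd.DataFrame(phen, index=animals)
    phenotypes.index.name = "animal_id"
    return SyntheticCohort(
        genotypes=genotypes,
        design=design,
        raw_layers=raw_layers,
        lod_masks=lod_masks,
        phenotypes=phenotypes,
        truth=CohortTruth(
            kernels=kernels,
            random_effects=random_effects,
            liabilities=liabilities,
            config=config,
        ),
    )


def liability_threshold(prevalence: float, total_variance: float = 1.0) -> float:
    """Threshold giving the requested prevalence under a normal liability."""
    if not 0.0 < prevalence < 1.0:
        raise SimulationError("prevalence must be in (0, 1)")
    return float(norm.ppf(1.0 - prevalence) * np.sqrt(total_variance))


# ---------------------------------------------------------------------------
# default study-layout configuration
# ---------------------------------------------------------------------------

#: trait -> (genomic share, litter share, prevalence-if-binary)
_TRAIT_TABLE: dict[str, tuple[float, float, float | None]] = {
    "qNurADG": (0.26, 0.13, None),
    "qNurHS1": (0.09, 0.00, None),
    "qNurHS2": (0.02, 0.04, None),
    "cNurADG": (0.30, 0.04, None),
    "cNurHS": (0.06, 0.02, None),
    "cNurTRT": (0.18, 0.00, None),
    "cNurMOR": (0.15, 0.00, 0.11),
    "FinADG": (0.20, 0.12, None),
    "FinHS": (0.01, 0.06, None),
    "FinTRT": (0.00, 0.05, None),
    "AllTRT": (0.15, 0.00, None),
    "FinMOR": (0.00, 0.00, 0.13),
    "AllMOR": (0.11, 0.00, 0.23),
    "ADFI": (0.37, 0.05, None),
    "FCR": (0.37, 0.18, None),
    "RFI": (0.68, 0.00, None),
    "CWT": (0.25, 0.17, None),
    "DRS": (0.30, 0.10, None),
    "LYD": (0.71, 0.02, None),
    "CLD": (0.43, 0.00, None),
    "CBF": (0.72, 0.03, None),
}

#: early (quarantine-nursery) traits get larger transcriptomic and
#: metabolomic shares, mirroring the stage-specific pattern the blood
#: profiles are expected to show.
_EARLY_TRAITS = {"qNurADG", "qNurHS1", "qNurHS2"}


def table1_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default cohort layout: 836 animals, 15 batches, 6 companies.

    Company/batch sizes mirror the enrolment table of the natural
    disease challenge cohort (companies with 2, 4, 1, 3, 3 and 2
    batches; batch sizes between 34 and 71 animals); three companies
    have at least three batches and are therefore eligible for
    leave-one-batch-out validation.  Per-trait genomic and litter
    variance shares follow the cohort's genomic-model estimates; pen
    share is 0.03 throughout; omics shares are larger for
    quarantine-nursery traits than for later traits.
    """
    varcomps = {}
    binary = {}
    for trait, (h2, lit, prev) in _TRAIT_TABLE.items():
        if trait in _EARLY_TRAITS:
            omics = {"T": 0.08, "P": 0.03, "M": 0.08}
        else:
            omics = {"T": 0.03, "P": 0.01, "M": 0.02}
        pen = 0.03
        resid = 1.0 - h2 - lit - pen - sum(omics.values())
        varcomps[trait] = {"G": h2, **omics, "pen": pen, "litter": lit,
                           "residual": round(resid, 10)}
        if prev is not None:
            binary[trait] = liability_threshold(prev, 1.0)
    defaults = dict(
        n_companies=6,
        batches_per_company=[2, 4, 1, 3, 3, 2],
        animals_per_batch=[67, 68, 53, 53, 67, 71, 45, 43, 49, 54,
                           34, 64, 60, 54, 54],
        pens_per_batch=5,
        litters_per_batch=10,
        n_snps=5000,
        maf_range=(0.05, 0.5),
        n_features_per_layer={
            "transcriptome": 2000, "proteome": 354, "metabolome": 44,
        },
        genetic_anchor={
            "transcriptome": 0.4, "proteome": 0.3, "metabolome": 0.3,
        },
        true_varcomps=varcomps,
        binary_traits=binary,
        missingness={"proteome": 0.10, "metabolome": 0.05},
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
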
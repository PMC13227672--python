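"""End-to-end orchestration: simulate -> preprocess -> kernels -> fits -> CV.

A single YAML config drives a full run; outputs are delimited tables in
a deterministic directory layout plus a JSON reproducibility manifest
(config hash, seed, package version, per-file digests, and the
non-convergence log).  Expensive REML results are written as one row
per trait x model, mirroring a variance-partition supplement, with the
cross-validation results in a companion accuracy table.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as oio
from .kernels import (
    RelationshipKernel,
    build_genomic_kernel,
    build_omics_kernel,
    stabilize_kernel,
)
from .preprocess import (
    FeatureModelSpec,
    filter_metabolites,
    knn_impute,
    normalize_counts,
    qc_genotypes,
    residualize_features,
    validate_imputation,
)
from .crossval import run_cv
from .synthdata import SimulationConfig, simulate_cohort, table1_config
from .varcomp import (
    ModelSpec,
    enumerate_model_specs,
    fit_reml,
    variance_report,
)

__all__ = ["RunManifest", "RunConfig", "run_all", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    nonconvergence: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps({
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "nonconvergence": self.nonconvergence,
        }, indent=2, sort_keys=True) + "\n")


@dataclass
class RunConfig:
    """Parsed run configuration: simulation plus analysis settings."""

    simulation: SimulationConfig
    traits: list[str]
    models: str | list[str] = "all"
    kernel_layers: tuple[str, ...] = ("G", "T", "P", "M")
    combined_variants: bool = True
    min_batches: int = 3
    adjust_mode: str = "per_fold"
    run_cv: bool = True
    imputation_k: int = 10
    validate_proteome_imputation: bool = True
    raw: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    sim_raw = raw.get("simulation", {})
    if sim_raw.get("layout") == "table1" or not sim_raw:
        overrides = {
            k: v for k, v in sim_raw.items() if k != "layout"
        }
        sim = table1_config(**overrides)
    else:
        sim = SimulationConfig.from_dict(sim_raw)
    analysis = raw.get("analysis", {})
    traits = analysis.get("traits", "all")
    if traits == "all":
        traits = list(sim.true_varcomps)
    return RunConfig(
        simulation=sim,
        traits=traits,
        models=analysis.get("models", "all"),
        kernel_layers=tuple(analysis.get("kernel_layers", "GTPM")),
        combined_variants=analysis.get("combined_variants", True),
        min_batches=analysis.get("min_batches", 3),
        adjust_mode=analysis.get("adjust_mode", "per_fold"),
        run_cv=analysis.get("run_cv", True),
        imputation_k=analysis.get("imputation_k", 10),
        validate_proteome_imputation=analysis.get(
            "validate_proteome_imputation", True
        ),
        raw=raw,
    )


def build_kernels_from_cohort(cohort, config: RunConfig,
                              manifest: RunManifest | None = None):
    """Preprocess raw layers and assemble all requested kernels."""
    kernels: dict[str, RelationshipKernel] = {}
    design = cohort.design
    if "G" in config.kernel_layers:
        qcd, report = qc_genotypes(cohort.genotypes)
        kernels["G"] = stabilize_kernel(build_genomic_kernel(
            qcd, design.set_index("animal_id")["company"]
        ))
        if manifest is not None:
            manifest.stages["qc_genotypes"] = report
    layer_of = {"T": "transcriptome", "P": "proteome", "M": "metabolome"}
    for letter in config.kernel_layers:
        if letter == "G":
            continue
        layer = layer_of[letter]
        if layer not in cohort.raw_layers:
            raise PipelineError(
                "kernels", f"layer {layer!r} not present in the cohort"
            )
        raw = cohort.raw_layers[layer]
        if layer == "transcriptome":
            mat = normalize_counts(raw)
        elif layer == "metabolome":
            mat, rep = filter_metabolites(
                raw, cohort.lod_masks.get("metabolome")
            )
            if manifest is not None:
                manifest.stages["filter_metabolites"] = {
                    "n_in": int(raw.shape[1]),
                    "n_retained": int(mat.shape[1]),
                }
        else:  # proteome: log2 first, then impute on the log scale
            logged = np.log2(raw)
            mat = knn_impute(logged, k=config.imputation_k)
            if config.validate_proteome_imputation:
                acc, retained = validate_imputation(
                    logged,
                    n_masked_features=min(100, logged.shape[1]),
                    n_repeats=10,
                    seed=config.simulation.seed,
                    k=config.imputation_k,
                )
                if not retained:
                    raise PipelineError(
                        "preprocess",
                        "no proteome feature passed the imputation-"
                        "accuracy retention rule",
                    )
                mat = mat.loc[:, retained]
                if manifest is not None:
                    manifest.stages["validate_imputation"] = {
                        "n_in": int(raw.shape[1]),
                        "n_retained": len(retained),
                    }
        spec = FeatureModelSpec(layer=layer)
        M = residualize_features(mat, spec, design)
        kernels[letter] = stabilize_kernel(build_omics_kernel(M))
    return kernels


def run_all(config_path, outdir, plot: bool = False) -> Path:
    """Execute the full pipeline from one YAML config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = load_config(config_path)
    cfg_hash = hashlib.sha256(
        Path(config_path).read_bytes()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=config.simulation.seed,
        version=__version__,
    )

    # ---- simulate --------------------------------------------------------
    try:
        cohort = simulate_cohort(config.simulation)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    write_cohort(cohort, outdir / "cohort")
    manifest.stages["simulate"] = {
        "n_animals": len(cohort.design),
        "n_batches": config.simulation.n_batches,
    }

    # ---- preprocess + kernels -------------------------------------------
    try:
        kernels = build_kernels_from_cohort(cohort, config, manifest)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("kernels", str(exc)) from exc
    kdir = outdir / "kernels"
    for letter, kern in kernels.items():
        oio.write_kernel(kern, kdir / f"{letter}.tsv")

    # ---- model grid ------------------------------------------------------
    if config.models == "all":
        specs = enumerate_model_specs(
            tuple(k for k in config.kernel_layers if k in kernels),
            combined_variants=config.combined_variants,
        )
    else:
        specs = []
        for label in config.models:
            combined = label.endswith("-mean")
            letters = tuple(label.replace("-mean", ""))
            specs.append(ModelSpec(trait="", kernel_set=letters,
                                   combined=combined))

    # ---- variance components --------------------------------------------
    var_rows = []
    cv_rows = []
    fold_rows = []
    for trait in config.traits:
        y = cohort.phenotypes[trait]
        for spec in specs:
            spec_t = ModelSpec(
                trait=trait, kernel_set=spec.kernel_set,
                combined=spec.combined, fixed_terms=list(spec.fixed_terms),
                include_pen=spec.include_pen,
                include_litter=spec.include_litter,
            )
            try:
                fit = fit_reml(y, cohort.design, spec_t, kernels)
            except Exception as exc:
                raise PipelineError(
                    "fit", f"trait={trait} model={spec_t.label}: {exc}"
                ) from exc
            row = {
                "trait": trait,
                "model": spec_t.label,
                "converged": fit.converged,
                "n_iterations": fit.n_iterations,
                "loglik": fit.loglik_restricted,
            }
            for name, v in fit.sigma2.items():
                row[f"sigma2_{name}"] = v
            if fit.converged:
                rep = variance_report(fit)
                row["total_omics_share"] = rep.total_omics_share
                for k, v in rep.per_kernel_share.items():
                    row[f"share_{k}"] = v
                row["pen_share"] = rep.pen_share
                row["litter_share"] = rep.litter_share
                row["residual_share"] = rep.residual_share
            else:
                manifest.nonconvergence.append(
                    f"fit trait={trait} model={spec_t.label}"
                )
            var_rows.append(row)

            if config.run_cv:
                try:
                    cv = run_cv(
                        trait, spec_t, cohort.design, kernels, y,
                        min_batches=config.min_batches,
                        adjust_mode=config.adjust_mode,
                    )
                except Exception as exc:
                    raise PipelineError(
                        "cv", f"trait={trait} model={spec_t.label}: {exc}"
                    ) from exc
                cv_rows.append({
                    "trait": trait,
                    "model": cv.model,
                    "weighted_accuracy": cv.weighted_accuracy,
                    "pooled_auc": cv.pooled_auc,
                    "n_folds_converged": cv.n_folds_converged,
                })
                for batch, nv, r in cv.per_fold:
                    fold_rows.append({
                        "trait": trait, "model": cv.model,
                        "validation_batch": batch, "n_validation": nv,
                        "correlation": r,
                    })
                manifest.nonconvergence.extend(
                    f"cv trait={trait} model={cv.model}: {msg}"
                    for msg in cv.fold_log
                )

    var_table = pd.DataFrame(var_rows)
    oio.write_table(var_table, outdir / "variance_components.tsv")
    if cv_rows:
        oio.write_table(pd.DataFrame(cv_rows), outdir / "cv_accuracy.tsv")
        oio.write_table(pd.DataFrame(fold_rows), outdir / "cv_folds.tsv")

    if plot:
        _plots(var_table, pd.DataFrame(cv_rows) if cv_rows else None, outdir)

    for f in sorted(outdir.rglob("*.tsv")):
        manifest.stages.setdefault("digests", {})[
            str(f.relative_to(outdir))
        ] = oio.file_digest(f)
    manifest.write(outdir / "manifest.json")
    return outdir


def write_cohort(cohort, outdir) -> None:
    """Serialize a cohort as delimited text plus a truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    oio.write_matrix(cohort.genotypes, outdir / "genotypes.tsv")
    oio.write_table(cohort.design, outdir / "design.tsv")
    oio.write_matrix(cohort.phenotypes, outdir / "phenotypes.tsv")
    for layer, df in cohort.raw_layers.items():
        oio.write_matrix(df, outdir / f"{layer}.tsv")
    for layer, mask in cohort.lod_masks.items():
        oio.write_matrix(mask.astype(int), outdir / f"{layer}_lod_mask.tsv")
    truth = {
        "config": cohort.truth.config.to_dict(),
        "realized_variances": {
            trait: {
                term: float(np.var(vec))
                for term, vec in effects.items()
            }
            for trait, effects in cohort.truth.random_effects.items()
        },
    }
    (outdir / "truth.json").write_text(
        json.dumps(oio._jsonable(truth), indent=2, sort_keys=True) + "\n"
    )


def _plots(var_table: pd.DataFrame, cv_table: pd.DataFrame | None,
           outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "total_omics_share" in var_table:
        fig, ax = plt.subplots(figsize=(10, 4))
        pivot = var_table.pivot_table(
            index="model", columns="trait", values="total_omics_share"
        )
        pivot.plot.bar(ax=ax)
        ax.set_ylabel("total omics variance share")
        fig.tight_layout()
        fig.savefig(outdir / "variance_shares.png", dpi=120)
        plt.close(fig)
    if cv_table is not None and not cv_table.empty:
        fig, ax = plt.subplots(figsize=(10, 4))
        pivot = cv_table.pivot_table(
            index="model", columns="trait", values="weighted_accuracy"
        )
        pivot.plot.bar(ax=ax)
        ax.set_ylabel("LOBO weighted accuracy")
        fig.tight_layout()
        fig.savefig(outdir / "cv_accuracy.png", dpi=120)
        plt.close(fig)
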
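"""Delimited-text readers/writers and sidecar metadata.

Everything is plain TSV: feature matrices are animals x features with an
``animal_id`` index column; kernels are square matrices with the animal
ids as both header row and index column.  Each writer can attach a JSON
"sidecar" (``<file>.meta.json``) recording provenance: filters applied,
features dropped, ridge added, and so on.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import RelationshipKernel

SEP = "\t"


def write_matrix(df: pd.DataFrame, path, index_label: str = "animal_id",
                 sidecar: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=SEP, index_label=index_label, float_format="%.10g")
    if sidecar is not None:
        write_sidecar(path, sidecar)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, index_col=0)


def write_table(df: pd.DataFrame, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=SEP, index=False, float_format="%.10g")
    if sidecar is not None:
        write_sidecar(path, sidecar)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP)


def write_kernel(kernel: RelationshipKernel, path) -> None:
    path = Path(path)
    write_matrix(kernel.to_dataframe(), path)
    write_sidecar(path, {
        "layer": kernel.layer,
        "ridge_applied": kernel.ridge_applied,
        "n": kernel.n,
        **kernel.meta,
    })


def read_kernel(path) -> RelationshipKernel:
    path = Path(path)
    df = read_matrix(path)
    meta = read_sidecar(path) or {}
    layer = meta.pop("layer", "K")
    ridge = float(meta.pop("ridge_applied", 0.0))
    meta.pop("n", None)
    return RelationshipKernel(
        animal_ids=[str(a) for a in df.index],
        values=df.to_numpy(dtype=float),
        layer=layer,
        ridge_applied=ridge,
        meta=meta,
    )


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.name + ".meta.json")


def write_sidecar(path, meta: dict) -> None:
    sidecar_path(path).write_text(
        json.dumps(_jsonable(meta), indent=2, sort_keys=True) + "\n"
    )


def read_sidecar(path) -> dict | None:
    sp = sidecar_path(path)
    if not sp.exists():
        return None
    return json.loads(sp.read_text())


def file_digest(path) -> str:
    """SHA-256 digest of a file, for the reproducibility manifest."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
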
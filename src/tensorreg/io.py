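"""Volume ingestion, parameter serialization and coefficient-surface export.

Volumes are read and written as NIfTI-1 via nibabel, with class labels in
a tab-separated sidecar table (``filename<TAB>class``).  Fitted parameters
are stored as JSON (component vectors are small: R*(d1+d2+d3) numbers per
class).  Coefficient surfaces — the pairwise outer-product matrices
``beta^1 o beta^2``, ``beta^1 o beta^3``, ``beta^2 o beta^3`` per
non-reference class — localize the image regions that drive each class's
log-odds against the reference; they are exported as CSV matrices and
rendered heatmaps, together with a top-|value| mask of the most
discriminative cells.

Axis convention: voxel indices are 0-based and surfaces are labeled by the
storage axis pair (``axes12`` etc.), not by anatomical orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import Dataset, ModelParams
from .tensor_algebra import CPTensor

__all__ = [
    "load_volumes",
    "save_volumes",
    "save_params",
    "load_params",
    "CoefficientSurfaces",
    "compute_surfaces",
    "export_surfaces",
]

_SURFACE_PAIRS = ((1, 2), (1, 3), (2, 3))


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def load_volumes(
    paths: Sequence, labels_table, class_names: Optional[Sequence[str]] = None
) -> Dataset:
    """Build a Dataset from NIfTI files and a label sidecar table.

    ``labels_table`` is a tab- or comma-separated file with columns
    ``filename`` and ``class``; every path's basename must appear in it.
    Volumes must share one shape and contain no NaN voxels; violations
    raise errors naming the offending file.
    """
    import nibabel as nib
    import pandas as pd

    labels_table = Path(labels_table)
    if not labels_table.exists():
        raise FileNotFoundError(f"labels table not found: {labels_table}")
    table = pd.read_csv(labels_table, sep=None, engine="python")
    if not {"filename", "class"} <= set(table.columns):
        raise ValueError(
            f"labels table {labels_table} must have 'filename' and 'class' columns, "
            f"found {list(table.columns)}"
        )
    label_of = dict(zip(table["filename"].astype(str), table["class"].astype(str)))
    if class_names is None:
        class_names = sorted(set(label_of.values()))
    class_index = {c: k for k, c in enumerate(class_names)}

    volumes, y = [], []
    shape = None
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"volume file not found: {p}")
        name = p.name
        if name not in label_of:
            raise ValueError(f"no label for volume {name} in {labels_table}")
        cls = label_of[name]
        if cls not in class_index:
            raise ValueError(
                f"volume {name} has unknown class {cls!r}; valid classes: {list(class_names)}"
            )
        vol = np.asanyarray(nib.load(str(p)).dataobj, dtype=float)
        if vol.ndim != 3:
            raise ValueError(f"volume {name} is not 3-D (ndim={vol.ndim})")
        if np.isnan(vol).any():
            raise ValueError(f"volume {name} contains NaN voxels")
        if shape is None:
            shape = vol.shape
        elif vol.shape != shape:
            raise ValueError(
                f"volume {name} has shape {vol.shape}, expected {shape} "
                f"(set by the first volume)"
            )
        volumes.append(vol)
        y.append(class_index[cls])
    if not volumes:
        raise ValueError("no volumes given")
    return Dataset.from_arrays(np.stack(volumes), np.asarray(y), class_names=list(class_names))


def save_volumes(data: Dataset, outdir, prefix: str = "vol") -> Path:
    """Write each volume as ``<prefix>_NNNN.nii`` plus a ``labels.tsv``
    sidecar; returns the sidecar path."""
    import nibabel as nib
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(data.n):
        name = f"{prefix}_{i:04d}.nii"
        img = nib.Nifti1Image(data.images[i], affine=np.eye(4))  # float64: lossless round trip
        nib.save(img, str(outdir / name))
        rows.append((name, data.class_names[data.label_indices[i]]))
    sidecar = outdir / "labels.tsv"
    pd.DataFrame(rows, columns=["filename", "class"]).to_csv(sidecar, sep="\t", index=False)
    return sidecar


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def save_params(
    params: ModelParams,
    path,
    config: Optional[dict] = None,
    class_names: Optional[Sequence[str]] = None,
    standardization: Optional[tuple] = None,
) -> None:
    """Serialize fitted parameters (component vectors + metadata) to JSON."""
    payload = {
        "format": "tensorreg-params-v1",
        "shape": list(params.shape),
        "rank": params.rank,
        "reference_class": params.reference_class,
        "cp": [[m.tolist() for m in t.factors] for t in params.cp],
        "intercepts": None if params.intercepts is None else params.intercepts.tolist(),
        "covariate_coefs": (
            None if params.covariate_coefs is None else params.covariate_coefs.tolist()
        ),
        "class_names": None if class_names is None else list(class_names),
        "standardization": None if standardization is None else list(standardization),
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_params(path) -> tuple[ModelParams, dict]:
    """Inverse of :func:`save_params`; returns ``(params, metadata)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    payload = json.loads(path.read_text())
    if payload.get("format") != "tensorreg-params-v1":
        raise ValueError(f"{path} is not a tensorreg parameter file")
    params = ModelParams(
        cp=[CPTensor([np.asarray(m) for m in t]) for t in payload["cp"]],
        reference_class=int(payload["reference_class"]),
        intercepts=None if payload["intercepts"] is None else np.asarray(payload["intercepts"]),
        covariate_coefs=(
            None
            if payload["covariate_coefs"] is None
            else np.asarray(payload["covariate_coefs"])
        ),
    )
    meta = {
        k: payload.get(k) for k in ("class_names", "standardization", "config", "shape", "rank")
    }
    return params, meta


# ---------------------------------------------------------------------------
# coefficient surfaces
# ---------------------------------------------------------------------------

@dataclass
class CoefficientSurfaces:
    """Pairwise outer-product coefficient matrices per non-reference class.

    ``surfaces[k][(j, l)]`` is the d_j x d_l matrix ``beta^j o beta^l``
    (summed over rank); ``masks`` holds boolean top-``top_fraction``
    |value| masks of the same shapes.
    """

    surfaces: dict       # class index -> {(1,2): M, (1,3): M, (2,3): M}
    masks: dict
    top_fraction: float

    @property
    def class_indices(self) -> list:
        return sorted(self.surfaces)


def _top_mask(M: np.ndarray, q: float) -> np.ndarray:
    flat = np.abs(M).ravel()
    k = max(1, int(round(q * flat.size)))
    if not flat.any():
        return np.zeros_like(M, dtype=bool)
    thresh = np.partition(flat, -k)[-k]
    return np.abs(M) >= thresh


def compute_surfaces(params: ModelParams, top_fraction: float = 0.05) -> CoefficientSurfaces:
    """Pairwise outer-product matrices and top-|value| masks for each class."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    surfaces, masks = {}, {}
    for m, k in enumerate(params.nonreference_classes):
        surfaces[k] = {pair: params.cp[m].surface(pair) for pair in _SURFACE_PAIRS}
        zero = not any(np.any(M) for M in surfaces[k].values())
        masks[k] = {
            pair: (np.zeros_like(M, dtype=bool) if zero else _top_mask(M, top_fraction))
            for pair, M in surfaces[k].items()
        }
    return CoefficientSurfaces(surfaces, masks, top_fraction)


def export_surfaces(
    params: ModelParams,
    outdir,
    top_fraction: float = 0.05,
    class_names: Optional[Sequence[str]] = None,
) -> CoefficientSurfaces:
    """Compute surfaces and write CSV matrices, heatmap PNGs, mask CSVs and
    a metadata JSON under ``outdir``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cs = compute_surfaces(params, top_fraction)
    written = []
    for k in cs.class_indices:
        label = class_names[k] if class_names is not None else f"class{k}"
        for (j, l), M in cs.surfaces[k].items():
            stem = f"{label}_axes{j}{l}"
            pd.DataFrame(M).to_csv(outdir / f"{stem}.csv", index=False, header=False)
            pd.DataFrame(cs.masks[k][(j, l)].astype(int)).to_csv(
                outdir / f"{stem}_mask.csv", index=False, header=False
            )
            fig, ax = plt.subplots(figsize=(5, 4))
            vmax = np.abs(M).max() or 1.0
            im = ax.imshow(M.T, origin="lower", cmap="viridis", vmin=-vmax, vmax=vmax)
            ax.set_xlabel(f"axis {j} (voxel index)")
            ax.set_ylabel(f"axis {l} (voxel index)")
            ax.set_title(f"{label}: beta^{j} ∘ beta^{l}")
            fig.colorbar(im, ax=ax)
            fig.savefig(outdir / f"{stem}.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(stem)
    meta = {
        "top_fraction": top_fraction,
        "shape": list(params.shape),
        "rank": params.rank,
        "reference_class": params.reference_class,
        "surfaces": written,
        "axis_convention": "0-based voxel indices, storage axis order (d1,d2,d3)",
    }
    (outdir / "surfaces_meta.json").write_text(json.dumps(meta, indent=1))
    return cs
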
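"""File formats, run configuration, and the end-to-end pipeline.

Masks are read from NIfTI volumes (spacing taken from the header, slice
user-selected), PNG images, or NumPy ``.npy`` arrays.  Reports are written
as pretty-printed JSON with sorted keys and as CSV rows so that reruns
with the same configuration and seed produce byte-identical outputs; every
output carries the hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import survival as surv_mod
from .errors import GlioshapeError, MaskError
from .geometry import GeometryConfig, GeometryReport, MaskSlice, measure_boundary

__all__ = ["RunConfig", "read_mask", "write_geometry_report",
           "geometry_reports_to_csv", "run_pipeline", "config_hash"]


@dataclass
class RunConfig:
    """Every knob of a full run, serializable to YAML/JSON.

    All randomness is controlled by the explicit seeds here; a rerun with
    an identical config is deterministic.
    """

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    cut_points: dict = field(default_factory=lambda: dict(cohort_mod.CUT_POINTS))
    yates_correction: bool = False
    p_enter: float = 0.05
    p_remove: float = 0.10
    horizon_months: float = 36.0
    bootstrap_b: int = 200
    cv_folds: int = 5
    seed: int = 0
    output_dir: str = "glioshape-out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        geo = d.pop("geometry", {})
        if isinstance(geo, dict):
            geo = GeometryConfig(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in geo.items()})
        return cls(geometry=geo, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# --------------------------------------------------------------------------
# mask I/O
# --------------------------------------------------------------------------

def read_mask(path: str | Path, slice_index: int | None = None,
              spacing: tuple[float, float] | None = None,
              medial_hint: tuple[float, float] = (1.0, 0.0),
              threshold: float | None = None) -> MaskSlice:
    """Load a binary mask slice from NIfTI, PNG, or ``.npy``.

    For NIfTI the axial slice ``data[:, :, slice_index]`` is taken and the
    in-plane voxel sizes from the header are used unless ``spacing``
    overrides them.  Non-binary data raise unless an explicit ``threshold``
    is given.
    """
    path = Path(path)
    if not path.exists():
        raise MaskError("missing-file", f"no such file: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3:
            if slice_index is None:
                raise MaskError("slice-required", "3D volume needs slice_index")
            if not (0 <= slice_index < data.shape[2]):
                raise MaskError("slice-out-of-range",
                                f"slice {slice_index} outside [0, {data.shape[2]})")
            data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise MaskError("bad-mask", f"unsupported NIfTI rank {data.ndim}")
        zooms = img.header.get_zooms()[:2]
        hdr_spacing = (float(zooms[0]), float(zooms[1]))
    elif name.endswith(".npy"):
        data = np.load(path)
        hdr_spacing = (1.0, 1.0)
    elif name.endswith(".png"):
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path))
        if data.ndim == 3:
            data = data[..., 0]
        hdr_spacing = (1.0, 1.0)
    else:
        raise MaskError("bad-format", f"unsupported mask format: {path.suffix}")
    data = np.asarray(data)
    values = np.unique(data)
    if not np.isin(values, [0, 1]).all():
        if threshold is None:
            raise MaskError("non-binary",
                            "mask is not binary; pass an explicit threshold")
        data = data > threshold
    sl = slice_index if slice_index is not None else 0
    return MaskSlice(data.astype(bool), spacing=spacing or hdr_spacing,
                     slice_index=sl, medial_hint=medial_hint)


def write_mask_nifti(mask: MaskSlice, path: str | Path) -> None:
    """Write a 2D mask slice as a single-slice NIfTI volume."""
    data = mask.pixels.astype(np.uint8)[:, :, None]
    affine = np.diag([mask.spacing[0], mask.spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((mask.spacing[0], mask.spacing[1], 1.0))
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# report output
# --------------------------------------------------------------------------

def write_geometry_report(report: GeometryReport, path: str | Path,
                          config: RunConfig | None = None) -> None:
    d = report.to_dict()
    if config is not None:
        d["config_hash"] = config_hash(config)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")


def geometry_reports_to_csv(reports: dict[str, GeometryReport],
                            path: str | Path) -> pd.DataFrame:
    rows = []
    for key, rep in reports.items():
        d = rep.to_dict()
        d.pop("config")
        d["fd_replicates"] = ";".join(f"{r:.6f}" for r in rep.fd_replicates)
        rows.append({"tumor": key, **d})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _evaluate_model(model, sub: pd.DataFrame, config: RunConfig) -> dict:
    """Apply a risk model to its shape subgroup and validate internally."""
    out: dict = {}
    try:
        scores = surv_mod.risk_score(model, sub)
        out["apparent_c"] = surv_mod.harrell_c(sub, scores)
        coded = surv_mod.code_covariates(model, sub)
        fitdf = pd.concat([sub[["pfs_months", "event"]].reset_index(drop=True),
                           coded.reset_index(drop=True)], axis=1)
        out["bootstrap"] = surv_mod.bootstrap_validate(
            fitdf, list(model.coefficients), B=config.bootstrap_b,
            seed=config.seed)
        try:
            out["crossvalidation"] = surv_mod.crossvalidate(
                fitdf, list(model.coefficients), k=config.cv_folds,
                horizon=config.horizon_months, seed=config.seed)
        except GlioshapeError as exc:
            out["crossvalidation"] = {"error": exc.code}
    except GlioshapeError as exc:
        out["error"] = exc.code
    return out


def run_pipeline(config: RunConfig, cohort: pd.DataFrame,
                 masks: dict[str, MaskSlice] | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Measure → classify → associate → model → validate.

    ``masks`` maps patient id to a mask slice; measured shape labels (and
    tortuosity, when curved) override the cohort columns for those ids.
    Writes the report bundle (JSON/CSV, sorted keys) plus a manifest with
    seeds and the config hash; returns the bundle in memory.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    chash = config_hash(config)
    cohort = cohort.copy()

    geometry_reports: dict[str, GeometryReport] = {}
    if masks:
        for pid, mask in masks.items():
            rep = measure_boundary(mask, config.geometry)
            geometry_reports[pid] = rep
            sel = cohort["id"] == pid
            cohort.loc[sel, "shape_label"] = rep.shape_label
            if rep.tortuosity is not None:
                cohort.loc[sel, "tortuosity"] = rep.tortuosity
        geometry_reports_to_csv(geometry_reports, out / "geometry.csv")
    log.append({"stage": "geometry", "n_masks": len(geometry_reports)})

    assoc = cohort_mod.association_table(cohort, cut_points=config.cut_points)
    assoc.to_csv(out / "association.csv", index=False)
    log.append({"stage": "association", "n_variables": len(assoc),
                "n_patients": len(cohort)})

    results: dict = {"config_hash": chash, "geometry": geometry_reports,
                     "association": assoc}

    models_out = {}
    for model in (surv_mod.RISK_L, surv_mod.RISK_C):
        label = "L" if model is surv_mod.RISK_L else "C"
        sub = cohort[cohort["shape_label"] == label]
        needed = [r.column for r in model.coding.values()]
        sub = sub.dropna(subset=[c for c in needed if c in sub.columns])
        entry = {"name": model.name, "coefficients": model.coefficients,
                 "points": surv_mod.to_points(model),
                 "points_threshold": model.points_threshold,
                 "recorded": model.recorded, "n": int(len(sub))}
        if len(sub) >= 30 and sub["event"].sum() >= 5:
            entry.update(_evaluate_model(model, sub, config))
        models_out[model.name] = entry
        log.append({"stage": f"model-{model.name}", "n": entry["n"]})
    results["models"] = models_out

    with open(out / "models.json", "w") as fh:
        json.dump(models_out, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    manifest = {"config_hash": chash, "config": config.to_dict(),
                "stages": log, "n_patients": int(len(cohort))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
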
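"""Volume and cohort-manifest I/O.

Volumes travel as NIfTI (.nii/.nii.gz, via nibabel) or NRRD (.nrrd, via
SimpleITK); masks are unsigned 8-bit {0, 1} and dose grids 32-bit float Gy.
Arrays are handled in (x, y, z) index order with spacing (dx, dy, dz) in mm;
grid spacing always comes from the file header, which overrides anything a
manifest claims.

A cohort manifest is a JSON or YAML document:

    {"threshold_gy": 15.0,
     "cases": [{"case_id": "...", "oar": "liver.nii.gz",
                "target": "ptv.nii.gz", "dose": "dose.nii.gz",
                "prescription": 50.0, "plan_style": "isotropic-like"}, ...]}

Paths are resolved relative to the manifest's directory.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .cases import PatientCase
from .errors import CohortError, DimensionError
from .phantoms import PhantomSpec, generate_phantom

logger = logging.getLogger(__name__)


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a volume, returning (array in (x,y,z) order, spacing in mm)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return data, spacing
    if name.endswith(".nrrd"):
        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
        return data, spacing
    raise CohortError(f"unsupported volume format: {path.name}")


def write_volume(path: str | Path, data: np.ndarray,
                 spacing: tuple[float, float, float]) -> None:
    """Write a volume in the format implied by the file suffix."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(spacing) + [1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return
    if name.endswith(".nrrd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in spacing))
        sitk.WriteImage(img, str(path))
        return
    raise CohortError(f"unsupported volume format: {path.name}")


def write_mask(path: str | Path, mask: np.ndarray,
               spacing: tuple[float, float, float]) -> None:
    write_volume(path, np.asarray(mask, dtype=np.uint8), spacing)


def write_dose(path: str | Path, dose: np.ndarray,
               spacing: tuple[float, float, float]) -> None:
    write_volume(path, np.asarray(dose, dtype=np.float32), spacing)


def _as_binary_mask(data: np.ndarray, what: str, case_id: str) -> np.ndarray:
    values = np.unique(data)
    if set(values.tolist()) <= {0, 1}:
        return data.astype(bool)
    if set(values.tolist()) <= {0, 255}:
        warnings.warn(f"case {case_id!r}: {what} mask uses {{0, 255}}; "
                      f"normalized to {{0, 1}}")
        return data > 0
    raise CohortError(
        f"case {case_id!r}: {what} mask is not binary (values {values[:8]}...)")


def load_manifest(manifest_path: str | Path) -> dict:
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    if manifest_path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_cohort(manifest_path: str | Path) -> list[PatientCase]:
    """Load and validate every case referenced by a cohort manifest.

    Failures are descriptive and name the offending case_id; within a case
    all grids must share one shape and one header spacing.
    """
    manifest_path = Path(manifest_path)
    manifest = load_manifest(manifest_path)
    base = manifest_path.parent
    entries = manifest.get("cases", [])
    if not entries:
        raise CohortError(f"manifest {manifest_path} lists no cases")
    ids = [e.get("case_id") for e in entries]
    if len(set(ids)) != len(ids):
        raise CohortError("manifest contains duplicate case_ids")
    cases = []
    for entry in entries:
        cid = entry["case_id"]
        paths = {}
        for key in ("oar", "target", "dose"):
            p = base / entry[key]
            if not p.exists():
                raise CohortError(f"case {cid!r}: missing file {p}")
            paths[key] = p
        oar, sp_oar = read_volume(paths["oar"])
        target, sp_t = read_volume(paths["target"])
        dose, sp_d = read_volume(paths["dose"])
        if not (oar.shape == target.shape == dose.shape):
            raise CohortError(
                f"case {cid!r}: grid shape mismatch — oar {oar.shape}, "
                f"target {target.shape}, dose {dose.shape}")
        if not (np.allclose(sp_oar, sp_t) and np.allclose(sp_oar, sp_d)):
            raise CohortError(
                f"case {cid!r}: header spacing mismatch — {sp_oar}, {sp_t}, {sp_d}")
        cases.append(PatientCase(
            case_id=cid,
            oar_mask=_as_binary_mask(oar, "OAR", cid),
            target_mask=_as_binary_mask(target, "target", cid),
            dose=dose.astype(np.float64),
            spacing=sp_oar,  # header spacing overrides any manifest value
            prescription=float(entry["prescription"]),
            plan_style=entry.get("plan_style", "clinical-unknown"),
        ))
    return cases


def save_cohort(cases: list[PatientCase], out_dir: str | Path,
                specs: list[PhantomSpec] | None = None,
                fmt: str = "nii.gz") -> Path:
    """Write a cohort's volumes plus a JSON manifest; returns manifest path.

    When phantom specs are given they are embedded in the manifest so the
    cohort can be regenerated exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, case in enumerate(cases):
        stem = case.case_id
        files = {"oar": f"{stem}_oar.{fmt}", "target": f"{stem}_target.{fmt}",
                 "dose": f"{stem}_dose.{fmt}"}
        write_mask(out_dir / files["oar"], case.oar_mask, case.spacing)
        write_mask(out_dir / files["target"], case.target_mask, case.spacing)
        write_dose(out_dir / files["dose"], case.dose, case.spacing)
        entry = {"case_id": case.case_id, **files,
                 "prescription": case.prescription,
                 "plan_style": case.plan_style}
        if specs is not None:
            entry["phantom_spec"] = specs[i].to_dict()
        entries.append(entry)
    manifest = {"threshold_gy": 15.0, "cases": entries}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def save_estimator(est, path: str | Path) -> None:
    """Serialize a BinEstimatorSet: JSON for parameters, .npz sidecar for
    non-parametric resample point sets."""
    path = Path(path)
    doc = {
        "method": est.method,
        "bin_edges": est.bin_edges.tolist(),
        "bin_counts": est.bin_counts.tolist(),
        "scalar": None if est.scalar is None else est.scalar.tolist(),
        "skew_params": None if est.skew_params is None else est.skew_params.tolist(),
        "fallback": None if est.fallback is None else est.fallback.tolist(),
        "resamples_sidecar": None,
    }
    if est.resamples is not None:
        sidecar = path.with_suffix(".resamples.npz")
        arrays = {f"bin_{i}": r for i, r in enumerate(est.resamples)
                  if r is not None}
        np.savez_compressed(sidecar, **arrays)
        doc["resamples_sidecar"] = sidecar.name
    path.write_text(json.dumps(doc, indent=2))


def load_estimator(path: str | Path):
    from .svdl import BinEstimatorSet

    path = Path(path)
    doc = json.loads(path.read_text())
    resamples = None
    if doc.get("resamples_sidecar"):
        data = np.load(path.parent / doc["resamples_sidecar"])
        n_bins = len(doc["bin_edges"]) - 1
        resamples = [data[f"bin_{i}"] if f"bin_{i}" in data else None
                     for i in range(n_bins)]
    return BinEstimatorSet(
        method=doc["method"],
        bin_edges=np.asarray(doc["bin_edges"], float),
        bin_counts=np.asarray(doc["bin_counts"], int),
        scalar=None if doc["scalar"] is None else np.asarray(doc["scalar"], float),
        skew_params=None if doc["skew_params"] is None
        else np.asarray(doc["skew_params"], float),
        resamples=resamples,
        fallback=None if doc["fallback"] is None
        else np.asarray(doc["fallback"], bool),
    )


def replay_cohort(manifest_path: str | Path) -> list[PatientCase]:
    """Regenerate a phantom cohort from the specs embedded in its manifest."""
    manifest = load_manifest(manifest_path)
    specs = [PhantomSpec.from_dict(e["phantom_spec"])
             for e in manifest["cases"] if "phantom_spec" in e]
    if not specs:
        raise CohortError("manifest embeds no phantom specs; load_cohort instead")
    return [generate_phantom(s) for s in specs]
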
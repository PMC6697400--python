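"""On-disk formats.

All tables are UTF-8 TSV with one header row. Volumes are written as a
single ``volumes.npz`` (subject-stacked float32 array + mask + planted
cluster) with a JSON sidecar carrying voxel size and subject order, or as
per-subject NIfTI via nibabel. A manifest JSON records the generating
spec and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CohortDataset, CohortSpec, GMVStack

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_nifti",
    "read_volume",
    "spec_to_dict",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if callable(obj):
        return f"<callable {getattr(obj, '__name__', 'anonymous')}>"
    return obj


def spec_to_dict(spec: CohortSpec) -> dict:
    return _jsonable(spec)


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> Path:
    """Write cohort.tsv, percept_events.tsv, trials.tsv, volumes.npz (+
    sidecar) and manifest.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "cohort.tsv", sep="\t", index=False)
    cohort.percept_events.to_csv(out / "percept_events.tsv", sep="\t", index=False)
    cohort.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
    if cohort.images is not None:
        np.savez_compressed(
            out / "volumes.npz",
            values=cohort.images.values.astype(np.float32),
            mask=cohort.images.mask,
            planted=cohort.images.planted,
        )
        sidecar = {
            "voxel_size_mm": cohort.images.voxel_size_mm,
            "subjects": list(cohort.subjects["subject"]),
            "shape": list(cohort.images.values.shape[1:]),
        }
        (out / "volumes.json").write_text(json.dumps(sidecar, indent=2))
    manifest = {"spec": spec_to_dict(cohort.spec), "seed": cohort.spec.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_cohort(in_dir: str | Path) -> CohortDataset:
    """Read a cohort directory written by write_cohort. The generating
    spec is restored for scalar fields; callables fall back to defaults.
    Latent traits are not persisted (they are diagnostics only)."""
    src = Path(in_dir)
    subjects = pd.read_csv(src / "cohort.tsv", sep="\t")
    percept = pd.read_csv(src / "percept_events.tsv", sep="\t")
    trials = pd.read_csv(src / "trials.tsv", sep="\t")
    spec = CohortSpec()
    manifest_path = src / "manifest.json"
    if manifest_path.exists():
        raw = json.loads(manifest_path.read_text())["spec"]
        fields = {f.name: f for f in dataclasses.fields(CohortSpec)}
        kwargs = {}
        for k, v in raw.items():
            if k not in fields or isinstance(v, (dict, str)) and k != "seed":
                continue
            if isinstance(v, list):
                v = tuple(v)
            if isinstance(v, (int, float, tuple, bool)):
                kwargs[k] = v
        spec = CohortSpec(**kwargs)
    images = None
    npz_path = src / "volumes.npz"
    if npz_path.exists():
        with np.load(npz_path) as data:
            sidecar = json.loads((src / "volumes.json").read_text())
            images = GMVStack(
                values=data["values"].astype(np.float64),
                mask=data["mask"].astype(bool),
                voxel_size_mm=float(sidecar["voxel_size_mm"]),
                planted=data["planted"].astype(bool),
            )
    latents = pd.DataFrame({"subject": subjects["subject"]})
    return CohortDataset(
        spec=spec, subjects=subjects, percept_events=percept, trials=trials,
        images=images, latents=latents,
    )


def write_nifti(
    image: np.ndarray, path: str | Path, voxel_size_mm: float = 1.0, affine=None
) -> Path:
    """Write one 3D volume as NIfTI (.nii or .nii.gz)."""
    import nibabel as nib

    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(image, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))
    return Path(path)


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a volume from NIfTI (returns data + affine) or .npz (returns
    the stacked values with an identity affine)."""
    path = Path(path)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        return np.asarray(img.get_fdata()), img.affine
    with np.load(path) as data:
        return data["values"], np.eye(4)
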
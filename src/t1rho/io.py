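"""NIfTI volume / mask / sidecar I/O and YAML run configuration.

Each volume is stored as NIfTI-1 with a JSON sidecar carrying the contrast tag
(TSL in ms or "pd"), the subject id and a units note. Cohorts are laid out in
a BIDS-like tree: one directory per subject holding the weighted volumes, the
PD surrogate, the labeled ROI mask and the ground-truth map.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import ROIMask, T1rhoMap, WeightedVolume
from .nets import LimiterConfig, MLPConfig, UNetConfig
from .train_engine import TABLE_COMBOS, AugmentConfig, Combo, TrainConfig

__all__ = [
    "read_volume",
    "write_volume",
    "read_roi",
    "write_roi",
    "read_map",
    "write_map",
    "write_subject",
    "read_subject",
    "RunConfig",
    "load_run_config",
    "config_hash",
]


def _affine(voxel_spacing) -> np.ndarray:
    aff = np.eye(4)
    # (slice, row, col) spacing onto the diagonal; no orientation games
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_spacing
    return aff


def write_volume(vol: WeightedVolume, path, subject_id: str | None = None, extra: dict | None = None) -> None:
    """Write a weighted volume as NIfTI-1 plus a JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), _affine(vol.voxel_spacing))
    nib.save(img, path)
    sidecar = {
        "contrast": "pd" if vol.is_pd else "t1rho",
        "units": "arbitrary magnitude intensity",
        "voxel_spacing_mm": list(vol.voxel_spacing),
    }
    if not vol.is_pd:
        sidecar["tsl_ms"] = float(vol.contrast)
    if subject_id is not None:
        sidecar["subject_id"] = subject_id
    if extra:
        sidecar.update(extra)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def read_volume(path) -> WeightedVolume:
    """Read a NIfTI volume with its sidecar; a missing sidecar yields an
    untagged (PD-tagged) volume with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    sc = _sidecar_path(path)
    if not sc.exists():
        warnings.warn(f"missing sidecar for {path}; volume left untagged", stacklevel=2)
        return WeightedVolume(data, contrast="pd", voxel_spacing=spacing)
    meta = json.loads(sc.read_text())
    contrast = "pd" if meta.get("contrast") == "pd" else float(meta["tsl_ms"])
    return WeightedVolume(data, contrast=contrast, voxel_spacing=spacing)


def write_roi(roi: ROIMask, path, voxel_spacing=(1.0, 1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(roi.labels.astype(np.int16), _affine(voxel_spacing)), Path(path))


def read_roi(path) -> ROIMask:
    img = nib.load(Path(path))
    return ROIMask(np.asarray(img.dataobj).astype(np.int16))


def write_map(t1rho_map: T1rhoMap, path, voxel_spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a T1rho map and its validity mask (sibling ``*_valid`` NIfTI)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(t1rho_map.values, _affine(voxel_spacing)), path)
    vp = _valid_path(path)
    nib.save(nib.Nifti1Image(t1rho_map.valid.astype(np.uint8), _affine(voxel_spacing)), vp)


def _valid_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + "_valid" + suf)
    return path


def read_map(path) -> T1rhoMap:
    path = Path(path)
    values = np.asarray(nib.load(path).dataobj, dtype=np.float64)
    vp = _valid_path(path)
    if vp.exists():
        valid = np.asarray(nib.load(vp).dataobj).astype(bool)
    else:
        valid = np.isfinite(values) & (values > 0)
    return T1rhoMap(values, valid)


def write_subject(subject, root, provenance: dict | None = None) -> Path:
    """Write one phantom subject into ``root/<subject_id>/``."""
    d = Path(root) / subject.subject_id
    d.mkdir(parents=True, exist_ok=True)
    sp = subject.spec.voxel_spacing
    extra = dict(provenance or {})
    extra["stratum"] = subject.stratum
    for v in subject.volumes:
        write_volume(v, d / f"tsl-{int(float(v.contrast)):03d}.nii.gz", subject.subject_id, extra)
    write_volume(subject.pd_volume, d / "pd.nii.gz", subject.subject_id, extra)
    write_roi(subject.roi, d / "roi.nii.gz", sp)
    write_map(subject.truth, d / "truth.nii.gz", sp)
    return d


def read_subject(subject_dir):
    """Read back a subject directory written by :func:`write_subject`.

    Returns a :class:`~t1rho.phantom.PhantomSubject` carrying default spec
    metadata (the on-disk grids are authoritative).
    """
    from .phantom import PhantomSpec, PhantomSubject

    d = Path(subject_dir)
    vols = sorted(d.glob("tsl-*.nii.gz"))
    if not vols:
        raise FileNotFoundError(f"no weighted volumes under {d}")
    volumes = [read_volume(p) for p in vols]
    volumes.sort(key=lambda v: float(v.contrast))
    meta = json.loads(_sidecar_path(vols[0]).read_text())
    return PhantomSubject(
        subject_id=d.name,
        volumes=volumes,
        pd_volume=read_volume(d / "pd.nii.gz"),
        roi=read_roi(d / "roi.nii.gz"),
        truth=read_map(d / "truth.nii.gz"),
        spec=PhantomSpec(grid_shape=volumes[0].shape),
        stratum=meta.get("stratum", "patient"),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """One reproducible run: cohort paths, input combination, model, configs."""

    cohort_root: str = "cohort"
    out_dir: str = "out"
    combo_i0: str = "tsl0"  # "pd" | "tsl0"
    combo_ik_tsl: float = 50.0
    model: str = "mlp"  # "unet" | "mlp" | "nlls"
    masked: bool = False
    n_subjects: int = 12
    k_folds: int = 3
    seed: int = 0
    fast: bool = True
    train: TrainConfig | None = None
    unet: UNetConfig | None = None
    mlp: MLPConfig | None = None

    def __post_init__(self) -> None:
        if self.model not in ("unet", "mlp", "nlls"):
            raise ValueError("model must be 'unet', 'mlp' or 'nlls'")
        legal = ", ".join(f"({c.i0}, {c.ik_tsl:g} ms)" for c in TABLE_COMBOS)
        try:
            combo = Combo(self.combo_i0, self.combo_ik_tsl)
        except ValueError as err:
            raise ValueError(
                f"combo ({self.combo_i0}, {self.combo_ik_tsl:g}) invalid ({err}); legal: {legal}"
            ) from err
        if self.model in ("unet", "mlp") and combo not in TABLE_COMBOS:
            raise ValueError(
                f"combo ({self.combo_i0}, {self.combo_ik_tsl:g}) not admissible; legal: {legal}"
            )

    @property
    def combo(self) -> Combo:
        return Combo(self.combo_i0, self.combo_ik_tsl)


_NESTED = {
    "train": TrainConfig,
    "unet": UNetConfig,
    "mlp": MLPConfig,
}


def _build_nested(cls, d):
    if d is None:
        return None
    d = dict(d)
    if cls is TrainConfig and "augment" in d and isinstance(d["augment"], dict):
        d["augment"] = AugmentConfig(**d["augment"])
    if cls in (UNetConfig, MLPConfig) and isinstance(d.get("limiter"), dict):
        d["limiter"] = LimiterConfig(**d["limiter"])
    _check_keys(cls, d)
    return cls(**d)


def _check_keys(cls, d):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration, strict on keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    for key, cls in _NESTED.items():
        if key in raw:
            raw[key] = _build_nested(cls, raw[key])
    _check_keys(RunConfig, raw)
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the scientific configuration (paths excluded), so
    identical experiments hash identically wherever their files live."""
    d = dataclasses.asdict(cfg)
    d.pop("cohort_root", None)
    d.pop("out_dir", None)
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
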
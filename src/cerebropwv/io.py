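"""NIfTI and sidecar I/O for flow volumes and derived maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from cerebropwv.angiography import FlowVolume4D


def _affine(voxel_size: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_volume(array: np.ndarray, voxel_size, path: str | Path) -> None:
    """Write an array as NIfTI-1 with a diagonal voxel-size affine."""
    voxel_size = np.asarray(voxel_size, dtype=float).reshape(3)
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, voxel_size_mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), np.asarray(img.header.get_zooms()[:3], dtype=float)


def save_flow_volume(flow: FlowVolume4D, out_dir: str | Path, stem: str = "flow") -> None:
    """Write magnitude + three velocity series and a YAML sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in (
        ("mag", flow.magnitude),
        ("velx", flow.vel_x),
        ("vely", flow.vel_y),
        ("velz", flow.vel_z),
    ):
        save_volume(arr, flow.voxel_size, out_dir / f"{stem}_{name}.nii.gz")
    sidecar = {
        "venc_cm_s": float(flow.venc),
        "frame_times_s": [float(t) for t in flow.frame_times],
        "voxel_size_mm": [float(v) for v in flow.voxel_size],
    }
    (out_dir / f"{stem}.yaml").write_text(yaml.safe_dump(sidecar))


def load_flow_volume(
    mag_path: str | Path,
    velx_path: str | Path,
    vely_path: str | Path,
    velz_path: str | Path,
    sidecar_path: str | Path,
) -> FlowVolume4D:
    """Assemble a :class:`FlowVolume4D` from four 4D NIfTI series + sidecar.

    The sidecar (YAML or JSON parsed as YAML) must provide ``venc_cm_s``
    and ``frame_times_s``; voxel size comes from the NIfTI header unless
    overridden by ``voxel_size_mm``.
    """
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar_path}")
    meta = yaml.safe_load(sidecar_path.read_text())
    mag, zooms = load_volume(mag_path)
    vx, _ = load_volume(velx_path)
    vy, _ = load_volume(vely_path)
    vz, _ = load_volume(velz_path)
    voxel_size = np.asarray(meta.get("voxel_size_mm", zooms), dtype=float)
    return FlowVolume4D(
        magnitude=mag,
        vel_x=vx,
        vel_y=vy,
        vel_z=vz,
        venc=float(meta["venc_cm_s"]),
        voxel_size=voxel_size,
        frame_times=np.asarray(meta["frame_times_s"], dtype=float),
    )
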
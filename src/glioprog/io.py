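"""NIfTI and table I/O.

NIfTI-1 is the sole volume format; tables, configs and reports are
CSV/JSON/YAML. Grid consistency is enforced on read: loading a case whose
volumes disagree in shape or spacing raises an error naming both files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import GridMismatchError, VolumeGrid

__all__ = ["read_volume", "write_volume", "write_case", "read_case"]


def write_volume(vol: VolumeGrid | np.ndarray, path: str | Path,
                 spacing=(1.0, 1.0, 1.0)) -> Path:
    """Write a 3D/4D volume as NIfTI-1, encoding spacing in the affine."""
    if not isinstance(vol, VolumeGrid):
        vol = VolumeGrid(np.asarray(vol), spacing)
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, path)
    return path


def read_volume(path: str | Path) -> VolumeGrid:
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(data, spacing, name=path.name)


def _require_consistent(volumes: dict[str, VolumeGrid]) -> None:
    items = list(volumes.items())
    ref_name, ref = items[0]
    for name, vol in items[1:]:
        if not ref.same_grid(vol):
            raise GridMismatchError(
                f"case volumes disagree: {ref_name!r} has shape {ref.shape3d} "
                f"spacing {ref.spacing} but {name!r} has shape {vol.shape3d} "
                f"spacing {vol.spacing}"
            )


def write_case(case, out_dir: str | Path) -> Path:
    """Write a StudyCase as a directory of NIfTI files plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sp = case.spacing
    write_volume(VolumeGrid(case.seg_prev.astype(np.uint8), sp), out_dir / "seg_prev.nii.gz")
    write_volume(VolumeGrid(case.seg_curr.astype(np.uint8), sp), out_dir / "seg_curr.nii.gz")
    write_volume(VolumeGrid(case.tissue.astype(np.uint8), sp), out_dir / "tissue.nii.gz")
    write_volume(VolumeGrid(case.fet.astype(np.float32), sp), out_dir / "fet.nii.gz")
    write_volume(VolumeGrid(case.dsc.astype(np.float32), sp), out_dir / "dsc.nii.gz")
    zs = np.concatenate(
        [case.zspec.volumes, case.zspec.reference[..., None]], axis=-1
    ).astype(np.float32)
    write_volume(VolumeGrid(zs, sp), out_dir / "zspec.nii.gz")
    write_volume(VolumeGrid(case.zspec.b0_shift_ppm.astype(np.float32), sp),
                 out_dir / "b0.nii.gz")
    sidecar = {
        "case_id": case.case_id,
        "label": case.label,
        "spacing_mm": list(sp),
        "zspec_offsets_ppm": list(map(float, case.zspec.offsets_ppm)),
        "zspec_reference_offset_ppm": float(case.zspec.reference_offset_ppm),
        "dsc": {"te_s": case.te_s, "tr_s": case.tr_s,
                "baseline_dynamics": case.baseline_dynamics},
        "planted": case.truth.params if case.truth is not None else None,
    }
    (out_dir / "case.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return out_dir


def read_case(case_dir: str | Path):
    """Load a StudyCase written by :func:`write_case` (planted truth maps are
    not round-tripped; the sidecar keeps the planted scalar parameters)."""
    from .synthdata import StudyCase, ZSpectrumStack

    case_dir = Path(case_dir)
    meta = json.loads((case_dir / "case.json").read_text())
    vols = {name: read_volume(case_dir / f"{name}.nii.gz")
            for name in ("seg_prev", "seg_curr", "tissue", "fet", "dsc", "zspec", "b0")}
    _require_consistent(vols)
    zs = vols["zspec"].data
    stack = ZSpectrumStack(
        volumes=zs[..., :-1],
        offsets_ppm=tuple(meta["zspec_offsets_ppm"]),
        reference=zs[..., -1],
        b0_shift_ppm=vols["b0"].data,
        reference_offset_ppm=meta["zspec_reference_offset_ppm"],
    )
    return StudyCase(
        case_id=meta["case_id"],
        label=meta["label"],
        seg_prev=vols["seg_prev"].data,
        seg_curr=vols["seg_curr"].data,
        tissue=vols["tissue"].data,
        fet=vols["fet"].data,
        dsc=vols["dsc"].data,
        zspec=stack,
        spacing=tuple(meta["spacing_mm"]),
        te_s=meta["dsc"]["te_s"],
        tr_s=meta["dsc"]["tr_s"],
        baseline_dynamics=meta["dsc"]["baseline_dynamics"],
        truth=None,
    )
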
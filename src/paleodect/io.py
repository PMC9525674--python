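"""Volume and table I/O plus overlay rendering.

Volumes travel as NIfTI-1 (via nibabel) or NRRD (via SimpleITK); arrays are
indexed (i, j, k) with spacing in mm per axis, and the two formats
round-trip to identical arrays.  Each energy is written as its own file
with ``_80kvp`` / ``_135kvp`` suffixes.
"""

from __future__ import annotations

import csv
from pathlib import Path

import matplotlib
import numpy as np

from .phantom import DualEnergyVolume
from .quantify import ROIRole

__all__ = [
    "read_volume",
    "write_volume",
    "read_dual_energy",
    "write_dual_energy",
    "read_roles_csv",
    "write_roles_csv",
    "render_overlay",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_NRRD_SUFFIXES = (".nrrd", ".nhdr")


def _format_of(path: Path) -> str:
    name = path.name.lower()
    if any(name.endswith(s) for s in _NIFTI_SUFFIXES):
        return "nifti"
    if any(name.endswith(s) for s in _NRRD_SUFFIXES):
        return "nrrd"
    raise ValueError(f"unsupported volume format: {path.name!r}")


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a scalar volume; returns (array, spacing in mm per axis)."""
    path = Path(path)
    fmt = _format_of(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return data, spacing
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    # SimpleITK arrays come back (z, y, x); transpose to (i, j, k) = (x, y, z)
    data = np.asarray(sitk.GetArrayFromImage(img), dtype=np.float64).T
    spacing = tuple(float(s) for s in img.GetSpacing())
    return data, spacing


def write_volume(
    array: np.ndarray, spacing: tuple[float, ...], path: str | Path
) -> Path:
    """Write a scalar volume; format chosen by extension (.nii[.gz]/.nrrd)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    array = np.asarray(array)
    fmt = _format_of(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(spacing) + [1.0])
        nib.save(nib.Nifti1Image(array.astype(np.float64), affine), str(path))
        return path
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(array.astype(np.float64).T)
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, str(path))
    return path


def read_dual_energy(low_path: str | Path, high_path: str | Path) -> DualEnergyVolume:
    """Read a co-registered 80/135-kVp pair; shapes and spacing must match."""
    low, sp_low = read_volume(low_path)
    high, sp_high = read_volume(high_path)
    if low.shape != high.shape:
        raise ValueError(
            f"paired energies differ in shape: {low.shape} vs {high.shape}"
        )
    if not np.allclose(sp_low, sp_high):
        raise ValueError(
            f"paired energies differ in spacing: {sp_low} vs {sp_high}"
        )
    return DualEnergyVolume(low=low, high=high, spacing=tuple(sp_low))


def write_dual_energy(
    vol: DualEnergyVolume, out_prefix: str | Path, fmt: str = ".nii.gz"
) -> tuple[Path, Path]:
    """Write both energies as ``<prefix>_80kvp<fmt>`` / ``<prefix>_135kvp<fmt>``."""
    prefix = Path(out_prefix)
    low = write_volume(vol.low, vol.spacing, prefix.parent / f"{prefix.name}_80kvp{fmt}")
    high = write_volume(vol.high, vol.spacing, prefix.parent / f"{prefix.name}_135kvp{fmt}")
    return low, high


def read_roles_csv(path: str | Path) -> dict[int, ROIRole]:
    """ROI roles from CSV (columns: code, structure, specimen, age_ma, habitat)."""
    roles: dict[int, ROIRole] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            roles[int(row["code"])] = ROIRole(
                structure=row["structure"],
                specimen=row["specimen"],
                age_ma=float(row.get("age_ma") or 0.0),
                habitat=row.get("habitat") or "terrestrial",
            )
    if not roles:
        raise ValueError(f"no ROI roles in {path}")
    return roles


def write_roles_csv(roles: dict[int, ROIRole], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "structure", "specimen", "age_ma", "habitat"])
        for code in sorted(roles):
            r = roles[code]
            writer.writerow([code, r.structure, r.specimen, r.age_ma, r.habitat])
    return path


def render_overlay(
    map_values: np.ndarray,
    base: np.ndarray,
    out_path: str | Path,
    axis: int = 2,
    index: int | None = None,
    vmax: float | None = None,
) -> Path:
    """Render a grayscale base slice with a red material-map overlay.

    Red intensity is proportional to the map value; a color bar annotates
    the HU scale.  ``index`` defaults to the middle slice along ``axis``.
    """
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.cm import ScalarMappable
    from matplotlib.colors import LinearSegmentedColormap, Normalize
    from matplotlib.figure import Figure

    map_values = np.asarray(map_values, dtype=np.float64)
    base = np.asarray(base, dtype=np.float64)
    if map_values.shape != base.shape:
        raise ValueError("map and base volume must share a grid")
    n = base.shape[axis]
    if index is None:
        index = n // 2
    if not 0 <= index < n:
        raise IndexError(f"slice {index} out of range for axis {axis} (size {n})")
    sl = [slice(None)] * base.ndim
    sl[axis] = index
    base2d = base[tuple(sl)]
    map2d = map_values[tuple(sl)]
    if vmax is None:
        vmax = float(map_values.max())

    fig = Figure(figsize=(6, 5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    ax.imshow(base2d.T, cmap="gray", origin="lower")
    red = LinearSegmentedColormap.from_list("red_overlay", [(1, 0, 0), (1, 0, 0)])
    norm = Normalize(vmin=0.0, vmax=vmax if vmax > 0 else 1.0)
    alpha = norm(np.clip(map2d.T, 0.0, None))
    ax.imshow(
        np.asarray(red(np.zeros_like(alpha))),
        origin="lower",
        alpha=np.asarray(alpha, dtype=float),
    )
    fig.colorbar(
        ScalarMappable(norm=norm, cmap="Reds"), ax=ax, label="material map (HU)"
    )
    ax.set_title("material-map overlay")
    ax.set_axis_off()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    return out_path
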
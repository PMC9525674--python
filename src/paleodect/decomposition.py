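"""Per-voxel three-material decomposition in the dual-energy HU plane.

Each voxel measures a point (HU80, HU135).  Its quotient q = HU135/HU80
selects which pair of adjacent basis directions brackets it:

* q at or below the lowest gradient g1: the whole signal is assigned to
  material 1 (c1 = HU80);
* g1 < q < g2: the exact 2x2 solve  c1 + c2 = HU80,
  c1*g1 + c2*g2 = HU135  splits the signal between materials 1 and 2;
* g2 <= q < g3: the analogous solve between materials 2 and 3;
* q at or above g3: everything goes to material 3.

Magnitudes c_i live on the 80-kVp scale and, inside a bracket, conserve the
voxel's 80-kVp HU (c_a + c_b = HU80).  Reported map values are c_i * g_i —
the material's contribution on the 135-kVp scale — clamped at zero, because
map statistics are conventionally quoted alongside the 135-kVp images.
Voxels whose 80-kVp HU is at or below the basis background threshold get
all-zero components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import DecompositionBasis

__all__ = [
    "VoxelComponents",
    "MaterialMap",
    "voxel_quotient",
    "decompose_voxel",
    "decompose_arrays",
    "material_map",
]


@dataclass(frozen=True)
class VoxelComponents:
    """Decomposition of a single voxel.

    ``magnitudes`` are the c_i on the 80-kVp scale; ``map_values`` are
    max(c_i * g_i, 0) on the 135-kVp scale; ``background`` marks voxels
    below the background threshold (all components zero).
    """

    magnitudes: dict[str, float]
    map_values: dict[str, float]
    background: bool


@dataclass
class MaterialMap:
    """Scalar volume of one material's per-voxel signal (135-kVp HU, >= 0)."""

    values: np.ndarray
    material: str
    basis: DecompositionBasis
    spacing: tuple[float, ...] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def voxel_quotient(
    hu_low: float, hu_high: float, background_threshold: float = 100.0
) -> float:
    """Voxel quotient HU135/HU80, or NaN for background voxels.

    Background (hu_low at or below the threshold) is a value, not an error;
    it is encoded as NaN so array code can propagate it cheaply.
    """
    if hu_low <= background_threshold:
        return math.nan
    return hu_high / hu_low


def decompose_voxel(
    hu_low: float, hu_high: float, basis: DecompositionBasis
) -> VoxelComponents:
    """Decompose one voxel; scalar reference implementation.

    The vectorized path (:func:`decompose_arrays`) must agree with this
    voxel-by-voxel.
    """
    names = basis.material_names
    g1, g2, g3 = basis.gradients
    c = [0.0, 0.0, 0.0]
    q = voxel_quotient(hu_low, hu_high, basis.background_threshold)
    background = math.isnan(q)
    if not background:
        if q <= g1:
            c[0] = hu_low
        elif q < g2:
            c2 = (hu_high - g1 * hu_low) / (g2 - g1)
            c[0] = hu_low - c2
            c[1] = c2
        elif q < g3:
            c3 = (hu_high - g2 * hu_low) / (g3 - g2)
            c[1] = hu_low - c3
            c[2] = c3
        else:
            c[2] = hu_low
    grads = (g1, g2, g3)
    return VoxelComponents(
        magnitudes=dict(zip(names, c)),
        map_values={n: max(ci * gi, 0.0) for n, ci, gi in zip(names, c, grads)},
        background=background,
    )


def decompose_arrays(
    hu_low: np.ndarray, hu_high: np.ndarray, basis: DecompositionBasis
) -> dict[str, np.ndarray]:
    """Vectorized decomposition: material name -> map array (135-kVp HU)."""
    low = np.asarray(hu_low, dtype=np.float64)
    high = np.asarray(hu_high, dtype=np.float64)
    if low.shape != high.shape:
        raise ValueError(
            f"energy volumes differ in shape: {low.shape} vs {high.shape}"
        )
    g1, g2, g3 = basis.gradients
    foreground = low > basis.background_threshold
    safe_low = np.where(foreground, low, 1.0)
    q = high / safe_low

    c = np.zeros((3,) + low.shape)
    r1 = foreground & (q <= g1)
    r12 = foreground & (q > g1) & (q < g2)
    r23 = foreground & (q >= g2) & (q < g3)
    r3 = foreground & (q >= g3)

    c[0][r1] = low[r1]
    c2 = (high - g1 * low) / (g2 - g1)
    c[1][r12] = c2[r12]
    c[0][r12] = low[r12] - c2[r12]
    c3 = (high - g2 * low) / (g3 - g2)
    c[2][r23] = c3[r23]
    c[1][r23] = low[r23] - c3[r23]
    c[2][r3] = low[r3]

    grads = (g1, g2, g3)
    return {
        name: np.maximum(c[i] * grads[i], 0.0)
        for i, name in enumerate(basis.material_names)
    }


def material_map(vol, basis: DecompositionBasis, material: str) -> MaterialMap:
    """Compute one material's map over a dual-energy volume.

    ``vol`` may be a :class:`~paleodect.phantom.DualEnergyVolume` or a
    ``(low, high)`` pair of equally shaped arrays.
    """
    if hasattr(vol, "low") and hasattr(vol, "high"):
        low, high, spacing = vol.low, vol.high, getattr(vol, "spacing", None)
    else:
        low, high = vol
        spacing = None
    basis.index(material)  # raises KeyError for unknown materials
    maps = decompose_arrays(low, high, basis)
    return MaterialMap(
        values=maps[material], material=material, basis=basis, spacing=spacing
    )
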
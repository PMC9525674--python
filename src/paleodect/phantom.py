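"""Synthetic paired dual-energy CT volumes with known ground truth.

The forward model is deliberately the model the image-domain decomposition
inverts: a voxel containing volume fractions f_m of materials with
signatures (HU80_m, HU135_m) measures the fraction-weighted sums at both
energies.  Polychromatic physics enters only through the per-material
two-energy signatures; independent additive Gaussian noise per energy
emulates the two sequential acquisitions of a rotate/rotate dual-energy
scanner; a surface band with a fixed HU offset emulates beam hardening near
the object/background boundary.

Bone mineral is modelled as a fluorite/calcite mixture: the fluorite
direction (quotient 0.691) plays the role of fluorapatite, calcite
(quotient 0.706) that of hydroxyapatite/carbonate, with "background"
(0 HU at both energies) as pore space.  Default region recipes reproduce
the printed 135-kVp bone statistics of the study specimens, e.g. fossil
theropod bone at 3040 +/- 542 HU and fresh bovine bone at 1658 +/- 90 HU;
the printed standard deviations are applied as voxel-level noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from collections.abc import Mapping, Sequence

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "MaterialSignature",
    "DEFAULT_SIGNATURES",
    "Box",
    "Sphere",
    "Ellipsoid",
    "Cylinder",
    "Difference",
    "Region",
    "SurfaceArtifact",
    "PhantomSpec",
    "DualEnergyVolume",
    "forward_hu",
    "build_phantom",
    "add_surface_artifact",
    "fossil_bone_phantom_spec",
    "SpecimenSpec",
    "DEFAULT_COHORT",
    "specimen_phantom_spec",
    "FOSSIL_BONE_COMPOSITION",
    "EXTANT_BONE_COMPOSITION",
    "SEDIMENT_COMPOSITION",
    "HU_RANGE",
]

#: Scanner measurement range in HU.
HU_RANGE: tuple[float, float] = (-32_768.0, 32_767.0)

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class MaterialSignature:
    """A material's noiseless HU pair at the two energies."""

    name: str
    hu_low: float
    hu_high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.hu_low) and math.isfinite(self.hu_high)):
            raise ValueError(f"non-finite signature for {self.name!r}")


#: Signatures of the bundled calibration materials plus background
#: (0 HU at both energies by convention).
DEFAULT_SIGNATURES: dict[str, MaterialSignature] = {
    s.name: s
    for s in (
        MaterialSignature("background", 0.0, 0.0),
        MaterialSignature("calcite", 4248.0, 3000.0),
        MaterialSignature("fluorite", 5432.0, 3753.0),
        MaterialSignature("iron", 24_422.0, 18_311.0),
    )
}

#: Fossil bone recipe: 135-kVp mean 3040 HU, fluorine map 1809 HU.
FOSSIL_BONE_COMPOSITION: dict[str, float] = {
    "fluorite": 0.51120,
    "calcite": 0.37382,
    "background": 0.11498,
}
#: Fresh bone recipe: 135-kVp mean 1658 HU, quotient on the calcite
#: direction, hence zero fluorine.
EXTANT_BONE_COMPOSITION: dict[str, float] = {
    "calcite": 1658.0 / 3000.0,
    "background": 1.0 - 1658.0 / 3000.0,
}
#: Calcite-rich embedding sediment, fluorine-free.
SEDIMENT_COMPOSITION: dict[str, float] = {"calcite": 0.45, "background": 0.55}


# --------------------------------------------------------------------------
# geometry descriptors
# --------------------------------------------------------------------------

def _grids(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    return np.indices(shape, dtype=np.float64)


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, half-open voxel-index bounds [lo, hi)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.ones(shape, dtype=bool)
        for ax, (a, b) in enumerate(zip(self.lo, self.hi)):
            idx = np.arange(shape[ax])
            sel = (idx >= a) & (idx < b)
            m &= sel.reshape([-1 if i == ax else 1 for i in range(3)])
        return m

    def to_dict(self) -> dict:
        return {"type": "box", "lo": list(self.lo), "hi": list(self.hi)}


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        gi, gj, gk = _grids(shape)
        ci, cj, ck = self.center
        ri, rj, rk = self.radii
        return ((gi - ci) / ri) ** 2 + ((gj - cj) / rj) ** 2 + ((gk - ck) / rk) ** 2 <= 1.0

    def to_dict(self) -> dict:
        return {"type": "ellipsoid", "center": list(self.center), "radii": list(self.radii)}


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        return Ellipsoid(self.center, (self.radius,) * 3).mask(shape)

    def to_dict(self) -> dict:
        return {"type": "sphere", "center": list(self.center), "radius": self.radius}


@dataclass(frozen=True)
class Cylinder:
    """Circular cylinder along one grid axis."""

    center: tuple[float, float, float]
    radius: float
    half_length: float
    axis: int = 2

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = _grids(shape)
        radial = [i for i in range(3) if i != self.axis]
        r2 = sum((grids[i] - self.center[i]) ** 2 for i in radial)
        along = np.abs(grids[self.axis] - self.center[self.axis])
        return (r2 <= self.radius**2) & (along <= self.half_length)

    def to_dict(self) -> dict:
        return {
            "type": "cylinder",
            "center": list(self.center),
            "radius": self.radius,
            "half_length": self.half_length,
            "axis": self.axis,
        }


@dataclass(frozen=True)
class Difference:
    """Voxels of ``outer`` not in ``inner`` (e.g. sediment around bone)."""

    outer: "Geometry"
    inner: "Geometry"

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        return self.outer.mask(shape) & ~self.inner.mask(shape)

    def to_dict(self) -> dict:
        return {
            "type": "difference",
            "outer": self.outer.to_dict(),
            "inner": self.inner.to_dict(),
        }


Geometry = Box | Sphere | Ellipsoid | Cylinder | Difference


def geometry_from_dict(payload: Mapping) -> Geometry:
    kind = payload["type"]
    if kind == "box":
        return Box(tuple(payload["lo"]), tuple(payload["hi"]))
    if kind == "sphere":
        return Sphere(tuple(payload["center"]), float(payload["radius"]))
    if kind == "ellipsoid":
        return Ellipsoid(tuple(payload["center"]), tuple(payload["radii"]))
    if kind == "cylinder":
        return Cylinder(
            tuple(payload["center"]),
            float(payload["radius"]),
            float(payload["half_length"]),
            int(payload.get("axis", 2)),
        )
    if kind == "difference":
        return Difference(
            geometry_from_dict(payload["outer"]), geometry_from_dict(payload["inner"])
        )
    raise ValueError(f"unknown geometry type {kind!r}")


# --------------------------------------------------------------------------
# spec and volume containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    label: str
    geometry: Geometry
    composition: dict[str, float]


@dataclass(frozen=True)
class SurfaceArtifact:
    band_width: int
    offset: float


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    regions: tuple[Region, ...]
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    noise_sd_low: float = 0.0
    noise_sd_high: float = 0.0
    artifact: SurfaceArtifact | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.noise_sd_low < 0 or self.noise_sd_high < 0:
            raise ValueError("noise SDs must be non-negative")
        for region in self.regions:
            _validate_composition(region.composition)

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_spacing": list(self.voxel_spacing),
            "noise_sd_low": self.noise_sd_low,
            "noise_sd_high": self.noise_sd_high,
            "seed": self.seed,
            "artifact": (
                {"band_width": self.artifact.band_width, "offset": self.artifact.offset}
                if self.artifact
                else None
            ),
            "regions": [
                {
                    "label": r.label,
                    "geometry": r.geometry.to_dict(),
                    "composition": dict(r.composition),
                }
                for r in self.regions
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PhantomSpec":
        artifact = payload.get("artifact")
        return cls(
            grid_shape=tuple(payload["grid_shape"]),
            voxel_spacing=tuple(payload.get("voxel_spacing", (0.5, 0.5, 0.5))),
            noise_sd_low=float(payload.get("noise_sd_low", 0.0)),
            noise_sd_high=float(payload.get("noise_sd_high", 0.0)),
            seed=int(payload.get("seed", 0)),
            artifact=(
                SurfaceArtifact(int(artifact["band_width"]), float(artifact["offset"]))
                if artifact
                else None
            ),
            regions=tuple(
                Region(
                    label=r["label"],
                    geometry=geometry_from_dict(r["geometry"]),
                    composition={k: float(v) for k, v in r["composition"].items()},
                )
                for r in payload["regions"]
            ),
        )

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class DualEnergyVolume:
    """Two co-registered HU volumes plus optional ground truth.

    ``truth`` maps material name -> per-voxel volume-fraction array;
    ``region_labels`` is an integer volume (0 = background, regions numbered
    in spec order from 1); ``artifact_mask`` marks voxels shifted by the
    surface-band artifact.
    """

    low: np.ndarray
    high: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    truth: dict[str, np.ndarray] | None = None
    region_labels: np.ndarray | None = None
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.low.shape != self.high.shape:
            raise ValueError(
                f"energy volumes differ in shape: {self.low.shape} vs {self.high.shape}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.low.shape


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

def _validate_composition(composition: Mapping[str, float]) -> None:
    if not composition:
        raise ValueError("empty composition")
    total = 0.0
    for name, frac in composition.items():
        if frac < 0:
            raise ValueError(f"negative volume fraction for {name!r}")
        total += frac
    if abs(total - 1.0) > _FRACTION_TOL:
        raise ValueError(f"volume fractions sum to {total!r}, expected 1")


def forward_hu(
    composition: Mapping[str, float],
    signatures: Mapping[str, MaterialSignature] = DEFAULT_SIGNATURES,
) -> tuple[float, float]:
    """Noiseless HU pair of a voxel: fraction-weighted sums per energy."""
    _validate_composition(composition)
    lo = hi = 0.0
    for name, frac in composition.items():
        if name not in signatures:
            raise KeyError(f"no signature for material {name!r}")
        sig = signatures[name]
        lo += frac * sig.hu_low
        hi += frac * sig.hu_high
    return lo, hi


def build_phantom(
    spec: PhantomSpec,
    signatures: Mapping[str, MaterialSignature] = DEFAULT_SIGNATURES,
) -> DualEnergyVolume:
    """Realize a phantom spec: regions, seeded noise, truth and artifacts.

    Region masks must be disjoint; voxels covered by no region are filled
    with background (0, 0).  The same seed yields bit-identical volumes.
    """
    shape = spec.grid_shape
    labels = np.zeros(shape, dtype=np.int16)
    low = np.zeros(shape)
    high = np.zeros(shape)
    materials = {"background"}
    for region in spec.regions:
        materials |= set(region.composition)
    truth = {m: np.zeros(shape) for m in materials}
    truth["background"][:] = 1.0

    for idx, region in enumerate(spec.regions, start=1):
        m = region.geometry.mask(shape)
        if (labels[m] != 0).any():
            raise ValueError(f"region {region.label!r} overlaps an earlier region")
        labels[m] = idx
        lo, hi = forward_hu(region.composition, signatures)
        low[m] = lo
        high[m] = hi
        truth["background"][m] = 0.0
        for name, frac in region.composition.items():
            truth[name][m] += frac

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_low > 0:
        low = low + rng.normal(0.0, spec.noise_sd_low, shape)
    if spec.noise_sd_high > 0:
        high = high + rng.normal(0.0, spec.noise_sd_high, shape)
    low = np.clip(low, *HU_RANGE)
    high = np.clip(high, *HU_RANGE)

    vol = DualEnergyVolume(
        low=low,
        high=high,
        spacing=spec.voxel_spacing,
        truth=truth,
        region_labels=labels,
        artifact_mask=np.zeros(shape, dtype=bool),
    )
    if spec.artifact is not None:
        vol = add_surface_artifact(vol, spec.artifact.band_width, spec.artifact.offset)
    return vol


def add_surface_artifact(
    vol: DualEnergyVolume, band_width: int, offset: float
) -> DualEnergyVolume:
    """Shift a surface band of the object by ``offset`` HU at both energies.

    The band comprises object voxels whose Euclidean distance to the nearest
    background voxel is at most ``band_width`` (in voxel units), emulating
    beam hardening near the object surface.  ``band_width = 0`` is a no-op.
    """
    if band_width < 0:
        raise ValueError("band_width must be non-negative")
    if vol.region_labels is None:
        raise ValueError("surface artifact needs region labels to locate the object")
    obj = vol.region_labels > 0
    band = np.zeros(vol.shape, dtype=bool)
    if band_width > 0 and obj.any() and (~obj).any():
        dist = ndimage.distance_transform_edt(obj)
        band = obj & (dist <= band_width)
    low = vol.low.copy()
    high = vol.high.copy()
    low[band] += offset
    high[band] += offset
    low = np.clip(low, *HU_RANGE)
    high = np.clip(high, *HU_RANGE)
    prior = vol.artifact_mask if vol.artifact_mask is not None else np.zeros(vol.shape, bool)
    return replace(vol, low=low, high=high, artifact_mask=prior | band)


# --------------------------------------------------------------------------
# default specimen recipes
# --------------------------------------------------------------------------

def _bone_in_sediment_regions(
    shape: tuple[int, int, int],
    bone_composition: Mapping[str, float],
    sediment_composition: Mapping[str, float] = SEDIMENT_COMPOSITION,
) -> tuple[Region, Region]:
    ni, nj, nk = shape
    center = ((ni - 1) / 2, (nj - 1) / 2, (nk - 1) / 2)
    bone = Ellipsoid(center, (0.32 * ni, 0.23 * nj, 0.23 * nk))
    block = Box((2, 2, 2), (ni - 2, nj - 2, nk - 2))
    return (
        Region("bone", bone, dict(bone_composition)),
        Region("sediment", Difference(block, bone), dict(sediment_composition)),
    )


def fossil_bone_phantom_spec(
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
    noise_sd: float = 542.0,
    bone_composition: Mapping[str, float] = FOSSIL_BONE_COMPOSITION,
    artifact: SurfaceArtifact | None = SurfaceArtifact(band_width=2, offset=300.0),
) -> PhantomSpec:
    """Default fossil-bone-in-sediment phantom.

    The bone recipe reproduces the printed fossil theropod statistics
    (135-kVp mean 3040 HU; printed SD 542 HU applied as voxel noise at both
    energies) and a noiseless fluorine-map value of 1809 HU.
    """
    return PhantomSpec(
        grid_shape=grid_shape,
        regions=_bone_in_sediment_regions(grid_shape, bone_composition),
        noise_sd_low=noise_sd,
        noise_sd_high=noise_sd,
        artifact=artifact,
        seed=seed,
    )


@dataclass(frozen=True)
class SpecimenSpec:
    """One study specimen of the default synthetic cohort."""

    name: str
    age_ma: float
    habitat: str  # "terrestrial" | "marine"
    bone_composition: dict[str, float]
    sediment_composition: dict[str, float]
    noise_sd: float


def _bone_mix(fluorite: float, calcite: float) -> dict[str, float]:
    comp = {"fluorite": fluorite, "calcite": calcite,
            "background": 1.0 - fluorite - calcite}
    return {k: v for k, v in comp.items() if v > 0}


#: Synthetic cohort mirroring the study's six specimens.  Fluorite/calcite
#: fractions are set so the noiseless 135-kVp and fluorine-map values track
#: the printed ones where printed (fresh bovine bone 1658 HU / 0 HU fluorine;
#: fossil theropod 3040 HU / 1809 HU; the oldest terrestrial fossil ~3500 HU
#: fluorine); the remaining specimens are realistic intermediates, with the
#: marine pair fluorine-poor.
DEFAULT_COHORT: tuple[SpecimenSpec, ...] = (
    SpecimenSpec("Bos taurus", 0.0, "terrestrial",
                 dict(EXTANT_BONE_COMPOSITION), dict(SEDIMENT_COMPOSITION), 90.0),
    SpecimenSpec("Alcelaphinae", 1.5, "terrestrial",
                 _bone_mix(0.10, 0.50), dict(SEDIMENT_COMPOSITION), 300.0),
    SpecimenSpec("Tyrannosaurus rex", 68.0, "terrestrial",
                 dict(FOSSIL_BONE_COMPOSITION), dict(SEDIMENT_COMPOSITION), 542.0),
    SpecimenSpec("Dysalotosaurus", 153.0, "terrestrial",
                 _bone_mix(0.98906, 0.01094), dict(SEDIMENT_COMPOSITION), 300.0),
    SpecimenSpec("Ichthyosauria", 175.0, "marine",
                 _bone_mix(0.0, 0.50), dict(SEDIMENT_COMPOSITION), 300.0),
    SpecimenSpec("Nothosaurus", 242.0, "marine",
                 _bone_mix(0.05, 0.50), dict(SEDIMENT_COMPOSITION), 300.0),
)


def specimen_phantom_spec(
    specimen: SpecimenSpec,
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    seed: int = 0,
    artifact: SurfaceArtifact | None = None,
) -> PhantomSpec:
    """Bone-in-sediment phantom for one cohort specimen."""
    return PhantomSpec(
        grid_shape=grid_shape,
        regions=_bone_in_sediment_regions(
            grid_shape, specimen.bone_composition, specimen.sediment_composition
        ),
        noise_sd_low=specimen.noise_sd,
        noise_sd_high=specimen.noise_sd,
        artifact=artifact,
        seed=seed,
    )
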
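"""Dual-energy calibration: quotients, measurement ingestion, decomposition bases.

A material scanned at two tube voltages (here 80 and 135 kVp) traces a ray
through the origin of the (HU80, HU135) plane.  Its slope

    g = HU(135 kVp) / HU(80 kVp)

— the *quotient*, or *gradient* — is independent of the material's density
and acts as a spectral fingerprint: low-Z, photoelectric-weak materials sit
near g = 1, while high-Z minerals (calcite, fluorite, iron oxides) attenuate
disproportionately at 80 kVp and fall well below it.  A three-material
decomposition basis is an ordered triple of such directions; the voxelwise
inversion lives in :mod:`paleodect.decomposition`.

Reference dual-energy signatures of the calibration minerals (measured on a
clinical 320-row scanner) are bundled as :data:`REFERENCE_MEASUREMENTS`,
together with the two bases used throughout:

* the custom **fluorine** basis — calcium anchor (4248, 3000), iron anchor
  (10000, 7365) and a gradient-only fluorine direction at 0.69, the fluorite
  quotient 3753/5432 rounded to two decimals;
* a **calcium** basis standing in for the scanner vendor's clinical
  calcium algorithm, built from the measured calcite and iron-rod anchors
  plus a soft-tissue direction at g = 1.00 (water has 0 HU at both energies,
  so water-like tissue attenuates nearly equally at both).
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._elements import ATOMIC_NUMBER

__all__ = [
    "UndefinedQuotientError",
    "DegenerateBasisError",
    "CalibrationEntry",
    "BasisComponent",
    "DecompositionBasis",
    "compute_quotient",
    "ingest_measurements",
    "build_fluorine_basis",
    "build_calcium_basis",
    "effective_z",
    "reference_entries",
    "read_measurements_csv",
    "write_measurements_csv",
    "CALCIUM_ANCHOR",
    "ALGORITHM_IRON_ANCHOR",
    "MEASURED_IRON_ANCHOR",
    "FLUORITE_ANCHOR",
    "REFERENCE_MEASUREMENTS",
]


class UndefinedQuotientError(ValueError):
    """Quotient requested for a material with zero HU at 80 kVp."""


class DegenerateBasisError(ValueError):
    """Basis directions too close (or wrongly ordered) to invert."""


# Printed anchors of the decomposition algorithms (HU at 80 kVp, HU at 135 kVp).
CALCIUM_ANCHOR: tuple[float, float] = (4248.0, 3000.0)
#: Iron direction used inside the fluorine algorithm (rescaled from the rod).
ALGORITHM_IRON_ANCHOR: tuple[float, float] = (10_000.0, 7365.0)
#: Iron rod as actually measured on the scanner.
MEASURED_IRON_ANCHOR: tuple[float, float] = (24_422.0, 18_311.0)
#: Fluorite crystal measurement; its quotient defines the fluorine gradient.
FLUORITE_ANCHOR: tuple[float, float] = (5432.0, 3753.0)

#: (material, formula, HU at 80 kVp, HU at 135 kVp, Z_eff as reported).
#: Z_eff values come from the original measurement report and are
#: informational only; they are not reproduced by common power-law formulas.
REFERENCE_MEASUREMENTS: tuple[tuple[str, str, float, float, float | None], ...] = (
    ("calcite crystal", "CaCO3", 4248.0, 3000.0, 15.88),
    ("fluorite crystal", "CaF2", 5432.0, 3753.0, 16.42),
    ("graphite cylinder", "C", 325.0, 381.0, 6.0),
    ("sulfur crystal", "S", 3196.0, 2153.0, 16.0),
    ("iron rod", "Fe", 24_422.0, 18_311.0, 26.0),
    ("sodium chloride", "NaCl", 1569.0, 939.0, 13.97),
)


def compute_quotient(hu_low: float, hu_high: float, digits: int = 3) -> float:
    """Dual-energy quotient HU(135 kVp)/HU(80 kVp), rounded half-even.

    Parameters
    ----------
    hu_low, hu_high:
        Hounsfield values at 80 and 135 kVp.
    digits:
        Decimal places for the half-even (banker's) rounding used for all
        printed quotients.

    Raises
    ------
    UndefinedQuotientError
        If ``hu_low`` is zero (the ray direction is vertical).
    """
    if hu_low == 0:
        raise UndefinedQuotientError("quotient undefined for hu_low = 0")
    return round(hu_high / hu_low, digits)


@dataclass(frozen=True)
class CalibrationEntry:
    """One material's dual-energy signature.

    ``quotient`` is the full-precision ratio (``None`` for materials with
    non-positive 80-kVp HU, for which the direction is ill-defined);
    :meth:`printed_quotient` applies the display rounding.
    """

    material: str
    formula: str
    hu_low: float
    hu_high: float
    z_eff: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.hu_low) and math.isfinite(self.hu_high)):
            raise ValueError(f"non-finite HU pair for {self.material!r}")

    @property
    def quotient(self) -> float | None:
        if self.hu_low <= 0:
            return None
        return self.hu_high / self.hu_low

    def printed_quotient(self, digits: int = 3) -> float | None:
        if self.hu_low <= 0:
            return None
        return compute_quotient(self.hu_low, self.hu_high, digits)


def ingest_measurements(
    rows: Iterable[tuple[str, str, float, float]],
) -> list[CalibrationEntry]:
    """Turn raw (material, formula, hu_low, hu_high) rows into entries.

    Order is preserved; duplicate material names and empty input are
    rejected.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no calibration measurements supplied")
    entries: list[CalibrationEntry] = []
    seen: set[str] = set()
    for material, formula, hu_low, hu_high in rows:
        if material in seen:
            raise ValueError(f"duplicate calibration material {material!r}")
        seen.add(material)
        entries.append(CalibrationEntry(material, formula, float(hu_low), float(hu_high)))
    return entries


def reference_entries() -> list[CalibrationEntry]:
    """The bundled scanner calibration table as entries."""
    return [
        CalibrationEntry(m, f, lo, hi, z)
        for m, f, lo, hi, z in REFERENCE_MEASUREMENTS
    ]


def read_measurements_csv(path: str | Path) -> list[CalibrationEntry]:
    """Read calibration measurements from CSV.

    Expected columns: ``material, formula, hu_low_80kvp, hu_high_135kvp``.
    """
    frame = pd.read_csv(path)
    required = {"material", "formula", "hu_low_80kvp", "hu_high_135kvp"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return ingest_measurements(
        zip(frame["material"], frame["formula"],
            frame["hu_low_80kvp"], frame["hu_high_135kvp"])
    )


def write_measurements_csv(entries: Iterable[CalibrationEntry], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "material": e.material,
                "formula": e.formula,
                "hu_low_80kvp": e.hu_low,
                "hu_high_135kvp": e.hu_high,
                "quotient": e.printed_quotient(),
            }
            for e in entries
        ]
    )
    frame.to_csv(path, index=False)


@dataclass(frozen=True)
class BasisComponent:
    """One direction of a decomposition basis.

    Either anchored at a measured (hu_low, hu_high) pair — in which case the
    gradient is the anchor's quotient — or gradient-only (direction through
    the origin with slope ``gradient``).
    """

    name: str
    gradient: float
    anchor: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.gradient) or self.gradient <= 0:
            raise DegenerateBasisError(
                f"component {self.name!r}: gradient must be finite and positive"
            )
        if self.anchor is not None:
            lo, hi = self.anchor
            if lo <= 0:
                raise DegenerateBasisError(
                    f"component {self.name!r}: anchor hu_low must be positive"
                )
            if not math.isclose(hi / lo, self.gradient, rel_tol=1e-12):
                raise DegenerateBasisError(
                    f"component {self.name!r}: anchor does not reproduce gradient"
                )

    @classmethod
    def from_anchor(cls, name: str, anchor: tuple[float, float]) -> "BasisComponent":
        lo, hi = float(anchor[0]), float(anchor[1])
        if lo <= 0:
            raise DegenerateBasisError(f"component {name!r}: anchor hu_low must be positive")
        return cls(name=name, gradient=hi / lo, anchor=(lo, hi))


_MIN_GRADIENT_SEPARATION = 1e-6


@dataclass(frozen=True)
class DecompositionBasis:
    """Ordered triple of material directions in the dual-energy plane.

    Components are stored sorted by ascending gradient; voxels with 80-kVp
    HU at or below ``background_threshold`` are treated as background.
    """

    name: str
    components: tuple[BasisComponent, BasisComponent, BasisComponent]
    background_threshold: float = 100.0

    def __post_init__(self) -> None:
        if len(self.components) != 3:
            raise DegenerateBasisError("a decomposition basis needs exactly three components")
        ordered = tuple(sorted(self.components, key=lambda c: c.gradient))
        object.__setattr__(self, "components", ordered)
        g = self.gradients
        for a, b in ((g[0], g[1]), (g[1], g[2])):
            if b - a < _MIN_GRADIENT_SEPARATION:
                raise DegenerateBasisError(
                    f"basis {self.name!r}: gradients {a:.6f} and {b:.6f} coincide"
                )

    @property
    def gradients(self) -> tuple[float, float, float]:
        return tuple(c.gradient for c in self.components)  # type: ignore[return-value]

    @property
    def material_names(self) -> tuple[str, str, str]:
        return tuple(c.name for c in self.components)  # type: ignore[return-value]

    def component(self, material: str) -> BasisComponent:
        for c in self.components:
            if c.name == material:
                return c
        raise KeyError(f"basis {self.name!r} has no material {material!r}")

    def index(self, material: str) -> int:
        for i, c in enumerate(self.components):
            if c.name == material:
                return i
        raise KeyError(f"basis {self.name!r} has no material {material!r}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "background_threshold": self.background_threshold,
            "components": [
                {"name": c.name, "gradient": c.gradient, "anchor": c.anchor}
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "DecompositionBasis":
        comps = tuple(
            BasisComponent(
                name=c["name"],
                gradient=float(c["gradient"]),
                anchor=tuple(c["anchor"]) if c.get("anchor") else None,
            )
            for c in payload["components"]
        )
        return cls(
            name=payload["name"],
            components=comps,  # type: ignore[arg-type]
            background_threshold=float(payload.get("background_threshold", 100.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DecompositionBasis":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_fluorine_basis(
    calcium_anchor: tuple[float, float] = CALCIUM_ANCHOR,
    iron_anchor: tuple[float, float] = ALGORITHM_IRON_ANCHOR,
    fluorine_gradient: float | None = None,
    background_threshold: float = 100.0,
) -> DecompositionBasis:
    """The custom fluorine three-material basis.

    The fluorine direction carries no anchor: it is specified by its
    gradient alone, by default the fluorite quotient rounded to two decimals
    (round(3753/5432, 2) = 0.69).
    """
    if fluorine_gradient is None:
        fluorine_gradient = compute_quotient(*FLUORITE_ANCHOR, digits=2)
    if not 0 < fluorine_gradient < 2:
        raise ValueError(f"implausible fluorine gradient {fluorine_gradient!r}")
    return DecompositionBasis(
        name="fluorine",
        components=(
            BasisComponent(name="fluorine", gradient=float(fluorine_gradient)),
            BasisComponent.from_anchor("calcium", calcium_anchor),
            BasisComponent.from_anchor("iron", iron_anchor),
        ),
        background_threshold=background_threshold,
    )


def build_calcium_basis(
    calcite_anchor: tuple[float, float] = CALCIUM_ANCHOR,
    iron_anchor: tuple[float, float] = MEASURED_IRON_ANCHOR,
    soft_tissue_gradient: float = 1.0,
    background_threshold: float = 100.0,
) -> DecompositionBasis:
    """A calcium basis mirroring the clinical calcium algorithm.

    The vendor's parameters are unpublished; this basis uses the measured
    calcite and iron-rod anchors plus a soft-tissue direction at g = 1.00.
    The soft-tissue gradient must lie above the iron gradient so that the
    mineral directions bracket from below.
    """
    iron = BasisComponent.from_anchor("iron", iron_anchor)
    if soft_tissue_gradient <= iron.gradient:
        raise DegenerateBasisError(
            "soft-tissue gradient must exceed the iron gradient "
            f"({soft_tissue_gradient} <= {iron.gradient:.4f})"
        )
    return DecompositionBasis(
        name="calcium",
        components=(
            BasisComponent.from_anchor("calcium", calcite_anchor),
            iron,
            BasisComponent(name="soft_tissue", gradient=float(soft_tissue_gradient)),
        ),
        background_threshold=background_threshold,
    )


def effective_z(composition: Mapping[str, float], exponent: float = 2.94) -> float:
    """Power-law effective atomic number (Mayneord form), informational only.

    ``Z_eff = (sum_i w_i Z_i**p)**(1/p)`` with ``w_i`` the electron fraction
    of element *i* (atom count times Z over total electrons) and
    ``p = exponent`` (default 2.94, the classical photoelectric value).

    Parameters
    ----------
    composition:
        Element symbol -> atom count, e.g. ``{"Ca": 1, "C": 1, "O": 3}``.
    """
    if not composition:
        raise ValueError("empty composition")
    z: list[float] = []
    electrons: list[float] = []
    for symbol, count in composition.items():
        if symbol not in ATOMIC_NUMBER:
            raise KeyError(f"unknown element symbol {symbol!r}")
        if count <= 0:
            raise ValueError(f"atom count for {symbol!r} must be positive")
        z.append(float(ATOMIC_NUMBER[symbol]))
        electrons.append(float(count) * ATOMIC_NUMBER[symbol])
    total = sum(electrons)
    acc = sum((e / total) * zi**exponent for e, zi in zip(electrons, z))
    return acc ** (1.0 / exponent)
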
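"""Unit-cell geometry, resolution computation, and wedge-series file I/O.

A *series* is an ordered set of narrow-rotation data wedges collected from
one crystal (or one crystal centering) under a burn protocol: each wedge is
tagged with the accumulated absorbed dose at its centre (MGy) and the dose
rate (kGy/s).  Reflections carry Lorentz-polarization-corrected, *unscaled*
integrated intensities; negative intensities from background subtraction are
retained on disk and filtering is left to the scaling stage.

On-disk dialect: one TSV per wedge (columns ``h  k  l  intensity  sigma``)
plus one YAML sidecar per series holding the cell, solvent fraction, the
shared high-resolution limit and the dose schedule.  Floats are written with
Python's shortest round-trip representation, so write -> load -> write is
byte-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    FormatError,
    InvalidCellError,
    InvalidInputError,
    ValidationError,
)

__all__ = [
    "UnitCell",
    "MillerIndex",
    "ReflectionRecord",
    "Wedge",
    "CrystalSeries",
    "d_spacing",
    "s_of_d",
    "reciprocal_metric",
    "load_series",
    "write_series",
]

WEDGE_COLUMNS = ("h", "k", "l", "intensity", "sigma")


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError(f"cell lengths must be positive: {self}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angle {name}={ang} outside (0, 180)")
        # positive-definiteness of the metric tensor
        try:
            np.linalg.cholesky(self.metric_tensor())
        except np.linalg.LinAlgError as exc:
            raise InvalidCellError(f"metric tensor not positive definite: {self}") from exc

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, Angstrom^2)."""
        a, b, c = self.a, self.b, self.c
        ca = math.cos(math.radians(self.alpha))
        cb = math.cos(math.radians(self.beta))
        cg = math.cos(math.radians(self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class MillerIndex:
    h: int
    k: int
    l: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


@dataclass(frozen=True)
class ReflectionRecord:
    """One LP-corrected integrated intensity observation.

    ``s`` is sin(theta)/lambda in 1/Angstrom, derived from the Miller index
    and the unit cell (s = 1/(2 d)).
    """

    hkl: MillerIndex
    intensity: float
    sigma: float
    s: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidInputError(f"sigma must be >= 0, got {self.sigma}")
        if self.s <= 0:
            raise InvalidInputError(f"s must be > 0, got {self.s}")


def reciprocal_metric(cell: UnitCell) -> np.ndarray:
    """Reciprocal-space metric tensor G* = inv(G) (1/Angstrom^2)."""
    return np.linalg.inv(cell.metric_tensor())


def d_spacing(cell: UnitCell, hkl: MillerIndex | tuple[int, int, int]) -> float:
    """Interplanar spacing d(hkl) in Angstrom for a general triclinic cell."""
    if isinstance(hkl, MillerIndex):
        hkl = hkl.as_tuple()
    if hkl == (0, 0, 0):
        raise InvalidInputError("d-spacing undefined for the (0,0,0) index")
    return cell.to_gemmi().calculate_d(hkl)


def s_of_d(d: float) -> float:
    """s = sin(theta)/lambda = 1/(2 d)."""
    return 1.0 / (2.0 * d)


def s_from_hkl_array(cell: UnitCell, hkl: np.ndarray) -> np.ndarray:
    """Vectorized s for an (n, 3) integer index array (via G*)."""
    gstar = reciprocal_metric(cell)
    h = np.asarray(hkl, dtype=float)
    d_star_sq = np.einsum("ni,ij,nj->n", h, gstar, h)
    return 0.5 * np.sqrt(d_star_sq)


@dataclass
class Wedge:
    """One data wedge: arrays of reflections plus dose metadata.

    Array-backed for speed; :meth:`records` yields scalar views.
    """

    index: int
    dose: float  # accumulated dose at wedge centre, MGy
    dose_rate: float  # kGy/s
    d_min: float  # high-resolution limit, Angstrom
    hkl: np.ndarray  # (n, 3) int
    intensity: np.ndarray  # (n,)
    sigma: np.ndarray  # (n,)
    s: np.ndarray  # (n,) sin(theta)/lambda

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        n = len(self.intensity)
        if n == 0:
            raise ValidationError(f"wedge {self.index} has no reflections")
        if self.hkl.shape != (n, 3) or self.sigma.shape != (n,) or self.s.shape != (n,):
            raise ValidationError(f"wedge {self.index}: inconsistent array shapes")
        if self.dose < 0:
            raise ValidationError(f"wedge {self.index}: negative dose {self.dose}")
        if np.any(self.sigma < 0):
            raise ValidationError(f"wedge {self.index}: negative sigma")
        if np.any(self.s <= 0):
            raise ValidationError(f"wedge {self.index}: non-positive s")
        d = 1.0 / (2.0 * self.s)
        if np.any(d < self.d_min * (1.0 - 1e-6)):
            raise ValidationError(
                f"wedge {self.index}: reflections beyond the d_min={self.d_min} limit"
            )

    @property
    def n_reflections(self) -> int:
        return len(self.intensity)

    def records(self) -> Iterator[ReflectionRecord]:
        for i in range(self.n_reflections):
            yield ReflectionRecord(
                hkl=MillerIndex(*map(int, self.hkl[i])),
                intensity=float(self.intensity[i]),
                sigma=float(self.sigma[i]),
                s=float(self.s[i]),
            )


@dataclass
class CrystalSeries:
    """Dose-ordered wedges from one crystal, with structure annotations."""

    acronym: str
    cell: UnitCell
    solvent_fraction: float
    wedges: list[Wedge]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.solvent_fraction < 1.0:
            raise ValidationError(
                f"solvent fraction {self.solvent_fraction} outside (0, 1)"
            )
        if not self.wedges:
            raise ValidationError("series has no wedges")
        doses = [w.dose for w in self.wedges]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValidationError(f"wedge doses not strictly increasing: {doses}")
        d_mins = {w.d_min for w in self.wedges}
        if len(d_mins) != 1:
            raise ValidationError(f"wedges disagree on d_min: {sorted(d_mins)}")

    @property
    def d_min(self) -> float:
        return self.wedges[0].d_min

    @property
    def doses(self) -> np.ndarray:
        return np.array([w.dose for w in self.wedges])


def _fmt(x: float) -> str:
    """Shortest exact decimal representation of a float."""
    return repr(float(x))


def write_series(series: CrystalSeries, path: str | Path) -> Path:
    """Write a series to ``path`` (a directory) in the TSV + sidecar dialect."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    wedge_entries = []
    for w in series.wedges:
        fname = f"wedge_{w.index:02d}.tsv"
        lines = ["\t".join(WEDGE_COLUMNS)]
        for i in range(w.n_reflections):
            lines.append(
                "\t".join(
                    [
                        str(int(w.hkl[i, 0])),
                        str(int(w.hkl[i, 1])),
                        str(int(w.hkl[i, 2])),
                        _fmt(w.intensity[i]),
                        _fmt(w.sigma[i]),
                    ]
                )
            )
        (path / fname).write_text("\n".join(lines) + "\n", encoding="utf-8")
        wedge_entries.append(
            {
                "index": int(w.index),
                "dose": float(w.dose),
                "dose_rate": float(w.dose_rate),
                "file": fname,
            }
        )
    sidecar = {
        "acronym": series.acronym,
        "cell": {
            "a": float(series.cell.a),
            "b": float(series.cell.b),
            "c": float(series.cell.c),
            "alpha": float(series.cell.alpha),
            "beta": float(series.cell.beta),
            "gamma": float(series.cell.gamma),
        },
        "solvent_fraction": float(series.solvent_fraction),
        "d_min": float(series.d_min),
        "provenance": series.provenance,
        "wedges": wedge_entries,
    }
    (path / "series.yaml").write_text(
        yaml.safe_dump(sidecar, sort_keys=False), encoding="utf-8"
    )
    return path


def load_series(path: str | Path) -> CrystalSeries:
    """Load a series written by :func:`write_series`.

    ``s`` on each record is recomputed from the Miller index and the cell.
    """
    path = Path(path)
    sidecar_path = path / "series.yaml"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar config {sidecar_path}")
    sidecar = yaml.safe_load(sidecar_path.read_text(encoding="utf-8"))
    for key in ("cell", "solvent_fraction", "d_min", "wedges"):
        if key not in sidecar:
            raise FormatError(f"sidecar lacks mandatory key '{key}'")
    cellspec = sidecar["cell"]
    for key in ("a", "b", "c", "alpha", "beta", "gamma"):
        if key not in cellspec:
            raise FormatError(f"sidecar cell lacks mandatory key '{key}'")
    cell = UnitCell(**{k: float(v) for k, v in cellspec.items()})
    d_min = float(sidecar["d_min"])

    wedges = []
    for entry in sidecar["wedges"]:
        tsv = path / entry["file"]
        if not tsv.exists():
            raise FormatError(f"missing wedge file {tsv}")
        table = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
        for col in WEDGE_COLUMNS:
            if col not in table.columns:
                raise FormatError(f"wedge file {tsv.name} lacks column '{col}'")
        if len(table) == 0:
            raise FormatError(f"wedge file {tsv.name} contains no reflections")
        hkl = table[["h", "k", "l"]].to_numpy(dtype=int)
        if np.any(np.all(hkl == 0, axis=1)):
            raise FormatError(f"wedge file {tsv.name} contains a (0,0,0) index")
        s = s_from_hkl_array(cell, hkl)
        wedges.append(
            Wedge(
                index=int(entry["index"]),
                dose=float(entry["dose"]),
                dose_rate=float(entry["dose_rate"]),
                d_min=d_min,
                hkl=hkl,
                intensity=table["intensity"].to_numpy(dtype=float),
                sigma=table["sigma"].to_numpy(dtype=float),
                s=s,
            )
        )

    return CrystalSeries(
        acronym=str(sidecar.get("acronym", "")),
        cell=cell,
        solvent_fraction=float(sidecar["solvent_fraction"]),
        wedges=wedges,
        provenance=sidecar.get("provenance") or {},
    )
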
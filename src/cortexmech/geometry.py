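"""Geometry of a cell confined between two parallel plates.

A non-adherent cell squeezed between the dish bottom and a wedged AFM
cantilever adopts, to good approximation, a surface of minimal area at
constant volume.  With a 90-degree contact angle at both plates the
meridional profile is a circular arc of radius ``R2 = h/2`` whose centre
sits at cylindrical radius ``r_con`` (the contact radius), so that the
equatorial radius is ``R1 = r_con + h/2``.  All closed forms below follow
from integrating this solid of revolution.

Units are fixed internally: lengths in µm, areas in µm², volumes in µm³,
forces in nN and tensions in mN/m (1 nN/µm = 1 mN/m).  Conversions, if
any, belong at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellShape",
    "UnconfinedGeometryError",
    "shape_from_radius",
    "solve_shape",
    "volume_from_equatorial_area",
    "effective_tension",
    "min_confined_volume",
]


class UnconfinedGeometryError(ValueError):
    """The requested geometry does not touch both plates."""


@dataclass(frozen=True)
class CellShape:
    """Geometric state of a plate-confined cell.

    Attributes
    ----------
    h : float
        Plate separation (cell height), µm.
    V : float
        Cell volume, µm³.
    R1 : float
        Equatorial radius, µm.
    R2 : float
        Meridional (profile) radius of curvature, µm; ``h/2`` for the
        90° contact-angle arc.
    r_con : float
        Contact radius at each plate, µm.
    A_con : float
        Contact area per plate, ``π·r_con²``, µm².
    A_lat : float
        Free (lateral) surface area, µm².
    A : float
        Total cortex area ``A_lat + 2·A_con`` — the cortex covers the
        plate-contact disks as well, µm².
    """

    h: float
    V: float
    R1: float
    R2: float
    r_con: float
    A_con: float
    A_lat: float
    A: float


def min_confined_volume(h: float) -> float:
    """Volume of the smallest cell that still spans a gap ``h``.

    This is the sphere of diameter ``h`` (contact radius zero):
    ``(4/3)·π·(h/2)³``.
    """
    return (4.0 / 3.0) * math.pi * (0.5 * h) ** 3


def shape_from_radius(R1: float, h: float) -> CellShape:
    """Build the confined shape from its equatorial radius and height.

    Parameters
    ----------
    R1 : float
        Equatorial radius, µm.  Must satisfy ``R1 >= h/2``.
    h : float
        Plate separation, µm, > 0.

    Returns
    -------
    CellShape

    Raises
    ------
    UnconfinedGeometryError
        If ``R1 < h/2`` — the shape would be a free sphere not touching
        both plates.
    """
    if h <= 0:
        raise ValueError(f"plate gap must be positive, got h={h}")
    R2 = 0.5 * h
    if R1 < R2 * (1.0 - 1e-12):
        raise UnconfinedGeometryError(
            f"unconfined geometry: R1={R1} µm < h/2={R2} µm (free sphere)"
        )
    r_con = max(R1 - R2, 0.0)
    A_con = math.pi * r_con**2
    # Solid of revolution of x(z) = r_con + sqrt(R2² − z²), z ∈ [−R2, R2]
    V = math.pi * (2.0 * R2 * r_con**2 + math.pi * r_con * R2**2 + (4.0 / 3.0) * R2**3)
    A_lat = 2.0 * math.pi * R2 * (math.pi * r_con + 2.0 * R2)
    A = A_lat + 2.0 * A_con
    return CellShape(h=h, V=V, R1=R1, R2=R2, r_con=r_con, A_con=A_con, A_lat=A_lat, A=A)


def solve_shape(V: float, h: float) -> CellShape:
    """Invert the volume closed form for the shape at fixed (V, h).

    The volume is quadratic in the contact radius,

        V/π = 2·R2·r_con² + π·R2²·r_con + (4/3)·R2³,

    so the unique physical shape is the positive root for ``r_con``.

    Raises
    ------
    UnconfinedGeometryError
        If ``V`` is below the volume of the sphere of diameter ``h``
        (the cell would be too small to touch both plates).
    """
    if h <= 0:
        raise ValueError(f"plate gap must be positive, got h={h}")
    R2 = 0.5 * h
    c = (4.0 / 3.0) * R2**3 - V / math.pi
    if c > 1e-12 * max(V / math.pi, 1.0):
        raise UnconfinedGeometryError(
            f"cell too small to touch both plates: V={V} µm³ < "
            f"{min_confined_volume(h):.6g} µm³ at h={h} µm"
        )
    a = 2.0 * R2
    b = math.pi * R2**2
    disc = b * b - 4.0 * a * c
    r_con = (-b + math.sqrt(max(disc, 0.0))) / (2.0 * a)
    r_con = max(r_con, 0.0)
    return shape_from_radius(r_con + R2, h)


def solve_shape_series(V: float, h: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised :func:`solve_shape` over a height series.

    Returns arrays ``R1, R2, r_con, A_con, A`` (keys named as the
    fields of :class:`CellShape`).  Used by the rheology pipeline where
    a per-sample Python object would be wasteful.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("non-positive cell height in series")
    R2 = 0.5 * h
    c = (4.0 / 3.0) * R2**3 - V / math.pi
    bad = c > 1e-12 * max(V / math.pi, 1.0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise UnconfinedGeometryError(
            f"cell too small to touch both plates at sample {i} (h={h[i]:.4g} µm)"
        )
    a = 2.0 * R2
    b = math.pi * R2**2
    r_con = np.maximum((-b + np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))) / (2.0 * a), 0.0)
    A_con = math.pi * r_con**2
    A_lat = 2.0 * math.pi * R2 * (math.pi * r_con + 2.0 * R2)
    return {
        "R1": r_con + R2,
        "R2": R2,
        "r_con": r_con,
        "A_con": A_con,
        "A": A_lat + 2.0 * A_con,
    }


def volume_from_equatorial_area(A_eq: float, h: float) -> float:
    """Cell volume from the equatorial cross-sectional area at height h.

    Mirrors the experimental volume estimate: a bright-field image of the
    equatorial plane of the confined cell yields ``A_eq = π·R1²``, which
    fixes the volume at the known plate gap.
    """
    R2 = 0.5 * h
    if A_eq < math.pi * R2**2 * (1.0 - 1e-12):
        raise UnconfinedGeometryError(
            f"unconfined geometry: A_eq={A_eq} µm² < π(h/2)²={math.pi * R2**2:.6g} µm²"
        )
    R1 = math.sqrt(A_eq / math.pi)
    return shape_from_radius(R1, h).V


def effective_tension(F, shape: CellShape):
    """Effective cortical tension from the Laplace force balance.

    ``γ_eff = F / (A_con·(1/R1 + 1/R2))`` — the tension a membrane of the
    given geometry must carry to push back on the plate with force ``F``.
    With ``F`` in nN and lengths in µm the result is in mN/m.

    ``F`` may be a scalar or an array (per-sample force series).
    """
    if shape.A_con <= 0:
        raise UnconfinedGeometryError(
            "undefined tension: no plate contact (A_con = 0)"
        )
    denom = shape.A_con * (1.0 / shape.R1 + 1.0 / shape.R2)
    return F / denom
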
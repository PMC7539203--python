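"""Cross-section morphometry of mitotic cells and spheroids.

Roundness of a cross-section is defined through the moment-fitted
ellipse as 4·Area/(π·major_axis²) — identical to the shape factor
reported by common image-analysis software — and equals the minor/major
axis ratio for a true ellipse (1 for a circle).  Spheroid size is the
largest cross-sectional area over the z-stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = ["CrossSection", "MorphometryError", "roundness", "largest_cross_section"]


class MorphometryError(ValueError):
    pass


@dataclass(frozen=True)
class CrossSection:
    """One binary cross-section slice of a cell or spheroid."""

    mask: np.ndarray
    pixel_size_um: float
    z_index: int = 0
    label: str = "cell"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        object.__setattr__(self, "mask", m)

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2


def _single_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n != 1:
        raise MorphometryError(f"expected exactly 1 foreground component, found {n}")
    return labels


def roundness(section: CrossSection) -> float:
    """Roundness 4·Area/(π·major²) of the moment-fitted ellipse.

    ``major`` is the full major-axis length of the ellipse with the same
    second central moments as the foreground.  Values marginally above 1
    from pixelation are clipped to 1.
    """
    labels = _single_component(section.mask)
    props = measure.regionprops(labels)[0]
    major = props.axis_major_length
    if major <= 0:
        raise MorphometryError("degenerate component: zero major axis")
    value = 4.0 * props.area / (np.pi * major**2)
    return float(min(value, 1.0))


def largest_cross_section(stack: list[CrossSection]) -> tuple[int, float]:
    """(z-index, area µm²) of the largest slice in a z-stack.

    Ties are broken toward the lowest z-index.
    """
    if not stack:
        raise MorphometryError("empty z-stack")
    ordered = sorted(stack, key=lambda s: s.z_index)
    best = max(ordered, key=lambda s: (s.area_um2, -s.z_index))
    if best.area_um2 <= 0:
        raise MorphometryError("all slices empty")
    return best.z_index, best.area_um2
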
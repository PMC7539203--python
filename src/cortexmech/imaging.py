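"""Cortex quantification from equatorial confocal sections.

The cortical actin (or myosin) of a round cell shows up in an equatorial
confocal slice as a bright rim on top of a cytoplasmic plateau.  Along
the cell boundary, 200 equidistant lines are drawn normal to the
contour, extending 2 µm into the interior and 2 µm out; the intensity
profiles along these lines are averaged and the average is fitted by

    I_sm(r) = I_cyt · ½(1 − erf((r−μ)/(σ1·√2)))
            + I_cort · G(r, μ, σ2) · (1 + erf(α·(r−μ)/(σ2·√2)))
            + I_BG

where G is the unit-peak Gaussian exp(−(r−μ)²/(2σ2²)), r is the
boundary-centred radial coordinate (negative = interior), μ locates the
cell boundary, σ1 smears the cytoplasmic step, σ2 is the cortex peak
width and α its skewness.  The skewed-Gaussian term is the cortical
fluorescence; its radial integral I_2D,cortex = I_cort·σ2·√(2π)
normalised by I_cyt is the cortex-to-cytoplasm ratio.

Cortical thickness is estimated from a two-channel recording (membrane
dye + actin label): both radial profiles are fitted with α = 0 and twice
the offset of the two Gaussian peak positions, 2·(μ_membrane − μ_actin),
is the thickness estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf
from skimage import measure
from skimage.filters import gaussian, threshold_otsu

__all__ = [
    "RadialProfile",
    "ProfileFit",
    "ThicknessResult",
    "SegmentationError",
    "MarginError",
    "RegistrationError",
    "FitFailureError",
    "profile_model",
    "detect_boundary",
    "radial_profile",
    "fit_profile",
    "cortex_ratio",
    "register_channels",
    "estimate_thickness",
    "thickness_from_images",
]


class SegmentationError(RuntimeError):
    pass


class MarginError(ValueError):
    pass


class RegistrationError(RuntimeError):
    pass


class FitFailureError(RuntimeError):
    pass


@dataclass(frozen=True)
class RadialProfile:
    """Circumference-averaged radial intensity profile.

    ``r_um`` is boundary-centred: negative inside the cell, positive
    outside, strictly increasing.
    """

    r_um: np.ndarray
    intensity: np.ndarray
    n_lines: int
    pixel_size_um: float

    def __post_init__(self) -> None:
        r = np.asarray(self.r_um, dtype=float)
        I = np.asarray(self.intensity, dtype=float)
        if len(r) != len(I) or len(r) < 20:
            raise ValueError("profile needs >= 20 matched (r, I) samples")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radial coordinate must be strictly increasing")
        if np.any(I < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "r_um", r)
        object.__setattr__(self, "intensity", I)


@dataclass(frozen=True)
class ProfileFit:
    """Converged parameters of the radial-profile model."""

    mu_um: float
    sigma1_um: float
    sigma2_um: float
    I_cyt: float
    I_cort: float
    I_bg: float
    alpha: float
    I2D_cortex: float
    ratio_um: float
    resid_rms: float
    skewed: bool


@dataclass(frozen=True)
class ThicknessResult:
    thickness_um: float
    fit_actin: ProfileFit
    fit_membrane: ProfileFit
    shift_px: tuple[float, float]
    unphysical: bool


def profile_model(r, mu, sigma1, sigma2, I_cyt, I_cort, I_bg, alpha=0.0):
    """Evaluate the cytoplasm-step + skewed-cortex-peak profile model."""
    r = np.asarray(r, dtype=float)
    step = I_cyt * 0.5 * (1.0 - erf((r - mu) / (sigma1 * math.sqrt(2.0))))
    peak = (
        I_cort
        * np.exp(-((r - mu) ** 2) / (2.0 * sigma2**2))
        * (1.0 + erf(alpha * (r - mu) / (sigma2 * math.sqrt(2.0))))
    )
    return step + peak + I_bg


# ---------------------------------------------------------------------------
# segmentation and profile extraction
# ---------------------------------------------------------------------------

def detect_boundary(
    image: np.ndarray,
    smooth_sigma_px: float = 2.0,
    min_area_px: int = 64,
) -> np.ndarray:
    """Locate the cell boundary of one dominant bright cell.

    Gaussian smoothing, Otsu threshold, hole filling, then the contour
    of the single resulting component is traced at subpixel resolution.
    Returns an (N, 2) array of (row, col) vertices ordered
    counter-clockwise (in x = col, y = −row convention).  A
    user-supplied binary mask may be passed instead of an intensity
    image; it is used as-is apart from hole filling.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if img.dtype == bool or set(np.unique(img)).issubset({0.0, 1.0}):
        mask = img > 0.5
    else:
        sm = gaussian(img, sigma=smooth_sigma_px, preserve_range=True)
        if sm.max() <= sm.min():
            raise SegmentationError("0 candidate components (blank image)")
        mask = sm > threshold_otsu(sm)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("0 candidate components above threshold")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    candidates = np.flatnonzero(areas >= min_area_px) + 1
    if len(candidates) != 1:
        raise SegmentationError(
            f"{len(candidates)} candidate components above threshold (need exactly 1)"
        )
    comp = labels == candidates[0]
    contours = measure.find_contours(comp.astype(float), 0.5)
    contour = max(contours, key=len)
    # enforce counter-clockwise orientation (positive shoelace area in
    # x = col, y = -row coordinates)
    x, y = contour[:, 1], -contour[:, 0]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        contour = contour[::-1]
    return contour


def _resample_closed(contour: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon at n equidistant arc-length anchors."""
    pts = np.asarray(contour, dtype=float)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.sqrt(np.sum(np.diff(pts, axis=0) ** 2, axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.column_stack(
        [np.interp(targets, s, pts[:, 0]), np.interp(targets, s, pts[:, 1])]
    )
    return out


def radial_profile(
    image: np.ndarray,
    contour: np.ndarray,
    pixel_size_um: float,
    n_lines: int = 200,
    reach_um: float = 2.0,
) -> RadialProfile:
    """Average intensity along lines normal to the contour.

    ``n_lines`` anchors are placed at equidistant arc-length positions
    on the contour; at each, intensity is sampled by bilinear
    interpolation along the outward normal from −reach to +reach in
    steps of half a pixel, and the per-line profiles are averaged.
    """
    img = np.asarray(image, dtype=float)
    anchors = _resample_closed(contour, n_lines)
    nxt = np.roll(anchors, -1, axis=0)
    prv = np.roll(anchors, 1, axis=0)
    tangent = nxt - prv
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    centroid = anchors.mean(axis=0)
    outward = np.sum(normal * (anchors - centroid), axis=1)
    normal[outward < 0] *= -1.0

    step_um = 0.5 * pixel_size_um
    n_samples = int(round(2.0 * reach_um / step_um)) + 1
    r_um = np.linspace(-reach_um, reach_um, n_samples)
    r_px = r_um / pixel_size_um
    # coords: (2, n_lines, n_samples)
    coords = anchors.T[:, :, None] + normal.T[:, :, None] * r_px[None, None, :]
    if (
        coords[0].min() < 0
        or coords[1].min() < 0
        or coords[0].max() > img.shape[0] - 1
        or coords[1].max() > img.shape[1] - 1
    ):
        raise MarginError(
            f"contour closer than {reach_um} µm to the image edge; "
            "cannot extract full radial lines"
        )
    lines = ndimage.map_coordinates(img, coords.reshape(2, -1), order=1).reshape(
        n_lines, n_samples
    )
    return RadialProfile(
        r_um=r_um,
        intensity=lines.mean(axis=0),
        n_lines=n_lines,
        pixel_size_um=pixel_size_um,
    )


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _initial_guess(profile: RadialProfile) -> np.ndarray:
    r, I = profile.r_um, profile.intensity
    n_tail = max(len(r) // 10, 3)
    I_bg = float(np.median(I[-n_tail:]))
    I_cyt = max(float(np.median(I[:n_tail])) - I_bg, 1e-6)
    i_pk = int(np.argmax(I))
    mu = float(r[i_pk])
    I_cort = max(float(I.max()) - I_cyt - I_bg, 1e-6)
    s1 = 3.0 * profile.pixel_size_um
    # σ2 from the FWHM of the part of the peak rising above the plateau
    half = I_bg + 0.5 * (I.max() - I_bg + I_cyt)
    above = np.flatnonzero(I > half)
    if len(above) >= 2:
        width = float(r[above[-1]] - r[above[0]])
        s2 = max(width / 2.355, profile.pixel_size_um)
    else:
        s2 = s1
    return np.array([mu, s1, s2, I_cyt, I_cort, I_bg, 0.0])


def fit_profile(
    profile: RadialProfile,
    skewed: bool = True,
    max_restarts: int = 5,
    seed: int = 0,
    weighting: str = "none",
) -> ProfileFit:
    """Nonlinear least-squares fit of the radial-profile model.

    With ``skewed=False`` the skewness α is fixed at zero (the
    convention used for thickness estimation).  Initialisation is
    deterministic — μ from the profile argmax, background from the outer
    10% tail, cytoplasm from the inner 10% — with up to ``max_restarts``
    jittered-σ restarts on failure.  ``weighting='poisson'`` weights
    residuals by 1/√I, the approximate maximum-likelihood weighting for
    photon-limited data.
    """
    r, I = profile.r_um, profile.intensity
    p0 = _initial_guess(profile)
    reach = float(r[-1] - r[0])
    lo = np.array([r[0], 1e-3, 1e-3, 0.0, 0.0, 0.0, -10.0])
    hi = np.array([r[-1], reach, reach, np.inf, np.inf, np.inf, 10.0])
    if not skewed:
        p0 = p0[:6]
        lo, hi = lo[:6], hi[:6]
    if weighting == "poisson":
        w = 1.0 / np.sqrt(np.clip(I, max(1e-3, 1e-6 * I.max()), None))
    elif weighting == "none":
        w = np.ones_like(I)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    def resid(p):
        alpha = p[6] if skewed else 0.0
        return w * (profile_model(r, p[0], p[1], p[2], p[3], p[4], p[5], alpha) - I)

    rng = np.random.default_rng(seed)
    attempts = []
    best = None
    scale = float(np.sqrt(np.mean(I**2))) or 1.0
    # deterministic multi-start over σ scalings, then jittered restarts;
    # the peak/step decomposition has local minima for wide peaks
    starts = []
    for fac in (1.0, 0.5, 2.0):
        p_try = p0.copy()
        p_try[1] *= fac
        p_try[2] *= fac
        starts.append(p_try)
    for attempt in range(len(starts) + max_restarts):
        if attempt < len(starts):
            p_try = starts[attempt]
        else:
            p_try = p0.copy()
            p_try[1] *= rng.uniform(0.3, 3.0)
            p_try[2] *= rng.uniform(0.3, 3.0)
        try:
            res = least_squares(
                resid, np.clip(p_try, lo, hi), bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            attempts.append(f"attempt {attempt}: raised {exc!r}")
            continue
        finite = np.all(np.isfinite(res.x))
        # accept a hit on the iteration cap when the residual is already
        # negligible (σ2 is unidentifiable at I_cort ≈ 0)
        acceptable = finite and (
            res.success or math.sqrt(2.0 * res.cost / len(I)) < 1e-6 * scale
        )
        if acceptable:
            if best is None or res.cost < best.cost:
                best = res
            # an essentially perfect fit cannot be improved upon
            if math.sqrt(2.0 * best.cost / len(I)) < 1e-8 * scale:
                break
            if attempt >= len(starts) - 1:
                break
        else:
            attempts.append(f"attempt {attempt}: status={res.status}, cost={res.cost:.4g}")
    if best is None:
        raise FitFailureError(
            "profile fit did not converge; initialisation p0="
            f"{np.array2string(p0, precision=4)}; " + "; ".join(attempts)
        )
    p = best.x
    alpha = float(p[6]) if skewed else 0.0
    model_best = profile_model(r, p[0], p[1], p[2], p[3], p[4], p[5], alpha)
    rms = float(np.sqrt(np.mean((model_best - I) ** 2)))
    I2d = float(p[4] * p[2] * math.sqrt(2.0 * math.pi))
    ratio = I2d / p[3] if p[3] > 0 else float("nan")
    return ProfileFit(
        mu_um=float(p[0]),
        sigma1_um=float(p[1]),
        sigma2_um=float(p[2]),
        I_cyt=float(p[3]),
        I_cort=float(p[4]),
        I_bg=float(p[5]),
        alpha=alpha,
        I2D_cortex=I2d,
        ratio_um=float(ratio),
        resid_rms=rms,
        skewed=skewed,
    )


def cortex_ratio(fit: ProfileFit) -> float:
    """Cortex-to-cytoplasm ratio I_2D,cortex / I_cyt (µm).

    The radial integral of the skewed cortical peak has the closed form
    I_cort·σ2·√(2π): the odd erf term integrates to zero for any
    skewness α.
    """
    if fit.I_cyt <= 0:
        raise ValueError("undefined ratio: fitted I_cyt <= 0")
    return fit.I_cort * fit.sigma2_um * math.sqrt(2.0 * math.pi) / fit.I_cyt


# ---------------------------------------------------------------------------
# two-channel thickness estimation
# ---------------------------------------------------------------------------

def register_channels(image_a: np.ndarray, image_b: np.ndarray) -> np.ndarray:
    """Lateral shift of channel B relative to channel A, in pixels.

    Computed as the difference of the intensity centres of gravity of
    the above-background (Otsu) pixels: shift = centroid(B) −
    centroid(A).  Background-subtracted weights make the result
    invariant to uniform intensity scaling.
    """

    def centroid(img):
        img = np.asarray(img, dtype=float)
        if img.max() <= img.min():
            raise RegistrationError("empty foreground: channel has no contrast")
        thr = threshold_otsu(img)
        w = np.where(img > thr, img - thr, 0.0)
        total = w.sum()
        if total <= 0:
            raise RegistrationError("empty foreground after thresholding")
        idx = np.indices(img.shape)
        return np.array([(idx[0] * w).sum(), (idx[1] * w).sum()]) / total

    return centroid(image_b) - centroid(image_a)


def estimate_thickness(fit_actin: ProfileFit, fit_membrane: ProfileFit) -> float:
    """Cortex thickness: 2·(μ_membrane − μ_actin), µm.

    The actin peak sits half a thickness inside the membrane peak, so
    twice the peak offset estimates the full thickness.  Both fits must
    use α = 0.  Negative values are returned but flagged unphysical.
    """
    if fit_actin.skewed or fit_membrane.skewed:
        raise ValueError("thickness estimation requires fits with skewness fixed to 0")
    t = 2.0 * (fit_membrane.mu_um - fit_actin.mu_um)
    if t < 0:
        warnings.warn(f"unphysical negative thickness estimate ({t:.4g} µm)")
    return t


def thickness_from_images(
    actin: np.ndarray,
    membrane: np.ndarray,
    pixel_size_um: float,
    n_lines: int = 200,
    reach_um: float = 2.0,
) -> ThicknessResult:
    """End-to-end two-channel thickness estimate.

    Removes the lateral channel shift (centre-of-gravity registration),
    detects the boundary on the actin channel, extracts both radial
    profiles along the same normal lines and fits each with α = 0.
    """
    shift = register_channels(actin, membrane)
    membrane_reg = ndimage.shift(np.asarray(membrane, dtype=float), -shift, order=1)
    contour = detect_boundary(actin)
    prof_a = radial_profile(actin, contour, pixel_size_um, n_lines, reach_um)
    prof_m = radial_profile(membrane_reg, contour, pixel_size_um, n_lines, reach_um)
    fit_a = fit_profile(prof_a, skewed=False)
    fit_m = fit_profile(prof_m, skewed=False)
    t = estimate_thickness(fit_a, fit_m)
    return ThicknessResult(
        thickness_um=t,
        fit_actin=fit_a,
        fit_membrane=fit_m,
        shift_px=(float(shift[0]), float(shift[1])),
        unphysical=t < 0,
    )
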
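"""Oscillatory AFM confinement rheology of the actin cortex.

A round cell is held between the dish and a wedged cantilever while the
plate gap is modulated sinusoidally (drive frequency f, typically 1 Hz,
sampled at 500 Hz).  Per sample, the confined-cell geometry at constant
volume converts the AFM force into an effective cortical tension

    γ_eff = F_AFM / (A_con·(1/R1 + 1/R2))

(stress readout) and the total cortex area into an area strain

    ε_A = (A − ⟨A⟩)/⟨A⟩

(strain readout).  Amplitudes and phases of the two signals at the drive
frequency give the three mechanical readouts per cell:

* cortical tension  γ  — time average of γ_eff over the analysis window,
* cortical stiffness K = γ̂_eff / ε̂_A,
* phase shift       φ = φ_γ − φ_A   (0° elastic solid … 90° viscous
  liquid), equivalently φ = 2πf·Δt for the tension–strain lag Δt.

The complex elastic modulus of the cortex is K* = K·e^{iφ}.

Analysis is restricted to a steady-state window of five to ten drive
periods chosen after the transient relaxation phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import effective_tension, solve_shape, solve_shape_series

__all__ = [
    "AFMTrace",
    "StrainSeries",
    "RheologyResult",
    "Window",
    "NoSteadyStateError",
    "CorruptCalibrationError",
    "compute_cell_height",
    "tension_strain_series",
    "select_steady_window",
    "fit_oscillation",
    "rheology_summary",
    "height_sensitivity",
    "wrap_phase_deg",
]


class NoSteadyStateError(RuntimeError):
    """No contiguous window of periods satisfies the steadiness rule."""


class CorruptCalibrationError(ValueError):
    """Height reconstruction produced non-positive cell heights."""


@dataclass(frozen=True)
class AFMTrace:
    """A raw oscillatory confinement recording plus its calibration.

    Attributes
    ----------
    time_s : np.ndarray
        Sample times, s, strictly increasing and uniformly spaced.
    force_nN : np.ndarray
        Cantilever force, nN.
    piezo_um : np.ndarray
        Piezo (cantilever base) height, µm, on the instrument axis;
        referenced to ``surface_ref_um`` below.
    spring_constant_N_per_m : float
        Cantilever spring constant from thermal-noise calibration, N/m.
    elevation_um : float
        Height the cantilever was retracted above the dish after the
        surface touch, µm.
    spike_height_um : float
        Height of the spikes at the wedge boundary (manufacturing
        imperfection), µm; added to the reconstructed gap.
    surface_ref_um : float
        Piezo reading recorded when the cantilever touched the dish
        surface, µm.  ``piezo_um − surface_ref_um`` is the wedge height
        above the dish.
    frequency_hz : float
        Drive frequency of the height oscillation, Hz.
    drive_amplitude_um : float
        Nominal piezo oscillation amplitude, µm (metadata).
    """

    time_s: np.ndarray
    force_nN: np.ndarray
    piezo_um: np.ndarray
    spring_constant_N_per_m: float
    elevation_um: float
    spike_height_um: float
    surface_ref_um: float
    frequency_hz: float
    drive_amplitude_um: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.force_nN, dtype=float)
        z = np.asarray(self.piezo_um, dtype=float)
        if not (len(t) == len(f) == len(z)):
            raise ValueError("time, force and piezo series must have equal length")
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing with >= 2 samples")
        rate = 1.0 / float(np.median(np.diff(t)))
        if rate < 20.0 * self.frequency_hz:
            raise ValueError(
                f"sampling rate {rate:.3g} Hz below 20x drive frequency "
                f"{self.frequency_hz} Hz"
            )
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "force_nN", f)
        object.__setattr__(self, "piezo_um", z)

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    @property
    def n_periods(self) -> int:
        # duration covered by the samples, including the final interval
        dt = float(np.median(np.diff(self.time_s)))
        dur = float(self.time_s[-1] - self.time_s[0]) + dt
        return int(math.floor(dur * self.frequency_hz + 1e-9))


@dataclass(frozen=True)
class Window:
    """Contiguous analysis window, in samples and whole drive periods."""

    start: int
    stop: int  # exclusive
    n_periods: int

    def slice(self) -> slice:
        return slice(self.start, self.stop)


@dataclass(frozen=True)
class StrainSeries:
    """Per-sample stress/strain readouts over the analysis window."""

    time_s: np.ndarray
    height_um: np.ndarray
    gamma_eff_mN_per_m: np.ndarray
    area_um2: np.ndarray
    area_mean_um2: float
    area_strain: np.ndarray


@dataclass(frozen=True)
class RheologyResult:
    """Cortex-mechanical readouts of one cell.

    ``K_complex`` is the complex elastic modulus K* = K·e^{iφ}.
    Phases are in degrees; ``phi_deg`` is wrapped to (−180°, 180°] and
    flagged (not clipped) when outside the physical band [−5°, 95°].
    """

    gamma_mN_per_m: float
    stiffness_mN_per_m: float
    phi_deg: float
    K_complex: complex
    gamma_amp_mN_per_m: float
    strain_amp: float
    phi_gamma_deg: float
    phi_strain_deg: float
    lag_s: float
    window: Window
    resid_rms_tension: float
    resid_rms_strain: float
    low_snr: bool = False
    unphysical_phase: bool = False
    flags: tuple[str, ...] = field(default_factory=tuple)


def compute_cell_height(trace: AFMTrace) -> np.ndarray:
    """Reconstruct the confined-cell height from a recording.

    The gap equals the cantilever elevation above the dish minus how far
    it was lowered onto the cell, plus the wedge spike height and the
    force-induced cantilever deflection F/k:

        h(t) = (elevation − lowering(t)) + spike + F(t)/k,
        lowering(t) = elevation − (piezo(t) − surface_ref).
    """
    if trace.spring_constant_N_per_m <= 0:
        raise CorruptCalibrationError("spring constant must be positive")
    # 1 N/m = 1000 nN/µm
    deflection_um = trace.force_nN / (trace.spring_constant_N_per_m * 1000.0)
    lowering = trace.elevation_um - (trace.piezo_um - trace.surface_ref_um)
    h = (trace.elevation_um - lowering) + trace.spike_height_um + deflection_um
    if np.any(h <= 0):
        i = int(np.argmax(h <= 0))
        raise CorruptCalibrationError(
            f"non-positive reconstructed cell height at t={trace.time_s[i]:.4g} s"
        )
    return h


def _period_slices(trace: AFMTrace) -> list[slice]:
    """Sample slices of consecutive whole drive periods from the start."""
    t0 = float(trace.time_s[0])
    edges = t0 + np.arange(trace.n_periods + 1) / trace.frequency_hz
    idx = np.searchsorted(trace.time_s, edges, side="left")
    return [slice(int(a), int(b)) for a, b in zip(idx[:-1], idx[1:]) if b > a]


def select_steady_window(
    trace: AFMTrace,
    window_periods: int = 8,
    rel_tol: float = 0.05,
    allow_shrink: bool = True,
) -> Window:
    """Pick the latest steady-state window of whole drive periods.

    Steadiness means constant force and constant height oscillation
    amplitude: within the candidate window, every per-period half
    peak-to-peak amplitude of both channels must lie within ``rel_tol``
    (default 5%) of the window median.  ``window_periods`` is clamped to
    the five-to-ten-period analysis band; when fewer periods were
    recorded and ``allow_shrink`` is set, the window shrinks down to 5
    periods before giving up.
    """
    W = int(min(max(window_periods, 5), 10))
    periods = _period_slices(trace)
    n = len(periods)
    if n < 5:
        raise NoSteadyStateError(f"recording holds only {n} whole periods (< 5)")
    h = compute_cell_height(trace)
    amp_f = np.array([0.5 * (trace.force_nN[s].max() - trace.force_nN[s].min()) for s in periods])
    amp_h = np.array([0.5 * (h[s].max() - h[s].min()) for s in periods])

    # when the recording is shorter than the requested window, fall back
    # to the 5-period minimum of the analysis band
    W_first = W if n >= W else 5
    for w in range(W_first, 4, -1):
        for start in range(n - w, -1, -1):
            ok = True
            for amp in (amp_f, amp_h):
                block = amp[start : start + w]
                med = np.median(block)
                if med <= 0 or np.any(np.abs(block - med) > rel_tol * med):
                    ok = False
                    break
            if ok:
                return Window(
                    start=periods[start].start,
                    stop=periods[start + w - 1].stop,
                    n_periods=w,
                )
        if not allow_shrink:
            break
    report = "; ".join(
        f"period {i}: F_amp={a:.4g} nN, h_amp={b:.4g} um"
        for i, (a, b) in enumerate(zip(amp_f, amp_h))
    )
    raise NoSteadyStateError(f"no steady state window found ({report})")


def tension_strain_series(trace: AFMTrace, V: float, window: Window | None = None) -> StrainSeries:
    """Convert a recording into stress/strain series over a window.

    For every sample the constant-volume shape at the reconstructed
    height gives the geometry; the force then maps to γ_eff and the
    total cortex area to the area strain.  The area average ⟨A⟩ (and
    hence ε_A, which is mean-free by construction) refers to the
    analysis window only.
    """
    h = compute_cell_height(trace)
    if window is None:
        window = Window(start=0, stop=len(h), n_periods=trace.n_periods)
    sl = window.slice()
    hw = h[sl]
    geo = solve_shape_series(V, hw)
    denom = geo["A_con"] * (1.0 / geo["R1"] + 1.0 / geo["R2"])
    if np.any(denom <= 0):
        i = int(np.argmax(denom <= 0))
        raise CorruptCalibrationError(
            f"no plate contact at t={trace.time_s[sl][i]:.4g} s (A_con = 0)"
        )
    gamma_eff = trace.force_nN[sl] / denom
    A = geo["A"]
    A_mean = float(np.mean(A))
    strain = (A - A_mean) / A_mean
    return StrainSeries(
        time_s=trace.time_s[sl],
        height_um=hw,
        gamma_eff_mN_per_m=gamma_eff,
        area_um2=A,
        area_mean_um2=A_mean,
        area_strain=strain,
    )


def fit_oscillation(
    time_s: np.ndarray,
    y: np.ndarray,
    frequency_hz: float,
    snr_factor: float = 3.0,
) -> tuple[float, float, float, float, bool]:
    """Harmonic least squares at a known drive frequency.

    Fits ``a + b·sin(2πft) + c·cos(2πft)`` and returns
    ``(mean, amplitude, phase_rad, resid_rms, low_snr)`` with
    amplitude = √(b²+c²) and phase = atan2(c, b), i.e. the signal is
    ``mean + amplitude·sin(2πft + phase)``.  The fit is exact for any
    window length, unlike FFT bin-picking which needs whole periods.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(y, dtype=float)
    w = 2.0 * math.pi * frequency_hz
    X = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = coef
    amp = math.hypot(b, c)
    phase = math.atan2(c, b)
    resid = y - X @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    low_snr = amp < snr_factor * rms / math.sqrt(len(y))
    return float(a), float(amp), float(phase), rms, low_snr


def wrap_phase_deg(phi: float) -> float:
    """Wrap a phase in degrees to the interval (−180°, 180°]."""
    return phi - 360.0 * math.ceil((phi - 180.0) / 360.0)


def rheology_summary(
    trace: AFMTrace,
    V: float,
    window_periods: int = 8,
    rel_tol: float = 0.05,
    allow_shrink: bool = True,
) -> RheologyResult:
    """Full per-cell analysis: steady window -> stress/strain -> (γ, K, φ).

    γ is the window mean of γ_eff; K and φ come from the harmonic fits
    of tension and area strain at the drive frequency.
    """
    window = select_steady_window(
        trace, window_periods=window_periods, rel_tol=rel_tol, allow_shrink=allow_shrink
    )
    series = tension_strain_series(trace, V, window)
    f = trace.frequency_hz
    g_mean, g_amp, g_phase, g_rms, g_low = fit_oscillation(series.time_s, series.gamma_eff_mN_per_m, f)
    _, e_amp, e_phase, e_rms, e_low = fit_oscillation(series.time_s, series.area_strain, f)
    phi = wrap_phase_deg(math.degrees(g_phase - e_phase))
    K = g_amp / e_amp if e_amp > 0 else float("nan")
    lag = math.radians(phi) / (2.0 * math.pi * f)
    flags: list[str] = []
    low_snr = bool(g_low or e_low)
    if low_snr:
        flags.append("low_snr")
    unphys = not (-5.0 <= phi <= 95.0)
    if unphys:
        flags.append("unphysical_phase")
    return RheologyResult(
        gamma_mN_per_m=g_mean,
        stiffness_mN_per_m=K,
        phi_deg=phi,
        K_complex=K * complex(math.cos(math.radians(phi)), math.sin(math.radians(phi))),
        gamma_amp_mN_per_m=g_amp,
        strain_amp=e_amp,
        phi_gamma_deg=math.degrees(g_phase),
        phi_strain_deg=math.degrees(e_phase),
        lag_s=lag,
        window=window,
        resid_rms_tension=g_rms,
        resid_rms_strain=e_rms,
        low_snr=low_snr,
        unphysical_phase=unphys,
        flags=tuple(flags),
    )


def height_sensitivity(trace: AFMTrace, V: float, dh_um: float = 0.5, **kwargs) -> dict[str, RheologyResult]:
    """Re-analyse with the cell height shifted by ±dh_um.

    The wedge irregularities and cantilever placement give an absolute
    height uncertainty of about 0.5 µm; this reports how (γ, K, φ) move
    when the whole height series is offset by that much, leaving the
    point estimate untouched.
    """
    out: dict[str, RheologyResult] = {}
    for label, d in (("minus", -dh_um), ("nominal", 0.0), ("plus", +dh_um)):
        shifted = AFMTrace(
            time_s=trace.time_s,
            force_nN=trace.force_nN,
            piezo_um=trace.piezo_um + d,
            spring_constant_N_per_m=trace.spring_constant_N_per_m,
            elevation_um=trace.elevation_um,
            spike_height_um=trace.spike_height_um,
            surface_ref_um=trace.surface_ref_um,
            frequency_hz=trace.frequency_hz,
            drive_amplitude_um=trace.drive_amplitude_um,
        )
        out[label] = rheology_summary(shifted, V, **kwargs)
    return out
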
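"""Forward simulation of every input the analysis pipeline consumes.

Each generator inverts the corresponding analysis: a viscoelastic cortex
with prescribed tension γ0, stiffness K and phase shift φ produces an
AFM force trace through the confined-cell geometry; a prescribed
radial-profile parameter set renders an equatorial fluorescence image;
an ellipsoid produces a z-stack of cross-section masks; and a cohort
design draws per-cell mechanical parameters with group shifts.  Every
fixture carries a :class:`SyntheticTruth` record, and identical seeds
yield identical fixtures — all randomness flows through one
``numpy.random.Generator`` per call.

Default simulation conditions mirror the measurement protocol: free
cell diameter 20 µm, confinement to 65% of the free height, piezo
amplitude 0.25 µm at 1 Hz, 500 Hz sampling, 12 analysis periods after a
transient, force noise 0.1 nN, and a piecewise-linear rendering of the
drive sine (the piezo controller approximates the sine by linear
segments; the analyser fits a true sinusoid to the fundamental).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .geometry import min_confined_volume, solve_shape_series
from .imaging import RadialProfile, profile_model
from .morphometry import CrossSection
from .rheology import AFMTrace, fit_oscillation

__all__ = [
    "SyntheticTruth",
    "CohortGroup",
    "CohortDesign",
    "default_emt_design",
    "gen_afm_trace",
    "gen_radial_profile",
    "gen_equatorial_image",
    "gen_two_channel_cell",
    "gen_cohort",
    "gen_spheroid_masks",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record attached to every generated fixture."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# AFM traces
# ---------------------------------------------------------------------------

def _drive_waveform(t: np.ndarray, f: float, piecewise_linear: bool, knots_per_period: int = 20) -> np.ndarray:
    """Unit drive waveform: sine or its piecewise-linear approximation."""
    if not piecewise_linear:
        return np.sin(2.0 * math.pi * f * t)
    t0, t1 = t[0], t[-1]
    knots = np.arange(t0, t1 + 1.0 / (f * knots_per_period), 1.0 / (f * knots_per_period))
    return np.interp(t, knots, np.sin(2.0 * math.pi * f * knots))


def gen_afm_trace(
    gamma0: float = 1.5,
    stiffness: float = 20.0,
    phi_deg: float = 30.0,
    free_diameter_um: float = 20.0,
    confinement: float = 0.65,
    drive_amplitude_um: float = 0.25,
    frequency_hz: float = 1.0,
    sampling_hz: float = 500.0,
    n_periods: int = 12,
    transient_periods: int = 2,
    transient_amplitude: float = 0.5,
    transient_tau_s: float = 1.0,
    noise_force_nN: float = 0.1,
    piecewise_linear_drive: bool = True,
    spring_constant_N_per_m: float = 0.3,
    spike_height_um: float = 0.5,
    seed: int = 0,
) -> tuple[AFMTrace, SyntheticTruth]:
    """Simulate an oscillatory confinement recording of one cell.

    The plate gap is h(t) = h0 + Δh·drive(t) with h0 = confinement ×
    free diameter.  The constant-volume geometry at each sample yields
    the area strain; the cortex responds linearly to the strain's
    fundamental Fourier component with modulus K·e^{iφ} on top of the
    resting tension γ0, and the force follows from the Laplace balance
    F = γ_eff·A_con·(1/R1 + 1/R2) plus Gaussian sensor noise.  An
    optional exponential transient multiplies the oscillatory force
    component to emulate the relaxation phase after initial confinement.
    """
    rng = np.random.default_rng(seed)
    R_free = 0.5 * free_diameter_um
    V = (4.0 / 3.0) * math.pi * R_free**3
    h0 = confinement * free_diameter_um
    if V < min_confined_volume(h0 + drive_amplitude_um):
        raise ValueError("infeasible geometry: cell does not span the plate gap")

    n_total = int(round((n_periods + transient_periods) * sampling_hz / frequency_hz))
    t = np.arange(n_total) / sampling_hz
    h = h0 + drive_amplitude_um * _drive_waveform(t, frequency_hz, piecewise_linear_drive)

    geo = solve_shape_series(V, h)
    A = geo["A"]
    A_mean = float(np.mean(A))
    strain = (A - A_mean) / A_mean
    _, e_amp, e_phase, _, _ = fit_oscillation(t, strain, frequency_hz)

    w = 2.0 * math.pi * frequency_hz
    phi = math.radians(phi_deg)
    osc = stiffness * e_amp * np.sin(w * t + e_phase + phi)
    if transient_amplitude != 0.0:
        osc = osc * (1.0 + transient_amplitude * np.exp(-t / transient_tau_s))
    gamma_eff = gamma0 + osc
    denom = geo["A_con"] * (1.0 / geo["R1"] + 1.0 / geo["R2"])
    F = gamma_eff * denom
    if noise_force_nN > 0:
        F = F + rng.normal(0.0, noise_force_nN, size=F.shape)

    # piezo such that height reconstruction (piezo - surface_ref + spike
    # + F/k) returns h(t) exactly
    deflection = F / (spring_constant_N_per_m * 1000.0)
    surface_ref = 0.0
    piezo = surface_ref + h - spike_height_um - deflection
    trace = AFMTrace(
        time_s=t,
        force_nN=F,
        piezo_um=piezo,
        spring_constant_N_per_m=spring_constant_N_per_m,
        elevation_um=h0 - spike_height_um,
        spike_height_um=spike_height_um,
        surface_ref_um=surface_ref,
        frequency_hz=frequency_hz,
        drive_amplitude_um=drive_amplitude_um,
    )
    truth = SyntheticTruth(
        kind="afm_trace",
        seed=seed,
        params=dict(
            gamma0=gamma0,
            stiffness=stiffness,
            phi_deg=phi_deg,
            V_um3=V,
            h0_um=h0,
            drive_amplitude_um=drive_amplitude_um,
            frequency_hz=frequency_hz,
            sampling_hz=sampling_hz,
            n_periods=n_periods,
            transient_periods=transient_periods,
            noise_force_nN=noise_force_nN,
            strain_amp=float(e_amp),
            strain_phase_rad=float(e_phase),
        ),
    )
    return trace, truth


# ---------------------------------------------------------------------------
# radial profiles and equatorial images
# ---------------------------------------------------------------------------

DEFAULT_PROFILE_PARAMS = dict(
    mu=0.0, sigma1=0.3, sigma2=0.25, I_cyt=50.0, I_cort=100.0, I_bg=5.0, alpha=1.0
)


def gen_radial_profile(
    params: dict | None = None,
    noise: str | None = None,
    peak_snr: float = 10.0,
    n_lines: int = 200,
    pixel_size_um: float = 0.1,
    reach_um: float = 2.0,
    seed: int = 0,
) -> tuple[RadialProfile, SyntheticTruth]:
    """Simulate a circumference-averaged radial profile.

    With ``noise='poisson'`` each of the ``n_lines`` raw line profiles
    receives independent Poisson noise scaled so the model peak
    corresponds to ``peak_snr²`` photon counts, and the noisy lines are
    averaged — the same averaging the imaging pipeline performs before
    fitting.  ``noise='gaussian'`` adds white noise of σ = peak/peak_snr
    to each line instead.
    """
    p = dict(DEFAULT_PROFILE_PARAMS, **(params or {}))
    rng = np.random.default_rng(seed)
    step = 0.5 * pixel_size_um
    n_samples = int(round(2.0 * reach_um / step)) + 1
    r = np.linspace(-reach_um, reach_um, n_samples)
    model = profile_model(r, p["mu"], p["sigma1"], p["sigma2"], p["I_cyt"], p["I_cort"], p["I_bg"], p["alpha"])
    if noise is None:
        mean_profile = model
    elif noise == "poisson":
        counts_per_au = peak_snr**2 / float(model.max())
        lines = rng.poisson(model * counts_per_au, size=(n_lines, n_samples)) / counts_per_au
        mean_profile = lines.mean(axis=0)
    elif noise == "gaussian":
        sigma = float(model.max()) / peak_snr
        lines = model[None, :] + rng.normal(0.0, sigma, size=(n_lines, n_samples))
        mean_profile = np.clip(lines, 0.0, None).mean(axis=0)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    profile = RadialProfile(
        r_um=r,
        intensity=np.clip(mean_profile, 0.0, None),
        n_lines=n_lines,
        pixel_size_um=pixel_size_um,
    )
    truth = SyntheticTruth(
        kind="radial_profile", seed=seed,
        params=dict(p, noise=noise, peak_snr=peak_snr, n_lines=n_lines),
    )
    return profile, truth


def _render_radial_image(
    shape_px: tuple[int, int],
    center_px: tuple[float, float],
    cell_radius_um: float,
    pixel_size_um: float,
    p: dict,
    angular_modulation: float,
) -> np.ndarray:
    rows, cols = np.indices(shape_px)
    dy = (rows - center_px[0]) * pixel_size_um
    dx = (cols - center_px[1]) * pixel_size_um
    r = np.hypot(dy, dx) - cell_radius_um
    cort = p["I_cort"]
    if angular_modulation != 0.0:
        theta = np.arctan2(dy, dx)
        cort = cort * (1.0 + angular_modulation * np.cos(theta))
    # cytoplasmic step + background, then the (possibly angularly
    # modulated) cortical peak
    base = profile_model(r, p["mu"], p["sigma1"], p["sigma2"], p["I_cyt"], 0.0, p["I_bg"], p["alpha"])
    peak = (
        cort
        * np.exp(-((r - p["mu"]) ** 2) / (2.0 * p["sigma2"] ** 2))
        * (1.0 + erf(p["alpha"] * (r - p["mu"]) / (p["sigma2"] * math.sqrt(2.0))))
    )
    return base + peak


def gen_equatorial_image(
    params: dict | None = None,
    cell_radius_um: float = 8.0,
    pixel_size_um: float = 0.1,
    margin_um: float = 3.0,
    angular_modulation: float = 0.0,
    noise: str | None = None,
    peak_snr: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Render a 16-bit equatorial confocal image of a round cell.

    The radial intensity cross-section of the rendered disk follows the
    radial-profile model with the given parameters; an optional angular
    modulation of the cortical amplitude exercises circumferential
    averaging.  Poisson noise is scaled so the model peak corresponds to
    ``peak_snr²`` counts.
    """
    p = dict(DEFAULT_PROFILE_PARAMS, **(params or {}))
    if p["sigma1"] <= 0 or p["sigma2"] <= 0 or p["I_cyt"] < 0 or p["I_cort"] < 0:
        raise ValueError("parameter out of admissible range")
    rng = np.random.default_rng(seed)
    half_um = cell_radius_um + 2.0 + margin_um
    n = 2 * int(round(half_um / pixel_size_um)) + 1
    if cell_radius_um + 2.0 >= half_um:
        raise ValueError("cell radius + 2 µm reach does not fit in the frame")
    c = (n - 1) / 2.0
    img = _render_radial_image((n, n), (c, c), cell_radius_um, pixel_size_um, p, angular_modulation)
    img = np.clip(img, 0.0, None)
    if noise == "poisson":
        counts_per_au = peak_snr**2 / float(img.max())
        img = rng.poisson(img * counts_per_au).astype(float)
        img_int = np.clip(img, 0, 65535).astype(np.uint16)
        au_per_count = 1.0 / counts_per_au
    elif noise == "gaussian":
        sigma = float(img.max()) / peak_snr
        img = np.clip(img + rng.normal(0.0, sigma, img.shape), 0.0, None)
        scale = 65535.0 / max(float(img.max()), 1e-9)
        img_int = np.round(img * scale).astype(np.uint16)
        au_per_count = 1.0 / scale
    elif noise is None:
        scale = 60000.0 / max(float(img.max()), 1e-9)
        img_int = np.round(img * scale).astype(np.uint16)
        au_per_count = 1.0 / scale
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    truth = SyntheticTruth(
        kind="equatorial_image",
        seed=seed,
        params=dict(
            p,
            cell_radius_um=cell_radius_um,
            pixel_size_um=pixel_size_um,
            angular_modulation=angular_modulation,
            noise=noise,
            peak_snr=peak_snr,
            au_per_count=au_per_count,
        ),
    )
    return img_int, truth


def gen_two_channel_cell(
    thickness_um: float = 0.3,
    cell_radius_um: float = 8.0,
    pixel_size_um: float = 0.05,
    channel_shift_px: tuple[float, float] = (0.0, 0.0),
    actin_params: dict | None = None,
    membrane_params: dict | None = None,
    noise: str | None = None,
    peak_snr: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Two-channel cell for thickness estimation.

    The actin peak is placed half a thickness inside the membrane peak
    (μ_actin = −T/2 relative to the membrane peak at the cell radius),
    so the two-channel estimator should return ``thickness_um``.  An
    optional lateral shift is applied to the membrane channel to
    exercise centre-of-gravity registration.
    """
    pa = dict(mu=-0.5 * thickness_um, sigma1=0.3, sigma2=0.2, I_cyt=60.0, I_cort=120.0,
              I_bg=5.0, alpha=0.0)
    pa.update(actin_params or {})
    pm = dict(mu=0.0, sigma1=0.3, sigma2=0.2, I_cyt=8.0, I_cort=150.0, I_bg=5.0, alpha=0.0)
    pm.update(membrane_params or {})
    actin, _ = gen_equatorial_image(
        pa, cell_radius_um, pixel_size_um, noise=noise, peak_snr=peak_snr, seed=seed
    )
    membrane, _ = gen_equatorial_image(
        pm, cell_radius_um, pixel_size_um, noise=noise, peak_snr=peak_snr, seed=seed + 1
    )
    if channel_shift_px != (0.0, 0.0):
        from scipy import ndimage

        membrane = ndimage.shift(membrane.astype(float), channel_shift_px, order=1)
        membrane = np.round(np.clip(membrane, 0, 65535)).astype(np.uint16)
    truth = SyntheticTruth(
        kind="two_channel_cell",
        seed=seed,
        params=dict(
            thickness_um=thickness_um,
            cell_radius_um=cell_radius_um,
            pixel_size_um=pixel_size_um,
            channel_shift_px=channel_shift_px,
            actin=pa,
            membrane=pm,
        ),
    )
    return actin, membrane, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortGroup:
    """Lognormal per-cell parameter distribution of one condition."""

    name: str
    condition: str  # e.g. pre_emt / post_emt
    phase: str  # interphase / mitosis
    n: int
    gamma_median: float
    stiffness_median: float
    phi_median_deg: float
    cv: float = 0.25


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[CohortGroup, ...]

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.n < 3:
                raise ValueError(f"design error: group {g.name} has n={g.n} < 3")


def default_emt_design(n_per_group: int = 25, cv: float = 0.25, effect: float = 1.0) -> CohortDesign:
    """Cohort design encoding the EMT shift directions.

    Interphase cells lose tension and stiffness after EMT; mitotic
    cells gain tension and stiffness and lose phase shift.  ``effect``
    linearly scales the log-median shifts (0 = null design).
    """

    def shifted(base, target):
        return base * (target / base) ** effect

    groups = (
        CohortGroup("interphase_pre", "pre_emt", "interphase", n_per_group, 1.0, 20.0, 30.0, cv),
        CohortGroup("interphase_post", "post_emt", "interphase", n_per_group,
                    shifted(1.0, 0.6), shifted(20.0, 12.0), 30.0, cv),
        CohortGroup("mitosis_pre", "pre_emt", "mitosis", n_per_group, 1.5, 25.0, 30.0, cv),
        CohortGroup("mitosis_post", "post_emt", "mitosis", n_per_group,
                    shifted(1.5, 2.2), shifted(25.0, 38.0), shifted(30.0, 22.0), cv),
    )
    return CohortDesign(groups=groups)


def gen_cohort(
    design: CohortDesign | None = None,
    seed: int = 0,
    generate_traces: bool = True,
    trace_kwargs: dict | None = None,
) -> tuple[list[tuple[AFMTrace, SyntheticTruth]], pd.DataFrame]:
    """Draw a cohort of cells and (optionally) their AFM recordings.

    Per-cell (γ0, K, φ) are lognormal draws around the group medians
    with coefficient of variation ``cv``.  When ``generate_traces`` is
    set, one synthetic recording per cell is produced (fixture list is
    empty otherwise).  The returned truth table has one row per cell.
    """
    design = design or default_emt_design()
    rng = np.random.default_rng(seed)
    rows = []
    fixtures: list[tuple[AFMTrace, SyntheticTruth]] = []
    tkw = dict(trace_kwargs or {})
    cell_id = 0
    for g in design.groups:
        slog = math.sqrt(math.log(1.0 + g.cv**2))
        for _ in range(g.n):
            gamma = g.gamma_median * math.exp(rng.normal(0.0, slog))
            K = g.stiffness_median * math.exp(rng.normal(0.0, slog))
            phi = g.phi_median_deg * math.exp(rng.normal(0.0, slog))
            phi = min(phi, 89.0)
            cell_seed = int(rng.integers(0, 2**31 - 1))
            rows.append(
                dict(
                    cell_id=cell_id, group=g.name, condition=g.condition, phase=g.phase,
                    gamma_true=gamma, stiffness_true=K, phi_true_deg=phi, seed=cell_seed,
                )
            )
            if generate_traces:
                fixtures.append(
                    gen_afm_trace(gamma0=gamma, stiffness=K, phi_deg=phi, seed=cell_seed, **tkw)
                )
            cell_id += 1
    return fixtures, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spheroid masks
# ---------------------------------------------------------------------------

def gen_spheroid_masks(
    semi_axes_um: tuple[float, float, float] = (40.0, 30.0, 35.0),
    pixel_size_um: float = 1.0,
    z_step_um: float = 2.0,
    label: str = "spheroid",
    seed: int = 0,
) -> tuple[list[CrossSection], SyntheticTruth]:
    """Voxelise an ellipsoid into a z-stack of binary cross-sections.

    Semi-axes are (a, b, c) with c along z; slice k at height z has an
    elliptical section with semi-axes scaled by √(1 − z²/c²) and
    analytic area π·a·b·(1 − z²/c²), recorded in the truth table.
    """
    a, b, c = semi_axes_um
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    nz = int(math.floor(c / z_step_um))
    zs = np.arange(-nz, nz + 1) * z_step_um
    half = max(a, b) + 2.0 * pixel_size_um
    npx = 2 * int(round(half / pixel_size_um)) + 1
    ctr = (npx - 1) / 2.0
    rows, cols = np.indices((npx, npx))
    x = (cols - ctr) * pixel_size_um
    y = (rows - ctr) * pixel_size_um
    stack = []
    areas = []
    kept_z = []
    i = 0
    for z in zs:
        s2 = 1.0 - (z / c) ** 2
        if s2 <= 0:
            continue  # slice misses the ellipsoid
        mask = (x / a) ** 2 + (y / b) ** 2 <= s2
        if not mask.any():
            continue
        stack.append(CrossSection(mask=mask, pixel_size_um=pixel_size_um, z_index=i, label=label))
        areas.append(math.pi * a * b * s2)
        kept_z.append(float(z))
        i += 1
    truth = SyntheticTruth(
        kind="spheroid_masks",
        seed=seed,
        params=dict(
            semi_axes_um=semi_axes_um,
            pixel_size_um=pixel_size_um,
            z_step_um=z_step_um,
            z_um=kept_z,
            analytic_area_um2=areas,
        ),
    )
    return stack, truth
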
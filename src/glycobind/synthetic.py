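"""Ground-truth synthetic data for every pipeline stage.

Scenario presets encode the study conditions for the two urothelial cell
lines: control T24 cells (strong condensation, xi0 = 4.2, c* = 2.6e11
particles/mL), heparinase-treated T24 (weak condensation, xi0 = 1.5,
c* = 1.2e11), UROtsa (no condensation, measured low-dose slope 17.0e-11
%.mL/particle; T24's is 6.6e-11) and a salt-free buffer in which
condensation is disabled.  Default dose grids are the ones used in the
binding assays (a nine-dose grid 4.97e10 ... 1.27e12 and a five-dose grid
1.12e11 ... 1.78e12 particles/mL).

All generators take an integer seed and are byte-deterministic for a fixed
seed.  Noise models: multiplicative log-normal for fluorescence readouts
(detector-gain-like), additive Gaussian for impedance, Poisson shot noise
for images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .binding import BindingModelParams, DoseBindingCurve, simulate_binding_curve
from .ecis import EcisParams
from .imaging import ImageStack
from .kinetics import HillParams, VacuoleTimeCourse, hill_vacuole_model

__all__ = [
    "GeneratorConfig",
    "BINDING_SCENARIOS",
    "ECIS_SCENARIOS",
    "VACUOLE_SCENARIOS",
    "NINE_DOSE_GRID",
    "FIVE_DOSE_GRID",
    "gen_binding_dataset",
    "gen_impedance_trace",
    "gen_vacuole_timecourse",
    "gen_cluster_image",
    "gen_motility_stack",
    "gen_vacuole_stack",
]

# Dose grids used in the binding assays [particles/mL]
NINE_DOSE_GRID = np.array([4.97e10, 7.46e10, 1.12e11, 1.68e11, 2.52e11,
                           3.78e11, 5.66e11, 8.48e11, 1.27e12])
FIVE_DOSE_GRID = np.array([1.12e11, 2.24e11, 4.48e11, 8.96e11, 1.78e12])

# Intrinsic (uncondensed) binding increment of T24 cells: the measured
# low-dose slope 6.6e-11 times xi0 = 4.2 (low-dose slope = slope_high/xi0).
_T24_SLOPE_HIGH = 6.6e-11 * 4.2

BINDING_SCENARIOS: dict[str, BindingModelParams] = {
    "t24_control": BindingModelParams(
        xi0=4.2, c_star=2.6e11, b_max=100.0, slope_high=_T24_SLOPE_HIGH),
    "t24_heparinase": BindingModelParams(
        xi0=1.5, c_star=1.2e11, b_max=100.0, slope_high=_T24_SLOPE_HIGH),
    "urotsa": BindingModelParams(  # xi0 < 1: condensation never engages
        xi0=0.9, c_star=2.6e11, b_max=100.0, slope_high=17.0e-11),
    "salt_free": BindingModelParams(  # condensation disabled at the threshold
        xi0=1.0, c_star=2.6e11, b_max=100.0, slope_high=_T24_SLOPE_HIGH),
}

# ECIS scenario parameters are unprinted in the source figures; these encode
# the qualitative contrast (T24 binds faster: larger a_inv, larger vacuole
# plateau) at magnitudes matching normalized-impedance traces.
ECIS_SCENARIOS: dict[str, EcisParams] = {
    "t24_cap250": EcisParams(z0=1.0, z_max=0.30, a=2.0,
                             hill=HillParams(0.20, 5.0, 2.0)),
    "urotsa_cap250": EcisParams(z0=1.0, z_max=0.15, a=4.0,
                                hill=HillParams(0.08, 7.0, 2.0)),
    "t24_cap125": EcisParams(z0=1.0, z_max=0.15, a=2.0,
                             hill=HillParams(1e-12, 5.0, 2.0)),
}

# Vacuole time-course scenarios: dose-scaled plateau; the 125 uM dose forms
# no detectable vacuoles (plateau 0), exercising the non-convergence path.
VACUOLE_SCENARIOS: dict[str, HillParams] = {
    "cap500": HillParams(nv_max=0.40, k_half=6.0, n_hill=2.5),
    "cap250": HillParams(nv_max=0.20, k_half=6.0, n_hill=2.5),
    "cap125": HillParams(nv_max=0.0, k_half=6.0, n_hill=2.5),
}


@dataclass
class GeneratorConfig:
    """Scenario + noise + replication + seed for any generator.

    ``scenario`` selects a preset parameter set (or ``"custom"`` with
    ``params`` supplied); ``noise`` is a multiplicative CV for fluorescence
    stages and an additive SD for impedance; ``options`` carries
    stage-specific extras (dose grid, field size, ...).
    """

    scenario: str = "custom"
    params: Any = None
    noise: float = 0.05
    n_replicates: int = 4
    seed: int = 0
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")

    def resolve(self, table: dict[str, Any], stage: str) -> Any:
        if self.scenario == "custom":
            if self.params is None:
                raise ValueError(f"custom {stage} scenario needs params")
            return self.params
        try:
            return table[self.scenario]
        except KeyError:
            raise ValueError(
                f"unknown {stage} scenario {self.scenario!r}; "
                f"known: {sorted(table)} or 'custom'") from None


def gen_binding_dataset(cfg: GeneratorConfig) -> DoseBindingCurve:
    """Replicate dose-binding curves for a scenario preset.

    Default grid is the nine-dose assay grid; override with
    ``options['concentrations']``.
    """
    params = cfg.resolve(BINDING_SCENARIOS, "binding")
    conc = np.asarray(cfg.options.get("concentrations", NINE_DOSE_GRID),
                      dtype=float)
    return simulate_binding_curve(params, conc, noise_cv=cfg.noise,
                                  n_replicates=cfg.n_replicates,
                                  seed=cfg.seed, condition=cfg.scenario)


def _rise_tau_free(t: np.ndarray, peak_h: float) -> np.ndarray:
    """Smoothstep binding rise: sin^2 ramp reaching exactly 1 at the peak."""
    r = np.ones_like(t)
    pre = t < peak_h
    r[pre] = np.sin(0.5 * math.pi * t[pre] / peak_h) ** 2
    return r


def gen_impedance_trace(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Raw impedance series [Ohm] around a treatment event.

    The normalized mean is z0 before treatment, then the impedance model
    with its binding term ramped up by a smooth rise that saturates exactly
    at ``peak_h`` (default 0.5 h, the observed ~30-min binding peak); the
    post-peak segment is therefore exactly the impedance model.  Additive
    Gaussian noise of SD ``cfg.noise`` (normalized units) is applied, and
    the whole trace is scaled to an absolute baseline (default 900 Ohm).

    Returns ``(times_h, ohm)`` with times absolute (treatment at
    ``options['treatment_time_h']``, default 2.0) so the normalization step
    is exercised downstream.
    """
    params = cfg.resolve(ECIS_SCENARIOS, "ecis")
    opt = cfg.options
    dt = opt.get("sampling_min", 5.0) / 60.0
    duration = opt.get("duration_h", 24.0)
    t_treat = opt.get("treatment_time_h", 2.0)
    peak_h = opt.get("peak_h", 0.5)
    baseline_ohm = opt.get("baseline_ohm", 900.0)

    t = np.arange(0.0, t_treat + duration + dt / 2, dt)
    rel = t - t_treat
    z = np.full_like(t, params.z0)
    post = rel >= 0
    tr = rel[post]
    z[post] = (params.z0
               + _rise_tau_free(tr, peak_h) * params.z_max * np.exp(-tr / params.a)
               - hill_vacuole_model(tr, params.hill))
    if cfg.noise > 0:
        rng = np.random.default_rng(cfg.seed)
        z = z + rng.normal(0.0, cfg.noise, size=z.size)
    return t, z * baseline_ohm


def gen_vacuole_timecourse(cfg: GeneratorConfig) -> list[VacuoleTimeCourse]:
    """Replicate vacuole-area time-courses (5-min sampling over 10 h).

    Multiplicative log-normal noise of CV ``cfg.noise``; the ``cap125``
    scenario generates a zero plateau so the downstream fit reports
    non-convergence.
    """
    params = cfg.resolve(VACUOLE_SCENARIOS, "vacuole")
    opt = cfg.options
    dt = opt.get("sampling_min", 5.0) / 60.0
    duration = opt.get("duration_h", 10.0)
    t = np.arange(0.0, duration + dt / 2, dt)
    mean = hill_vacuole_model(t, params) if params.nv_max > 0 \
        else np.zeros_like(t)
    rng = np.random.default_rng(cfg.seed)
    sigma = np.sqrt(np.log1p(cfg.noise**2)) if cfg.noise > 0 else 0.0
    out = []
    for _ in range(max(cfg.n_replicates, 1)):
        if sigma > 0:
            vals = mean * np.exp(
                sigma * rng.standard_normal(t.size) - 0.5 * sigma**2)
        else:
            vals = mean.copy()
        out.append(VacuoleTimeCourse(times=t, values=vals,
                                     condition=cfg.scenario))
    return out


def gen_cluster_image(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """STED-like glycan-cluster field: Poisson points, PSF blur, shot noise.

    Options: ``density_per_um2`` (default 22, the T24 cluster density),
    ``field_um`` (default 2.0, i.e. a 4 um^2 field), ``pixel_size_nm``
    (default 20, the acquisition voxel), ``psf_fwhm_nm`` (default 60,
    STED-like), ``peak_photons`` (default 150), ``background_photons``
    (default 5).  Returns ``(image, true_coordinates_px)``.
    """
    opt = cfg.options
    density = opt.get("density_per_um2", 22.0)
    field_um = opt.get("field_um", 2.0)
    px_nm = opt.get("pixel_size_nm", 20.0)
    fwhm = opt.get("psf_fwhm_nm", 60.0)
    peak = opt.get("peak_photons", 150.0)
    bg = opt.get("background_photons", 5.0)

    rng = np.random.default_rng(cfg.seed)
    npx = int(round(field_um * 1000.0 / px_nm))
    n_spots = rng.poisson(density * field_um**2)
    coords = rng.uniform(0, npx, size=(n_spots, 2))

    yy, xx = np.mgrid[0:npx, 0:npx]
    sigma_px = fwhm / 2.355 / px_nm
    mean = np.full((npx, npx), float(bg))
    for cy, cx in coords:
        mean += peak * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                              / (2.0 * sigma_px**2))
    img = rng.poisson(mean).astype(float)
    return img, coords


def gen_motility_stack(cfg: GeneratorConfig) -> ImageStack:
    """Phase-contrast-like stack of textured cell blobs with frame jitter.

    ``options['sigma_profile']`` gives the per-transition jitter SD in
    pixels (length n_frames - 1); the default is the observed step profile
    (brief elevation after treatment, dip, recovery).  sigma = 0 freezes the
    field, giving a zero motility index.
    """
    opt = cfg.options
    n_frames = opt.get("n_frames", 12)
    size = opt.get("size_px", 96)
    n_blobs = opt.get("n_blobs", 6)
    profile = opt.get("sigma_profile")
    if profile is None:
        third = (n_frames - 1) // 3 or 1
        profile = np.concatenate([
            np.full(third, 2.0), np.full(third, 0.5),
            np.full((n_frames - 1) - 2 * third, 1.0)])
    profile = np.asarray(profile, dtype=float)
    if profile.size != n_frames - 1:
        raise ValueError("sigma_profile must have n_frames - 1 entries")

    rng = np.random.default_rng(cfg.seed)
    centers = rng.uniform(0.2 * size, 0.8 * size, size=(n_blobs, 2))
    radii = rng.uniform(0.08 * size, 0.15 * size, size=n_blobs)
    # frozen per-blob texture so motion, not texture, drives the index
    phases = rng.uniform(0, 2 * np.pi, size=(n_blobs, 2))

    yy, xx = np.mgrid[0:size, 0:size]

    def render(offsets: np.ndarray) -> np.ndarray:
        img = np.full((size, size), 40.0)
        for (cy, cx), r, (py, px_) , (dy, dx) in zip(
                centers, radii, phases, offsets):
            d2 = (yy - cy - dy) ** 2 + (xx - cx - dx) ** 2
            body = np.exp(-d2 / (2 * r**2))
            texture = 0.5 + 0.5 * np.sin(0.35 * (yy + dy) + py) \
                * np.sin(0.35 * (xx + dx) + px_)
            img += 160.0 * body * texture
        return img

    offsets = np.zeros((n_blobs, 2))
    frames = [render(offsets)]
    for sigma in profile:
        if sigma > 0:
            offsets = offsets + rng.normal(0.0, sigma, size=(n_blobs, 2))
        frames.append(render(offsets))
    stack = np.clip(np.stack(frames), 0, 255).astype(np.uint8)
    return ImageStack(frames=stack, pixel_size_um=opt.get("pixel_um", 0.5),
                      frame_interval_min=opt.get("interval_min", 5.0),
                      channel="phase-contrast")


def gen_vacuole_stack(cfg: GeneratorConfig) -> tuple[ImageStack, HillParams]:
    """Fluorescence stack of vacuole disks growing per the Hill schedule.

    Total disk area per frame follows ``n_cells x N_v(t)`` with the
    scenario's Hill time constants; the area amplitude is re-expressed on
    the imaging scale (``options['nv_max_um2_per_cell']``, default 4 um^2
    of vacuole per cell at plateau, i.e. a handful of micron-sized vacuoles)
    so the disks are resolvable at the configured pixel size.  Disk area is
    split over fixed random centres; background is dim Poisson noise, disks
    are bright.  Returns the stack and the generating parameters (imaging
    scale) so end-to-end recovery can be scored.
    """
    base = cfg.resolve(VACUOLE_SCENARIOS, "vacuole")
    opt = cfg.options
    amp = opt.get("nv_max_um2_per_cell", 4.0)
    params = HillParams(nv_max=amp if base.nv_max > 0 else 0.0,
                        k_half=base.k_half, n_hill=base.n_hill)
    n_frames = opt.get("n_frames", 25)
    duration = opt.get("duration_h", 10.0)
    size = opt.get("size_px", 128)
    pixel_um = opt.get("pixel_um", 0.5)
    n_cells = opt.get("n_cells", 10)
    n_disks = opt.get("n_disks", 15)

    rng = np.random.default_rng(cfg.seed)
    centers = rng.uniform(0.1 * size, 0.9 * size, size=(n_disks, 2))
    weights = rng.uniform(0.5, 1.5, size=n_disks)
    weights /= weights.sum()

    times = np.linspace(0.0, duration, n_frames)
    yy, xx = np.mgrid[0:size, 0:size]
    frames = np.empty((n_frames, size, size), dtype=np.uint8)
    for i, t in enumerate(times):
        total_area_um2 = n_cells * hill_vacuole_model(float(t), params)
        mean = np.full((size, size), 8.0)
        for (cy, cx), w in zip(centers, weights):
            r_um = math.sqrt(w * total_area_um2 / math.pi)
            r_px = r_um / pixel_um
            if r_px > 0.3:
                mean = np.where((yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2,
                                200.0, mean)
        frames[i] = np.clip(rng.poisson(mean), 0, 255).astype(np.uint8)
    interval_min = duration * 60.0 / max(n_frames - 1, 1)
    stack = ImageStack(frames=frames, pixel_size_um=pixel_um,
                       frame_interval_min=interval_min,
                       channel="fluorescence")
    return stack, params
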
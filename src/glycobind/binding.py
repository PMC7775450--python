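"""Cooperative nanocapsule binding gated by counterion condensation.

The model: below a critical particle concentration ``c*`` the glycan chains of
the glycocalyx carry a condensed counterion cloud (initial line charge density
``xi0 > 1``) that screens most binding sites; only a fraction ``1/xi0`` of
sites is available.  Bound cationic nanocapsules neutralize chain charge, and
above ``c*`` the condensed counterions are released, restoring the full site
population.  The available-site fraction is

    f(c) = 1 / xi_eff(c),   xi_eff(c) = xi0^(1 - s(c)),

with ``s`` a logistic switch in log10-concentration centred at ``c*`` (width
``transition_width`` decades), so ``xi_eff`` slides geometrically from ``xi0``
to 1.  Bound signal accumulates over a finite site pool (Langmuir-like
depletion):

    B(c) = b_max * (1 - exp(-(1/b_max) * integral_0^c slope_high * f(u) du))

whose low-dose limit is a straight line of slope ``slope_high / xi0`` and
whose pre-saturation high-dose slope is ``slope_high``; the ratio of the two
regimes therefore estimates ``xi0`` directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit

__all__ = [
    "BindingModelParams",
    "DoseBindingCurve",
    "BindingFit",
    "ChainGeometry",
    "CooperativityResult",
    "available_site_fraction",
    "mean_binding_curve",
    "simulate_binding_curve",
    "normalize_curve",
    "initial_slope",
    "fit_condensation_model",
    "cooperativity_index",
    "estimate_chain_length",
]


@dataclass(frozen=True)
class BindingModelParams:
    """Parameters of the condensation-gated binding model.

    Attributes
    ----------
    xi0
        Initial line charge density of the glycan chains before any particle
        binds.  ``xi0 <= 1`` means no condensation: all sites available.
    c_star
        Critical particle concentration [particles/mL] at which condensed
        counterions are released.
    b_max
        Saturation binding signal (100 for normalized curves).
    slope_high
        Intrinsic binding increment in the uncondensed regime
        [signal per (particles/mL)].
    transition_width
        Width of the condensation-release transition in decades of
        concentration.
    """

    xi0: float
    c_star: float
    b_max: float = 100.0
    slope_high: float = 1.0e-10
    transition_width: float = 0.15

    def __post_init__(self) -> None:
        for name in ("xi0", "c_star", "b_max", "slope_high",
                     "transition_width"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class DoseBindingCurve:
    """Dose-binding readout: particle concentration vs binding signal.

    ``signal`` is the per-dose mean; ``replicates`` (optional) is an
    (n_doses, n_replicates) array of individual replicate signals.
    """

    concentrations: np.ndarray
    signal: np.ndarray
    replicates: np.ndarray | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.concentrations.ndim != 1:
            raise ValueError("concentrations must be 1-D")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.signal.shape != self.concentrations.shape:
            raise ValueError("signal must have one value per concentration")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates, dtype=float)
            if self.replicates.shape[0] != self.concentrations.size:
                raise ValueError("replicates must have one row per dose")


@dataclass
class BindingFit:
    """Result of fitting the condensation binding model."""

    params: BindingModelParams
    uncertainties: dict[str, float]
    residual_norm: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class ChainGeometry:
    """Geometry linking the critical concentration to a glycan chain length.

    All parameters must be supplied explicitly except ``charges_per_nm``
    (default 4, the charge density of fully sulfated heparan sulphate).
    """

    charges_per_particle: float
    cells_per_ml: float
    chains_per_cell: float
    charges_per_nm: float = 4.0

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            if not getattr(self, f_.name) > 0:
                raise ValueError(f"{f_.name} must be > 0")


@dataclass(frozen=True)
class CooperativityResult:
    """Slope-ratio cooperativity readout of a dose-binding curve."""

    ratio: float
    cooperative: bool
    low_slope: float
    high_slope: float


def _xi_eff(c: np.ndarray, params: BindingModelParams) -> np.ndarray:
    """Effective line charge density at particle concentration c."""
    c = np.asarray(c, dtype=float)
    if params.xi0 <= 1.0:
        return np.ones_like(c)
    with np.errstate(divide="ignore"):
        logc = np.log10(np.where(c > 0, c, np.finfo(float).tiny))
    s = expit((logc - np.log10(params.c_star)) / params.transition_width)
    s = np.where(c > 0, s, 0.0)
    return params.xi0 ** (1.0 - s)


def available_site_fraction(c, params: BindingModelParams):
    """Fraction of binding sites available at particle concentration ``c``.

    Returns ``1/xi_eff(c)``: ``1/xi0`` far below ``c*``, 1 far above, with a
    geometric interpolation through ``sqrt(xi0)`` at ``c = c*``.  Identically
    1 when ``xi0 <= 1`` (no condensation).
    """
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentration must be non-negative")
    out = 1.0 / _xi_eff(arr, params)
    return float(out) if np.isscalar(c) or arr.ndim == 0 else out


def mean_binding_curve(concentrations, params: BindingModelParams,
                       grid_per_decade: int = 400) -> np.ndarray:
    """Noiseless mean binding signal at the given doses.

    Evaluates B(c) = b_max (1 - exp(-I(c)/b_max)) with
    I(c) = slope_high * integral_0^c f(u) du via trapezoidal quadrature on a
    log-spaced grid that includes the dose points exactly.
    """
    c = np.atleast_1d(np.asarray(concentrations, dtype=float))
    if c.size == 0:
        raise ValueError("empty dose list")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    cmax = c.max()
    if cmax == 0:
        return np.zeros_like(c)
    # grid from far below the transition up to cmax, plus the doses themselves
    lo = min(c[c > 0].min(), params.c_star) / 1e3
    n = max(int(grid_per_decade * np.log10(cmax / lo)), 50)
    grid = np.unique(np.concatenate([
        [0.0], np.logspace(np.log10(lo), np.log10(cmax), n), c]))
    f = 1.0 / _xi_eff(grid, params)
    f[grid == 0] = 1.0 / max(params.xi0, 1.0)
    integral = np.concatenate([[0.0], np.cumsum(
        0.5 * (f[1:] + f[:-1]) * np.diff(grid))])
    i_at_c = np.interp(c, grid, integral) * params.slope_high
    b = params.b_max * (1.0 - np.exp(-i_at_c / params.b_max))
    return b if np.asarray(concentrations).ndim else float(b[0])


def simulate_binding_curve(params: BindingModelParams, concentrations,
                           noise_cv: float = 0.0, n_replicates: int = 1,
                           seed: int | None = None,
                           condition: str = "custom") -> DoseBindingCurve:
    """Simulate a dose-binding curve with multiplicative log-normal noise.

    Replicate signals are the model mean perturbed by log-normal noise with
    coefficient of variation ``noise_cv`` (mean-preserving); the returned
    ``signal`` is the replicate mean.  Deterministic for a fixed ``seed``.
    """
    c = np.asarray(concentrations, dtype=float)
    if c.size == 0:
        raise ValueError("empty dose list")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    mean = mean_binding_curve(c, params)
    if noise_cv == 0 or n_replicates == 0:
        reps = np.tile(mean[:, None], (1, max(n_replicates, 1)))
    else:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        z = rng.standard_normal((c.size, n_replicates))
        reps = mean[:, None] * np.exp(sigma * z - 0.5 * sigma**2)
    return DoseBindingCurve(concentrations=c, signal=reps.mean(axis=1),
                            replicates=reps, condition=condition)


def normalize_curve(curve: DoseBindingCurve) -> DoseBindingCurve:
    """Rescale so the maximum mean signal is exactly 100.  Idempotent."""
    peak = np.max(curve.signal)
    if not peak > 0:
        raise ValueError("cannot normalize: no positive signal")
    scale = 100.0 / peak
    signal = curve.signal * scale
    signal[np.argmax(signal)] = 100.0  # exact despite float rounding
    return DoseBindingCurve(
        concentrations=curve.concentrations.copy(),
        signal=signal,
        replicates=None if curve.replicates is None
        else curve.replicates * scale,
        condition=curve.condition,
    )


def initial_slope(curve: DoseBindingCurve, c_star: float | None = None,
                  n_lowest: int = 3) -> tuple[float, float]:
    """Low-dose binding increment: zero-intercept OLS slope and its SE.

    The window is all doses ``<= c_star/2`` when ``c_star`` is given,
    otherwise the ``n_lowest`` lowest doses.  The intercept is pinned at 0
    (unbound controls define zero background).
    """
    c = curve.concentrations
    y = curve.signal
    if c_star is not None:
        mask = c <= c_star / 2.0
        if mask.sum() < 3:
            mask = np.zeros_like(c, dtype=bool)
            mask[:3] = True
    else:
        mask = np.zeros_like(c, dtype=bool)
        mask[:n_lowest] = True
    if mask.sum() < 3:
        raise ValueError("need >= 3 doses in the low-dose window")
    x, yy = c[mask], y[mask]
    sxx = np.sum(x * x)
    slope = np.sum(x * yy) / sxx
    resid = yy - slope * x
    dof = max(x.size - 1, 1)
    se = np.sqrt(np.sum(resid**2) / dof / sxx)
    return float(slope), float(se)


_PARAM_NAMES = ("xi0", "c_star", "b_max", "slope_high")


def _pack(p: BindingModelParams) -> np.ndarray:
    return np.array([np.log(p.xi0), np.log10(p.c_star),
                     np.log(p.b_max), np.log(p.slope_high)])


def _unpack(theta: np.ndarray, width: float) -> BindingModelParams:
    return BindingModelParams(
        xi0=float(np.exp(theta[0])), c_star=float(10.0 ** theta[1]),
        b_max=float(np.exp(theta[2])), slope_high=float(np.exp(theta[3])),
        transition_width=width)


def fit_condensation_model(curve: DoseBindingCurve,
                           init: BindingModelParams | None = None,
                           transition_width: float = 0.15,
                           n_starts: int = 5) -> BindingFit:
    """Fit (xi0, c*, b_max, slope_high) to a dose-binding curve.

    Nonlinear least squares of the ``mean_binding_curve`` model on
    log-signal residuals, in log-parameter space, with a deterministic
    multi-start schedule to avoid local minima.  Binding readouts carry
    multiplicative (detector-gain-like) noise, so log residuals are the
    homoscedastic — i.e. correctly inverse-variance-weighted — error
    model; it also keeps the information-rich low-dose points from being
    swamped by the large-signal doses.

    A fit is flagged unconverged when the optimizer fails or the estimate
    sits on a parameter bound (e.g. single-regime curves where ``c*`` is
    unidentifiable).
    """
    c = curve.concentrations
    y = curve.signal
    if c.size < 5:
        raise ValueError("need >= 5 doses to fit the binding model")
    if c.max() <= 5 * c.min():
        raise ValueError("dose range too narrow: curve must span both "
                         "regimes (max dose > 5x min dose)")

    ymax = max(y.max(), 1e-9)
    lo_slope, _ = initial_slope(curve)
    lo_slope = max(lo_slope, ymax / c.max() * 1e-3)
    y_floor = 1e-9 * ymax

    def residuals(theta):
        p = _unpack(theta, transition_width)
        m = mean_binding_curve(c, p)
        return np.log(np.maximum(m, y_floor)) - np.log(np.maximum(y, y_floor))

    bounds = (
        np.array([np.log(0.2), np.log10(c.min() / 3.0),
                  np.log(0.3 * ymax), np.log(lo_slope * 1e-2)]),
        np.array([np.log(60.0), np.log10(c.max() * 3.0),
                  np.log(5.0 * ymax), np.log(lo_slope * 1e3)]),
    )

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(_pack(init))
    geo_mid = np.sqrt(c.min() * c.max())
    for xi0_0, cs_0 in ((2.0, geo_mid), (4.0, geo_mid), (1.2, geo_mid),
                        (8.0, np.sqrt(geo_mid * c.max())),
                        (2.0, np.sqrt(geo_mid * c.min()))):
        starts.append(_pack(BindingModelParams(
            xi0=xi0_0, c_star=cs_0, b_max=1.1 * ymax,
            slope_high=lo_slope * xi0_0, transition_width=transition_width)))
    starts = starts[:max(n_starts, 1 if init is None else 2)]

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, bounds[0] + 1e-9, bounds[1] - 1e-9)
        try:
            sol = optimize.least_squares(residuals, theta0, bounds=bounds,
                                         x_scale="jac", method="trf")
        except Exception:  # numerical failure on this start only
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        p0 = init or _unpack(starts[0], transition_width)
        return BindingFit(params=p0, uncertainties={}, residual_norm=np.inf,
                          converged=False, message="all starts failed")

    params = _unpack(best.x, transition_width)
    at_bound = bool(np.any(best.x <= bounds[0] + 1e-6) or
                    np.any(best.x >= bounds[1] - 1e-6))
    converged = bool(best.success) and not at_bound

    # SEs in natural units via the delta method from the log-space Jacobian
    uncertainties: dict[str, float] = {}
    try:
        jtj = best.jac.T @ best.jac
        dof = max(c.size - best.x.size, 1)
        s2 = 2.0 * best.cost / dof
        cov = s2 * np.linalg.pinv(jtj)
        sd_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
        vals = [params.xi0, params.c_star, params.b_max, params.slope_high]
        scale = [1.0, np.log(10.0), 1.0, 1.0]
        for name, v, sl, sc in zip(_PARAM_NAMES, vals, sd_log, scale):
            uncertainties[name] = float(v * sl * sc)
    except Exception:
        pass

    return BindingFit(params=params, uncertainties=uncertainties,
                      residual_norm=float(np.sqrt(2.0 * best.cost)),
                      converged=converged,
                      message="ok" if converged else
                      ("at parameter bound" if at_bound else best.message))


def cooperativity_index(curve: DoseBindingCurve,
                        threshold: float = 1.5) -> CooperativityResult:
    """Ratio of the steepest dose-to-dose slope to the low-dose slope.

    The high-regime slope is the maximum raw incremental slope
    dB/dc between consecutive doses; the low-regime slope is the
    zero-intercept OLS slope through the lowest three doses.  In the
    sharp-transition, pre-saturation limit of the condensation model the
    ratio estimates ``xi0`` (slope_high / (slope_high/xi0)); a linear
    non-cooperative curve gives a ratio near 1.  Site depletion near
    saturation attenuates the incremental slopes, so on strongly
    saturating curves the index *underestimates* xi0 — it never inflates.
    A ratio above ``threshold`` classifies the curve cooperative.
    """
    c = curve.concentrations
    y = curve.signal
    if c.size < 6:
        raise ValueError("need >= 6 doses for a cooperativity index")
    if y[-1] - y[0] < 0.05 * max(y.max(), 1e-12):
        raise ValueError("curve is saturated (or flat) across the whole "
                         "grid: regimes unidentifiable")
    inc = np.diff(y) / np.diff(c)
    low, _ = initial_slope(curve)
    if low <= 0:
        raise ValueError("non-positive low-dose slope")
    high = float(np.max(inc))
    ratio = high / low
    return CooperativityResult(ratio=float(ratio),
                               cooperative=bool(ratio > threshold),
                               low_slope=float(low), high_slope=high)


def estimate_chain_length(c_star: float, geometry: ChainGeometry) -> float:
    """Glycan chain length [nm] implied by the critical concentration.

    Charge bookkeeping: at ``c*`` the particles present can neutralize the
    condensed charge of the whole chain population, so

        L = c* * charges_per_particle
            / (cells_per_ml * chains_per_cell * charges_per_nm)

    Linear in ``c*`` for fixed geometry — only length *ratios* between
    conditions are meaningful without an absolute geometry calibration.
    """
    if not c_star > 0:
        raise ValueError("c_star must be > 0")
    return (c_star * geometry.charges_per_particle
            / (geometry.cells_per_ml * geometry.chains_per_cell
               * geometry.charges_per_nm))
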
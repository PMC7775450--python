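"""Hill-type vacuole-formation kinetics.

Vacuole area per cell after nanocapsule treatment follows a sigmoidal
time-course

    N_v(t) = nv_max * t^n / (k_half^n + t^n)

with half-maximum time ``k_half`` [h] and steepness exponent ``n``.  The
inverse half-time ``k_inv = 1/k_half`` is the deposition-ability metric used
to compare cell lines: faster vacuole build-up means larger ``k_inv``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "HillParams",
    "VacuoleTimeCourse",
    "HillFit",
    "hill_vacuole_model",
    "fit_vacuole_kinetics",
]


@dataclass(frozen=True)
class HillParams:
    """nv_max: plateau signal; k_half: half-maximum time [h]; n_hill: exponent."""

    nv_max: float
    k_half: float
    n_hill: float

    def __post_init__(self) -> None:
        if self.nv_max < 0:
            raise ValueError("nv_max must be >= 0")
        if not self.k_half > 0:
            raise ValueError("k_half must be > 0")
        if not self.n_hill > 0:
            raise ValueError("n_hill must be > 0")


@dataclass
class VacuoleTimeCourse:
    """Vacuole area per cell vs time since treatment [h]."""

    times: np.ndarray
    values: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class HillFit:
    """Fit of the vacuole kinetics; k_inv = 1/k_half is the deposition ability."""

    params: HillParams
    k_inv: float
    uncertainties: dict[str, float]
    converged: bool
    message: str = ""


def hill_vacuole_model(t, params: HillParams):
    """Evaluate N_v(t) = nv_max t^n / (k_half^n + t^n); zero at t = 0."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("time must be non-negative")
    tn = np.power(arr, params.n_hill)
    out = params.nv_max * tn / (params.k_half**params.n_hill + tn)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def fit_vacuole_kinetics(tc: VacuoleTimeCourse,
                         init: HillParams | None = None) -> HillFit:
    """Nonlinear least squares of the Hill model to a vacuole time-course.

    Non-convergence is a reported outcome, not an exception: flat or
    essentially-zero series (no detectable vacuole formation), optimizer
    failure, a plateau SE exceeding the plateau itself, or a half-time
    outside the observed span all return ``converged = False`` with the
    best-effort estimates retained.
    """
    t, y = tc.times, tc.values
    if t.size < 5:
        raise ValueError("need >= 5 time points")

    ymax = float(y.max()) if y.size else 0.0
    span = float(t[-1])
    if ymax <= 0 or np.ptp(y) < 1e-12 * max(abs(ymax), 1.0):
        p = HillParams(nv_max=max(ymax, 0.0), k_half=max(span, 1.0),
                       n_hill=1.0)
        return HillFit(params=p, k_inv=1.0 / p.k_half, uncertainties={},
                       converged=False, message="no vacuole signal")

    if init is None:
        above = t[y >= 0.5 * ymax]
        k0 = float(above[0]) if above.size and above[0] > 0 else span / 2.0
        init = HillParams(nv_max=ymax, k_half=k0, n_hill=2.0)

    def residuals(theta):
        p = HillParams(*np.exp(theta))
        return hill_vacuole_model(t, p) - y

    theta0 = np.log([max(init.nv_max, 1e-9), init.k_half, init.n_hill])
    lb = np.log([1e-9 * max(ymax, 1.0), max(t[t > 0].min(), 1e-6) / 10.0,
                 0.2])
    ub = np.log([10.0 * ymax, 10.0 * span, 12.0])
    theta0 = np.clip(theta0, lb + 1e-9, ub - 1e-9)
    sol = optimize.least_squares(residuals, theta0, bounds=(lb, ub),
                                 x_scale="jac", method="trf")
    params = HillParams(*np.exp(sol.x))

    uncertainties: dict[str, float] = {}
    try:
        dof = max(t.size - 3, 1)
        s2 = 2.0 * sol.cost / dof
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        sd_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for name, v, sl in zip(("nv_max", "k_half", "n_hill"),
                               (params.nv_max, params.k_half, params.n_hill),
                               sd_log):
            uncertainties[name] = float(v * sl)
        uncertainties["k_inv"] = uncertainties["k_half"] / params.k_half**2
    except Exception:
        pass

    reasonable = (bool(sol.success)
                  and uncertainties.get("nv_max", np.inf) < params.nv_max
                  and t[0] <= params.k_half <= span)
    return HillFit(params=params, k_inv=1.0 / params.k_half,
                   uncertainties=uncertainties, converged=reasonable,
                   message="ok" if reasonable else "no reasonable fit")
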
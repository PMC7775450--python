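"""Impedance decomposition for cell-substrate impedance (ECIS) traces.

After nanocapsule treatment, the normalized impedance of a confluent cell
layer is modelled as a baseline plus a decaying binding term minus the
vacuole term:

    Z(t) = z0 + z_max * exp(-t/a) - N_v(t)

``a`` [h] is the binding decay constant (its inverse ``a_inv`` is the
binding-ability metric) and ``N_v`` the Hill vacuole kinetics.  Measured
traces first *rise* for ~30 min as particles settle onto the layer and only
then decay, so the model is fitted from the post-treatment maximum onward;
the fitted components can be segregated back into a pure binding curve and a
pure vacuole curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .kinetics import HillParams, hill_vacuole_model

__all__ = [
    "EcisParams",
    "ImpedanceTrace",
    "EcisFit",
    "impedance_model",
    "normalize_impedance",
    "fit_impedance",
    "segregate_components",
]


@dataclass(frozen=True)
class EcisParams:
    """z0: baseline; z_max: binding increment; a: decay constant [h]; hill: vacuole term."""

    z0: float
    z_max: float
    a: float
    hill: HillParams

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("a must be > 0")


@dataclass
class ImpedanceTrace:
    """Normalized impedance vs time [h] relative to treatment (t = 0)."""

    times: np.ndarray
    values: np.ndarray
    frequency_hz: float | None = None
    condition: str = ""
    normalization_reference: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class EcisFit:
    """Joint fit of the impedance model.

    ``a_inv`` is the binding ability, ``k_inv`` the deposition ability from
    the nested vacuole term; ``hill_identified`` is False when the data carry
    no resolvable vacuole component.
    """

    params: EcisParams
    a_inv: float
    k_inv: float
    uncertainties: dict[str, float]
    converged: bool
    hill_identified: bool = True
    message: str = ""


def impedance_model(t, params: EcisParams):
    """Evaluate Z(t) = z0 + z_max exp(-t/a) - N_v(t) for t >= 0."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("time must be non-negative")
    out = (params.z0 + params.z_max * np.exp(-arr / params.a)
           - hill_vacuole_model(arr, params.hill))
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def normalize_impedance(times_h, values_ohm, treatment_time_h: float,
                        baseline_window_h: float = 2.0,
                        frequency_hz: float | None = None,
                        condition: str = "") -> ImpedanceTrace:
    """Normalize a raw impedance series to its pre-treatment baseline.

    Values are divided by the mean raw impedance over the
    ``baseline_window_h`` hours preceding ``treatment_time_h``, and time is
    re-referenced so that treatment occurs at t = 0.  Scale-invariant: any
    overall gain on the raw trace cancels.
    """
    t = np.asarray(times_h, dtype=float)
    z = np.asarray(values_ohm, dtype=float)
    mask = (t >= treatment_time_h - baseline_window_h) & (t < treatment_time_h)
    if mask.sum() < 2:
        raise ValueError("raw series does not cover the baseline window "
                         f"[{treatment_time_h - baseline_window_h}, "
                         f"{treatment_time_h}) h")
    ref = float(z[mask].mean())
    if not ref > 0:
        raise ValueError("non-positive baseline impedance")
    return ImpedanceTrace(times=t - treatment_time_h, values=z / ref,
                          frequency_hz=frequency_hz, condition=condition,
                          normalization_reference=ref)


def fit_impedance(trace: ImpedanceTrace,
                  fit_window: tuple[float, float] | None = None,
                  init: EcisParams | None = None,
                  n_hill_fixed: float | None = 2.0) -> EcisFit:
    """Joint nonlinear least squares of the impedance model.

    By default the window runs from the post-treatment maximum (the
    binding peak) to the end of the trace; the model keeps its original time
    origin at treatment, so parameters retain their meaning.  Pre-treatment
    samples (t < 0), where the model reduces to the constant z0, are
    included in the residuals: they anchor the baseline and break the
    degeneracy between z0 and the vacuole plateau.

    Five parameters (z0, z_max, a, nv_max, k_half) are free, with a
    deterministic multi-start over the decay constant; the Hill exponent is
    held at ``n_hill_fixed`` (default 2) because the decaying binding term
    and a free-exponent sigmoid are nearly collinear over a single trace —
    freeing it (``n_hill_fixed=None``) roughly triples the decay-constant
    uncertainty.

    ``converged`` is False on optimizer failure or a non-positive fitted
    z_max (uninterpretable trace); ``hill_identified`` is False when the
    fitted vacuole plateau is negligible or dominated by its own SE.
    """
    t, z = trace.times, trace.values
    post = t >= 0
    if post.sum() < 8:
        raise ValueError("need >= 8 post-treatment points")
    tp, zp = t[post], z[post]
    if fit_window is None:
        i_peak = int(np.argmax(zp))
        fit_window = (float(tp[i_peak]), float(tp[-1]))
    w0, w1 = fit_window
    sel = (tp >= w0) & (tp <= w1)
    if sel.sum() < 8:
        raise ValueError("fit window contains < 8 points")
    tf, zf = tp[sel], zp[sel]
    tb, zb = t[t < 0], z[t < 0]  # baseline anchor: model == z0 there

    z0_guess = float(zb.mean()) if tb.size else float(zf[-1])
    zmax_guess = max(float(zf.max() - z0_guess), 1e-3)
    span = float(tf[-1] - tf[0]) if tf[-1] > tf[0] else 1.0
    nv_guess = max(float(z0_guess - zf[-1]), 1e-3)

    free_n = n_hill_fixed is None

    def unpack(theta) -> EcisParams:
        ln = theta[5] if free_n else np.log(n_hill_fixed)
        return EcisParams(z0=float(theta[0]), z_max=float(np.exp(theta[1])),
                          a=float(np.exp(theta[2])),
                          hill=HillParams(float(np.exp(theta[3])),
                                          float(np.exp(theta[4])),
                                          float(np.exp(ln))))

    def residuals(theta):
        p = unpack(theta)
        res = impedance_model(tf, p) - zf
        if tb.size:
            res = np.concatenate([theta[0] - zb, res])
        return res

    lb = np.array([z0_guess - 2.0, np.log(1e-4), np.log(span / 100.0),
                   np.log(1e-6), np.log(max(tf[0], 1e-3) / 3.0), np.log(0.2)])
    ub = np.array([z0_guess + 2.0, np.log(10.0 * zmax_guess + 1.0),
                   np.log(50.0 * span), np.log(5.0 * (abs(nv_guess) + 1.0)),
                   np.log(10.0 * span), np.log(12.0)])
    if not free_n:
        lb, ub = lb[:5], ub[:5]

    def make_theta(z0, zmax, a, nv, k, n):
        th = [z0, np.log(zmax), np.log(a), np.log(nv), np.log(k), np.log(n)]
        return np.array(th if free_n else th[:5])

    if init is not None:
        starts = [make_theta(init.z0, max(init.z_max, 1e-4), init.a,
                             max(init.hill.nv_max, 1e-6), init.hill.k_half,
                             init.hill.n_hill)]
    else:
        starts = [make_theta(z0_guess, zmax_guess, a0, nv_guess,
                             span / 2.0, 2.0)
                  for a0 in (span / 10.0, span / 3.0, span)]

    best = None
    for th in starts:
        th = np.clip(th, lb + 1e-9, ub - 1e-9)
        try:
            sol = optimize.least_squares(residuals, th, bounds=(lb, ub),
                                         x_scale="jac", method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        raise RuntimeError("impedance fit failed on all starts")

    params = unpack(best.x)

    uncertainties: dict[str, float] = {}
    try:
        dof = max(tf.size + tb.size - best.x.size, 1)
        s2 = 2.0 * best.cost / dof
        cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
        names = ["z0", "z_max", "a", "nv_max", "k_half"]
        vals = [1.0, params.z_max, params.a, params.hill.nv_max,
                params.hill.k_half]
        if free_n:
            names.append("n_hill")
            vals.append(params.hill.n_hill)
        for name, v, s in zip(names, vals, sd):
            uncertainties[name] = float(v * s) if name != "z0" else float(s)
    except Exception:
        pass

    converged = bool(best.success) and params.z_max > 1e-3
    resid_sd = float(np.std(residuals(best.x)))
    hill_identified = (params.hill.nv_max > max(3.0 * resid_sd, 1e-3)
                       and uncertainties.get("nv_max", np.inf)
                       < params.hill.nv_max)
    return EcisFit(params=params, a_inv=1.0 / params.a,
                   k_inv=1.0 / params.hill.k_half,
                   uncertainties=uncertainties, converged=converged,
                   hill_identified=hill_identified,
                   message="ok" if converged else "no reasonable fit")


def segregate_components(fit: EcisFit, times) -> tuple[np.ndarray, np.ndarray]:
    """Split a converged fit into its binding and vacuole component curves.

    Returns ``(z_max exp(-t/a), N_v(t))``; by construction
    ``z0 + binding - vacuole`` reproduces the model prediction at every t.
    """
    if not fit.converged:
        raise ValueError("cannot segregate an unconverged fit")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    binding = fit.params.z_max * np.exp(-t / fit.params.a)
    vacuole = hill_vacuole_model(t, fit.params.hill)
    return binding, vacuole
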
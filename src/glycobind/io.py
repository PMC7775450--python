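"""Readers/writers for the project's CSV/TIFF/JSON formats and the pipeline.

Tabular formats (header required, locale-independent decimal points,
scientific notation accepted):

* dose-binding: ``concentration_particles_per_ml, signal, replicate, condition``
* time-series:  ``time_h, value, replicate, condition``
* raw ECIS:     ``time_h, impedance_ohm, well, frequency_hz, condition``

Reports are JSON: stage name, parameter -> (estimate, SE) map, convergence
flag and provenance (input path, config hash, seed, package version), with a
write -> read round trip guaranteed equal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .binding import DoseBindingCurve, fit_condensation_model, normalize_curve
from .ecis import fit_impedance, normalize_impedance
from .imaging import ImageStack
from .kinetics import VacuoleTimeCourse, fit_vacuole_kinetics
from .synthetic import (GeneratorConfig, gen_binding_dataset,
                        gen_impedance_trace, gen_vacuole_timecourse)

__all__ = [
    "SchemaError",
    "AnalysisReport",
    "read_table",
    "write_dose_binding",
    "write_timeseries",
    "write_ecis_raw",
    "read_stack",
    "write_stack",
    "run_pipeline",
]

logger = logging.getLogger("glycobind")

_SCHEMAS = {
    "dose_binding": ["concentration_particles_per_ml", "signal"],
    "timeseries": ["time_h", "value"],
    "ecis_raw": ["time_h", "impedance_ohm"],
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _load_frame(path, schema: str) -> pd.DataFrame:
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; "
                          f"known: {sorted(_SCHEMAS)}")
    df = pd.read_csv(path)
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in _SCHEMAS[schema]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row {int(bad[0]) + 2} (1-based, incl. header)")
        if coerced.isna().any():
            raise SchemaError(f"{path}: empty cell in column {col!r}")
        df[col] = coerced
    return df


def read_table(path, schema: str, strict: bool = False):
    """Read and validate a CSV table, returning the typed carrier.

    ``dose_binding`` -> :class:`DoseBindingCurve` (replicates pivoted wide),
    ``timeseries`` -> :class:`VacuoleTimeCourse` (replicate means),
    ``ecis_raw`` -> the validated :class:`pandas.DataFrame`.

    Axes that must be increasing are sorted with a warning, or rejected
    when ``strict`` is True.
    """
    df = _load_frame(path, schema)
    axis = _SCHEMAS[schema][0]

    def ensure_sorted(frame: pd.DataFrame) -> pd.DataFrame:
        if not frame[axis].is_monotonic_increasing:
            if strict:
                raise SchemaError(f"{path}: column {axis!r} is not "
                                  "increasing (strict mode)")
            warnings.warn(f"{path}: sorting by {axis!r}", stacklevel=3)
            frame = frame.sort_values(axis, kind="stable")
        return frame

    if schema == "dose_binding":
        cond = str(df["condition"].iloc[0]) if "condition" in df else ""
        if "replicate" in df.columns and df["replicate"].nunique() > 1:
            wide = df.pivot_table(index=axis, columns="replicate",
                                  values="signal")
            wide = wide.sort_index()
            reps = wide.to_numpy()
            return DoseBindingCurve(concentrations=wide.index.to_numpy(),
                                    signal=np.nanmean(reps, axis=1),
                                    replicates=reps, condition=cond)
        df = ensure_sorted(df)
        return DoseBindingCurve(concentrations=df[axis].to_numpy(),
                                signal=df["signal"].to_numpy(),
                                condition=cond)
    if schema == "timeseries":
        cond = str(df["condition"].iloc[0]) if "condition" in df else ""
        grouped = df.groupby(axis, sort=True)["value"].mean().reset_index()
        return VacuoleTimeCourse(times=grouped[axis].to_numpy(),
                                 values=grouped["value"].to_numpy(),
                                 condition=cond)
    return ensure_sorted(df).reset_index(drop=True)


def _fmt_conc(x: float) -> str:
    return f"{x:.6e}"


def write_dose_binding(curve: DoseBindingCurve, path) -> None:
    """Write a dose-binding curve in long form (one row per replicate)."""
    rows = []
    reps = curve.replicates
    if reps is None:
        reps = curve.signal[:, None]
    for c, row in zip(curve.concentrations, reps):
        for j, v in enumerate(row, start=1):
            rows.append((_fmt_conc(c), repr(float(v)), j, curve.condition))
    pd.DataFrame(rows, columns=["concentration_particles_per_ml", "signal",
                                "replicate", "condition"]
                 ).to_csv(path, index=False)


def write_timeseries(tc: VacuoleTimeCourse, path, replicate: int = 1) -> None:
    pd.DataFrame({"time_h": tc.times, "value": tc.values,
                  "replicate": replicate, "condition": tc.condition}
                 ).to_csv(path, index=False)


def write_ecis_raw(times_h, ohm, path, well: str = "A1",
                   frequency_hz: float = 4000.0, condition: str = "") -> None:
    pd.DataFrame({"time_h": np.asarray(times_h),
                  "impedance_ohm": np.asarray(ohm), "well": well,
                  "frequency_hz": frequency_hz, "condition": condition}
                 ).to_csv(path, index=False)


def read_stack(path, pixel_size_um: float, frame_interval_min: float,
               channel: str = "fluorescence") -> ImageStack:
    """Load a single- or multi-page TIFF as an :class:`ImageStack`."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return ImageStack(frames=arr, pixel_size_um=pixel_size_um,
                      frame_interval_min=frame_interval_min, channel=channel)


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(path, stack.frames, photometric="minisblack")


@dataclass
class AnalysisReport:
    """Serializable record of one pipeline stage."""

    stage: str
    parameters: dict[str, tuple[float, float]]
    converged: bool
    provenance: dict[str, object] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": 1,
            "stage": self.stage,
            "parameters": {k: [float(v[0]), float(v[1])]
                           for k, v in self.parameters.items()},
            "converged": bool(self.converged),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "AnalysisReport":
        text = Path(source).read_text() if isinstance(source, (str, Path)) \
            and "\n" not in str(source) and Path(str(source)).exists() \
            else str(source)
        d = json.loads(text)
        return cls(stage=d["stage"],
                   parameters={k: (v[0], v[1])
                               for k, v in d["parameters"].items()},
                   converged=d["converged"],
                   provenance=d.get("provenance", {}))


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _provenance(cfg: dict, seed: int, source: str = "synthetic") -> dict:
    return {"input": source, "config_hash": _config_hash(cfg),
            "seed": int(seed), "version": __version__}


def run_pipeline(config: dict, seed: int | None = None
                 ) -> list[AnalysisReport]:
    """Run simulate -> fit -> report chains described by a config mapping.

    ``config['stages']`` is a list of stage dicts, each with a ``stage`` key
    in {binding, vacuole, ecis} plus scenario/noise options.  Non-convergence
    is a reported result, not an error; unknown stages raise.
    """
    stages = config.get("stages")
    if not stages:
        raise ValueError("config must define a non-empty 'stages' list")
    base_seed = int(config.get("seed", 0) if seed is None else seed)
    reports: list[AnalysisReport] = []
    for i, st in enumerate(stages):
        kind = st.get("stage")
        st_seed = int(st.get("seed", base_seed + i))
        cfg = GeneratorConfig(scenario=st.get("scenario", "custom"),
                              noise=float(st.get("noise", 0.05)),
                              n_replicates=int(st.get("n_replicates", 4)),
                              seed=st_seed, options=st.get("options", {}))
        if kind == "binding":
            curve = normalize_curve(gen_binding_dataset(cfg))
            fit = fit_condensation_model(curve)
            params = {"xi0": (fit.params.xi0,
                              fit.uncertainties.get("xi0", float("nan"))),
                      "c_star": (fit.params.c_star,
                                 fit.uncertainties.get("c_star",
                                                       float("nan"))),
                      "b_max": (fit.params.b_max,
                                fit.uncertainties.get("b_max", float("nan"))),
                      "slope_high": (fit.params.slope_high,
                                     fit.uncertainties.get("slope_high",
                                                           float("nan")))}
            converged = fit.converged
        elif kind == "vacuole":
            tcs = gen_vacuole_timecourse(cfg)
            fit = fit_vacuole_kinetics(tcs[0])
            params = {"nv_max": (fit.params.nv_max,
                                 fit.uncertainties.get("nv_max",
                                                       float("nan"))),
                      "k_half": (fit.params.k_half,
                                 fit.uncertainties.get("k_half",
                                                       float("nan"))),
                      "n_hill": (fit.params.n_hill,
                                 fit.uncertainties.get("n_hill",
                                                       float("nan"))),
                      "k_inv": (fit.k_inv,
                                fit.uncertainties.get("k_inv", float("nan")))}
            converged = fit.converged
        elif kind == "ecis":
            t, ohm = gen_impedance_trace(cfg)
            t_treat = cfg.options.get("treatment_time_h", 2.0)
            trace = normalize_impedance(t, ohm, treatment_time_h=t_treat)
            fit = fit_impedance(trace)
            params = {"a": (fit.params.a,
                            fit.uncertainties.get("a", float("nan"))),
                      "a_inv": (fit.a_inv, float("nan")),
                      "k_half": (fit.params.hill.k_half,
                                 fit.uncertainties.get("k_half",
                                                       float("nan"))),
                      "k_inv": (fit.k_inv, float("nan")),
                      "z_max": (fit.params.z_max,
                                fit.uncertainties.get("z_max", float("nan")))}
            converged = fit.converged
        else:
            raise ValueError(f"unknown pipeline stage {kind!r}")
        report = AnalysisReport(stage=kind, parameters=params,
                                converged=converged,
                                provenance=_provenance(st, st_seed))
        logger.info("stage=%s seed=%d hash=%s converged=%s", kind, st_seed,
                    report.provenance["config_hash"], converged)
        reports.append(report)
    return reports
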
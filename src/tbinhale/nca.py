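"""Non-compartmental analysis and the prediction-error validation gate.

``nca`` extracts Cmax/Tmax from the grid maximum, AUC0-t by the linear
trapezoid rule, and the terminal slope (lambda_z) by log-linear regression
over a fixed terminal window (the last 5 positive-concentration points after
Tmax; deterministic by design, with the regression R² reported and a warning
attached below 0.99).  AUC0-inf = AUC0-t + C(t_last)/lambda_z.

``prediction_error`` and ``validate_model`` implement the percentage
prediction error, %PE = 100*|sim - obs|/obs, and the ±20% model-acceptance
gate applied to simulated vs observed PK metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


class NCAInputError(ValueError):
    """Concentration-time input unusable for NCA."""


@dataclass(frozen=True)
class NCAResult:
    cmax: float
    tmax: float
    auc_0_t: float
    auc_0_inf: float | None
    lambda_z: float | None
    extrapolated_fraction: float | None
    r_squared: float | None
    n_terminal: int

    @property
    def auc_available(self) -> bool:
        return self.auc_0_inf is not None


def nca(times_h, conc, t_last: float | None = None, n_terminal: int = 5,
        r2_warn: float = 0.99) -> NCAResult:
    """Non-compartmental metrics for one concentration-time series."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or t.size < 3:
        raise NCAInputError("need matching 1-D arrays with at least 3 points")
    if np.any(np.diff(t) <= 0):
        raise NCAInputError("times must be strictly increasing")
    if np.any(c < 0):
        raise NCAInputError("concentrations must be non-negative")
    if not np.any(c > 0):
        raise NCAInputError("no positive concentrations")

    if t_last is not None:
        keep = t <= t_last + 1e-12
        if keep.sum() < 3:
            raise NCAInputError("fewer than 3 points at or before t_last")
        t, c = t[keep], c[keep]

    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_t = float(np.trapezoid(c, t))
    if auc_t <= 0:
        raise NCAInputError("AUC0-t is not positive")

    term = np.flatnonzero((t > tmax) & (c > 0))
    if term.size >= 3:
        sel = term[-min(n_terminal, term.size):]
        fit = stats.linregress(t[sel], np.log(c[sel]))
        lz = -float(fit.slope)
        r2 = float(fit.rvalue ** 2)
        if lz <= 0:
            lz, r2 = None, None
        elif r2 < r2_warn:
            warnings.warn(
                f"terminal log-linear fit R²={r2:.4f} below {r2_warn}", stacklevel=2
            )
    else:
        lz, r2 = None, None

    if lz is not None:
        tail = float(c[-1]) / lz
        auc_inf = auc_t + tail
        extrap = tail / auc_inf
    else:
        auc_inf, extrap = None, None
    return NCAResult(
        cmax=cmax, tmax=tmax, auc_0_t=auc_t, auc_0_inf=auc_inf,
        lambda_z=lz, extrapolated_fraction=extrap, r_squared=r2,
        n_terminal=int(term.size if term.size < n_terminal else n_terminal),
    )


def prediction_error(observed: float, simulated: float) -> float:
    """Percentage prediction error, 100*|simulated - observed|/observed."""
    if observed <= 0:
        raise NCAInputError("observed value must be > 0")
    return 100.0 * abs(simulated - observed) / observed


@dataclass(frozen=True)
class ValidationReport:
    table: pd.DataFrame  # columns: api, metric, observed, simulated, pe_percent
    threshold_percent: float

    @property
    def max_pe_percent(self) -> float:
        return float(self.table["pe_percent"].max())

    @property
    def overall_pass(self) -> bool:
        return bool((self.table["pe_percent"] <= self.threshold_percent).all())

    def to_text(self) -> str:
        lines = [
            f"Model validation gate: ±{self.threshold_percent:g}% prediction error",
            self.table.to_string(index=False, float_format=lambda x: f"{x:.3f}"),
            f"max %PE = {self.max_pe_percent:.2f}  ->  "
            + ("PASS" if self.overall_pass else "FAIL"),
        ]
        return "\n".join(lines)


def validate_model(
    observed: Mapping[str, Mapping[str, float]],
    simulated: Mapping[str, Mapping[str, float]],
    threshold_percent: float = 20.0,
) -> ValidationReport:
    """Per-metric %PE of simulated vs observed values, with an overall gate.

    Both inputs are nested mappings ``{api: {metric: value}}``; every
    observed metric must be present in the simulated table.
    """
    rows = []
    for api, metrics in observed.items():
        if api not in simulated:
            raise NCAInputError(f"simulated table missing API {api!r}")
        for metric, obs in metrics.items():
            if metric not in simulated[api]:
                raise NCAInputError(f"simulated table missing {api}/{metric}")
            sim = simulated[api][metric]
            rows.append({
                "api": api, "metric": metric, "observed": obs,
                "simulated": sim, "pe_percent": prediction_error(obs, sim),
            })
    return ValidationReport(table=pd.DataFrame(rows), threshold_percent=threshold_percent)
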
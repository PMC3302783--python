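"""Transport-kinetics fitting: initial rates and saturation curves.

Uptake time courses (accumulated substrate vs time) yield an initial rate
as the ordinary-least-squares slope over the longest initial stretch that
is still linear (R² ≥ 0.98).  Concentration–response data are fitted by
nonlinear least squares to the Hill equation

    I = Imax · [S]^n / ([S]^n + K0.5^n)

with the Michaelis–Menten case being n fixed at 1.  The *unnormalised*
response is fitted with Imax free — normalising by an observed maximum and
then fitting the normalised curve would make the fit circular.  Multi-start
initialisation guards against local minima; parameter uncertainties are
asymptotic (Jacobian-based) standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError

__all__ = [
    "TimeCourse",
    "SaturationDataset",
    "SaturationFit",
    "InitialRate",
    "initial_rate",
    "fit_saturation",
    "predict_response",
    "read_timecourse_csv",
    "read_saturation_csv",
]

LINEAR_R2 = 0.98  # "linear portion" acceptance threshold for initial rates


@dataclass
class TimeCourse:
    """An uptake time course: accumulated substrate vs time (minutes)."""

    times: np.ndarray
    signals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.shape != self.signals.shape or self.times.ndim != 1:
            raise DataError("times and signals must be matching 1-D arrays")
        if self.times.size < 3:
            raise DataError("a time course needs ≥ 3 points")
        if not np.all(np.diff(self.times) > 0):
            raise DataError("times must be strictly increasing")


@dataclass
class SaturationDataset:
    """Concentration–response data for a saturation fit."""

    concentrations: np.ndarray
    responses: np.ndarray
    concentration_unit: str = "mM"
    response_unit: str = ""
    fixed_hill: float | None = None
    truth: dict | None = None  # attached by synthetic generators

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape or self.concentrations.ndim != 1:
            raise DataError("concentrations and responses must be matching 1-D arrays")
        if np.any(self.concentrations < 0):
            raise DataError("concentrations must be ≥ 0")
        if not np.all(np.diff(self.concentrations) > 0):
            raise DataError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class SaturationFit:
    """Fitted (K0.5, Hill n, Imax) with asymptotic standard errors."""

    k05: float
    k05_error: float
    n_hill: float
    n_hill_error: float
    imax: float
    imax_error: float
    model: str  # "MM" | "Hill"
    converged: bool
    ssr: float = float("nan")


class InitialRate(NamedTuple):
    rate: float  # signal/min
    error: float  # OLS standard error of the slope
    n_points_used: int
    linear_portion_found: bool


def _linear_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope, slope SE and R²; a perfect (zero-residual) fit counts as R²=1."""
    n = t.size
    X = np.column_stack([t, np.ones(n)])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    scale = max(ss_tot, float(np.sum(y**2)), 1.0)
    if ss_tot <= 1e-12 * scale:
        r2 = 1.0 if ss_res <= 1e-12 * scale else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    if n > 2:
        s2 = ss_res / (n - 2)
        sxx = float(np.sum((t - t.mean()) ** 2))
        se = float(np.sqrt(s2 / sxx))
    else:
        se = 0.0
    return float(coef[0]), se, r2


def initial_rate(tc: TimeCourse, r2_threshold: float = LINEAR_R2) -> InitialRate:
    """Initial uptake rate from the linear portion of a time course.

    The slope is taken over the longest initial prefix (≥ 3 points) whose
    linear fit reaches R² ≥ ``r2_threshold``.  If no prefix qualifies the
    first 3 points are used and the result is flagged
    (``linear_portion_found=False``).
    """
    t, y = tc.times, tc.signals
    for k in range(t.size, 2, -1):
        slope, se, r2 = _linear_fit(t[:k], y[:k])
        if r2 >= r2_threshold:
            return InitialRate(slope, se, k, True)
    slope, se, _ = _linear_fit(t[:3], y[:3])
    return InitialRate(slope, se, 3, False)


def _hill(s: np.ndarray, k05: float, n: float, imax: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sn = np.power(s, n)
        out = imax * sn / (sn + k05**n)
    return np.where(s == 0.0, 0.0, out)


def fit_saturation(data: SaturationDataset, model: str = "Hill") -> SaturationFit:
    """Nonlinear least-squares fit of the (un-normalised) Hill/MM equation.

    ``model="MM"`` fixes n = 1; ``model="Hill"`` fits n freely unless
    ``data.fixed_hill`` pins it.  Five-ish starts span K0.5 over the
    geometric quartiles of the concentration grid and n over {0.5, 1, 2, 3}.
    A fit whose K0.5 lands above the highest tested concentration, or whose
    asymptotic errors are unbounded, is returned with ``converged=False``
    (non-saturating data cannot constrain the plateau).
    """
    if model not in ("MM", "Hill"):
        raise ValueError("model must be 'MM' or 'Hill'")
    s, y = data.concentrations, data.responses
    fixed_n = 1.0 if model == "MM" else data.fixed_hill
    n_free = fixed_n is None
    min_pts = 4 if n_free else 3
    if s.size < min_pts:
        raise DataError(f"need ≥ {min_pts} points for this fit, have {s.size}")

    pos = s[s > 0]
    if pos.size == 0:
        raise DataError("need at least one positive concentration")
    logspan = np.log(pos)
    k_starts = np.exp(np.quantile(logspan, [0.25, 0.5, 0.75]))
    n_starts = [0.5, 1.0, 2.0, 3.0] if n_free else [float(fixed_n)]
    imax0 = max(float(np.max(np.abs(y))), 1e-12)

    best = None
    for k0 in k_starts:
        for n0 in n_starts:
            if n_free:
                f = _hill
                p0 = [k0, n0, imax0]
                bounds = ([1e-12, 0.05, 1e-12], [np.inf, 10.0, np.inf])
            else:
                f = lambda sv, k, im: _hill(sv, k, fixed_n, im)  # noqa: E731
                p0 = [k0, imax0]
                bounds = ([1e-12, 1e-12], [np.inf, np.inf])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(
                        f, s, y, p0=p0, bounds=bounds, maxfev=20000
                    )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((y - f(s, *popt)) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)

    if best is None:
        raise DataError("saturation fit failed from every starting point")
    ssr, popt, pcov = best
    perr = np.sqrt(np.diag(pcov))
    if n_free:
        k05, n_hill, imax = popt
        k05_e, n_e, imax_e = perr
    else:
        k05, imax = popt
        k05_e, imax_e = perr
        n_hill, n_e = float(fixed_n), 0.0
    errors_ok = bool(np.all(np.isfinite([k05_e, n_e, imax_e])))
    converged = bool(errors_ok and (k05 <= float(s.max())))
    return SaturationFit(
        k05=float(k05),
        k05_error=float(k05_e),
        n_hill=float(n_hill),
        n_hill_error=float(n_e),
        imax=float(imax),
        imax_error=float(imax_e),
        model=model,
        converged=converged,
        ssr=ssr,
    )


def predict_response(fit: SaturationFit, s) -> np.ndarray | float:
    """Normalised response I/Imax = S^n/(S^n + K0.5^n); 0 at S = 0, → 1 as S → ∞."""
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentration must be ≥ 0")
    out = _hill(arr, fit.k05, fit.n_hill, 1.0)
    return float(out) if np.isscalar(s) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV readers


def read_timecourse_csv(path, label: str = "") -> TimeCourse:
    """CSV with columns (time, signal)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "time" not in cols or "signal" not in cols:
        raise DataError(f"{path}: expected columns (time, signal), got {list(df.columns)}")
    df = df.sort_values(cols["time"])
    return TimeCourse(
        times=df[cols["time"]].to_numpy(float),
        signals=df[cols["signal"]].to_numpy(float),
        label=label,
    )


def read_saturation_csv(path, concentration_unit: str = "mM") -> SaturationDataset:
    """CSV with columns (conc, response[, replicate]); replicates are averaged."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "conc" not in cols or "response" not in cols:
        raise DataError(f"{path}: expected columns (conc, response), got {list(df.columns)}")
    pooled = df.groupby(cols["conc"], sort=True)[cols["response"]].mean()
    return SaturationDataset(
        concentrations=pooled.index.to_numpy(float),
        responses=pooled.to_numpy(float),
        concentration_unit=concentration_unit,
    )
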
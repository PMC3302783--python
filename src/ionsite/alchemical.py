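"""Alchemical free-energy estimation from per-window sample series.

Two standard estimators of the interaction (translocation) free energy
ΔG_int are provided:

* **Thermodynamic integration (TI)** — ΔG = ∫₀¹ ⟨∂U/∂λ⟩_λ dλ, evaluated by
  a seven-point Gauss–Legendre quadrature over the coupling parameter λ.
  The standard rule on [−1, 1] is mapped to [0, 1] by λ = (x+1)/2,
  w = w_GL/2, so it integrates polynomials up to degree 13 exactly.

* **Free-energy perturbation (FEP, Zwanzig)** — ΔG = Σ_w −k_BT ln
  ⟨exp(−ΔU/k_BT)⟩ over windows tiling [0, 1], with overflow-guarded
  exponential averaging.

Statistical errors come from block averaging: the correlated sample series
is cut into contiguous blocks (50 ps by default) long compared with the
correlation time, and the standard error is the spread of block means.
Convergence is diagnosed from running averages, which flatten once
sampling is sufficient; forward and backward transformations are averaged
and their discrepancy (hysteresis) flagged when it exceeds the combined
statistical error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, KB_KCAL
from .errors import (
    DataError,
    InsufficientDataError,
    OrientationError,
    ScheduleError,
)

__all__ = [
    "LambdaSchedule",
    "TIWindowSeries",
    "FEPWindowSeries",
    "FreeEnergyEstimate",
    "CombinedEstimate",
    "RunningAverage",
    "ti_integrate",
    "fep_estimate",
    "block_error",
    "running_average",
    "combine_forward_backward",
    "oriented_forward",
    "read_ti_tsv",
    "write_ti_tsv",
    "read_fep_tsv",
    "write_fep_tsv",
]

DEFAULT_BLOCK_PS = 50.0
CONVERGENCE_TOL = 0.5  # kcal/mol over the final 20% of the running average


# ---------------------------------------------------------------------------
# schedules and series containers


@dataclass(frozen=True)
class LambdaSchedule:
    """Quadrature nodes λ_i ∈ (0,1) with weights summing to one."""

    nodes: tuple[float, ...]
    weights: tuple[float, ...]
    kind: str = "custom"

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape != weights.shape or nodes.ndim != 1 or nodes.size == 0:
            raise ScheduleError("nodes and weights must be matching 1-D sequences")
        if not (np.all(nodes > 0) and np.all(nodes < 1)):
            raise ScheduleError("λ nodes must lie strictly inside (0, 1)")
        if not np.all(np.diff(nodes) > 0):
            raise ScheduleError("λ nodes must be strictly increasing")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ScheduleError(f"weights must sum to 1 (got {weights.sum():.16f})")
        object.__setattr__(self, "nodes", tuple(float(x) for x in nodes))
        object.__setattr__(self, "weights", tuple(float(w) for w in weights))

    @classmethod
    def gauss7(cls) -> "LambdaSchedule":
        """Seven-point Gauss–Legendre rule mapped from [−1,1] to [0,1]."""
        x, w = np.polynomial.legendre.leggauss(7)
        w = w / w.sum()  # exact unit normalisation
        return cls(nodes=tuple((x + 1.0) / 2.0), weights=tuple(w), kind="gauss7")

    def __len__(self) -> int:
        return len(self.nodes)


def _validate_series(samples: Sequence[np.ndarray], minimum: int = 2) -> list[np.ndarray]:
    out = []
    for k, s in enumerate(samples):
        arr = np.asarray(s, dtype=float).ravel()
        if arr.size < minimum:
            raise DataError(f"window {k}: need ≥ {minimum} samples, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise DataError(f"window {k}: non-finite samples")
        out.append(arr)
    return out


@dataclass
class TIWindowSeries:
    """Per-λ-node time series of ∂U/∂λ (kcal/mol)."""

    nodes: tuple[float, ...]
    samples: list[np.ndarray]
    sample_interval_ps: float
    direction: str = "forward"  # provenance label; values are forward-oriented
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.samples):
            raise ScheduleError("one sample series required per λ node")
        self.samples = _validate_series(self.samples)
        if self.sample_interval_ps <= 0:
            raise DataError("sample_interval_ps must be positive")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")


@dataclass
class FEPWindowSeries:
    """Per-window series of perturbation energies ΔU (kcal/mol).

    Windows (λ_lo, λ_hi) tile [0, 1].  For a forward series the sampling
    state of window *i* is λ_lo and ΔU = U(λ_hi) − U(λ_lo); a backward
    series samples at λ_hi with ΔU = U(λ_lo) − U(λ_hi), so its summed
    estimate is −ΔG(0→1) and must be re-oriented (see
    :func:`oriented_forward`) before forward/backward averaging.
    """

    windows: tuple[tuple[float, float], ...]
    samples: list[np.ndarray]
    sample_interval_ps: float
    direction: str = "forward"
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.samples):
            raise ScheduleError("one ΔU series required per window")
        if len(self.windows) == 0:
            raise DataError("at least one window required")
        lo = np.array([w[0] for w in self.windows])
        hi = np.array([w[1] for w in self.windows])
        order = np.argsort(lo)
        lo, hi = lo[order], hi[order]
        if abs(lo[0]) > 1e-9 or abs(hi[-1] - 1.0) > 1e-9 or np.any(
            np.abs(hi[:-1] - lo[1:]) > 1e-9
        ):
            raise ScheduleError("FEP windows must tile [0, 1] without gaps or overlap")
        self.samples = _validate_series(self.samples)
        if self.sample_interval_ps <= 0:
            raise DataError("sample_interval_ps must be positive")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A ΔG with its statistical error and convergence diagnostics."""

    value: float  # kcal/mol
    error: float  # kcal/mol, ≥ 0
    direction: str
    method: str  # "TI" | "FEP"
    per_node_means: tuple[float, ...] = ()
    converged: bool = True

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be ≥ 0")


def oriented_forward(est: FreeEnergyEstimate) -> FreeEnergyEstimate:
    """Orient an estimate to the forward (0→1 transfer) sign convention.

    A backward FEP pass traverses λ 1→0, so its path value is −ΔG(0→1) and
    is negated here.  TI integrates the same ⟨∂U/∂λ⟩ integrand regardless
    of traversal order, so TI estimates pass through unchanged.
    """
    if est.method == "FEP" and est.direction == "backward":
        return replace(est, value=-est.value)
    return est


# ---------------------------------------------------------------------------
# block averaging


def block_error(
    samples: np.ndarray,
    sample_interval_ps: float,
    block_length_ps: float = DEFAULT_BLOCK_PS,
) -> float:
    """Standard error of the mean by block averaging.

    The series is partitioned into contiguous non-overlapping blocks of
    ``block_length_ps`` (a trailing partial block is dropped) and the SEM is
    sd(block means)/√n_blocks.  For blocks long compared with the
    correlation time this is an unbiased SEM for correlated data.
    """
    arr = np.asarray(samples, dtype=float).ravel()
    if sample_interval_ps <= 0 or block_length_ps <= 0:
        raise DataError("sample_interval_ps and block_length_ps must be positive")
    per_block = block_length_ps / sample_interval_ps
    if abs(per_block - round(per_block)) > 1e-9:
        raise DataError(
            f"block length {block_length_ps} ps is not a multiple of the "
            f"sample interval {sample_interval_ps} ps"
        )
    per_block = int(round(per_block))
    n_blocks = arr.size // per_block
    if n_blocks < 2:
        raise InsufficientDataError(
            f"need ≥ 2 complete blocks of {per_block} samples; have {arr.size} samples"
        )
    means = arr[: n_blocks * per_block].reshape(n_blocks, per_block).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(n_blocks))


def _sem_with_fallback(arr: np.ndarray, interval: float, block_ps: float) -> float:
    """Block SEM, falling back to the naive sd/√n when the series is too short."""
    try:
        return block_error(arr, interval, block_ps)
    except InsufficientDataError:
        return float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0


# ---------------------------------------------------------------------------
# running averages / convergence


@dataclass(frozen=True)
class RunningAverage:
    curve: np.ndarray  # cumulative means
    converged: bool
    tolerance: float


def running_average(samples: np.ndarray, tolerance: float = CONVERGENCE_TOL) -> RunningAverage:
    """Cumulative mean of a series and a flatness-based convergence flag.

    Converged ⇔ over the final 20% of samples, the running average deviates
    from its final value by at most ``tolerance`` (kcal/mol by convention).
    """
    arr = np.asarray(samples, dtype=float).ravel()
    if arr.size < 10:
        raise DataError(f"running average needs ≥ 10 samples, got {arr.size}")
    curve = np.cumsum(arr) / np.arange(1, arr.size + 1)
    tail = curve[int(np.floor(0.8 * arr.size)) :]
    converged = bool(np.max(np.abs(tail - curve[-1])) <= tolerance)
    return RunningAverage(curve=curve, converged=converged, tolerance=tolerance)


def _series_converged(arr: np.ndarray, tolerance: float) -> bool:
    if arr.size < 10:
        return True  # too short to diagnose; do not veto tiny fixtures
    return running_average(arr, tolerance).converged


# ---------------------------------------------------------------------------
# estimators


def ti_integrate(
    series: TIWindowSeries,
    schedule: LambdaSchedule,
    block_length_ps: float = DEFAULT_BLOCK_PS,
    convergence_tol: float = CONVERGENCE_TOL,
) -> FreeEnergyEstimate:
    """TI estimate: ΔG = Σ_i w_i ⟨∂U/∂λ⟩_i with block-averaged errors.

    The error is √(Σ w_i² sem_i²), treating nodes as independent; sem_i is
    the block SEM of node i (naive SEM when fewer than two 50-ps blocks
    exist).  The convergence flag requires every node's running average to
    be flat.
    """
    if len(series.nodes) != len(schedule):
        raise ScheduleError(
            f"series has {len(series.nodes)} nodes, schedule has {len(schedule)}"
        )
    if not np.allclose(series.nodes, schedule.nodes, atol=1e-9, rtol=0.0):
        raise ScheduleError("series λ nodes do not match the schedule nodes")
    w = np.asarray(schedule.weights)
    means = np.array([s.mean() for s in series.samples])
    sems = np.array(
        [_sem_with_fallback(s, series.sample_interval_ps, block_length_ps) for s in series.samples]
    )
    value = float(w @ means)
    error = float(np.sqrt(np.sum(w**2 * sems**2)))
    converged = all(_series_converged(s, convergence_tol) for s in series.samples)
    return FreeEnergyEstimate(
        value=value,
        error=error,
        direction=series.direction,
        method="TI",
        per_node_means=tuple(float(m) for m in means),
        converged=converged,
    )


def fep_estimate(
    series: FEPWindowSeries,
    block_length_ps: float = DEFAULT_BLOCK_PS,
    convergence_tol: float = CONVERGENCE_TOL,
) -> FreeEnergyEstimate:
    """FEP (exponential-averaging) estimate over all windows.

    Per window, ΔG_w = −k_BT ln⟨exp(−ΔU/k_BT)⟩ evaluated via log-sum-exp.
    The per-window error is obtained by block averaging exp(−ΔU/k_BT)
    (computed with a shift for overflow safety) and pushing the SEM through
    the logarithm by the delta method (err = k_BT·sem/mean); window errors
    combine in quadrature.
    """
    kbt = KB_KCAL * series.temperature
    values, errors, conv = [], [], []
    for arr in series.samples:
        x = -arr / kbt
        dg_w = -kbt * (logsumexp(x) - np.log(arr.size))
        values.append(float(dg_w))
        # shifted exponentials: relative SEM is shift-invariant
        y = np.exp(x - x.max())
        sem = _sem_with_fallback(y, series.sample_interval_ps, block_length_ps)
        m = y.mean()
        errors.append(float(kbt * sem / m) if m > 0 else float("nan"))
        # convergence of the window's cumulative exponential average, on the
        # free-energy scale so the kcal/mol tolerance applies
        if arr.size >= 10:
            cum = -kbt * (
                np.logaddexp.accumulate(x) - np.log(np.arange(1, arr.size + 1))
            )
            tail = cum[int(np.floor(0.8 * arr.size)) :]
            conv.append(bool(np.max(np.abs(tail - cum[-1])) <= convergence_tol))
        else:
            conv.append(True)
    return FreeEnergyEstimate(
        value=float(np.sum(values)),
        error=float(np.sqrt(np.sum(np.square(errors)))),
        direction=series.direction,
        method="FEP",
        per_node_means=tuple(values),
        converged=all(conv),
    )


# ---------------------------------------------------------------------------
# forward/backward combination


@dataclass(frozen=True)
class CombinedEstimate:
    """Average of forward and backward passes with a hysteresis diagnostic."""

    value: float  # kcal/mol, the ΔG_int estimate
    error: float  # kcal/mol
    hysteresis: float  # |forward − backward|
    flagged: bool
    forward: FreeEnergyEstimate
    backward: FreeEnergyEstimate


def combine_forward_backward(
    fwd: FreeEnergyEstimate, bwd: FreeEnergyEstimate
) -> CombinedEstimate:
    """Average two same-convention estimates; flag significant hysteresis.

    Both inputs must already carry the forward (binding) sign convention —
    see :func:`oriented_forward`.  The combined value is the plain mean,
    its error ½√(e_f² + e_b²), and the pass is flagged when the hysteresis
    |ΔG_f − ΔG_b| exceeds twice the combined error √(e_f² + e_b²).
    """
    if fwd.direction == bwd.direction:
        raise OrientationError(
            f"need one forward and one backward estimate, got two {fwd.direction!r}"
        )
    comb = float(np.hypot(fwd.error, bwd.error))
    hyst = abs(fwd.value - bwd.value)
    return CombinedEstimate(
        value=(fwd.value + bwd.value) / 2.0,
        error=comb / 2.0,
        hysteresis=hyst,
        flagged=bool(hyst > 2.0 * comb),
        forward=fwd,
        backward=bwd,
    )


# ---------------------------------------------------------------------------
# TSV I/O (one file per direction)


def write_ti_tsv(series: TIWindowSeries, path) -> Path:
    """Write a TI series as TSV with columns (lambda, time_ps, dudl)."""
    rows = []
    for lam, s in zip(series.nodes, series.samples):
        t = np.arange(1, s.size + 1) * series.sample_interval_ps
        rows.append(pd.DataFrame({"lambda": lam, "time_ps": t, "dudl": s}))
    path = Path(path)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path


def read_ti_tsv(
    path,
    direction: str = "forward",
    temperature: float = DEFAULT_TEMPERATURE,
) -> TIWindowSeries:
    """Read a (lambda, time_ps, dudl) TSV into a :class:`TIWindowSeries`."""
    df = pd.read_csv(path, sep="\t")
    missing = {"lambda", "time_ps", "dudl"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing TI columns {sorted(missing)}")
    nodes, samples, intervals = [], [], []
    for lam, grp in df.groupby("lambda", sort=True):
        grp = grp.sort_values("time_ps")
        nodes.append(float(lam))
        samples.append(grp["dudl"].to_numpy(dtype=float))
        dt = np.diff(grp["time_ps"].to_numpy(dtype=float))
        if dt.size:
            intervals.append(float(np.median(dt)))
    interval = float(np.median(intervals)) if intervals else 1.0
    return TIWindowSeries(
        nodes=tuple(nodes),
        samples=samples,
        sample_interval_ps=interval,
        direction=direction,
        temperature=temperature,
    )


def write_fep_tsv(series: FEPWindowSeries, path) -> Path:
    """Write a FEP series as TSV with columns (window_lo, window_hi, time_ps, deltaU)."""
    rows = []
    for (lo, hi), s in zip(series.windows, series.samples):
        t = np.arange(1, s.size + 1) * series.sample_interval_ps
        rows.append(
            pd.DataFrame({"window_lo": lo, "window_hi": hi, "time_ps": t, "deltaU": s})
        )
    path = Path(path)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path


def read_fep_tsv(
    path,
    direction: str = "forward",
    temperature: float = DEFAULT_TEMPERATURE,
) -> FEPWindowSeries:
    """Read a (window_lo, window_hi, time_ps, deltaU) TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = {"window_lo", "window_hi", "time_ps", "deltaU"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing FEP columns {sorted(missing)}")
    windows, samples, intervals = [], [], []
    for (lo, hi), grp in df.groupby(["window_lo", "window_hi"], sort=True):
        grp = grp.sort_values("time_ps")
        windows.append((float(lo), float(hi)))
        samples.append(grp["deltaU"].to_numpy(dtype=float))
        dt = np.diff(grp["time_ps"].to_numpy(dtype=float))
        if dt.size:
            intervals.append(float(np.median(dt)))
    interval = float(np.median(intervals)) if intervals else 1.0
    return FEPWindowSeries(
        windows=tuple(windows),
        samples=samples,
        sample_interval_ps=interval,
        direction=direction,
        temperature=temperature,
    )
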
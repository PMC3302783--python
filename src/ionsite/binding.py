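"""Standard-state entropy correction and binding free-energy composition.

The total binding free energy of an ion is composed as

    ΔG_b = ΔG_int + ΔG_tr

where ΔG_int is the interaction (site↔bulk translocation) free energy from
the alchemical estimators and ΔG_tr accounts for the translational entropy
lost when an ion that samples the 1 M standard-state volume V₀ = 1660 Å³ in
bulk is confined to a binding site.  Modelling the bound ion's fluctuations
as an anisotropic 3-D Gaussian with rms amplitudes (σx, σy, σz),

    ΔG_tr = −k_B T ln[(2πe)^{3/2} σx σy σz / V₀]

which is positive (unfavourable) whenever the effective confinement volume
(2πe)^{3/2}σxσyσz is smaller than V₀.

When raw bound-ion positions are supplied, the σ are by default the square
roots of the position-covariance eigenvalues (principal-axis rms
fluctuations), which makes ΔG_tr invariant under rotation of the lab frame;
per-axis (lab-frame) σ are available via ``mode="lab"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from math import e, pi
from typing import Iterable, NamedTuple

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_KCAL, STANDARD_VOLUME
from .errors import DataError, InsufficientDataError
from .utils import round_half_away

__all__ = [
    "ThermoContext",
    "FluctuationStats",
    "BindingFreeEnergy",
    "DeltaDeltaG",
    "fluctuations_from_positions",
    "translational_entropy",
    "sigma_for_entropy",
    "binding_free_energy",
    "delta_delta_g",
    "format_binding_table",
]

_GAUSS_VOLUME_FACTOR = (2.0 * pi * e) ** 1.5


@dataclass(frozen=True)
class ThermoContext:
    """Temperature, standard-state volume and Boltzmann constant."""

    temperature: float = DEFAULT_TEMPERATURE  # K
    v0: float = STANDARD_VOLUME  # Å³
    k_b: float = KB_KCAL  # kcal/mol/K

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.v0 <= 0:
            raise ValueError("temperature and v0 must be positive")

    @property
    def kbt(self) -> float:
        return self.k_b * self.temperature


@dataclass(frozen=True)
class FluctuationStats:
    """Rms positional fluctuations of a bound ion along three axes (Å)."""

    sigma: tuple[float, float, float]
    n_samples: int

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma):
            raise DataError(f"all σ must be positive, got {self.sigma}")


def fluctuations_from_positions(
    positions: np.ndarray, mode: str = "principal"
) -> FluctuationStats:
    """σ estimates from raw (n, 3) bound-ion positions.

    Positions are centred on their mean (no detrending — the bound ion is
    assumed stationary).  ``mode="principal"`` returns the square roots of
    the covariance eigenvalues; ``mode="lab"`` the per-axis standard
    deviations.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise DataError(f"positions must be (n, 3), got {pos.shape}")
    n = pos.shape[0]
    if n < 2:
        raise InsufficientDataError("need ≥ 2 position samples to estimate fluctuations")
    centered = pos - pos.mean(axis=0)
    if mode == "principal":
        cov = centered.T @ centered / (n - 1)
        eig = np.linalg.eigvalsh(cov)
        if np.any(eig <= 0):
            raise DataError("degenerate confinement: zero fluctuation along some axis")
        sigma = tuple(float(s) for s in np.sqrt(eig))
    elif mode == "lab":
        sd = centered.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise DataError("degenerate confinement: zero fluctuation along some axis")
        sigma = tuple(float(s) for s in sd)
    else:
        raise ValueError("mode must be 'principal' or 'lab'")
    return FluctuationStats(sigma=sigma, n_samples=n)


def translational_entropy(
    fluct, ctx: ThermoContext = ThermoContext(), mode: str = "principal"
) -> float:
    """Standard-state translational-entropy correction ΔG_tr (kcal/mol).

    ``fluct`` is either a :class:`FluctuationStats` or an (n, 3) array of
    bound-ion positions (σ estimated first; see
    :func:`fluctuations_from_positions`).
    """
    if not isinstance(fluct, FluctuationStats):
        fluct = fluctuations_from_positions(np.asarray(fluct), mode=mode)
    sx, sy, sz = fluct.sigma
    return float(-ctx.kbt * np.log(_GAUSS_VOLUME_FACTOR * sx * sy * sz / ctx.v0))


def sigma_for_entropy(dg_tr: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Isotropic σ (Å per axis) that reproduces a given ΔG_tr — the formula's inverse."""
    return float((ctx.v0 * np.exp(-dg_tr / ctx.kbt) / _GAUSS_VOLUME_FACTOR) ** (1.0 / 3.0))


@dataclass(frozen=True)
class BindingFreeEnergy:
    """The (ΔG_int, ΔG_tr, ΔG_b) triple for one ion/site/variant."""

    site_label: str
    variant: str
    dg_int: float
    dg_int_error: float
    dg_tr: float
    dg_b: float
    dg_b_error: float

    def __post_init__(self) -> None:
        if abs(self.dg_b - (self.dg_int + self.dg_tr)) > 1e-9:
            raise ValueError("ΔG_b must equal ΔG_int + ΔG_tr")


def binding_free_energy(
    dg_int: float,
    dg_tr: float,
    dg_int_error: float = 0.0,
    site_label: str = "",
    variant: str = "wild-type",
) -> BindingFreeEnergy:
    """Compose ΔG_b = ΔG_int + ΔG_tr.

    The statistical error passes through from ΔG_int; no error is attached
    to the entropy correction.
    """
    for v in (dg_int, dg_tr, dg_int_error):
        if not np.isfinite(v):
            raise ValueError("binding components must be finite")
    return BindingFreeEnergy(
        site_label=site_label,
        variant=variant,
        dg_int=float(dg_int),
        dg_int_error=float(dg_int_error),
        dg_tr=float(dg_tr),
        dg_b=float(dg_int + dg_tr),
        dg_b_error=float(dg_int_error),
    )


class DeltaDeltaG(NamedTuple):
    value: float
    error: float


def delta_delta_g(a: BindingFreeEnergy, b: BindingFreeEnergy) -> DeltaDeltaG:
    """ΔΔG = ΔG_b(a) − ΔG_b(b), errors combined in quadrature."""
    return DeltaDeltaG(
        value=float(a.dg_b - b.dg_b),
        error=float(np.hypot(a.dg_b_error, b.dg_b_error)),
    )


def format_binding_table(entries: Iterable[BindingFreeEnergy], decimals: int = 1) -> str:
    """Report-style TSV (site, variant, ΔG_int ±, ΔG_tr, ΔG_b ±), 1-decimal display."""
    buf = StringIO()
    buf.write("site\tvariant\tdG_int\tdG_int_err\tdG_tr\tdG_b\tdG_b_err\n")
    for x in entries:
        fields = [
            x.site_label,
            x.variant,
            f"{round_half_away(x.dg_int, decimals):.{decimals}f}",
            f"{round_half_away(x.dg_int_error, decimals):.{decimals}f}",
            f"{round_half_away(x.dg_tr, decimals):.{decimals}f}",
            f"{round_half_away(x.dg_b, decimals):.{decimals}f}",
            f"{round_half_away(x.dg_b_error, decimals):.{decimals}f}",
        ]
        buf.write("\t".join(fields) + "\n")
    return buf.getvalue()
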
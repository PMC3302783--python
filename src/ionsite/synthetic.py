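"""Synthetic inputs with known ground truth for every pipeline stage.

No raw MD trajectories or laboratory traces accompany the analysis this
package implements, so each input class is emulated by a generator whose
ground truth is available in closed form:

* **Harmonic alchemy** — a coupled harmonic oscillator with spring constant
  k(λ) = (1−λ)k₀ + λk₁ has ∂U/∂λ = ½(k₁−k₀)x² with x Gaussian at
  equilibrium (⟨x²⟩ = k_BT/k(λ)), giving the exact result
  ΔG = n_dof·(k_BT/2)·ln(k₁/k₀).  Samples are AR(1)-correlated in x so
  block averaging is non-trivial; φ=0 recovers iid sampling.
* **Bound-ion fluctuations** — draws from an axis-aligned 3-D Gaussian with
  chosen σ, feeding the translational-entropy correction.
* **Coordination trajectories** — an ion at the origin plus ligand oxygens
  on fixed random directions at chosen mean distances with Gaussian radial
  jitter, optionally with exchanging water oxygens; writable as multi-model
  PDB.
* **Saturation curves / uptake time courses** — Hill-shaped responses and
  saturating exponentials with additive Gaussian noise.

Every generator is deterministic under a fixed seed (one seeded
``numpy.random.Generator`` per call) and attaches its ground truth
machine-readably (a returned closed-form value, a ``truth`` dict, or the
spec object itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alchemical import FEPWindowSeries, LambdaSchedule, TIWindowSeries
from .constants import DEFAULT_TEMPERATURE, KB_KCAL
from .kinetics import SaturationDataset, TimeCourse
from .trajectory_io import AtomID, Frame, Trajectory

__all__ = [
    "HarmonicAlchemySpec",
    "CoordinationSpec",
    "gen_harmonic_ti",
    "gen_harmonic_fep",
    "gen_bound_ion_positions",
    "gen_coordination_traj",
    "gen_saturation_data",
    "gen_uptake_timecourse",
]


# ---------------------------------------------------------------------------
# harmonic alchemical fixture


@dataclass(frozen=True)
class HarmonicAlchemySpec:
    """A λ-coupled harmonic oscillator with a closed-form ΔG.

    ``ar1_phi`` sets the lag-1 autocorrelation of the underlying coordinate
    series; the marginal distribution stays the exact equilibrium Gaussian.
    """

    k0: float = 1.0  # kcal/mol/Å²
    k1: float = float(np.e) ** 2  # k1/k0 = e² gives ΔG = k_BT per dof
    n_dof: int = 1
    temperature: float = DEFAULT_TEMPERATURE
    samples_per_node: int = 10_000
    ar1_phi: float = 0.0
    sample_interval_ps: float = 0.1  # 10⁴ samples ≙ a 1-ns production window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 <= 0 or self.k1 <= 0:
            raise ValueError("spring constants must be positive")
        if not (0.0 <= self.ar1_phi < 1.0):
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.samples_per_node < 2:
            raise ValueError("samples_per_node must be ≥ 2")

    @property
    def true_dg(self) -> float:
        """Exact ΔG = n_dof·(k_BT/2)·ln(k1/k0), kcal/mol."""
        return self.n_dof * KB_KCAL * self.temperature / 2.0 * np.log(self.k1 / self.k0)

    def k_at(self, lam: float) -> float:
        return (1.0 - lam) * self.k0 + lam * self.k1


def _ar1_unit(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary AR(1) series with unit marginal variance."""
    from scipy.signal import lfilter

    eps = rng.standard_normal(n)
    if phi == 0.0:
        return eps
    # x_t = φ·x_{t−1} + √(1−φ²)·ε_t with a unit-variance stationary start
    inp = np.sqrt(1.0 - phi * phi) * eps
    inp[0] = eps[0]
    return lfilter([1.0], [1.0, -phi], inp)


def _harmonic_node_samples(
    spec: HarmonicAlchemySpec, rng: np.random.Generator, lam: float
) -> np.ndarray:
    kbt = KB_KCAL * spec.temperature
    sd_x = np.sqrt(kbt / spec.k_at(lam))
    total = np.zeros(spec.samples_per_node)
    for _ in range(spec.n_dof):
        x = sd_x * _ar1_unit(rng, spec.samples_per_node, spec.ar1_phi)
        total += x * x
    return 0.5 * (spec.k1 - spec.k0) * total


def gen_harmonic_ti(
    spec: HarmonicAlchemySpec, schedule: LambdaSchedule
) -> tuple[TIWindowSeries, TIWindowSeries, float]:
    """Forward and backward ∂U/∂λ series plus the exact ΔG.

    The backward pass revisits the nodes in reverse with fresh noise; since
    TI integrates the same ⟨∂U/∂λ⟩ either way, its values are already in
    the forward orientation.
    """
    rng = np.random.default_rng(spec.seed)
    fwd = [_harmonic_node_samples(spec, rng, lam) for lam in schedule.nodes]
    bwd = [_harmonic_node_samples(spec, rng, lam) for lam in reversed(schedule.nodes)]
    bwd.reverse()  # store in schedule (ascending-λ) order
    make = lambda s, d: TIWindowSeries(  # noqa: E731
        nodes=schedule.nodes,
        samples=s,
        sample_interval_ps=spec.sample_interval_ps,
        direction=d,
        temperature=spec.temperature,
    )
    return make(fwd, "forward"), make(bwd, "backward"), spec.true_dg


def gen_harmonic_fep(
    spec: HarmonicAlchemySpec, n_windows: int = 20
) -> tuple[FEPWindowSeries, FEPWindowSeries, float]:
    """Forward and backward ΔU window series plus the exact ΔG.

    Forward window (λᵢ, λᵢ₊₁) samples x at λᵢ with ΔU = ½(kᵢ₊₁−kᵢ)x²; the
    backward series samples at λᵢ₊₁ with the opposite ΔU, so its summed
    estimate is −ΔG(0→1) until re-oriented with
    :func:`ionsite.alchemical.oriented_forward`.
    """
    rng = np.random.default_rng(spec.seed)
    edges = np.linspace(0.0, 1.0, n_windows + 1)
    kbt = KB_KCAL * spec.temperature

    def du_samples(sample_lam: float, dk: float) -> np.ndarray:
        sd_x = np.sqrt(kbt / spec.k_at(sample_lam))
        total = np.zeros(spec.samples_per_node)
        for _ in range(spec.n_dof):
            x = sd_x * _ar1_unit(rng, spec.samples_per_node, spec.ar1_phi)
            total += x * x
        return 0.5 * dk * total

    windows = tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))
    fwd = [
        du_samples(lo, spec.k_at(hi) - spec.k_at(lo)) for lo, hi in windows
    ]
    bwd = [
        du_samples(hi, spec.k_at(lo) - spec.k_at(hi)) for lo, hi in reversed(windows)
    ]
    bwd.reverse()
    make = lambda s, d: FEPWindowSeries(  # noqa: E731
        windows=windows,
        samples=s,
        sample_interval_ps=spec.sample_interval_ps,
        direction=d,
        temperature=spec.temperature,
    )
    return make(fwd, "forward"), make(bwd, "backward"), spec.true_dg


# ---------------------------------------------------------------------------
# bound-ion positions


def gen_bound_ion_positions(
    sigma: tuple[float, float, float],
    n: int,
    seed: int = 0,
    mean: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """n draws from an axis-aligned 3-D Gaussian with the given σ (Å)."""
    sig = np.asarray(sigma, dtype=float)
    if sig.shape != (3,) or np.any(sig <= 0):
        raise ValueError("sigma must be three positive values")
    rng = np.random.default_rng(seed)
    return np.asarray(mean, dtype=float) + rng.standard_normal((n, 3)) * sig


# ---------------------------------------------------------------------------
# coordination trajectories


@dataclass(frozen=True)
class CoordinationSpec:
    """Ground truth for a synthetic ion + ligand-oxygen trajectory."""

    means: tuple[float, ...]  # Å, per-ligand mean ion–O distance
    jitters: tuple[float, ...]  # Å, Gaussian radial sd per ligand
    labels: tuple[str, ...] | None = None
    n_frames: int = 1000
    frame_interval_ps: float = 1.0
    include_waters: int = 0
    water_mean: float = 2.4  # Å, nearest-water target distance
    water_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.means) != len(self.jitters):
            raise ValueError("means and jitters must have equal length")
        if any(m <= 0 for m in self.means) or any(j < 0 for j in self.jitters):
            raise ValueError("means must be > 0 and jitters ≥ 0")
        if self.labels is not None and len(self.labels) != len(self.means):
            raise ValueError("labels must match means in length")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")

    def ligand_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        return tuple(f"L{i + 1} (O)" for i in range(len(self.means)))


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


ION_ATOM = AtomID(chain="A", residue_name="NA", residue_number=900, atom_name="NA")


def gen_coordination_traj(spec: CoordinationSpec) -> Trajectory:
    """Ion fixed at the origin; ligand oxygens on fixed directions with radial jitter.

    Atom layout: the ion is residue 900 ("NA"/"NA"), ligand *i* is residue
    *i*+1 ("LIG"/"O1"), waters are residues 901… ("HOH"/"O").  Waters get a
    fresh random direction every frame at ``water_mean ± water_jitter``, so
    the identity of the nearest water exchanges across frames.  The spec
    itself is the machine-readable ground truth (means, jitters).
    """
    rng = np.random.default_rng(spec.seed)
    n_lig = len(spec.means)
    dirs = _random_unit_vectors(rng, n_lig)

    atoms = [ION_ATOM]
    for i in range(n_lig):
        atoms.append(AtomID("A", "LIG", i + 1, "O1"))
    for w in range(spec.include_waters):
        atoms.append(AtomID("A", "HOH", 901 + w, "O"))
    atoms = tuple(atoms)

    means = np.asarray(spec.means)
    jitters = np.asarray(spec.jitters)
    frames = []
    for _ in range(spec.n_frames):
        coords = np.zeros((len(atoms), 3))
        r = means + jitters * rng.standard_normal(n_lig)
        coords[1 : 1 + n_lig] = dirs * r[:, None]
        if spec.include_waters:
            wdirs = _random_unit_vectors(rng, spec.include_waters)
            wr = spec.water_mean + spec.water_jitter * rng.standard_normal(
                spec.include_waters
            )
            coords[1 + n_lig :] = wdirs * wr[:, None]
        frames.append(Frame(coords, atoms))
    return Trajectory(
        frames, frame_interval_ps=spec.frame_interval_ps, source_format=None
    )


# ---------------------------------------------------------------------------
# kinetics fixtures


def gen_saturation_data(
    k05: float,
    n: float,
    imax: float,
    noise_sd: float,
    conc_grid,
    seed: int = 0,
    concentration_unit: str = "mM",
) -> SaturationDataset:
    """Hill-shaped responses Imax·S^n/(S^n+K0.5^n) + N(0, noise_sd)."""
    if k05 <= 0 or imax <= 0:
        raise ValueError("k05 and imax must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    s = np.asarray(conc_grid, dtype=float)
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        sn = np.power(s, n)
        clean = np.where(s == 0.0, 0.0, imax * sn / (sn + k05**n))
    y = clean + noise_sd * rng.standard_normal(s.size)
    return SaturationDataset(
        concentrations=s,
        responses=y,
        concentration_unit=concentration_unit,
        truth={"k05": k05, "n": n, "imax": imax, "noise_sd": noise_sd, "seed": seed},
    )


def gen_uptake_timecourse(
    amplitude: float,
    rate_constant: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic uptake",
) -> tuple[TimeCourse, float]:
    """Saturating uptake A·(1−e^{−kt}) + noise; returns (time course, true initial rate A·k)."""
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    y = amplitude * (1.0 - np.exp(-rate_constant * t)) + noise_sd * rng.standard_normal(
        t.size
    )
    return TimeCourse(times=t, signals=y, label=label), amplitude * rate_constant
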
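"""Ion coordination-shell analysis.

Given a trajectory, a bound ion and a list of candidate ligand oxygens, the
module reports the mean ± sd ion–oxygen distance for each candidate and
classifies shell membership by a cutoff on the *mean* distance.  The default
cutoff of 3.0 Å separates typical Na⁺–O coordination distances (2.1–2.4 Å)
from non-coordinating oxygens (≥3.5 Å) with maximal margin.

A "water" candidate is special: bulk water exchanges on the nanosecond
timescale, so no single water oxygen stays coordinated.  The per-frame
distance for a water candidate is therefore the distance to the *nearest*
water oxygen in that frame, whichever molecule that happens to be.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np

from .errors import DataError, SelectionError
from .trajectory_io import AtomID, Frame, Trajectory, distance_series, resolve
from .utils import round_half_away

__all__ = [
    "LigandCandidate",
    "CoordinationRow",
    "CoordinationTable",
    "coordination_table",
    "residue_displacement",
    "WATER_RESNAMES",
]

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC", "H2O"})

DEFAULT_CUTOFF = 3.0  # Å, on the mean ion–oxygen distance


@dataclass(frozen=True)
class LigandCandidate:
    """A candidate coordinating oxygen, or a nearest-water placeholder."""

    label: str
    atom: AtomID | None = None
    is_water_placeholder: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("ligand label must be nonempty")
        if self.is_water_placeholder and self.atom is not None:
            raise ValueError("water placeholder must not carry a fixed AtomID")
        if not self.is_water_placeholder and self.atom is None:
            raise ValueError(f"candidate {self.label!r} needs an AtomID")

    @classmethod
    def water(cls, label: str = "H2O (O)") -> "LigandCandidate":
        return cls(label=label, is_water_placeholder=True)


@dataclass(frozen=True)
class CoordinationRow:
    candidate: LigandCandidate
    mean_distance: float  # Å
    sd_distance: float  # Å; NaN when n_frames < 2
    in_shell: bool


@dataclass
class CoordinationTable:
    """Per-ligand distance statistics for one ion (one table row per ligand)."""

    rows: list[CoordinationRow]
    ion: AtomID
    cutoff: float
    n_frames: int

    def in_shell_labels(self) -> list[str]:
        return [r.candidate.label for r in self.rows if r.in_shell]

    def to_tsv(self, decimals: int = 1) -> str:
        """Report-style TSV, one decimal by default (ligand, mean, sd, in_shell)."""
        buf = StringIO()
        buf.write("ligand\tmean_A\tsd_A\tin_shell\n")
        for r in self.rows:
            sd = "" if np.isnan(r.sd_distance) else f"{round_half_away(r.sd_distance, decimals):.{decimals}f}"
            buf.write(
                f"{r.candidate.label}\t{round_half_away(r.mean_distance, decimals):.{decimals}f}"
                f"\t{sd}\t{str(r.in_shell).lower()}\n"
            )
        return buf.getvalue()


def _water_oxygen_indices(traj: Trajectory) -> list[int]:
    return [
        i
        for i, a in enumerate(traj.atoms)
        if a.residue_name.upper() in WATER_RESNAMES and a.atom_name.upper().startswith("O")
    ]


def _nearest_water_series(traj: Trajectory, ion_idx: int) -> np.ndarray:
    ox = _water_oxygen_indices(traj)
    if not ox:
        raise DataError("water candidate requested but trajectory contains no water oxygens")
    xyz = traj.coords
    d = np.linalg.norm(xyz[:, ox, :] - xyz[:, [ion_idx], :], axis=2)  # (F, n_wat)
    return d.min(axis=1)


def coordination_table(
    traj: Trajectory,
    ion: AtomID,
    candidates: list[LigandCandidate],
    cutoff: float = DEFAULT_CUTOFF,
) -> CoordinationTable:
    """Mean ± sd ion–ligand distances and shell membership.

    The sd is the sample standard deviation (n−1 denominator); with a single
    frame it is reported as NaN.  ``in_shell`` is ``mean ≤ cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ion_idx = resolve(traj, ion)
    ddof = 1 if traj.n_frames >= 2 else 0
    rows = []
    for cand in candidates:
        if cand.is_water_placeholder:
            d = _nearest_water_series(traj, ion_idx)
        else:
            d = distance_series(traj, ion_idx, resolve(traj, cand.atom))
        mean = float(np.mean(d))
        if traj.n_frames < 2:
            sd = float("nan")
        elif np.ptp(d) == 0.0:  # noiseless series: sd exactly 0, no summation fuzz
            sd = 0.0
        else:
            sd = float(np.std(d, ddof=ddof))
        rows.append(CoordinationRow(cand, mean, sd, in_shell=mean <= cutoff))
    return CoordinationTable(rows=rows, ion=ion, cutoff=cutoff, n_frames=traj.n_frames)


def residue_displacement(
    reference: Frame, traj: Trajectory, atom: AtomID
) -> tuple[float, float]:
    """Mean and max per-frame displacement (Å) of one atom from a reference.

    Inputs are assumed pre-aligned: no superposition is performed, so rigid
    drift of the whole system shows up as displacement.
    """
    try:
        ref_idx = reference.atoms.index(atom)
    except ValueError:
        raise SelectionError(f"atom {atom} not present in reference frame") from None
    traj_idx = resolve(traj, atom)
    disp = np.linalg.norm(
        traj.coords[:, traj_idx, :] - reference.coords[ref_idx], axis=1
    )
    return float(disp.mean()), float(disp.max())
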
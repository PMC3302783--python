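"""Multi-frame coordinate I/O and distance primitives.

Coordinate data arrive either as multi-model PDB (MODEL/ENDMDL delimited,
fixed columns) or as concatenated-block XYZ.  Both are parsed through
MDAnalysis; a light line-aware pre-scan of PDB files produces precise
diagnostics (line numbers, per-model atom counts) before the heavy parser
runs.  The in-memory representation is deliberately small: a ``Trajectory``
is an ordered list of ``Frame`` objects holding an ``(n_atoms, 3)`` float
array plus a parallel tuple of ``AtomID`` labels.

Distances are plain Euclidean distances in Å.  No periodic-boundary
minimum-image correction is applied: the analyses downstream concern a
binding pocket far smaller than any simulation box, and inputs are assumed
pre-wrapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParseError, SelectionError, StructureError

__all__ = [
    "AtomID",
    "Frame",
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
    "select_atom",
    "distance_series",
]

_KEPT_ALTLOCS = ("", "A")


@dataclass(frozen=True)
class AtomID:
    """Identity of one atom: chain, residue and atom name.

    Residue numbers are taken verbatim from the source file, so selections
    like residue 312 / "OD1" follow the 1-based crystallographic numbering
    used when discussing binding-site residues (T92, D312, ...).
    """

    chain: str
    residue_name: str
    residue_number: int
    atom_name: str

    def __str__(self) -> str:  # e.g. "A/ASP312/OD1"
        return f"{self.chain}/{self.residue_name}{self.residue_number}/{self.atom_name}"


@dataclass
class Frame:
    """One snapshot: coordinates (Å) plus parallel atom identities."""

    coords: np.ndarray  # (n_atoms, 3)
    atoms: tuple[AtomID, ...]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError(f"frame coordinates must be (n, 3); got {self.coords.shape}")
        if len(self.atoms) != self.coords.shape[0]:
            raise StructureError(
                f"{len(self.atoms)} atom identities for {self.coords.shape[0]} coordinates"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in frame")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """An ordered stack of frames sharing one atom-identity scheme."""

    frames: list[Frame]
    frame_interval_ps: float | None = None
    source_format: str | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("trajectory must contain at least one frame")
        ref = self.frames[0].atoms
        for k, fr in enumerate(self.frames[1:], start=2):
            if fr.atoms != ref:
                raise StructureError(f"frame {k} differs in atom identity/order from frame 1")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def atoms(self) -> tuple[AtomID, ...]:
        return self.frames[0].atoms

    @property
    def coords(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3)."""
        return np.stack([fr.coords for fr in self.frames])


# ---------------------------------------------------------------------------
# reading


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower().replace("multi-model-", "")
        if f not in ("pdb", "xyz"):
            raise ValueError(f"unsupported trajectory format: {fmt!r}")
        return f
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    raise ValueError(f"cannot infer trajectory format from {path.name!r}; pass format=")


def _prescan_pdb(path: Path) -> None:
    """Validate coordinate fields and per-model atom counts, with line numbers."""
    counts: list[int] = []
    current = 0
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
            elif rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}, line {lineno}: truncated {rec} record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise ParseError(
                        f"{path}, line {lineno}: unparsable coordinate fields in {rec} record"
                    ) from None
                if line[16].strip() in _KEPT_ALTLOCS or line[16] == " ":
                    current += 1
    if not saw_model:
        counts = [current]
    elif current:  # trailing MODEL without ENDMDL
        counts.append(current)
    counts = [c for c in counts if c > 0]
    if not counts:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    if len(set(counts)) > 1:
        raise StructureError(
            f"{path}: inconsistent atom count across models: {sorted(set(counts))}"
        )


def _read_pdb(path: Path) -> Trajectory:
    import MDAnalysis as mda

    _prescan_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # pragma: no cover - prescan catches most
            raise ParseError(f"{path}: {exc}") from exc

    ag = u.atoms
    if hasattr(ag, "altLocs"):
        keep = np.array([al.strip() in _KEPT_ALTLOCS for al in ag.altLocs])
        if not keep.all():
            dropped = int((~keep).sum())
            warnings.warn(
                f"{path.name}: dropped {dropped} alternate-location atoms (kept altloc ''/'A')",
                stacklevel=3,
            )
            ag = ag[keep]

    chains = _chain_ids(ag)
    atoms = tuple(
        AtomID(chains[i], str(ag.resnames[i]), int(ag.resids[i]), str(ag.names[i]))
        for i in range(len(ag))
    )
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in u.trajectory:
            frames.append(Frame(ag.positions.astype(float).copy(), atoms))
    return Trajectory(frames, source_format="multi-model-PDB")


def _chain_ids(ag) -> list[str]:
    if hasattr(ag, "chainIDs"):
        ids = [str(c).strip() or "A" for c in ag.chainIDs]
    elif hasattr(ag, "segids"):
        ids = [str(s).strip() or "A" for s in ag.segids]
    else:  # pragma: no cover
        ids = ["A"] * len(ag)
    return ids


def _read_xyz(path: Path) -> Trajectory:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format="XYZ", topology_format="XYZ")
        except Exception as exc:
            raise ParseError(f"{path}: malformed XYZ file ({exc})") from exc

        names = [str(n) for n in u.atoms.names]
        # XYZ carries no residue scheme: synthesize chain A, sequential residues,
        # element symbol as atom name.
        atoms = tuple(
            AtomID("A", "UNK", i + 1, names[i]) for i in range(len(names))
        )
        frames = []
        try:
            for _ in u.trajectory:
                frames.append(Frame(u.atoms.positions.astype(float).copy(), atoms))
        except (ValueError, EOFError) as exc:
            raise ParseError(f"{path}: malformed XYZ frame block ({exc})") from exc
    return Trajectory(frames, source_format="XYZ")


def read_trajectory(path, format: str | None = None) -> Trajectory:
    """Read a multi-model PDB or XYZ file into a :class:`Trajectory`.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"`` / ``"xyz"`` (aliases ``"multi-model-PDB"``, ``"XYZ"``).
        Inferred from the suffix when omitted.

    Raises
    ------
    ParseError
        Malformed records (the message names the offending line for PDB).
    StructureError
        Frames disagree in atom count or identity.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_pdb(path) if fmt == "pdb" else _read_xyz(path)


# ---------------------------------------------------------------------------
# writing (fixture/report support)


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> Path:
    """Write a trajectory as multi-model PDB or XYZ.

    PDB output uses fixed v3.3 columns (3-decimal coordinates), one MODEL
    block per frame, so ``read_trajectory`` round-trips coordinates to
    0.001 Å and atom identity exactly.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    fmt = _infer_format(path, format)

    atoms = traj.atoms
    n = traj.n_atoms
    resid_keys: list[tuple[str, int, str]] = []
    atom_resindex = []
    for a in atoms:
        key = (a.chain, a.residue_number, a.residue_name)
        if key not in resid_keys:
            resid_keys.append(key)
        atom_resindex.append(resid_keys.index(key))
    seg_keys = sorted({k[0] for k in resid_keys})
    res_segindex = [seg_keys.index(k[0]) for k in resid_keys]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=len(resid_keys),
            n_segments=len(seg_keys),
            atom_resindex=np.array(atom_resindex),
            residue_segindex=np.array(res_segindex),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.atom_name for a in atoms])
        u.add_TopologyAttr("resnames", [k[2] for k in resid_keys])
        u.add_TopologyAttr("resids", [k[1] for k in resid_keys])
        u.add_TopologyAttr("chainIDs", [a.chain for a in atoms])
        u.add_TopologyAttr("segids", seg_keys)
        u.add_TopologyAttr("occupancies", np.ones(n))
        u.add_TopologyAttr("tempfactors", np.zeros(n))
        u.load_new(traj.coords.astype(np.float32), format=MemoryReader)
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for ts in u.trajectory:
                w.write(u.atoms)
    return path


# ---------------------------------------------------------------------------
# selection and distances


def select_atom(
    traj: Trajectory,
    chain: str | None,
    residue_number: int,
    atom_name: str,
) -> int:
    """Resolve an atom to its index, valid for every frame.

    ``chain=None`` matches any chain but errors if that makes the selection
    ambiguous.
    """
    hits = [
        i
        for i, a in enumerate(traj.atoms)
        if a.residue_number == residue_number
        and a.atom_name == atom_name
        and (chain is None or a.chain == chain)
    ]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        near = [str(a) for a in traj.atoms if a.residue_number == residue_number]
        hint = f"; atoms of residue {residue_number}: {near}" if near else ""
        raise SelectionError(
            f"no atom matches chain={chain!r} residue {residue_number} name {atom_name!r}{hint}"
        )
    raise SelectionError(
        "ambiguous selection "
        f"(chain={chain!r}, residue {residue_number}, name {atom_name!r}) matches: "
        + ", ".join(str(traj.atoms[i]) for i in hits)
    )


def resolve(traj: Trajectory, atom: AtomID) -> int:
    """Index of an exact :class:`AtomID` within the trajectory."""
    return select_atom(traj, atom.chain, atom.residue_number, atom.atom_name)


def distance_series(traj: Trajectory, i: int, j: int) -> np.ndarray:
    """Per-frame Euclidean distance (Å) between atoms ``i`` and ``j``.

    No minimum-image convention is applied; see the module docstring.
    """
    n = traj.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise SelectionError(f"atom index out of range (n_atoms={n}): {i}, {j}")
    if i == j:
        raise SelectionError(f"degenerate atom pair: i == j == {i}")
    xyz = traj.coords
    return np.linalg.norm(xyz[:, i, :] - xyz[:, j, :], axis=1)
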
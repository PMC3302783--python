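"""Coordination-shell statistics and displacement analysis."""

import numpy as np
import pytest

from ionsite import (
    AtomID,
    CoordinationSpec,
    DataError,
    Frame,
    LigandCandidate,
    SelectionError,
    Trajectory,
    coordination_table,
    gen_coordination_traj,
    residue_displacement,
)
from ionsite.synthetic import ION_ATOM
from conftest import make_static_trajectory, random_rotation

NA3_SHELL_MEANS = (2.3, 2.4, 2.3, 2.2, 2.1, 3.5)  # Y89, T92, S93, N310, D312 O1/O2
NA3_LABELS = ("Y89 (O)", "T92 (OH)", "S93 (OH)", "N310 (OD)", "D312 (O1)", "D312 (O2)")


def ligand_candidates(spec):
    return [
        LigandCandidate(label, AtomID("A", "LIG", i + 1, "O1"))
        for i, label in enumerate(spec.ligand_labels())
    ]


def test_static_ligand_in_shell():
    atoms = (ION_ATOM, AtomID("A", "LIG", 1, "O1"))
    traj = make_static_trajectory([[0, 0, 0], [0, 0, 2.3]], atoms=atoms)
    tab = coordination_table(traj, ION_ATOM, [LigandCandidate("L1", atoms[1])], cutoff=3.0)
    row = tab.rows[0]
    assert row.mean_distance == pytest.approx(2.3)
    assert row.sd_distance == 0.0
    assert row.in_shell


def test_shell_classification_of_tight_site():
    """Five coordinating oxygens at 2.1–2.4 Å; the 3.5 Å carboxyl oxygen is excluded."""
    spec = CoordinationSpec(
        means=NA3_SHELL_MEANS, jitters=(0.0,) * 6, labels=NA3_LABELS, n_frames=20
    )
    traj = gen_coordination_traj(spec)
    tab = coordination_table(traj, ION_ATOM, ligand_candidates(spec), cutoff=3.0)
    assert len(tab.in_shell_labels()) == 5
    assert "D312 (O2)" not in tab.in_shell_labels()
    for row, mean in zip(tab.rows, NA3_SHELL_MEANS):
        assert row.mean_distance == pytest.approx(mean)
        assert row.sd_distance == 0.0  # noiseless ⇒ sd exactly 0


def test_mean_recovery_within_three_se():
    means, sds, n = (2.4, 4.3), (0.1, 0.2), 10_000
    spec = CoordinationSpec(means=means, jitters=sds, n_frames=n, seed=11)
    traj = gen_coordination_traj(spec)
    tab = coordination_table(traj, ION_ATOM, ligand_candidates(spec), cutoff=3.0)
    for row, mu, sd in zip(tab.rows, means, sds):
        se = sd / np.sqrt(n)
        assert abs(row.mean_distance - mu) < 3 * se
    assert tab.in_shell_labels() == [tab.rows[0].candidate.label]


def test_water_placeholder_uses_nearest_water():
    spec = CoordinationSpec(
        means=(2.2,), jitters=(0.0,), n_frames=200, include_waters=3,
        water_mean=2.4, water_jitter=0.2, seed=3,
    )
    traj = gen_coordination_traj(spec)
    tab = coordination_table(
        traj, ION_ATOM, [LigandCandidate.water()], cutoff=3.0
    )
    row = tab.rows[0]
    # nearest-of-three is biased below the single-water mean but stays bonded-range
    assert 1.8 < row.mean_distance < 2.4
    assert row.in_shell


def test_water_placeholder_without_waters_errors():
    spec = CoordinationSpec(means=(2.2,), jitters=(0.0,), n_frames=5)
    traj = gen_coordination_traj(spec)
    with pytest.raises(DataError, match="water"):
        coordination_table(traj, ION_ATOM, [LigandCandidate.water()])


def test_rotation_translation_invariance(rng):
    spec = CoordinationSpec(means=(2.3, 3.6), jitters=(0.1, 0.2), n_frames=50, seed=5)
    traj = gen_coordination_traj(spec)
    cands = ligand_candidates(spec)
    base = coordination_table(traj, ION_ATOM, cands)
    R, t = random_rotation(rng), rng.uniform(-20, 20, 3)
    moved = Trajectory(
        [Frame(f.coords @ R.T + t, f.atoms) for f in traj.frames]
    )
    rotated = coordination_table(moved, ION_ATOM, cands)
    for a, b in zip(base.rows, rotated.rows):
        assert a.mean_distance == pytest.approx(b.mean_distance, abs=1e-9)
        assert a.sd_distance == pytest.approx(b.sd_distance, abs=1e-9)
        assert a.in_shell == b.in_shell


def test_shell_membership_monotone_in_cutoff():
    spec = CoordinationSpec(means=NA3_SHELL_MEANS, jitters=(0.05,) * 6, n_frames=30, seed=9)
    traj = gen_coordination_traj(spec)
    cands = [
        LigandCandidate(f"L{i+1}", AtomID("A", "LIG", i + 1, "O1"))
        for i in range(6)
    ]
    members = []
    for cutoff in (2.0, 2.25, 3.0, 4.0):
        tab = coordination_table(traj, ION_ATOM, cands, cutoff=cutoff)
        members.append(set(tab.in_shell_labels()))
    for small, large in zip(members, members[1:]):
        assert small <= large  # enlarging the cutoff never removes a member


def test_displacement_identity_and_translation():
    atoms = (AtomID("A", "ASN", 310, "CA"),)
    ref = Frame(np.array([[1.0, 1.0, 1.0]]), atoms)
    same = Trajectory([Frame(ref.coords.copy(), atoms) for _ in range(4)])
    assert residue_displacement(ref, same, atoms[0]) == (0.0, 0.0)
    shifted = Trajectory(
        [Frame(ref.coords + [2.0, 0.0, 0.0], atoms) for _ in range(4)]
    )
    mean, mx = residue_displacement(ref, shifted, atoms[0])
    assert mean == pytest.approx(2.0)
    assert mx == pytest.approx(2.0)


def test_displacement_missing_atom_errors():
    atoms = (AtomID("A", "ASN", 310, "CA"),)
    ref = Frame(np.zeros((1, 3)), atoms)
    traj = Trajectory([Frame(np.zeros((1, 3)), atoms)])
    with pytest.raises(SelectionError):
        residue_displacement(ref, traj, AtomID("A", "ASN", 311, "CA"))


def test_displacement_gaussian_jitter_matches_chi_mean(rng):
    """Isotropic jitter σ ⇒ mean displacement σ·√(8/π); oracle by brute-force MC."""
    sigma, n = 0.5, 20_000
    atoms = (AtomID("A", "ASN", 310, "CA"),)
    ref = Frame(np.zeros((1, 3)), atoms)
    jitter = sigma * rng.standard_normal((n, 1, 3))
    traj = Trajectory([Frame(j, atoms) for j in jitter])
    mean, _ = residue_displacement(ref, traj, atoms[0])
    oracle_rng = np.random.default_rng(999)  # independent brute-force oracle
    oracle = np.linalg.norm(sigma * oracle_rng.standard_normal((200_000, 3)), axis=1)
    se = oracle.std() / np.sqrt(n)
    assert abs(mean - oracle.mean()) < 3 * se
    assert oracle.mean() == pytest.approx(sigma * np.sqrt(8 / np.pi), rel=0.01)
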
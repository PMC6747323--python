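"""Coordinate metrics against closed forms and independent numeric oracles."""

import numpy as np
import pytest

import pepmine.confmetrics as cm


def toy_structure(coords, elements=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return cm.Structure(
        atom_names=np.array([f"A{i}" for i in range(n)]),
        elements=np.array(elements or ["C"] * n),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["GLY"] * n),
        chains=np.array(["A"] * n),
        coords=coords,
    )


def quaternion_rmsd(P, Q):
    """Independent superposition oracle (Horn's quaternion method)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    Sxx, Sxy, Sxz = (P[:, 0] @ Q[:, 0], P[:, 0] @ Q[:, 1], P[:, 0] @ Q[:, 2])
    Syx, Syy, Syz = (P[:, 1] @ Q[:, 0], P[:, 1] @ Q[:, 1], P[:, 1] @ Q[:, 2])
    Szx, Szy, Szz = (P[:, 2] @ Q[:, 0], P[:, 2] @ Q[:, 1], P[:, 2] @ Q[:, 2])
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P**2) + np.sum(Q**2) - 2.0 * lam) / P.shape[0]
    return np.sqrt(max(msd, 0.0))


def test_rmsd_identical_coordinates_is_zero(rng):
    coords = rng.normal(size=(8, 3))
    s = toy_structure(coords)
    assert cm.rmsd(s, s) == pytest.approx(0.0, abs=1e-12)


def test_rmsd_rigid_translation_closed_form(rng):
    coords = rng.normal(size=(6, 3))
    t = np.array([1.0, -2.0, 2.0])
    a, b = toy_structure(coords), toy_structure(coords + t)
    assert cm.rmsd(a, b, superpose_first=True) == pytest.approx(0.0, abs=1e-9)
    assert cm.rmsd(a, b, superpose_first=False) == pytest.approx(np.linalg.norm(t))


def test_rmsd_matches_quaternion_oracle(rng):
    for _ in range(50):
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        got = cm.rmsd(toy_structure(P), toy_structure(Q), superpose_first=True)
        assert abs(got - quaternion_rmsd(P, Q)) <= 1e-8


def test_rmsd_selection_mismatch_errors(rng):
    a = toy_structure(rng.normal(size=(5, 3)))
    b = toy_structure(rng.normal(size=(6, 3)))
    with pytest.raises(ValueError, match="atom count"):
        cm.rmsd(a, b)


def make_trajectory(frames, times=None):
    frames = np.asarray(frames, dtype=float)
    return cm.Trajectory(
        template=toy_structure(frames[0]), coords=frames, times=times
    )


def test_rmsf_static_trajectory_is_zero(rng):
    base = rng.normal(size=(5, 3))
    traj = make_trajectory([base, base, base])
    _, values = cm.rmsf(traj)
    assert np.allclose(values, 0.0)


def test_rmsf_oscillating_atom_closed_form(rng):
    """One atom oscillating +/- d along an axis has RMSF d; the others
    pick up only the small recentring of the joint superposition fit."""
    base = rng.normal(scale=5.0, size=(40, 3))
    d = 0.8
    frames = []
    for f in range(20):
        frame = base.copy()
        frame[0, 0] += d if f % 2 == 0 else -d
        frames.append(frame)
    labels, values = cm.rmsf(make_trajectory(frames))
    assert values[0] == pytest.approx(d, rel=0.05)
    assert np.all(values[1:] < 0.1 * d)


def test_rmsf_invariant_under_frame_permutation(rng):
    # frames are aligned to the first frame, so any permutation that keeps
    # the reference frame first leaves the fluctuations unchanged
    frames = rng.normal(size=(6, 5, 3))
    permuted = frames[[0, 3, 1, 5, 2, 4]]
    _, forward = cm.rmsf(make_trajectory(frames))
    _, shuffled = cm.rmsf(make_trajectory(permuted))
    assert np.allclose(forward, shuffled)


def test_rmsf_requires_two_frames(rng):
    with pytest.raises(ValueError, match="2 frames"):
        cm.rmsf(make_trajectory(rng.normal(size=(1, 5, 3))))


def test_radius_of_gyration_closed_forms():
    one = toy_structure([[3.0, 4.0, 5.0]])
    assert cm.radius_of_gyration(one) == pytest.approx(0.0)
    two = toy_structure([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
    assert cm.radius_of_gyration(two) == pytest.approx(1.0)


def test_radius_of_gyration_translation_invariance(rng):
    coords = rng.normal(size=(12, 3))
    s = toy_structure(coords)
    t = toy_structure(coords + np.array([10.0, -5.0, 3.0]))
    assert cm.radius_of_gyration(s) == pytest.approx(cm.radius_of_gyration(t))


def test_radius_of_gyration_mass_weighting():
    s = toy_structure([[1.0, 0, 0], [-1.0, 0, 0]], elements=["C", "ZN"])
    m1, m2 = cm.ELEMENT_MASSES["C"], cm.ELEMENT_MASSES["ZN"]
    com = (m1 - m2) / (m1 + m2)
    expected = np.sqrt((m1 * (1 - com) ** 2 + m2 * (-1 - com) ** 2) / (m1 + m2))
    assert cm.radius_of_gyration(s) == pytest.approx(expected)


def test_sasa_single_sphere_closed_form():
    s = toy_structure([[0.0, 0.0, 0.0]], elements=["C"])
    total, per_atom = cm.sasa(s, probe=1.4, n_points=960)
    exact = 4.0 * np.pi * (1.7 + 1.4) ** 2
    assert total == pytest.approx(exact, rel=0.01)
    assert per_atom[0] == total


def test_sasa_distant_atoms_additive():
    s = toy_structure([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]], elements=["C", "O"])
    total, per_atom = cm.sasa(s)
    exact = 4.0 * np.pi * ((1.7 + 1.4) ** 2 + (1.52 + 1.4) ** 2)
    assert total == pytest.approx(exact, rel=0.01)


def test_sasa_overlapping_dimer_matches_dense_oracle():
    """Buried-area fraction of an overlapping dimer vs a high-density run."""
    coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    s = toy_structure(coords, elements=["C", "C"])
    total, _ = cm.sasa(s, n_points=960)
    dense, _ = cm.sasa(s, n_points=100_000)
    assert total == pytest.approx(dense, rel=0.02)


def test_sasa_deterministic_and_missing_radius_errors():
    s = toy_structure([[0.0, 0.0, 0.0]], elements=["C"])
    assert cm.sasa(s) == cm.sasa(s)
    weird = toy_structure([[0.0, 0.0, 0.0]], elements=["XX"])
    with pytest.raises(KeyError, match="XX"):
        cm.sasa(weird)
    total_big, _ = cm.sasa(weird, radii={"XX": 2.0})
    assert total_big == pytest.approx(4.0 * np.pi * 3.4**2, rel=0.01)


def test_hbond_geometric_criteria():
    # linear N-H...O at 2.9 A donor-acceptor distance
    s = toy_structure(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.9, 0.0, 0.0]],
        elements=["N", "H", "O"],
    )
    assert cm.count_hbonds(s, donors=[(0, 1)], acceptors=[2]) == 1
    far = toy_structure(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [4.0, 0.0, 0.0]],
        elements=["N", "H", "O"],
    )
    assert cm.count_hbonds(far, donors=[(0, 1)], acceptors=[2]) == 0
    # 90-degree donor-H-acceptor angle fails the 120-degree cutoff
    bent = toy_structure(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 2.0, 0.0]],
        elements=["N", "H", "O"],
    )
    assert cm.count_hbonds(bent, donors=[(0, 1)], acceptors=[2]) == 0


def test_hbond_histogram_frequencies_sum_to_one():
    counts = np.array([2, 2, 3, 1, 2, 3])
    hist = cm.hbond_histogram(counts)
    assert sum(hist.values()) == pytest.approx(1.0)
    assert hist[2] == pytest.approx(0.5)


def test_coordination_distances_series():
    frames = np.array(
        [
            [[0.0, 0.0, 0.0], [0.0, 0.0, 2.1], [3.0, 0.0, 0.0]],
            [[0.0, 0.0, 0.0], [0.0, 0.0, 2.5], [4.0, 0.0, 0.0]],
        ]
    )
    traj = make_trajectory(frames)
    distances = cm.coordination_distances(traj, center=0, partners=[1, 2])
    assert distances.shape == (2, 2)
    assert distances[0, 0] == pytest.approx(2.1)
    assert distances[1, 1] == pytest.approx(4.0)


def test_equilibration_check_cases():
    stable, t = cm.equilibration_check(np.full(20, 1.3), window=5, tolerance=1.0)
    assert stable and t == 0.0
    drift = np.arange(20) * 0.5
    stable, t = cm.equilibration_check(drift, window=5, tolerance=1.0)
    assert not stable and t is None
    # ramp ends below the plateau value, so stability starts exactly there
    series = np.concatenate([np.linspace(0, 4.5, 10), np.full(10, 5.0)])
    stable, t = cm.equilibration_check(series, window=5, tolerance=0.1)
    assert stable and t == 10.0  # plateau start
    times = 10.0 * np.arange(series.size)
    stable, t = cm.equilibration_check(series, window=5, tolerance=0.1, times=times)
    assert t == 100.0
    with pytest.raises(ValueError, match="longer than the series"):
        cm.equilibration_check(np.zeros(3), window=5)


def test_pdb_round_trip(tmp_path, rng):
    from pepmine.synthetic import synth_trajectory

    traj, _ = synth_trajectory(n_atoms=6, n_frames=4, jitter_sd=0.2,
                               flexible_atom=1, amplitude=0.5, rng=rng)
    path = tmp_path / "traj.pdb"
    cm.write_trajectory_pdb(traj, path)
    loaded = cm.load_structure(path)
    assert isinstance(loaded, cm.Trajectory)
    assert loaded.n_frames == 4
    # PDB stores 3 decimals
    assert np.allclose(loaded.coords, traj.coords, atol=1e-3)
    single = tmp_path / "single.pdb"
    cm.write_trajectory_pdb(
        cm.Trajectory(template=traj.template, coords=traj.coords[:1]), single
    )
    assert isinstance(cm.load_structure(single), cm.Structure)


def test_structure_selection(rng):
    s = toy_structure(rng.normal(size=(4, 3)))
    s.atom_names = np.array(["CA", "CB", "CA", "ZN"])
    s.elements = np.array(["C", "C", "C", "ZN"])
    assert list(s.select(name="CA")) == [0, 2]
    assert list(s.select(element="ZN")) == [3]
    assert list(s.select(name="CA", res_id=3)) == [2]
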
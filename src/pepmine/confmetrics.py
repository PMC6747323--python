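"""Conformational analysis metrics on coordinate data.

This module consumes coordinates (single- and multi-model PDB; docking and
molecular-dynamics engines are upstream producers, not reimplemented here)
and computes the standard trajectory metrics: superposed/raw RMSD (Kabsch),
per-residue RMSF, mass-weighted radius of gyration, Shrake-Rupley
solvent-accessible surface area, geometric hydrogen-bond counts with a
frequency histogram, metal-coordination distance series, and a sliding
window equilibration check on an RMSD series.

Units: coordinates and distances in Angstrom, areas in Angstrom^2, times in
picoseconds, masses in Dalton.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: atomic masses (Da) by element symbol
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "ZN": 65.38, "FE": 55.845, "MG": 24.305,
    "NA": 22.990, "K": 39.098, "CA": 40.078, "CL": 35.45,
}

#: van der Waals radii (Angstrom) by element symbol; override per call.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "ZN": 1.39, "FE": 1.40, "MG": 1.73,
    "NA": 2.27, "K": 2.75, "CA": 2.31, "CL": 1.75,
}


@dataclass
class Structure:
    """One conformation: parallel per-atom arrays plus coordinates (N, 3)."""

    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    masses: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.masses is None:
            self.masses = np.array(
                [ELEMENT_MASSES.get(str(e).upper(), 12.011) for e in self.elements]
            )

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def select(self, name=None, element=None, res_id=None, chain=None) -> np.ndarray:
        """Indices of atoms matching all given criteria (scalars or sets)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        for values, array in (
            (name, self.atom_names),
            (element, self.elements),
            (res_id, self.res_ids),
            (chain, self.chains),
        ):
            if values is None:
                continue
            values = {values} if np.isscalar(values) else set(values)
            mask &= np.isin(array, list(values))
        return np.flatnonzero(mask)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            atom_names=self.atom_names,
            elements=self.elements,
            res_ids=self.res_ids,
            res_names=self.res_names,
            chains=self.chains,
            coords=np.asarray(coords, dtype=float),
            masses=self.masses,
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one atom table.

    ``coords`` has shape (n_frames, n_atoms, 3); ``times`` (ps) must be
    strictly increasing.
    """

    template: Structure
    coords: np.ndarray
    times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (F, N, 3)")
        if self.coords.shape[1] != self.template.n_atoms:
            raise ValueError("frame atom count does not match the atom table")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.n_frames,):
            raise ValueError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.template.with_coords(self.coords[i])


def load_structure(path):
    """Read a PDB file: a Structure, or a Trajectory for multi-model files."""
    from biotite.structure.io import pdb as _pdb

    pdb_file = _pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure()  # AtomArrayStack
    template = Structure(
        atom_names=np.asarray(stack.atom_name),
        elements=np.asarray(stack.element),
        res_ids=np.asarray(stack.res_id),
        res_names=np.asarray(stack.res_name),
        chains=np.asarray(stack.chain_id),
        coords=np.asarray(stack.coord[0], dtype=float),
    )
    if stack.stack_depth() == 1:
        return template
    return Trajectory(
        template=template, coords=np.asarray(stack.coord, dtype=float)
    )


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB (text, one MODEL per frame)."""
    import biotite.structure as _struc
    from biotite.structure.io import pdb as _pdb

    t = traj.template
    frames = []
    for f in range(traj.n_frames):
        arr = _struc.AtomArray(t.n_atoms)
        arr.atom_name = t.atom_names.astype("U6")
        arr.element = t.elements.astype("U2")
        arr.res_id = t.res_ids.astype(int)
        arr.res_name = t.res_names.astype("U5")
        arr.chain_id = t.chains.astype("U4")
        arr.coord = traj.coords[f]
        frames.append(arr)
    stack = _struc.stack(frames)
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# superposition and deviation metrics


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal least-squares rotation matrix mapping centred ``mobile`` onto
    centred ``reference`` (proper rotation; reflections are corrected)."""
    H = mobile.T @ reference
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return (U @ D @ Vt).T


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly superpose ``mobile`` onto ``reference`` (both (N, 3))."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    R = kabsch_rotation(mobile - mc, reference - rc)
    return (mobile - mc) @ R.T + rc


def _selected(structure: Structure, selection) -> np.ndarray:
    if selection is None:
        return structure.coords
    return structure.coords[np.asarray(selection)]


def rmsd(
    a: Structure,
    b: Structure,
    superpose_first: bool = True,
    selection=None,
) -> float:
    """Root-mean-square deviation between two conformations (Angstrom).

    With ``superpose_first`` the optimal rigid-body superposition (Kabsch)
    is applied before measuring; without it the raw coordinate deviation is
    reported (the convention difference matters when comparing docking
    poses placed in a common receptor frame).
    """
    pa = _selected(a, selection)
    pb = _selected(b, selection)
    if pa.shape != pb.shape:
        raise ValueError(
            f"selections differ in atom count: {pa.shape[0]} vs {pb.shape[0]}"
        )
    if superpose_first:
        pa = superpose(pa, pb)
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory, reference_frame: int = 0, superpose_first: bool = True,
    selection=None,
) -> np.ndarray:
    """Per-frame RMSD to a reference frame."""
    ref = traj.frame(reference_frame)
    return np.array(
        [
            rmsd(traj.frame(i), ref, superpose_first=superpose_first,
                 selection=selection)
            for i in range(traj.n_frames)
        ]
    )


def rmsf(traj: Trajectory, selection=None, by_residue: bool = True):
    """Root-mean-square fluctuation about the time-averaged position.

    Frames are first superposed onto the first frame (whole-selection
    Kabsch fit), then the per-atom fluctuation is computed; with
    ``by_residue`` atoms are pooled by residue id
    (RMSF_res = sqrt(mean over atoms and frames of |r - <r>|^2)).

    Returns ``(labels, values)`` where labels are residue ids or atom
    indices.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    idx = (
        np.arange(traj.template.n_atoms)
        if selection is None
        else np.asarray(selection)
    )
    ref = traj.coords[0][idx]
    aligned = np.empty((traj.n_frames, idx.size, 3))
    for f in range(traj.n_frames):
        aligned[f] = superpose(traj.coords[f][idx], ref)
    mean_pos = aligned.mean(axis=0)
    msf = np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0)  # per atom
    if not by_residue:
        return idx, np.sqrt(msf)
    res_ids = traj.template.res_ids[idx]
    labels = np.unique(res_ids)
    values = np.array([np.sqrt(msf[res_ids == r].mean()) for r in labels])
    return labels, values


def radius_of_gyration(structure: Structure, selection=None) -> float:
    """Mass-weighted radius of gyration (Angstrom)."""
    idx = (
        np.arange(structure.n_atoms) if selection is None else np.asarray(selection)
    )
    coords = structure.coords[idx]
    masses = structure.masses[idx]
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (coords * masses[:, None]).sum(axis=0) / total
    return float(np.sqrt((masses * np.sum((coords - com) ** 2, axis=1)).sum() / total))


def rg_series(traj: Trajectory, selection=None) -> np.ndarray:
    return np.array(
        [radius_of_gyration(traj.frame(i), selection) for i in range(traj.n_frames)]
    )


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Optional[dict] = None,
    selection=None,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom is inflated by the probe radius and sampled with a fixed,
    deterministic point set; a point is accessible when outside every other
    inflated sphere.  Returns ``(total, per_atom)`` in Angstrom^2.  Atom
    radii come from the per-element table (or the ``radii`` override); an
    element with no radius is an error naming it.
    """
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    idx = (
        np.arange(structure.n_atoms) if selection is None else np.asarray(selection)
    )
    coords = structure.coords[idx]
    r = np.empty(idx.size)
    for i, e in enumerate(structure.elements[idx]):
        key = str(e).upper()
        if key not in table:
            raise KeyError(f"no van der Waals radius for element {key!r}")
        r[i] = table[key]
    R = r + probe
    unit = _sphere_points(n_points)
    per_atom = np.zeros(idx.size)
    for i in range(idx.size):
        points = coords[i] + R[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(idx.size):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) > R[i] + R[j]:
                continue
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= d2 > R[j] ** 2
        per_atom[i] = 4.0 * np.pi * R[i] ** 2 * accessible.mean()
    return float(per_atom.sum()), per_atom


# ---------------------------------------------------------------------------
# hydrogen bonds and coordination


def count_hbonds(
    structure: Structure,
    donors: Sequence[tuple],
    acceptors: Sequence[int],
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> int:
    """Geometric hydrogen-bond count for one frame.

    ``donors`` are (donor-heavy-atom, attached-hydrogen) index pairs;
    ``acceptors`` are acceptor-atom indices.  A pair is bonded when the
    donor-acceptor distance is <= ``d_max`` (Angstrom) and the
    donor-H-acceptor angle is >= ``angle_min`` (degrees).  The defaults are
    common MD-analysis practice; both are tunable.
    """
    coords = structure.coords
    count = 0
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            d = coords[d_idx]
            h = coords[h_idx]
            a = coords[a_idx]
            if np.linalg.norm(a - d) > d_max:
                continue
            v1 = d - h
            v2 = a - h
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
            if np.degrees(np.arccos(cosang)) >= angle_min:
                count += 1
    return count


def hbond_series(
    traj: Trajectory, donors, acceptors, d_max: float = 3.5,
    angle_min: float = 120.0,
) -> np.ndarray:
    return np.array(
        [
            count_hbonds(traj.frame(i), donors, acceptors, d_max, angle_min)
            for i in range(traj.n_frames)
        ]
    )


def hbond_histogram(counts: np.ndarray) -> dict[int, float]:
    """Relative frequency of each hydrogen-bond count (frequencies sum to 1)."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty hydrogen-bond series")
    values, freq = np.unique(counts, return_counts=True)
    return {int(v): float(f) / counts.size for v, f in zip(values, freq)}


def coordination_distances(
    traj: Trajectory, center: int, partners: Sequence[int]
) -> np.ndarray:
    """Euclidean distance series (n_frames, n_partners) from one centre atom
    (e.g. the catalytic Zn) to each partner atom."""
    partners = np.asarray(partners, dtype=int)
    return np.linalg.norm(
        traj.coords[:, partners, :] - traj.coords[:, [center], :], axis=2
    )


# ---------------------------------------------------------------------------
# equilibration


def equilibration_check(
    series: np.ndarray,
    window: int,
    tolerance: float = 1.0,
    times: Optional[np.ndarray] = None,
) -> tuple[bool, Optional[float]]:
    """Sliding-window stability check on an RMSD series.

    The system is considered equilibrated from the earliest index ``t``
    such that every length-``window`` window starting at or after ``t`` has
    ``max - min <= tolerance`` (default 1 Angstrom = 0.1 nm).  Returns
    ``(stable, first_stable_time)`` where the time is taken from ``times``
    when given, else the frame index; ``(False, None)`` when never stable.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if window < 2:
        raise ValueError("window must span at least 2 samples")
    if window > n:
        raise ValueError("window longer than the series")
    sw = np.lib.stride_tricks.sliding_window_view(series, window)
    spread = sw.max(axis=1) - sw.min(axis=1)
    bad = np.flatnonzero(spread > tolerance)
    start = 0 if bad.size == 0 else int(bad[-1]) + 1
    if start > n - window:
        return False, None
    t = float(times[start]) if times is not None else float(start)
    return True, t
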
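"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its seed (or of a
:class:`numpy.random.Generator` substream): random proteins of controlled
composition, proteins with spiked cleavable motifs whose release under a
named enzyme is guaranteed by construction, logistic dose-response data
with known IC50 and noise, and toy rigid-body trajectories with one
designated flexible atom of known fluctuation amplitude.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .confmetrics import Structure, Trajectory
from .digest import digest, find_cleavage_sites
from .enzymes import EnzymeSpec
from .io import AMINO_ACIDS, ProteinRecord


def _as_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generator substreams from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def random_protein(
    length: int,
    composition: Optional[dict] = None,
    rng=None,
    id: str = "synthetic",
) -> ProteinRecord:
    """Random protein with the given residue composition (multinomial draws).

    ``composition`` maps residues to weights (normalised internally;
    residues with weight 0 never appear); the default is uniform over the
    20-letter alphabet.
    """
    rng = _as_rng(rng)
    if length < 1:
        raise ValueError("length must be >= 1")
    if composition is None:
        composition = {aa: 1.0 for aa in AMINO_ACIDS}
    residues = sorted(composition)
    weights = np.array([composition[r] for r in residues], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("composition weights must be non-negative, not all zero")
    probs = weights / weights.sum()
    seq = "".join(rng.choice(list(residues), size=length, p=probs))
    return ProteinRecord(id=id, sequence=seq)


def _releasing_flanks(motif: str, enzyme: EnzymeSpec, context: str) -> tuple[str, str]:
    """Find flank residues (left, right) so the enzyme releases the motif.

    Searches the alphabet for a pair such that, in a probe embedding
    ``context + left + motif + right + context``, the bonds immediately
    before and after the motif are cleaved and no internal motif bond is.
    """
    m = len(motif)
    for left in AMINO_ACIDS:
        for right in AMINO_ACIDS:
            probe = context + left + motif + right + context
            sites = find_cleavage_sites(probe, enzyme)
            start = len(context) + 1  # 1-based position of `left`
            want_before = start  # bond after the left flank
            want_after = start + m  # bond after the motif's last residue
            internal = set(range(start + 1, start + m))
            if (
                want_before in sites
                and want_after in sites
                and not (sites & internal)
            ):
                return left, right
    raise ValueError(
        f"motif {motif!r} cannot be released exactly by enzyme {enzyme.name!r}"
    )


def spike_motifs(
    background: ProteinRecord,
    motifs: Sequence[tuple],
    enzyme: EnzymeSpec,
    id: Optional[str] = None,
) -> tuple[ProteinRecord, dict]:
    """Embed motifs so that digestion by ``enzyme`` provably releases them.

    ``motifs`` is a list of ``(sequence, count)`` pairs.  Each copy is
    inserted with flanks drawn from the enzyme's accept sets, at evenly
    spaced points of the background.  The construction is verified against
    the digestion engine itself: the returned ground truth maps each motif
    to its released count, and a background that interferes (extra
    occurrences or blocked release) raises instead of returning a wrong
    map.
    """
    inserts = []
    for motif, count in motifs:
        if count < 1:
            raise ValueError("motif counts must be >= 1")
        left, right = _releasing_flanks(motif, enzyme, context="GG")
        inserts.extend([left + motif + right] * count)
    bg = background.sequence
    n = len(inserts)
    if n == 0:
        return background, {}
    step = len(bg) // (n + 1)
    if step < 1:
        raise ValueError("background too short for the requested motif spikes")
    pieces = []
    prev = 0
    for i, insert in enumerate(inserts, start=1):
        pieces.append(bg[prev : i * step])
        pieces.append(insert)
        prev = i * step
    pieces.append(bg[prev:])
    seq = "".join(pieces)
    protein = ProteinRecord(id=id or f"{background.id}+spikes", sequence=seq)

    released = [p.sequence for p in digest(protein, enzyme).peptides]
    truth = {}
    for motif, count in motifs:
        got = released.count(motif)
        if got != count:
            raise ValueError(
                f"background interferes with motif {motif!r}: expected "
                f"{count} releases, digestion yields {got}"
            )
        occurrences = protein.sequence.count(motif)  # non-overlapping lower bound
        if _overlapping_count(protein.sequence, motif) != count:
            raise ValueError(
                f"background contains extra occurrences of motif {motif!r} "
                f"({occurrences} present, {count} spiked)"
            )
        truth[motif] = count
    return protein, truth


def _overlapping_count(seq: str, sub: str) -> int:
    count = 0
    start = 0
    while True:
        idx = seq.find(sub, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def synth_dose_response(
    ic50: float,
    hill: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    rng=None,
) -> list[tuple]:
    """Logistic inhibition data: ``100/(1+(IC50/c)^h)`` plus Gaussian noise."""
    rng = _as_rng(rng)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if not (conc.min() < ic50 < conc.max()):
        raise ValueError("concentrations must bracket the true IC50")
    inhibition = 100.0 / (1.0 + (ic50 / conc) ** hill)
    if noise_sd > 0:
        inhibition = inhibition + rng.normal(0.0, noise_sd, size=conc.size)
    return list(zip(conc.tolist(), inhibition.tolist()))


def synth_trajectory(
    n_atoms: int = 20,
    n_frames: int = 50,
    jitter_sd: float = 0.0,
    flexible_atom: Optional[int] = None,
    amplitude: float = 1.0,
    frame_dt: float = 10.0,
    rng=None,
) -> tuple[Trajectory, dict]:
    """Rigid-body trajectory with optional jitter and one flexible atom.

    Every frame is the same base conformation under a random rigid rotation
    and translation, plus per-atom Gaussian jitter of ``jitter_sd``.  The
    designated flexible atom is additionally displaced by ``+/- amplitude``
    along a fixed axis, alternating between frames, so its fluctuation
    about the mean is exactly ``amplitude`` (up to the superposition fit).

    Returns the trajectory and the analytic expectations
    ``{"rmsd_superposed": 0 (jitter-free), "flexible_rmsf": amplitude}``.
    """
    rng = _as_rng(rng)
    if n_atoms < 4:
        raise ValueError("need at least 4 atoms for a well-posed superposition")
    base = rng.normal(scale=5.0, size=(n_atoms, 3))
    axis = np.array([1.0, 0.0, 0.0])
    coords = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        frame = base.copy()
        if flexible_atom is not None:
            sign = 1.0 if f % 2 == 0 else -1.0
            frame[flexible_atom] += sign * amplitude * axis
        if jitter_sd > 0:
            frame += rng.normal(scale=jitter_sd, size=frame.shape)
        rotation = _random_rotation(rng)
        translation = rng.normal(scale=10.0, size=3)
        coords[f] = frame @ rotation.T + translation
    template = Structure(
        atom_names=np.array(["CA"] * n_atoms),
        elements=np.array(["C"] * n_atoms),
        res_ids=np.arange(1, n_atoms + 1),
        res_names=np.array(["GLY"] * n_atoms),
        chains=np.array(["A"] * n_atoms),
        coords=coords[0],
    )
    traj = Trajectory(
        template=template,
        coords=coords,
        times=frame_dt * np.arange(n_frames, dtype=float),
    )
    expected = {
        "rmsd_superposed": 0.0 if jitter_sd == 0 and flexible_atom is None else None,
        "flexible_rmsf": amplitude if flexible_atom is not None else None,
    }
    return traj, expected


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
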
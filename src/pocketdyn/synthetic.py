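"""Deterministic synthetic fixture systems with machine-readable truth.

Four generators emulate the statistical structure that the analysis
modules assume in real enzyme-inhibitor trajectories, at toy scale:

* :func:`make_pose_trajectory` — a ring "protein" with a multi-fragment
  rod ligand hopping between planted binding poses with distinct
  residue-contact patterns (for featurization/clustering/energetics);
* :func:`make_channel` — breathing cylindrical/funnel channels with an
  analytic radius profile (for the gorge profiler);
* :func:`make_waterbox` — water boxes with exactly scheduled site
  occupancies and a guard band around every cutoff (for water counting);
* :func:`make_harmonic` — harmonic ensembles with known fluctuation
  amplitudes and optional planted collective modes (for RMSF and PCA).

Every generator is bit-reproducible from (spec, seed): one RNG family
(numpy Generator) with explicit spawn keys, no global state. Ground
truth is returned alongside the Trajectory and consumed directly by the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import (PocketdynError, Topology, Trajectory,
                   assign_molecule_tags, write_frames)
from .interactions import FragmentScheme
from .water import OccupancyTable


# ---------------------------------------------------------------------------
# small topology builders
# ---------------------------------------------------------------------------

def _build_topology(names, elements, res_index, res_names, res_numbers,
                    chains, charges=None, lj_sigma=None, lj_epsilon=None,
                    vdw=None) -> Topology:
    from .core import mass_of
    names = np.array(names, dtype=object)
    elements = np.array(elements, dtype=object)
    res_index = np.asarray(res_index, dtype=int)
    res_names = np.array(res_names, dtype=object)
    masses = np.array([mass_of(str(e)) for e in elements])
    tags = assign_molecule_tags(res_names, elements, res_index)
    return Topology(
        atom_names=names, elements=elements, residue_index=res_index,
        residue_names=res_names,
        residue_numbers=np.asarray(res_numbers, dtype=int),
        chain_ids=np.array(chains, dtype=object), masses=masses,
        molecule_tags=tags,
        charges=None if charges is None else np.asarray(charges, float),
        lj_sigma=None if lj_sigma is None else np.asarray(lj_sigma, float),
        lj_epsilon=None if lj_epsilon is None else np.asarray(lj_epsilon,
                                                              float),
        vdw_radius=None if vdw is None else np.asarray(vdw, float))


def chain_topology(n_atoms: int) -> Topology:
    """Bare carbon-chain topology (one CA per residue), for writing
    reconstructed selection-only coordinates."""
    return _build_topology(
        names=["CA"] * n_atoms, elements=["C"] * n_atoms,
        res_index=np.arange(n_atoms), res_names=["GLY"] * n_atoms,
        res_numbers=np.arange(1, n_atoms + 1), chains=["A"] * n_atoms)


# ---------------------------------------------------------------------------
# planted-pose protein-ligand trajectories
# ---------------------------------------------------------------------------

@dataclass
class PoseSpec:
    """Stated world for the pose generator.

    Defaults follow the planted-pose recovery fixture: 3 poses, 3000
    frames, coordinate noise sigma 0.2 Å, dwell blocks of 50 frames.
    Occupancies must sum to 1; block quotas are exact (largest-remainder
    rounding), so realized populations match them up to one block.
    """

    n_poses: int = 3
    occupancies: tuple = ()
    n_frames: int = 3000
    noise_sigma: float = 0.2
    dwell: int = 50
    n_residues: int = 12
    ring_radius: float = 26.0
    rng_seed: int = 7

    def __post_init__(self):
        if not self.occupancies:
            self.occupancies = tuple([1.0 / self.n_poses] * self.n_poses)
        occ = np.asarray(self.occupancies, float)
        if occ.size != self.n_poses or np.any(occ <= 0) or \
                abs(occ.sum() - 1.0) > 1e-9:
            raise PocketdynError("pose occupancies must be positive and sum to 1")


@dataclass
class PoseSystem:
    trajectory: Trajectory
    labels: np.ndarray               # planted pose per frame
    fragments: FragmentScheme        # construction ground truth
    contact_residues: list           # per pose, residue indices
    ligand_atoms: np.ndarray         # indices into the topology
    spec: PoseSpec = None


def _pose_protein(spec: PoseSpec):
    """Ring protein: per residue N, CA, C, O backbone + CB, CG side chain
    pointing inward. Returns (coords, topology arrays)."""
    names, elements, res_index, res_names, res_numbers, chains = \
        [], [], [], [], [], []
    charges, sigma, eps = [], [], []
    coords = []
    r = spec.ring_radius
    resnames_cycle = ["SER", "THR", "VAL", "LEU", "ASN", "GLN"]
    for i in range(spec.n_residues):
        th = 2.0 * np.pi * i / spec.n_residues
        d = np.array([np.cos(th), 0.0, np.sin(th)])
        t = np.array([-np.sin(th), 0.0, np.cos(th)])
        up = np.array([0.0, 1.0, 0.0])
        atoms = [
            ("N", "N", r * d - 1.2 * t, 0.02),
            ("CA", "C", r * d, 0.00),
            ("C", "C", r * d + 1.2 * t, 0.02),
            ("O", "O", r * d + 1.2 * t + 1.0 * up, -0.04),
            ("CB", "C", (r - 1.5) * d, 0.10),
            ("CG", "C", (r - 3.0) * d, -0.20),
        ]
        for nm, el, pos, q in atoms:
            names.append(nm)
            elements.append(el)
            res_index.append(i)
            res_names.append(resnames_cycle[i % len(resnames_cycle)])
            res_numbers.append(i + 1)
            chains.append("A")
            charges.append(q)
            sigma.append(0.32)
            eps.append(0.35)
            coords.append(pos)
    return (np.array(coords), names, elements, res_index, res_names,
            res_numbers, chains, charges, sigma, eps)


def _rod_ligand():
    """Three diamond rings joined by single cuttable bonds.

    Local coordinates along +x; within-ring bonds ~1.41 Å, inter-ring
    bridge bonds 1.4 Å between the unique on-axis atoms, so the default
    fragmenter recovers exactly the three rings.
    """
    coords = []
    frag_truth = []
    spacing = 3.4
    for k in range(3):
        c = k * spacing
        ring = [(c - 1.0, 0.0, 0.0), (c, 1.0, 0.0),
                (c + 1.0, 0.0, 0.0), (c, -1.0, 0.0)]
        frag_truth.append(np.arange(len(coords), len(coords) + 4))
        coords.extend(ring)
    coords = np.array(coords)
    coords -= coords.mean(axis=0)
    return coords, frag_truth


def make_pose_trajectory(spec: PoseSpec | None = None) -> PoseSystem:
    """Planted-pose protein-ligand trajectory with ground-truth labels.

    Pose p binds two adjacent residues (contact side-chain tips < 4 Å
    from ligand atoms) while all other residues stay > 8 Å away; the
    pose sequence is drawn in dwell blocks with exact occupancy quotas.
    """
    spec = spec or PoseSpec()
    (prot, names, elements, res_index, res_names, res_numbers, chains,
     charges, sigma, eps) = _pose_protein(spec)
    lig_local, frag_truth = _rod_ligand()
    n_prot = prot.shape[0]
    n_lig = lig_local.shape[0]
    lig_atoms = np.arange(n_prot, n_prot + n_lig)
    for a in range(n_lig):
        names.append(f"C{a + 1}")
        elements.append("C")
        res_index.append(spec.n_residues)
        res_names.append("LIG")
        res_numbers.append(900)
        chains.append("L")
        charges.append(0.08)
        sigma.append(0.32)
        eps.append(0.35)
    top = _build_topology(names, elements, res_index, res_names,
                          res_numbers, chains, charges, sigma, eps)

    # pose placements: ligand axis along the chord between the two
    # contact side-chain tips, pulled slightly inward
    step = spec.n_residues // spec.n_poses
    tip_r = spec.ring_radius - 3.0
    contact = []
    placements = []
    for p in range(spec.n_poses):
        a, b = p * step, p * step + 1
        contact.append([a, b])
        tha = 2 * np.pi * a / spec.n_residues
        thb = 2 * np.pi * b / spec.n_residues
        tip_a = tip_r * np.array([np.cos(tha), 0.0, np.sin(tha)])
        tip_b = tip_r * np.array([np.cos(thb), 0.0, np.sin(thb)])
        mid = 0.5 * (tip_a + tip_b)
        u = tip_b - tip_a
        u /= np.linalg.norm(u)
        center = mid - 2.0 * mid / np.linalg.norm(mid)
        rot = np.eye(3)
        # rotate ligand +x onto u (both in the xz plane)
        v = np.array([1.0, 0.0, 0.0])
        c = float(v @ u)
        axis = np.cross(v, u)
        s = np.linalg.norm(axis)
        if s > 1e-12:
            axis /= s
            kmat = np.array([[0, -axis[2], axis[1]],
                             [axis[2], 0, -axis[0]],
                             [-axis[1], axis[0], 0]])
            rot = np.eye(3) + s * kmat + (1 - c) * (kmat @ kmat)
        elif c < 0:
            rot = np.diag([-1.0, -1.0, 1.0])
        placements.append(lig_local @ rot.T + center)

    # dwell-block pose sequence with exact quotas (largest remainder)
    n_blocks = int(np.ceil(spec.n_frames / spec.dwell))
    occ = np.asarray(spec.occupancies)
    raw = occ * n_blocks
    quota = np.floor(raw).astype(int)
    rem = n_blocks - quota.sum()
    order = np.argsort(-(raw - quota))
    quota[order[:rem]] += 1
    blocks = np.repeat(np.arange(spec.n_poses), quota)
    rng = np.random.default_rng([spec.rng_seed, 1])
    rng.shuffle(blocks)
    labels = np.repeat(blocks, spec.dwell)[:spec.n_frames]

    noise_rng = np.random.default_rng([spec.rng_seed, 2])
    n_atoms = n_prot + n_lig
    coords = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        coords[f, :n_prot] = prot
        coords[f, n_prot:] = placements[int(labels[f])]
        if spec.noise_sigma > 0:
            coords[f] += noise_rng.normal(0.0, spec.noise_sigma,
                                          size=(n_atoms, 3))
    traj = Trajectory(topology=top, coords=coords,
                      times=0.1 * np.arange(spec.n_frames))
    frags = FragmentScheme(fragments=[(f"F{i + 1}", fi)
                                      for i, fi in enumerate(frag_truth)])
    return PoseSystem(trajectory=traj, labels=labels, fragments=frags,
                      contact_residues=contact, ligand_atoms=lig_atoms,
                      spec=spec)


# ---------------------------------------------------------------------------
# analytic channels
# ---------------------------------------------------------------------------

@dataclass
class ChannelSpec:
    """Channel wall built from atom rings so the inscribed radius is
    radius_fn(y) (+ breathing modulation); ring/azimuthal spacing <= 1 Å
    keeps the discretisation error below ~0.02 Å."""

    radius_fn: Callable = None        # y -> Å; default constant 8
    axis_range: tuple = (0.0, 20.0)
    ring_spacing: float = 0.8
    az_spacing: float = 0.8
    vdw: float = 1.5
    n_frames: int = 1
    breathing_amplitude: float = 0.0
    rng_seed: int = 7

    def __post_init__(self):
        if self.radius_fn is None:
            self.radius_fn = lambda y: 8.0


@dataclass
class ChannelSystem:
    trajectory: Trajectory
    truth: Callable                  # (y, frame) -> wall radius fn R(y,t), Å
    seed_point: np.ndarray
    spec: ChannelSpec = None

    def axis_radius(self, y, frame: int = 0) -> np.ndarray:
        """Exact inscribed-sphere radius at axis points (independent oracle).

        By radial symmetry the optimal sphere center lies on the channel
        axis, so the true slice radius is the pore function evaluated
        there: min over all wall atoms of (distance - vdw). For sloped
        walls this is smaller than the in-plane wall radius R(y) — the
        sphere touches the narrower wall below the slice plane (for a
        linear funnel of slope b the radius slope is b/sqrt(1+b²)).
        """
        atoms = self.trajectory.coords[frame]
        vdw = self.trajectory.topology.vdw_radius
        out = []
        for yy in np.atleast_1d(np.asarray(y, dtype=float)):
            c = np.array([0.0, yy, 0.0])
            out.append(float(
                (np.linalg.norm(atoms - c, axis=1) - vdw).min()))
        return np.array(out) if np.ndim(y) else out[0]


def make_channel(spec: ChannelSpec | None = None) -> ChannelSystem:
    spec = spec or ChannelSpec()
    lo, hi = spec.axis_range
    ys = np.arange(lo, hi + 1e-9, spec.ring_spacing)
    amp = spec.breathing_amplitude

    def truth(y, frame=0):
        phase = 2.0 * np.pi * frame / max(spec.n_frames, 1)
        return spec.radius_fn(y) + amp * np.sin(phase)

    base_r = np.array([spec.radius_fn(y) for y in ys])
    if np.any(base_r - abs(amp) <= 0):
        raise PocketdynError("radius function must stay positive")
    # fixed atom count: azimuthal grid sized for the largest wall radius
    n_az = [max(8, int(np.ceil(2 * np.pi * (r + abs(amp) + spec.vdw)
                               / spec.az_spacing)))
            for r in base_r]
    n_atoms = int(np.sum(n_az))
    names, elements, res_index, res_names, res_numbers, chains = \
        [], [], [], [], [], []
    for i, (y, na) in enumerate(zip(ys, n_az)):
        for a in range(na):
            names.append("CA")
            elements.append("C")
            res_index.append(i)
            res_names.append("GLY")
            res_numbers.append(i + 1)
            chains.append("A")
    top = _build_topology(names, elements, res_index, res_names,
                          res_numbers, chains,
                          vdw=np.full(n_atoms, spec.vdw))
    coords = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        k = 0
        for i, (y, na) in enumerate(zip(ys, n_az)):
            wall = truth(y, f) + spec.vdw
            ang = 2 * np.pi * np.arange(na) / na
            coords[f, k:k + na, 0] = wall * np.cos(ang)
            coords[f, k:k + na, 1] = y
            coords[f, k:k + na, 2] = wall * np.sin(ang)
            k += na
    traj = Trajectory(topology=top, coords=coords,
                      times=0.1 * np.arange(spec.n_frames))
    seed_point = np.array([0.0, 0.5 * (lo + hi), 0.0])
    return ChannelSystem(trajectory=traj, truth=truth,
                         seed_point=seed_point, spec=spec)


# ---------------------------------------------------------------------------
# scheduled water boxes
# ---------------------------------------------------------------------------

@dataclass
class WaterBoxSpec:
    """Waters placed in shells around one site atom per an exact schedule.

    inner_occupancy / mid_occupancy: fraction of frames (or per-frame
    integer arrays) with one water inside the inner shell
    (< cutoffs[0] - guard) / between the cutoffs. Jitter is seeded and
    never crosses a cutoff (guard band 0.2 Å).
    """

    n_frames: int = 100
    cutoffs: tuple = (3.0, 3.5)
    guard: float = 0.2
    inner_occupancy: object = 0.5
    mid_occupancy: object = 0.0
    n_far_waters: int = 5
    rng_seed: int = 7


@dataclass
class WaterBoxSystem:
    trajectory: Trajectory
    expected: OccupancyTable
    site_label: str
    spec: WaterBoxSpec = None


def _schedule_counts(occ, n_frames: int) -> np.ndarray:
    if np.isscalar(occ):
        k = int(round(float(occ) * n_frames))
        counts = np.zeros(n_frames, dtype=int)
        if k:
            idx = np.unique(np.floor(np.arange(k) * n_frames / k).astype(int))
            counts[idx[:k]] = 1
        if counts.sum() != k:  # collisions cannot happen for k <= n, but guard
            counts[:] = 0
            counts[:k] = 1
        return counts
    counts = np.asarray(occ, dtype=int)
    if counts.size != n_frames or np.any(counts < 0):
        raise PocketdynError("per-frame schedule must be non-negative, "
                             "one entry per frame")
    return counts


def make_waterbox(spec: WaterBoxSpec | None = None) -> WaterBoxSystem:
    spec = spec or WaterBoxSpec()
    lo_cut, hi_cut = spec.cutoffs
    g = spec.guard
    if lo_cut - g <= 2.2 or hi_cut - g <= lo_cut + g:
        raise PocketdynError("schedule infeasible within the shell geometry")
    inner = _schedule_counts(spec.inner_occupancy, spec.n_frames)
    mid = _schedule_counts(spec.mid_occupancy, spec.n_frames)
    n_inner_max = int(inner.max(initial=0))
    n_mid_max = int(mid.max(initial=0))
    n_waters = n_inner_max + n_mid_max + spec.n_far_waters

    names = ["CB", "OH"]
    elements = ["C", "O"]
    res_index = [0, 0]
    res_names = ["TYR", "TYR"]
    res_numbers = [282, 282]
    chains = ["A", "A"]
    for w in range(n_waters):
        for nm, el in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
            names.append(nm)
            elements.append(el)
            res_index.append(1 + w)
            res_names.append("SOL")
            res_numbers.append(1000 + w)
            chains.append("W")
    top = _build_topology(names, elements, res_index, res_names,
                          res_numbers, chains)
    site_pos = np.zeros(3)
    rng = np.random.default_rng([spec.rng_seed, 3])
    coords = np.empty((spec.n_frames, top.n_atoms, 3))
    far_grid = (np.arange(n_waters) * 4.0)[:, None] * np.array([[1.0, 0, 0]])
    far_grid += np.array([hi_cut + 5.0 + g, 0.0, 0.0])

    def water_at(pos):
        return np.stack([pos, pos + np.array([0.76, 0.59, 0.0]),
                         pos + np.array([-0.76, 0.59, 0.0])])

    for f in range(spec.n_frames):
        coords[f, 0] = site_pos + np.array([0.0, -1.5, 0.0])
        coords[f, 1] = site_pos
        placed = []
        for w in range(n_waters):
            shell = None
            if w < n_inner_max and inner[f] > w:
                shell = (2.3, lo_cut - g)
            elif n_inner_max <= w < n_inner_max + n_mid_max and \
                    mid[f] > (w - n_inner_max):
                shell = (lo_cut + g, hi_cut - g)
            if shell is None:
                pos = far_grid[w]
            else:
                r = rng.uniform(*shell)
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                pos = site_pos + r * v
            placed.append(water_at(pos))
        coords[f, 2:] = np.concatenate(placed, axis=0)
    traj = Trajectory(topology=top, coords=coords,
                      times=0.1 * np.arange(spec.n_frames))
    label = "Tyr282_OH"
    expected = OccupancyTable(
        counts={(label, float(lo_cut)): inner.copy(),
                (label, float(hi_cut)): inner + mid},
        sites=[label], cutoffs=tuple(float(c) for c in spec.cutoffs))
    return WaterBoxSystem(trajectory=traj, expected=expected,
                          site_label=label, spec=spec)


# ---------------------------------------------------------------------------
# harmonic ensembles
# ---------------------------------------------------------------------------

@dataclass
class HarmonicSpec:
    """Isotropic Gaussian jitter about a fixed helix, optional planted
    collective mode (orthogonalised against rigid-body motions)."""

    n_atoms: int = 60
    sigma: object = 0.5              # Å, scalar or per-atom
    n_frames: int = 2000
    mode_amplitude: float = 0.0      # Å (std of the mode coefficient)
    mode_vector: np.ndarray | None = None
    rng_seed: int = 7


@dataclass
class HarmonicSystem:
    trajectory: Trajectory
    expected_rmsf: np.ndarray        # per atom, Å
    mode_vector: np.ndarray | None   # (M, 3), unit Frobenius norm
    base: np.ndarray
    spec: HarmonicSpec = None


def _rigid_orthogonalize(mode: np.ndarray, base: np.ndarray) -> np.ndarray:
    m = base.shape[0]
    cen = base - base.mean(axis=0)
    basis = []
    for k in range(3):
        t = np.zeros((m, 3))
        t[:, k] = 1.0
        basis.append(t.ravel())
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        basis.append(np.cross(np.broadcast_to(e, (m, 3)), cen).ravel())
    q, _ = np.linalg.qr(np.array(basis).T)
    v = mode.ravel().astype(float)
    v = v - q @ (q.T @ v)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise PocketdynError("mode vanishes after removing rigid components")
    return (v / n).reshape(m, 3)


def make_harmonic(spec: HarmonicSpec | None = None) -> HarmonicSystem:
    spec = spec or HarmonicSpec()
    m = spec.n_atoms
    i = np.arange(m)
    base = np.stack([2.3 * np.cos(np.deg2rad(100) * i), 1.5 * i,
                     2.3 * np.sin(np.deg2rad(100) * i)], axis=1)
    sigma = np.broadcast_to(np.asarray(spec.sigma, dtype=float), (m,)).copy()
    top = chain_topology(m)
    mode = None
    if spec.mode_amplitude > 0:
        if spec.mode_vector is not None:
            mode = _rigid_orthogonalize(np.asarray(spec.mode_vector), base)
        else:
            raw = np.zeros((m, 3))
            raw[:, 0] = np.sin(2 * np.pi * i / m)
            raw[:, 2] = np.cos(4 * np.pi * i / m)
            mode = _rigid_orthogonalize(raw, base)
    rng = np.random.default_rng([spec.rng_seed, 4])
    coords = np.empty((spec.n_frames, m, 3))
    coeffs = (rng.normal(0.0, spec.mode_amplitude, size=spec.n_frames)
              if mode is not None else np.zeros(spec.n_frames))
    for f in range(spec.n_frames):
        coords[f] = base + rng.normal(0.0, 1.0, size=(m, 3)) * sigma[:, None]
        if mode is not None:
            coords[f] += coeffs[f] * mode
    expected = np.sqrt(3.0 * sigma ** 2
                       + (spec.mode_amplitude ** 2
                          * (mode ** 2).sum(axis=1) if mode is not None
                          else 0.0))
    traj = Trajectory(topology=top, coords=coords,
                      times=0.1 * np.arange(spec.n_frames))
    return HarmonicSystem(trajectory=traj, expected_rmsf=expected,
                          mode_vector=mode, base=base, spec=spec)


def save_system(trajectory: Trajectory, outdir: str, basename: str = "system"
                ) -> tuple[str, str]:
    """Write a generated system through the real I/O path (PDB + DCD)."""
    import os
    os.makedirs(outdir, exist_ok=True)
    pdb = os.path.join(outdir, f"{basename}.pdb")
    dcd = os.path.join(outdir, f"{basename}.dcd")
    write_frames(trajectory, [0], pdb, fmt="pdb")
    write_frames(trajectory, list(range(trajectory.n_frames)), dcd, fmt="dcd")
    return pdb, dcd
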
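"""Per-residue molecular-mechanics interaction energies for pose clusters.

Only the vacuum MM terms are computed: Coulomb with f = 138.935458
kJ·mol⁻¹·nm·e⁻² and dielectric 1, plus Lennard-Jones with
Lorentz-Berthelot combination, summed over all intermolecular pairs with
no cutoff (the complexes are compact, finite sums are exact). The
Poisson-Boltzmann and surface-area solvation terms of an MM-PBSA
workflow require an external solver and are deliberately not included;
reports are labelled "MM term" so they are not mistaken for full MM-PBSA
binding energies.

Frame selection per cluster follows the protocol: the frames closest to
the cluster's central structure in feature space, thinned so selected
trajectory indices are pairwise at least `stride` frames apart, up to
`count` frames ("evenly spaced by 20 frames" codified as this greedy
minimum-separation rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AtomSelection, PocketdynError, Topology, Trajectory
from .interactions import PoseClusterResult

#: Coulomb conversion factor, kJ mol⁻¹ nm e⁻²
COULOMB_CONST = 138.935458
CLASH_NM = 0.05

#: residue names carrying a net charge at physiological pH; nonstandard
#: protonation states must be declared explicitly
CHARGED_RESNAMES = {"ASP", "GLU", "LYS", "ARG", "HIP", "HSP"}

STRONG_THRESHOLD = -10.0     # kJ/mol
FAVORABLE_THRESHOLD = -5.0   # kJ/mol


@dataclass
class EnergyDecomposition:
    """Per (cluster, residue) mean MM interaction terms in kJ/mol."""

    clusters: list                   # cluster ids
    residue_indices: np.ndarray
    residue_labels: list
    coulomb: np.ndarray              # (n_clusters, n_residues) means
    lj: np.ndarray
    per_frame: dict                  # cluster -> (n_frames, n_residues, 2)
    frames_used: dict                # cluster -> frame indices
    charge_class: np.ndarray         # "charged" / "noncharged"
    populations: np.ndarray | None = None

    @property
    def total(self) -> np.ndarray:
        return self.coulomb + self.lj

    def grand_mean(self) -> np.ndarray:
        """Cluster-weighted per-residue totals (weights = populations)."""
        w = (np.ones(len(self.clusters)) / len(self.clusters)
             if self.populations is None else self.populations)
        return (w[:, None] * self.total).sum(axis=0)

    def summary(self) -> pd.DataFrame:
        rows = []
        for ci, c in enumerate(self.clusters):
            for ri in range(len(self.residue_indices)):
                rows.append({
                    "cluster": c,
                    "residue": self.residue_labels[ri],
                    "coulomb_kJ_mol": self.coulomb[ci, ri],
                    "lj_kJ_mol": self.lj[ci, ri],
                    "mm_total_kJ_mol": self.total[ci, ri],
                    "charge_class": self.charge_class[ri],
                })
        return pd.DataFrame(rows)


def select_energy_frames(ranked_frames: np.ndarray, stride: int = 20,
                         count: int = 20) -> np.ndarray:
    """Greedy thinning of distance-ranked cluster members.

    Walk the ranked list (nearest to the central structure first), taking
    a frame only when its trajectory index differs by >= stride from
    every frame already taken; stop at `count`. Deterministic.
    """
    taken: list[int] = []
    for f in np.asarray(ranked_frames, dtype=int):
        if all(abs(int(f) - t) >= stride for t in taken):
            taken.append(int(f))
            if len(taken) >= count:
                break
    if len(taken) < count:
        warnings.warn(
            f"cluster too small for {count} frames at stride {stride}; "
            f"returning {len(taken)}")
    return np.array(taken, dtype=int)


def _require_params(topology: Topology, atoms: np.ndarray):
    probs = []
    for arr, what in ((topology.charges, "charge"),
                      (topology.lj_sigma, "sigma"),
                      (topology.lj_epsilon, "epsilon")):
        if arr is None:
            raise PocketdynError(f"topology has no {what} parameters")
        bad = atoms[~np.isfinite(np.asarray(arr)[atoms])]
        if bad.size:
            probs.append(f"{what}: atoms {bad[:8].tolist()}")
    if probs:
        raise PocketdynError("missing parameters — " + "; ".join(probs))


def mm_interaction(coords: np.ndarray, topology: Topology,
                   ligand_sel: AtomSelection, residue_index: int,
                   ) -> tuple[float, float]:
    """(Coulomb, LJ) interaction of one residue with the ligand, kJ/mol.

    All intermolecular pairs, no cutoff; r in nm. Pairs closer than
    0.05 nm raise a clash error.
    """
    lig = ligand_sel.indices if isinstance(ligand_sel, AtomSelection) \
        else np.asarray(ligand_sel, dtype=int)
    res = topology.residue_atoms(int(residue_index))
    res = res[~np.isin(res, lig)]
    if res.size == 0 or lig.size == 0:
        return 0.0, 0.0
    _require_params(topology, np.concatenate([res, lig]))
    c = np.asarray(coords, dtype=float)
    diff = c[res][:, None, :] - c[lig][None, :, :]
    r_nm = np.sqrt((diff ** 2).sum(axis=2)) / 10.0
    if np.any(r_nm < CLASH_NM):
        i, j = np.unravel_index(int(np.argmin(r_nm)), r_nm.shape)
        raise PocketdynError(
            f"clash: atoms {int(res[i])} and {int(lig[j])} at "
            f"{r_nm[i, j]:.4f} nm")
    q = topology.charges
    coul = COULOMB_CONST * float(
        ((q[res][:, None] * q[lig][None, :]) / r_nm).sum())
    sig = 0.5 * (topology.lj_sigma[res][:, None]
                 + topology.lj_sigma[lig][None, :])
    eps = np.sqrt(topology.lj_epsilon[res][:, None]
                  * topology.lj_epsilon[lig][None, :])
    sr6 = (sig / r_nm) ** 6
    lj = float((4.0 * eps * (sr6 ** 2 - sr6)).sum())
    return coul, lj


def classify_residue_charges(topology: Topology,
                             residue_indices: np.ndarray,
                             charged_extra: set | None = None) -> np.ndarray:
    charged = CHARGED_RESNAMES | (charged_extra or set())
    out = []
    for ri in residue_indices:
        a = int(topology.residue_atoms(int(ri))[0])
        rn = str(topology.residue_names[a]).upper()
        out.append("charged" if rn in charged else "noncharged")
    return np.array(out, dtype=object)


def decompose_clusters(trajectory: Trajectory, result: PoseClusterResult,
                       ligand_sel: AtomSelection,
                       residue_indices: np.ndarray | None = None,
                       stride: int = 20, count: int = 20,
                       charged_extra: set | None = None,
                       ) -> EnergyDecomposition:
    """Per-residue MM interaction means over the selected frames per cluster."""
    if result.status != "ok":
        raise PocketdynError("pose clustering did not select a k")
    top = trajectory.topology
    if residue_indices is None:
        tags = top.molecule_tags.astype(str)
        residue_indices = np.unique(top.residue_index[tags == "protein"])
    residue_indices = np.asarray(residue_indices, dtype=int)
    labels = [top.residue_label(int(ri)) for ri in residue_indices]
    clusters = sorted(result.members_by_distance)
    n_c, n_r = len(clusters), residue_indices.size
    coul = np.zeros((n_c, n_r))
    lj = np.zeros((n_c, n_r))
    per_frame, frames_used = {}, {}
    for ci, c in enumerate(clusters):
        frames = select_energy_frames(result.members_by_distance[c],
                                      stride, count)
        frames_used[c] = frames
        vals = np.zeros((frames.size, n_r, 2))
        for fi, f in enumerate(frames):
            for ri, res in enumerate(residue_indices):
                vals[fi, ri] = mm_interaction(trajectory.coords[int(f)], top,
                                              ligand_sel, int(res))
        per_frame[c] = vals
        coul[ci] = vals[:, :, 0].mean(axis=0)
        lj[ci] = vals[:, :, 1].mean(axis=0)
    return EnergyDecomposition(
        clusters=clusters, residue_indices=residue_indices,
        residue_labels=labels, coulomb=coul, lj=lj, per_frame=per_frame,
        frames_used=frames_used,
        charge_class=classify_residue_charges(top, residue_indices,
                                              charged_extra),
        populations=result.populations)


def classify_band(total_kj_mol: float) -> str:
    """strong (<= -10), favorable (<= -5), weak (<= -4), minor otherwise."""
    if total_kj_mol <= STRONG_THRESHOLD:
        return "strong"
    if total_kj_mol <= FAVORABLE_THRESHOLD:
        return "favorable"
    if total_kj_mol <= -4.0:
        return "weak"
    return "minor"


def filter_contributors(decomp: EnergyDecomposition,
                        threshold: float = -4.0) -> dict:
    """Noncharged residues contributing <= threshold kJ/mol, per cluster.

    Charged residues are reported separately (their large Coulomb terms
    are not comparable without the solvation screening that is out of
    scope here), never silently dropped.
    """
    report = {}
    for ci, c in enumerate(decomp.clusters):
        tot = decomp.total[ci]
        nonch = decomp.charge_class == "noncharged"
        keep = nonch & (tot <= threshold)
        order = np.argsort(tot[keep], kind="stable")
        idx = np.flatnonzero(keep)[order]
        report[c] = {
            "contributors": [
                {"residue": decomp.residue_labels[i],
                 "mm_total_kJ_mol": float(tot[i]),
                 "band": classify_band(float(tot[i]))}
                for i in idx],
            "charged": [
                {"residue": decomp.residue_labels[i],
                 "mm_total_kJ_mol": float(tot[i])}
                for i in np.flatnonzero(~nonch)],
        }
    return report
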
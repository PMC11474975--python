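"""Least-squares superposition (Kabsch) and RMSD/RMSF metrics.

Fits are mass-unweighted by default (uniform weights), matching common
MD-analysis defaults on a plain atom selection; pass weights explicitly
for a mass-weighted fit. No periodic-boundary unwrapping is performed:
inputs are assumed to contain whole molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AtomSelection, PocketdynError, Trajectory


@dataclass
class Transform:
    """Proper rigid-body transform x -> rotation @ x + translation."""

    rotation: np.ndarray    # 3x3, det +1
    translation: np.ndarray  # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class FluctuationProfile:
    """Per-atom or per-residue RMSF (Å)."""

    values: np.ndarray
    ids: np.ndarray          # atom indices, or residue indices if per_residue
    labels: list             # human-readable residue/atom labels
    per_residue: bool
    selection_label: str = ""
    reference: str = ""


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               weights: np.ndarray | None = None) -> Transform:
    """Optimal proper rotation + translation of `mobile` onto `reference`.

    Minimises the (weighted) sum of squared deviations; a reflection in
    the SVD solution is corrected to keep det(R) = +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise PocketdynError(
            f"coordinate shapes differ: {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise PocketdynError("need at least 3 atoms for a rigid fit")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise PocketdynError("invalid fit weights")
    wf = w / w.sum()
    mc = (wf[:, None] * mobile).sum(axis=0)
    rc = (wf[:, None] * reference).sum(axis=0)
    m0 = mobile - mc
    r0 = reference - rc
    h = (wf[:, None] * m0).T @ r0
    u, s, vt = np.linalg.svd(h)
    # degenerate geometry: all points collinear leaves the rotation about
    # the line undetermined
    scale = max(s[0], 1e-30)
    if s[1] / scale < 1e-10:
        raise PocketdynError("degenerate (collinear) geometry in kabsch_fit")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return Transform(rotation=rot, translation=trans)


def rmsd(a: np.ndarray, b: np.ndarray,
         weights: np.ndarray | None = None) -> float:
    """Plain (weighted) RMSD between two coordinate sets, no fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise PocketdynError("coordinate shapes differ in rmsd")
    d2 = ((a - b) ** 2).sum(axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def _sel_indices(sel) -> np.ndarray:
    if isinstance(sel, AtomSelection):
        return sel.indices
    return np.asarray(sel, dtype=int)


def rmsd_series(trajectory: Trajectory, reference: np.ndarray,
                fit_selection: AtomSelection | None,
                measure_selection: AtomSelection,
                weights: np.ndarray | None = None) -> np.ndarray:
    """Per-frame RMSD (Å): fit on `fit_selection`, measure on `measure_selection`.

    `reference` holds full-system coordinates (N x 3); pass
    fit_selection=None to measure without superposition.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (trajectory.n_atoms, 3):
        raise PocketdynError(
            "reference must hold full-system coordinates "
            f"({trajectory.n_atoms} x 3), got {reference.shape}")
    meas = _sel_indices(measure_selection)
    out = np.empty(trajectory.n_frames)
    if fit_selection is None:
        for f in range(trajectory.n_frames):
            out[f] = rmsd(trajectory.coords[f, meas], reference[meas], weights)
        return out
    fit = _sel_indices(fit_selection)
    ref_fit = reference[fit]
    for f in range(trajectory.n_frames):
        tr = kabsch_fit(trajectory.coords[f, fit], ref_fit)
        out[f] = rmsd(tr.apply(trajectory.coords[f, meas]), reference[meas],
                      weights)
    return out


def rmsf(trajectory: Trajectory,
         fit_selection: AtomSelection | None,
         measure_selection: AtomSelection,
         per_residue: bool = False,
         reference: np.ndarray | None = None) -> FluctuationProfile:
    """RMSF_i = sqrt(<|x_i - <x_i>|^2>) after per-frame superposition.

    The reference for fitting defaults to the first frame. With
    fit_selection=None raw coordinates are used (appropriate for
    ensembles generated about a fixed mean with no net rigid motion).
    per_residue=True averages atomic RMSF over each residue's atoms in
    the measure selection.
    """
    if trajectory.n_frames < 2:
        raise PocketdynError("RMSF needs at least 2 frames")
    meas = _sel_indices(measure_selection)
    top = trajectory.topology
    if fit_selection is None:
        fitted = trajectory.coords[:, meas, :]
    else:
        fit = _sel_indices(fit_selection)
        ref = trajectory.coords[0] if reference is None else \
            np.asarray(reference, dtype=float)
        ref_fit = ref[fit]
        fitted = np.empty((trajectory.n_frames, meas.size, 3))
        for f in range(trajectory.n_frames):
            tr = kabsch_fit(trajectory.coords[f, fit], ref_fit)
            fitted[f] = tr.apply(trajectory.coords[f, meas])
    mean = fitted.mean(axis=0)
    msf = ((fitted - mean) ** 2).sum(axis=2).mean(axis=0)
    atom_rmsf = np.sqrt(msf)
    if not per_residue:
        labels = [f"{top.atom_names[i]}/{top.residue_label(top.residue_index[i])}"
                  for i in meas]
        return FluctuationProfile(values=atom_rmsf, ids=meas, labels=labels,
                                  per_residue=False,
                                  selection_label=getattr(
                                      measure_selection, "label", ""))
    res_of = top.residue_index[meas]
    resids = np.unique(res_of)
    vals = np.array([atom_rmsf[res_of == r].mean() for r in resids])
    labels = [top.residue_label(int(r)) for r in resids]
    return FluctuationProfile(values=vals, ids=resids, labels=labels,
                              per_residue=True,
                              selection_label=getattr(
                                  measure_selection, "label", ""))


def flag_flexible(profile: FluctuationProfile,
                  threshold: float) -> np.ndarray:
    """Indices (into the profile) whose RMSF meets or exceeds `threshold` Å.

    Used to flag flexible loop residues (e.g. RMSF >= 2 Å for apo gorge
    loops, >= 4 Å for complex Ω-loop excursions).
    """
    return np.flatnonzero(profile.values >= threshold)
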
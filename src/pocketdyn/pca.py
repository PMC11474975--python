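"""Essential-dynamics PCA, elbow K-means state clustering, PC overlap.

The model diagonalises the (optionally mass-weighted) covariance matrix
of superposed coordinates: frames are least-squares fitted to a reference
on the analysis selection, displacements from the ensemble mean are
scaled per-coordinate by sqrt(mass), and the population covariance
(divide by n_frames, as in the common MD tools) is eigendecomposed.
Projections of the trajectory on the leading eigenvectors ("PCs") are the
collective-motion coordinates used downstream for state clustering.

Eigenvector sign is fixed by orienting the largest-magnitude component
positive, so repeated runs agree; :func:`flip_pc_sign` flips a component
for presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core import AtomSelection, PocketdynError, Topology, Trajectory
from .superpose import kabsch_fit

#: above this coordinate dimension the frame-space (Gram) dual is used
DIRECT_EIG_MAX_DIM = 5000


@dataclass
class PCAModel:
    """Mean, eigenvectors and eigenvalues of a (weighted) covariance.

    Eigenvalues are in Å²·amu when mass-weighted, Å² otherwise, sorted
    non-increasing. Eigenvector columns are orthonormal in the weighted
    coordinate space.
    """

    mean: np.ndarray           # (3M,) Å
    eigenvectors: np.ndarray   # (3M, K)
    eigenvalues: np.ndarray    # (K,)
    weights: np.ndarray        # (M,) per-atom mass or 1
    selection_label: str = ""
    sel_indices: np.ndarray | None = None   # into the full topology
    reference: np.ndarray | None = None     # (M, 3) Å, fit target
    n_atoms_full: int | None = None
    mass_weighted: bool = False
    dim_weights: np.ndarray | None = None   # full-dimension weights (features)

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def sqrt_w(self) -> np.ndarray:
        if self.dim_weights is not None:
            return np.sqrt(self.dim_weights)
        return np.sqrt(np.repeat(self.weights, 3))


@dataclass
class Projection:
    """Per-frame PC scores (frames x K)."""

    scores: np.ndarray
    source: str = "trajectory"

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]


@dataclass
class ConfClusterResult:
    """Conformational-state clustering of PC scores (elbow K-means)."""

    labels: np.ndarray
    k: int
    ssr_sst: dict            # k -> SSR(k)/SST
    populations: np.ndarray  # per-cluster fraction, sums to 1
    central_frames: np.ndarray  # per-cluster frame index nearest centroid
    seed: int = 0


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    out = vecs.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca_from_matrix(x: np.ndarray, n_components: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecompose the population covariance of row-observations `x`.

    Returns (mean, eigenvectors, eigenvalues), eigenvalues clipped at 0
    and sorted non-increasing. Uses a direct symmetric solve for
    dimension <= DIRECT_EIG_MAX_DIM, otherwise the frame-space Gram dual
    (identical nonzero spectrum).
    """
    x = np.asarray(x, dtype=float)
    f, d = x.shape
    mean = x.mean(axis=0)
    y = x - mean
    if d <= DIRECT_EIG_MAX_DIM:
        cov = (y.T @ y) / f
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
    else:
        gram = (y @ y.T) / f
        gvals, gvecs = np.linalg.eigh(gram)
        order = np.argsort(gvals)[::-1]
        gvals = np.clip(gvals[order], 0.0, None)
        gvecs = gvecs[:, order]
        nz = gvals > 1e-12 * max(gvals[0], 1e-30)
        evecs = np.zeros((d, f))
        evecs[:, nz] = y.T @ gvecs[:, nz] / np.sqrt(f * gvals[nz])
        evals = gvals
    if n_components is not None:
        evals = evals[:n_components]
        evecs = evecs[:, :n_components]
    return mean, _fix_signs(evecs), evals


def _superposed_sel_coords(trajectory: Trajectory, sel: np.ndarray,
                           reference: np.ndarray,
                           fit_weights: np.ndarray | None) -> np.ndarray:
    out = np.empty((trajectory.n_frames, sel.size, 3))
    for f in range(trajectory.n_frames):
        tr = kabsch_fit(trajectory.coords[f, sel], reference, fit_weights)
        out[f] = tr.apply(trajectory.coords[f, sel])
    return out


def fit_pca(trajectory: Trajectory, selection: AtomSelection,
            mass_weighted: bool = True,
            reference: np.ndarray | None = None) -> PCAModel:
    """PCA of superposed selection coordinates.

    Frames are fitted (on the selection, weighted by mass when
    mass_weighted) to `reference` — full-system or selection-sized
    coordinates, default the first frame — before the covariance is
    accumulated.
    """
    if trajectory.n_frames < 2:
        raise PocketdynError("PCA needs at least 2 frames")
    sel = selection.indices
    if sel.size == 0:
        raise PocketdynError("empty selection for PCA")
    top = trajectory.topology
    if reference is None:
        ref = trajectory.coords[0, sel]
    else:
        reference = np.asarray(reference, dtype=float)
        ref = reference[sel] if reference.shape[0] == top.n_atoms else reference
        if ref.shape != (sel.size, 3):
            raise PocketdynError("reference shape incompatible with selection")
    w = top.masses[sel] if mass_weighted else np.ones(sel.size)
    fit_w = top.masses[sel] if mass_weighted else None
    fitted = _superposed_sel_coords(trajectory, sel, ref, fit_w)
    sqrt_w = np.sqrt(np.repeat(w, 3))
    flat = fitted.reshape(trajectory.n_frames, -1)
    mean = flat.mean(axis=0)
    weighted = (flat - mean) * sqrt_w
    _, evecs, evals = pca_from_matrix(weighted + 0.0)
    return PCAModel(mean=mean, eigenvectors=evecs, eigenvalues=evals,
                    weights=w, selection_label=selection.label,
                    sel_indices=sel, reference=ref,
                    n_atoms_full=top.n_atoms, mass_weighted=mass_weighted)


def _coerce_coords(model: PCAModel, obj) -> np.ndarray:
    """Extract (F, M, 3) selection coordinates from the accepted inputs."""
    if isinstance(obj, Trajectory):
        if model.sel_indices is None:
            raise PocketdynError("model lacks selection indices")
        return obj.coords[:, model.sel_indices, :]
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    m = model.mean.size // 3
    if arr.shape[1] == m:
        return arr
    if model.n_atoms_full is not None and arr.shape[1] == model.n_atoms_full \
            and model.sel_indices is not None:
        return arr[:, model.sel_indices, :]
    raise PocketdynError(
        f"coordinate dimension {arr.shape[1]} matches neither the model "
        f"selection ({m}) nor the full system ({model.n_atoms_full})")


def project(model: PCAModel, obj, n_components: int | None = None,
            superpose: bool = True, source: str = "trajectory") -> Projection:
    """Project coordinates onto the model's leading eigenvectors.

    External structures are superposed onto the model's fit reference on
    the same selection first. Scores are sqrt(w)-weighted displacements
    dotted with the eigenvectors.
    """
    coords = _coerce_coords(model, obj)
    k = model.n_components if n_components is None else int(n_components)
    if k > model.n_components:
        raise PocketdynError("more components requested than the model holds")
    sqrt_w = model.sqrt_w
    fit_w = model.weights if model.mass_weighted else None
    scores = np.empty((coords.shape[0], k))
    for f in range(coords.shape[0]):
        x = coords[f]
        if superpose and model.reference is not None:
            x = kabsch_fit(x, model.reference, fit_w).apply(x)
        scores[f] = ((x.reshape(-1) - model.mean) * sqrt_w) @ \
            model.eigenvectors[:, :k]
    return Projection(scores=scores, source=source)


def reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Inverse of :func:`project`: Cartesian Å coordinates (F, M, 3)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    k = scores.shape[1]
    flat = model.mean + (model.eigenvectors[:, :k] @ scores.T).T / model.sqrt_w
    return flat.reshape(scores.shape[0], -1, 3)


def flip_pc_sign(projection: Projection, component: int) -> Projection:
    """Negate one PC (1-based) of a projection, e.g. for visual parity."""
    scores = projection.scores.copy()
    j = component - 1
    if not (0 <= j < scores.shape[1]):
        raise PocketdynError(f"component {component} out of range")
    scores[:, j] = -scores[:, j]
    return Projection(scores=scores, source=projection.source)


def pc_overlap(model_a: PCAModel, model_b: PCAModel, component: int) -> float:
    """Inner product of the two models' unit eigenvectors for one PC (1-based).

    Sign is retained; report abs() alongside if only magnitude matters.
    """
    if model_a.eigenvectors.shape[0] != model_b.eigenvectors.shape[0]:
        raise PocketdynError("models have different coordinate dimensions")
    j = component - 1
    va = model_a.eigenvectors[:, j]
    vb = model_b.eigenvectors[:, j]
    return float(va @ vb)


def interpolate_extremes(model: PCAModel, projection: Projection,
                         component: int, n: int = 100,
                         topology: Topology | None = None) -> Trajectory:
    """n conformations scanning [min, max] of one PC's observed scores.

    Coordinates are reconstructed as mean + t * v (un-weighted back to
    Cartesian Å). A selection-sized Topology can be supplied; otherwise a
    subset of the model's source topology cannot be rebuilt and a bare
    carbon-chain stand-in topology is synthesised for writing.
    """
    if n < 2:
        raise PocketdynError("need n >= 2 interpolation points")
    j = component - 1
    if model.eigenvalues[j] <= 1e-12:
        raise PocketdynError(f"degenerate PC {component} (zero variance)")
    lo = float(projection.scores[:, j].min())
    hi = float(projection.scores[:, j].max())
    ts = np.linspace(lo, hi, n)
    scores = np.zeros((n, model.n_components))
    scores[:, j] = ts
    coords = reconstruct(model, scores)
    if topology is None:
        from .synthetic import chain_topology
        topology = chain_topology(coords.shape[1])
    return Trajectory(topology=topology, coords=coords,
                      times=np.arange(n, dtype=float))


def _ssr_sst_curve(x: np.ndarray, k_max: int, seed: int
                   ) -> tuple[dict, dict]:
    sst = float(((x - x.mean(axis=0)) ** 2).sum())
    ratios, fits = {}, {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed, tol=1e-6)
        km.fit(x)
        ratios[k] = float(km.inertia_) / sst if sst > 0 else 0.0
        fits[k] = km
    return ratios, fits


def elbow_kmeans(projection: Projection, n_components: int = 3,
                 threshold: float = 0.025, k_max: int = 10,
                 seed: int = 0) -> ConfClusterResult:
    """K-means over the leading PCs with the elbow rule on SSR/SST.

    SSR(k) is the within-cluster sum of squares and SST the total sum of
    squares; the chosen k is the smallest k whose ratio improvement to
    k+1 falls below `threshold` (default 2.5%). K-means uses k-means++
    with 10 restarts and a fixed seed.
    """
    if k_max < 2:
        raise PocketdynError("k_max must be at least 2")
    x = projection.scores[:, :n_components]
    if x.shape[0] < k_max:
        raise PocketdynError("fewer frames than k_max")
    ratios, fits = _ssr_sst_curve(x, k_max + 1, seed)
    chosen = k_max
    for k in range(1, k_max + 1):
        if ratios[k] - ratios[k + 1] < threshold:
            chosen = k
            break
    else:
        warnings.warn("elbow threshold never met; returning k_max")
    km = fits[chosen]
    labels = km.labels_.astype(int)
    pops = np.bincount(labels, minlength=chosen) / labels.size
    centers = km.cluster_centers_
    central = np.empty(chosen, dtype=int)
    for c in range(chosen):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(x[members] - centers[c], axis=1)
        central[c] = int(members[np.lexsort((members, d))[0]])
    ratios.pop(k_max + 1)
    return ConfClusterResult(labels=labels, k=chosen, ssr_sst=ratios,
                             populations=pops, central_frames=central,
                             seed=seed)
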
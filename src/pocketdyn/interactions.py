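"""Pose clustering from reciprocal residue-fragment minimum distances.

The representation: for every frame, the minimum heavy-atom distance
between each protein residue and each ligand fragment is computed and
reciprocated (1/max(d, floor)). Reciprocation damps fluctuations of
distant residues and amplifies those of residues neighbouring the
ligand, so the feature matrix encodes the binding interaction network.
The features are internal coordinates: no superposition to a reference
and no frames-x-frames matrix is ever needed, which keeps memory at
O(frames x features) and makes the method fast on long trajectories.

The first three PCs of the feature covariance are clustered with
K-means; the cluster count is chosen by maximising the Silhouette score
subject to the Davies-Bouldin index ranking lowest or second lowest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .core import AtomSelection, PocketdynError, Topology, Trajectory
from .pca import PCAModel, Projection, pca_from_matrix

#: Silhouette is subsampled (fixed seed) above this many frames; the
#: Davies-Bouldin index is always computed on the full data.
SILHOUETTE_SUBSAMPLE = 5000


@dataclass
class FragmentScheme:
    """Disjoint ligand heavy-atom fragments (indices within the ligand)."""

    fragments: list  # of (name, np.ndarray of ligand-atom indices)

    def __post_init__(self):
        seen = set()
        for name, idx in self.fragments:
            idx = np.asarray(idx)
            if idx.size == 0:
                raise PocketdynError(f"fragment {name} is empty")
            dup = seen.intersection(idx.tolist())
            if dup:
                raise PocketdynError(f"fragments overlap on atoms {sorted(dup)}")
            seen.update(idx.tolist())

    @property
    def names(self) -> list:
        return [n for n, _ in self.fragments]

    def __len__(self):
        return len(self.fragments)


@dataclass
class FeatureMatrix:
    """frames x (residue, fragment) reciprocal minimum distances (Å⁻¹)."""

    values: np.ndarray                     # (F, P)
    columns: list                          # of (residue_index, fragment_name)
    distance_floor: float = 0.5

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class PoseClusterResult:
    """K-means pose clusters with Silhouette / Davies-Bouldin selection."""

    labels: np.ndarray | None
    k: int | None
    silhouette: dict                 # k -> score
    davies_bouldin: dict             # k -> index
    populations: np.ndarray | None
    central_frame: dict | None       # cluster -> frame index
    members_by_distance: dict | None  # cluster -> frames sorted by distance
    chosen_rationale: dict = field(default_factory=dict)
    status: str = "ok"
    seed: int = 0


# ---------------------------------------------------------------------------
# Fragmenting
# ---------------------------------------------------------------------------

def _perceive_bonds(elements: np.ndarray, coords: np.ndarray
                    ) -> list[tuple[int, int]]:
    """Distance-based bond perception between heavy atoms."""
    n = len(elements)
    bonds = []
    big = {"S", "CL", "BR", "P", "SE", "I"}
    for i in range(n):
        for j in range(i + 1, n):
            cut = 2.1 if (str(elements[i]).upper() in big
                          or str(elements[j]).upper() in big) else 1.85
            if np.linalg.norm(coords[i] - coords[j]) < cut:
                bonds.append((i, j))
    return bonds


def _bridges(n: int, edges: list[tuple[int, int]]) -> set[tuple[int, int]]:
    """Tarjan bridge finding (iterative DFS)."""
    adj = [[] for _ in range(n)]
    for e, (a, b) in enumerate(edges):
        adj[a].append((b, e))
        adj[b].append((a, e))
    disc = [-1] * n
    low = [0] * n
    bridges = set()
    timer = 0
    for root in range(n):
        if disc[root] != -1:
            continue
        stack = [(root, -1, iter(adj[root]))]
        disc[root] = low[root] = timer
        timer += 1
        while stack:
            node, pedge, it = stack[-1]
            advanced = False
            for nb, e in it:
                if e == pedge:
                    continue
                if disc[nb] == -1:
                    disc[nb] = low[nb] = timer
                    timer += 1
                    stack.append((nb, e, iter(adj[nb])))
                    advanced = True
                    break
                low[node] = min(low[node], disc[nb])
            if not advanced:
                stack.pop()
                if stack:
                    parent = stack[-1][0]
                    low[parent] = min(low[parent], low[node])
                    if low[node] > disc[parent]:
                        a, b = edges[pedge]
                        bridges.add((min(a, b), max(a, b)))
        # restart loop continues for next component
    return bridges


def _components(n: int, edges: list[tuple[int, int]]) -> list[np.ndarray]:
    adj = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for nb in adj[v]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(np.array(sorted(comp)))
    return comps


def default_fragments(ligand_topology: Topology,
                      coords: np.ndarray) -> FragmentScheme:
    """Heuristic ligand fragmenter (a stand-in for curated fragment lists).

    Bonds are perceived by distance; acyclic single bonds (graph bridges)
    joining two non-terminal heavy atoms are cut when at least one side
    contains a ring or three or more atoms. Fragments are the resulting
    connected components, named F1..Fn in atom order.
    """
    heavy = np.flatnonzero(
        np.char.upper(ligand_topology.elements.astype(str)) != "H")
    if heavy.size < 2:
        raise PocketdynError("ligand must have at least 2 heavy atoms")
    hcoords = np.asarray(coords)[heavy]
    helems = ligand_topology.elements[heavy]
    edges = _perceive_bonds(helems, hcoords)
    n = heavy.size
    comps0 = _components(n, edges)
    if len(comps0) > 1:
        warnings.warn("disconnected ligand; fragmenting each component")
    bridges = _bridges(n, edges)
    degree = np.zeros(n, dtype=int)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    ring_atoms = set()
    for a, b in edges:
        if (min(a, b), max(a, b)) not in bridges:
            ring_atoms.update((a, b))

    def side_stats(cut_edge):
        rest = [e for e in edges
                if (min(e), max(e)) != cut_edge]
        adj = [[] for _ in range(n)]
        for a, b in rest:
            adj[a].append(b)
            adj[b].append(a)
        a0, b0 = cut_edge
        out = []
        for start in (a0, b0):
            stack, seen = [start], {start}
            while stack:
                v = stack.pop()
                for nb in adj[v]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            out.append(seen)
        return out

    cuts = []
    for a, b in sorted(bridges):
        if degree[a] < 2 or degree[b] < 2:
            continue  # terminal atom: don't shave single atoms off
        side_a, side_b = side_stats((a, b))
        ok = False
        for side in (side_a, side_b):
            if len(side) >= 3 or side & ring_atoms:
                ok = True
        if ok:
            cuts.append((a, b))
    kept = [e for e in edges if (min(e), max(e)) not in
            {(min(c), max(c)) for c in cuts}]
    comps = _components(n, kept)
    comps.sort(key=lambda c: int(c[0]))
    frags = [(f"F{i + 1}", heavy[c]) for i, c in enumerate(comps)]
    return FragmentScheme(fragments=frags)


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def residue_heavy_groups(topology: Topology,
                         residue_indices: np.ndarray | None = None,
                         atoms: str = "heavy") -> list:
    """Per-residue atom groups for the distance featurization.

    atoms="heavy" (default; ligand contacts are mostly side-chain
    mediated) or "main_chain". Only protein residues are used unless an
    explicit residue list is given.
    """
    tags = topology.molecule_tags.astype(str)
    el = np.char.upper(topology.elements.astype(str))
    names = np.char.upper(topology.atom_names.astype(str))
    if residue_indices is None:
        residue_indices = np.unique(topology.residue_index[tags == "protein"])
    groups = []
    for ri in residue_indices:
        mask = topology.residue_index == ri
        if atoms == "heavy":
            mask &= el != "H"
        elif atoms == "main_chain":
            mask &= np.isin(names, ("N", "CA", "C", "O"))
        else:
            raise PocketdynError(f"unknown atom set {atoms!r}")
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise PocketdynError(
                f"residue {topology.residue_label(int(ri))} has no atoms in "
                f"the {atoms} set")
        groups.append((int(ri), idx))
    return groups


def min_distance_matrix(trajectory: Trajectory, residue_groups: list,
                        fragments: FragmentScheme,
                        ligand_selection: AtomSelection | None = None,
                        ) -> tuple[np.ndarray, list]:
    """frames x (residue, fragment) minimum-distance matrix in Å.

    Exact: the vectorised computation is algebraically identical to the
    brute-force double loop over atom pairs. Fragment atom indices are
    within the ligand selection (default: atoms tagged ligand, in order).
    """
    top = trajectory.topology
    if ligand_selection is None:
        lig = np.flatnonzero(top.molecule_tags.astype(str) == "ligand")
    else:
        lig = ligand_selection.indices
    if lig.size == 0:
        raise PocketdynError("no ligand atoms")
    prot_atoms = np.concatenate([g for _, g in residue_groups])
    bounds = np.cumsum([0] + [g.size for _, g in residue_groups])
    frag_idx = [np.asarray(fi) for _, fi in fragments.fragments]
    ncol = len(residue_groups) * len(fragments)
    out = np.empty((trajectory.n_frames, ncol))
    for f in range(trajectory.n_frames):
        # explicit (dx²+dy²+dz²) then sqrt: bit-equal to a per-pair loop
        diff = trajectory.coords[f, prot_atoms][:, None, :] \
            - trajectory.coords[f, lig][None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
        col = 0
        for gi in range(len(residue_groups)):
            block = d[bounds[gi]:bounds[gi + 1]]
            for fi in frag_idx:
                out[f, col] = block[:, fi].min()
                col += 1
    columns = [(ri, fname)
               for ri, _ in residue_groups
               for fname in fragments.names]
    return out, columns


def reciprocal_features(distances: np.ndarray, columns: list | None = None,
                        distance_floor: float = 0.5) -> FeatureMatrix:
    """1/max(d, floor): bounded reciprocal-distance features in Å⁻¹."""
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise PocketdynError("distances must be non-negative")
    vals = 1.0 / np.maximum(d, distance_floor)
    if columns is None:
        columns = [(i, "F1") for i in range(d.shape[1])]
    return FeatureMatrix(values=vals, columns=columns,
                         distance_floor=distance_floor)


def featurize(trajectory: Trajectory, fragments: FragmentScheme,
              residue_indices: np.ndarray | None = None,
              atoms: str = "heavy", distance_floor: float = 0.5,
              ligand_selection: AtomSelection | None = None) -> FeatureMatrix:
    """Convenience: residue groups -> min distances -> reciprocals."""
    groups = residue_heavy_groups(trajectory.topology, residue_indices, atoms)
    d, cols = min_distance_matrix(trajectory, groups, fragments,
                                  ligand_selection)
    return reciprocal_features(d, cols, distance_floor)


def feature_pca(features: FeatureMatrix, n_components: int = 3
                ) -> tuple[PCAModel, Projection]:
    """Unweighted PCA of the (column-mean-centred) feature matrix.

    Features are internal coordinates, so no superposition or mass
    weighting applies.
    """
    x = features.values
    if x.shape[0] <= n_components:
        raise PocketdynError("need more frames than components")
    if np.allclose(x.var(axis=0), 0.0):
        warnings.warn("constant feature matrix; projections are all zero")
    mean, evecs, evals = pca_from_matrix(x)
    model = PCAModel(mean=mean, eigenvectors=evecs, eigenvalues=evals,
                     weights=np.ones(1), selection_label="features",
                     mass_weighted=False, dim_weights=np.ones(x.shape[1]))
    scores = (x - mean) @ evecs[:, :max(n_components, 3)]
    return model, Projection(scores=scores, source="features")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def choose_k(silhouette: dict, davies_bouldin: dict) -> tuple[int | None, dict]:
    """Deterministic k rule: max Silhouette with DB rank 1 or 2.

    Rank is by ascending Davies-Bouldin (1 = lowest). Ties on the
    Silhouette go to the smaller k. Returns (k, rationale) or
    (None, rationale) when no candidate is admissible.
    """
    ks = sorted(silhouette)
    db_sorted = sorted(ks, key=lambda k: (davies_bouldin[k], k))
    rank = {k: i + 1 for i, k in enumerate(db_sorted)}
    admissible = [k for k in ks
                  if rank[k] <= 2 and np.isfinite(silhouette[k])]
    if not admissible:
        return None, {"rule": "max silhouette, DB rank <= 2",
                      "admissible": []}
    best = max(admissible, key=lambda k: (silhouette[k], -k))
    return best, {
        "rule": "max silhouette, DB rank <= 2",
        "admissible": admissible,
        "silhouette": silhouette[best],
        "db_rank": rank[best],
    }


def cluster_poses(projection: Projection, k_candidates=range(2, 11),
                  seed: int = 0) -> PoseClusterResult:
    """K-means over the first three feature PCs, metric-guided k choice.

    Silhouette is computed on a fixed-seed subsample above
    SILHOUETTE_SUBSAMPLE frames; Davies-Bouldin always on all frames.
    """
    x = projection.scores[:, :3]
    f = x.shape[0]
    ks = sorted(int(k) for k in k_candidates)
    if not ks or ks[0] < 2 or ks[-1] >= f:
        raise PocketdynError("k candidates must lie in [2, frames-1]")
    sil, db, fits = {}, {}, {}
    if f > SILHOUETTE_SUBSAMPLE:
        sub = np.random.default_rng(seed).choice(
            f, SILHOUETTE_SUBSAMPLE, replace=False)
        sub.sort()
    else:
        sub = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed, tol=1e-6)
        labels = km.fit_predict(x)
        fits[k] = km
        db[k] = float(davies_bouldin_score(x, labels))
        if sub is not None and np.unique(labels[sub]).size > 1:
            sil[k] = float(silhouette_score(x[sub], labels[sub]))
        elif sub is None:
            sil[k] = float(silhouette_score(x, labels))
        else:
            sil[k] = float("nan")
    k, rationale = choose_k(sil, db)
    if k is None:
        return PoseClusterResult(labels=None, k=None, silhouette=sil,
                                 davies_bouldin=db, populations=None,
                                 central_frame=None, members_by_distance=None,
                                 chosen_rationale=rationale,
                                 status="no_admissible_k", seed=seed)
    km = fits[k]
    labels = km.labels_.astype(int)
    pops = np.bincount(labels, minlength=k) / labels.size
    central, members = {}, {}
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        d = np.linalg.norm(x[idx] - km.cluster_centers_[c], axis=1)
        order = np.lexsort((idx, d))          # ties -> lower frame index
        members[c] = idx[order]
        central[c] = int(idx[order[0]])
    return PoseClusterResult(labels=labels, k=k, silhouette=sil,
                             davies_bouldin=db, populations=pops,
                             central_frame=central,
                             members_by_distance=members,
                             chosen_rationale=rationale, status="ok",
                             seed=seed)


def extract_representatives(result: PoseClusterResult,
                            projection: Projection,
                            n: int = 1000) -> dict:
    """Central frame plus the n nearest cluster members, per cluster.

    Distances are Euclidean in the 3-PC feature space; clusters smaller
    than n return all members, ascending by distance (ties by frame
    index).
    """
    if result.status != "ok":
        raise PocketdynError("clustering did not select a k")
    out = {}
    for c, members in result.members_by_distance.items():
        out[c] = {
            "central": int(result.central_frame[c]),
            "frames": members[:n].tolist(),
        }
    return out
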
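"""Core data model and structure/trajectory I/O.

Internal unit conventions, used everywhere in this package:

* lengths in Å (XTC/GRO native nm are converted at the I/O boundary),
* times in ns,
* masses in amu,
* charges in elementary charge units,
* Lennard-Jones sigma in nm and epsilon in kJ/mol (the force-field
  convention, converted inside the energetics module),
* energies in kJ/mol.

Atom and frame indices are 0-based internally; author-assigned residue
numbers are preserved for reporting.

File parsing and writing is delegated to MDAnalysis; the lightweight
:class:`Topology` / :class:`Trajectory` containers keep the analysis code
free of reader state and make synthetic systems first-class citizens.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda


class PocketdynError(Exception):
    """Base class for all package errors."""


class ParseError(PocketdynError):
    """A structure or trajectory file could not be parsed."""


class TopologyError(PocketdynError):
    """Inconsistent topology or topology/trajectory mismatch."""


class SelectionError(PocketdynError):
    """An atom selection expression is invalid or selects nothing."""


# Standard atomic masses (amu), CODATA/IUPAC abridged values.
ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CU": 63.546, "ZN": 65.38, "SE": 78.971, "BR": 79.904, "I": 126.904,
}

#: Residue names recognised as water (TIP3P and friends); configurable
#: through the ``water_resnames`` argument of :func:`read_topology`.
WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP3", "TIP3P", "TIP4", "SPC", "T3P"}

ION_RESNAMES = {
    "NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU",
    "NA+", "CL-", "K+", "SOD", "CLA", "POT", "CAL", "MG2",
}

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation/disulfide variants and caps
    "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX", "CYM", "ASH", "GLH",
    "LYN", "ACE", "NME", "NMA",
}

MAIN_CHAIN_NAMES = ("N", "CA", "C", "O")


def guess_element(name: str, resname: str = "") -> str:
    """Guess the element from an atom name (PDB-style fallback).

    Digits are stripped first; a leading H then means hydrogen, otherwise
    the leading alphabetic character is used, with two-letter ion names
    resolved through the residue name.
    """
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        raise TopologyError(f"cannot guess element for atom name {name!r}")
    if resname.strip().upper() in ION_RESNAMES and stripped in ELEMENT_MASSES:
        return stripped
    if stripped[0] == "H":
        return "H"
    if stripped[:2] in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE") and \
            resname.strip().upper() not in PROTEIN_RESNAMES:
        return stripped[:2]
    return stripped[0]


def mass_of(element: str, atom_label: str = "") -> float:
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise TopologyError(
            f"unknown element {element!r} for atom {atom_label or '<unnamed>'}"
        ) from None


@dataclass
class Topology:
    """Per-atom static description of the molecular system.

    All fields are parallel numpy arrays of length ``n_atoms``. Optional
    force-field fields (``charges``, ``lj_sigma`` nm, ``lj_epsilon``
    kJ/mol, ``vdw_radius`` Å) are None until supplied.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    residue_index: np.ndarray      # 0-based, contiguous
    residue_names: np.ndarray
    residue_numbers: np.ndarray    # author numbering
    chain_ids: np.ndarray
    masses: np.ndarray
    molecule_tags: np.ndarray      # {protein, ligand, water, ion, other}
    charges: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None
    vdw_radius: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.atom_names)
        for name in ("elements", "residue_index", "residue_names",
                     "residue_numbers", "chain_ids", "masses",
                     "molecule_tags"):
            if len(getattr(self, name)) != n:
                raise TopologyError(f"field {name} has wrong length")
        if n and not np.all(np.asarray(self.masses) > 0):
            bad = int(np.argmin(self.masses))
            raise TopologyError(
                f"non-positive mass for atom {self.atom_names[bad]} (index {bad})"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return 0 if self.n_atoms == 0 else int(self.residue_index.max()) + 1

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        return np.flatnonzero(self.residue_index == residue_index)

    def residue_label(self, residue_index: int) -> str:
        i = self.residue_atoms(residue_index)
        if i.size == 0:
            raise TopologyError(f"no residue with index {residue_index}")
        a = int(i[0])
        return (f"{self.residue_names[a]}{self.residue_numbers[a]}"
                f":{self.chain_ids[a]}")

    def iter_residues(self):
        """Yield (residue_index, chain_id, residue_number, residue_name)."""
        for ri in range(self.n_residues):
            a = int(self.residue_atoms(ri)[0])
            yield ri, self.chain_ids[a], int(self.residue_numbers[a]), \
                self.residue_names[a]

    def subset(self, indices: np.ndarray) -> "Topology":
        """New Topology for the given atoms, residue indices recompacted."""
        idx = np.asarray(indices, dtype=int)
        old_res = self.residue_index[idx]
        uniq = np.unique(old_res)
        remap = {int(o): i for i, o in enumerate(uniq)}
        new_res = np.array([remap[int(r)] for r in old_res], dtype=int)

        def take(arr):
            return None if arr is None else np.asarray(arr)[idx].copy()

        return Topology(
            atom_names=take(self.atom_names),
            elements=take(self.elements),
            residue_index=new_res,
            residue_names=take(self.residue_names),
            residue_numbers=take(self.residue_numbers),
            chain_ids=take(self.chain_ids),
            masses=take(self.masses),
            molecule_tags=take(self.molecule_tags),
            charges=take(self.charges),
            lj_sigma=take(self.lj_sigma),
            lj_epsilon=take(self.lj_epsilon),
            vdw_radius=take(self.vdw_radius),
        )


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates (Å) with time stamps (ns)."""

    topology: Topology
    coords: np.ndarray                     # (n_frames, n_atoms, 3) Å
    times: np.ndarray                      # (n_frames,) ns
    box: np.ndarray | None = None          # (n_frames, 3, 3) Å or None
    provenance: dict | None = None         # e.g. replicate id, original time

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"coordinate frames have {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if len(self.times) != len(self.coords):
            raise TopologyError("times and coords disagree on frame count")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise TopologyError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class AtomSelection:
    """Ordered, unique 0-based atom indices with a human-readable label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size != np.unique(self.indices).size:
            raise SelectionError("selection indices must be unique")

    def __len__(self):
        return int(self.indices.size)


def assign_molecule_tags(residue_names: Sequence[str],
                         elements: Sequence[str],
                         residue_index: Sequence[int],
                         water_resnames: set[str] = WATER_RESNAMES,
                         ) -> np.ndarray:
    """Tag every atom as protein/water/ion/ligand/other by residue name."""
    tags = np.empty(len(residue_names), dtype=object)
    residue_index = np.asarray(residue_index)
    for ri in np.unique(residue_index):
        sel = residue_index == ri
        rn = str(np.asarray(residue_names)[sel][0]).strip().upper()
        if rn in water_resnames:
            tag = "water"
        elif rn in PROTEIN_RESNAMES:
            tag = "protein"
        elif rn in ION_RESNAMES:
            tag = "ion"
        elif "C" in [str(e).upper() for e in np.asarray(elements)[sel]]:
            tag = "ligand"
        else:
            tag = "other"
        tags[sel] = tag
    return tags.astype(object)


# ---------------------------------------------------------------------------
# MDAnalysis bridge
# ---------------------------------------------------------------------------

def _topology_from_universe(u, water_resnames=WATER_RESNAMES) -> Topology:
    atoms = u.atoms
    names = atoms.names.astype(object)
    resnames_at = atoms.resnames.astype(object)
    try:
        elements = np.array(
            [e if str(e).strip() else None for e in atoms.elements],
            dtype=object)
    except (mda.exceptions.NoDataError, AttributeError):
        elements = np.array([None] * len(atoms), dtype=object)
    out_el = []
    for nm, rn, el in zip(names, resnames_at, elements):
        if el:
            out_el.append(str(el).strip().upper()
                          if len(str(el).strip()) > 1
                          else str(el).strip().upper())
        else:
            out_el.append(guess_element(str(nm), str(rn)))
    elements = np.array(out_el, dtype=object)
    masses = np.array([mass_of(e, f"{n} in {r}")
                       for e, n, r in zip(elements, names, resnames_at)])
    try:
        chain_ids = atoms.chainIDs.astype(object)
    except (mda.exceptions.NoDataError, AttributeError):
        try:
            chain_ids = atoms.segids.astype(object)
        except (mda.exceptions.NoDataError, AttributeError):
            chain_ids = np.array(["A"] * len(atoms), dtype=object)
    chain_ids = np.array([c if str(c).strip() else "A" for c in chain_ids],
                         dtype=object)
    resindices = atoms.resindices.astype(int)
    # recompact (MDAnalysis guarantees grouping, we guarantee 0..R-1)
    uniq, new = np.unique(resindices, return_inverse=True)
    tags = assign_molecule_tags(resnames_at, elements, new, water_resnames)
    return Topology(
        atom_names=names,
        elements=elements,
        residue_index=new,
        residue_names=resnames_at,
        residue_numbers=atoms.resids.astype(int),
        chain_ids=chain_ids,
        masses=masses,
        molecule_tags=tags,
    )


def _universe_from_topology(topology: Topology, coords: np.ndarray):
    """Build an in-memory MDAnalysis Universe used for writing."""
    n = topology.n_atoms
    n_res = topology.n_residues
    # residue -> segment mapping from the chain of its first atom
    res_chain = []
    for ri in range(n_res):
        a = int(topology.residue_atoms(ri)[0])
        res_chain.append(str(topology.chain_ids[a]))
    seg_ids = sorted(set(res_chain))
    seg_index = {s: i for i, s in enumerate(seg_ids)}
    residue_segindex = np.array([seg_index[c] for c in res_chain], dtype=int)

    u = mda.Universe.empty(
        n_atoms=n, n_residues=n_res, n_segments=len(seg_ids),
        atom_resindex=topology.residue_index,
        residue_segindex=residue_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in topology.atom_names])
    u.add_TopologyAttr("elements", [str(x) for x in topology.elements])
    u.add_TopologyAttr("masses", topology.masses)
    res_names = []
    res_nums = []
    for ri in range(n_res):
        a = int(topology.residue_atoms(ri)[0])
        res_names.append(str(topology.residue_names[a]))
        res_nums.append(int(topology.residue_numbers[a]))
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", res_nums)
    u.add_TopologyAttr("segids", seg_ids)
    u.add_TopologyAttr("chainIDs", [str(c) for c in topology.chain_ids])
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.add_TopologyAttr("tempfactors", np.zeros(n))
    u.atoms.positions = np.asarray(coords, dtype=np.float32)
    return u


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lstrip(".").lower()
    return {"pdb": "pdb", "ent": "pdb", "gro": "gro", "xtc": "xtc",
            "dcd": "dcd"}.get(ext, ext)


def read_structure(path: str, fmt: str | None = None,
                   water_resnames=WATER_RESNAMES,
                   ) -> tuple[Topology, np.ndarray]:
    """Read a single-structure file, returning (Topology, coords Å)."""
    fmt = _infer_format(path, fmt)
    if fmt not in ("pdb", "gro"):
        raise ParseError(f"unsupported structure format {fmt!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path, format=fmt)
    except FileNotFoundError:
        raise
    except Exception as exc:  # MDA raises many flavors
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    top = _topology_from_universe(u, water_resnames)
    return top, u.atoms.positions.astype(float)


def read_topology(path: str, fmt: str | None = None,
                  water_resnames=WATER_RESNAMES) -> Topology:
    """Read a PDB or GRO file and return its :class:`Topology`.

    Masses are assigned from the element (standard atomic masses);
    molecule tags are assigned from residue names.
    """
    return read_structure(path, fmt, water_resnames)[0]


_READERS = {
    "xtc": "XTC", "dcd": "DCD", "pdb": "PDB", "pdb_models": "PDB",
    "gro": "GRO",
}


def read_trajectory(path: str, topology: Topology,
                    fmt: str | None = None) -> Trajectory:
    """Read a coordinate trajectory against an existing topology.

    Coordinates are converted to Å (XTC stores nm) and times to ns.
    Formats without time stamps (multi-model PDB) get the frame index
    as the time in ns.
    """
    fmt = _infer_format(path, fmt)
    if fmt not in _READERS:
        raise ParseError(f"unsupported trajectory format {fmt!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    from MDAnalysis import coordinates as mdacoords
    reader_cls = {
        "XTC": mdacoords.XTC.XTCReader,
        "DCD": mdacoords.DCD.DCDReader,
        "PDB": mdacoords.PDB.PDBReader,
        "GRO": mdacoords.GRO.GROReader,
    }[_READERS[fmt]]
    try:
        reader = reader_cls(path)
    except Exception as exc:
        raise ParseError(f"cannot open {path}: {exc}") from exc
    if reader.n_atoms != topology.n_atoms:
        raise TopologyError(
            f"atom count mismatch: file {path} has {reader.n_atoms} atoms, "
            f"topology has {topology.n_atoms}"
        )
    frames, times, boxes = [], [], []
    has_time = _READERS[fmt] in ("XTC", "DCD")
    try:
        for i, ts in enumerate(reader):
            frames.append(ts.positions.astype(float).copy())
            times.append(float(ts.time) / 1000.0 if has_time else float(i))
            if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
                from MDAnalysis.lib.mdamath import triclinic_vectors
                boxes.append(triclinic_vectors(ts.dimensions).astype(float))
            else:
                boxes.append(None)
    except Exception as exc:
        if not frames:
            raise ParseError(f"cannot read any frame from {path}: {exc}")
        warnings.warn(
            f"truncated trajectory {path}: last good frame {len(frames) - 1} "
            f"({exc})"
        )
    box = None
    if all(b is not None for b in boxes) and boxes:
        box = np.array(boxes)
    return Trajectory(topology=topology, coords=np.array(frames),
                      times=np.array(times), box=box)


def write_frames(trajectory: Trajectory, frame_indices: Sequence[int],
                 path: str, fmt: str | None = None) -> str:
    """Write selected frames to pdb_models/xtc/dcd/gro.

    Output is bit-stable for fixed input; PDB occupancy is 1.00 and
    B-factor 0.00.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "pdb_models":
        fmt = "pdb"
    if fmt not in ("pdb", "gro", "xtc", "dcd"):
        raise ParseError(f"unsupported output format {fmt!r}")
    idx = list(frame_indices)
    if len(idx) == 0:
        raise PocketdynError("empty frame index list")
    for i in idx:
        if not (0 <= int(i) < trajectory.n_frames):
            raise PocketdynError(
                f"frame index {i} out of range 0..{trajectory.n_frames - 1}")
    if fmt == "gro" and len(idx) != 1:
        raise PocketdynError("GRO output holds exactly one frame")
    u = _universe_from_topology(trajectory.topology, trajectory.coords[idx[0]])
    dims = None
    if trajectory.box is not None:
        from MDAnalysis.lib.mdamath import triclinic_box
        b = trajectory.box[idx[0]]
        dims = triclinic_box(b[0], b[1], b[2])
    else:
        # writers for XTC need some box; a zero box means "no box"
        dims = np.zeros(6, dtype=np.float32)
    if fmt == "gro":
        # 4-decimal variable-precision GRO (0.0001 nm = 0.001 Å), the
        # GROMACS "%n.me, n = m+5" convention; standard readers accept it
        _write_gro_highprec(trajectory, int(idx[0]), path)
        return path
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt in ("pdb", "gro"):
            with mda.Writer(path, n_atoms=trajectory.n_atoms,
                            multiframe=(fmt == "pdb")) as w:
                for i in idx:
                    u.atoms.positions = trajectory.coords[int(i)].astype(
                        np.float32)
                    u.trajectory.ts.dimensions = dims
                    w.write(u.atoms)
        else:
            with mda.Writer(path, n_atoms=trajectory.n_atoms) as w:
                for k, i in enumerate(idx):
                    u.atoms.positions = trajectory.coords[int(i)].astype(
                        np.float32)
                    ts = u.trajectory.ts
                    ts.frame = k
                    ts.time = float(trajectory.times[int(i)]) * 1000.0  # ps
                    ts.dimensions = dims
                    w.write(u.atoms)
    return path


def _write_gro_highprec(trajectory: Trajectory, frame: int, path: str):
    top = trajectory.topology
    coords_nm = trajectory.coords[frame] / 10.0
    with open(path, "w") as fh:
        fh.write("written by pocketdyn\n")
        fh.write(f"{top.n_atoms:5d}\n")
        for i in range(top.n_atoms):
            fh.write(
                f"{int(top.residue_numbers[i]) % 100000:5d}"
                f"{str(top.residue_names[i])[:5]:<5s}"
                f"{str(top.atom_names[i])[:5]:>5s}"
                f"{(i + 1) % 100000:5d}"
                f"{coords_nm[i, 0]:9.4f}{coords_nm[i, 1]:9.4f}"
                f"{coords_nm[i, 2]:9.4f}\n")
        if trajectory.box is not None:
            b = trajectory.box[frame] / 10.0
            fh.write(f"{b[0, 0]:10.5f}{b[1, 1]:10.5f}{b[2, 2]:10.5f}\n")
        else:
            fh.write(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def _term_mask(topology: Topology, term: str) -> np.ndarray:
    term = term.strip()
    n = topology.n_atoms
    names = np.char.upper(topology.atom_names.astype(str))
    low = term.lower()
    if low == "all":
        return np.ones(n, dtype=bool)
    if low in ("protein", "ligand", "water", "ion", "other"):
        return topology.molecule_tags.astype(str) == low
    if low == "main_chain":
        return (np.isin(names, MAIN_CHAIN_NAMES)
                & (topology.molecule_tags.astype(str) == "protein"))
    if low == "calpha":
        return ((names == "CA")
                & (topology.molecule_tags.astype(str) == "protein"))
    if low == "heavy":
        return np.char.upper(topology.elements.astype(str)) != "H"
    if low == "hydrogen":
        return np.char.upper(topology.elements.astype(str)) == "H"
    if low == "sidechain":
        return ((topology.molecule_tags.astype(str) == "protein")
                & ~np.isin(names, MAIN_CHAIN_NAMES))
    if low == "water_oxygen":
        return ((topology.molecule_tags.astype(str) == "water")
                & (np.char.upper(topology.elements.astype(str)) == "O"))
    if low.startswith("not "):
        return ~_term_mask(topology, term[4:])
    parts = term.split(None, 1)
    if len(parts) == 2:
        key, value = parts[0].lower(), parts[1].strip()
        if key == "chain":
            return np.isin(topology.chain_ids.astype(str), value.split(","))
        if key == "resname":
            return np.isin(np.char.upper(topology.residue_names.astype(str)),
                           [v.upper() for v in value.split(",")])
        if key == "name":
            return np.isin(names, [v.upper() for v in value.split(",")])
        if key == "element":
            return np.isin(np.char.upper(topology.elements.astype(str)),
                           [v.upper() for v in value.split(",")])
        if key in ("resnum", "resid"):
            mask = np.zeros(n, dtype=bool)
            for chunk in value.split(","):
                if "-" in chunk[1:]:  # allow negative start, not used in practice
                    a, b = chunk.rsplit("-", 1) if not chunk.startswith("-") \
                        else (chunk, chunk)
                    lo, hi = int(a), int(b)
                    mask |= ((topology.residue_numbers >= lo)
                             & (topology.residue_numbers <= hi))
                else:
                    mask |= topology.residue_numbers == int(chunk)
            return mask
    raise SelectionError(f"unknown selection term {term!r}")


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression (terms joined by ``and``).

    Supported terms: ``protein``, ``ligand``, ``water``, ``ion``,
    ``main_chain``, ``sidechain``, ``calpha``, ``heavy``, ``hydrogen``,
    ``water_oxygen``, ``all``, ``not <term>``, ``chain A``,
    ``resnum 228-255``, ``resname LIG``, ``name CA,CB``, ``element O``.
    An empty result is an error, never a silent empty selection.
    """
    if not expression or not expression.strip():
        raise SelectionError("empty selection expression")
    mask = np.ones(topology.n_atoms, dtype=bool)
    for term in expression.split(" and "):
        mask &= _term_mask(topology, term)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {expression!r} matches no atoms")
    return AtomSelection(indices=idx, label=expression)


# ---------------------------------------------------------------------------
# Trajectory assembly
# ---------------------------------------------------------------------------

def concatenate_trim(trajectories: Sequence[Trajectory],
                     discard_before: float) -> Trajectory:
    """Discard the head of each replicate and concatenate the remainders.

    Frames with ``time < discard_before`` (ns) are removed per replicate;
    the survivors are concatenated in input order. Output times are made
    continuous (each replicate re-zeroed at the cutoff and offset by the
    accumulated span); the original replicate id and time stamps are kept
    in ``provenance``.
    """
    if not trajectories:
        raise PocketdynError("no trajectories given")
    top = trajectories[0].topology
    for t in trajectories[1:]:
        if t.topology.n_atoms != top.n_atoms or \
                not np.array_equal(t.topology.atom_names, top.atom_names):
            raise TopologyError("trajectories have incompatible topologies")
    coords, times, rep_ids, orig_times = [], [], [], []
    offset = 0.0
    for r, t in enumerate(trajectories):
        keep = t.times >= discard_before
        if not np.any(keep):
            raise PocketdynError(
                f"no frames remain in replicate {r} after discarding "
                f"t < {discard_before} ns")
        tt = t.times[keep]
        coords.append(t.coords[keep])
        times.append(tt - discard_before + offset)
        rep_ids.append(np.full(int(keep.sum()), r, dtype=int))
        orig_times.append(tt)
        offset += float(tt[-1] - discard_before)
    return Trajectory(
        topology=top,
        coords=np.concatenate(coords, axis=0),
        times=np.concatenate(times),
        provenance={
            "replicate": np.concatenate(rep_ids),
            "original_time": np.concatenate(orig_times),
        },
    )


def load_parameter_table(path: str, topology: Topology) -> Topology:
    """Attach per-atom charges and LJ parameters from a whitespace/TSV table.

    Expected columns: atom index (0-based), charge (e), sigma (nm),
    epsilon (kJ/mol). Lines starting with ``#`` are ignored. Returns a
    new Topology; every atom must be covered.
    """
    charges = np.full(topology.n_atoms, np.nan)
    sigma = np.full(topology.n_atoms, np.nan)
    eps = np.full(topology.n_atoms, np.nan)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: expected 4 columns")
            i = int(parts[0])
            if not (0 <= i < topology.n_atoms):
                raise ParseError(f"{path}:{ln}: atom index {i} out of range")
            charges[i], sigma[i], eps[i] = map(float, parts[1:4])
    missing = np.flatnonzero(np.isnan(charges))
    if missing.size:
        raise TopologyError(
            f"parameter table misses atoms {missing[:10].tolist()}"
            + ("..." if missing.size > 10 else ""))
    return dataclasses.replace(topology, charges=charges, lj_sigma=sigma,
                               lj_epsilon=eps)
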
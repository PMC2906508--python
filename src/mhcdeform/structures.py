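"""Structures, trajectories and region selections.

This module defines the in-memory model every analysis stage consumes: a
:class:`Structure` (an ordered list of atoms in one conformation), a
:class:`Trajectory` (one topology plus a ``T x N x 3`` coordinate tensor with
times in nanoseconds) and a :class:`RegionSelection` (a named residue-interval
selection on one chain, restricted to an atom subset).

Coordinates are stored in Angstrom throughout; conversion to nanometres
happens only at the reporting boundary of the deformation metrics.  Residue
numbering is the author numbering of the input file — spans such as
residues 65-69 of an MHC alpha1-helix are addressed exactly as published,
with no renumbering.

PDB input/output is delegated to :mod:`biotite`; a light pre-scan of the raw
file adds the error context (model number, line number) that matters when a
multi-model trajectory file is malformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure import infer_elements
from biotite.structure.info import mass as element_mass
from biotite.structure.io.pdb import PDBFile


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be interpreted as a structure/trajectory."""


class SelectionError(ValueError):
    """Raised when a region selection cannot be resolved against a structure."""


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


#: Named atom subsets used by :class:`RegionSelection`.
ATOM_SUBSETS = {
    "CA": ("CA",),
    "BACKBONE": ("N", "CA", "C", "O"),
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, in file order.

    ``mass`` is in amu and derived from the element; ``coords`` are Angstrom.
    """

    serial: int
    atom_name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    coords: tuple[float, float, float]
    i_code: str = ""
    mass: float = field(default=0.0)

    def __post_init__(self):
        if self.mass <= 0.0:
            m = element_mass(self.element.capitalize() if len(self.element) > 1
                             else self.element.upper())
            if m is None or m <= 0:
                raise ValidationError(
                    f"cannot derive a positive mass for element {self.element!r} "
                    f"(atom {self.atom_name} {self.chain_id}{self.res_seq})"
                )
            object.__setattr__(self, "mass", float(m))
        if not all(math.isfinite(c) for c in self.coords):
            raise ValidationError(
                f"non-finite coordinates for atom {self.atom_name} "
                f"{self.chain_id}{self.res_seq}: {self.coords}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.res_seq, self.i_code, self.atom_name)


class Structure:
    """An ordered set of atoms forming one conformation.

    Atoms must be grouped contiguously by (chain_id, res_seq) in file order
    and atom identities (chain, residue, insertion code, name) must be unique.
    """

    def __init__(self, atoms: Sequence[AtomRecord], id: str = ""):
        atoms = tuple(atoms)
        if not atoms:
            raise ValidationError("a Structure must contain at least one atom")
        keys = [a.key for a in atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValidationError(f"duplicate atom identity {dup} in structure")
        # residues must not be interleaved
        res_order = []
        for a in atoms:
            rk = (a.chain_id, a.res_seq, a.i_code)
            if not res_order or res_order[-1] != rk:
                res_order.append(rk)
        if len(set(res_order)) != len(res_order):
            raise ValidationError("atoms of one residue are not contiguous")
        self.atoms = atoms
        self.id = id
        self._coords = np.array([a.coords for a in atoms], dtype=np.float64)
        self._chain_ids = np.array([a.chain_id for a in atoms])
        self._res_seqs = np.array([a.res_seq for a in atoms], dtype=np.int64)
        self._atom_names = np.array([a.atom_name for a in atoms])
        self._elements = np.array([a.element for a in atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"<Structure {self.id!r}: {len(self)} atoms>"

    @property
    def coords(self) -> np.ndarray:
        """``(N, 3)`` coordinate array, Angstrom."""
        return self._coords

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def chains(self) -> list[str]:
        out: list[str] = []
        for c in self._chain_ids:
            if c not in out:
                out.append(c)
        return out

    def residues(self, chain_id: str) -> list[int]:
        """Residue numbers present on a chain, in file order."""
        mask = self._chain_ids == chain_id
        out: list[int] = []
        for r in self._res_seqs[mask]:
            if not out or out[-1] != r:
                out.append(int(r))
        return out

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (len(self), 3):
            raise ValidationError(
                f"coordinate shape {coords.shape} does not match atom count {len(self)}"
            )
        atoms = [replace(a, coords=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, id=self.id if id is None else id)


@dataclass
class Trajectory:
    """A topology plus ``T`` coordinate frames (Angstrom) with times in ns."""

    topology: Structure
    frames: np.ndarray
    times: np.ndarray
    id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError(f"frames must be (T, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.topology):
            raise ValidationError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )
        if self.frames.shape[0] < 1:
            raise ValidationError("a Trajectory needs at least one frame")
        if self.times.shape != (self.frames.shape[0],):
            raise ValidationError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int, id: str | None = None) -> Structure:
        return self.topology.with_coords(
            self.frames[i], id=id if id is not None else f"{self.id}[frame {i}]"
        )

    def window_indices(self, t0: float, t1: float) -> np.ndarray:
        """Indices of frames with t0 <= time <= t1; error if empty."""
        idx = np.nonzero((self.times >= t0) & (self.times <= t1))[0]
        if idx.size == 0:
            raise ValueError(
                f"time window [{t0}, {t1}] ns selects no frames; trajectory "
                f"covers [{self.times[0]:g}, {self.times[-1]:g}] ns"
            )
        return idx


@dataclass(frozen=True)
class RegionSelection:
    """A named residue-interval selection on one chain.

    ``atom_subset`` is one of ``"CA"``, ``"BACKBONE"`` (N, CA, C, O),
    ``"HEAVY"``, ``"ALL"`` or an explicit tuple of atom names.
    """

    name: str
    chain_id: str
    residue_intervals: tuple[tuple[int, int], ...]
    atom_subset: str | tuple[str, ...] = "BACKBONE"

    def __post_init__(self):
        if not self.residue_intervals:
            raise ValidationError(f"selection {self.name!r} has no residue intervals")
        object.__setattr__(
            self,
            "residue_intervals",
            tuple((int(a), int(b)) for a, b in self.residue_intervals),
        )
        for a, b in self.residue_intervals:
            if a > b:
                raise ValidationError(
                    f"selection {self.name!r}: interval [{a}, {b}] has start > end"
                )
        if isinstance(self.atom_subset, list):
            object.__setattr__(self, "atom_subset", tuple(self.atom_subset))

    @classmethod
    def span(
        cls,
        name: str,
        chain_id: str,
        start: int,
        end: int,
        atom_subset: str | tuple[str, ...] = "BACKBONE",
    ) -> "RegionSelection":
        """Convenience constructor for a single contiguous residue span."""
        return cls(name, chain_id, ((start, end),), atom_subset)

    @property
    def single_interval(self) -> tuple[int, int]:
        if len(self.residue_intervals) != 1:
            raise ValidationError(
                f"selection {self.name!r} has {len(self.residue_intervals)} "
                "intervals where exactly one is required"
            )
        return self.residue_intervals[0]


def _subset_mask(struct: Structure, atom_subset: str | tuple[str, ...]) -> np.ndarray:
    if isinstance(atom_subset, tuple):
        return np.isin(struct._atom_names, atom_subset)
    if atom_subset == "ALL":
        return np.ones(len(struct), dtype=bool)
    if atom_subset == "HEAVY":
        return struct._elements != "H"
    if atom_subset in ATOM_SUBSETS:
        return np.isin(struct._atom_names, ATOM_SUBSETS[atom_subset])
    raise SelectionError(f"unknown atom subset {atom_subset!r}")


def resolve_selection(struct: Structure, sel: RegionSelection) -> np.ndarray:
    """Resolve a region selection to an ordered array of atom indices.

    Indices are in topology order and the result is deterministic.  Raises
    :class:`SelectionError` if the chain is absent or no atom matches.
    """
    chain_mask = struct._chain_ids == sel.chain_id
    if not chain_mask.any():
        raise SelectionError(
            f"selection {sel.name!r}: chain {sel.chain_id!r} not present "
            f"(available: {struct.chains()})"
        )
    res_mask = np.zeros(len(struct), dtype=bool)
    for a, b in sel.residue_intervals:
        res_mask |= (struct._res_seqs >= a) & (struct._res_seqs <= b)
    mask = chain_mask & res_mask & _subset_mask(struct, sel.atom_subset)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise SelectionError(
            f"selection {sel.name!r}: no atoms matched chain {sel.chain_id!r} "
            f"intervals {list(sel.residue_intervals)} subset {sel.atom_subset!r}"
        )
    return idx


def flank_selection(
    sel: RegionSelection, n_flank: int, struct: Structure | None = None
) -> RegionSelection:
    """Selection covering the ``n_flank`` residues on each side of a span.

    The returned selection excludes the span itself: for a span [s, e] it
    covers [s - n_flank, s - 1] and [e + 1, e + n_flank] on the same chain
    with the same atom subset.  If ``struct`` is given, every flank residue
    must exist on the chain, otherwise a :class:`SelectionError` is raised
    (the caller must shrink or re-site the span).
    """
    if n_flank < 1:
        raise ValidationError("n_flank must be >= 1")
    start, end = sel.single_interval
    intervals = ((start - n_flank, start - 1), (end + 1, end + n_flank))
    flank = RegionSelection(
        name=f"{sel.name}_flank{n_flank}",
        chain_id=sel.chain_id,
        residue_intervals=intervals,
        atom_subset=sel.atom_subset,
    )
    if struct is not None:
        present = set(struct.residues(sel.chain_id))
        needed = [r for a, b in intervals for r in range(a, b + 1)]
        missing = sorted(set(needed) - present)
        if missing:
            raise SelectionError(
                f"flank of {sel.name!r} extends past chain {sel.chain_id!r} "
                f"termini: residues {missing} absent"
            )
    return flank


# ---------------------------------------------------------------------------
# PDB input / output


def _prescan_pdb(path: Path) -> list[int]:
    """Count ATOM/HETATM records per model and float-check coordinate fields.

    Returns per-model atom counts (a single entry for files without MODEL
    records).  Raises :class:`PDBFormatError` with a line number on the first
    unparseable coordinate field, or naming the offending model on an atom
    count mismatch.
    """
    counts: list[int] = []
    current = 0
    in_model = False
    any_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                any_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fld = line[lo:hi]
                    try:
                        float(fld)
                    except ValueError:
                        raise PDBFormatError(
                            f"{path}: unparseable {what} coordinate field "
                            f"{fld!r} at line {lineno}"
                        ) from None
                current += 1
    if not any_model:
        counts = [current]
    elif in_model:  # MODEL without ENDMDL — count it anyway
        counts.append(current)
    if not counts or sum(counts) == 0:
        raise PDBFormatError(f"{path}: no ATOM records found")
    ref = counts[0]
    for i, c in enumerate(counts[1:], start=2):
        if c != ref:
            raise PDBFormatError(
                f"{path}: model {i} has {c} atoms, expected {ref} (model 1)"
            )
    return counts


def _atoms_from_array(arr: bst.AtomArray) -> list[AtomRecord]:
    elements = np.asarray(arr.element)
    blank = elements == ""
    if blank.any():
        inferred = infer_elements(arr.atom_name)
        elements = np.where(blank, inferred, elements)
    ins = (
        np.asarray(arr.ins_code)
        if "ins_code" in arr.get_annotation_categories()
        else np.full(arr.array_length(), "")
    )
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                atom_name=str(arr.atom_name[i]),
                element=str(elements[i]),
                res_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                res_seq=int(arr.res_id[i]),
                i_code=str(ins[i]).strip(),
                coords=tuple(float(c) for c in arr.coord[i]),
            )
        )
    return atoms


def read_pdb(path: str | Path, dt: float = 0.001, id: str | None = None):
    """Read a PDB file into a :class:`Structure` or :class:`Trajectory`.

    A single-model file yields a Structure; a multi-model (MODEL/ENDMDL)
    file yields a Trajectory whose frame times are ``frame_index * dt`` ns.
    Atom ordering must be identical across models.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    label = id if id is not None else path.stem
    if n_models == 1:
        arr = pdb.get_structure(model=1)
        return Structure(_atoms_from_array(arr), id=label)
    stack = pdb.get_structure(model=None)
    topo = Structure(_atoms_from_array(stack[0]), id=label)
    times = np.arange(n_models, dtype=np.float64) * dt
    return Trajectory(topology=topo, frames=np.asarray(stack.coord), times=times, id=label)


def _array_from_structure(struct: Structure) -> bst.AtomArray:
    n = len(struct)
    arr = bst.AtomArray(n)
    arr.coord = struct.coords.astype(np.float32)
    arr.chain_id = struct._chain_ids
    arr.res_id = struct._res_seqs
    arr.ins_code = np.array([a.i_code for a in struct.atoms], dtype="U1")
    arr.res_name = np.array([a.res_name for a in struct.atoms])
    arr.atom_name = struct._atom_names
    arr.element = struct._elements
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a Structure (single model) or Trajectory (MODEL/ENDMDL blocks)."""
    path = Path(path)
    if isinstance(obj, Structure):
        arr = _array_from_structure(obj)
    elif isinstance(obj, Trajectory):
        base = _array_from_structure(obj.topology)
        arr = bst.AtomArrayStack(obj.n_frames, len(obj.topology))
        for cat in base.get_annotation_categories():
            arr.set_annotation(cat, base.get_annotation(cat))
        arr.coord = obj.frames.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__} as PDB")
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
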
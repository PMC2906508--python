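"""Backbone hydrogen bonds and alpha-helix conformity.

The question this module answers is binary and local: does a residue span
still conform to the definition of an alpha-helix in a given frame?  The
operational criterion is the classic electrostatic backbone hydrogen-bond
energy of Kabsch & Sander,

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  kcal/mol,

with a bond accepted when E < -0.5 kcal/mol, combined with the minimal-helix
rule: residue i is labelled H when i->i+4 turns exist at both i-1 and i
(two consecutive i->i+4 hydrogen bonds).  Amide hydrogens are rebuilt
geometrically (1.01 A from N, along the preceding C=O direction) since MD
snapshots and crystal structures routinely lack them.

The energy constant (0.084 * 332) and the -0.5 kcal/mol threshold are fixed,
not configurable, so assignments stay comparable across runs.  Extended /
sheet states are not distinguished; anything that is not helical is 'C'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import RegionSelection, SelectionError, Structure, Trajectory

KS_CONSTANT = 0.084 * 332.0  # kcal/mol * A
HBOND_THRESHOLD = -0.5  # kcal/mol
NH_LENGTH = 1.01  # A
_MIN_SEQ_SEP = 2  # no bonds between a residue and itself or its neighbour
_CA_PREFILTER = 9.0  # A, coarse donor-acceptor distance cut


@dataclass(frozen=True)
class HBond:
    """An accepted backbone hydrogen bond, donor N-H to acceptor C=O."""

    donor: tuple[str, int]  # (chain_id, res_seq) of the N-H residue
    acceptor: tuple[str, int]  # (chain_id, res_seq) of the C=O residue
    energy: float  # kcal/mol


@dataclass
class SSAssignment:
    """Per-residue secondary-structure labels, 'H' (alpha-helix) or 'C'."""

    labels: dict[tuple[str, int], str]

    def label(self, chain_id: str, res_seq: int) -> str:
        return self.labels.get((chain_id, res_seq), "C")

    def chain_string(self, struct: Structure, chain_id: str) -> str:
        return "".join(self.label(chain_id, r) for r in struct.residues(chain_id))


@dataclass
class HelicitySeries:
    """Per-frame fraction of a span's residues labelled H, plus the mean."""

    times: np.ndarray
    fractions: np.ndarray
    mean: float
    span: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "fraction": self.fractions})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class _Segment:
    """A run of consecutive residues on one chain with full backbone."""

    chain_id: str
    res_seqs: list[int]
    n_idx: np.ndarray
    ca_idx: np.ndarray
    c_idx: np.ndarray
    o_idx: np.ndarray
    is_pro: np.ndarray


def _backbone_segments(struct: Structure) -> list[_Segment]:
    """Split each chain into runs of consecutive residues with N, CA, C, O.

    Residues missing backbone atoms are skipped with a warning; a gap in
    residue numbering also breaks a segment (no H can be inferred across it).
    """
    segments: list[_Segment] = []
    by_res: dict[tuple[str, int], dict[str, int]] = {}
    res_meta: dict[tuple[str, int], str] = {}
    order: list[tuple[str, int]] = []
    for i, atom in enumerate(struct.atoms):
        key = (atom.chain_id, atom.res_seq)
        if key not in by_res:
            by_res[key] = {}
            res_meta[key] = atom.res_name
            order.append(key)
        if atom.atom_name in ("N", "CA", "C", "O"):
            by_res[key][atom.atom_name] = i

    def flush(buf: list[tuple[tuple[str, int], dict[str, int]]]):
        if not buf:
            return
        chain = buf[0][0][0]
        segments.append(
            _Segment(
                chain_id=chain,
                res_seqs=[k[1] for k, _ in buf],
                n_idx=np.array([d["N"] for _, d in buf]),
                ca_idx=np.array([d["CA"] for _, d in buf]),
                c_idx=np.array([d["C"] for _, d in buf]),
                o_idx=np.array([d["O"] for _, d in buf]),
                is_pro=np.array([res_meta[k] == "PRO" for k, _ in buf]),
            )
        )

    buf: list[tuple[tuple[str, int], dict[str, int]]] = []
    for key in order:
        d = by_res[key]
        if len(d) < 4:
            warnings.warn(
                f"residue {key[0]}{key[1]} lacks a full backbone "
                "(N, CA, C, O); skipped in secondary-structure assignment",
                stacklevel=3,
            )
            flush(buf)
            buf = []
            continue
        if buf and not (key[0] == buf[-1][0][0] and key[1] == buf[-1][0][1] + 1):
            flush(buf)
            buf = []
        buf.append((key, d))
    flush(buf)
    return segments


def _amide_h(coords: np.ndarray, seg: _Segment) -> np.ndarray:
    """Inferred amide H positions for residues 1.. of a segment.

    ``coords`` may be ``(N, 3)`` or ``(T, N, 3)``; the leading residue of a
    segment (no preceding C=O) and prolines get NaN (no donor).  The N-H
    vector points along the preceding C=O bond (O -> C direction), the
    standard reconstruction for hydrogen-less models.
    """
    n = coords[..., seg.n_idx, :]
    h = np.full_like(n, np.nan)
    if len(seg.res_seqs) < 2:
        return h
    c_prev = coords[..., seg.c_idx[:-1], :]
    o_prev = coords[..., seg.o_idx[:-1], :]
    co = c_prev - o_prev
    co /= np.linalg.norm(co, axis=-1, keepdims=True)
    h[..., 1:, :] = n[..., 1:, :] + NH_LENGTH * co
    h[..., seg.is_pro, :] = np.nan
    return h


def _ks_energy(c_a, o_a, n_d, h_d) -> np.ndarray:
    """Kabsch-Sander electrostatic energy, broadcastable over leading axes."""
    r_on = np.linalg.norm(o_a - n_d, axis=-1)
    r_ch = np.linalg.norm(c_a - h_d, axis=-1)
    r_oh = np.linalg.norm(o_a - h_d, axis=-1)
    r_cn = np.linalg.norm(c_a - n_d, axis=-1)
    return KS_CONSTANT * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def backbone_hbonds(struct: Structure) -> list[HBond]:
    """All accepted backbone hydrogen bonds in a structure.

    Pairs closer than two positions in sequence are excluded, as are donor/
    acceptor pairs whose CA atoms are further apart than 9 A (the energy is
    then far above threshold).  Cross-chain bonds are allowed.
    """
    segments = _backbone_segments(struct)
    coords = struct.coords
    # flatten all residues with their per-segment amide H
    ca, c, o, n, h, keys, segpos = [], [], [], [], [], [], []
    for si, seg in enumerate(segments):
        hh = _amide_h(coords, seg)
        for j in range(len(seg.res_seqs)):
            ca.append(coords[seg.ca_idx[j]])
            c.append(coords[seg.c_idx[j]])
            o.append(coords[seg.o_idx[j]])
            n.append(coords[seg.n_idx[j]])
            h.append(hh[j])
            keys.append((seg.chain_id, seg.res_seqs[j]))
            segpos.append((si, j))
    ca_arr = np.array(ca)
    bonds: list[HBond] = []
    for di in range(len(keys)):
        if np.any(np.isnan(h[di])):
            continue  # no amide H: segment start or proline
        dist = np.linalg.norm(ca_arr - ca_arr[di], axis=1)
        for ai in np.nonzero(dist < _CA_PREFILTER)[0]:
            if segpos[di][0] == segpos[ai][0] and abs(segpos[di][1] - segpos[ai][1]) < _MIN_SEQ_SEP:
                continue
            e = float(_ks_energy(c[ai], o[ai], n[di], h[di]))
            if e < HBOND_THRESHOLD:
                bonds.append(HBond(donor=keys[di], acceptor=keys[int(ai)], energy=e))
    return bonds


def _turn_energies(coords: np.ndarray, seg: _Segment) -> np.ndarray:
    """Energies of the i -> i+4 turn bonds of one segment.

    ``coords`` is ``(N, 3)`` or ``(T, N, 3)``; returns an array over
    positions ``0 .. len(seg) - 5`` (leading axes preserved): entry p is the
    energy of acceptor residue p with donor residue p+4.  NaN where the
    donor has no amide hydrogen.
    """
    k = len(seg.res_seqs)
    if k < 5:
        return np.full(coords.shape[:-2] + (0,), np.nan)
    h = _amide_h(coords, seg)
    c_a = coords[..., seg.c_idx[:-4], :]
    o_a = coords[..., seg.o_idx[:-4], :]
    n_d = coords[..., seg.n_idx[4:], :]
    h_d = h[..., 4:, :]
    return _ks_energy(c_a, o_a, n_d, h_d)


def assign_ss(struct: Structure) -> SSAssignment:
    """Label every residue H (alpha-helical) or C.

    Residue at segment position p is H when i->i+4 turn bonds exist with
    acceptors at both p-1 and p.  Terminal residues can never be H (they
    lack one of the two required turns).
    """
    labels: dict[tuple[str, int], str] = {}
    for seg in _backbone_segments(struct):
        e = _turn_energies(struct.coords, seg)
        turn = np.nan_to_num(e, nan=np.inf) < HBOND_THRESHOLD
        for p, r in enumerate(seg.res_seqs):
            is_h = 1 <= p < turn.size and bool(turn[p - 1]) and bool(turn[p])
            labels[(seg.chain_id, r)] = "H" if is_h else "C"
    return SSAssignment(labels)


def span_helicity(traj: Trajectory, span: RegionSelection) -> HelicitySeries:
    """Per-frame fraction of a span's residues that are alpha-helical.

    The span's H labels need hydrogen-bond partners up to four residues
    beyond each end, so the chain must extend at least one residue before
    the span and four after it; otherwise a :class:`SelectionError` asks
    for padding.  The turn energies are evaluated vectorised over all
    frames, which keeps 20k-frame trajectories cheap.
    """
    start, end = span.single_interval
    seg = None
    for s in _backbone_segments(traj.topology):
        if s.chain_id == span.chain_id and s.res_seqs[0] <= start and end <= s.res_seqs[-1]:
            seg = s
            break
    if seg is None:
        raise SelectionError(
            f"span {span.name!r} does not lie inside a contiguous backbone "
            f"segment of chain {span.chain_id!r}"
        )
    p0 = seg.res_seqs.index(start)
    p1 = seg.res_seqs.index(end)
    if p0 < 1 or p1 + 4 > len(seg.res_seqs) - 1:
        raise SelectionError(
            f"span {span.name!r} is too close to the chain terminus for "
            "i->i+4 hydrogen-bond partners; pad the chain by at least one "
            "residue before the span and four after it"
        )
    e = _turn_energies(traj.frames, seg)  # (T, K-4)
    turn = np.nan_to_num(e, nan=np.inf) < HBOND_THRESHOLD
    # residue at position p is H iff turns at p-1 and p
    is_h = turn[:, p0 - 1 : p1] & turn[:, p0 : p1 + 1]
    fractions = is_h.mean(axis=1)
    return HelicitySeries(
        times=traj.times,
        fractions=fractions,
        mean=float(fractions.mean()),
        span=span.name,
    )
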
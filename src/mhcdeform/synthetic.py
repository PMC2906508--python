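"""Synthetic conformational ensembles with known injected deformation.

Real MD trajectories of a peptide-MHC complex are expensive and carry no
ground truth; this module builds statistical stand-ins whose every feature
is controlled: an ideal poly-alanine alpha-helix (optionally with a second
groove-wall helix, a sheet-like floor slab and a lysine-like probe residue
seated in a pocket), temporally correlated thermal noise (an
Ornstein-Uhlenbeck process per atom per coordinate), a deformation that
grows over simulation time (either confined to a residue span or spread
over the whole helix as a bending mode), optional escape of the probe from
the pocket, and global rigid-body tumbling.

The generator fakes statistics, not physics: no force field, solvent or
thermostat is involved.  Its purpose is to give every analysis stage a test
bed whose correct answer is known by construction.

Geometry is built by internal-coordinate (NeRF) chain extension with
standard backbone bond lengths and angles; the canonical helix dihedrals
(phi = -57 deg, psi = -47 deg) yield a rise of ~1.5 A per residue, ~100 deg
twist and CA-CA distances of ~3.8 A, and the rebuilt amide hydrogens form
the i -> i+4 hydrogen bonds an alpha-helix requires.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .structures import AtomRecord, RegionSelection, Structure, Trajectory

# backbone internal coordinates (A / degrees), standard values
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
HELIX_PHI, HELIX_PSI = -57.0, -47.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: new atom at given internal coordinates from a-b-c."""
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * (-np.cos(theta) * bc + np.sin(theta) * (np.cos(phi) * m + np.sin(phi) * n))
    return c + d


def _build_backbone(n_residues: int, phi: float, psi: float) -> dict[str, np.ndarray]:
    """N, CA, C, O coordinates for an n-residue chain at fixed (phi, psi)."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    th = np.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])]
    for _ in range(1, n_residues):
        N.append(_place(N[-1], CA[-1], C[-1], _B_C_N, _A_CA_C_N, psi))
        CA.append(_place(CA[-1], C[-1], N[-1], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(_place(C[-1], N[-1], CA[-1], _B_CA_C, _A_N_CA_C, phi))
    O = [_place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
         for i in range(n_residues)]
    return {"N": np.array(N), "CA": np.array(CA), "C": np.array(C), "O": np.array(O)}


def _chain_atoms(bb: dict[str, np.ndarray], chain_id: str, start_res: int,
                 serial0: int = 1) -> list[AtomRecord]:
    atoms = []
    serial = serial0
    for i in range(bb["N"].shape[0]):
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(AtomRecord(
                serial=serial, atom_name=name, element=elem, res_name="ALA",
                chain_id=chain_id, res_seq=start_res + i,
                coords=tuple(bb[name][i]),
            ))
            serial += 1
    return atoms


def build_ideal_helix(n_residues: int, chain_id: str = "A",
                      start_res: int = 1) -> Structure:
    """Poly-alanine backbone on canonical alpha-helix dihedrals.

    Needs at least 5 residues (an i -> i+4 hydrogen-bond partner must
    exist).  Rise ~1.5 A/residue, ~100 deg/residue twist, CA-CA ~3.8 A.
    """
    if n_residues < 5:
        raise ValueError(
            f"an alpha-helix needs >= 5 residues for an i->i+4 partner, got {n_residues}"
        )
    bb = _build_backbone(n_residues, HELIX_PHI, HELIX_PSI)
    return Structure(_chain_atoms(bb, chain_id, start_res),
                     id=f"ideal_helix_{chain_id}{start_res}-{start_res + n_residues - 1}")


def build_extended_chain(n_residues: int, chain_id: str = "A",
                         start_res: int = 1) -> Structure:
    """Poly-alanine backbone in the fully extended state (phi = psi = 180)."""
    if n_residues < 2:
        raise ValueError("an extended chain needs >= 2 residues")
    bb = _build_backbone(n_residues, 180.0, 180.0)
    return Structure(_chain_atoms(bb, chain_id, start_res), id="extended_chain")


def _slab_atoms(n_strands: int, strand_len: int, chain_id: str, start_res: int,
                spacing: float = 4.8) -> list[AtomRecord]:
    """Sheet-like slab: parallel extended strands, contiguous numbering."""
    atoms: list[AtomRecord] = []
    serial = 1
    res = start_res
    for s in range(n_strands):
        bb = _build_backbone(strand_len, 180.0, 180.0)
        offset = np.array([0.0, 0.0, s * spacing])
        shifted = {k: v + offset for k, v in bb.items()}
        for rec in _chain_atoms(shifted, chain_id, res, serial):
            atoms.append(rec)
            serial += 1
        res += strand_len
    return atoms


_PROBE_SIDECHAIN = ("CB", "CG", "CD", "CE", "NZ")


def _probe_atoms(chain_id: str, res_seq: int, center: np.ndarray) -> list[AtomRecord]:
    """A lysine-like probe residue: backbone stub plus a 5-atom side chain."""
    bb_offsets = {"N": (-1.2, 0.9, 0.0), "CA": (0.0, 0.0, 0.0),
                  "C": (1.3, 0.8, 0.0), "O": (2.3, 0.2, 0.3)}
    atoms = [AtomRecord(serial=1, atom_name=name, element=name[0],
                        res_name="LYS", chain_id=chain_id, res_seq=res_seq,
                        coords=tuple(center + np.array(off)))
             for name, off in bb_offsets.items()]
    for k, name in enumerate(_PROBE_SIDECHAIN):
        pos = center + np.array([0.0, -1.3 * (k + 1), 0.2 * k])
        atoms.append(AtomRecord(serial=5 + k, atom_name=name, element=name[0],
                                res_name="LYS", chain_id=chain_id, res_seq=res_seq,
                                coords=tuple(pos)))
    return atoms


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterisation of one generated ensemble.

    Every stochastic element is driven by ``seed`` alone: the same scenario
    produces bit-identical trajectories.  Amplitudes and noise are in
    Angstrom, times in ns.
    """

    name: str = "scenario"
    n_residues_helix: int = 31
    helix_start_res: int = 55
    extra_bodies: bool = True
    dt: float = 0.001
    n_frames: int = 2000
    noise_sigma: float = 0.2
    noise_tau: float = 0.05
    deformation_mode: str = "NONE"  # LOCAL_SPAN | DISTRIBUTED | NONE
    deformation_span: tuple[int, int] = (65, 69)
    deformation_amplitude: float = 0.0
    deformation_onset: float | None = None  # default: 20% of the run
    deformation_rise: float | None = None  # ns to full amplitude; None: ramp to end
    deformation_static: bool = False  # full amplitude in every frame
    sheet_deformation_amplitude: float = 0.0
    drift_rot_speed: float = 0.0  # deg/ns about a fixed axis
    drift_trans_speed: float = 0.0  # A/ns
    probe_escape_onset: float | None = None  # ns; None: probe stays seated
    probe_speed: float = 15.0  # A/ns once escaping
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0 or self.noise_tau <= 0:
            raise ValueError("noise_sigma must be >= 0 and noise_tau > 0")
        if self.deformation_amplitude < 0 or self.n_frames < 1:
            raise ValueError("amplitude must be >= 0 and n_frames >= 1")
        if self.deformation_mode not in ("LOCAL_SPAN", "DISTRIBUTED", "NONE"):
            raise ValueError(f"unknown deformation mode {self.deformation_mode!r}")
        s, e = self.deformation_span
        lo = self.helix_start_res
        hi = lo + self.n_residues_helix - 1
        if self.deformation_mode == "LOCAL_SPAN" and not (lo <= s <= e <= hi):
            raise ValueError(
                f"deformation span {self.deformation_span} outside helix "
                f"residues {lo}-{hi}"
            )

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.dt

    def build_base(self) -> Structure:
        """The undeformed, noise-free start structure of this scenario."""
        helix = build_ideal_helix(self.n_residues_helix, "A", self.helix_start_res)
        atoms = list(helix.atoms)
        if self.extra_bodies:
            # second groove wall: same helix translated 10 A off-axis
            wall = [replace(a, chain_id="B", res_seq=a.res_seq + 75,
                            coords=(a.coords[0], a.coords[1], a.coords[2] + 10.0))
                    for a in helix.atoms]
            atoms += wall
            slab = _slab_atoms(3, 6, "C", 181)
            # seat the slab below the groove, between the two walls
            slab_xyz = np.array([a.coords for a in slab])
            shift = (np.array([5.0, -8.0, 5.0]) - slab_xyz.mean(axis=0))
            atoms += [replace(a, coords=tuple(np.array(a.coords) + shift)) for a in slab]
            pocket_xyz = np.array(
                [np.array(a.coords) + shift for a in slab if 185 <= a.res_seq <= 190]
            )
            atoms += _probe_atoms("P", 4, pocket_xyz.mean(axis=0) + np.array([0.0, 1.5, 0.0]))
        # re-serialise in file order
        atoms = [replace(a, serial=i + 1) for i, a in enumerate(atoms)]
        return Structure(atoms, id=f"{self.name}_base")

    # -- standard region vocabulary on the generated geometry ---------------

    def default_regions(self) -> dict[str, RegionSelection]:
        s, e = self.deformation_span
        lo = self.helix_start_res
        hi = lo + self.n_residues_helix - 1
        regions = {
            "span": RegionSelection.span("span", "A", s, e),
            "helix_a1": RegionSelection.span("helix_a1", "A", lo, hi),
        }
        if self.extra_bodies:
            regions.update({
                "helix_a2": RegionSelection.span("helix_a2", "B", lo + 75, hi + 75),
                "sheet_floor": RegionSelection.span("sheet_floor", "C", 185, 190),
                "pocket": RegionSelection.span("pocket", "C", 185, 190, "ALL"),
                "probe": RegionSelection.span("probe", "P", 4, 4, _PROBE_SIDECHAIN),
                "groove_a": RegionSelection.span("groove_a", "A", lo, hi, "CA"),
                "groove_b": RegionSelection.span("groove_b", "B", lo + 75, hi + 75, "CA"),
            })
        return regions


def _ramp(times: np.ndarray, sc: SyntheticScenario) -> np.ndarray:
    """Deformation amplitude factor per frame, in [0, 1]."""
    if sc.deformation_static:
        return np.ones_like(times)
    onset = sc.deformation_onset
    if onset is None:
        onset = 0.2 * sc.duration
    rise = sc.deformation_rise
    if rise is None:
        rise = max(sc.duration - onset, sc.dt)
    if rise <= 0:
        return (times >= onset).astype(float)
    return np.clip((times - onset) / rise, 0.0, 1.0)


def _ou_noise(rng: np.random.Generator, shape: tuple[int, ...],
              sigma: float, tau: float, dt: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise along axis 0.

    Mean-reverting with stationary standard deviation ``sigma`` and
    correlation time ``tau``: lag-1 autocorrelation exp(-dt/tau).
    """
    if sigma == 0.0:
        return np.zeros(shape)
    a = np.exp(-dt / tau)
    x0 = rng.standard_normal(shape[1:]) * sigma
    w = rng.standard_normal(shape) * sigma * np.sqrt(1.0 - a * a)
    zi = (a * x0)[None, ...]
    out, _ = lfilter([1.0], [1.0, -a], w, axis=0, zi=zi)
    return out


def _rotation_about(axis: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices, one per angle: (T, 3, 3)."""
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    c = np.cos(angles_rad)[:, None, None]
    s = np.sin(angles_rad)[:, None, None]
    eye = np.eye(3)
    return c * eye + s * K + (1 - c[:, 0, 0])[:, None, None] * np.outer(k, k)


def _helix_frame(base: Structure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Helix axis of chain A and two perpendicular unit vectors."""
    ca = np.array([a.coords for a in base.atoms
                   if a.chain_id == "A" and a.atom_name == "CA"])
    axis = ca[-1] - ca[0]
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v1 = np.cross(axis, ref)
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(axis, v1)
    return axis, v1, v2


def _deformation_field(base: Structure, sc: SyntheticScenario) -> np.ndarray:
    """Per-atom unit-ramp displacement (N, 3): the injected deformation shape.

    LOCAL_SPAN displaces every atom of the span residues by the same
    off-axis vector of length ``deformation_amplitude`` (flanks untouched),
    so the flank-fitted span RMSD at full ramp equals the amplitude exactly
    in the noise-free case.  DISTRIBUTED applies a smooth bending mode over
    the whole helix, peaking at ``deformation_amplitude`` at the centre,
    with the displacement direction precessing along the chain so no single
    rigid transform can absorb it; optionally the same mode is applied to
    the sheet slab.
    """
    n = len(base)
    field_ = np.zeros((n, 3))
    if sc.deformation_mode == "NONE" and sc.sheet_deformation_amplitude == 0.0:
        return field_
    _, v1, v2 = _helix_frame(base)
    chain = np.array([a.chain_id for a in base.atoms])
    res = np.array([a.res_seq for a in base.atoms])
    lo = sc.helix_start_res
    hi = lo + sc.n_residues_helix - 1
    if sc.deformation_mode == "LOCAL_SPAN":
        s, e = sc.deformation_span
        mask = (chain == "A") & (res >= s) & (res <= e)
        field_[mask] = sc.deformation_amplitude * v1
    elif sc.deformation_mode == "DISTRIBUTED":
        mask = chain == "A"
        u = (res[mask] - lo) / max(hi - lo, 1)
        env = sc.deformation_amplitude * np.sin(np.pi * u)
        direction = (np.cos(2 * np.pi * u)[:, None] * v1
                     + np.sin(2 * np.pi * u)[:, None] * v2)
        field_[mask] = env[:, None] * direction
    if sc.sheet_deformation_amplitude > 0.0:
        mask = chain == "C"
        if mask.any():
            r = res[mask]
            u = (r - r.min()) / max(r.max() - r.min(), 1)
            env = sc.sheet_deformation_amplitude * np.sin(np.pi * u)
            direction = (np.cos(2 * np.pi * u)[:, None] * v1
                         + np.sin(2 * np.pi * u)[:, None] * v2)
            field_[mask] = env[:, None] * direction
    return field_


def generate_trajectory(scenario: SyntheticScenario) -> Trajectory:
    """Generate the scenario's trajectory; the topology is the undeformed base.

    Frame t is ``Drift(t) applied to [base + ramp(t) * deformation +
    probe_escape(t) + OU_noise(t)]``.  Identical scenarios (including the
    seed) produce bit-identical output.
    """
    sc = scenario
    base = sc.build_base()
    n = len(base)
    times = np.arange(sc.n_frames, dtype=np.float64) * sc.dt
    rng = np.random.default_rng(sc.seed)
    coords = np.broadcast_to(base.coords, (sc.n_frames, n, 3)).copy()

    shape = _deformation_field(base, sc)
    if np.any(shape):
        coords += _ramp(times, sc)[:, None, None] * shape[None, :, :]

    if sc.probe_escape_onset is not None:
        probe_mask = np.array([a.chain_id == "P" for a in base.atoms])
        travel = np.clip((times - sc.probe_escape_onset) * sc.probe_speed, 0.0, 25.0)
        coords[:, probe_mask, :] += travel[:, None, None] * np.array([0.0, 1.0, 0.0])

    coords += _ou_noise(rng, (sc.n_frames, n, 3), sc.noise_sigma, sc.noise_tau, sc.dt)

    if sc.drift_rot_speed != 0.0 or sc.drift_trans_speed != 0.0:
        com = base.coords.mean(axis=0)
        angles = np.radians(sc.drift_rot_speed) * times
        rots = _rotation_about(np.array([1.0, 1.0, 1.0]), angles)
        trans = (sc.drift_trans_speed * times)[:, None] * np.array([1.0, 0.0, 0.0])
        coords = np.einsum("tij,tnj->tni", rots, coords - com) + com + trans[:, None, :]

    return Trajectory(topology=base, frames=coords, times=times, id=sc.name)


@dataclass(frozen=True)
class ScenarioTriptych:
    """Three scenarios sharing geometry, noise, drift and seed policy.

    They differ only in their deformation fields, mirroring the contrast
    between a groove-escaping peptide that disrupts a five-residue helix
    span (native-like), a variant that bends the whole helix and the sheet
    floor while staying anchored (methionine-like), and a variant that
    leaves the MHC essentially undeformed (alanine-like).
    """

    native_like: SyntheticScenario
    m4_like: SyntheticScenario
    a4_like: SyntheticScenario

    _DEFORMATION_FIELDS = frozenset({
        "name", "deformation_mode", "deformation_span", "deformation_amplitude",
        "sheet_deformation_amplitude", "probe_escape_onset",
    })

    def __post_init__(self):
        ref = asdict(self.native_like)
        for other in (self.m4_like, self.a4_like):
            for key, val in asdict(other).items():
                if key not in self._DEFORMATION_FIELDS and val != ref[key]:
                    raise ValueError(
                        f"triptych scenarios must share {key!r}; "
                        f"{other.name} has {val!r} vs {ref[key]!r}"
                    )

    def scenarios(self) -> dict[str, SyntheticScenario]:
        return {"NATIVE_LIKE": self.native_like, "M4_LIKE": self.m4_like,
                "A4_LIKE": self.a4_like}


def triptych_presets(n_frames: int = 22000, dt: float = 0.001,
                     seed: int = 0) -> ScenarioTriptych:
    """The shipped three-scenario contrast at the study's time scale.

    Defaults: 22 ns at 1 ps/frame, OU noise of 0.2 A stationary s.d. with
    50 ps correlation time, gentle global tumbling.  NATIVE_LIKE ramps a
    0.40 nm local displacement onto the residue 65-69 span and sends the
    probe out of the pocket within the first nanosecond; M4_LIKE bends the
    whole helix and the sheet slab to 0.30 nm; A4_LIKE injects no
    deformation at all.  These amplitudes are declared test parameters of
    the generator, not measured MD values.
    """
    shared = dict(
        n_frames=n_frames, dt=dt, seed=seed,
        noise_sigma=0.2, noise_tau=0.05,
        drift_rot_speed=3.0, drift_trans_speed=0.2,
        extra_bodies=True,
    )
    native = SyntheticScenario(
        name="NATIVE_LIKE", deformation_mode="LOCAL_SPAN",
        deformation_span=(65, 69), deformation_amplitude=4.0,
        probe_escape_onset=0.2, **shared,
    )
    m4 = SyntheticScenario(
        name="M4_LIKE", deformation_mode="DISTRIBUTED",
        deformation_amplitude=3.0, sheet_deformation_amplitude=3.0,
        probe_escape_onset=None, **shared,
    )
    a4 = SyntheticScenario(
        name="A4_LIKE", deformation_mode="NONE", deformation_amplitude=0.0,
        probe_escape_onset=None, **shared,
    )
    return ScenarioTriptych(native_like=native, m4_like=m4, a4_like=a4)


def generate_triptych(
    triptych: ScenarioTriptych,
) -> tuple[dict[str, Trajectory], dict]:
    """Generate the three trajectories plus a ground-truth manifest."""
    trajs = {name: generate_trajectory(sc)
             for name, sc in triptych.scenarios().items()}
    manifest = {name: asdict(sc) for name, sc in triptych.scenarios().items()}
    return trajs, manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
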
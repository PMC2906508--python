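# Methods

`mhcdeform` quantifies how a bound peptide deforms an MHC class II molecule
over a trajectory.  This note documents the models, the numerical choices,
what the synthetic test bed does and does not emulate, and the known
limitations.

## Superposition and RMSD

All deformation metrics reduce to one primitive: the weighted Kabsch fit.
Given corresponding point sets **x** (mobile) and **y** (reference) with
weights *w*, the proper rotation *R* and translation *t* minimising

RMSD = sqrt( Σ wᵢ ‖R xᵢ + t − yᵢ‖² / Σ wᵢ )

are obtained from the SVD of the weighted covariance matrix, with the sign
of the smallest singular value's contribution flipped when the unconstrained
optimum would be a reflection — the returned rotation always has det = +1.
Rank-deficient (collinear) fit sets produce a warning and an
`ill_conditioned` flag rather than an error, because tiny fit groups can
degenerate transiently along a trajectory.  The quaternion
characteristic-polynomial method is implemented independently in the test
suite as a cross-check oracle; it is never used in the analysis path.

Weights default to atomic masses, matching the convention of mainstream MD
analysis tools; unit weights are available via `mass_weighted=False`.  When
all masses are equal the two paths coincide exactly.

**Fit/measure separation.**  `fit_measure_rmsd` computes the superposition
on one atom set and the RMSD on another.  This is the mechanism behind the
package's central observable, the *flank-fitted span RMSD*: the structure is
superposed onto the reference using only the `n_flank` residues on each side
of a span (default 5 per side, i.e. 10 fit residues for a 5-residue span),
and the RMSD is then measured over the span alone.  Rigid motion of the
whole molecule, or of the local helix segment, cancels in the fit; what
remains is the span's internal deformation.  With the flanks undeformed and
the span displaced uniformly by *d*, the measured value is exactly *d* — the
identity the acceptance suite verifies to 1e-9 nm.

Whole-region series support two fit modes: `REGION_SELF` (superpose on the
measured region itself, so only internal rearrangement registers) and
`GLOBAL(anchor)` (superpose on an independent anchor selection, so rigid
drift of the region relative to the anchor also contributes).  Which mode a
published whole-helix RMSD used is generally ambiguous; the pipeline default
is `REGION_SELF` and every series records its fit mode.

**Units.**  All computation is in Å (the native PDB unit); every reported
series and summary is converted to nm at the reporting boundary, the
convention in which MD deformation results are quoted.

**Reference structure.**  The default reference is frame 0 of the
trajectory; a separate single-model PDB can be supplied instead.  The choice
is recorded in each series' metadata because mean RMSD values are not
comparable across different references.

**Average structures** over a time window are built by superposing every
in-window frame onto the *first in-window frame* (not a global reference) on
a configurable fit selection, then averaging coordinates atom-wise.  Fitting
to the first in-window frame means that an ensemble of pure rigid
transforms of one structure averages to that structure in the anchor frame's
pose; the shape, not the absolute pose, is the meaningful output.

## Smoothing and summaries

The moving average at frame *i* covers frames `[i − h, i + h]` with
half-width *h* (default 500, i.e. the 1000 neighbouring frames plus the
centre).  Edge policy `TRUNCATE` (default) intersects the window with valid
indices so the series keeps its length and covers the full time axis;
`DROP` keeps only full windows.  The implementation uses prefix sums; the
test suite checks it against a direct-summation oracle.  Windowed summaries
report mean, max and frame count; the "late" window defaults to the final
third of the run and is set to 15–22 ns in the shipped full-scale configs.

## Pocket residency and groove width

The published observation that a peptide side chain "leaves" or "stays
inside" a pocket is qualitative; the package operationalises it with a
declared criterion: a frame counts as *inside* when the centroid of the
probe atoms (the position-4 side chain) lies within a cutoff (default 8 Å)
of the centroid of the pocket-lining atoms.  Reported are the per-frame
residency trace, the residency fraction, the first exit time and an
`early_exit` flag (exit at or before the threshold, default 1 ns).  Both
the residue lists and the cutoff live in the config, because the criterion —
not just its parameters — is a modelling choice.

Groove width is the per-frame distance between the centroids of the CA
atoms of the two groove-wall helices: the simplest strictly
rotation-invariant width proxy.  It does not resolve *where* along the
groove widening occurs; a per-position width profile is future work.

## Helix conformity

Whether a span "still conforms to the definition of an α-helix" is decided
per frame with the Kabsch–Sander electrostatic hydrogen-bond energy

E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332 kcal/mol,

a bond being accepted at E < −0.5 kcal/mol, combined with the minimal-helix
rule: residue *i* is helical iff i→i+4 turn bonds exist with acceptors at
both *i−1* and *i*.  Amide hydrogens are rebuilt geometrically (1.01 Å from
N along the preceding C=O direction) since MD snapshots and crystal models
routinely lack them.  The energy constant and threshold are deliberately
*not* configurable so that assignments stay comparable across runs.

This is a simpler criterion than STRIDE's (which adds empirical dihedral
propensities); it answers the same binary question and is fully specified
and testable.  Consequences of the rule worth knowing: terminal residues
are never helical (they lack one of the two required turns), and the last
four residues of a chain cannot be helical either, because their i→i+4
partner does not exist.  A span's helicity therefore requires the chain to
extend at least one residue before the span and four after it; the API
raises a padding error otherwise.  Anything not helical is labelled C;
sheet states are not distinguished.

## The synthetic test bed

The generator produces ensembles whose correct analysis outcome is known by
construction.  It fakes statistics, not physics — no force field, solvent
or thermostat.  A generated frame is

frame(t) = Drift(t) ∘ [ base + ramp(t)·Deformation + ProbeEscape(t) + OU(t) ]

* **Geometry.**  A 31-residue poly-alanine backbone helix (chain A,
  residues 55–85, built by internal-coordinate extension at φ = −57°,
  ψ = −47°), optionally a second identical helix 10 Å off-axis (chain B,
  the other groove wall), a slab of three parallel extended strands
  (chain C, residues 181–198, the sheet-floor analogue) and a lysine-like
  probe residue seated near the slab (chain P).  About 330 backbone atoms
  in total.  Residue numbering is chosen so the published span labels
  (65–69 for the watched span, 185–190 for the sheet floor) address the
  analogous synthetic regions directly.
* **Noise.**  An Ornstein–Uhlenbeck process per atom per coordinate:
  stationary s.d. `noise_sigma`, correlation time `noise_tau` (defaults
  0.2 Å and 50 ps at dt = 1 ps).  Temporal correlation matters — against
  white noise a 1000-frame moving average would be trivially effective.
  Because the noise is *independent across atoms*, relative displacements
  fluctuate ~√2 larger than the per-atom s.d.; real thermal motion is
  locally correlated.  The 0.2 Å default is chosen so that the pairwise
  fluctuation scale is realistic and an undisturbed ideal helix keeps its
  hydrogen bonds in the large majority of frames, as a stable helix in MD
  does.  Larger sigmas melt the helix assignment spuriously.
* **Deformation.**  `LOCAL_SPAN` displaces every atom of a residue span by
  a common off-axis vector (flanks untouched), making the flank-fitted RMSD
  analytically predictable.  `DISTRIBUTED` applies a smooth bending mode
  over the whole helix — a sine envelope peaking at the target amplitude at
  the helix centre, with the displacement direction precessing along the
  chain so that no single rigid transform can absorb the field.  Amplitude
  grows linearly from `deformation_onset` (default 20 % of the run) to the
  final frame; `deformation_static` applies the full amplitude throughout
  (used by the analytic recovery tests), and `deformation_rise` makes the
  ramp plateau early.
* **Probe escape.**  When enabled, the probe translates away from the
  pocket at `probe_speed` (default 15 Å/ns) from `probe_escape_onset`.
* **Drift.**  Global tumbling (rotation about a fixed axis plus uniform
  translation) applied last.  Fitted metrics must be blind to it; the
  acceptance suite checks this with random per-frame rigid transforms.

**Shipped three-scenario contrast** (`triptych_presets`): 22,000 frames at
1 ps (22 ns), shared geometry, noise (σ = 0.2 Å, τ = 50 ps), drift
(3°/ns, 0.2 Å/ns) and seed; the scenarios differ only in deformation:

| preset | deformation | probe |
|---|---|---|
| NATIVE_LIKE | LOCAL_SPAN on residues 65–69, 4.0 Å (0.40 nm) | escapes from 0.2 ns |
| M4_LIKE | DISTRIBUTED over the helix and the sheet slab, 3.0 Å | stays |
| A4_LIKE | none | stays |

The amplitudes (0.40 nm local, 0.30 nm distributed, 0 for A4_LIKE) are
declared generator parameters selected so the scenario *design* reproduces
the qualitative contrast of interest — a locally disrupting, groove-escaping
peptide vs. a globally bending anchored one vs. an inert one.  They are not
measurements, and the package nowhere presents the resulting numbers as MD
values.

**What passing tests show — and don't.**  The synthetic bed validates the
*analysis machinery*: that fitted metrics reject global motion exactly,
recover injected amplitudes, rank scenarios as constructed, and reproduce
bit-identically under a fixed seed.  It does not validate force fields,
sampling adequacy, or any claim about real pMHC dynamics; real trajectories
have correlated, anisotropic fluctuations, side chains, and deformations
that are not uniform translations of a span.

## Problem sizes and determinism

Default scales are chosen to keep a full test cycle interactive on one
core: the shipped presets run 22,000 frames × ~330 atoms (about 20 s for
generation plus the full metric battery per scenario); unit tests use a few
hundred to 20,000 frames.  RMSD series are computed with batched covariance
construction and batched 3×3 SVDs over all frames at once.

All randomness flows from one integer seed through `numpy`'s Generator;
identical configs reproduce trajectories, CSVs and PDB outputs
byte-for-byte.  CSVs use '.' decimals and are locale-independent.

## Known limitations

* Multi-model PDB is the only guaranteed trajectory format; binary formats
  (XTC/DCD) are out of scope in this version.  PDB coordinate precision is
  10⁻³ Å, which bounds round-trip fidelity.
* The helix criterion ignores 3₁₀/π helices and sheet bookkeeping.
* Groove width is a single scalar per frame, not a profile.
* The pocket criterion is centroid-based; an atom-contact count would be
  stricter but needs side-chain detail the synthetic bed does not model.
* Exact residue bounds for "the whole helix" regions on real structures are
  an editorial choice; every report echoes the bounds used.
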
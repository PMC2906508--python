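# Template for analysing a real peptide-MHC class II trajectory supplied as
# a multi-model PDB file (topology identical across models).
#
# Residue numbers follow the author numbering of the input structure; the
# spans below suit a 1K2D-like I-A complex and MUST be checked against your
# file: the exact bounds of the two groove-wall helices are an editorial
# choice, and every report records the bounds actually used.
trajectory_path: trajectory.pdb
dt: 0.001                      # ns per model; required for a correct time axis
# reference_path: start_model.pdb   # optional; default reference is frame 0

regions:
  span:        {chain: A, intervals: [[65, 69]], atoms: BACKBONE}
  helix_a1:    {chain: A, intervals: [[52, 87]], atoms: BACKBONE}
  helix_a2:    {chain: B, intervals: [[53, 91]], atoms: BACKBONE}
  sheet_floor: {chain: B, intervals: [[185, 190]], atoms: BACKBONE}
  pocket:      {chain: A, intervals: [[61, 68]], atoms: HEAVY}   # pocket lining
  probe:       {chain: C, intervals: [[4, 4]],
                atoms: [CB, CG, CD, CE, NZ]}                     # peptide position 4
  groove_a:    {chain: A, intervals: [[52, 87]], atoms: CA}
  groove_b:    {chain: B, intervals: [[53, 91]], atoms: CA}

n_flank: 5            # flank residues each side of the span
half_width: 500       # moving-average half window, frames
edge_policy: TRUNCATE
late_window: [15.0, 22.0]
average_window: [15.0, 22.0]
pocket_cutoff: 8.0    # A, centroid-distance residency criterion
exit_threshold: 1.0   # ns; exits at or before this count as early
mass_weighted: true
out_dir: results/pmhc_run
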
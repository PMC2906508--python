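# Full-scale distributed-deformation scenario: a 0.30 nm bending mode over
# the whole groove-wall helix plus the sheet-floor slab; the probe stays
# anchored in the pocket.  22,000 frames at 1 ps.
scenario: M4_LIKE
n_flank: 5
half_width: 500
edge_policy: TRUNCATE
late_window: [15.0, 22.0]
average_window: [15.0, 22.0]
pocket_cutoff: 8.0
exit_threshold: 1.0
out_dir: results/m4_like
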
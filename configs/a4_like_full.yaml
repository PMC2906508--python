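# Full-scale minimal-deformation scenario: noise and tumbling only, probe
# seated in the pocket for the whole run.  22,000 frames at 1 ps.
scenario: A4_LIKE
n_flank: 5
half_width: 500
edge_policy: TRUNCATE
late_window: [15.0, 22.0]
average_window: [15.0, 22.0]
pocket_cutoff: 8.0
exit_threshold: 1.0
out_dir: results/a4_like
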
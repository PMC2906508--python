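# Full-scale native-like scenario: a 0.40 nm local displacement ramped onto
# the residue 65-69 span of the groove-wall helix, with the position-4 probe
# escaping the pocket within the first nanosecond.  22,000 frames at 1 ps.
# Regions default to the scenario's own vocabulary (chains A/B/C/P).
scenario: NATIVE_LIKE
n_flank: 5
half_width: 500
edge_policy: TRUNCATE
late_window: [15.0, 22.0]
average_window: [15.0, 22.0]
pocket_cutoff: 8.0
exit_threshold: 1.0
out_dir: results/native_like
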
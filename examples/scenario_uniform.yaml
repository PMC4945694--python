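# Axisymmetric-equivalent uniform-radial spreading run (desk scale).
scenario: uniform_spread
coupling: simultaneous
t_f: 1.0
t_end: 5.0
a_star: 4.0
volume_factor: 1.3
out_dir: runs/uniform_1s
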
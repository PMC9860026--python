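# Acquisition-protocol presets for the 3 T multi-echo GRE comparison.
# Times in ms, bandwidth per pixel in Hz; total BW = bw_per_px_hz * n_x.
# Echo spacing differs between monopolar (fly-back) and bipolar readouts,
# so each bandwidth ships one preset per polarity scheme.
bw801_monopolar: {scheme: monopolar, te1_ms: 3.84, delta_te_ms: 2.92, te_max_ms: 97.0, bw_per_px_hz: 801, matrix: 240, n_x: 240}
bw801_bipolar:   {scheme: bipolar,   te1_ms: 3.84, delta_te_ms: 1.47, te_max_ms: 97.0, bw_per_px_hz: 801, matrix: 240, n_x: 240}
bw718_monopolar: {scheme: monopolar, te1_ms: 3.90, delta_te_ms: 3.05, te_max_ms: 97.0, bw_per_px_hz: 718, matrix: 240, n_x: 240}
bw718_bipolar:   {scheme: bipolar,   te1_ms: 3.90, delta_te_ms: 1.60, te_max_ms: 97.0, bw_per_px_hz: 718, matrix: 240, n_x: 240}
bw613_monopolar: {scheme: monopolar, te1_ms: 4.00, delta_te_ms: 3.27, te_max_ms: 97.0, bw_per_px_hz: 613, matrix: 240, n_x: 240}
bw613_bipolar:   {scheme: bipolar,   te1_ms: 4.00, delta_te_ms: 1.82, te_max_ms: 97.0, bw_per_px_hz: 613, matrix: 240, n_x: 240}
bw342_monopolar: {scheme: monopolar, te1_ms: 4.62, delta_te_ms: 4.48, te_max_ms: 97.0, bw_per_px_hz: 342, matrix: 240, n_x: 240}
bw342_bipolar:   {scheme: bipolar,   te1_ms: 4.62, delta_te_ms: 3.03, te_max_ms: 97.0, bw_per_px_hz: 342, matrix: 240, n_x: 240}
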
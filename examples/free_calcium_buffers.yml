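# EGTA / Ca-EGTA reciprocal dilution series for equilibrium Ca2+ titrations.
#
# Free calcium follows correction * kd_chelator_eff * f / (1 - f) with
# f = ca_total / chelator_total.  The effective chelator Kd depends on ionic
# strength, pH and temperature; 287 nM approximately reproduces the standard
# 16-point series (2.1 ... 81276 nM free Ca) for the interior dilution points.
chelator_total_mM: 10.0
ca_total_mM: [0, 0.25, 0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 9.5, 9.75, 9.875]
kd_chelator_eff_nM: 287.0
correction: 1.084
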
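# Impulse head-only asymmetric gradient coil (three winding layers).
# Nominal amplitude is the duty-cycle limit sustained through EPI readouts.
name = impulse
g_abs_max_mT_per_m = 200
g_nom_max_mT_per_m = 85
sr_max_T_per_m_per_s = 900
# Echo spacings excluded to avoid mechanical resonances of the coil former.
forbidden_es_bands_ms = 0.82-0.92, 0.46-0.48, 0.35-0.36, 0.26
sensitivity_mT_per_m_per_A = 0.16
linearity_pct = 5.73, 6.32, 5.64
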
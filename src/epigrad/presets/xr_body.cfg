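# XR whole-body gradient coil of a standard 7 T system.
name = xr_body
g_abs_max_mT_per_m = 80
g_nom_max_mT_per_m = 40
sr_max_T_per_m_per_s = 200
forbidden_es_bands_ms =
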
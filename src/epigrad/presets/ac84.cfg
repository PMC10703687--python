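# AC84 head-only gradient coil insert (two winding layers).
name = ac84
g_abs_max_mT_per_m = 80
g_nom_max_mT_per_m = 50
sr_max_T_per_m_per_s = 333
forbidden_es_bands_ms =
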
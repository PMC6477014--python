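name,velocity_m_per_s,attenuation_db_per_cm_per_mhz
fat,1436,0.7
muscle,1550,0.7
urine,1551,0.00014
soft_tissue,1550,0.7
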
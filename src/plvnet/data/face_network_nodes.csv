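parcel_label,system
lh_G_and_S_occipital_inf,core
lh_G_oc-temp_lat-fusifor,core
lh_S_temporal_sup,core
lh_G_front_sup,extended
lh_G_front_inf-Opercular,extended
lh_G_front_inf-Orbital,extended
lh_G_front_inf-Triangul,extended
lh_Pole_temporal,extended
lh_G_insular_short,extended
lh_G_Ins_lg_and_S_cent_ins,extended
lh_G_and_S_subcentral,extended
rh_G_and_S_occipital_inf,core
rh_G_oc-temp_lat-fusifor,core
rh_S_temporal_sup,core
rh_G_front_sup,extended
rh_G_front_inf-Opercular,extended
rh_G_front_inf-Orbital,extended
rh_G_front_inf-Triangul,extended
rh_Pole_temporal,extended
rh_G_insular_short,extended
rh_G_Ins_lg_and_S_cent_ins,extended
rh_G_and_S_subcentral,extended
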
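lh_fusiform
lh_inferiortemporal
lh_insula
lh_isthmuscingulate
lh_lateralorbitofrontal
lh_lingual
lh_parahippocampal
lh_posteriorcingulate
lh_precentral
lh_precuneus
lh_rostralanteriorcingulate
lh_superiorfrontal
lh_superiorparietal
rh_fusiform
rh_inferiortemporal
rh_insula
rh_isthmuscingulate
rh_lateralorbitofrontal
rh_lingual
rh_parahippocampal
rh_posteriorcingulate
rh_precentral
rh_precuneus
rh_rostralanteriorcingulate
rh_superiorfrontal
rh_superiorparietal
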
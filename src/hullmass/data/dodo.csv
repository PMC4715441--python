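specimen,accession,ch_vol_mm3,ch_vol_minus_feet_mm3
NHMUK Tring dodo,S/1988.50.1,8942820,8445134
NHMUK Kensington dodo,NHM A.9040,9730367,9283795
Edinburgh dodo,NMS.Z.1993.13,12147000,11787000
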
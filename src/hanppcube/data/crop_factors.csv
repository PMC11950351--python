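# Per-crop-class factors for converting reported fresh production to carbon
# harvest flows.  carbon_per_t: tC per tonne fresh weight (moisture + carbon
# content); expansion: dimensionless >= 1, accounts for by-products and
# harvest losses; preharvest_share: fraction of actual NPP lost before
# harvest.  Values are package defaults in the literature's typical range;
# they are configuration, and every computation accepts an override table.
crop,carbon_per_t,expansion,preharvest_share
CL-WHEA,0.40,2.0,0.10
CL-RICE,0.40,1.8,0.10
CL-BARL,0.40,2.0,0.10
CL-MAIZ,0.40,1.9,0.10
CL-REST,0.35,1.7,0.10
CL-MILL,0.40,2.2,0.10
CL-SORG,0.40,2.2,0.10
CL-POTA,0.10,1.4,0.10
CL-SWPY,0.12,1.4,0.10
CL-CASS,0.16,1.4,0.10
CL-SUGC,0.13,1.5,0.10
CL-SUGB,0.10,1.5,0.10
CL-BEAN,0.38,2.1,0.10
CL-OPUL,0.38,2.1,0.10
CL-SOYB,0.40,1.9,0.10
CL-GROU,0.42,1.9,0.10
CL-OOIL,0.45,1.9,0.10
CL-COTT,0.42,2.4,0.10
CL-BANP,0.12,1.5,0.10
CL-COFF,0.40,2.3,0.10
CL-VEFR,0.08,1.4,0.10
CL-OFIB,0.42,2.4,0.10
CL-FODD,0.45,1.1,0.10
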
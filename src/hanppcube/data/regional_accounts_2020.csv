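# Published global and world-regional land-use / HANPP accounts for 2020.
# Areas in Mkm2; NPP flows in MtC/yr; hanpp_pct in % of NPP_pot (integer-rounded).
# Forestry land-conversion flow (hanpp_luc) is zero by definition.
# Wilderness values are derivable as Total minus the four named types.
region,lu_type,area_Mkm2,npp_pot,hanpp_harv,hanpp_luc,hanpp,hanpp_pct
Global,Cropland,15.7,8646,6776,-858,5918,68
Global,Grazing,47.1,23060,1783,1655,3439,15
Global,Forestry,19.9,14510,1636,0,1636,11
Global,Built-up,1.6,881,147,588,734,20
Global,Total,131.6,62348,10342,1385,11727,19
Northern America,Cropland,2.3,1121,875,-88,787,70
Northern America,Grazing,9.1,3273,265,181,446,14
Northern America,Forestry,3.9,2476,240,0,240,10
Northern America,Built-up,0.3,145,24,96,121,20
Northern America,Total,28.6,11187,1404,190,1594,14
Latin America & the Caribbean,Cropland,1.8,1257,1044,-156,888,71
Latin America & the Caribbean,Grazing,8.4,5196,439,366,805,16
Latin America & the Caribbean,Forestry,4.2,3488,251,0,251,7
Latin America & the Caribbean,Built-up,0.2,119,20,79,99,20
Latin America & the Caribbean,Total,20.2,15058,1754,290,2044,14
Central Asia and Russian Federation,Cropland,2.1,937,512,144,655,70
Central Asia and Russian Federation,Grazing,5.3,1973,78,208,285,14
Central Asia and Russian Federation,Forestry,3.4,1870,126,0,126,7
Central Asia and Russian Federation,Built-up,0.2,85,14,57,71,20
Central Asia and Russian Federation,Total,21.4,9088,730,408,1138,13
Europe,Cropland,1.2,637,501,-51,451,71
Europe,Grazing,1.8,999,114,134,248,25
Europe,Forestry,1.4,841,182,0,182,22
Europe,Built-up,0.2,112,19,74,93,20
Europe,Total,4.7,2681,816,158,974,36
Africa,Cropland,3.3,1879,835,517,1352,72
Africa,Grazing,14.1,7458,652,378,1030,14
Africa,Forestry,3.0,2738,196,0,196,7
Africa,Built-up,0.3,137,23,91,114,20
Africa,Total,34.1,13412,1707,986,2692,20
Asia,Cropland,4.9,2815,3009,-1224,1786,63
Asia,Grazing,8.5,4162,235,388,623,15
Asia,Forestry,4.0,3096,639,0,639,21
Asia,Built-up,0.5,284,47,190,237,20
Asia,Total,22.5,10922,3931,-646,3285,30
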
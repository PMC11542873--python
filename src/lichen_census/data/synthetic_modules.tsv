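module_id	name	definition
M00123	Biotin biosynthesis, pimeloyl-ACP/CoA to biotin (synthetic stand-in)	K90101 K90102 K90103 K90104
M00950	Biotin biosynthesis, BioU pathway (synthetic stand-in)	K90111 (K90112,K90113) K90114
M00127	Thiamine biosynthesis, de novo (synthetic stand-in)	K90211 K90212+K90213 K90214 K90215
M00899	Thiamine salvage pathway (synthetic stand-in)	K90201 K90202 (K90203,K90204)
M00122	Cobalamin biosynthesis, prokaryotic (synthetic stand-in)	K90301 K90302 K90303 K90304 K90305 K90306 K90307
M00925	Cobalamin biosynthesis, eukaryotic salvage route (synthetic stand-in)	K90311 K90312 K90313 K90314 K90315 K90316 K90317 K90318 K90319 K90320 K90321
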
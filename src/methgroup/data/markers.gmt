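PROLIFERATION_MARKERS	synthetic proliferation marker panel	MKI67	TOP2A	FOXM1
DECOY_SET_A	synthetic decoy	G00000	G00001	G00002	G00003	G00004	G00005	G00006	G00007	G00008	G00009
DECOY_SET_B	synthetic decoy	G00100	G00101	G00102	G00103	G00104	G00105	G00106	G00107	G00108	G00109	G00110	G00111
DECOY_SET_C	synthetic decoy	G00200	G00201	G00202	G00203	G00204	G00205	G00206	G00207
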
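	RAJI	K562	HCT	NHDF	Me45
AID	0.009824	0.010643	0.086131	0.002238	0.001404
SMUG1	1.195942	1.19889	16.01112	0.914257	0.361182
TDG	0.29466	0.174258	0.449975	0.030231	0.076355
DNMT1	0.092437	0.236583	0.081149	0.082171	0.038231
TET1	0.064967	0.169337	0.056229	0.033814	0.096231
TET2	0.614074	0.73099	0.620413	0.497276	0.043056
TET3	0.004811	0.003187	0.027295	0.002800	0.000876
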
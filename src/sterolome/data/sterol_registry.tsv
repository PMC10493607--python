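# Named reference sterols with their ST(c:d) class assignments.
# reference_rt_min values are SYNTHETIC placeholders (the published
# standards appendix is not distributed with this package); only the
# d7-cholesterol internal standard's 5.6 min is a reported elution time.
# Isomers sharing a class are spaced >= 0.15 min apart so that level-1
# matching at the 0.1 min window is unambiguous.
name	carbons	dbe	reference_rt_min	internal_standard	deuterium
cholesterol	27	1	5.55	0	0
desmosterol	27	2	5.05	0	0
campesterol	28	1	6.10	0	0
episterol	28	2	5.90	0	0
24-methylenecholesterol	28	2	5.30	0	0
brassicasterol	28	2	5.10	0	0
ergosterol	28	3	4.80	0	0
anthelsterol	28	3	5.20	0	0
sitostanol	29	0	7.30	0	0
beta-sitosterol	29	1	6.90	0	0
schottenol	29	1	7.10	0	0
stigmasterol	29	2	6.00	0	0
isofucosterol	29	2	6.30	0	0
avenasterol	29	2	6.55	0	0
spinasterol	29	2	6.75	0	0
cycloartanol	30	1	8.20	0	0
obtusifoliol	30	2	7.60	0	0
cycloartenol	30	2	7.90	0	0
cycloeucalenol	30	3	7.40	0	0
24-methylenecycloartanol	31	2	8.60	0	0
cyclolaudenol	31	2	8.90	0	0
d7-cholesterol	27	1	5.60	1	7
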
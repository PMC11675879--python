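# Running times of a sample of 30 devices (Meeker & Escobar 1998,
# Statistical Methods for Reliability Data). Transcribed from the
# published table; times of 300 are the test horizon reached by
# survivors, analysed here as observed values as in the lifetime
# distribution-fitting literature.
275
13
147
23
181
30
65
10
300
173
106
300
300
212
300
300
300
2
261
293
88
247
28
143
300
23
300
80
245
266
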
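# Lifetimes of 50 devices (Aarset 1987, IEEE Trans. Reliability).
# Transcribed from the published table; a classic bathtub-hazard sample.
0.1
0.2
1
1
1
1
1
2
3
6
7
11
12
18
18
18
18
18
21
32
36
40
45
46
47
50
55
60
63
63
67
67
67
67
72
75
79
82
82
83
84
84
84
85
85
85
85
85
86
86
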
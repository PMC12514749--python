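label	n
16–9	71
15–9	43
16–11	10
13–11	6
15–11	6
10–9	4
13–9	1
17–11	1
19–9	1
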
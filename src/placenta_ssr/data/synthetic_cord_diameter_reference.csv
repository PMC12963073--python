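# SYNTHETIC reference curve for tests/demo only - NOT clinical norms
ga_weeks,p3,p10,p50,p90,p97
20,4.2,4.8,6.0,7.2,7.8
21,4.4,5.0,6.3,7.6,8.2
22,4.6,5.3,6.6,7.9,8.6
23,4.8,5.5,6.9,8.3,9.0
24,5.0,5.8,7.2,8.6,9.4
25,5.2,6.0,7.5,9.0,9.8
26,5.5,6.2,7.8,9.4,10.1
27,5.7,6.5,8.1,9.7,10.5
28,5.9,6.7,8.4,10.1,10.9
29,6.1,7.0,8.7,10.4,11.3
30,6.3,7.2,9.0,10.8,11.7
31,6.5,7.4,9.3,11.2,12.1
32,6.7,7.7,9.6,11.5,12.5
33,6.9,7.9,9.9,11.9,12.9
34,7.1,8.2,10.2,12.2,13.3
35,7.3,8.4,10.5,12.6,13.7
36,7.6,8.6,10.8,13.0,14.0
37,7.8,8.9,11.1,13.3,14.4
38,8.0,9.1,11.4,13.7,14.8
39,8.2,9.4,11.7,14.0,15.2
40,8.4,9.6,12.0,14.4,15.6
41,8.6,9.8,12.3,14.8,16.0
42,8.8,10.1,12.6,15.1,16.4
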
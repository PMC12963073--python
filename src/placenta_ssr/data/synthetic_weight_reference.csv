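# SYNTHETIC reference curve for tests/demo only - NOT clinical norms
ga_weeks,p3,p10,p50,p90,p97
20,65,75,100,125,135
21,81,94,125,156,169
22,98,112,150,188,202
23,114,131,175,219,236
24,130,150,200,250,270
25,146,169,225,281,304
26,162,188,250,312,338
27,179,206,275,344,371
28,195,225,300,375,405
29,211,244,325,406,439
30,228,262,350,438,473
31,244,281,375,469,506
32,260,300,400,500,540
33,276,319,425,531,574
34,292,338,450,562,608
35,309,356,475,594,641
36,325,375,500,625,675
37,341,394,525,656,709
38,358,412,550,688,742
39,374,431,575,719,776
40,390,450,600,750,810
41,406,469,625,781,844
42,422,488,650,812,878
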
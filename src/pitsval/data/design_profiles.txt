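11114
13355
14423
15541
21225
22343
23411
24534
25152
31331
32454
33522
34145
35213
41442
42515
43133
44251
45324
51553
52121
53244
54312
55435
12232
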
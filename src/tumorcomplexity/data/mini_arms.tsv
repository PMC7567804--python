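chrom	length	cen_start	cen_end
1	24925062	12153543	12453543
2	24319937	9232617	9532617
3	19802243	9050485	9350485
4	19115427	4966011	5266011
5	18091526	4640564	4940564
6	17111506	5883016	6183016
7	15913866	5805433	6105433
8	14636402	4383888	4683888
9	14121343	4736767	5036767
10	13553474	3925493	4225493
11	13500651	5164420	5464420
12	13385189	3485669	3785669
13	11516987	1600000	1900000
14	10734954	1600000	1900000
15	10253139	1700000	2000000
16	9035475	3533580	3833580
17	8119521	2226300	2526300
18	7807724	1546089	1846089
19	5912898	2468178	2768178
20	6302552	2636956	2936956
21	4812989	1128812	1428812
22	5130456	1300000	1600000
X	15527056	5863201	6163201
Y	5937356	1010455	1310455
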
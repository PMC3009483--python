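# Weight-distribution statistics published for the original sMCL-WMR program,
# kept verbatim for comparison only. Left block: n = 20 with (l, d) varying;
# right block: (l, d) = (15, 4) with n varying; the (15, 4, 20) row appears in
# both blocks. Several rows are internally inconsistent (see docs/methods.md);
# nothing in the package consumes these values as thresholds.
l	d	n	mu_m	mu_d	sd_m	sd_d	alpha_m	alpha_d	block
15	4	20	794	1439	84	84	989	1243	ld
16	5	20	850	1651	86	102	1050	1413	ld
18	6	20	899	2204	89	140	1106	1878	ld
25	8	20	954	2670	111	175	1212	2262	ld
28	9	20	1024	3230	152	199	1378	2767	ld
30	11	20	1069	3882	169	245	1462	3312	ld
15	4	15	432	980	52	60	552	840	n
15	4	20	794	1439	84	84	989	1243	n
15	4	25	1529	2250	129	110	1829	1994	n
15	4	30	1845	3263	196	169	2300	2869	n
15	4	35	2240	4523	246	213	2812	4027	n
15	4	40	3709	6110	389	275	4613	5460	n
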
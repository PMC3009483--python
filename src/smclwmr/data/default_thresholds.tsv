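l	d	n	mu_m	sd_m	mu_d	sd_d	alpha_m	alpha_d	n_samples	seed
10	2	20	639.117	19.94088638827146	619.994	18.42442464294132	685	577	1000	7
12	3	20	924.284	22.936028544746044	916.55	23.18342017414538	977	862	1000	7
14	4	20	1199.794	23.78683201641987	1237.325	25.695245097500443	1255	1177	1000	7
15	4	15	675.459	16.551443117422398	699.382	16.590036326220186	713	660	1000	7
15	4	20	1221.338	25.563905594984295	1242.185	25.622788730001705	1280	1182	1000	7
15	4	25	1929.509	33.00510954770877	1937.77	33.91187277510806	2006	1858	1000	7
16	5	20	1470.564	26.263504634295778	1576.127	28.308306753164015	1531	1510	1000	7
18	6	20	1738.799	28.124181207078166	1923.581	29.97365274468327	1804	1853	1000	7
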
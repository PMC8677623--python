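gene	EGFR	TGFb	JAK_STAT	Hypoxia	PI3K	MAPK	p53
BG.0001	0.0	-1.04	0.0	0.0	-0.0	-0.0	0.0
BG.0002	-0.0	-0.0	-0.853	0.0	0.0	0.0	0.0
BG.0003	0.468	-0.0	0.369	-0.959	0.0	-0.0	-0.185
BG.0004	-0.681	1.223	-0.155	-0.428	-0.0	0.532	0.0
BG.0005	0.0	0.0	2.142	-0.0	-0.0	-0.0	0.0
BG.0006	0.0	-0.0	-0.84	-0.0	0.651	0.0	0.0
BG.0007	-0.666	0.0	0.117	0.0	0.871	0.0	0.679
BG.0008	0.0	0.0	0.0	-0.0	-0.0	-0.0	-0.639
BG.0009	-0.0	1.495	-0.0	0.968	-0.0	-0.0	0.0
BG.0010	0.0	0.0	0.0	-0.0	-0.0	0.0	-0.191
BG.0011	-1.276	-1.133	-0.0	0.0	0.0	0.0	-0.427
BG.0012	0.0	0.0	-0.309	0.457	-0.662	-0.363	-0.382
BG.0013	-0.0	0.0	-0.469	0.0	0.0	0.0	0.0
BG.0014	-0.0	-0.423	-0.0	-0.0	-0.0	-1.323	-0.0
BG.0015	0.0	-0.905	-0.0	0.0	-0.356	0.0	-0.0
BG.0016	-0.205	-0.0	-0.0	0.84	-0.0	0.0	0.238
BG.0017	-0.0	-0.0	0.072	-0.0	0.233	0.0	0.0
BG.0018	-0.0	-1.023	0.0	0.22	1.359	0.835	0.0
BG.0019	1.463	-0.0	-0.0	-0.927	-0.39	-1.377	0.0
BG.0020	-0.0	-1.471	-0.0	0.314	0.0	0.0	0.0
BG.0021	0.0	-0.0	-2.132	0.268	-0.813	-0.0	-0.0
BG.0022	-0.0	0.0	0.157	-0.0	-1.036	-1.675	-0.0
BG.0023	-0.0	0.0	0.13	0.0	-0.499	-0.0	-0.0
BG.0024	-0.725	2.128	-0.821	0.0	-0.0	0.0	0.0
BG.0025	-0.0	-0.041	-0.0	0.446	-0.0	-0.0	-0.0
BG.0026	0.0	1.579	0.0	-0.0	0.0	1.306	0.219
BG.0027	-0.411	1.106	0.0	0.0	0.0	-0.0	-0.0
BG.0028	1.651	0.0	-0.18	-0.383	0.0	-0.0	-0.895
BG.0029	0.0	-0.0	-0.0	-0.0	0.0	1.407	0.0
BG.0030	0.0	-0.0	-0.0	-0.843	-0.0	-0.0	-0.0
BG.0031	0.0	-0.0	0.0	-0.0	-0.328	0.0	0.0
BG.0032	1.337	-0.155	-0.0	-0.224	0.242	0.177	-1.084
BG.0033	0.09	0.0	2.517	0.0	-0.0	-0.287	-1.463
BG.0034	-0.0	0.316	1.206	-0.0	-0.0	-0.0	-0.163
BG.0035	-0.0	-0.0	-0.877	-0.0	-1.758	-1.467	0.0
BG.0036	-1.287	-1.097	0.0	0.0	-0.0	-0.0	0.0
BG.0037	1.729	-0.0	-0.245	0.777	0.0	-0.0	-0.0
BG.0038	-1.375	-0.238	-0.0	0.232	-0.555	0.472	0.0
BG.0039	0.0	0.0	0.053	0.0	-0.0	0.0	-0.0
BG.0040	0.0	0.0	0.386	-0.763	-0.0	1.191	0.0
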
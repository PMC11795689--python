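residue	E_helix	E_sheet	E_other	P1_helix	P1_sheet	P1_other	P2_helix	P2_sheet	P2_other	B1_helix	B1_sheet	B1_other	B2_helix	B2_sheet	B2_other	B3_helix	B3_sheet	B3_other
A	0.111	0.022	0.048	0.275	0.187	0.212	0.216	0.127	0.153	0.441	0.352	0.378	0.398	0.309	0.335	0.31	0.222	0.247
C	-0.032	0.041	0.013	0.132	0.206	0.177	0.072	0.146	0.117	0.368	0.441	0.413	0.3	0.373	0.345	0.167	0.241	0.212
D	0.331	0.261	0.33	0.222	0.151	0.22	0.281	0.211	0.28	-0.079	-0.149	-0.08	0.054	-0.016	0.053	0.186	0.116	0.185
E	0.406	0.235	0.33	0.297	0.126	0.22	0.356	0.185	0.28	-0.004	-0.175	-0.08	0.129	-0.042	0.053	0.261	0.09	0.185
F	0.017	0.054	-0.003	0.182	0.219	0.162	0.122	0.159	0.102	0.447	0.485	0.428	0.349	0.387	0.33	0.217	0.254	0.197
G	0.215	0.242	0.28	0.311	0.338	0.375	0.32	0.347	0.385	0.15	0.177	0.215	0.283	0.31	0.347	0.24	0.268	0.305
H	0.315	0.295	0.315	0.235	0.215	0.235	0.295	0.275	0.295	-0.065	-0.085	-0.065	0.067	0.048	0.067	0.2	0.181	0.2
I	-0.075	0.003	-0.087	0.089	0.167	0.077	0.03	0.108	0.018	0.39	0.468	0.378	0.257	0.335	0.245	0.124	0.203	0.112
K	0.374	0.311	0.35	0.224	0.161	0.2	0.284	0.221	0.26	-0.076	-0.139	-0.1	0.056	-0.007	0.032	0.189	0.126	0.165
L	-0.021	-0.008	-0.053	0.144	0.158	0.112	0.084	0.098	0.052	0.444	0.457	0.412	0.311	0.325	0.28	0.179	0.193	0.148
M	0.11	0.05	0.043	0.275	0.215	0.207	0.215	0.155	0.148	0.45	0.39	0.383	0.407	0.347	0.34	0.31	0.25	0.242
N	0.368	0.401	0.418	0.258	0.291	0.307	0.283	0.316	0.332	-0.042	-0.009	0.007	0.091	0.124	0.14	0.153	0.186	0.202
P	0.276	0.273	0.34	0.371	0.368	0.435	0.31	0.307	0.375	0.09	0.087	0.155	0.223	0.22	0.287	0.18	0.177	0.245
Q	0.434	0.433	0.418	0.324	0.322	0.307	0.349	0.347	0.332	0.024	0.022	0.007	0.157	0.155	0.14	0.219	0.217	0.202
R	0.332	0.325	0.335	0.167	0.16	0.17	0.227	0.22	0.23	-0.133	-0.14	-0.13	-0.001	-0.008	0.003	0.132	0.124	0.135
S	0.248	0.245	0.283	0.308	0.305	0.342	0.423	0.42	0.458	0.108	0.105	0.143	0.24	0.237	0.275	0.303	0.3	0.337
T	0.252	0.306	0.278	0.312	0.366	0.337	0.427	0.481	0.453	0.122	0.176	0.148	0.255	0.309	0.28	0.317	0.371	0.342
V	-0.064	0.032	-0.073	0.101	0.197	0.092	0.042	0.138	0.033	0.402	0.497	0.393	0.269	0.365	0.26	0.137	0.232	0.128
W	0.299	0.343	0.287	0.359	0.403	0.347	0.474	0.518	0.462	0.15	0.193	0.138	0.282	0.326	0.27	0.345	0.388	0.333
Y	0.261	0.378	0.307	0.321	0.438	0.367	0.396	0.513	0.442	0.071	0.188	0.117	0.203	0.32	0.25	0.266	0.383	0.313
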
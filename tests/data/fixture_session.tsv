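# animal_id	fixture01
# group	EYFP_CONTROL
# day	1
# protocol	NONE
time_s	code	payload
0.00	BLOCK_FORCED_START	
1.00	BEAM_OUT	
2.00	LP1	
2.50	LP1	
3.00	LP1	
3.50	LP1	
4.50	LP2	
5.00	LP2	
5.50	LP2	
6.00	LP2	
6.30	REWARD	
7.00	MAG_IN	
9.00	BEAM_OUT	
10.00	LP1	
10.40	LP1	
11.50	MAG_IN	
11.50	TIMEOUT_START	
23.00	BEAM_OUT	
24.00	LP1	
24.50	LP1	
25.00	LP1	
25.50	LP1	
26.50	LP2	
28.00	MAG_IN	
28.00	TIMEOUT_START	
40.00	BEAM_OUT	
41.00	LP1	
41.50	LP1	
42.00	LP1	
42.50	LP1	
43.50	LP2	
44.00	LP2	
44.50	LP2	
45.00	LP2	
45.30	REWARD	
46.00	MAG_IN	
47.00	BLOCK_SELF_START	
48.00	BEAM_OUT	
48.00	LP1	
48.50	LP1	
49.00	LP1	
49.50	LP1	
50.50	LP2	
51.00	LP2	
51.50	LP2	
52.00	LP2	
52.30	REWARD	
53.00	MAG_IN	
55.00	BEAM_OUT	
56.00	LP1	
56.40	LP1	
56.80	LP1	
57.20	LP1	
57.60	LP1	
58.40	LP2	
58.80	LP2	
59.20	LP2	
59.60	LP2	
59.90	REWARD	
60.50	MAG_IN	
62.00	BEAM_OUT	
63.00	LP2	
63.40	LP2	
64.50	MAG_IN	
64.50	TIMEOUT_START	
76.00	BEAM_OUT	
77.00	LP1	
77.50	LP1	
78.50	LP2	
80.00	MAG_IN	
80.00	TIMEOUT_START	
92.00	BEAM_OUT	
93.00	LP1	
93.50	LP1	
94.00	LP1	
95.50	MAG_IN	
95.50	TIMEOUT_START	
107.00	BEAM_OUT	
108.00	LP1	
108.50	LP1	
109.00	LP1	
109.50	LP1	
110.00	LP1	
111.00	LP2	
111.40	LP2	
111.80	LP2	
113.00	MAG_IN	
113.00	TIMEOUT_START	
125.00	BEAM_OUT	
126.00	MAG_IN	
128.00	BEAM_OUT	
129.00	BEAM_OUT	
130.00	LP1	
130.50	LP1	
131.00	LP1	
131.50	LP1	
132.30	LP2	
132.80	LP2	
133.30	LP2	
133.80	LP2	
134.10	REWARD	
134.80	MAG_IN	
137.00	BEAM_OUT	
138.00	LP1	
138.50	LP1	
139.00	LP1	
139.50	LP1	
140.50	LP2	
141.00	LP1	
141.50	LP2	
142.00	LP2	
142.50	LP2	
142.80	REWARD	
143.50	MAG_IN	
150.00	SESSION_END	
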
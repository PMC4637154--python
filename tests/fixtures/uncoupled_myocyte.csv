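# fmgap 0.1.0
# parameter_set_hash 2efe2bc864d395c6
# fixture uncoupled_myocyte.csv
t,V_myo,stim
0.0,-84.38,0.0
1.0,-84.421628,0.0
2.0,-84.452398,0.0
3.0,-84.475137,0.0
4.0,-84.491943,0.0
5.0,-84.504368,0.0
6.0,-84.51356,0.0
7.0,-84.520366,0.0
8.0,-84.52541,0.0
9.0,-84.529154,0.0
10.0,-84.531937,1.0
11.0,-45.394649,0.0
12.0,42.698856,0.0
13.0,37.032828,0.0
14.0,32.004993,0.0
15.0,27.645478,0.0
16.0,23.906808,0.0
17.0,20.743736,0.0
18.0,18.110088,0.0
19.0,15.955348,0.0
20.0,14.224043,0.0
21.0,12.858203,0.0
22.0,11.801107,0.0
23.0,11.000388,0.0
24.0,10.40975,0.0
25.0,9.989427,0.0
26.0,9.705896,0.0
27.0,9.531214,0.0
28.0,9.442263,0.0
29.0,9.420019,0.0
30.0,9.448891,0.0
31.0,9.516157,0.0
32.0,9.61148,0.0
33.0,9.726504,0.0
34.0,9.854509,0.0
35.0,9.990128,0.0
36.0,10.12911,0.0
37.0,10.268115,0.0
38.0,10.404552,0.0
39.0,10.536439,0.0
40.0,10.662289,0.0
41.0,10.781014,0.0
42.0,10.891846,0.0
43.0,10.994278,0.0
44.0,11.088004,0.0
45.0,11.172881,0.0
46.0,11.248893,0.0
47.0,11.316122,0.0
48.0,11.374722,0.0
49.0,11.424908,0.0
50.0,11.466934,0.0
51.0,11.501081,0.0
52.0,11.527654,0.0
53.0,11.546967,0.0
54.0,11.559341,0.0
55.0,11.565099,0.0
56.0,11.564559,0.0
57.0,11.558038,0.0
58.0,11.54584,0.0
59.0,11.528266,0.0
60.0,11.505604,0.0
61.0,11.478129,0.0
62.0,11.44611,0.0
63.0,11.4098,0.0
64.0,11.369443,0.0
65.0,11.325269,0.0
66.0,11.2775,0.0
67.0,11.226342,0.0
68.0,11.171995,0.0
69.0,11.114646,0.0
70.0,11.054472,0.0
71.0,10.99164,0.0
72.0,10.926309,0.0
73.0,10.858627,0.0
74.0,10.788736,0.0
75.0,10.716766,0.0
76.0,10.642845,0.0
77.0,10.567087,0.0
78.0,10.489605,0.0
79.0,10.410501,0.0
80.0,10.329873,0.0
81.0,10.247812,0.0
82.0,10.164405,0.0
83.0,10.079731,0.0
84.0,9.993867,0.0
85.0,9.906884,0.0
86.0,9.818846,0.0
87.0,9.729817,0.0
88.0,9.639855,0.0
89.0,9.549014,0.0
90.0,9.457344,0.0
91.0,9.364893,0.0
92.0,9.271706,0.0
93.0,9.177823,0.0
94.0,9.083282,0.0
95.0,8.988121,0.0
96.0,8.892371,0.0
97.0,8.796064,0.0
98.0,8.699228,0.0
99.0,8.601891,0.0
100.0,8.504076,0.0
101.0,8.405806,0.0
102.0,8.307102,0.0
103.0,8.207983,0.0
104.0,8.108468,0.0
105.0,8.008572,0.0
106.0,7.908311,0.0
107.0,7.807697,0.0
108.0,7.706743,0.0
109.0,7.605461,0.0
110.0,7.503859,0.0
111.0,7.401948,0.0
112.0,7.299734,0.0
113.0,7.197226,0.0
114.0,7.094428,0.0
115.0,6.991348,0.0
116.0,6.887988,0.0
117.0,6.784353,0.0
118.0,6.680446,0.0
119.0,6.576269,0.0
120.0,6.471824,0.0
121.0,6.367112,0.0
122.0,6.262134,0.0
123.0,6.156889,0.0
124.0,6.051378,0.0
125.0,5.945599,0.0
126.0,5.83955,0.0
127.0,5.733231,0.0
128.0,5.626638,0.0
129.0,5.51977,0.0
130.0,5.412622,0.0
131.0,5.305191,0.0
132.0,5.197474,0.0
133.0,5.089467,0.0
134.0,4.981164,0.0
135.0,4.872562,0.0
136.0,4.763655,0.0
137.0,4.654438,0.0
138.0,4.544905,0.0
139.0,4.43505,0.0
140.0,4.324867,0.0
141.0,4.214351,0.0
142.0,4.103493,0.0
143.0,3.992288,0.0
144.0,3.880728,0.0
145.0,3.768807,0.0
146.0,3.656516,0.0
147.0,3.543847,0.0
148.0,3.430794,0.0
149.0,3.317348,0.0
150.0,3.203501,0.0
151.0,3.089244,0.0
152.0,2.974568,0.0
153.0,2.859466,0.0
154.0,2.743928,0.0
155.0,2.627944,0.0
156.0,2.511506,0.0
157.0,2.394605,0.0
158.0,2.27723,0.0
159.0,2.159371,0.0
160.0,2.04102,0.0
161.0,1.922166,0.0
162.0,1.802799,0.0
163.0,1.682908,0.0
164.0,1.562483,0.0
165.0,1.441513,0.0
166.0,1.319988,0.0
167.0,1.197897,0.0
168.0,1.075228,0.0
169.0,0.951972,0.0
170.0,0.828115,0.0
171.0,0.703648,0.0
172.0,0.578558,0.0
173.0,0.452834,0.0
174.0,0.326464,0.0
175.0,0.199436,0.0
176.0,0.071738,0.0
177.0,-0.056641,0.0
178.0,-0.185715,0.0
179.0,-0.315495,0.0
180.0,-0.445994,0.0
181.0,-0.577224,0.0
182.0,-0.709198,0.0
183.0,-0.841929,0.0
184.0,-0.97543,0.0
185.0,-1.109712,0.0
186.0,-1.244791,0.0
187.0,-1.380677,0.0
188.0,-1.517385,0.0
189.0,-1.654928,0.0
190.0,-1.793319,0.0
191.0,-1.932571,0.0
192.0,-2.072698,0.0
193.0,-2.213713,0.0
194.0,-2.35563,0.0
195.0,-2.498462,0.0
196.0,-2.642222,0.0
197.0,-2.786925,0.0
198.0,-2.932584,0.0
199.0,-3.079212,0.0
200.0,-3.226824,0.0
201.0,-3.375432,0.0
202.0,-3.525051,0.0
203.0,-3.675694,0.0
204.0,-3.827374,0.0
205.0,-3.980105,0.0
206.0,-4.133901,0.0
207.0,-4.288774,0.0
208.0,-4.444739,0.0
209.0,-4.601808,0.0
210.0,-4.759994,0.0
211.0,-4.919312,0.0
212.0,-5.079772,0.0
213.0,-5.24139,0.0
214.0,-5.404176,0.0
215.0,-5.568143,0.0
216.0,-5.733304,0.0
217.0,-5.899672,0.0
218.0,-6.067256,0.0
219.0,-6.236071,0.0
220.0,-6.406126,0.0
221.0,-6.577433,0.0
222.0,-6.750004,0.0
223.0,-6.923848,0.0
224.0,-7.098976,0.0
225.0,-7.275397,0.0
226.0,-7.453123,0.0
227.0,-7.632161,0.0
228.0,-7.812521,0.0
229.0,-7.99421,0.0
230.0,-8.177238,0.0
231.0,-8.361612,0.0
232.0,-8.547338,0.0
233.0,-8.734423,0.0
234.0,-8.922874,0.0
235.0,-9.112695,0.0
236.0,-9.303893,0.0
237.0,-9.496469,0.0
238.0,-9.69043,0.0
239.0,-9.885777,0.0
240.0,-10.082513,0.0
241.0,-10.28064,0.0
242.0,-10.480158,0.0
243.0,-10.681068,0.0
244.0,-10.883368,0.0
245.0,-11.087059,0.0
246.0,-11.292136,0.0
247.0,-11.498598,0.0
248.0,-11.70644,0.0
249.0,-11.915657,0.0
250.0,-12.126244,0.0
251.0,-12.338194,0.0
252.0,-12.551498,0.0
253.0,-12.76615,0.0
254.0,-12.982139,0.0
255.0,-13.199454,0.0
256.0,-13.418084,0.0
257.0,-13.638017,0.0
258.0,-13.859239,0.0
259.0,-14.081735,0.0
260.0,-14.30549,0.0
261.0,-14.530489,0.0
262.0,-14.756712,0.0
263.0,-14.984143,0.0
264.0,-15.212762,0.0
265.0,-15.44255,0.0
266.0,-15.673485,0.0
267.0,-15.905546,0.0
268.0,-16.138711,0.0
269.0,-16.372958,0.0
270.0,-16.608263,0.0
271.0,-16.844603,0.0
272.0,-17.081953,0.0
273.0,-17.320291,0.0
274.0,-17.559592,0.0
275.0,-17.799831,0.0
276.0,-18.040985,0.0
277.0,-18.283031,0.0
278.0,-18.525946,0.0
279.0,-18.769707,0.0
280.0,-19.014294,0.0
281.0,-19.259686,0.0
282.0,-19.505864,0.0
283.0,-19.752812,0.0
284.0,-20.000515,0.0
285.0,-20.248958,0.0
286.0,-20.498132,0.0
287.0,-20.748028,0.0
288.0,-20.99864,0.0
289.0,-21.249966,0.0
290.0,-21.502008,0.0
291.0,-21.754769,0.0
292.0,-22.00826,0.0
293.0,-22.262492,0.0
294.0,-22.517484,0.0
295.0,-22.773257,0.0
296.0,-23.02984,0.0
297.0,-23.287265,0.0
298.0,-23.545571,0.0
299.0,-23.804802,0.0
300.0,-24.065008,0.0
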
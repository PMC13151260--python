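age,sex,stroke_type,affected_side,days_to_ragt,gaa_baseline,sias_hip_flexion,sias_knee_extension,sias_ankle_dorsiflexion,sias_touch,sias_position_sense,sias_trunk_verticality,sias_abdominal,fim_comprehension,fim_expression,fim_social_interaction,fim_problem_solving,fim_memory,gaa_4wk
64.8,male,hemorrhage,right,36.0,1,0,0,0,1,1,0,0,5,3,6,4,2,3
82.1,female,hemorrhage,right,36.0,1,0,0,0,0,0,1,1,2,1,4,2,2,4
68.8,male,hemorrhage,left,69.0,2,1,0,1,2,3,3,3,5,5,5,2,2,2
73.4,male,infarction,right,109.0,3,0,0,0,1,1,3,0,7,7,3,5,6,5
57.2,male,hemorrhage,left,38.0,3,1,0,0,0,1,1,0,2,3,4,1,1,4
68.0,female,infarction,left,63.0,4,2,1,0,3,3,3,2,4,3,1,3,3,5
47.4,male,infarction,right,39.0,4,3,2,3,2,2,1,1,3,3,6,1,2,2
61.2,male,hemorrhage,left,32.0,2,0,1,0,3,1,2,1,4,2,3,3,4,6
58.3,male,infarction,left,47.0,2,0,0,0,0,1,1,0,5,3,5,2,4,2
80.1,male,infarction,left,48.0,3,0,1,0,2,0,2,2,4,5,5,2,4,2
57.8,female,hemorrhage,left,40.0,4,4,0,0,3,1,2,1,7,6,3,5,2,3
54.5,male,hemorrhage,right,49.0,3,0,1,0,1,2,2,2,3,3,5,5,5,5
65.8,female,hemorrhage,right,37.0,3,1,2,2,2,2,3,1,6,5,3,4,7,5
66.6,female,hemorrhage,right,61.0,3,1,0,0,2,2,2,0,2,1,2,2,1,4
59.2,male,infarction,left,30.0,3,1,1,0,1,0,1,0,1,2,5,1,1,5
57.1,male,infarction,left,28.0,3,0,0,0,2,3,3,3,6,7,3,1,3,5
47.8,female,hemorrhage,right,57.0,2,3,1,0,3,2,2,1,4,5,4,2,3,4
64.8,female,infarction,left,26.0,3,0,0,0,1,0,3,0,7,6,7,6,6,6
60.8,male,hemorrhage,right,44.0,2,0,0,0,2,2,3,1,1,2,5,3,2,5
45.2,male,hemorrhage,right,53.0,4,2,5,2,3,3,3,1,5,4,6,2,3,4
65.1,male,hemorrhage,right,44.0,3,0,0,0,0,0,3,3,7,7,6,6,6,3
79.9,male,infarction,left,29.0,3,2,0,0,1,0,3,2,6,7,5,4,7,5
51.4,male,hemorrhage,left,64.0,3,0,0,0,2,1,3,3,1,1,5,1,3,2
70.9,male,hemorrhage,left,74.0,3,5,3,1,1,0,1,1,7,7,5,4,3,2
61.6,male,hemorrhage,right,27.0,3,2,1,0,1,0,3,3,4,4,2,5,5,5
53.8,male,hemorrhage,left,44.0,3,1,0,0,2,3,2,1,3,4,3,3,1,2
53.6,male,hemorrhage,left,68.0,2,2,0,1,2,3,2,0,2,2,3,4,1,5
51.5,male,hemorrhage,left,33.0,2,2,0,0,1,2,2,2,3,3,5,6,3,6
52.6,male,hemorrhage,right,24.0,2,0,1,0,3,2,2,1,5,7,5,4,4,5
47.0,female,hemorrhage,right,40.0,2,2,2,2,3,0,3,2,2,4,1,5,4,6
73.0,male,hemorrhage,right,53.0,3,0,0,0,1,0,2,1,4,2,5,4,4,2
42.9,female,infarction,right,34.0,2,2,0,0,1,2,1,0,4,4,4,5,2,4
55.4,male,hemorrhage,left,65.0,2,1,0,0,0,1,3,3,4,5,6,2,5,5
82.3,female,hemorrhage,right,41.0,3,4,2,1,2,1,0,0,5,6,5,4,6,7
46.9,female,infarction,right,35.0,1,0,1,2,2,2,3,0,3,3,6,4,3,2
76.0,male,hemorrhage,left,76.0,3,0,2,0,2,2,0,0,7,5,3,2,4,2
55.0,male,infarction,left,28.0,4,4,4,5,2,1,2,3,4,3,4,1,2,5
56.8,male,hemorrhage,right,50.0,3,0,0,0,3,2,0,0,3,2,5,3,2,4
57.2,male,hemorrhage,right,52.0,4,2,0,0,0,0,3,1,4,1,4,6,5,5
76.5,female,hemorrhage,right,47.0,1,0,0,0,2,1,2,2,4,5,2,2,2,4
61.6,female,hemorrhage,right,22.0,2,2,1,0,1,2,3,1,5,4,5,7,6,6
48.6,female,hemorrhage,right,58.0,1,0,0,0,1,0,3,3,1,3,1,1,1,3
79.0,male,infarction,right,50.0,2,0,0,0,2,3,1,1,4,5,5,3,5,2
48.3,male,hemorrhage,left,38.0,3,2,1,0,1,1,3,1,3,5,7,3,2,6
42.2,male,infarction,left,22.0,3,1,3,4,2,1,3,2,5,4,4,3,7,5
43.9,male,hemorrhage,right,35.0,4,0,0,0,1,1,3,1,4,6,7,2,2,6
43.7,male,hemorrhage,left,29.0,3,0,0,0,2,2,3,1,4,3,5,3,1,2
80.3,male,infarction,right,25.0,3,2,1,2,0,1,3,1,6,7,7,2,4,5
55.0,male,hemorrhage,right,21.0,2,0,1,0,1,1,3,3,3,4,4,4,4,5
59.5,female,hemorrhage,right,36.0,4,1,0,0,0,1,3,1,4,2,5,2,1,5
67.7,female,infarction,left,41.0,3,2,2,0,0,1,3,2,2,3,5,1,1,5
73.9,male,hemorrhage,left,45.0,2,0,0,0,0,1,2,0,4,5,4,4,6,3
66.8,male,hemorrhage,left,37.0,1,0,0,1,1,0,1,0,2,1,2,2,2,3
83.1,female,infarction,right,31.0,3,0,2,0,0,0,2,0,5,6,3,4,5,3
60.0,male,hemorrhage,right,59.0,3,0,0,0,2,2,2,0,4,3,5,4,3,5
46.3,male,hemorrhage,right,39.0,2,1,2,0,2,3,3,0,3,4,2,2,4,6
50.0,female,hemorrhage,right,46.0,1,1,0,0,0,1,1,1,3,4,4,3,3,2
63.6,male,infarction,right,60.0,3,0,0,0,1,1,3,3,6,5,6,6,4,2
42.5,male,infarction,left,49.0,2,0,1,0,2,1,2,3,5,6,4,5,7,3
46.1,male,infarction,right,45.0,1,0,0,0,1,2,2,2,4,5,2,6,6,3
70.1,male,infarction,right,54.0,2,0,0,0,1,2,3,2,3,4,6,3,4,1
79.0,male,hemorrhage,right,46.0,3,0,1,0,2,1,3,2,4,5,1,6,5,6
55.1,male,hemorrhage,right,55.0,2,0,0,0,0,0,3,3,4,1,3,4,4,3
66.3,female,hemorrhage,left,72.0,2,0,1,0,2,2,3,2,6,4,5,4,6,4
71.4,male,hemorrhage,right,54.0,1,0,0,0,2,0,2,2,4,2,6,3,3,3
81.5,male,infarction,right,31.0,3,3,2,0,1,1,2,0,3,4,1,6,3,6
79.4,male,infarction,left,36.0,3,0,0,0,0,0,1,0,2,4,5,2,2,3
77.3,male,hemorrhage,left,47.0,1,0,0,0,3,2,3,2,6,7,4,4,4,6
60.0,male,infarction,right,67.0,2,3,4,3,1,2,2,0,5,5,5,3,3,2
80.6,male,hemorrhage,left,45.0,1,1,2,0,2,1,1,0,5,5,3,3,2,2
60.2,male,infarction,right,57.0,3,0,1,1,1,1,3,3,7,6,4,2,2,6
71.9,male,hemorrhage,right,42.0,4,3,2,0,1,0,2,2,1,2,1,2,3,5
45.5,female,hemorrhage,right,62.0,1,0,0,0,1,3,2,2,3,2,4,3,1,4
64.2,male,infarction,right,30.0,2,0,0,0,0,0,2,3,5,4,5,4,4,3
66.5,female,infarction,left,31.0,3,1,1,0,1,2,2,1,4,6,2,2,3,5
50.3,male,infarction,right,34.0,2,2,4,0,1,2,3,2,4,3,5,6,5,5
66.4,male,hemorrhage,right,88.0,3,1,0,1,1,3,1,0,2,2,2,3,3,3
47.9,male,hemorrhage,right,56.0,3,2,2,1,0,1,2,0,3,3,4,3,1,4
62.8,male,hemorrhage,left,39.0,1,0,0,0,1,2,0,0,6,3,7,3,5,6
78.9,female,hemorrhage,right,35.0,4,1,2,0,0,2,2,0,6,4,5,1,2,5
77.0,female,hemorrhage,left,58.0,3,0,0,0,0,0,2,2,7,5,3,5,4,2
80.4,female,infarction,right,48.0,3,0,1,0,2,1,2,0,1,4,4,4,2,2
74.0,male,infarction,right,71.0,2,4,3,4,3,2,2,0,6,6,5,4,7,5
42.4,female,hemorrhage,left,17.0,2,1,1,0,0,0,1,1,3,6,4,7,5,4
44.5,male,infarction,right,55.0,3,0,0,0,0,0,2,1,1,3,1,2,1,4
46.8,male,infarction,right,41.0,3,1,1,0,2,2,2,0,5,4,7,4,5,5
79.6,female,infarction,left,95.0,2,1,0,0,0,0,2,0,3,6,1,5,3,2
65.6,male,infarction,left,40.0,4,0,1,0,0,0,3,1,7,4,7,7,7,5
63.5,female,hemorrhage,left,43.0,4,3,0,0,0,2,3,2,3,4,3,2,4,7
44.6,male,hemorrhage,right,33.0,1,0,0,0,1,2,2,0,6,7,6,3,2,5
43.4,female,infarction,left,39.0,1,0,0,1,2,0,2,1,3,4,6,4,3,5
46.4,male,infarction,right,37.0,3,2,3,1,2,0,3,2,2,1,3,2,1,6
77.8,female,infarction,right,43.0,3,1,0,0,2,2,3,2,3,2,4,3,3,1
70.4,male,hemorrhage,left,51.0,3,1,0,0,3,2,3,1,4,2,7,3,6,7
62.2,male,infarction,left,41.0,2,1,3,0,0,0,3,0,6,5,4,4,4,5
58.7,male,infarction,left,32.0,4,2,0,0,0,1,3,3,6,3,6,4,5,5
57.6,female,hemorrhage,right,33.0,2,0,0,0,0,1,2,2,1,1,5,2,3,5
75.5,male,hemorrhage,right,42.0,2,1,1,2,1,2,1,0,5,6,7,5,4,5
63.6,female,hemorrhage,right,78.0,1,1,1,0,0,0,2,1,5,2,7,7,5,3
56.9,male,hemorrhage,left,51.0,4,1,0,0,1,1,3,2,5,4,3,3,5,3
55.9,female,infarction,right,30.0,4,3,2,0,1,1,2,1,4,2,3,3,2,7
46.5,female,hemorrhage,right,52.0,4,0,0,0,0,0,3,2,1,2,5,2,1,3
41.9,male,hemorrhage,right,49.0,2,1,0,0,0,0,3,3,5,5,7,1,2,5
68.3,male,hemorrhage,left,84.0,2,0,1,1,2,2,3,1,4,5,2,2,3,6
66.4,male,infarction,right,24.0,3,0,0,0,0,1,3,2,2,1,2,5,5,5
80.8,male,hemorrhage,left,27.0,4,1,2,1,3,3,2,2,2,2,5,4,3,6
56.8,male,infarction,right,44.0,3,0,1,0,1,1,3,1,4,1,4,5,6,5
58.0,male,hemorrhage,right,43.0,3,1,0,0,1,2,3,0,2,1,2,7,5,4
68.8,male,hemorrhage,left,50.0,2,1,1,0,3,3,3,0,1,4,3,2,2,2
70.5,male,hemorrhage,right,33.0,4,0,1,0,0,2,3,2,4,3,6,1,2,5
54.6,male,hemorrhage,right,29.0,2,3,0,2,1,2,2,3,5,4,6,1,2,4
44.4,male,hemorrhage,left,32.0,3,0,1,0,0,0,2,1,2,2,5,1,2,1
62.7,male,hemorrhage,right,42.0,3,0,0,1,2,3,3,1,5,2,7,2,6,5
71.5,male,hemorrhage,right,80.0,3,0,1,0,1,0,1,1,3,3,5,1,3,4
74.6,male,hemorrhage,right,27.0,3,2,1,0,2,0,3,3,4,4,7,2,3,5
52.5,male,infarction,left,46.0,4,1,0,1,1,1,3,2,4,5,3,7,5,5
44.6,male,infarction,right,37.0,2,1,0,2,0,0,3,3,3,2,4,5,4,6
51.9,female,hemorrhage,right,19.0,2,0,0,0,0,0,3,2,5,4,4,3,5,3
53.6,male,infarction,left,66.0,1,0,0,0,0,1,0,0,5,7,6,5,6,2
51.2,male,hemorrhage,left,34.0,1,0,0,0,2,2,2,1,6,5,6,5,3,3
76.2,female,hemorrhage,left,26.0,3,0,1,0,2,0,2,1,4,6,6,1,3,6
56.8,male,infarction,left,60.0,2,0,0,0,2,1,1,0,6,4,4,1,3,6
53.1,male,hemorrhage,right,23.0,2,1,0,0,0,1,1,0,3,1,6,3,1,6
50.2,female,hemorrhage,left,53.0,1,0,0,0,0,0,1,1,5,4,4,4,5,3
57.4,female,hemorrhage,left,62.0,3,0,0,1,0,0,3,1,3,1,4,5,5,5
63.1,male,infarction,left,38.0,2,1,3,0,2,2,2,2,2,5,2,4,3,6
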
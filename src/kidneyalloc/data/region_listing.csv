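region,cost_of_living_month,expected_wait_years,n_evaluations,evaluation_cost,survival_5yr,distance_miles,utility
1,2454,2.4,4,6381,0.73,2200,9.1
2,1879,1.8,3,4614,0.70,1904,13.2
3,1637,1.9,3,4541,0.76,1706,13.6
4,2328,1.4,2,3166,0.75,1160,12.8
5,2130,2.5,5,7815,0.79,374,13.5
6,2413,1.6,3,0,0.83,0,9.7
7,2686,2.3,4,6474,0.74,670,12.0
8,2869,1.4,2,3274,0.76,569,11.9
9,2705,2.2,4,6482,0.69,1195,8.9
10,2005,1.8,3,4651,0.72,565,12.7
11,2706,1.4,2,3241,0.72,941,12.8
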
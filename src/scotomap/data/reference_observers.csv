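observer,loc_h,loc_v,loc_h_min,loc_h_max,loc_h_sd,loc_v_min,loc_v_max,loc_v_sd,loc_stdist,loc_dist_min,loc_dist_max,width,width_min,width_max,width_sd,height,height_min,height_max,height_sd,raw_border_sum_stdist,adj_border_sum_stdist
1,15.21,-1.51,15.00,15.63,0.22,-1.94,-1.18,0.30,0.28,0.08,0.53,5.97,5.81,6.19,0.15,6.35,5.99,6.61,0.26,0.97,0.87
2,15.17,-2.19,14.99,15.27,0.11,-2.31,-2.02,0.11,0.14,0.06,0.20,5.79,5.43,5.97,0.21,6.45,6.09,6.74,0.30,0.61,0.59
3,16.51,-0.52,16.39,16.64,0.09,-0.69,-0.36,0.11,0.12,0.06,0.20,6.71,6.54,6.85,0.11,7.57,7.36,7.81,0.19,0.42,0.65
4,16.42,-0.50,16.23,16.59,0.12,-0.69,-0.31,0.15,0.15,0.10,0.20,7.12,6.58,7.52,0.31,6.83,6.60,7.05,0.20,0.74,0.85
5,15.91,-2.40,15.72,16.21,0.23,-2.86,-1.99,0.34,0.29,0.22,0.55,6.72,6.44,7.00,0.24,5.79,5.42,6.20,0.37,1.11,1.15
7,16.38,-1.40,16.25,16.59,0.14,-1.57,-1.25,0.15,0.17,0.16,0.22,6.57,6.21,6.71,0.18,7.40,7.12,7.65,0.20,0.85,0.68
8,16.24,-2.01,15.98,16.50,0.21,-2.36,-1.45,0.38,0.27,0.16,0.62,5.39,4.82,5.69,0.33,7.47,6.95,7.76,0.34,1.03,1.01
9,16.18,-2.27,15.92,16.31,0.14,-2.46,-2.05,0.15,0.18,0.06,0.33,5.92,5.73,6.14,0.15,5.91,5.77,6.06,0.11,0.68,0.69
10,15.92,-4.33,15.71,16.23,0.21,-4.49,-4.04,0.16,0.27,0.10,0.34,7.44,7.24,7.66,0.15,8.14,7.85,8.49,0.26,1.10,0.98
11,15.31,-3.03,15.19,15.49,0.13,-3.33,-2.84,0.22,0.16,0.13,0.33,6.15,6.00,6.21,0.08,7.91,7.46,8.28,0.36,0.75,0.72
12,16.05,-3.66,15.84,16.25,0.15,-4.45,-3.18,0.48,0.20,0.05,0.81,5.88,4.97,6.51,0.52,7.54,7.02,8.08,0.44,0.75,1.16
13,16.73,-0.74,16.60,16.79,0.07,-1.21,0.08,0.50,0.09,0.11,0.82,5.71,5.19,6.27,0.38,6.94,6.41,7.24,0.34,0.62,0.73
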
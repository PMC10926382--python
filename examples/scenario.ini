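# Reference two-station scenario: nest 400 m north of BS1.
# Units: metres, seconds, m/s, degrees.

[model]
t_nest = 45
s_min = 1.8
s_max = 5.4
angle_short = 10
angle_long = 15
threshold_s = 600
min_trips = 3

[simulation]
nest_x_m = 0
nest_y_m = 400
stations = BS1:0:0, BS2:300:150
n_hornets_per_station = 1
trips_per_hornet = 4
speed_mean = 2.7
speed_sd = 0.5
handling_mean = 45
handling_sd = 10
bearing_noise_sd = 3
seed = 7
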
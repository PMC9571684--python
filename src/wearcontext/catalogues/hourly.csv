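name,domain
mean,time
std,time
variance,time
minimum,time
maximum,time
median,time
range,time
rms,time
abs_energy,time
skewness,time
kurtosis,time
zero_crossings,time
mean_abs_change,time
mean_change,time
abs_max,time
quantile_25,time
quantile_75,time
iqr,time
autocorr_lag_1,time
autocorr_lag_2,time
autocorr_lag_5,time
count_above_mean,time
count_below_mean,time
sum_abs,time
dominant_frequency,frequency
spectral_centroid,frequency
spectral_spread,frequency
spectral_entropy,frequency
spectral_flatness,frequency
median_frequency,frequency
spectral_rolloff_85,frequency
total_power,frequency
peak_power,frequency
band_energy_0.3_1,frequency
band_energy_1_3,frequency
band_energy_3_5,frequency
band_energy_5_8,frequency
band_energy_8_15,frequency
low_high_power_ratio,frequency
quantile_05,time
quantile_10,time
quantile_90,time
quantile_95,time
mean_abs_dev,time
median_abs_dev,time
autocorr_lag_3,time
autocorr_lag_4,time
autocorr_lag_6,time
autocorr_lag_7,time
autocorr_lag_8,time
autocorr_lag_9,time
autocorr_lag_10,time
cid_ce,time
number_peaks_3,time
binned_entropy_10,time
first_location_of_max,time
last_location_of_max,time
first_location_of_min,time
last_location_of_min,time
ratio_beyond_1_sigma,time
ratio_beyond_2_sigma,time
ratio_beyond_3_sigma,time
longest_strike_above_mean,time
longest_strike_below_mean,time
variation_coefficient,time
energy_ratio_first_half,time
index_mass_quantile_50,time
linear_trend_slope,time
linear_trend_intercept,time
sum_values,time
abs_sum_changes,time
mean_second_derivative,time
time_reversal_asymmetry_1,time
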
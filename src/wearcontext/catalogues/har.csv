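name,domain,inputs
mean,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
std,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
variance,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
minimum,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
maximum,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
median,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
range,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
rms,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
abs_energy,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
skewness,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
kurtosis,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
zero_crossings,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
mean_abs_change,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
mean_change,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
abs_max,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
quantile_25,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
quantile_75,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
iqr,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
autocorr_lag_1,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
autocorr_lag_2,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
autocorr_lag_5,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
count_above_mean,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
count_below_mean,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
sum_abs,time,accel_x;accel_y;accel_z;accel_norm;gsr_phasic;gsr_tonic;skin_temp
dominant_frequency,frequency,accel_x;accel_y;accel_z;accel_norm
spectral_centroid,frequency,accel_x;accel_y;accel_z;accel_norm
spectral_spread,frequency,accel_x;accel_y;accel_z;accel_norm
spectral_entropy,frequency,accel_x;accel_y;accel_z;accel_norm
spectral_flatness,frequency,accel_x;accel_y;accel_z;accel_norm
median_frequency,frequency,accel_x;accel_y;accel_z;accel_norm
spectral_rolloff_85,frequency,accel_x;accel_y;accel_z;accel_norm
total_power,frequency,accel_x;accel_y;accel_z;accel_norm
peak_power,frequency,accel_x;accel_y;accel_z;accel_norm
band_energy_0.3_1,frequency,accel_x;accel_y;accel_z;accel_norm
band_energy_1_3,frequency,accel_x;accel_y;accel_z;accel_norm
band_energy_3_5,frequency,accel_x;accel_y;accel_z;accel_norm
band_energy_5_8,frequency,accel_x;accel_y;accel_z;accel_norm
band_energy_8_15,frequency,accel_x;accel_y;accel_z;accel_norm
low_high_power_ratio,frequency,accel_x;accel_y;accel_z;accel_norm
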
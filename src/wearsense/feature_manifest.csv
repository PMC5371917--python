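name,group,axis,ordinal,units
x_time_max,time,x,0,m/s^2
x_time_min,time,x,1,m/s^2
x_time_ptp,time,x,2,m/s^2
x_time_variance,time,x,3,(m/s^2)^2
x_time_hist_entropy,time,x,4,bit
x_fft_dom_freq,fft,x,5,Hz
x_fft_dom_mag,fft,x,6,m/s^2
x_fft_centroid,fft,x,7,Hz
x_fft_spec_entropy,fft,x,8,bit
x_fft_band_0_3,fft,x,9,1
x_fft_band_3_12,fft,x,10,1
x_dct_c1,dct,x,11,m/s^2
x_dct_c2,dct,x,12,m/s^2
x_dct_c3,dct,x,13,m/s^2
x_dct_c4,dct,x,14,m/s^2
x_dct_first10_energy,dct,x,15,1
x_zt_r095_pi8,zt,x,16,m/s^2
x_zt_r095_pi4,zt,x,17,m/s^2
x_zt_r095_pi2,zt,x,18,m/s^2
x_zt_r095_3pi4,zt,x,19,m/s^2
x_bispec_max,bispec,x,20,(m/s^2)^3
x_bispec_mean,bispec,x,21,(m/s^2)^3
x_bispec_sum_pd,bispec,x,22,(m/s^2)^3
x_bispec_entropy_p1,bispec,x,23,bit
x_bispec_entropy_p2,bispec,x,24,bit
x_bispec_argmax_f1,bispec,x,25,Hz
x_wb_max,wb,x,26,(m/s^2)^3
x_wb_mean,wb,x,27,(m/s^2)^3
x_wb_entropy,wb,x,28,bit
x_wb_diag_max_tavg,wb,x,29,(m/s^2)^3
x_wb_diag_peak_freq,wb,x,30,Hz
x_wt_diag_max,wt,x,31,(m/s^2)^4
x_wt_diag_mean,wt,x,32,(m/s^2)^4
x_wt_diag_entropy,wt,x,33,bit
y_time_max,time,y,34,m/s^2
y_time_min,time,y,35,m/s^2
y_time_ptp,time,y,36,m/s^2
y_time_variance,time,y,37,(m/s^2)^2
y_time_hist_entropy,time,y,38,bit
y_fft_dom_freq,fft,y,39,Hz
y_fft_dom_mag,fft,y,40,m/s^2
y_fft_centroid,fft,y,41,Hz
y_fft_spec_entropy,fft,y,42,bit
y_fft_band_0_3,fft,y,43,1
y_fft_band_3_12,fft,y,44,1
y_dct_c1,dct,y,45,m/s^2
y_dct_c2,dct,y,46,m/s^2
y_dct_c3,dct,y,47,m/s^2
y_dct_c4,dct,y,48,m/s^2
y_dct_first10_energy,dct,y,49,1
y_zt_r095_pi8,zt,y,50,m/s^2
y_zt_r095_pi4,zt,y,51,m/s^2
y_zt_r095_pi2,zt,y,52,m/s^2
y_zt_r095_3pi4,zt,y,53,m/s^2
y_bispec_max,bispec,y,54,(m/s^2)^3
y_bispec_mean,bispec,y,55,(m/s^2)^3
y_bispec_sum_pd,bispec,y,56,(m/s^2)^3
y_bispec_entropy_p1,bispec,y,57,bit
y_bispec_entropy_p2,bispec,y,58,bit
y_bispec_argmax_f1,bispec,y,59,Hz
y_wb_max,wb,y,60,(m/s^2)^3
y_wb_mean,wb,y,61,(m/s^2)^3
y_wb_entropy,wb,y,62,bit
y_wb_diag_max_tavg,wb,y,63,(m/s^2)^3
y_wb_diag_peak_freq,wb,y,64,Hz
y_wt_diag_max,wt,y,65,(m/s^2)^4
y_wt_diag_mean,wt,y,66,(m/s^2)^4
y_wt_diag_entropy,wt,y,67,bit
z_time_max,time,z,68,m/s^2
z_time_min,time,z,69,m/s^2
z_time_ptp,time,z,70,m/s^2
z_time_variance,time,z,71,(m/s^2)^2
z_time_hist_entropy,time,z,72,bit
z_fft_dom_freq,fft,z,73,Hz
z_fft_dom_mag,fft,z,74,m/s^2
z_fft_centroid,fft,z,75,Hz
z_fft_spec_entropy,fft,z,76,bit
z_fft_band_0_3,fft,z,77,1
z_fft_band_3_12,fft,z,78,1
z_dct_c1,dct,z,79,m/s^2
z_dct_c2,dct,z,80,m/s^2
z_dct_c3,dct,z,81,m/s^2
z_dct_c4,dct,z,82,m/s^2
z_dct_first10_energy,dct,z,83,1
z_zt_r095_pi8,zt,z,84,m/s^2
z_zt_r095_pi4,zt,z,85,m/s^2
z_zt_r095_pi2,zt,z,86,m/s^2
z_zt_r095_3pi4,zt,z,87,m/s^2
z_bispec_max,bispec,z,88,(m/s^2)^3
z_bispec_mean,bispec,z,89,(m/s^2)^3
z_bispec_sum_pd,bispec,z,90,(m/s^2)^3
z_bispec_entropy_p1,bispec,z,91,bit
z_bispec_entropy_p2,bispec,z,92,bit
z_bispec_argmax_f1,bispec,z,93,Hz
z_wb_max,wb,z,94,(m/s^2)^3
z_wb_mean,wb,z,95,(m/s^2)^3
z_wb_entropy,wb,z,96,bit
z_wb_diag_max_tavg,wb,z,97,(m/s^2)^3
z_wb_diag_peak_freq,wb,z,98,Hz
z_wt_diag_max,wt,z,99,(m/s^2)^4
z_wt_diag_mean,wt,z,100,(m/s^2)^4
z_wt_diag_entropy,wt,z,101,bit
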
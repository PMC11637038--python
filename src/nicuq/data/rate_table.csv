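shift,respiratory_type,arrival_rate_per_min,mean_duration_min
early,mechanical,0.034,10.76
early,ncpap,0.030,8.48
early,high_flow,0.022,7.81
early,miscellaneous,0.017,30.11
late,mechanical,0.037,8.93
late,ncpap,0.025,8.54
late,high_flow,0.017,9.66
late,miscellaneous,0.020,15.28
night,mechanical,0.038,6.87
night,ncpap,0.022,6.47
night,high_flow,0.014,12.25
night,miscellaneous,0.029,7.30
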
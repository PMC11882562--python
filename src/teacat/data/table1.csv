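response,intercept,rainfall,temp_avg,eat,temp_max,temp_min,humidity,ground_temp,irradiance,rmsep,rmsecv,rmsec
egc,0.14,-0.009,-0.002,-0.0002,0.012,-0.002,0.003,0.004,0.000004,0.00042,0.00044,0.00044
c,-1.08,-0.054,0.122,-0.002,-0.006,-0.077,0.038,-0.048,-0.000003,0.00229,0.00242,0.00538
ec,1.538,-0.002,-0.006,0.0001,-0.0029,-0.001,-0.005,0.005,0.000003,0.00049,0.00057,0.00051
egcg,8.637,0.367,-0.042,-0.002,0.079,-0.031,0.024,-0.087,-0.00001,0.01184,0.01329,0.01559
gcg,-0.633,0.031,0.011,-0.0004,0.037,0.002,0.005,0.009,-0.00004,0.00105,0.0012,0.00206
ecg,1.27,0.094,0.06,-0.002,0.078,-0.01,0.001,-0.012,-0.00004,0.00325,0.00363,0.00847
cg,-0.122,0.0005,0.001,-0.00004,0.008,-0.0003,0.001,-0.0005,-0.000002,0.0002,0.00021,0.00038
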
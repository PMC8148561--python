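trait,regression_coefficient,p_value,r2_partial,r2_cumulative,direct_effect,indirect_effect,correlation,direct_r2
Intercept,16.232,0.0001,,,,,,
GLA,0.492,0.010,0.104,0.104,-0.065,0.511,0.446,0.004
LAI,0.373,0.001,0.141,0.245,0.264,0.230,0.493,0.069
RWC,0.772,0.030,0.171,0.416,0.189,0.201,0.390,0.036
CT,-0.497,0.0001,0.400,0.816,-0.653,0.020,-0.633,0.426
Gs,0.326,0.040,0.070,0.886,-0.173,0.479,0.306,0.030
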
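case,tracer,structure,abbreviation,auto_ml,auto_ap,auto_dv,expert_ml,expert_ap,expert_dv,discrepancy_mm
CJ70,DY,area 10 of cortex,A10,1.0,-19.5,11.9,1.0,-19.5,11.9,0.01
CJ70,FR,area 8a of cortex dorsal part,A8aD,3.9,-16.3,13.6,4.0,-16.0,13.0,0.66
CJ71,FE,area 10 of cortex,A10,0.6,-18.5,11.8,0.5,-18.5,12.1,0.32
CJ71,DY,area 10 of cortex,A10,1.4,-19.5,11.0,1.2,-19.5,11.1,0.22
CJ71,FB,area 10 of cortex,A10,2.8,-19.0,11.0,3.0,-19.0,11.5,0.52
CJ73,DY,area 9 of cortex,A9,0.6,-16.3,14.4,1.0,-16.5,13.6,0.96
CJ73,FB,area 46 of cortex ventral part,A46V,5.2,-16.8,13.2,5.1,-17.0,12.5,0.78
CJ73,FR,area 10 of cortex,A10,1.1,-18.4,10.7,0.7,-18.5,11.1,0.58
CJ74,DY,area 8b of cortex,A8b,0.2,-13.3,15.0,0.5,-14.0,15.0,0.79
CJ74,FB,area 8b of cortex,A8b,1.4,-15.2,14.2,1.5,-15.0,14.1,0.32
CJ75,DY,area 8a of cortex ventral part,A8aV,7.3,-15.0,12.4,7.0,-15.0,12.5,0.29
CJ83,DY,area 8b of cortex,A8b,0.9,-14.3,14.4,1.4,-15.5,14.3,1.31
CJ94,DY,area 8a of cortex ventral part,A8aV,6.6,-14.0,12.9,7.4,-14.0,11.8,1.36
CJ108,FE,area 8a of cortex ventral part,A8aV,5.8,-16.0,12.7,6.4,-16.0,12.5,0.66
CJ108,FR,area 8a of cortex dorsal part,A8aD,3.9,-15.4,13.7,4.0,-15.0,14.0,0.56
CJ125,FE,area 6 of cortex dorsorostral part,A6DR,4.1,-13.4,14.6,4.0,-13.5,15.0,0.47
CJ125,FR,area 8a of cortex ventral part,A8aV,6.7,-14.9,12.4,6.5,-14.5,12.6,0.44
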
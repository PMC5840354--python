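genotype,treatment,trait,mean,se
WT,control,plant_height_cm,68.3,0.53
WT,control,panicles_per_plant,20,1.63
WT,control,spikelets_per_panicle,118,1.72
WT,control,filled_spikelets_per_panicle,84,3.26
WT,control,total_yield_filled_grains,1680,65.3
WT,control,grain_weight_1000_g,35,0.81
KDIF2,control,plant_height_cm,73.7,0.32
KDIF2,control,panicles_per_plant,12,0.81
KDIF2,control,spikelets_per_panicle,92,3.26
KDIF2,control,filled_spikelets_per_panicle,44,0.82
KDIF2,control,total_yield_filled_grains,528,6.53
KDIF2,control,grain_weight_1000_g,30,0.82
OEIF2,control,plant_height_cm,76.3,0.18
OEIF2,control,panicles_per_plant,20,3.63
OEIF2,control,spikelets_per_panicle,117,3.52
OEIF2,control,filled_spikelets_per_panicle,91,2.6
OEIF2,control,total_yield_filled_grains,1816,10.8
OEIF2,control,grain_weight_1000_g,36,1.8
WT,salinity,plant_height_cm,48.6,0.32
WT,salinity,panicles_per_plant,5,0.81
WT,salinity,spikelets_per_panicle,81,2.4
WT,salinity,filled_spikelets_per_panicle,31.2,0.16
WT,salinity,total_yield_filled_grains,3,0.81
WT,salinity,grain_weight_1000_g,32,0.4
KDIF2,salinity,plant_height_cm,36.1,0.48
KDIF2,salinity,panicles_per_plant,0,0
KDIF2,salinity,spikelets_per_panicle,0,0
KDIF2,salinity,filled_spikelets_per_panicle,0,0
KDIF2,salinity,total_yield_filled_grains,0,0
KDIF2,salinity,grain_weight_1000_g,0,0
OEIF2,salinity,plant_height_cm,67.6,0.16
OEIF2,salinity,panicles_per_plant,17,0.81
OEIF2,salinity,spikelets_per_panicle,112,4.8
OEIF2,salinity,filled_spikelets_per_panicle,67,2.4
OEIF2,salinity,total_yield_filled_grains,1155,4.08
OEIF2,salinity,grain_weight_1000_g,33,0.42
WT,heat,plant_height_cm,64,1.6
WT,heat,panicles_per_plant,13,1.62
WT,heat,spikelets_per_panicle,40,3.2
WT,heat,filled_spikelets_per_panicle,18,1.6
WT,heat,total_yield_filled_grains,234,3.3
WT,heat,grain_weight_1000_g,32,0.5
KDIF2,heat,plant_height_cm,62,0.4
KDIF2,heat,panicles_per_plant,11,0.8
KDIF2,heat,spikelets_per_panicle,35,0.8
KDIF2,heat,filled_spikelets_per_panicle,8,0.8
KDIF2,heat,total_yield_filled_grains,88,6.4
KDIF2,heat,grain_weight_1000_g,28,0.4
OEIF2,heat,plant_height_cm,68,1.2
OEIF2,heat,panicles_per_plant,17,0.81
OEIF2,heat,spikelets_per_panicle,96,2.4
OEIF2,heat,filled_spikelets_per_panicle,62,0.81
OEIF2,heat,total_yield_filled_grains,1054,3.2
OEIF2,heat,grain_weight_1000_g,33,0.38
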
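{
 "waveform": {
  "amplitude_mT_m": 1534.6372461449726,
  "delta_ms": 1.0,
  "separation_ms": 30.0,
  "dt_ms": 0.02,
  "b_ms_um2": 5.0
 },
 "conditions": [
  {
   "radius_um": 5.0,
   "d_intra_um2_ms": 3.0,
   "n_walkers": 100000,
   "seed": 20260,
   "max_step_um": 0.025,
   "mc_fine": 0.47212792846045537,
   "coarse_step_um": 0.05,
   "coarse_seed": 20261,
   "mc_coarse": 0.47204378019745896,
   "mc_signal": 0.4722120767234518
  },
  {
   "radius_um": 5.0,
   "d_intra_um2_ms": 1.0,
   "n_walkers": 100000,
   "seed": 20260,
   "max_step_um": 0.025,
   "mc_fine": 0.4339364039336876,
   "coarse_step_um": 0.05,
   "coarse_seed": 20261,
   "mc_coarse": 0.4297462650957232,
   "mc_signal": 0.438126542771652
  },
  {
   "radius_um": 10.0,
   "d_intra_um2_ms": 3.0,
   "n_walkers": 100000,
   "seed": 20260,
   "max_step_um": 0.035,
   "mc_fine": 0.011409685927011165,
   "mc_signal": 0.011409685927011165
  },
  {
   "radius_um": 10.0,
   "d_intra_um2_ms": 1.0,
   "n_walkers": 100000,
   "seed": 20260,
   "max_step_um": 0.035,
   "mc_fine": 0.08167074943720105,
   "mc_signal": 0.08167074943720105
  },
  {
   "radius_um": 2.0,
   "d_intra_um2_ms": 3.0,
   "n_walkers": 100000,
   "seed": 20260,
   "max_step_um": 0.035,
   "mc_fine": 0.9432053743185983,
   "mc_signal": 0.9432053743185983
  },
  {
   "radius_um": 2.0,
   "d_intra_um2_ms": 1.0,
   "n_walkers": 100000,
   "seed": 20260,
   "max_step_um": 0.035,
   "mc_fine": 0.9075351751066062,
   "mc_signal": 0.9075351751066062
  }
 ]
}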
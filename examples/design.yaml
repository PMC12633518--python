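batch_scales:
  SITE1-A: 1.0
  SITE2-A: 1.1
  SITE3-B: 0.95
  SITE4-C: 1.05
blockade_factor: 0.5
covariate_effects:
  age_per_year: -0.002
  dw_per_unit: 0.01
  genotype_mab: 0.05
  sex_m: 0.04
dose_mean_mbq: 350.0
groups:
- affected_rois: []
  batch: SITE1-A
  blockade: false
  k1_effect: 0.0
  n: 8
  name: HC
  retest: false
  tracer: TRACER-A
- affected_rois:
  - lh_putamen
  - rh_pallidum
  - lh_frontalpole
  batch: SITE1-A
  blockade: true
  k1_effect: 0.15
  n: 4
  name: SCZ
  retest: false
  tracer: TRACER-A
- affected_rois:
  - lh_lateralorbitofrontal
  - lh_rostralanteriorcingulate
  - lh_medialorbitofrontal
  batch: SITE1-A
  blockade: false
  k1_effect: 0.15
  n: 4
  name: TBI
  retest: false
  tracer: TRACER-A
- affected_rois:
  - lh_hippocampus
  - rh_hippocampus
  batch: SITE1-A
  blockade: false
  k1_effect: 0.12
  n: 3
  name: AD
  retest: true
  tracer: TRACER-A
- affected_rois: []
  batch: SITE2-A
  blockade: false
  k1_effect: 0.0
  n: 6
  name: HC
  retest: false
  tracer: TRACER-A
- affected_rois:
  - lh_accumbens
  - rh_caudalanteriorcingulate
  - lh_bankssts
  batch: SITE2-A
  blockade: false
  k1_effect: 0.15
  n: 5
  name: cLBP
  retest: false
  tracer: TRACER-A
- affected_rois: []
  batch: SITE3-B
  blockade: false
  k1_effect: 0.0
  n: 8
  name: HC
  retest: true
  tracer: TRACER-B
- affected_rois:
  - lh_putamen
  - rh_putamen
  - lh_thalamus
  batch: SITE3-B
  blockade: false
  k1_effect: 0.18
  n: 6
  name: MS
  retest: false
  tracer: TRACER-B
- affected_rois: []
  batch: SITE4-C
  blockade: false
  k1_effect: 0.0
  n: 8
  name: HC
  retest: false
  tracer: TRACER-C
- affected_rois:
  - rh_caudalmiddlefrontal
  - lh_rostralanteriorcingulate
  - lh_parsopercularis
  batch: SITE4-C
  blockade: false
  k1_effect: 0.12
  n: 6
  name: DEP
  retest: false
  tracer: TRACER-C
if_params:
  a1: 851.1
  a2: 21.88
  a3: 20.81
  l1: 4.1339
  l2: 0.1191
  l3: 0.01043
k2: 0.0
noise_kappa: 0.3
subject_k1_sd: 0.03
tracers_without_genotype:
- TRACER-C
vb_scale: 1.0
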
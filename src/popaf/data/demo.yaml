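# Laptop-scale demo: a 200-sample, 20,000-locus admixed cohort with three
# ancestral components, one WGS representative per component, and a
# 200-call structural-variant intersection.
seed: 7

cohort:
  n_samples: 200
  n_loci: 20000
  n_pops: 3
  fst: 0.1
  missing_rate: 0.01
  known_fraction: 0.9725

cohort_af:
  population: LOCAL
  min_call_rate: 0.95

panels:
  n_ref: 5000

ancestry:
  d: 2
  admix_loci: 4000
  tree_samples: 30

wgs:
  extra_loci: 2000
  indel_fraction: 0.2
  discordance_rate: 0.002

prioritize:
  mode: global
  strong_z: 4.0
  weak_z: 1.96

sv:
  n_true: 200
  genome_len: 10000000
  jitter_sd: 20
  sens_a: 0.9
  sens_b: 0.8
  db_fraction: 0.865
  ro_min: 0.5

patho:
  clinvar_non_benign: 3.0e-4
  clinvar_pathogenic: 6.0e-5
  sift_deleterious: 1.2e-3
  polyphen_deleterious: 1.2e-3
  protein_altering: 7.5e-3
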
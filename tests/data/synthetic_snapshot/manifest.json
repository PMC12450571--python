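{
 "manifest_hash": "af1a9d48976e7f5f274826e224fd820808ac2cf753dd59198d010753dde37ff3",
 "tool_version": "0.1.0",
 "stage": "simulate",
 "config": {
  "rng_seed": 420,
  "n_loci": 150,
  "two_arm_fraction": 0.62,
  "taxon_nodes": [
   "Bilateria",
   "Vertebrata",
   "Mammalia",
   "Primates",
   "Homo sapiens"
  ],
  "taxon_ages_mya": [
   650.0,
   530.0,
   180.0,
   75.0,
   0.0
  ],
  "taxon_node_probabilities": [
   0.15,
   0.2,
   0.25,
   0.2,
   0.2
  ],
  "member_prob_by_node": [
   0.8,
   0.6,
   0.3,
   0.15,
   0.08
  ],
  "low_prob_member": [
   0.0,
   0.02,
   0.08,
   0.12,
   0.2
  ],
  "low_prob_nonmember": [
   0.3,
   0.45,
   0.6,
   0.7,
   0.85
  ],
  "mirgenedb_fraction": null,
  "seed_pool_size": 120,
  "mu_log10_low": 1.0,
  "sigma_log10_low": 0.45,
  "mu_log10_high": 3.0,
  "sigma_log10_high": 0.45,
  "n_datasets": 3,
  "samples_per_dataset": 6,
  "sample_noise_sd_log": 0.35,
  "dataset_names": [
   "sim_microRNAome",
   "sim_miTED_cells",
   "sim_miTED_tissues"
  ],
  "K": 2000.0,
  "h": 1.3,
  "w": 0.05,
  "floor": 0.02,
  "n_bio": 3,
  "n_tech": 4,
  "measurement_cv": 0.15,
  "bio_cv": 0.08,
  "firefly_mean": 10000.0,
  "firefly_cv": 0.1,
  "control_ratio": 2.0,
  "repression_off": false,
  "mimic_repression": 0.1
 },
 "input_digests": {},
 "rng_seed": 420,
 "outputs": {
  "annotation.tsv": "16ba1a85674effc64b41f97fbed9cac25f5428b0e051d52c04ac6ce589510096",
  "expr_dataset1.tsv": "24175efe574b2349f4bb943b39b062d6a1a55ceb2982b9db40bbe1cf04bae779",
  "expr_dataset2.tsv": "7b2e81a956d2b49d59e28dc9b57064a0ba9fea6c22a19a7a747af739948056c0",
  "expr_dataset3.tsv": "da1ad1e7863e97b2073e730a8b67abe7a0bcb75f481043d03a74c8247cdef37f",
  "plates.csv": "9ac64db8b3fba0bb1d57388c1a2b58591862c3891eff798fda1433fdb70e9930",
  "cell_profile.tsv": "1faaf16a3c585daabfdc838b962a65dd15ec6869e8c90e1430439e0c71f4aae1",
  "truth.json": "7f12127c40eb540e6ed5997e3d687d2245daf026d7056b9ea8add3ceadfd8dc4"
 },
 "timestamp": "2026-09-27T16:16:04.724339+00:00"
}
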
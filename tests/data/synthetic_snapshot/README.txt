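Synthetic fixture snapshot generated by miraudit.synthetic_data
(SimulationConfig(rng_seed=420, n_loci=150, n_datasets=3,
samples_per_dataset=6, seed_pool_size=120)). Stand-in data for the
public expression resources; no real measurements.
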
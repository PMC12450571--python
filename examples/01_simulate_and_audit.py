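"""Simulate the full study conditions and run the maximal-expression audit.

Generates the default synthetic complement (1,744 miRNA loci, three cpm
datasets), audits the maximal expression of every mature miRNA across all
samples, aggregates to loci, and prints the headline fractions: how many
annotated miRNAs/loci never exceed 100 cpm (the level below which reporter
repression is undetectable) anywhere.
"""

from miraudit import pipeline
from miraudit.synthetic_data import SimulationConfig, generate_annotation, \
    generate_expression

cfg = SimulationConfig(rng_seed=1)
rng = cfg.rng()
annotations, truth = generate_annotation(cfg, rng)
matrices = generate_expression(annotations, truth, cfg, rng)

res = pipeline.full_audit(matrices, annotations)
rec, locus = res.records, res.locus_records

print(f"{len(rec)} mature miRNAs from {len(locus)} loci, "
      f"{res.summary.n_samples} samples in {res.summary.n_datasets} datasets")
print(f"miRNAs never above 100 cpm: {(rec.max_cpm <= 100).sum()} "
      f"({100 * (rec.max_cpm <= 100).mean():.1f}%)")
print(f"loci never above 100 cpm:   {(locus.max_cpm <= 100).sum()} "
      f"({100 * (locus.max_cpm <= 100).mean():.1f}%)")
print(f"loci never above 10 cpm:    {(locus.max_cpm <= 10).sum()} "
      f"({100 * (locus.max_cpm <= 10).mean():.1f}%)")
print("\nCumulative locus counts (max cpm <= threshold):")
print(res.cumulative.to_string(index=False))
print("\nBy curation status (percent of loci per expression bin):")
cols = ["stratum", "n_loci", "pct <=10", "pct (10,100]", "pct (100,1000]",
        "pct >1000"]
print(res.strata_mirgenedb.table[cols].round(1).to_string(index=False))
# A high "pct <=10" + "pct (10,100]" among uncurated loci mirrors the
# observation that most miRNAs absent from curated databases never reach
# functionally meaningful expression.
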
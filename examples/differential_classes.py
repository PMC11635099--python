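"""Differential clone abundance and UP/DOWN/NS classification.

Runs the complete recovery experiment at reduced scale: simulate a library
with known fitness effects, sequence, count, test first vs last timepoint
with the negative-binomial Wald workflow, and score the recovered classes
against the simulator's ground truth.
"""

from denovopool import GrowthSimConfig
from denovopool.benchmark import run_recovery_experiment

config = GrowthSimConfig(n_replicates=5, n_timepoints=10,
                         cells_per_passage=3_000_000,
                         read_depth=150_000, error_rate=0.001)
rec = run_recovery_experiment(n_clones=500, frac_up=0.10, frac_down=0.20,
                              effect=0.05, config=config, seed=11)

print(f"simulated 500 clones: 10% at s=+0.05, 20% at s=-0.05 per doubling")
print(f"reference clones rebuilt from reads: {rec.n_reference}")
print(f"mean mapping rate: {rec.mapping_rate:.4f}")
print("recovered classes:", rec.class_counts.to_dict())
print(f"non-neutral clones with correct sign: {rec.sign_recovery:.1%}")
print(f"neutral clones falsely called:        {rec.false_call_rate:.1%}")
print("\nA correct sign rate near 100% with a false-call rate near the "
      "5% FDR target shows the pipeline separates real growth effects "
      "from multinomial drift and sequencing noise at this depth.")
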
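"""How reliable is the scan?  A small power and calibration study.

Over ten seeded 500 kb genomes: with no depletion planted, the scanner
should report nothing (type-I calibration); with a 6-mer depleted to 10% of
expectation it should flag that word (power).  Both rates should be at or
near 100% at the default -6.7 cutoff.
"""

from stealth import SyntheticGenomeSpec, generate_markov_genome, scan_genome

MOTIF, N_SEEDS = "GCTAAC", 10

empty = flagged = 0
for seed in range(N_SEEDS):
    null = generate_markov_genome(SyntheticGenomeSpec(length=500_000, seed=seed))
    empty += len(scan_genome(null)) == 0
    depleted = generate_markov_genome(
        SyntheticGenomeSpec(length=500_000, seed=seed, planted=[(MOTIF, 0.1)])
    )
    flagged += MOTIF in scan_genome(depleted).motifs()

print(f"calibration: {empty}/{N_SEEDS} undepleted genomes report no motif")
print(f"power      : {flagged}/{N_SEEDS} depleted genomes flag {MOTIF}")
print(
    "\nAn empty list on null genomes means the -6.7 cutoff controls false "
    "positives across all 87,296 tested words; flagging the planted word "
    "shows a 10x depletion of a 6-mer is well within reach at 500 kb."
)
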
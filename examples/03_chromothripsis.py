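"""Chromothripsis calling on a simulated shattered chromosome.

Plants a 12-fragment shattering event on chr2 of one tumor and calls every
sample x chromosome pair; the shattered chromosome should meet the
high-confidence criteria while chromosomes with only background SVs do not.
"""

from cisbreak import SimConfig, generate
from cisbreak.chromothripsis import call_chromothripsis

cfg = SimConfig(seed=7, n_samples=30, n_genes=200,
                chromothripsis_plan=((0, "chr2", 12),))
cohort, truth = generate(cfg)
genome = dict(cfg.genome)

svs = cohort.svs_by_sample()["s00"]
segs = [s for s in cohort.cn_segments if s.sample_id == "s00"]

for chrom in sorted(genome):
    call = call_chromothripsis("s00", chrom, svs, segs, genome)
    mark = " <-- planted" if (("s00", chrom) in truth.chromothripsis) else ""
    print(f"{chrom}: interleaved={call.n_intra_interleaved:2d} "
          f"oscillation={call.max_oscillation_run:2d} "
          f"joins_p={call.p_fragment_joins:.2f} "
          f"criterion={call.criterion_met}{mark}")
print("\ncriterion 1 needs >=6 interleaved intra SVs, a >=7-segment CN "
      "oscillation,\nrandom-looking join types and clustered breakpoints")
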
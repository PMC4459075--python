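"""Simulate library construction and watch the GC bias appear.

Runs the full generative pipeline — community genomes, fragmentation with a
debris component, 40-70 kb size selection, promoter-dependent clone loss, and
90-base paired-end reads — for a community where AT-rich genomes carry more
sigma-70 consensus sites, then prints percent GC of each sequenced stage.
"""

from cosmidbias import library_sim, seqio
from cosmidbias.studies import gc_gradient_params

params = gc_gradient_params(seed=2026, retention_rate=1.0)
result = library_sim.run_experiment(params)

print("per-stage percent GC of the sequenced reads (lambda = 1):")
for stage in library_sim.STAGES:
    gc = seqio.gc_percent(result.reads[stage])
    print(f"  {stage:<15} {gc:.1f}")

truth = result.abundance_truth.pivot(index="genome_id", columns="stage",
                                     values="base_share_percent")
print("\nper-genome base share (%, truth):")
print(truth.round(1).to_string())
# Crude extract and size-selected GC agree (fragmentation introduces no
# bias); the cosmid library shifts several points GC-rich because AT-rich,
# promoter-dense fragments fail to establish as clones.
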
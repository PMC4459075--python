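"""Scan a small genome for sigma-factor consensus promoters.

Builds a 200 kb AT-rich genome with 10 planted sigma-70 (rpoD) consensus
sites, scans it for all five built-in consensus motifs on both strands, and
compares the observed rpoD density with the closed-form chance expectation
for an i.i.d. background at the same GC.
"""

import numpy as np

from cosmidbias import library_sim, motif_scan

rng = np.random.default_rng(42)
genome = library_sim.generate_genome("demo", 200_000, gc_target=0.38,
                                     planted_rpoD=10, rng=rng)
print(f"genome: {genome.length:,} bp at GC target {genome.gc_target:.0%}, "
      f"{genome.planted_rpoD} planted rpoD sites")

table = motif_scan.scan_dataset([genome.as_record()], sample_name="demo")
print(f"\n{'motif':<10}{'hits':>6}{'hits/Mb':>10}{'chance/Mb':>11}")
for motif in motif_scan.builtin_motifs():
    expected = motif_scan.expected_hits_per_mb(motif, 0.38, motif_scan.BOTH)
    print(f"{motif.name:<10}{table.hit_counts[motif.name]:>6}"
          f"{table.hits_per_mb[motif.name]:>10.2f}{expected:>11.2f}")

# The rpoD count is the 10 plants plus any chance hits (an AT-rich background
# yields ~3/Mb at 38 % GC, so ~0.6 expected on 0.2 Mb); the other motifs sit
# at their chance rates since nothing was planted for them.
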
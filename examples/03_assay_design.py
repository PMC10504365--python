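"""Design validation reagents for a planted circle and test them in silico.

For one simulated circular locus: the 30-nt junction-spanning probe (15 nt
complementary to each side of the junction) hybridizes to the circle but
nowhere in the linear genome, and the divergent primer pair yields products
only on the circular template (as a rolling-circle ladder), while the
convergent pair amplifies both — the discrimination logic used to validate
circular RNAs experimentally.
"""

from circbact import (
    CircleJunction,
    SimConfig,
    design_junction_probe,
    simulate,
    suggest_primers,
    virtual_pcr,
)
from circbact.genome_io import reverse_complement

config = SimConfig(
    genome_length=20_000, n_linear_loci=3, n_circ_loci=3, n_samples=1,
    coverage_per_sample=0, substitution_error_rate=0.0, seed=7,
)
sim_genome, truth, _ = simulate(config)
genome = sim_genome.reference
junction_truth = truth.junctions[0]
junction = CircleJunction(junction_truth.acceptor_5p, junction_truth.donor_3p)
circle = genome.slice(junction.acceptor_5p, junction.donor_3p)

probe = design_junction_probe(genome, junction, arm=15)
target = reverse_complement(probe)
print(f"circle {junction_truth.locus_id}: {junction.acceptor_5p}-{junction.donor_3p} "
      f"({len(circle)} nt)")
print(f"junction probe (30 nt): {probe}")
print(f"  probe target in linear genome? {target in genome.bases}")
print(f"  probe target in doubled circle? {target in circle * 2}")

primers = suggest_primers(genome, junction)
for name in ("convergent", "divergent"):
    pair = primers[name]
    linear = virtual_pcr(circle, circular=False, pair=pair, max_amplicon=1000)
    circ = virtual_pcr(circle, circular=True, pair=pair, max_amplicon=1000)
    print(f"{name} PCR: linear template -> {linear}, circular template -> {circ}")
print("(divergent products step by one circle length: rolling-circle ladder)")
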
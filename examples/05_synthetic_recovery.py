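"""Validate the mass-apportioning estimator end-to-end on synthetic truth.

Simulates an ssDNA-dominated community with known per-family abundances,
pushes it through the forward measurement model (masses with 10% noise), and
inverts the masses with the estimator: the genome-size-envelope interval
should bracket the true abundance.
"""

from viromass import (
    NucleicAcidType,
    SimulationConfig,
    copies_interval,
    simulate_community,
    simulate_direct_counts,
    simulate_dna_masses,
)

cfg = SimulationConfig(seed=11, mass_noise_cv=0.1, s1_carryover_f=0.0)
truth = simulate_community(cfg)
true_ss = truth.total(NucleicAcidType.SSDNA)

ss_mass, ds_mass = simulate_dna_masses(truth, cfg)
interval = copies_interval(ss_mass, cfg.ss_genome_kb_range)
counts = simulate_direct_counts(truth, cfg)

print(f"true ssDNA abundance:      {true_ss:.3e} copies/cm^3")
print(f"measured ssDNA mass:       {ss_mass.concentration:.3f} ng/cm^3")
print(f"estimated interval:        [{interval.low:.3e}, {interval.high:.3e}]")
print(f"interval contains truth:   {interval.contains(true_ss)}")
print(f"simulated direct count:    {counts.viral_particles:.3e} particles/cm^3")
print(f"truth / direct count:      {true_ss / counts.viral_particles:.0f}x")
print(
    "\nReading: the interval spans the 1.8-24.9 kb genome-size assumption and "
    "brackets the true abundance despite measurement noise, while the "
    "stain-limited direct count underestimates the ssDNA community by "
    "one-to-two orders of magnitude — the regime the estimator exposes."
)
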
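"""Generate the two synthetic cohorts and inspect the planted truth.

Builds a small discovery/replication pair with planted diet-metabolite
effects and prints the cohort layout and one planted mediation trio.
"""

from metadiet.synthio import SynthConfig, generate_cohorts

cfg = SynthConfig(n_discovery=200, n_replication=200, n_metabolites=80,
                  n_species=50, n_informative_metabolites=10,
                  effect_size_beta=0.3, seed=42)
disc, repl = generate_cohorts(cfg)

print(f"discovery: {len(disc.participants)} participants, "
      f"{disc.ffq_line_items.shape[1]} FFQ items, "
      f"{disc.metabolites_raw.shape[1]} metabolites, "
      f"{disc.species_counts.shape[1]} species")
print(disc.participants["zygosity"].value_counts().to_dict(),
      "<- MZ/DZ twin pairs share family effects; UP are singletons")

g, met, beta = disc.truth.diet_metabolite_effects[0]
print(f"planted effect: {g} -> {met} with standardized slope {beta}")
trio = disc.truth.mediation_params[0]
print(f"planted mediation: {trio['exposure']} -> {trio['mediator']} -> "
      f"{trio['outcome']}, true proportion mediated "
      f"{trio['true_prop_mediated']:.2f}")
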
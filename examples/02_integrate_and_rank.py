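"""From endpoint potencies to consensus indices and a potency ranking.

Runs a noise-free in vitro study so every index is exactly computable, then
integrates the endpoint slopes into the consensus hierarchy: beta_V (mean
viability slope per cell line), beta_R (mean |slope|, 'reactivity'),
viability-adjusted inflammation beta_I-V under the HI and LO cytokine-sign
scenarios, and the integrated index Ibeta = mean(reactivity, inflammation).
Rank 1 marks the most potent particle.
"""

import pmpotency as pm

design = pm.default_invitro_design(noise_sigma=0.0)
panel = pm.generate_particle_panel(n_urban=3, n_mineral=2, seed=11,
                                   endpoint_roles=design.roles())
dataset = pm.simulate_measurements(design, panel, seed=11)
potencies = pm.fit_all(pm.compute_fold_effect(dataset.measurements))

scenario = pm.ScenarioConfig(roles=design.roles())
indices = pm.integrate_invitro(potencies, scenario)

show = ["beta_v_cells", "beta_r_cells", "beta_iv_hi", "beta_iv_lo",
        "beta_iv_cells", "ibeta"]
print(indices[show].round(4).to_string())
print("\nranking by integrated potency (1 = most potent):")
print(pm.rank_particles(indices["ibeta"]).to_string())
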
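"""Rescale an evolutionary model by Q and verify what the transform preserves.

Builds the human-like "full" catalog model (N=10,000, 25 Mb, mu=r=1.2e-8,
neutral + beneficial + deleterious mutations) and rescales it by Q=10.
"""

from wfscale import build_catalog_model, rescale_model

model = build_catalog_model("full")
scaled = rescale_model(model, 10)

print(f"{'':24}{'unscaled':>14}{'Q=10':>14}")
print(f"{'N':24}{model.demography.N_anc:>14}{scaled.demography.N_anc:>14}")
print(f"{'mu (per bp)':24}{model.mu:>14.3g}{scaled.mu:>14.3g}")
print(f"{'r (per bp)':24}{model.r:>14.3g}{scaled.r:>14.3g}")
print(f"{'s (beneficial)':24}{model.dfe_beneficial.s_fixed:>14.3g}"
      f"{scaled.dfe_beneficial.s_fixed:>14.3g}")
print(f"{'gamma mean (deleterious)':24}{model.dfe_deleterious.gamma_mean:>14.4g}"
      f"{scaled.dfe_deleterious.gamma_mean:>14.4g}")
print(f"{'gamma shape':24}{model.dfe_deleterious.gamma_shape:>14.3g}"
      f"{scaled.dfe_deleterious.gamma_shape:>14.3g}")
print(f"{'burn-in (generations)':24}{model.demography.burn_in_generations:>14}"
      f"{scaled.demography.burn_in_generations:>14}")
print(f"{'recording (generations)':24}{model.demography.recording_generations:>14}"
      f"{scaled.demography.recording_generations:>14}")
print(f"{'theta = 4*N*mu':24}{model.theta:>14.6g}{scaled.theta:>14.6g}")
print()
print("Population size and time spans shrink by Q; rates and selection")
print("coefficients grow by Q, so the population-scaled parameters theta and")
print("N*s are preserved — the premise of the rescaling shortcut.")
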
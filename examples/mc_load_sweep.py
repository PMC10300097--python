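"""Stochastic box-model sweep of the tubulin dimerization energy over load.

Runs replicate alpha/beta walker pairs from the box centre to the electrode
wall at each applied load (load sets the per-step displacement through the
t/t_eq time fraction), summarises |E_ad| per load and fits the cubic load
response.
"""

from tubuvolt import MCConfig, fit_load_response, load_sweep

cfg = MCConfig(rng_seed=42)
sweep = load_sweep(cfg, n_seeds=500)
print(sweep.table.round(4).to_string(index=False))

poly = fit_load_response(sweep)
print(
    f"\ncubic fit E_ad(L): c3={poly.c3:.3e}, c2={poly.c2:.3e}, "
    f"c1={poly.c1:.3e}, c0={poly.c0:.4f} eV"
)
print(
    "\nmean_Ead_eV is the mean dimerization-energy magnitude per load; the "
    "acceptance rate sits near 1 - exp(-F*0.007/RT) ~ 0.24, the Boltzmann "
    "gate on the 7 meV alpha/beta species gap. The forced-symmetric limit "
    "of the walk pins E_ad at exactly -0.007 eV."
)
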
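# tubuvolt

Electrochemical energetics of tubulin self-assembly on gold, and the battery
arithmetic of a microtubule-cathode bio-cell — as one tested Python library
with a thin CLI.

Microtubules are hollow cytoskeletal polymers of α/β-tubulin heterodimers.
When a tubulin solution is probed by cyclic voltammetry (CV) at a gold
electrode, the forward-sweep adsorption peak near +0.3 V carries, through
Butler–Volmer/Arrhenius kinetics, an estimate of the adsorption free energy
and of the electronic conductivity of the adsorbed protein layer; the same
peak currents invert through the Randles–Ševčík relation to K⁺ diffusion
coefficients and Einstein–Smoluchowski mobilities. A coarse-grained Monte
Carlo box model of the electrode/electrolyte interface yields the tubulin
dimerization energy as a function of the applied load, and galvanostatic
charge/discharge (GCD) traces give the figures of merit of the assembled
bio-battery cell. This package implements each of those estimator chains,
plus synthetic voltammogram/GCD generators so every stage runs and is
testable from embedded constants alone — no instrument data required.

## The models

**Butler–Volmer energetics** (per scan rate/load, from the peak current
i_p):

    i_0   = i_p / A
    ΔG    = | RT ln( i_0 A h / (n F k_B T C) ) |        (reported in eV)
    R_ct  = RT / (n F i_0)
    ρ     = R_ct A / l,   σ = 1/ρ
    k_het = (k_B T / h) exp(−ΔG e / (k_B T))

with the concentration C entered as its numeric value in mol/L and the
charge-transfer resistance reported as the bare tabulated number (see
`docs/methods.md` for the unit conventions these formulas imply).

**K⁺ transport**: the quasi-reversible Randles–Ševčík relation
`i_p = 0.446 n F (A·C) sqrt(n F D v / RT)` is inverted for D (cm²/s) using a
calibrated effective area–concentration product, and
`µ = |z| F D / (R T)` gives the mobility at 293 K.

**Monte Carlo box model**: paired α/β-tubulin walkers advance from the
centre of a 690 Å half-length box toward the wall (the electrode) in steps
of `Δd = x · t/t_eq` (x = 3 Å solvation radius; the time fraction is set by
the applied load). A Boltzmann gate on the chemical-potential gap between
the two species, `exp(−F(µ₂−µ₁)/RT)`, filters each move; the walk ends when
the first walker comes within the Au–S bond distance (2.39 Å) of the wall,
and the dimerization energy is `E_ad = E_i1 − E_i2` there. Sweeping the
load and fitting a cubic gives the load response of E_ad, whose zero-load
limit is the field-free dimerization energy (3.0 eV for the published
coefficients).

**Battery metrics**: per-cycle specific capacity `Q = IΔt/m` (mAh/g) and
capacitance `IΔt/(mΔV)` (F/g) from the discharge segments, theoretical
capacity `zF/M`, gravimetric energy density `V·Q` (Wh/kg) and the capacity
fade/retention split.

## Worked example

```python
from tubuvolt import build_energetics_table, peaks_from_traces, table1_fixture_traces
from tubuvolt.config import DEFAULT_LOADS_BY_SCAN_RATE

peaks = peaks_from_traces(table1_fixture_traces())
table = build_energetics_table(peaks, DEFAULT_LOADS_BY_SCAN_RATE)
print(table[["scan_rate", "load", "dG", "R_ct", "sigma"]].round(4).to_string(index=False))
```

prints

```
 scan_rate  load     dG   R_ct  sigma
      0.01  1.81 1.1853 2.3272 0.0009
      0.02  2.21 1.1725 1.4164 0.0014
      0.05  3.85 1.1633 0.9882 0.0020
      0.10  5.13 1.1529 0.6588 0.0030
      0.15  7.35 1.1517 0.6297 0.0032
      0.20  8.00 1.1465 0.5139 0.0039
```

Reading the table: as the applied load rises from 1.81 to 8.00 MΩ the peak
current grows five-fold, the adsorption free energy relaxes from 1.19 to
1.15 eV (a 40 meV span — adsorption becomes more facile) and the electronic
conductivity climbs from 0.86 to 3.89 mS/m, the semiconducting-protein
signature the cell design relies on.

The other capabilities each have a narrative script under `examples/`:
`mc_load_sweep.py` (stochastic dimerization-energy sweep and cubic fit),
`potassium_transport.py` (diffusion/mobility table and averages),
`battery_cycle_metrics.py` (GCD capacity fade, 42.48% loss and
13.52 Wh/kg), `electrolyte_conductance.py` (KCl/microtubule conductance
grid). The `tubuvolt` CLI exposes the same operations
(`tubuvolt reproduce --out report.json` recomputes every desk-scale
quantity and reports the deltas against the embedded reference values).

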
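"""Bio-battery figures of merit from a synthetic charge/discharge train.

Generates a 100-cycle constant-current GCD profile whose capacity fades
exponentially from 63.2 to 36.35 mAh/g, recovers per-cycle capacities from
the discharge segments and prints the cell summary.
"""

from tubuvolt import BatteryInputs, battery_summary, cycle_metrics
from tubuvolt.synthetic import GCDSynthParams, synth_gcd_profile

params = GCDSynthParams(n_cycles=100, Q0=63.2, Q_floor=36.35)
profile = synth_gcd_profile(params)
inputs = BatteryInputs(m=params.m, I=params.I)
metrics = cycle_metrics(profile, inputs)
print(metrics.head(3).round(3).to_string(index=False))
print("...")
print(metrics.tail(3).round(3).to_string(index=False))

summary = battery_summary(metrics, inputs)
print(
    f"\nQ_initial = {summary.Q_initial:.2f} mAh/g, Q_final = {summary.Q_final:.2f} mAh/g"
    f"\ncapacity loss = {summary.fade_pct:.2f}% (retention {summary.retention_pct:.2f}%)"
    f"\nenergy density = {summary.ED:.2f} Wh/kg at 0.214 V nominal"
    f"\ntheoretical capacity zF/M = {summary.Q_theoretical:.2f} mAh/g"
)
print(
    "\nThe 42.48% loss over the cycle train and ~13.5 Wh/kg gravimetric "
    "energy density are the headline cell metrics; zF/M uses the "
    "reconstructed molar mass of 300 g/mol."
)
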
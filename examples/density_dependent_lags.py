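"""Why low-density met17Δ cultures lag: simulate the sulfide-coupled model.

Integrates the two-ODE model at three inoculum densities (OD 0.001,
0.01, 0.1), measures each culture's lag against the model's balanced
growth rate, then shows how sulfide loss (δ > 0) stretches the lags and
how a 50-fold better sulfide assimilation (k_s / 50) abolishes both.
"""

from sulfgrowth import REFERENCE_PARAMS, density_delta_sweep, ks_reduction_experiment

print("Parameters:", REFERENCE_PARAMS, "\n")

sweep = density_delta_sweep(
    REFERENCE_PARAMS, [0.001, 0.01, 0.1], [0.0, 0.1, 0.2], x0_in_od=True
)
print("Lag time (h) by inoculum density and sulfide loss rate δ:")
print(sweep.pivot(index="x0", columns="delta", values="lag_h").round(1), "\n")

res = ks_reduction_experiment(REFERENCE_PARAMS, factor=50.0)
base = res.baseline.query("delta == 0").set_index("x0")["lag_h"]
red = res.reduced.query("delta == 0").set_index("x0")["lag_h"]
print("Lag at δ=0, baseline k_s vs k_s/50 (h):")
for x0 in base.index:
    print(f"  x0 = {x0:9.0f} cells/ml: {base[x0]:6.1f} -> {red[x0]:5.1f}")
print("\nδ-sensitivity (max-min lag across δ grid, h):")
print("  baseline:", res.delta_sensitivity("baseline").round(1).to_dict())
print("  k_s/50:  ", res.delta_sensitivity("reduced").round(2).to_dict())

# Reading: a 100-fold sparser inoculum lags tens of hours longer, an
# inf entry means the culture never reached 10x its inoculum (sulfide
# loss outran accumulation), and with efficient assimilation every lag
# shrinks below ~4 h and barely responds to δ.
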
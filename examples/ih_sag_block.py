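"""I_h, sag and rebound analysis with pharmacological HCN block.

Measures the hyperpolarization-activated current of the Clarke's-column
archetype in voltage clamp (with instantaneous leak subtraction), the
sag potentials and rebound firing in current clamp, then repeats the
protocol after a 70% HCN block and computes the block statistics.
"""

import spinephys as sp

params = sp.make_archetype("CC")
cfg = sp.SimulationConfig(noise=False)
protocols = sp.standard_protocols()

vc = sp.simulate_voltage_clamp(params, protocols["vc_hyperpol_steps"], cfg)
ih = sp.measure_ih(vc)
print("leak-subtracted I_h per voltage step (pA):")
for d, v in zip(ih.delta_mV, ih.i_h):
    print(f"  Δ{d:+.0f} mV -> {v:8.1f}")

cc = sp.simulate_current_clamp(params, protocols["cc_hyperpol_steps"], cfg)
sag = sp.measure_sag(cc)
rebound = sp.analyze_rebound(cc)
print(f"\nsag present: {sag.sag_present} "
      f"(Δ up to {sag.sag_delta.max():.1f} mV)")
print(f"rebound APs per step: {rebound.n_rebound_APs.tolist()}")
print(f"rebound threshold: {rebound.rebound_threshold_mV:.0f} mV "
      "(most depolarized step trough with a rebound AP)")

blocked = sp.apply_channel_block(params, "Ih", fraction=0.7)
ih_drug = sp.measure_ih(sp.simulate_voltage_clamp(
    blocked, protocols["vc_hyperpol_steps"], cfg))
block = sp.compute_block(ih, ih_drug)
print(f"\nmeasured I_h block fraction: {block.ih_block_fraction:.2f} "
      "(configured 0.70)")

full = sp.apply_channel_block(params, "Ih", fraction=1.0)
sag_drug = sp.measure_sag(sp.simulate_current_clamp(
    full, protocols["cc_hyperpol_steps"], cfg))
pct = sp.compute_sag_delta_change(sag, sag_drug)
print(f"sag delta change with full block: {pct:.0f}% "
      "(>100% means the blocked trace keeps hyperpolarizing)")
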
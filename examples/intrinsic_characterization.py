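"""Passive properties, rheobase and firing type of one model cell.

Simulates the default Clarke's-column archetype, measures its passive
membrane properties from rest and hyperpolarizing-step sweeps, searches
the rheobase with the coarse/fine two-stage protocol, and classifies the
ten-step firing battery.
"""

import spinephys as sp

params = sp.make_archetype("CC")
cfg = sp.SimulationConfig(noise=False)
protocols = sp.standard_protocols()

rec = sp.CellRecording(
    cell_id="cc_demo", group="CC",
    sweep_sets={
        "rest": sp.simulate_current_clamp(params, protocols["rest"], cfg),
        "cc_hyperpol_steps": sp.simulate_current_clamp(
            params, protocols["cc_hyperpol_steps"], cfg),
    },
    protocols={k: protocols[k] for k in ("rest", "cc_hyperpol_steps")},
)

passive = sp.measure_passive(rec)
print(f"V_m_rest = {passive.Vm_rest:.1f} mV   (resting potential, "
      "junction-corrected)")
print(f"R_m      = {passive.Rm:.2f} GΩ   (input resistance from the "
      "-50 pA step)")
print(f"C_m      = {passive.Cm:.0f} pF    (tau_m / R_m)")

rheo = sp.find_rheobase(sp.step_response_fn(params, cfg))
print(f"rheobase = {rheo.rheobase:.0f} pA   (first fine step firing with "
      "the two following steps also firing)")

battery = sp.simulate_current_clamp(params, protocols["firing_steps"], cfg)
result = sp.classify_firing_type(battery)
curve = sp.build_fI_curve(battery)
print(f"firing type = {result.label}   (T tonic / F fading / S single / "
      "U undefined)")
print("f-I curve (pA -> APs):",
      ", ".join(f"{int(i)}:{n}" for i, n in curve))
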
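"""Group-level report: summaries, proportions, pairwise Welch tests.

Simulates a small cohort from each cell group, runs the intrinsic
pipeline per cell, and compiles the group report tables.
"""

import spinephys as sp
from spinephys.stats import CellAnalysis, write_report

cells = []
for group, n in (("CC", 6), ("medial", 6), ("lateral", 6)):
    for rec in sp.generate_population(
            group, n, seed=13,
            protocols=("rest", "firing_steps", "cc_hyperpol_steps")):
        cells.append(CellAnalysis(
            cell_id=rec.cell_id,
            group=group,
            passive=sp.measure_passive(rec),
            firing=sp.classify_firing_type(rec.get("firing_steps")),
        ))

bundle = sp.compile_report(cells)
print("group summaries (mean ± SEM):")
print(bundle.summaries.to_string(index=False))
print("\nfiring-type percentages per group (rows sum to 100):")
print(bundle.firing_proportions.to_string(index=False))
print("\npairwise Welch tests (two-sided, no multiplicity correction):")
print(bundle.pairwise_tests.to_string(index=False))
print("\ncapacitance fold ratios:")
print(bundle.fold_ratios.to_string(index=False))

out = write_report(bundle, "scratch_example_report")
print(f"\nTSV tables written to {out}/")
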
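"""Simulate a labeled experiment, run the isotopomer search, evaluate it.

Builds a 25-molecule synthetic panel with planted ¹³C envelopes, decoy
features and realistic m/z / RT jitter, pools the unlabeled export into a
reference list, searches the labeled feature list, and scores the hits
against the planted ground truth.
"""

import tempfile
from pathlib import Path

from isotrace import SimulationConfig, flux_result, pool_references, simulate
from isotrace.reference import load_metabolite_export
from isotrace.synth import default_metabolite_panel, evaluate

config = SimulationConfig(
    molecules=default_metabolite_panel(25, seed=42),
    n_decoys=150,
    seed=42,
)
sim = simulate(config)

with tempfile.TemporaryDirectory() as tmp:
    export = Path(tmp) / "metabolite_export.csv"
    sim.metabolite_export.to_csv(export, index=False)
    refs = pool_references(load_metabolite_export(str(export)))

hits = flux_result(refs, sim.features)
metrics = evaluate(hits, sim.truth)

print(f"references          : {len(refs)}")
print(f"planted isotopomers : {metrics['n_planted']}")
print(f"hits                : {len(hits)}")
print(f"precision / recall  : {metrics['precision']:.3f} / {metrics['recall']:.3f}")
print("\nfirst hits (reference ion, annotation, score, grade):")
for _, h in hits.head(5).iterrows():
    print(f"  {h['Metabolite/Lipid']:<8s} {h['Annotation']:<5s} "
          f"score={h['Score']:.3f}  grade={h['Grades']}  dmz={h['dmz_ppm']:.2f} ppm")
# precision/recall near 1 show the joint m/z-RT score separates planted
# envelope components from uniform decoys at default gates
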
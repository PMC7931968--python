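"""Inspect the packaged agent tables and recompute the overall calls.

The training table lists the 28 agent conditions used to develop the
biomarker; the validation table lists 48 external agents with per-method
and overall DDI calls plus chromosomal-damage and Ames results.
"""

from collections import Counter

from tgxddi import TernaryCall, load_fixture, overall_call

training = load_fixture("training_agents")
validation = load_fixture("validation_calls")
print(f"training conditions: {len(training)}; validation agents: {len(validation)}")

agree = sum(overall_call(r.pa, r.c2dc, r.pca) is r.overall for r in validation)
print(f"overall calls reproduced from PA/2DC/PCA by the any-positive rule: "
      f"{agree}/{len(validation)}")

pos_by_class = Counter(
    r.class_label for r in validation if r.overall is TernaryCall.POS
)
print("overall-positive agents per class:", dict(sorted(pos_by_class.items())))
print("class 5 holds agents with irrelevant positive chromosomal-damage results;"
      "\nonly one of its 12 agents is called DDI, illustrating the de-risking use.")
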
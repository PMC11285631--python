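"""Build lenient (k=2) and stringent (k=3) commonality models across five
development cohorts and test them on three held-out cohorts.

Prints per-model clump counts, causal-clump recovery against the simulator's
ground truth, and the development-to-holdout AUC drop for both models.
"""

import numpy as np

from clumprs.harmonize import build_panel
from clumprs.selection import apply_model, commonality, pd_first_pass, pd_second_pass
from clumprs.simulate import CohortSpec, SimConfig, simulate_family

fam = simulate_family(SimConfig(seed=3, cohorts=[CohortSpec(100, 100, 0.9) for _ in range(8)]))
table, tags = fam.truth.clump_table(), fam.truth.tags()
panels = [build_panel(c, tags, fam.stats, table) for c in fam.cohorts]
dev_c, dev_p = fam.cohorts[:5], panels[:5]
val_c, val_p = fam.cohorts[5:], panels[5:]

traces = [pd_second_pass(c, p, pd_first_pass(c, p)) for c, p in zip(dev_c, dev_p)]
for name, k in (("lenient", 2), ("stringent", 3)):
    model = commonality(traces, k, panels=dev_p)
    rec = len(model.clump_ids & fam.truth.causal_shared) / len(fam.truth.causal_shared)
    dev_auc = np.mean([apply_model(model, c, p)[0].auc for c, p in zip(dev_c, dev_p)])
    val_auc = np.mean([apply_model(model, c, p)[0].auc for c, p in zip(val_c, val_p)])
    print(f"{name} (k={k}): {len(model.clump_ids)} clumps, causal recovery {rec:.0%}, "
          f"dev AUC {dev_auc:.3f}, holdout AUC {val_auc:.3f}, drop {dev_auc - val_auc:+.3f}")
print("-> the stringent model keeps fewer clumps but generalizes with a smaller")
print("   AUC drop: clumps that contribute to perfect discrimination in several")
print("   cohorts are enriched for the shared causal signal.")
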
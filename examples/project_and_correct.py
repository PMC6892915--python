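"""Projecting new profiles onto a fixed basis and removing module effects.

Two uses of a frozen component matrix S:
 1. A' = pinv(S) X' gives least-squares activities for new centered
    profiles over the genes shared with the basis (cross-strain use).
 2. x2' = x2 - sum_i s~_i (a_i2 - a_i1) subtracts selected i-modulon
    effects from a profile, which accounts for strain-specific expression
    differences gene-by-gene.
"""

import numpy as np
import pandas as pd

from imodkit import (
    center_to_reference,
    correct_profile,
    compute_imodulons,
    generate_compendium,
    project_onto_basis,
)

compendium, truth, _ = generate_compendium(seed=5)
centered = center_to_reference(
    compendium.values, compendium.reference_samples, compendium.metadata
)

# 1. projection: the true basis recovers the true activities of any sample
S = truth.S_true
module = truth.modules[0]
# pick the sample where the first planted module is most active
sample_id = truth.A_true.loc[module].abs().idxmax()
sample = centered.values[[sample_id]]
activities = project_onto_basis(S, sample)
true_activities = truth.A_true[sample_id]
err = float(np.max(np.abs(activities.iloc[:, 0] - true_activities)))
print(f"projection of one profile: max |estimated - true activity| = {err:.3f}")

# restriction to shared genes: drop a quarter of the genes, as if the new
# strain lacked them, and project again
core = sample.iloc[: int(0.75 * len(sample))]
restricted = project_onto_basis(S, core)
err_core = float(np.max(np.abs(restricted.iloc[:, 0] - true_activities)))
print(
    f"projection over {len(restricted.attrs['shared_genes'])} core genes: "
    f"max error = {err_core:.3f}"
)

# 2. correction: subtract one module's contribution from the same sample
from imodkit.thresholding import IModulon

idx = list(truth.S_true.columns).index(module)
weights = truth.S_true[module][truth.members[module]]
im = IModulon(
    name=module, component_index=idx, gene_weights=weights, threshold_stat=550.0
)
a_now = {module: float(truth.A_true.loc[module, sample_id])}
a_ref = {module: 0.0}
corrected = correct_profile(sample.iloc[:, 0], [im], truth.S_true, a_now, a_ref)
before = float(sample.loc[truth.members[module]].iloc[:, 0].abs().mean())
after = float(corrected[truth.members[module]].abs().mean())
print(
    f"correction of {module}: mean |centered expression| of member genes "
    f"{before:.2f} -> {after:.2f}"
)

# After correction the module's member genes sit near the reference level:
# its condition-specific effect has been subtracted out.
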
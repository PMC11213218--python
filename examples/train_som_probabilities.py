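"""Train the self-organizing map and derive neuron model probabilities.

Normalized dR1 shapes from a phantom study are clustered on the default
8x8 hexagonal map; each neuron's best-matching-unit hits are tagged with
the conventional NMS labels, giving per-neuron probabilities of the three
nested models.
"""

import numpy as np

from dcepnms import (
    PhantomSpec, batch_train, compute_hitmap, fit_volume,
    neuron_probabilities, normalize_profiles, quantization_error,
    simulate_study,
)

study = simulate_study(PhantomSpec(shape=(24, 24, 1), tumor_radius=7.0,
                                   core_radius=4.0, noise_sd=0.05, seed=5))
res = fit_volume(study.delta_r1, study.brain_mask, study.aif, study.grid)

profiles, included = normalize_profiles(study.delta_r1[study.brain_mask],
                                        study.grid)
labels = res.label_map[study.brain_mask][included]
profiles = profiles[included]

weights = batch_train(profiles)  # 8x8 hex map, batch mode, 250 epochs max
hitmap = compute_hitmap(weights, profiles, labels)
table = neuron_probabilities(hitmap, weights.grid)

print(f"trained on {len(profiles)} normalized profiles "
      f"({weights.n_features} retained frames each)")
print(f"quantization error: {quantization_error(weights, profiles):.4f}")
print(f"neurons hit: {(hitmap.total > 0).sum()}/64, "
      f"borrowed probabilities: {(table.provenance >= 0).sum()}")
pure = (table.probs.max(axis=1) > 0.9).sum()
print(f"neurons >90% pure in one model: {pure}/64")
for m in (1, 2, 3):
    share = hitmap.per_label[:, m - 1].sum() / hitmap.total.sum()
    print(f"  Model-{m} profiles: {100 * share:.1f}% of hits")
# A well-ordered map concentrates each kinetic shape family on a
# contiguous patch of neurons, so most neurons are nearly pure.
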
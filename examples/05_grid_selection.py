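"""The hyperparameter selection protocol for the SWE pooler.

The pooler has two tuned knobs: the reference-set size m and whether the
slicers/reference stay frozen at their random initialization (the
SWE_Simple variant trains only the m combination weights).  Every
configuration is trained, the one with the best validation metric across
all epochs is selected (ties: smaller m, then frozen), and the winner is
re-trained across seeds to report mean and standard deviation of the test
metric.
"""

import swepool as sw
from swepool.train import RunConfig, grid_search_select, select_best

# selection logic on a fabricated validation table
table = [(100, True, 0.7), (200, True, 0.9), (100, False, 0.8)]
print("fabricated validation table (m, frozen, val):", table)
print("selected:", select_best(table), " (argmax of the validation value)\n")

# full protocol on a small planted-signal dataset
spec = sw.SyntheticSpec(n_proteins=300, d=8, length_min=10, length_max=30,
                        k_signal=3, signal_strength=4.0, noise_sd=1.0,
                        task="binary", seed=5)
data = sw.gen_property_dataset(spec)
configs = [RunConfig(task="ec", pooler="swe", m=m, freeze=fr, epochs=5, seeds=(0, 1))
           for m in (4, 8) for fr in (True, False)]
result = grid_search_select(configs, data)
for m, fr, val in result.per_config:
    print(f"  m={m:2d} frozen={fr!s:5}  best val Fmax = {val:.4f}")
print(f"selected: m={result.selected[0]}, frozen={result.selected[1]}")
rep = result.test_report
print(f"test {rep.metric_name}: {rep.mean:.4f} +/- {rep.std:.4f} "
      f"over {len(rep.per_seed)} seeds")
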
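"""Why learned transport pooling beats averaging on long sequences.

Generates a small planted-signal dataset — each positive protein hides
five "key" residues whose embeddings are shifted along a fixed direction,
against isotropic noise, with lengths from 50 to 600 — then trains the
SWE pooler and average pooling end-to-end with the same binary head and
compares test AUPR overall and per length quartile.  Averaging dilutes
the five-token signal by k/n, so its performance decays with length while
the transport pooler, which can attend to extreme quantiles of learned
slices, keeps it.  Runs in about two minutes.
"""

import numpy as np

import swepool as sw
from swepool.train import (RunConfig, ScoredResult, compute_metric,
                           length_stratified_gains, predict_scores, train_erm)

spec = sw.SyntheticSpec(n_proteins=800, d=32, length_min=50, length_max=600,
                        k_signal=5, signal_strength=3.0, noise_sd=1.0,
                        task="binary", seed=1)
data = sw.gen_property_dataset(spec)
test = data.split["test"]
labels, lengths = data.labels[test], data.lengths[test]

swe_model, _ = train_erm(RunConfig(task="ec", pooler="swe", m=16, epochs=10), data, 0)
avg_model, _ = train_erm(RunConfig(task="ec", pooler="avg", epochs=10), data, 0)
s_swe = predict_scores(swe_model, data, test)
s_avg = predict_scores(avg_model, data, test)

print(f"test AUPR  SWE: {compute_metric('ec', s_swe, labels, 'AUPR'):.4f}")
print(f"test AUPR  avg: {compute_metric('ec', s_avg, labels, 'AUPR'):.4f}")

print("\nAUPR gain of SWE over averaging per length quartile:")
gains = length_stratified_gains(ScoredResult(s_swe, labels, lengths),
                                ScoredResult(s_avg, labels, lengths))
for row in gains:
    lo, hi = row["bin"]
    print(f"  lengths [{lo:4.0f}, {hi:4.0f}]  delta AUPR = {row['delta']:+.4f}"
          f"  (n={row['n']})")
print("\nGains concentrate in the longer quartiles, where average pooling "
      "dilutes the localized signal; at this small scale (~30 test proteins "
      "per bin) individual bins are noisy — the full-size benchmark in the "
      "test suite averages over 5 seeds and 113 proteins per bin.")
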
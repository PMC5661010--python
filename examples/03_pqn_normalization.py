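"""Probabilistic quotient normalization removes per-sample dilution.

The generator multiplies each sample by a dilution factor uniform on
(0.5, 2); PQN recovers those factors (up to one global scale) from the
median of bucket-wise quotients against the median spectrum.
"""

import numpy as np

from nmrfingerprint import SyntheticConfig, generate_bucket_table, pqn_normalize

table, _, truth = generate_bucket_table(SyntheticConfig(seed=3))
result = pqn_normalize(table)

recovered = np.array([result.dilution_factors[s] for s in table.samples])
planted = np.array([truth.dilution_factors[s] for s in table.samples])
recovered /= np.median(recovered)
planted /= np.median(planted)
rel_err = np.abs(recovered - planted) / planted

print("sample              planted  recovered")
for s, p, r in list(zip(table.samples, planted, recovered))[:6]:
    print(f"{s:<20s} {p:.3f}    {r:.3f}")
print(f"...\nmedian relative error over {table.n_samples} samples: "
      f"{np.median(rel_err):.2%}")
print("(<2% with the default 2% technical noise: dilution is effectively removed)")
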
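"""Small-train benchmarking: how well does a GP rank unseen variants when
trained on only 33 measurements?

Run:  python examples/04_model_benchmark.py
"""

import numpy as np

from taqdesign import (EmbedderSpec, EvalProtocol, GPSpec, LandscapeConfig,
                       embedding_matrix, fit_gp, generate_landscape,
                       run_protocol)
from taqdesign.variants import apply_variant

land = generate_landscape(LandscapeConfig(seed=0), n_variants=120)
seqs = [apply_variant(land.reference, v) for v in land.variants]
X = embedding_matrix(seqs, EmbedderSpec(seed=0))
y = -land.measured.values["rt90"].to_numpy(dtype=float)  # higher = better RTase
keep = np.isfinite(y)
X, y = X[keep], y[keep]
names = [n for n, k in zip(land.measured.values.index, keep) if k]
wt = y[names.index("WT")]


def gp_factory(Xtr, ytr):
    model = fit_gp(Xtr, ytr, GPSpec(seed=0))
    return lambda Xte: model.predict_mean_var(Xte)[0]


dists = run_protocol(X, y, wt, gp_factory,
                     EvalProtocol(train_size=33, repetitions=10, seed=0), names)
for name, d in dists.items():
    lo, hi = d.iqr
    print(f"{name:10s} median {d.median:.3f}  IQR [{lo:.3f}, {hi:.3f}]")
# spearman: rank agreement on held-out variants; topK: fraction of the K
# best-predicted variants that truly beat the wild type
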
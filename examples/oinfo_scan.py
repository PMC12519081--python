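"""O-info tuple scan of a phenotype-constrained parameter ensemble.

Generates a population of 'models' whose parameters are conditioned on a
shared phenotype (a soft linear constraint), scans O-info across tuple
orders, compares against column-shuffled surrogates, and ranks parameters
by their frequency in the most synergistic tuples.
"""

import numpy as np

from hoinfo import ScanConfig, scan, shuffle_surrogates, top_fraction_frequency
from hoinfo.synthetic import gen_synergistic

ds = gen_synergistic(n=4000, p=8, seed=1, tau=0.5)
config = ScanConfig(orders=range(3, 8), budget=500, seed=1)

curve = scan(ds.data, config)
band = shuffle_surrogates(ds.data, config, n_surrogates=30, seed=1)

print(curve.summary().to_string(index=False,
                                float_format=lambda v: f"{v: .4f}"))
print()
for order, lo, hi in zip(band.orders, band.min_negative, band.max_positive):
    print(f"order {order}: surrogate band [{lo:+.4f}, {hi:+.4f}]")
print()
freq = top_fraction_frequency(curve, fraction=0.05, side="min")
print("top contributors to high-synergy tuples (mean frequency):")
print(freq.mean_frequency().head(4).to_string(float_format="{:.3f}".format))
print()
print("Negative per-order minima far below the surrogate band mean the "
      "constraint induces genuine multi-parameter synergy: no single "
      "parameter, only combinations, carries the phenotype information.")
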
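"""Selecting a high-covariance sub-ensemble flips synergy to redundancy.

From a synergy-dominated constrained ensemble with weak coexpression
factors, keep the 1,000 samples best reconstructed from the top 5 principal
components (the high-covariance subset) and compare O-info dominance
against an equal-size random subset.
"""

from hoinfo.recipes import high_covariance_flip

flip = high_covariance_flip(seed=0)

print("synergy AUC / redundancy AUC of the mean O-info trajectory:")
print(f"  full ensemble (n=10000): {flip.full[0]:.3f} / {flip.full[1]:.3f}")
print(f"  high-covariance subset (n=1000): "
      f"{flip.subset[0]:.3f} / {flip.subset[1]:.3f}")
print(f"  random subset (n=1000): {flip.random[0]:.3f} / {flip.random[1]:.3f}")
print()
print(f"full synergy-dominated: {flip.full_synergy_dominated}; "
      f"subset redundancy-dominated: {flip.subset_redundancy_dominated}; "
      f"random synergy-dominated: {flip.random_synergy_dominated}")
print()
print("Selection by PCA reconstruction error keeps only models lying close "
      "to the dominant covariance plane; their parameter covariation alone "
      "is enough to shift the interaction structure toward redundancy, "
      "with no change to the generative model.")
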
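"""Detection power over outlier size and separation (small-scale demo).

Scans a reduced grid of the Gaussian-mixture validation scheme: the case
group hides an outlier subpopulation of varying size, shifted by a fixed
number of standard deviations, and each grid cell records how often the
permutation test rejects over seeded replicates.
"""

from csea import CseaParams, GaussianMixtureSpec, detection_threshold, power_grid

grid = power_grid(
    scheme="gaussian",
    separations=(2.0,),
    fractions=(0.02, 0.06, 0.10, 0.16),  # within-case outlier proportions
    replicates=10,
    base_spec=GaussianMixtureSpec(n_per_group=500),
    params=CseaParams(n_permutations=100),
    master_seed=0,
)
print("rejection rate at 2 SD separation (500 cells per group, 10 replicates):")
print(grid.power().round(2).to_string())

thr = detection_threshold(grid, axis="fraction")
print(f"\nmajority-detection threshold: within-case proportion {thr:.2f} "
      f"(= {thr * 100 / 2:.0f}% of the total population)")
print(
    "Power rises with the outlier share; the threshold is the smallest\n"
    "scanned share detected in more than half of the replicates, with the\n"
    "detection persisting at every larger share."
)
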
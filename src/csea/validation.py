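"""Prepackaged validation experiments at the study's reference conditions.

These helpers wire the simulation schemes to the power/threshold machinery
at the conditions used for validating the method: equal case/control
groups, outlier shares expressed as percent of the total population
(equal group sizes, so the within-case mixture proportion is twice the
total share), 100 label permutations, alpha 0.05, majority detection over
20 replicates.
"""

from __future__ import annotations

import numpy as np

from .evaluate import PowerGrid, detection_threshold, power_grid
from .simulate import CountSimSpec, GaussianMixtureSpec
from .types import CseaParams

# outlier shares of the total population scanned in the threshold studies
SHARE_GRID_PCT = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0)
SEPARATION_GRID_SD = (0.5, 1.0, 1.5, 2.0, 3.0)


def _case_fracs(shares_pct) -> tuple:
    """Within-case mixture proportions for total-population shares (%)."""
    return tuple(2.0 * s / 100.0 for s in shares_pct)


def gaussian_fraction_threshold(
    seed: int,
    separation_sd: float = 2.0,
    shares_pct=SHARE_GRID_PCT,
    n_per_group: int = 1000,
    replicates: int = 20,
    params: "CseaParams | None" = None,
) -> dict:
    """Smallest detectable outlier share (% of total) at a fixed separation."""
    grid = power_grid(
        scheme="gaussian",
        separations=(separation_sd,),
        fractions=_case_fracs(shares_pct),
        replicates=replicates,
        base_spec=GaussianMixtureSpec(n_per_group=n_per_group),
        params=params or CseaParams(),
        master_seed=seed,
    )
    thr_frac = detection_threshold(grid, axis="fraction")
    thr_pct = thr_frac * 100.0 / 2.0 if np.isfinite(thr_frac) else thr_frac
    return {
        "threshold_pct_of_total": thr_pct,
        "power": grid.power(),
        "n_cells": 2 * n_per_group,
        "grid": grid,
    }


def gaussian_separation_threshold(
    seed: int,
    share_pct: float = 10.0,
    separations_sd=SEPARATION_GRID_SD,
    n_per_group: int = 1000,
    replicates: int = 20,
    params: "CseaParams | None" = None,
) -> dict:
    """Smallest detectable mean separation (SD) at a fixed outlier share."""
    grid = power_grid(
        scheme="gaussian",
        separations=tuple(separations_sd),
        fractions=(2.0 * share_pct / 100.0,),
        replicates=replicates,
        base_spec=GaussianMixtureSpec(n_per_group=n_per_group),
        params=params or CseaParams(),
        master_seed=seed,
    )
    return {
        "threshold_sd": detection_threshold(grid, axis="separation"),
        "power": grid.power(),
        "n_cells": 2 * n_per_group,
        "grid": grid,
    }


def counts_fraction_threshold(
    seed: int,
    separation_sd: float = 2.0,
    shares_pct=SHARE_GRID_PCT,
    n_per_group: int = 300,
    n_genes: int = 500,
    replicates: int = 20,
    params: "CseaParams | None" = None,
) -> dict:
    """Count-scheme analogue of :func:`gaussian_fraction_threshold`."""
    base = CountSimSpec(
        n_per_group=n_per_group,
        n_genes=n_genes,
        mixture=GaussianMixtureSpec(n_per_group=n_per_group),
    )
    grid = power_grid(
        scheme="counts",
        separations=(separation_sd,),
        fractions=_case_fracs(shares_pct),
        replicates=replicates,
        base_spec=base,
        params=params or CseaParams(),
        master_seed=seed,
    )
    thr_frac = detection_threshold(grid, axis="fraction")
    thr_pct = thr_frac * 100.0 / 2.0 if np.isfinite(thr_frac) else thr_frac
    return {
        "threshold_pct_of_total": thr_pct,
        "power": grid.power(),
        "n_cells": 2 * n_per_group,
        "grid": grid,
    }
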
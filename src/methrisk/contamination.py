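"""In-silico tumour-DNA contamination of control methylomes.

Observed betas of a contaminated sample are the convex combination
beta = (1 - rho) * beta_control + rho * beta_tumour.  Because the index is
linear in the betas, the mean index shift of a contaminated cohort is exactly
linear in rho; the module computes the shift curve (in control-SD units) over
a rho grid and locates the smallest contamination level reaching a target
shift.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .index import IndexModel, compute_index

__all__ = ["mix_betas", "contamination_shift_curve"]


def mix_betas(control_matrix: pd.DataFrame, tumour_profile: pd.Series, rho: float) -> pd.DataFrame:
    """Elementwise convex combination of a control matrix with a tumour profile."""
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    t = tumour_profile.reindex(control_matrix.index)
    if t.isna().any():
        raise ValueError("tumour profile does not cover all control CpGs")
    return (1 - rho) * control_matrix + rho * t.to_numpy()[:, None]


def contamination_shift_curve(
    model: IndexModel,
    controls: pd.DataFrame,
    tumour_profile: pd.Series,
    rho_grid,
    target_shift_sd: float = 1.25,
):
    """Mean index shift versus tumour fraction, and the level hitting a target.

    shift(rho) = (mean index of the mixed cohort - mean index of the unmixed
    controls) / SD of the unmixed controls' index.  rho* is the smallest
    contamination reaching ``target_shift_sd``, linearly interpolated between
    grid points; if the target is not reached at the largest grid value the
    result reports it unreachable (rho* is None) rather than extrapolating.

    Returns ``(curve, rho_star)`` with curve columns ``rho, mean_shift_sd``.
    """
    rho_grid = np.sort(np.asarray(rho_grid, dtype=float))
    if np.any((rho_grid < 0) | (rho_grid > 1)):
        raise ValueError("rho grid must lie in [0, 1]")
    base = compute_index(model, controls)
    sd0 = float(base.std(ddof=1))
    if not sd0 > 0:
        raise ValueError("controls' index SD must be positive")
    mean0 = float(base.mean())
    shifts = np.empty(len(rho_grid))
    for i, rho in enumerate(rho_grid):
        mixed = mix_betas(controls, tumour_profile, rho)
        shifts[i] = (float(compute_index(model, mixed).mean()) - mean0) / sd0
    curve = pd.DataFrame({"rho": rho_grid, "mean_shift_sd": shifts})
    rho_star = None
    reach = np.nonzero(shifts >= target_shift_sd)[0]
    if len(reach):
        j = reach[0]
        if j == 0 or shifts[j] == target_shift_sd:
            rho_star = float(rho_grid[j])
        else:
            r0, r1, s0, s1 = rho_grid[j - 1], rho_grid[j], shifts[j - 1], shifts[j]
            rho_star = float(r0 + (target_shift_sd - s0) * (r1 - r0) / (s1 - s0))
    return curve, rho_star
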
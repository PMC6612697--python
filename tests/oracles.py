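"""Independent reference implementations used as test oracles.

These deliberately avoid the package's candidate-window machinery: the
gamma map is an exhaustive double loop over every evaluated point with no
search-radius cap, written directly from the defining formula.
"""
import numpy as np


def brute_force_gamma_map(reference, evaluated, dd_pct, dta_mm, ldt_pct=5.0):
    """Exhaustive per-point gamma: min Γ over ALL evaluated points.

    Returns (gamma, included_mask); excluded points are NaN.
    """
    norm = float(reference.values.max())
    dd_abs = dd_pct / 100.0 * norm
    mask = reference.values >= ldt_pct / 100.0 * norm
    ex = evaluated.origin[0] + evaluated.dx * np.arange(evaluated.nx)
    ey = evaluated.origin[1] + evaluated.dy * np.arange(evaluated.ny)
    rx = reference.origin[0] + reference.dx * np.arange(reference.nx)
    ry = reference.origin[1] + reference.dy * np.arange(reference.ny)

    gamma = np.full(reference.shape, np.nan)
    for i in range(reference.nx):
        for j in range(reference.ny):
            if not mask[i, j]:
                continue
            d2 = (ex[:, None] - rx[i]) ** 2 + (ey[None, :] - ry[j]) ** 2
            delta = evaluated.values - reference.values[i, j]
            g2 = (delta / dd_abs) ** 2 + d2 / (dta_mm * dta_mm)
            gamma[i, j] = np.sqrt(g2.min())
    return gamma, mask
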
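"""Global gamma evaluation on planar dose grids.

The gamma index at a reference point r_r is the minimum, over evaluated
points r_e, of

    Gamma(r_e, r_r) = sqrt( delta^2 / dD^2  +  r^2 / dd^2 )

where ``delta`` is the dose difference between the evaluated and reference
doses, ``r`` the 2D Euclidean distance in mm, ``dD`` the absolute dose
tolerance (percent of the global maximum reference dose under global
normalization) and ``dd`` the distance-to-agreement tolerance in mm.  A
point agrees with the evaluated distribution when γ ≤ 1.0 (inclusive); the
gamma agreement index (GAI, "pass rate") is the percentage of analysed
points that agree.

Reference points below the lower dose threshold (LDT, percent of the
normalization dose, inclusive ≥ comparison) are excluded from analysis.
The evaluated grid is bilinearly resampled to a finer pitch before the
candidate search, since the minimum is otherwise quantized to the detector
pitch.

Candidate geometry: a candidate farther than Δd from the reference point
always has Γ > 1, so pass/fail and the GAI are exact with a search disc of
radius Δd.  When full γ values are wanted the disc is enlarged to
``gamma_radius_factor``·Δd (default 3) so values up to 3 are exact; beyond
that the stored value is the guaranteed lower bound radius/Δd, flagged
censored.  ``radius_mm=None`` removes the cap entirely (exact γ map).
"""
from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import EmptyMaskError, NormalizationError
from .model import (
    DoseGrid,
    GammaCriteria,
    GammaResult,
    SearchSettings,
    validate_pair,
)

#: Distances below this (mm) are treated as exact co-location.
R_EPS = 1e-9


def normalization_dose(reference: DoseGrid) -> float:
    """Global normalization dose: the maximum dose of the reference grid."""
    m = float(reference.values.max())
    if m <= 0:
        raise NormalizationError("zero normalization dose (all-zero reference grid)")
    return m


def inclusion_mask(
    reference: DoseGrid,
    criteria: GammaCriteria | None = None,
    *,
    ldt_pct: float | None = None,
    norm_dose: float | None = None,
) -> np.ndarray:
    """Boolean grid of reference points at or above the lower dose threshold.

    The comparison is inclusive: a point exactly at the threshold dose is
    analysed.  The threshold is a percentage of the normalization dose,
    which defaults to the reference grid's global maximum.
    """
    if ldt_pct is None:
        ldt_pct = criteria.ldt_pct if criteria is not None else 0.0
    if norm_dose is None:
        norm_dose = normalization_dose(reference)
    return reference.values >= (ldt_pct / 100.0) * norm_dose


def _refined_axis(x0: float, d: float, n: int, step: float):
    """Coordinates and spacing of one axis refined to pitch <= step."""
    if n == 1 or step >= d * (1.0 - 1e-12):
        return x0 + d * np.arange(n), d, False
    extent = (n - 1) * d
    ncells = int(np.ceil(extent / step - 1e-9))
    nd = extent / ncells
    return x0 + nd * np.arange(ncells + 1), nd, True


def resample_evaluated(
    evaluated: DoseGrid, settings: SearchSettings | None = None
) -> DoseGrid:
    """Bilinearly resample the evaluated grid onto a finer regular grid.

    The resampled grid covers the same physical extent with spacing no
    larger than ``settings.interp_step_mm`` on each axis.  When the target
    step equals (or exceeds) the native spacing the input is returned
    unchanged — the grid is never coarsened.
    """
    settings = settings or SearchSettings()
    step = settings.interp_step_mm
    xq, ndx, chx = _refined_axis(evaluated.origin[0], evaluated.dx, evaluated.nx, step)
    yq, ndy, chy = _refined_axis(evaluated.origin[1], evaluated.dy, evaluated.ny, step)
    if not (chx or chy):
        return evaluated

    x = evaluated.x_coords
    y = evaluated.y_coords
    # clip query coords so FP jitter at the far edge cannot fall outside
    xq = np.clip(xq, x[0], x[-1])
    yq = np.clip(yq, y[0], y[-1])
    if evaluated.nx == 1:
        new = np.interp(yq, y, evaluated.values[0])[None, :]
    elif evaluated.ny == 1:
        new = np.interp(xq, x, evaluated.values[:, 0])[:, None]
    else:
        interp = RegularGridInterpolator((x, y), evaluated.values, method="linear")
        gx, gy = np.meshgrid(xq, yq, indexing="ij")
        new = interp(np.stack([gx.ravel(), gy.ravel()], axis=1)).reshape(
            gx.shape
        )
    new = np.clip(new, 0.0, None)  # guard FP undershoot of non-negative doses
    return DoseGrid(new, (ndx, ndy), evaluated.origin, evaluated.dose_unit)


def candidate_window(
    grid: DoseGrid, x: float, y: float, radius_mm: float | None
):
    """Evaluated doses and squared distances within a disc around (x, y).

    Returns flat arrays ``(doses, r2)``.  Squared distances within 1e-18
    mm² are snapped to exactly 0 (co-location) and values marginally above
    radius² from FP round-off are clamped to radius², so boundary
    candidates behave exactly as their algebraic distance dictates.
    ``radius_mm=None`` means the whole grid.
    """
    vals = grid.values
    if radius_mm is None:
        i0, i1, j0, j1 = 0, grid.nx - 1, 0, grid.ny - 1
    else:
        x0, y0 = grid.origin
        i0 = max(int(np.ceil((x - radius_mm - x0) / grid.dx - 1e-12)), 0)
        i1 = min(int(np.floor((x + radius_mm - x0) / grid.dx + 1e-12)), grid.nx - 1)
        j0 = max(int(np.ceil((y - radius_mm - y0) / grid.dy - 1e-12)), 0)
        j1 = min(int(np.floor((y + radius_mm - y0) / grid.dy + 1e-12)), grid.ny - 1)
        if i0 > i1 or j0 > j1:
            return np.empty(0), np.empty(0)
    ddx = grid.x_coords[i0 : i1 + 1] - x
    ddy = grid.y_coords[j0 : j1 + 1] - y
    r2 = ddx[:, None] ** 2 + ddy[None, :] ** 2
    sub = vals[i0 : i1 + 1, j0 : j1 + 1]
    if radius_mm is not None:
        rad2 = radius_mm * radius_mm
        keep = r2 <= rad2 * (1.0 + 1e-12)
        r2 = np.minimum(r2[keep], rad2)
        sub = sub[keep]
    else:
        r2 = r2.ravel()
        sub = sub.ravel()
    r2 = np.where(r2 < R_EPS * R_EPS, 0.0, r2)
    return sub, r2


def gamma_point(
    x: float,
    y: float,
    ref_dose: float,
    evaluated: DoseGrid,
    dd_abs: float,
    dta_mm: float,
    radius_mm: float | None,
) -> float:
    """γ at one reference point: min Γ over candidates within the disc.

    ``dd_abs`` is the absolute dose tolerance (same unit as the doses).
    Degenerate criteria are the limits of the Γ formula: Δd = 0 restricts
    the test to co-located candidates (pure dose difference), ΔD = 0
    requires an exact dose match within the distance tolerance.  Returns
    +inf when no candidate can be scored.
    """
    if dta_mm == 0:
        radius_mm = R_EPS
    doses, r2 = candidate_window(evaluated, x, y, radius_mm)
    if doses.size == 0:
        return np.inf
    delta = doses - ref_dose
    if dta_mm == 0:
        if dd_abs == 0:
            return 0.0 if np.any(delta == 0.0) else np.inf
        return float(np.min(np.abs(delta)) / dd_abs)
    if dd_abs == 0:
        exact = delta == 0.0
        if not np.any(exact):
            return np.inf
        return float(np.sqrt(np.min(r2[exact])) / dta_mm)
    g2 = (delta / dd_abs) ** 2 + r2 / (dta_mm * dta_mm)
    return float(np.sqrt(np.min(g2)))


def gamma_map(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria | None = None,
    settings: SearchSettings | None = None,
    *,
    norm_dose: float | None = None,
    radius_mm: float | None | str = "auto",
    resample: bool = True,
) -> GammaResult:
    """Global gamma comparison of an evaluated grid against a reference.

    Parameters
    ----------
    criteria
        ΔD/Δd/LDT; defaults to 3%/2 mm with a 5% threshold.
    settings
        Resampling pitch and candidate-disc policy.
    norm_dose
        Override of the global normalization dose (defaults to the
        reference maximum).
    radius_mm
        ``"auto"`` — disc of ``gamma_radius_factor``·Δd with censoring
        beyond; ``None`` — no cap (exact γ everywhere); a number — explicit
        disc radius (must be ≥ Δd for exact pass/fail).
    resample
        Bilinearly refine the evaluated grid to ``interp_step_mm`` first.
    """
    criteria = criteria or GammaCriteria()
    settings = settings or SearchSettings()
    if norm_dose is None:
        norm_dose = normalization_dose(reference)
    validate_pair(reference, evaluated, ldt_pct=criteria.ldt_pct, norm_dose=norm_dose)
    mask = inclusion_mask(reference, criteria, norm_dose=norm_dose)

    ev = resample_evaluated(evaluated, settings) if resample else evaluated
    dd_abs = criteria.dose_criterion_pct / 100.0 * norm_dose
    dta = criteria.dta_mm
    if radius_mm == "auto":
        radius = settings.gamma_radius_factor * dta if dta > 0 else None
    else:
        radius = radius_mm

    bound = None
    if radius is not None and dta > 0:
        bound = radius / dta

    gamma = np.full(reference.shape, np.nan)
    censored = np.zeros(reference.shape, dtype=bool)
    xs = reference.x_coords
    ys = reference.y_coords
    vals = reference.values
    for i, j in np.argwhere(mask):
        g = gamma_point(xs[i], ys[j], vals[i, j], ev, dd_abs, dta, radius)
        if bound is not None and g > bound * (1.0 + 1e-12):
            gamma[i, j] = bound  # guaranteed lower bound: disc exhausted
            censored[i, j] = True
        else:
            gamma[i, j] = g

    # a censored point's true gamma exceeds the stored bound (>= radius/dta
    # >= 1 for any valid disc), so censored points never pass
    with np.errstate(invalid="ignore"):
        passing = mask & ~censored & (gamma <= criteria.pass_threshold)
    n_inc = int(mask.sum())
    if n_inc == 0:
        raise EmptyMaskError("no points above threshold")
    n_pass = int(passing.sum())
    gai_pct = 100.0 * n_pass / n_inc
    return GammaResult(
        gamma=gamma,
        included_mask=mask,
        gai_pct=gai_pct,
        n_included=n_inc,
        n_passed=n_pass,
        criteria=criteria,
        norm_dose=norm_dose,
        censored=censored,
    )


def gai(
    gamma: np.ndarray,
    included_mask: np.ndarray | None = None,
    pass_threshold: float = 1.0,
    *,
    counts: bool = False,
):
    """Gamma agreement index: percentage of included points with γ ≤ 1.

    The comparison is inclusive; +inf sentinels count as failures; NaN
    marks excluded points (ignored).  Raises when no point is included.
    """
    gamma = np.asarray(gamma, dtype=float)
    if included_mask is None:
        included_mask = ~np.isnan(gamma)
    vals = gamma[included_mask]
    n = vals.size
    if n == 0:
        raise EmptyMaskError("no points above threshold")
    n_pass = int(np.sum(vals <= pass_threshold))
    pct = 100.0 * n_pass / n
    if counts:
        return pct, n, n_pass
    return pct
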
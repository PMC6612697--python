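"""Inverse gamma: minimum acceptance criteria for a target pass rate.

Standard gamma evaluation answers "what fraction of points agree at
criteria (ΔD, Δd)?".  The inverse gamma (IG) evaluation answers the
converse: "what is the smallest criterion at which a specified gamma
agreement index (GAI) is reached?".  Three modes exist:

* ``fixed_dd``   — hold ΔD (e.g. 3%), search the minimum Δd in mm;
* ``fixed_dta``  — hold Δd, search the minimum ΔD in %;
* ``fixed_ratio``— hold the ratio k = ΔD/Δd (%/mm), search the minimum Δd
  (reporting the linked pair ΔD = k·Δd, Δd).

The search is iterative: full global gamma evaluations with the free
criterion increasing from 0 in fixed steps (0.1 mm for Δd, 0.1% for ΔD),
stopping at the first value whose GAI reaches the target; if the cap is
reached first the cap's GAI is reported.  The GAI-vs-target comparison is
count based — the target is met when n_passed ≥ ceil(target/100 ·
n_included) — so floating-point round-off in the percentage can never
decide convergence.

Per-point requirement maps give the same information pointwise in closed
form: for each analysed reference point, the minimum free-criterion value
at which *that* point passes.  The m-th smallest requirement, rounded up
to the search lattice, equals the iterative search result exactly; this
quantile fast path serves as a cross-check and optional accelerator.

A target GAI of 100% is extremely noise-sensitive: a single corrupted
pixel with no in-tolerance dose anywhere drives the search to the cap.
Targets near 100% (99%, 99.5%) are recommended instead.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .engine import (
    R_EPS,
    candidate_window,
    gamma_point,
    inclusion_mask,
    normalization_dose,
    resample_evaluated,
)
from .errors import EmptyMaskError, SearchError
from .model import (
    DoseGrid,
    IGMode,
    IGResult,
    RequirementKind,
    RequirementMap,
    SearchSettings,
    SearchStatus,
    validate_pair,
)

#: Recommended near-100% targets when a strict 100% GAI would be noise-driven.
RECOMMENDED_NEAR_FULL_TARGETS = (99.0, 99.5)


def required_count(target_gai_pct: float, n_included: int) -> int:
    """Number of passing points needed to meet the target GAI (count-based)."""
    if not (0 < target_gai_pct <= 100):
        raise SearchError("target GAI must be in (0, 100]")
    return max(1, math.ceil(target_gai_pct * n_included / 100.0 - 1e-9))


def ceil_to_step(value: float, step: float) -> float:
    """Smallest non-negative multiple of ``step`` that is >= ``value``.

    The comparison is carried out against the exact float lattice
    ``k*step`` that the iterative search visits, so the two routes agree
    bit-for-bit.
    """
    if value <= 0:
        return 0.0
    k = int(math.ceil(value / step))
    while k > 0 and (k - 1) * step >= value:
        k -= 1
    while k * step < value:
        k += 1
    return k * step


# ---------------------------------------------------------------------------
# per-point requirement maps (closed form)
# ---------------------------------------------------------------------------

def _prepare(reference, evaluated, settings, ldt_pct, norm_dose, resampled):
    settings = settings or SearchSettings()
    norm = norm_dose if norm_dose is not None else normalization_dose(reference)
    validate_pair(reference, evaluated, ldt_pct=ldt_pct, norm_dose=norm)
    mask = inclusion_mask(reference, ldt_pct=ldt_pct, norm_dose=norm)
    if not mask.any():
        raise EmptyMaskError("no points above threshold")
    ev = resampled if resampled is not None else resample_evaluated(evaluated, settings)
    return settings, norm, mask, ev


def per_point_min_dta(
    reference: DoseGrid,
    evaluated: DoseGrid,
    dd_pct: float,
    settings: SearchSettings | None = None,
    *,
    ldt_pct: float = 5.0,
    norm_dose: float | None = None,
    resampled: DoseGrid | None = None,
) -> RequirementMap:
    """Minimum Δd (mm) per reference point at a fixed dose criterion.

    A point's requirement is min over candidates with |δ| ≤ ΔD_abs of
    r / sqrt(1 − δ²/ΔD_abs²); a co-located in-tolerance candidate gives 0.
    Points with no in-tolerance candidate inside the ``max_dta_mm`` disc
    are unreachable (+inf): no distance criterion can rescue them.
    """
    if dd_pct <= 0:
        raise SearchError("dose criterion must be > 0")
    settings, norm, mask, ev = _prepare(
        reference, evaluated, settings, ldt_pct, norm_dose, resampled
    )
    dd_abs = dd_pct / 100.0 * norm
    out = np.full(reference.shape, np.nan)
    xs, ys, vals = reference.x_coords, reference.y_coords, reference.values
    for i, j in np.argwhere(mask):
        doses, r2 = candidate_window(ev, xs[i], ys[j], settings.max_dta_mm)
        if doses.size == 0:
            out[i, j] = np.inf
            continue
        u = ((doses - vals[i, j]) / dd_abs) ** 2
        tol = u <= 1.0
        if not tol.any():
            out[i, j] = np.inf
            continue
        r2t, ut = r2[tol], u[tol]
        with np.errstate(divide="ignore", invalid="ignore"):
            req2 = r2t / (1.0 - ut)
        req2[r2t == 0.0] = 0.0  # co-located candidate passes at any dd<=tol
        out[i, j] = math.sqrt(np.min(req2))
    return RequirementMap(RequirementKind.MIN_DTA_MM, out, mask, dd_pct, norm)


def per_point_min_dd(
    reference: DoseGrid,
    evaluated: DoseGrid,
    dta_mm: float,
    settings: SearchSettings | None = None,
    *,
    ldt_pct: float = 5.0,
    norm_dose: float | None = None,
    resampled: DoseGrid | None = None,
) -> RequirementMap:
    """Minimum ΔD (%) per reference point at a fixed distance criterion.

    Requirement: min over candidates with r < Δd of
    100·|δ| / (norm · sqrt(1 − r²/Δd²)); a candidate exactly at r = Δd can
    only pass with δ = 0 (requirement 0), since the Γ distance term alone
    already reaches 1 there.  Unreachable when no candidate lies within
    the (inclusive) disc.
    """
    if dta_mm < 0:
        raise SearchError("distance criterion must be >= 0")
    settings, norm, mask, ev = _prepare(
        reference, evaluated, settings, ldt_pct, norm_dose, resampled
    )
    out = np.full(reference.shape, np.nan)
    radius = dta_mm if dta_mm > 0 else R_EPS
    dta2 = dta_mm * dta_mm
    xs, ys, vals = reference.x_coords, reference.y_coords, reference.values
    for i, j in np.argwhere(mask):
        doses, r2 = candidate_window(ev, xs[i], ys[j], radius)
        if doses.size == 0:
            out[i, j] = np.inf
            continue
        adelta = np.abs(doses - vals[i, j])
        if dta_mm == 0:
            out[i, j] = 100.0 * np.min(adelta) / norm
            continue
        s = 1.0 - r2 / dta2
        with np.errstate(divide="ignore", invalid="ignore"):
            req = np.where(
                adelta == 0.0,
                0.0,
                np.where(s > 0.0, 100.0 * adelta / (norm * np.sqrt(np.maximum(s, 0.0))), np.inf),
            )
        out[i, j] = float(np.min(req))
    return RequirementMap(RequirementKind.MIN_DD_PCT, out, mask, dta_mm, norm)


def per_point_min_scale(
    reference: DoseGrid,
    evaluated: DoseGrid,
    ratio_pct_per_mm: float,
    settings: SearchSettings | None = None,
    *,
    ldt_pct: float = 5.0,
    norm_dose: float | None = None,
    resampled: DoseGrid | None = None,
) -> RequirementMap:
    """Minimum Δd (mm) per point when ΔD is linked to Δd by a fixed ratio.

    With ΔD = k·Δd the passing condition Γ ≤ 1 collapses to
    Δd ≥ sqrt((100·δ/(k·norm))² + r²), so the requirement is the minimum
    of that expression over candidates in the ``max_dta_mm`` disc.  It is
    finite for any candidate; +inf only when the disc is empty.
    """
    if ratio_pct_per_mm <= 0:
        raise SearchError("criteria ratio must be > 0")
    settings, norm, mask, ev = _prepare(
        reference, evaluated, settings, ldt_pct, norm_dose, resampled
    )
    out = np.full(reference.shape, np.nan)
    k = ratio_pct_per_mm
    xs, ys, vals = reference.x_coords, reference.y_coords, reference.values
    for i, j in np.argwhere(mask):
        doses, r2 = candidate_window(ev, xs[i], ys[j], settings.max_dta_mm)
        if doses.size == 0:
            out[i, j] = np.inf
            continue
        dd_equiv = 100.0 * (doses - vals[i, j]) / (k * norm)
        out[i, j] = math.sqrt(np.min(dd_equiv**2 + r2))
    return RequirementMap(RequirementKind.MIN_SCALE, out, mask, k, norm)


_REQ_DISPATCH = {
    IGMode.FIXED_DD: per_point_min_dta,
    IGMode.FIXED_DTA: per_point_min_dd,
    IGMode.FIXED_RATIO: per_point_min_scale,
}


def per_point_requirements(
    reference: DoseGrid,
    evaluated: DoseGrid,
    mode: IGMode | str,
    fixed_value: float,
    settings: SearchSettings | None = None,
    **kwargs,
) -> RequirementMap:
    """Requirement map matching an :func:`ig_search` mode and fixed value."""
    mode = IGMode(mode)
    return _REQ_DISPATCH[mode](reference, evaluated, fixed_value, settings, **kwargs)


# ---------------------------------------------------------------------------
# quantile fast path
# ---------------------------------------------------------------------------

def quantile_fast_path(
    req_map: RequirementMap,
    target_gai_pct: float,
    step: float,
    cap: float | None = None,
) -> float:
    """Search result from a requirement map, without iterating.

    Returns the smallest multiple of ``step`` ≥ the m-th smallest
    per-point requirement, m = ceil(target/100 · n_included); unreachable
    (+inf) requirements sort last.  Returns +inf (cap failure) when the
    m-th requirement is unreachable or exceeds the cap.
    """
    vals = req_map.included_values
    if vals.size == 0:
        raise EmptyMaskError("empty requirement map")
    m = required_count(target_gai_pct, vals.size)
    v = float(np.partition(vals, m - 1)[m - 1])
    if not np.isfinite(v):
        return np.inf
    out = ceil_to_step(v, step)
    if cap is not None and out > cap * (1.0 + 1e-12):
        return np.inf
    return out


def requirement_histogram(req_map: RequirementMap) -> pd.DataFrame:
    """Sorted per-point requirements with cumulative GAI.

    Each row is one distinct finite requirement value with its count and
    the cumulative percentage of analysed points whose requirement is ≤
    that value — i.e. the GAI that a standard gamma evaluation at (fixed
    criterion, value) would report on the same resampled grid.  With
    unreachable points present the cumulative GAI never reaches 100%.
    """
    vals = req_map.included_values
    if vals.size == 0:
        raise EmptyMaskError("empty requirement map")
    finite = np.sort(vals[np.isfinite(vals)])
    uniq, counts = np.unique(finite, return_counts=True)
    cum = np.cumsum(counts)
    return pd.DataFrame(
        {
            "value": uniq,
            "count": counts,
            "cumulative_count": cum,
            "cumulative_gai_pct": 100.0 * cum / vals.size,
        }
    )


# ---------------------------------------------------------------------------
# iterative search
# ---------------------------------------------------------------------------

def ig_search(
    reference: DoseGrid,
    evaluated: DoseGrid,
    mode: IGMode | str,
    fixed_value: float,
    target_gai_pct: float,
    settings: SearchSettings | None = None,
    *,
    ldt_pct: float = 5.0,
    norm_dose: float | None = None,
    use_fast_path: bool = False,
) -> IGResult:
    """Minimum criteria achieving a target GAI, by iterative gamma runs.

    The free criterion starts at 0 and advances on its step lattice; at
    each value a global gamma evaluation is performed and the first value
    whose passing count reaches ceil(target/100 · n_included) is returned
    (status ``converged``).  If the cap is reached first, status is
    ``cap_reached`` and the cap's GAI is reported.  The full
    (criterion, GAI) trace is attached to the result.

    Points that fail even at the cap are detected once (a gamma test at
    the cap) and skipped thereafter; points that have passed stay passed
    (γ is monotone in the criteria), so only undecided points are
    re-evaluated each step.  The outcome is identical to re-evaluating the
    whole grid at every step.

    ``use_fast_path=True`` computes the same result from the closed-form
    requirement map instead (no trace).
    """
    mode = IGMode(mode)
    settings = settings or SearchSettings()
    if fixed_value <= 0:
        raise SearchError("fixed criterion value must be > 0")
    if not (0 < target_gai_pct <= 100):
        raise SearchError("target GAI must be in (0, 100]")
    norm = norm_dose if norm_dose is not None else normalization_dose(reference)
    validate_pair(reference, evaluated, ldt_pct=ldt_pct, norm_dose=norm)
    mask = inclusion_mask(reference, ldt_pct=ldt_pct, norm_dose=norm)
    n = int(mask.sum())
    if n == 0:
        raise EmptyMaskError("no points above threshold")
    m = required_count(target_gai_pct, n)
    ev = resample_evaluated(evaluated, settings)

    if mode is IGMode.FIXED_DTA:
        step, cap = settings.dd_step_pct, settings.max_dd_pct
    else:
        step, cap = settings.dta_step_mm, settings.max_dta_mm
    kmax = int(math.floor(cap / step + 1e-9))
    cmax = kmax * step

    if use_fast_path:
        req = per_point_requirements(
            reference, evaluated, mode, fixed_value, settings,
            ldt_pct=ldt_pct, norm_dose=norm, resampled=ev,
        )
        found = quantile_fast_path(req, target_gai_pct, step, cap=cmax)
        vals = req.included_values
        if np.isfinite(found):
            n_passed = int(np.sum(vals <= found))
            return _make_result(
                mode, target_gai_pct, fixed_value, found,
                100.0 * n_passed / n, SearchStatus.CONVERGED,
                int(round(found / step)) + 1, (),
            )
        n_passed = int(np.sum(vals <= cmax))
        return _make_result(
            mode, target_gai_pct, fixed_value, cmax,
            100.0 * n_passed / n, SearchStatus.CAP_REACHED, kmax + 1, (),
        )

    xs, ys, vals = reference.x_coords, reference.y_coords, reference.values
    pts = [(xs[i], ys[j], vals[i, j]) for i, j in np.argwhere(mask)]

    def passes(pt, c: float) -> bool:
        x, y, d = pt
        if mode is IGMode.FIXED_DD:
            dd_abs = fixed_value / 100.0 * norm
            g = gamma_point(x, y, d, ev, dd_abs, c, c if c > 0 else R_EPS)
        elif mode is IGMode.FIXED_DTA:
            dd_abs = c / 100.0 * norm
            g = gamma_point(x, y, d, ev, dd_abs, fixed_value,
                            fixed_value if fixed_value > 0 else R_EPS)
        else:  # FIXED_RATIO: dD = k*c, dd = c
            dd_abs = fixed_value * c / 100.0 * norm
            g = gamma_point(x, y, d, ev, dd_abs, c, c if c > 0 else R_EPS)
        return g <= 1.0

    # one honest gamma test at the cap tells us which points can never pass
    survivors = [pt for pt in pts if passes(pt, cmax)]
    n_hopeless = n - len(survivors)
    n_passed = 0
    trace: list[tuple[float, float]] = []
    for k in range(kmax + 1):
        c = k * step
        if survivors:
            still = []
            for pt in survivors:
                if passes(pt, c):
                    n_passed += 1
                else:
                    still.append(pt)
            survivors = still
        gai_k = 100.0 * n_passed / n
        trace.append((c, gai_k))
        if n_passed >= m:
            return _make_result(
                mode, target_gai_pct, fixed_value, c, gai_k,
                SearchStatus.CONVERGED, len(trace), tuple(trace),
            )
        if not survivors and n_hopeless > 0:
            # remaining steps cannot change the GAI; complete the trace
            trace.extend((kk * step, gai_k) for kk in range(k + 1, kmax + 1))
            break
    gai_cap = 100.0 * n_passed / n
    return _make_result(
        mode, target_gai_pct, fixed_value, cmax, gai_cap,
        SearchStatus.CAP_REACHED, len(trace), tuple(trace),
    )


def _make_result(mode, target, fixed_value, found, achieved, status, n_iter, trace):
    if mode is IGMode.FIXED_DTA:
        return IGResult(
            mode=mode, target_gai_pct=target, fixed_value=fixed_value,
            achieved_gai_pct=achieved, status=status, n_iterations=n_iter,
            found_dd_pct=found, trace=trace,
        )
    found_dd = fixed_value * found if mode is IGMode.FIXED_RATIO else None
    return IGResult(
        mode=mode, target_gai_pct=target, fixed_value=fixed_value,
        achieved_gai_pct=achieved, status=status, n_iterations=n_iter,
        found_dta_mm=found, found_dd_pct=found_dd, trace=trace,
    )
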
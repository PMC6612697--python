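"""Domain types for planar dose distributions and gamma-comparison results.

The package compares two absorbed-dose fields sampled on regular 2D grids:
a *reference* distribution (typically a treatment-planning-system
calculation) and an *evaluated* distribution (typically a detector-array
measurement).  Grid positions refer to element *centres* — the physical
position of element (i, j) is ``origin + (i*dx, j*dy)`` — which matches
detector-array semantics and makes a change of origin a pure spatial
translation.

Dose units are never interpreted: only ratios to the normalization dose
(the global maximum of the reference field) enter the gamma computation,
so any consistent unit (Gy, cGy, relative) is acceptable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

import numpy as np

from .errors import GridValidationError, PairValidationError


@dataclass(frozen=True)
class DoseGrid:
    """A 2D absorbed-dose field on a regular grid.

    Parameters
    ----------
    values
        2D array of doses, shape ``(nx, ny)``; ``values[i, j]`` is the dose
        at physical position ``(origin[0] + i*dx, origin[1] + j*dy)`` mm.
        Must be finite and non-negative.
    spacing
        ``(dx, dy)`` grid pitch in mm, both strictly positive.
    origin
        ``(x0, y0)`` position in mm of the centre of element (0, 0).
    dose_unit
        Free-text unit label; carried through I/O, never interpreted.
    analytic
        Optional closed-form field ``f(x, y) -> dose`` that generated the
        values (set by the synthetic generators); enables exact, sampling-
        free spatial shifts.  Ignored by comparisons and equality.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    dose_unit: str = "Gy"
    analytic: Optional[Callable] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        vals = np.array(self.values, dtype=float, copy=True)
        object.__setattr__(self, "values", vals)
        object.__setattr__(
            self, "spacing", (float(self.spacing[0]), float(self.spacing[1]))
        )
        object.__setattr__(
            self, "origin", (float(self.origin[0]), float(self.origin[1]))
        )
        if vals.ndim != 2 or vals.size == 0:
            raise GridValidationError("dose grid must be a non-empty 2D array")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise GridValidationError("invalid spacing: dx and dy must be > 0")
        if not np.all(np.isfinite(vals)):
            raise GridValidationError("invalid dose value: doses must be finite")
        if np.any(vals < 0):
            raise GridValidationError("invalid dose value: doses must be >= 0")

    # -- geometry -----------------------------------------------------------
    @property
    def nx(self) -> int:
        return self.values.shape[0]

    @property
    def ny(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def dx(self) -> float:
        return self.spacing[0]

    @property
    def dy(self) -> float:
        return self.spacing[1]

    @property
    def x_coords(self) -> np.ndarray:
        """Physical x positions (mm) of the grid columns (element centres)."""
        return self.origin[0] + self.dx * np.arange(self.nx)

    @property
    def y_coords(self) -> np.ndarray:
        return self.origin[1] + self.dy * np.arange(self.ny)

    def position(self, i: int, j: int) -> tuple[float, float]:
        """Physical position (mm) of element (i, j)."""
        return (self.origin[0] + i * self.dx, self.origin[1] + j * self.dy)

    @property
    def bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """((xmin, xmax), (ymin, ymax)) of element centres, in mm."""
        return (
            (self.origin[0], self.origin[0] + (self.nx - 1) * self.dx),
            (self.origin[1], self.origin[1] + (self.ny - 1) * self.dy),
        )

    def with_values(self, values: np.ndarray, analytic=None) -> "DoseGrid":
        """A copy of this grid geometry carrying new dose values."""
        return DoseGrid(values, self.spacing, self.origin, self.dose_unit, analytic)


@dataclass(frozen=True)
class GammaCriteria:
    """Acceptance parameters of a global gamma comparison.

    ``dose_criterion_pct`` (ΔD) is the dose tolerance as percent of the
    normalization dose; ``dta_mm`` (Δd) the distance-to-agreement in mm;
    ``ldt_pct`` the lower dose threshold — reference points below this
    percent of the normalization dose are excluded from analysis.  Points
    pass when γ ≤ ``pass_threshold`` (inclusive), fixed at 1.0.
    """

    dose_criterion_pct: float = 3.0
    dta_mm: float = 2.0
    ldt_pct: float = 5.0
    normalization: str = "global"
    pass_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.dose_criterion_pct <= 0:
            raise GridValidationError("dose criterion must be > 0")
        if self.dta_mm < 0:
            raise GridValidationError("distance-to-agreement must be >= 0")
        if not (0 <= self.ldt_pct < 100):
            raise GridValidationError("lower dose threshold must be in [0, 100)")
        if self.normalization != "global":
            raise GridValidationError("only global normalization is supported")
        if self.pass_threshold != 1.0:
            raise GridValidationError("pass threshold is fixed at 1.0")


@dataclass(frozen=True)
class SearchSettings:
    """Numerical settings of the candidate search and inverse iteration.

    ``dta_step_mm`` / ``dd_step_pct`` are the criterion increments of the
    inverse search (the Δd search advances from 0 in 0.1 mm steps);
    ``max_dta_mm`` / ``max_dd_pct`` cap the search; ``interp_step_mm`` is
    the target spacing for bilinear resampling of the evaluated grid; the
    candidate search is restricted to a disc of radius Δd for standard
    gamma pass/fail (any farther candidate has Γ > 1) and to
    ``gamma_radius_factor``·Δd when full γ values are reported.
    """

    dta_step_mm: float = 0.1
    dd_step_pct: float = 0.1
    max_dta_mm: float = 20.0
    max_dd_pct: float = 20.0
    interp_step_mm: float = 0.2
    gamma_radius_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.dta_step_mm <= 0 or self.dd_step_pct <= 0:
            raise GridValidationError("search steps must be > 0")
        if self.max_dta_mm < self.dta_step_mm or self.max_dd_pct < self.dd_step_pct:
            raise GridValidationError("search caps must be >= their steps")
        if self.interp_step_mm <= 0:
            raise GridValidationError("interpolation step must be > 0")
        if self.gamma_radius_factor < 1:
            raise GridValidationError("gamma radius factor must be >= 1")


class IGMode(str, Enum):
    """Which criterion the inverse search holds fixed."""

    FIXED_DD = "fixed_dd"      # hold ΔD, search Δd
    FIXED_DTA = "fixed_dta"    # hold Δd, search ΔD
    FIXED_RATIO = "fixed_ratio"  # hold ΔD/Δd ratio, search the pair


class SearchStatus(str, Enum):
    CONVERGED = "converged"
    CAP_REACHED = "cap_reached"


class RequirementKind(str, Enum):
    MIN_DTA_MM = "min_dta_mm"
    MIN_DD_PCT = "min_dd_pct"
    MIN_SCALE = "min_scale"


@dataclass(frozen=True)
class GammaResult:
    """Outcome of a global gamma comparison.

    ``gamma`` holds per-reference-point γ values on the reference grid;
    excluded (below-threshold) points carry NaN.  ``censored`` marks points
    whose stored value is a guaranteed lower bound rather than the exact γ
    (the minimizing candidate may lie beyond the search disc; pass/fail is
    unaffected).  ``gai_pct`` is the gamma agreement index: the percentage
    of included points with γ ≤ 1.0 (inclusive).
    """

    gamma: np.ndarray
    included_mask: np.ndarray
    gai_pct: float
    n_included: int
    n_passed: int
    criteria: GammaCriteria
    norm_dose: float
    censored: Optional[np.ndarray] = None

    @property
    def pass_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            ok = self.included_mask & (self.gamma <= self.criteria.pass_threshold)
        if self.censored is not None:
            ok &= ~self.censored  # a censored value is a lower bound >= 1
        return ok


@dataclass(frozen=True)
class RequirementMap:
    """Per-reference-point minimum criterion needed for that point to pass.

    ``values`` is on the reference grid: NaN marks points excluded by the
    lower dose threshold, +inf marks included points for which no candidate
    can satisfy the condition within the search cap (unreachable).  The two
    sentinels are deliberately distinct.
    """

    kind: RequirementKind
    values: np.ndarray
    included_mask: np.ndarray
    fixed_value: float
    norm_dose: float

    @property
    def included_values(self) -> np.ndarray:
        return self.values[self.included_mask]

    @property
    def n_included(self) -> int:
        return int(self.included_mask.sum())

    @property
    def n_unreachable(self) -> int:
        return int(np.isinf(self.included_values).sum())


@dataclass(frozen=True)
class IGResult:
    """Outcome of an inverse-gamma criteria search.

    ``trace`` lists the (criterion value, GAI %) pairs the iteration
    visited, in order.  ``status`` is ``converged`` when the target GAI was
    reached, else ``cap_reached`` with the cap's GAI in
    ``achieved_gai_pct``.
    """

    mode: IGMode
    target_gai_pct: float
    fixed_value: float
    achieved_gai_pct: float
    status: SearchStatus
    n_iterations: int
    found_dta_mm: Optional[float] = None
    found_dd_pct: Optional[float] = None
    trace: tuple = ()

    @property
    def converged(self) -> bool:
        return self.status is SearchStatus.CONVERGED

    @property
    def found_value(self) -> float:
        """The free criterion's final value (Δd in mm, or ΔD in % for fixed_dta)."""
        if self.mode is IGMode.FIXED_DTA:
            return self.found_dd_pct
        return self.found_dta_mm


def validate_pair(
    reference: DoseGrid,
    evaluated: DoseGrid,
    *,
    ldt_pct: float | None = None,
    norm_dose: float | None = None,
    margin_mm: float = 0.0,
) -> tuple[DoseGrid, DoseGrid]:
    """Check that two grids can be meaningfully compared.

    Every reference point that survives the lower dose threshold (all
    points when ``ldt_pct`` is None) must lie inside the evaluated grid's
    bounding box expanded by ``margin_mm``.  Returns the pair unchanged or
    raises :class:`PairValidationError`.
    """
    for name, grid in (("reference", reference), ("evaluated", evaluated)):
        if not np.all(np.isfinite(grid.values)):
            raise PairValidationError(f"invalid dose value in {name} grid")

    (rx0, rx1), (ry0, ry1) = reference.bounds
    (ex0, ex1), (ey0, ey1) = evaluated.bounds
    if rx1 < ex0 - margin_mm or rx0 > ex1 + margin_mm or \
            ry1 < ey0 - margin_mm or ry0 > ey1 + margin_mm:
        raise PairValidationError("no spatial overlap between reference and evaluated grids")

    if ldt_pct is not None:
        if norm_dose is None:
            norm_dose = float(reference.values.max())
        mask = reference.values >= (ldt_pct / 100.0) * norm_dose
    else:
        mask = np.ones(reference.shape, dtype=bool)

    xs = reference.x_coords[:, None] + np.zeros((1, reference.ny))
    ys = np.zeros((reference.nx, 1)) + reference.y_coords[None, :]
    inside = (
        (xs >= ex0 - margin_mm) & (xs <= ex1 + margin_mm)
        & (ys >= ey0 - margin_mm) & (ys <= ey1 + margin_mm)
    )
    n_outside = int((mask & ~inside).sum())
    if n_outside:
        raise PairValidationError(
            f"no spatial overlap for {n_outside} analysed reference point(s) "
            f"(outside the evaluated grid extent; margin {margin_mm} mm)"
        )
    return reference, evaluated
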
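"""Synthetic dose-field pairs with known ground truth.

Clinical PSQA comparisons (planning-system dose vs detector-array
measurement) are proprietary, so tests and examples work on synthetic
fields that reproduce their salient features: square/rectangular plateaus
with an erf-shaped penumbra a few mm wide, rigid spatial shifts, uniform
dose scalings, Gaussian dose noise and isolated corrupted pixels.

Shifts are applied *analytically* — the field's closed form is re-sampled
at displaced positions — never by interpolating the discrete grid, so a
shifted pair is exact ground truth for distance-to-agreement recovery:
the acceptance tolerance of the inverse search is then attributable to
the engine alone.  Every generator is deterministic given its parameters
and seed.
"""
from __future__ import annotations

import numpy as np
from scipy.special import erf

from .errors import GridValidationError
from .model import DoseGrid


def _edge_profile(x: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """Unit plateau of width 2·half_width rolled off by an erf penumbra.

    The profile is the convolution of a top-hat with a Gaussian of scale
    ``sigma``: it equals 0.5·plateau at the field edge and reaches the
    plateau (within 1%) at the centre once the width exceeds ~10·sigma.
    """
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((x + half_width) / s) - erf((x - half_width) / s))


def square_field(
    extent_mm: float = 90.0,
    spacing_mm: float = 1.0,
    field_width_mm: float = 60.0,
    penumbra_sigma_mm: float = 3.0,
    max_dose: float = 2.0,
) -> DoseGrid:
    """Separable square field D(x, y) = max_dose · P(x) · P(y), centred at 0.

    ``extent_mm`` is the full grid extent per axis (grid spans ±extent/2),
    ``field_width_mm`` the nominal field size (50% dose at ±width/2) and
    ``penumbra_sigma_mm`` the Gaussian penumbra scale (80%–20% falloff over
    roughly 1.7·sigma).  Defaults emulate a 60 mm field measured on a 1 mm
    export grid with a realistic ~3 mm penumbra; ``max_dose`` of 2 Gy is a
    typical per-fraction plateau dose.
    """
    if field_width_mm >= extent_mm:
        raise GridValidationError("field width must be smaller than the grid extent")
    if penumbra_sigma_mm <= 0:
        raise GridValidationError("penumbra sigma must be > 0")
    if extent_mm <= 0 or spacing_mm <= 0:
        raise GridValidationError("degenerate extent or spacing")
    n = int(round(extent_mm / spacing_mm)) + 1
    half = (n - 1) * spacing_mm / 2.0
    hw = field_width_mm / 2.0

    def analytic(x, y):
        return max_dose * _edge_profile(np.asarray(x), hw, penumbra_sigma_mm) * \
            _edge_profile(np.asarray(y), hw, penumbra_sigma_mm)

    coords = -half + spacing_mm * np.arange(n)
    vals = analytic(coords[:, None], coords[None, :])
    return DoseGrid(vals, (spacing_mm, spacing_mm), (-half, -half), "Gy", analytic)


def shift_field(grid: DoseGrid, dx_mm: float, dy_mm: float) -> DoseGrid:
    """Rigidly shift an analytic field by (dx, dy) mm; grid geometry unchanged.

    The dose at position p becomes the original dose at p − shift, sampled
    from the generator's closed form (no resampling error).  Requires a
    grid produced by a generator in this module.
    """
    f = grid.analytic
    if f is None:
        raise GridValidationError(
            "shift_field requires an analytic grid from a synthetic generator"
        )

    def shifted(x, y, _f=f, _dx=dx_mm, _dy=dy_mm):
        return _f(np.asarray(x) - _dx, np.asarray(y) - _dy)

    x = grid.x_coords
    y = grid.y_coords
    vals = shifted(x[:, None], y[None, :])
    return grid.with_values(vals, analytic=shifted)


def scale_dose(grid: DoseGrid, factor: float) -> DoseGrid:
    """Uniform multiplicative dose scaling (e.g. an output calibration error)."""
    if factor <= 0:
        raise GridValidationError("scale factor must be > 0")
    f = grid.analytic
    scaled = None
    if f is not None:
        def scaled(x, y, _f=f, _c=factor):  # noqa: E731 - closure, keeps analytic chain
            return _c * _f(x, y)
    return grid.with_values(grid.values * factor, analytic=scaled)


def add_noise(grid: DoseGrid, sigma_pct_of_max: float, seed: int) -> DoseGrid:
    """Additive Gaussian dose noise, sigma expressed as percent of max dose.

    Expressing the amplitude relative to the maximum aligns it with the
    globally-normalized dose criterion.  Doses are floored at 0.  The
    analytic form is dropped (noise has none).
    """
    if sigma_pct_of_max < 0:
        raise GridValidationError("noise sigma must be >= 0")
    if sigma_pct_of_max == 0:
        return grid.with_values(grid.values, analytic=grid.analytic)
    rng = np.random.default_rng(seed)
    sigma = sigma_pct_of_max / 100.0 * float(grid.values.max())
    vals = np.clip(grid.values + rng.normal(0.0, sigma, grid.shape), 0.0, None)
    return grid.with_values(vals)


def corrupt_pixel(grid: DoseGrid, i: int, j: int, delta_pct: float) -> DoseGrid:
    """Corrupt a single element by delta_pct of the max dose (dead/noisy pixel)."""
    if not (0 <= i < grid.nx and 0 <= j < grid.ny):
        raise GridValidationError("pixel index out of range")
    vals = grid.values.copy()
    vals[i, j] = max(vals[i, j] + delta_pct / 100.0 * float(grid.values.max()), 0.0)
    return grid.with_values(vals)
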
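"""Continuous yield-response surfaces from factorial anchors.

Six potential-yield anchors per cell and crop — fertiliser at 0/200/1000
kgN/ha, each rain-fed or fully irrigated — are turned into a smooth surface

    y(F, x, m, t) = c * g(m) * [ y_rf(F) + (y_irr(F) - y_rf(F)) * w(x) ]
                      * (1 + tech_rate)^(t - base_year)

where each water regime's fertiliser response is a saturating exponential
``y(F) = y0 + (y_inf - y0) (1 - exp(-k_F F))`` solved exactly through its
three anchors, ``w`` is a concave irrigation blend with w(0)=0, w(1)=1,
``g`` a concave management multiplier with g(1)=1 and floor g(0)=g0, ``c``
the calibration factor to observed yields, and the technology term an
exogenous annual yield increment (default 0.2 %/yr).

Diminishing returns hold along every axis; at the anchor inputs (m=1,
base year) the surface reproduces the anchors exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .commodities import FERT_LEVELS
from .grid import YieldAnchorSet

#: Default shape parameters (the anchor data do not constrain these).
DEFAULT_K_I = 2.0  # irrigation blend curvature
DEFAULT_G0 = 0.5  # yield multiplier at zero management
DEFAULT_K_M = 2.0  # management curvature
DEFAULT_TECH_RATE = 0.002  # 0.2 %/yr exogenous technology increment
BASE_YEAR = 2010

_F1, _F2 = FERT_LEVELS[1], FERT_LEVELS[2]
#: Anchor ratio below which the response is no longer concave-exponential.
_LINEAR_RATIO = _F1 / _F2


class AnchorFitError(ValueError):
    """Anchors violate the monotonicity the fit requires."""


def _ratio(k: float) -> float:
    return -np.expm1(-_F1 * k) / -np.expm1(-_F2 * k)


def solve_k(y0: float, y200: float, y1000: float) -> float:
    """Response rate k_F such that the exponential passes through all three
    anchors; 0 for a flat response."""
    dy = y1000 - y0
    if dy <= 1e-9:
        return 0.0
    r = (y200 - y0) / dy
    if r >= 1.0:
        r = 1.0 - 1e-12
    if r <= _LINEAR_RATIO + 1e-12:
        # sub-exponential (quasi-linear/convex) anchors: no exact concave
        # exponential exists; use a near-linear curve.
        warnings.warn("anchor response is not concave-exponential; using near-linear fit")
        return 1e-6
    return brentq(lambda k: _ratio(k) - r, 1e-9, 1.0, xtol=1e-15, rtol=8.9e-16)


@dataclass
class RegimeCurve:
    """Fertiliser response within one water regime."""

    y0: float
    y_inf: float
    k_F: float

    def __call__(self, F):
        F = np.asarray(F, dtype=float)
        if self.k_F == 0.0:
            return np.broadcast_to(self.y0, F.shape).copy() if F.ndim else float(self.y0)
        return self.y0 + (self.y_inf - self.y0) * -np.expm1(-self.k_F * F)


@dataclass
class YieldSurface:
    """Fitted yield surface for one cell (or cluster) and crop."""

    rainfed: RegimeCurve
    irrigated: RegimeCurve
    irrigation_requirement: float = 0.0  # km3/ha/yr at full irrigation
    k_I: float = DEFAULT_K_I
    g0: float = DEFAULT_G0
    k_M: float = DEFAULT_K_M
    calibration_factor: float = 1.0
    tech_rate: float = DEFAULT_TECH_RATE
    base_year: int = BASE_YEAR

    def management_multiplier(self, m):
        m = np.asarray(m, dtype=float)
        return self.g0 + (1 - self.g0) * -np.expm1(-self.k_M * m) / -np.expm1(-self.k_M)

    def irrigation_blend(self, x):
        x = np.asarray(x, dtype=float)
        return -np.expm1(-self.k_I * x) / -np.expm1(-self.k_I)


def fit_curve(y0: float, y200: float, y1000: float, where: str = "") -> RegimeCurve:
    """Exact saturating-exponential fit through three fertiliser anchors."""
    if y200 < y0 - 1e-9 or y1000 < y0 - 1e-9:
        raise AnchorFitError(f"anchors decrease with fertiliser {where}".strip())
    if y200 > y1000 + 1e-9:
        warnings.warn(f"mid anchor above high anchor {where}; clamping".strip())
        y200 = y1000
    y200 = min(y200, y1000)
    k = solve_k(y0, y200, y1000)
    if k == 0.0:
        return RegimeCurve(y0=y0, y_inf=y0, k_F=0.0)
    y_inf = y0 + (y1000 - y0) / -np.expm1(-_F2 * k)
    return RegimeCurve(y0=y0, y_inf=y_inf, k_F=k)


def fit_surface(
    anchors: YieldAnchorSet,
    cell: int,
    crop: int | str,
    *,
    calibration_factor: float = 1.0,
    tech_rate: float = DEFAULT_TECH_RATE,
    k_I: float = DEFAULT_K_I,
    g0: float = DEFAULT_G0,
    k_M: float = DEFAULT_K_M,
    base_year: int = BASE_YEAR,
) -> YieldSurface:
    """Fit the full surface for one cell x land-use from its six anchors."""
    if isinstance(crop, str):
        crop = anchors.land_uses.index(crop)
    y = anchors.yields[cell, crop]
    if (y[:, 1] - y[:, 0] < -1e-9).any():
        raise AnchorFitError(f"irrigated anchor below rain-fed at cell {cell}, land use {crop}")
    where = f"(cell {cell}, land use {crop})"
    return YieldSurface(
        rainfed=fit_curve(*y[:, 0], where=where),
        irrigated=fit_curve(*y[:, 1], where=where),
        irrigation_requirement=float(anchors.irrigation_requirement[cell, crop]),
        k_I=k_I,
        g0=g0,
        k_M=k_M,
        calibration_factor=calibration_factor,
        tech_rate=tech_rate,
        base_year=base_year,
    )


def evaluate_yield(surface: YieldSurface, F, irr_frac, m, year):
    """Yield (t/ha) at fertiliser rate F (kgN/ha), irrigation fraction,
    management intensity and calendar year."""
    F = np.asarray(F, dtype=float)
    irr_frac = np.asarray(irr_frac, dtype=float)
    m = np.asarray(m, dtype=float)
    if (F < 0).any() or (irr_frac < 0).any() or (irr_frac > 1 + 1e-12).any():
        raise ValueError("F must be >= 0 and irr_frac in [0, 1]")
    if (m < 0).any() or (m > 1 + 1e-12).any():
        raise ValueError("management intensity must be in [0, 1]")
    y_rf = surface.rainfed(F)
    y_irr = surface.irrigated(F)
    blend = y_rf + (y_irr - y_rf) * surface.irrigation_blend(irr_frac)
    tech = (1.0 + surface.tech_rate) ** (year - surface.base_year)
    out = surface.calibration_factor * surface.management_multiplier(m) * blend * tech
    return np.maximum(out, 0.0)


def calibrate_factor(simulated, observed, weights=None) -> float:
    """Slope-only (through-origin) regression of observed on simulated yields.

    Returns ``c = sum(w s o) / sum(w s^2)``, the weighted least-squares slope
    with intercept fixed at zero; weights default to 1.
    """
    s = np.asarray(simulated, dtype=float)
    o = np.asarray(observed, dtype=float)
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    denom = float((w * s * s).sum())
    if denom <= 0:
        raise ValueError("all simulated yields are zero; calibration slope undefined")
    return float((w * s * o).sum() / denom)


# ---------------------------------------------------------------------------
# Vectorised surfaces over clusters x land uses, used by the optimiser.
# ---------------------------------------------------------------------------


@dataclass
class SurfaceArray:
    """Surfaces for a (clusters x land-uses) block, evaluated vectorised.

    All parameter arrays share the shape (n_clusters, n_land_uses).
    """

    y0_rf: np.ndarray
    dy_rf: np.ndarray  # y_inf - y0
    k_rf: np.ndarray
    y0_irr: np.ndarray
    dy_irr: np.ndarray
    k_irr: np.ndarray
    irrigation_requirement: np.ndarray  # km3/ha/yr
    calibration_factor: np.ndarray  # per land use, broadcastable
    k_I: float = DEFAULT_K_I
    g0: float = DEFAULT_G0
    k_M: float = DEFAULT_K_M
    tech_rate: float = DEFAULT_TECH_RATE
    base_year: int = BASE_YEAR

    @classmethod
    def from_anchor_block(
        cls,
        anchor_block: np.ndarray,
        irrigation_requirement: np.ndarray,
        calibration_factor=1.0,
        **params,
    ) -> "SurfaceArray":
        """Fit from an anchor block of shape (n, n_lu, 3, 2)."""
        n, n_lu = anchor_block.shape[:2]
        shp = (n, n_lu)
        arrs = {
            k: np.empty(shp)
            for k in ("y0_rf", "dy_rf", "k_rf", "y0_irr", "dy_irr", "k_irr")
        }
        for i in range(n):
            for j in range(n_lu):
                for reg, suffix in ((0, "rf"), (1, "irr")):
                    cur = fit_curve(*anchor_block[i, j, :, reg], where=f"(cluster {i}, lu {j})")
                    arrs[f"y0_{suffix}"][i, j] = cur.y0
                    arrs[f"dy_{suffix}"][i, j] = cur.y_inf - cur.y0
                    arrs[f"k_{suffix}"][i, j] = cur.k_F
        return cls(
            irrigation_requirement=np.asarray(irrigation_requirement, dtype=float),
            calibration_factor=np.broadcast_to(
                np.asarray(calibration_factor, dtype=float), (n_lu,)
            ).copy(),
            **arrs,
            **params,
        )

    def evaluate(self, F, irr_frac, m, year):
        y_rf = self.y0_rf + self.dy_rf * -np.expm1(-self.k_rf * F)
        y_irr = self.y0_irr + self.dy_irr * -np.expm1(-self.k_irr * F)
        w = -np.expm1(-self.k_I * irr_frac) / -np.expm1(-self.k_I)
        g = self.g0 + (1 - self.g0) * -np.expm1(-self.k_M * m) / -np.expm1(-self.k_M)
        tech = (1.0 + self.tech_rate) ** (year - self.base_year)
        return self.calibration_factor * g * (y_rf + (y_irr - y_rf) * w) * tech


def plot_surface(surface: YieldSurface, year: int | None = None, ax=None):
    """Response-surface plot: yield vs fertiliser at several irrigation
    fractions, at maximum management."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    year = surface.base_year if year is None else year
    F = np.linspace(0, FERT_LEVELS[-1], 200)
    for x in (0.0, 0.25, 0.5, 0.75, 1.0):
        ax.plot(F, evaluate_yield(surface, F, x, 1.0, year), label=f"irr={x:.2f}")
    ax.set_xlabel("fertiliser (kgN/ha)")
    ax.set_ylabel("yield (t/ha)")
    ax.legend()
    return ax
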
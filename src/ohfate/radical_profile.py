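"""Hydroxyl-radical dosimetry from measured hydrogen peroxide.

During anodic water electrolysis, •OH radicals recombine to H2O2 and the two
species sit in a fast equilibrium, so the (hard to measure) transient radical
level is proportional to the (easy to measure) peroxide level.  The measured,
normalised H2O2 series is smoothed with a low-order polynomial f(t); the
normalised radical profile is then

    OH*(t) = k * f(t)_+        (clamped at zero)

where the proportionality factor k lumps the equilibrium constants and the
electrode's radical yield.  k itself scales linearly with the applied current
density j, which is what lets a single calibration generalise across
operating currents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from .errors import ContractViolation, DomainError, EstimationError

__all__ = [
    "H2O2Poly",
    "OhProfile",
    "CurrentDensityLaw",
    "PRINTED_CURRENT_LAW",
    "fit_h2o2_polynomial",
    "oh_star",
    "oh_exposure",
    "k_of_j",
    "fit_current_law",
]


@dataclass(frozen=True)
class H2O2Poly:
    """Polynomial model of normalised H2O2 versus time.

    ``coefficients`` are ordered low-to-high: B0 (dimensionless), B1 (1/s),
    B2 (1/s^2), ...  Evaluation is clamped at zero (a concentration cannot be
    negative) and restricted to ``valid_domain`` — extrapolating a cubic fit
    outside the measured window is never meaningful.
    """

    coefficients: tuple[float, ...]
    valid_domain: tuple[float, float]
    fit_r2: float | None = None

    def __post_init__(self):
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        lo, hi = self.valid_domain
        if not (lo < hi):
            raise ContractViolation("valid_domain must be a non-empty interval")
        object.__setattr__(self, "valid_domain", (float(lo), float(hi)))

    def _check_domain(self, t: np.ndarray) -> None:
        lo, hi = self.valid_domain
        # small slack for floating grid endpoints
        tol = 1e-9 * max(1.0, hi - lo)
        if np.any(t < lo - tol) or np.any(t > hi + tol):
            raise DomainError(
                f"time outside polynomial validity domain [{lo}, {hi}] s"
            )

    def raw(self, t):
        """Unclamped polynomial value (still domain-checked)."""
        arr = np.asarray(t, dtype=float)
        self._check_domain(arr)
        return npoly.polyval(arr, np.asarray(self.coefficients))

    def __call__(self, t):
        """Clamped evaluation max(f(t), 0)."""
        return np.maximum(self.raw(t), 0.0)


@dataclass(frozen=True)
class OhProfile:
    """Normalised •OH profile: OH*(t) = k_prop * f(t)_+.

    ``reference_conc`` (C0, mol/L) converts the normalised level to absolute
    molarity: [OH](t) = C0 * OH*(t).
    """

    poly: H2O2Poly
    k_prop: float
    reference_conc: float

    def __post_init__(self):
        if not self.k_prop > 0:
            raise ContractViolation("proportionality factor k must be > 0")
        if not self.reference_conc > 0:
            raise ContractViolation("reference concentration C0 must be > 0")

    def oh_star(self, t):
        return self.k_prop * self.poly(t)

    def oh_molar(self, t):
        return self.reference_conc * self.oh_star(t)


def oh_star(profile: OhProfile, t):
    """Normalised radical level at time ``t`` (s)."""
    return profile.oh_star(t)


def _positive_breakpoints(poly: H2O2Poly, t0: float, t1: float) -> list[float]:
    """Sorted breakpoints partitioning [t0, t1] at real roots of the polynomial."""
    coeffs = np.trim_zeros(np.asarray(poly.coefficients, float), "b")
    pts = {t0, t1}
    if coeffs.size > 1:
        roots = npoly.polyroots(coeffs)
        for r in roots:
            if abs(r.imag) < 1e-9 * max(1.0, abs(r.real)) and t0 < r.real < t1:
                pts.add(float(r.real))
    return sorted(pts)


def oh_exposure(profile: OhProfile, t0: float, t1: float) -> float:
    """Radical exposure u = C0 * k * INT_{t0}^{t1} f(t)_+ dt, in M*s.

    The integral of the clamped polynomial is evaluated in closed form,
    piecewise between the polynomial's real roots, so the exposure is exact
    (no quadrature) and exactly additive over adjacent intervals.
    """
    if t0 > t1:
        raise ContractViolation("require t0 <= t1")
    profile.poly._check_domain(np.asarray([t0, t1], dtype=float))
    anti = npoly.polyint(np.asarray(profile.poly.coefficients, float))
    total = 0.0
    pts = _positive_breakpoints(profile.poly, float(t0), float(t1))
    for a, b in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (a + b)
        if npoly.polyval(mid, np.asarray(profile.poly.coefficients)) > 0.0:
            total += npoly.polyval(b, anti) - npoly.polyval(a, anti)
    return profile.reference_conc * profile.k_prop * total


def fit_h2o2_polynomial(times: Sequence[float], values: Sequence[float],
                        order: int = 3) -> H2O2Poly:
    """Ordinary least-squares polynomial fit of a normalised H2O2 series.

    Times are rescaled to [0, 1] internally before building the Vandermonde
    system; with measurement windows of ~1e4 s a raw-time design matrix is
    catastrophically ill-conditioned for a cubic.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if order < 0:
        raise ContractViolation("polynomial order must be >= 0")
    if t.size != y.size or t.size < order + 2:
        raise ContractViolation(
            f"need at least order+2 = {order + 2} points; got {t.size}"
        )
    if np.any(t < 0):
        raise ContractViolation("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise EstimationError("times must be strictly increasing (duplicates?)")
    t_max = t[-1]
    scaled = t / t_max
    design = np.vander(scaled, order + 1, increasing=True)
    coef_scaled, residuals, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < order + 1:
        raise EstimationError("rank-deficient polynomial design matrix")
    coeffs = coef_scaled / t_max ** np.arange(order + 1)
    pred = design @ coef_scaled
    rss = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if rss <= 1e-28 else (1.0 - rss / tss if tss > 0 else 1.0)
    return H2O2Poly(tuple(coeffs), (0.0, float(t_max)), fit_r2=r2)


# ---------------------------------------------------------------------------
# Current-density scaling of the proportionality factor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurrentDensityLaw:
    """Linear map from current density j (mA/cm^2) to the factor k.

    k(j) = slope * j + intercept, with slope in cm^2/mA (acting on the
    dimensionless k) and a dimensionless intercept.
    """

    slope: float
    intercept: float
    fit_r2: float | None = None

    def __call__(self, j: float) -> float:
        return k_of_j(self, j)


def k_of_j(law: CurrentDensityLaw, j: float) -> float:
    """Proportionality factor at current density ``j`` (mA/cm^2).

    j = 0 is allowed and reads out the intercept (zero-current baseline).
    """
    if j < 0:
        raise ContractViolation("current density must be >= 0")
    k = law.slope * j + law.intercept
    if not k > 0:
        raise ContractViolation(f"law yields non-positive k at j={j}")
    return k


#: Calibration of the SnO2-MWCNT@SS anode: k(j) = 6.48e-12 cm^2/mA * j + 8.55e-12.
PRINTED_CURRENT_LAW = CurrentDensityLaw(slope=6.48e-12, intercept=8.55e-12,
                                        fit_r2=0.989)


def fit_current_law(pairs: Sequence[tuple[float, float]]) -> CurrentDensityLaw:
    """Least-squares straight line through (j, k) calibration points."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ContractViolation("need >= 2 (j, k) pairs")
    j, k = arr[:, 0], arr[:, 1]
    if np.ptp(j) == 0:
        raise EstimationError("all current densities identical; line undefined")
    slope, intercept = np.polyfit(j, k, 1)
    pred = slope * j + intercept
    rss = float(np.sum((k - pred) ** 2))
    tss = float(np.sum((k - k.mean()) ** 2))
    r2 = 1.0 if rss <= 1e-28 else (1.0 - rss / tss if tss > 0 else 1.0)
    return CurrentDensityLaw(float(slope), float(intercept), fit_r2=r2)
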
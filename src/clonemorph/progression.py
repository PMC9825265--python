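"""Per-clone density-dependent trends and growth variables.

A clone's morphological progression is the trajectory of its shape and
network properties as a function of confluency over one subculture cycle.
Each property is summarized by a low-order polynomial fit against
confluency (density — not time — is the independent variable), and the fits
are distilled into a fixed-length *growth-variable vector*: each property
evaluated at low / mid / high confluency anchors (suffixes ``_l``, ``_m``,
``_h``; defaults 0.15 / 0.40 / 0.70). These vectors feed clustering and
correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_ANCHORS = (0.15, 0.40, 0.70)
ANCHOR_SUFFIXES = ("l", "m", "h")


@dataclass
class PolynomialFit:
    """Least-squares polynomial fit of one property against confluency.

    ``coefficients`` are in ascending order: value(d) = Σ c_k d^k.
    ``residual_variance`` is the unbiased residual variance (SSR / (n − p));
    0 in the exact-interpolation regime.
    """

    coefficients: np.ndarray
    residual_variance: float
    degree: int
    n_points: int
    confluency_range: tuple[float, float]

    def __call__(self, d) -> np.ndarray | float:
        out = np.polynomial.polynomial.polyval(np.asarray(d, dtype=float), self.coefficients)
        return float(out) if np.isscalar(d) else out


@dataclass
class CloneProgression:
    """Ordered snapshots of one clone vs density, with per-property fits."""

    clone_id: str
    points: list[dict[str, float]]  # each has 'confluency' + property values
    fits: dict[str, PolynomialFit] = field(default_factory=dict)

    @property
    def n_images(self) -> int:
        return len(self.points)

    def fit_all(self, degree: int = 2) -> "CloneProgression":
        """Fit every property with ≥ degree+1 points; skip the rest."""
        if not self.points:
            return self
        props = [k for k in self.points[0] if k != "confluency"]
        conf = np.array([p["confluency"] for p in self.points], dtype=float)
        for prop in props:
            vals = np.array([p.get(prop, np.nan) for p in self.points], dtype=float)
            ok = ~np.isnan(vals)
            if np.unique(conf[ok]).size >= degree + 1:
                self.fits[prop] = fit_progression(list(zip(conf[ok], vals[ok])), degree=degree)
        return self


@dataclass
class GrowthVariableVector:
    """Anchor-evaluated growth variables of one clone.

    ``values`` maps ``<property>_<l|m|h>`` to the fitted polynomial
    evaluated at the corresponding anchor; names are emitted in a fixed
    sorted order so vectors are comparable across clones. ``extrapolated``
    flags anchors outside the observed confluency range; ``missing`` lists
    properties without a fit.
    """

    clone_id: str
    values: dict[str, float]
    extrapolated: set[str] = field(default_factory=set)
    missing: set[str] = field(default_factory=set)

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else sorted(self.values)
        return np.array([self.values.get(n, np.nan) for n in names], dtype=float)


def fit_progression(points: list[tuple[float, float]], degree: int = 2) -> PolynomialFit:
    """Least-squares polynomial of ``value`` against ``confluency``.

    Requires at least degree+1 distinct confluency values. Residual
    variance is SSR/(n − (degree+1)), or 0 when the system is exactly
    determined.
    """
    if degree < 0:
        raise ValueError("degree must be non-negative")
    pts = [(float(c), float(v)) for c, v in points]
    conf = np.array([c for c, _ in pts])
    vals = np.array([v for _, v in pts])
    if np.unique(conf).size < degree + 1:
        raise ValueError(
            f"need >= {degree + 1} distinct confluency values, got {np.unique(conf).size}")
    # ascending-order coefficients via the numpy polynomial API
    coeffs = np.polynomial.polynomial.polyfit(conf, vals, degree)
    residuals = vals - np.polynomial.polynomial.polyval(conf, coeffs)
    dof = len(pts) - (degree + 1)
    resid_var = float(residuals @ residuals / dof) if dof > 0 else 0.0
    return PolynomialFit(
        coefficients=coeffs,
        residual_variance=resid_var,
        degree=degree,
        n_points=len(pts),
        confluency_range=(float(conf.min()), float(conf.max())),
    )


def growth_variables(prog: CloneProgression,
                     anchors: tuple[float, ...] = DEFAULT_ANCHORS) -> GrowthVariableVector:
    """Evaluate every fitted property at the confluency anchors.

    Anchors outside a property's observed confluency range are still
    evaluated but flagged as extrapolated; properties without fits yield
    missing entries (NaN) and are flagged.
    """
    if len(anchors) != len(ANCHOR_SUFFIXES):
        raise ValueError(f"expected {len(ANCHOR_SUFFIXES)} anchors, got {len(anchors)}")
    props = sorted({k for p in prog.points for k in p if k != "confluency"})
    values: dict[str, float] = {}
    extrapolated: set[str] = set()
    missing: set[str] = set()
    for prop in props:
        fit = prog.fits.get(prop)
        for anchor, suffix in zip(anchors, ANCHOR_SUFFIXES):
            name = f"{prop}_{suffix}"
            if fit is None:
                values[name] = float("nan")
                missing.add(name)
                continue
            values[name] = fit(anchor)
            lo, hi = fit.confluency_range
            if not (lo <= anchor <= hi):
                extrapolated.add(name)
    return GrowthVariableVector(clone_id=prog.clone_id, values=values,
                                extrapolated=extrapolated, missing=missing)
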
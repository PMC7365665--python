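"""Autoradiograph densitometry: calibration, density conversion, areal means.

Receptor autoradiographs are exposed together with plastic standards of known
radioactivity.  The standards define a monotone transformation from film gray
value to tissue radioactivity ("linearized" autoradiographs); with the ligand
parameters of the binding assay the radioactivity converts to a binding-site
density in fmol/mg protein:

    density = C(gray) / (specific activity x protein factor) x (K_D + L) / L

where L is the free ligand concentration and (K_D + L)/L corrects for partial
receptor saturation at the incubation concentration.  The exact units of the
standard activities and the protein conversion constant are assay metadata and
enter as configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "LigandConfig",
    "fit_calibration",
    "gray_to_density",
    "mean_area_density",
    "pseudocolor_export",
]

#: relative isotonic-cleanup residual above which standards are rejected
ISOTONIC_RESIDUAL_TOL = 0.05


@dataclass
class LigandConfig:
    """Binding-assay parameters of one receptor/ligand pair."""

    receptor: str
    L_nM: float                  # free ligand concentration during incubation
    K_D_nM: float                # equilibrium dissociation constant
    specific_activity: float = 1.0
    protein_factor: float = 1.0

    def __post_init__(self):
        if self.L_nM <= 0 or self.K_D_nM <= 0:
            raise ValueError("ligand concentration and K_D must be positive")
        if self.specific_activity <= 0 or self.protein_factor <= 0:
            raise ValueError("specific activity and protein factor must be positive")

    @property
    def saturation_correction(self) -> float:
        return (self.K_D_nM + self.L_nM) / self.L_nM


@dataclass
class CalibrationCurve:
    """Monotone piecewise-linear gray-value -> radioactivity mapping."""

    gray: np.ndarray             # strictly increasing knot gray values
    concentration: np.ndarray    # strictly monotone knot concentrations
    clamped: bool = False        # set when an evaluation fell outside the range

    def __post_init__(self):
        g = np.asarray(self.gray, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        if g.size != c.size or g.size < 2:
            raise ValueError("calibration curve needs >= 2 matched knots")
        if np.any(np.diff(g) <= 0):
            raise ValueError("gray knots must be strictly increasing")
        d = np.diff(c)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("concentration must be strictly monotone over the gray range")
        self.gray, self.concentration = g, c

    @property
    def gray_range(self) -> tuple[float, float]:
        return float(self.gray[0]), float(self.gray[-1])

    def __call__(self, gray_values) -> np.ndarray:
        """Concentration at the given gray values; clamped to the end knots."""
        g = np.asarray(gray_values, dtype=float)
        if np.any(g < self.gray[0]) or np.any(g > self.gray[-1]):
            self.clamped = True
            warnings.warn("gray values outside the calibrated range were clamped")
        return np.interp(np.clip(g, self.gray[0], self.gray[-1]),
                         self.gray, self.concentration)

    def concentration_to_gray(self, conc) -> np.ndarray:
        """Inverse evaluation (used by round-trip checks)."""
        order = np.argsort(self.concentration)
        return np.interp(np.asarray(conc, dtype=float),
                         self.concentration[order], self.gray[order])


def fit_calibration(standards) -> CalibrationCurve:
    """Fit the transformation curve through co-exposed standards.

    ``standards`` is a sequence of (concentration, gray) pairs or a DataFrame
    with those columns.  Knots are sorted by gray value; small departures from
    monotonicity are repaired by isotonic pooling (pool-adjacent-violators),
    but a relative residual above ``ISOTONIC_RESIDUAL_TOL`` rejects the
    standards as unusable.  Evaluation beyond the end knots clamps.
    """
    if isinstance(standards, pd.DataFrame):
        pairs = standards[["concentration", "gray"]].to_numpy(dtype=float)
    else:
        pairs = np.asarray(list(standards), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (concentration, gray) standards")
    conc, gray = pairs[:, 0], pairs[:, 1]
    if np.unique(gray).size != gray.size:
        raise ValueError("duplicated gray value among standards")
    order = np.argsort(gray)
    gray, conc = gray[order], conc[order]
    increasing = conc[-1] >= conc[0]
    fitted = _pava(conc if increasing else -conc)
    fitted = fitted if increasing else -fitted
    scale = max(np.abs(conc).max(), 1e-12)
    residual = float(np.max(np.abs(fitted - conc))) / scale
    if residual > ISOTONIC_RESIDUAL_TOL:
        raise ValueError(
            f"standards are severely non-monotone (isotonic residual {residual:.3f})")
    # pooling can create ties; nudge them apart infinitesimally to stay strict
    fitted = _break_ties(fitted, increasing)
    return CalibrationCurve(gray, fitted)


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for a nondecreasing fit (unit weights)."""
    y = y.astype(float).copy()
    n = y.size
    level = y.copy()
    weight = np.ones(n)
    idx = list(range(n))
    blocks = [[i] for i in range(n)]
    vals = list(level)
    wts = list(weight)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1]:
            w = wts[i] + wts[i + 1]
            v = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / w
            blocks[i] = blocks[i] + blocks[i + 1]
            vals[i], wts[i] = v, w
            del blocks[i + 1], vals[i + 1], wts[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.empty(n)
    for v, blk in zip(vals, blocks):
        out[blk] = v
    return out


def _break_ties(c: np.ndarray, increasing: bool) -> np.ndarray:
    out = c.copy()
    eps = max(np.abs(c).max(), 1.0) * 1e-9
    for i in range(1, out.size):
        if increasing and out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
        elif not increasing and out[i] >= out[i - 1]:
            out[i] = out[i - 1] - eps
    return out


def gray_to_density(image, curve: CalibrationCurve, ligand: LigandConfig) -> np.ndarray:
    """Pixelwise binding-site density (fmol/mg protein) of an autoradiograph.

    Applies the calibration curve, divides by specific activity and the
    protein conversion factor, and multiplies by the saturation correction
    ``(K_D + L) / L``.  Gray values outside the calibrated range are clamped
    (the curve records the event); densities are therefore never extrapolated
    into negative values.
    """
    conc = curve(np.asarray(image, dtype=float))
    return (conc / (ligand.specific_activity * ligand.protein_factor)
            * ligand.saturation_correction)


def mean_area_density(profiles, min_profiles: int = 90, max_profiles: int = 150
                      ) -> tuple[float, float]:
    """Mean areal density: flat average over all depth samples of all profiles.

    Returns ``(mean, sd)`` where the sd is taken across the per-profile mean
    densities (the between-profile spread).  A profile count outside
    ``[min_profiles, max_profiles]`` raises a warning, not an error.
    """
    arrs = [np.asarray(getattr(p, "values", p), dtype=float) for p in profiles]
    if not arrs:
        raise ValueError("empty profile list")
    n = len(arrs)
    if not (min_profiles <= n <= max_profiles):
        warnings.warn(
            f"profile count {n} outside the recommended range "
            f"[{min_profiles}, {max_profiles}]")
    allvals = np.concatenate(arrs)
    per_profile = np.array([a.mean() for a in arrs])
    sd = float(per_profile.std(ddof=1)) if n > 1 else 0.0
    return float(allvals.mean()), sd


#: black -> blue -> cyan -> green -> yellow -> red spectral assignment
_SPECTRUM = [(0, 0, 0), (0, 0, 255), (0, 255, 255), (0, 255, 0),
             (255, 255, 0), (255, 0, 0)]


def pseudocolor_export(density_image, vmin: float | None = None,
                       vmax: float | None = None) -> tuple[np.ndarray, dict]:
    """Linear contrast-enhanced pseudocolor rendering of a density image.

    Densities are mapped linearly from [vmin, vmax] (image min/max by default)
    onto a black-to-red spectral colormap; a constant image maps to the lowest
    color.  Returns the uint8 RGB image and color-bar metadata recording the
    true density limits.
    """
    img = np.asarray(density_image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("density image must be finite")
    lo = float(img.min()) if vmin is None else float(vmin)
    hi = float(img.max()) if vmax is None else float(vmax)
    span = hi - lo
    t = np.zeros_like(img) if span <= 0 else np.clip((img - lo) / span, 0.0, 1.0)
    anchors = np.linspace(0.0, 1.0, len(_SPECTRUM))
    chans = [np.interp(t, anchors, [c[i] for c in _SPECTRUM]) for i in range(3)]
    rgb = np.stack(chans, axis=-1).round().astype(np.uint8)
    meta = {"vmin": lo, "vmax": hi, "colormap": "black-red spectrum",
            "n_anchors": len(_SPECTRUM)}
    return rgb, meta
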
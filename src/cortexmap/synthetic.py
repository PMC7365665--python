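"""Synthetic cortical ribbons, section images and autoradiographs.

Everything downstream of wet-lab histology is exercised on generated inputs
with known ground truth: piecewise-constant ribbons of laminar profiles with
additive Gaussian noise and known border positions, rendered section images on
analytically tractable geometries (rectangle, annulus sector), autoradiograph
images with co-exposed calibration standards passed through a film response,
and simulated per-hemisphere receptor density observations.  The packaged
area x receptor mean-density table ships here as well.
"""

from __future__ import annotations

import importlib.resources as resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LaminarTemplate",
    "RibbonSpec",
    "RectangleRibbon",
    "AnnulusSectorRibbon",
    "generate_ribbon",
    "render_section_image",
    "render_autoradiograph",
    "logistic_film",
    "default_standard_concentrations",
    "ips_density_table",
    "ligand_parameters",
    "gli_template",
    "two_area_spec",
    "simulate_density_observations",
]


@dataclass(frozen=True)
class LaminarTemplate:
    """Expected profile value as a function of cortical depth (0-100 %)."""

    depth_grid: np.ndarray
    mean_curve: np.ndarray
    name: str = ""

    def __post_init__(self):
        g = np.asarray(self.depth_grid, dtype=float)
        c = np.asarray(self.mean_curve, dtype=float)
        if g.ndim != 1 or g.shape != c.shape:
            raise ValueError("LaminarTemplate: depth_grid/mean_curve shape mismatch")
        if g[0] != 0 or g[-1] != 100 or np.any(np.diff(g) <= 0):
            raise ValueError("LaminarTemplate: depth_grid must increase strictly from 0 to 100")
        object.__setattr__(self, "depth_grid", g)
        object.__setattr__(self, "mean_curve", c)

    def __call__(self, depth_pct: np.ndarray) -> np.ndarray:
        return np.interp(depth_pct, self.depth_grid, self.mean_curve)


def gli_template(peaks: list[tuple[float, float, float]], baseline: float = 0.2,
                 name: str = "") -> LaminarTemplate:
    """Smooth GLI-like template: baseline plus Gaussian laminar bumps.

    ``peaks`` is a list of (depth %, amplitude, width %) triples.  Values are
    clipped into [0, 1] to satisfy the GLI-mode template invariant.
    """
    g = np.linspace(0.0, 100.0, 201)
    c = np.full_like(g, baseline)
    for mu, amp, sd in peaks:
        c = c + amp * np.exp(-0.5 * ((g - mu) / sd) ** 2)
    return LaminarTemplate(g, np.clip(c, 0.0, 1.0), name=name)


@dataclass
class RibbonSpec:
    """Generation recipe for a 1-D ribbon of laminar profiles."""

    n_traverses: int
    depth_samples: int
    areas: list[tuple[str, LaminarTemplate]]
    border_positions: list[int] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    mode: str = "gli"          # "gli" (templates in [0,1]) or "density" (>= 0)

    def validate(self) -> None:
        if self.n_traverses < 1:
            raise ValueError("n_traverses must be a positive integer")
        if self.depth_samples < 2:
            raise ValueError("depth_samples must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        bp = list(self.border_positions)
        if bp != sorted(bp) or len(set(bp)) != len(bp):
            raise ValueError("border_positions must be strictly increasing")
        if any(not (0 < b < self.n_traverses) for b in bp):
            raise ValueError("border_positions must lie in (0, n_traverses)")
        if len(self.areas) != len(bp) + 1:
            raise ValueError("areas count must equal border_positions count + 1")
        for label, tpl in self.areas:
            lo, hi = tpl.mean_curve.min(), tpl.mean_curve.max()
            if self.mode == "gli" and (lo < 0 or hi > 1):
                raise ValueError(f"template {label!r}: GLI-mode values must lie in [0, 1]")
            if self.mode == "density" and lo < 0:
                raise ValueError(f"template {label!r}: density-mode values must be >= 0")


def generate_ribbon(spec: RibbonSpec) -> tuple[np.ndarray, list[int]]:
    """Profile matrix (n_traverses, depth_samples) plus ground-truth borders.

    Each traverse is its area's template evaluated on the uniform depth grid
    plus iid Gaussian noise of the requested amplitude; samples are floored at
    zero because neither a cell-body volume fraction nor a receptor density can
    be negative.  Identical seeds give bitwise-identical matrices.
    """
    spec.validate()
    grid = np.linspace(0.0, 100.0, spec.depth_samples)
    area_idx = np.searchsorted(spec.border_positions, np.arange(spec.n_traverses),
                               side="right")
    curves = np.stack([tpl(grid) for _, tpl in spec.areas])
    matrix = curves[area_idx]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        matrix = matrix + rng.normal(0.0, spec.noise_sd, size=matrix.shape)
        matrix = np.maximum(matrix, 0.0)
    return matrix, list(spec.border_positions)


# ---------------------------------------------------------------------------
# ribbon geometries with analytically known traverses


@dataclass(frozen=True)
class RectangleRibbon:
    """Axis-aligned ribbon: pial surface on top, white matter below."""

    width: int
    thickness: int
    y0: int = 0
    x0: int = 0

    def contours(self, n_vertices: int = 64) -> tuple[np.ndarray, np.ndarray]:
        x = np.linspace(self.x0, self.x0 + self.width - 1, n_vertices)
        pial = np.column_stack([x, np.full_like(x, float(self.y0))])
        wm = np.column_stack([x, np.full_like(x, float(self.y0 + self.thickness - 1))])
        return pial, wm

    def depth_pos(self, xx: np.ndarray, yy: np.ndarray):
        depth = (yy - self.y0) / (self.thickness - 1) * 100.0
        pos = (xx - self.x0) / (self.width - 1)
        inside = (depth >= 0) & (depth <= 100) & (pos >= 0) & (pos <= 1)
        return depth, pos, inside

    def border_x(self, traverse_fraction: float) -> float:
        return self.x0 + traverse_fraction * (self.width - 1)


@dataclass(frozen=True)
class AnnulusSectorRibbon:
    """Curved ribbon between two concentric arcs; pial = outer radius."""

    center: tuple[float, float]
    r_pial: float
    r_wm: float
    theta0: float               # radians, start angle
    theta1: float

    def __post_init__(self):
        if self.r_pial <= self.r_wm:
            raise ValueError("r_pial must exceed r_wm")

    def contours(self, n_vertices: int = 256) -> tuple[np.ndarray, np.ndarray]:
        th = np.linspace(self.theta0, self.theta1, n_vertices)
        cx, cy = self.center
        pial = np.column_stack([cx + self.r_pial * np.cos(th),
                                cy + self.r_pial * np.sin(th)])
        wm = np.column_stack([cx + self.r_wm * np.cos(th),
                              cy + self.r_wm * np.sin(th)])
        return pial, wm

    def depth_pos(self, xx: np.ndarray, yy: np.ndarray):
        cx, cy = self.center
        r = np.hypot(xx - cx, yy - cy)
        th = np.arctan2(yy - cy, xx - cx)
        span = self.theta1 - self.theta0
        # measure angles from theta0 modulo 2*pi so the arc may cross the
        # arctan2 branch cut
        rel = np.mod(th - self.theta0, 2 * np.pi) if span >= 0 \
            else -np.mod(self.theta0 - th, 2 * np.pi)
        depth = (self.r_pial - r) / (self.r_pial - self.r_wm) * 100.0
        pos = rel / span if span != 0 else np.zeros_like(rel)
        inside = (depth >= 0) & (depth <= 100) & (pos >= 0) & (pos <= 1)
        return depth, pos, inside


def render_section_image(spec: RibbonSpec, geometry, shape: tuple[int, int]
                         ) -> tuple[np.ndarray, dict]:
    """Render a ribbon spec onto a geometry as a grayscale section image.

    Inside the ribbon each pixel takes the value of its area's laminar template
    at the pixel's cortical depth; outside pixels are zero.  The ribbon is
    padded by a fraction of a layer (2 % depth) so that bilinear sampling at
    the pial/white-matter boundary is not contaminated by background zeros.
    Returns the float image and a ground-truth dictionary with the
    pial/white-matter contours and the border positions as traverse fractions
    (and x columns for rectangles).
    """
    spec.validate()
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    depth, pos, inside = geometry.depth_pos(xx, yy)
    pad = 2.0
    inside = (depth >= -pad) & (depth <= 100.0 + pad) & (pos >= 0) & (pos <= 1)
    frac = np.asarray(spec.border_positions, dtype=float) / spec.n_traverses
    img = np.zeros(shape, dtype=float)
    if np.any(inside):
        area_idx = np.searchsorted(frac, pos[inside], side="right")
        curves = [tpl for _, tpl in spec.areas]
        d = np.clip(depth[inside], 0.0, 100.0)
        vals = np.empty(d.size)
        for k, tpl in enumerate(curves):
            sel = area_idx == k
            if np.any(sel):
                vals[sel] = tpl(d[sel])
        img[inside] = vals
    pial, wm = geometry.contours()
    truth = {"pial": pial, "wm": wm, "border_fractions": frac.tolist()}
    if isinstance(geometry, RectangleRibbon):
        truth["border_x"] = [geometry.border_x(f) for f in frac]
    return img, truth


# ---------------------------------------------------------------------------
# autoradiographs


def logistic_film(gmax: float = 250.0, c50: float = 600.0, slope: float = 200.0):
    """Saturating film response: gray value as a logistic function of activity."""

    def response(c):
        return gmax / (1.0 + np.exp(-(np.asarray(c, dtype=float) - c50) / slope))

    return response


def default_standard_concentrations(c_max: float = 1200.0, n: int = 14) -> np.ndarray:
    """Evenly spaced co-exposed standard activities from 0 to ``c_max``.

    Commercial tritium microscale strips carry on the order of 8-16 graded
    steps; 14 evenly spaced steps keep the piecewise-linear calibration error
    of a smoothly saturating film response well below one percent over the
    interior of the range.
    """
    return np.linspace(0.0, c_max, n)


def render_autoradiograph(density_image: np.ndarray, standards: np.ndarray,
                          film_response, patch_px: int = 8
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Expose a tissue activity image and standard patches to the same film.

    The returned image has the tissue on the left and one rectangular patch
    per standard stacked in a reserved right margin (mirroring co-exposed
    plastic scales); the standards table lists the true concentration and the
    mean gray value of each patch.  A non-monotone film response is rejected.
    """
    tissue = np.asarray(density_image, dtype=float)
    conc = np.asarray(standards, dtype=float)
    probe = np.linspace(min(conc.min(), tissue.min()),
                        max(conc.max(), tissue.max()), 512)
    resp = film_response(probe)
    diffs = np.diff(resp)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("film response must be strictly monotone")
    h, w = tissue.shape
    n = conc.size
    if h < 2 * n:
        raise ValueError("tissue image too short to host all standard patches")
    margin = patch_px + 4
    img = np.zeros((h, w + margin), dtype=float)
    img[:, :w] = film_response(tissue)
    step = h // n
    rows = []
    for i, c in enumerate(conc):
        y0, y1 = i * step, i * step + max(step - 1, 1)
        patch = film_response(np.full((y1 - y0, patch_px), c))
        img[y0:y1, w + 2:w + 2 + patch_px] = patch
        rows.append({"concentration": float(c), "gray": float(patch.mean())})
    return img, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged reference data


def ips_density_table():
    """Packaged area x receptor mean (+/- sd) density table, fmol/mg protein.

    16 cortical areas of the macaque intraparietal/parieto-occipital region by
    15 receptor types (V4d carries no fingerprint and is absent).  Returns a
    :class:`~cortexmap.fingerprints.DensityTable`.
    """
    from .fingerprints import DensityTable

    ref = resources.files("cortexmap.data") / "ips_receptor_densities.csv"
    try:
        with resources.as_file(ref) as path:
            frame = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise OSError("packaged density table is missing or corrupt") from exc
    return DensityTable.from_long(frame)


def ligand_parameters() -> dict:
    """Ligand metadata keyed by receptor: tracer name and free concentration (nM)."""
    ref = resources.files("cortexmap.data") / "ligands.json"
    with resources.as_file(ref) as path:
        return json.loads(path.read_text())


# ---------------------------------------------------------------------------
# canned ribbon recipes and group-level observation simulation


def two_area_spec(n_traverses: int = 200, border: int = 100,
                  depth_samples: int = 101, separation: float = 3.0,
                  noise_sd: float = 0.03, contrast: float | None = None,
                  seed: int = 0) -> RibbonSpec:
    """Two-area ribbon with a controlled laminar contrast across the border.

    The two laminar templates share a baseline but place their main cellular
    band at different depths; the second template is blended toward the first
    so that the root-mean-square template difference over depth equals
    ``contrast`` (in GLI units).  By default the contrast is ``separation``
    times the profile noise amplitude — the per-sample signal-to-noise of the
    border — referenced to the default noise amplitude when ``noise_sd`` is
    zero so that noise-free ribbons keep a genuine border.
    """
    if contrast is None:
        contrast = separation * (noise_sd if noise_sd > 0 else 0.03)
    a = gli_template([(30.0, 0.45, 12.0), (75.0, 0.25, 10.0)], name="A")
    b_raw = gli_template([(50.0, 0.45, 14.0)], name="B")
    g = np.linspace(0.0, 100.0, 201)
    diff = b_raw(g) - a(g)
    rms = float(np.sqrt(np.mean(diff**2)))
    lam = min(contrast / rms, 1.0) if rms > 0 else 0.0
    b = LaminarTemplate(g, np.clip(a(g) + lam * diff, 0.0, 1.0), name="B")
    return RibbonSpec(n_traverses=n_traverses, depth_samples=depth_samples,
                      areas=[("A", a), ("B", b)], border_positions=[border],
                      noise_sd=noise_sd, seed=seed)


def homogeneous_spec(n_traverses: int = 200, depth_samples: int = 101,
                     noise_sd: float = 0.03, seed: int = 0) -> RibbonSpec:
    """Single-area null ribbon used for false-positive-rate experiments."""
    a = gli_template([(30.0, 0.45, 12.0), (75.0, 0.25, 10.0)], name="A")
    return RibbonSpec(n_traverses=n_traverses, depth_samples=depth_samples,
                      areas=[("A", a)], border_positions=[], noise_sd=noise_sd,
                      seed=seed)


def simulate_density_observations(n_subjects: int = 4,
                                  areas: list[str] | None = None,
                                  receptors: list[str] | None = None,
                                  subject_cv: float = 0.15,
                                  noise_cv: float = 0.03,
                                  effect: tuple[str, str, str, float] | None = None,
                                  base: str = "table",
                                  seed: int = 0) -> pd.DataFrame:
    """Per-hemisphere receptor density observations mirroring the study design.

    Four hemispheres by 16 areas by 15 receptors by default, built around the
    packaged mean-density table:

        density = mean(area, receptor) * (1 + subject) * (1 + noise)

    with a proportional per-hemisphere subject factor (coefficient of
    variation ``subject_cv``) and proportional measurement noise
    (``noise_cv``), floored at 1 fmol/mg.  Both effects are multiplicative
    because the hemisphere-to-hemisphere spreads printed for real density
    tables scale with the mean; the measurement term is small because every
    observation is itself an average over on the order of a hundred laminar
    profiles.  With ``base="table"`` the area/receptor means are the packaged
    table entries (real between-area structure); with ``base="null"`` every
    area shares its receptor's grand mean, so the only systematic area
    contrast is the optionally planted one.  The planted contrast
    ``(area_a, area_b, receptor, delta)`` raises area_a's mean by ``delta``
    (fmol/mg) relative to area_b for that receptor; ``receptor`` may be a
    tuple of receptors sharing the shift (a profile-wide contrast).
    """
    from .fingerprints import RECEPTOR_ORDER

    table = ips_density_table()
    if areas is None:
        areas = list(table.means.index)
    if receptors is None:
        receptors = list(RECEPTOR_ORDER)
    if base not in ("table", "null"):
        raise ValueError("base must be 'table' or 'null'")
    grand = table.means.mean(axis=0)
    rng = np.random.default_rng(seed)
    subj_eff = rng.normal(0.0, subject_cv, size=n_subjects)
    rows = []
    for s in range(n_subjects):
        for a in areas:
            for r in receptors:
                mu = (float(table.means.loc[a, r]) if base == "table"
                      else float(grand[r]))
                if effect is not None:
                    ea, eb, er, delta = effect
                    shifted = (r in er) if isinstance(er, (tuple, list, set)) else r == er
                    if shifted and a == ea:
                        mu += delta
                value = mu * (1.0 + subj_eff[s]) * (1.0 + rng.normal(0.0, noise_cv))
                rows.append((a, r, f"S{s}", value))
    df = pd.DataFrame(rows, columns=["area", "receptor", "subject", "density"])
    df["density"] = df["density"].clip(lower=1.0)
    return df
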
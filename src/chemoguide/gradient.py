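"""Radial chemical-gradient profiles and an annulus diffusion model.

The attractant (serum, visualized by a fluorescent dye) diffuses from an
inner reservoir into the surrounding matrix; by azimuthal symmetry of the
device its concentration field is well described by radial diffusion in
an annulus,

    dc/dt = D (d2c/dr2 + (1/r) dc/dr),    r_inner <= r <= r_outer,

with fixed reservoir concentrations at both walls.  The steady state of
this equation is c(r) = a + b*ln(r); over a window narrow compared to the
annulus the profile is approximately linear, which is what the assay
relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.stats import linregress

from .io import DeviceGeometry, ImageFrame

logger = logging.getLogger("chemoguide")

#: fraction of the inner radius used as the normalization (plateau) region
NORMALIZATION_RADIUS_FRACTION = 0.8


@dataclass(frozen=True)
class RadialProfile:
    """Azimuthally averaged intensity vs distance from the device center.

    ``symmetry_cv`` is the per-bin coefficient of variation of the mean
    across 8 azimuthal sectors (0 for perfectly symmetric signal); bins
    with no pixels carry NaN intensity and ``n_pixels = 0``.
    """

    r_um: np.ndarray
    intensity: np.ndarray
    time_h: float
    n_pixels: np.ndarray
    symmetry_cv: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        d = {"r_um": self.r_um, "intensity": self.intensity, "n_pixels": self.n_pixels}
        if self.symmetry_cv is not None:
            d["symmetry_cv"] = self.symmetry_cv
        df = pd.DataFrame(d)
        df["time_h"] = self.time_h
        return df


def radial_profile(
    frame: ImageFrame,
    geometry: DeviceGeometry,
    n_bins: int = 50,
    r_max_um: float | None = None,
    mask: np.ndarray | None = None,
) -> RadialProfile:
    """Azimuthal mean intensity per radial bin, reservoir-normalized.

    Intensity is normalized by the mean inside 0.8x the inner-reservoir
    radius at the same time point, which self-normalizes against
    photobleaching.  An optional boolean ``mask`` restricts which pixels
    contribute (e.g. to exclude occluded regions).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    img = np.asarray(frame.pixels, dtype=float)
    h, w = img.shape
    psz = frame.pixel_size_um
    cx_px, cy_px = geometry.center_px
    if not (0 <= cx_px < w and 0 <= cy_px < h):
        raise ValueError("geometry center lies outside the image")

    cx, cy = geometry.center_um
    xx, yy = np.meshgrid(np.arange(w) * psz - cx, np.arange(h) * psz - cy)
    r = np.hypot(xx, yy)
    if r_max_um is None:
        r_max_um = float(r.max())

    admitted = r < r_max_um
    if mask is not None:
        admitted &= np.asarray(mask, dtype=bool)

    # normalization plateau: inner reservoir interior
    plateau = r <= NORMALIZATION_RADIUS_FRACTION * geometry.inner_radius_um
    if mask is not None:
        plateau &= np.asarray(mask, dtype=bool)
    if not plateau.any():
        raise ValueError("no pixels inside the normalization region")
    ref = float(img[plateau].mean())
    if ref <= 0:
        raise ValueError("non-positive reservoir reference intensity")

    edges = np.linspace(0.0, r_max_um, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(r[admitted], edges) - 1, 0, n_bins - 1)
    vals = img[admitted] / ref

    n_px = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(n_px > 0, sums / np.maximum(n_px, 1), np.nan)

    # symmetry diagnostic: CV of sector means across 8 azimuthal sectors
    sector = ((np.arctan2(-yy, xx)[admitted] + np.pi) / (2 * np.pi) * 8).astype(int) % 8
    cv = np.full(n_bins, np.nan)
    flat_idx = idx * 8 + sector
    s_n = np.bincount(flat_idx, minlength=n_bins * 8).reshape(n_bins, 8)
    s_sum = np.bincount(flat_idx, weights=vals, minlength=n_bins * 8).reshape(n_bins, 8)
    for b in range(n_bins):
        pop = s_n[b] > 0
        if pop.sum() >= 2:
            sm = s_sum[b, pop] / s_n[b, pop]
            if sm.mean() != 0:
                cv[b] = sm.std() / abs(sm.mean())

    return RadialProfile(centers, means, frame.time_h, n_px, cv)


def gradient_linearity(
    profile: RadialProfile, r_lo_um: float, r_hi_um: float
) -> tuple[float, float]:
    """Least-squares line on intensity vs r over [r_lo, r_hi].

    Returns (slope per um, R^2).  Requires >= 4 populated bins in the
    window.
    """
    sel = (
        (profile.r_um >= r_lo_um)
        & (profile.r_um <= r_hi_um)
        & (profile.n_pixels > 0)
        & np.isfinite(profile.intensity)
    )
    if sel.sum() < 4:
        raise ValueError("need at least 4 populated bins in the fit window")
    x = profile.r_um[sel]
    y = profile.intensity[sel]
    if np.ptp(y) == 0:  # constant profile: slope 0, R^2 conventionally 1
        return 0.0, 1.0
    res = linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def annulus_steady_state(
    r_um: np.ndarray,
    inner_radius_um: float,
    outer_radius_um: float,
    inner_value: float,
    outer_value: float,
) -> np.ndarray:
    """Closed-form steady state a + b*ln(r) of annulus diffusion."""
    b = (outer_value - inner_value) / np.log(outer_radius_um / inner_radius_um)
    a = inner_value - b * np.log(inner_radius_um)
    return a + b * np.log(np.asarray(r_um, dtype=float))


def simulate_radial_diffusion(
    geometry: DeviceGeometry,
    diffusivity_um2_per_s: float,
    inner_value: float,
    outer_value: float,
    times_h: list[float],
    outer_radius_um: float,
    n_grid: int = 500,
    initial_value: float | None = None,
) -> list[RadialProfile]:
    """Solve radial diffusion in the annulus with fixed wall concentrations.

    Crank-Nicolson in time (unconditionally stable; the internal step is
    refined so no output requires extrapolation) on a uniform radial grid
    from the inner-reservoir wall to ``outer_radius_um``.  The initial
    interior concentration defaults to ``outer_value`` (gradient not yet
    established).  Returned profiles carry the raw concentrations.
    """
    if diffusivity_um2_per_s <= 0:
        raise ValueError("diffusivity must be positive")
    r_in = geometry.inner_radius_um
    if not 0 < r_in < outer_radius_um:
        raise ValueError("need 0 < inner_radius < outer_radius")
    times = sorted(float(t) for t in times_h)
    if times[0] < 0:
        raise ValueError("times must be nonnegative")

    r = np.linspace(r_in, outer_radius_um, n_grid)
    dr = r[1] - r[0]
    c = np.full(n_grid, outer_value if initial_value is None else initial_value, dtype=float)
    c[0], c[-1] = inner_value, outer_value

    D = diffusivity_um2_per_s * 3600.0  # um^2 per hour
    dt = 0.01  # hours; both schemes below are unconditionally stable

    # spatial operator L on the interior: L c = alpha2 c'' + gamma c'/r terms
    ri = r[1:-1]
    alpha2 = D / (dr * dr)
    gamma = D / (2 * dr * ri)
    l_lo = alpha2 - gamma  # coefficient of c[i-1]
    l_di = -2 * alpha2
    l_up = alpha2 + gamma

    def step(c: np.ndarray, dt: float, theta: float) -> np.ndarray:
        """One theta-scheme step: (I - theta dt L) c_new = (I + (1-theta) dt L) c_old."""
        e = (1 - theta) * dt
        rhs = c[1:-1] + e * (l_lo * c[:-2] + l_di * c[1:-1] + l_up * c[2:])
        i = theta * dt
        rhs[0] += i * l_lo[0] * inner_value
        rhs[-1] += i * l_up[-1] * outer_value
        ab = np.zeros((3, n_grid - 2))
        ab[0, 1:] = -i * l_up[:-1]
        ab[1, :] = 1 - i * l_di
        ab[2, :-1] = -i * l_lo[1:]
        new = solve_banded((1, 1), ab, rhs)
        out = c.copy()
        out[1:-1] = new
        return out

    profiles: list[RadialProfile] = []
    t_now = 0.0
    # Rannacher startup: damped implicit-Euler substeps absorb the initial
    # wall discontinuity that would otherwise make Crank-Nicolson ring
    startup_left = 16
    for t_target in times:
        span = t_target - t_now
        if span > 0:
            n_steps = max(1, int(np.ceil(span / dt)))
            h = span / n_steps
            for _ in range(n_steps):
                if startup_left > 0:
                    nsub = 8
                    for _ in range(nsub):
                        c = step(c, h / nsub, 1.0)
                    startup_left -= 1
                else:
                    c = step(c, h, 0.5)
            t_now = t_target
        profiles.append(
            RadialProfile(
                r_um=r.copy(),
                intensity=c.copy(),
                time_h=t_target,
                n_pixels=np.ones(n_grid, dtype=int),
            )
        )
    return profiles
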
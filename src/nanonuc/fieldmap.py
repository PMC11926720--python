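"""Simplified linear focused-ultrasound field and nucleation-area extraction.

A monochromatic spherically focused bowl radiating into a water/tissue
bilayer.  The peak-negative-pressure (PNP) map is computed with a
Rayleigh diffraction integral over the bowl surface (exact source
geometry, linear propagation) and a frequency-power-law amplitude
attenuation applied along the tissue path.  This is a deliberately
simplified stand-in for full nonlinear wave simulation: the maps are
qualitative, not quantitative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GridError


@dataclass(frozen=True)
class TransducerConfig:
    """Single-element focused bowl and propagation medium."""

    roc: float = 0.060              # radius of curvature, m (focus at z = roc)
    aperture_diameter: float = 0.060  # m
    f: float = 1e6                  # Hz
    source_pressure: float = 1e5    # surface pressure amplitude rho*c*u0, Pa
    sound_speed: float = 1500.0     # m/s
    water_path: float = 0.030       # water/tissue interface depth, m
    alpha0: float = 0.5             # tissue attenuation, dB/(cm MHz^y)
    attenuation_power: float = 1.0  # y

    def __post_init__(self) -> None:
        if self.roc <= 0:
            raise ValueError("roc must be positive")
        if not 0 < self.aperture_diameter <= 2 * self.roc:
            raise ValueError("aperture must be positive and <= 2*roc")
        if self.f <= 0 or self.sound_speed <= 0:
            raise ValueError("f and sound_speed must be positive")
        if self.alpha0 < 0:
            raise ValueError("attenuation must be non-negative")

    @property
    def wavelength(self) -> float:
        return self.sound_speed / self.f

    @property
    def wavenumber(self) -> float:
        return 2.0 * math.pi / self.wavelength

    @property
    def half_angle(self) -> float:
        """Half-opening angle of the bowl."""
        return math.asin(self.aperture_diameter / (2.0 * self.roc))


@dataclass(frozen=True)
class FieldMap:
    """Axisymmetric PNP map on a (z, r) grid."""

    z: np.ndarray = field(repr=False)   # axial positions, m (bowl apex at 0)
    r: np.ndarray = field(repr=False)   # radial positions, m (r >= 0)
    pnp: np.ndarray = field(repr=False)  # shape (len(z), len(r)), Pa
    config: TransducerConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        zz, rr = np.meshgrid(self.z, self.r, indexing="ij")
        return pd.DataFrame({"z_mm": zz.ravel() * 1e3, "r_mm": rr.ravel() * 1e3,
                             "PNP_Pa": self.pnp.ravel()})


def attenuation_factor(config: TransducerConfig, z) -> np.ndarray:
    """Amplitude attenuation for the tissue path beyond the water interface."""
    depth_cm = np.clip(np.asarray(z, dtype=float) - config.water_path, 0.0, None) * 100.0
    db = config.alpha0 * (config.f / 1e6) ** config.attenuation_power * depth_cm
    return 10.0 ** (-db / 20.0)


def axial_pressure_analytic(config: TransducerConfig, z) -> np.ndarray:
    """Closed-form on-axis amplitude of the focused bowl (no attenuation).

    |p(z)| = p0 |F/(F - z)| |exp(i k d_edge) - exp(i k z)| with d_edge the
    rim-to-field-point distance; the removable singularity at the focus
    evaluates to p0 * k * (d_edge(F) - F)... computed by a small-offset
    limit for robustness.
    """
    F, k = config.roc, config.wavenumber
    theta = config.half_angle
    z = np.asarray(z, dtype=float)
    z_safe = np.where(np.abs(z - F) < 1e-9, F + 1e-9, z)
    z_rim = F * (1.0 - math.cos(theta))
    r_rim = F * math.sin(theta)
    d_edge = np.hypot(z_safe - z_rim, r_rim)
    amp = np.abs(F / (F - z_safe)) * np.abs(np.exp(1j * k * d_edge) - np.exp(1j * k * z_safe))
    return config.source_pressure * amp


def _bowl_quadrature(config: TransducerConfig, z, r, n_theta=None, n_phi=None):
    """Quadrature nodes over the bowl sized from the phase spread seen by
    the extreme field points."""
    F = config.roc
    theta_max = config.half_angle
    lam = config.wavelength
    # Estimate the per-field-point spread of source distances at the
    # corners of the field window with a coarse surface sample.
    tt = np.linspace(0.0, theta_max, 48)
    pp = np.linspace(0.0, math.pi, 24)
    zs = F * (1.0 - np.cos(tt))[:, None]
    rs = F * np.sin(tt)[:, None]
    corners = [(zv, rv) for zv in (z.min(), z.max()) for rv in (r.min(), r.max())]
    spread = 0.0
    for zf, rf in corners:
        d = np.sqrt((zf - zs) ** 2 + rf**2 + rs**2
                    - 2.0 * rf * rs * np.cos(pp)[None, :])
        spread = max(spread, float(d.max() - d.min()))
    n_osc = spread / lam
    if n_theta is None:
        n_theta = int(min(2048, max(64, 8 * n_osc)))
    if n_phi is None:
        n_phi = int(min(512, max(32, 4 * n_osc)))
    # Gauss-Legendre in theta, midpoint in phi over [0, pi] (symmetry x2).
    x, w = np.polynomial.legendre.leggauss(n_theta)
    theta = 0.5 * theta_max * (x + 1.0)
    w_theta = 0.5 * theta_max * w * F**2 * np.sin(theta)
    phi = (np.arange(n_phi) + 0.5) * math.pi / n_phi
    w_phi = 2.0 * math.pi / n_phi  # mirrored half-plane
    return theta, w_theta, phi, w_phi


def linear_focused_field(config: TransducerConfig,
                         z_span: tuple[float, float] = (0.010, 0.110),
                         r_max: float = 0.010,
                         dx: float = 1e-4,
                         n_theta: int | None = None,
                         n_phi: int | None = None) -> FieldMap:
    """Rayleigh-integral PNP map of the focused bowl on a (z, r) grid.

    Grid spacing must satisfy dx <= lambda/4, else :class:`GridError`.
    """
    lam = config.wavelength
    if dx > lam / 4.0:
        raise GridError(f"grid spacing {dx:.3g} m exceeds lambda/4 = {lam / 4:.3g} m; "
                        "refine the grid or lower the frequency")
    z = np.arange(z_span[0], z_span[1] + 0.5 * dx, dx)
    r = np.arange(0.0, r_max + 0.5 * dx, dx)
    pnp = rayleigh_pnp(config, z, r, n_theta=n_theta, n_phi=n_phi)
    pnp *= attenuation_factor(config, z)[:, None]
    return FieldMap(z=z, r=r, pnp=pnp, config=config)


def rayleigh_pnp(config: TransducerConfig, z, r,
                 n_theta: int | None = None,
                 n_phi: int | None = None) -> np.ndarray:
    """Unattenuated pressure amplitude on the outer product of z and r.

    ``r`` may contain negative values (axisymmetry makes them redundant).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    k = config.wavenumber
    F = config.roc
    theta, w_theta, phi, w_phi = _bowl_quadrature(config, z, np.abs(r),
                                                  n_theta, n_phi)
    zs = F * (1.0 - np.cos(theta))          # (nt,)
    rs = F * np.sin(theta)                  # (nt,)
    cphi = np.cos(phi)                      # (nf,)

    pnp = np.empty((z.size, r.size))
    # Chunk the z rows so the (chunk, nr, nt, nf) distance tensor stays small.
    max_elems = 8_000_000
    chunk = max(1, int(max_elems / max(1, r.size * theta.size * phi.size)))
    for i0 in range(0, z.size, chunk):
        zc = z[i0:i0 + chunk]
        dz2 = (zc[:, None, None, None] - zs[None, None, :, None]) ** 2
        r2 = (r[None, :, None, None] ** 2 + rs[None, None, :, None] ** 2
              - 2.0 * r[None, :, None, None] * rs[None, None, :, None]
              * cphi[None, None, None, :])
        d = np.sqrt(dz2 + r2)
        integrand = np.exp(1j * k * d) / d
        integral = (integrand.sum(axis=3) * w_phi * w_theta[None, None, :]).sum(axis=2)
        pnp[i0:i0 + chunk] = np.abs(integral) * (k / (2.0 * math.pi))
    return pnp * config.source_pressure


def nucleation_area(fmap: FieldMap, thresholds) -> pd.DataFrame:
    """Super-threshold region metrics per droplet size.

    ``thresholds`` is an iterable of ``(diameter_m, P_INT_Pa)`` pairs.  For
    each threshold the connected region of the PNP map (containing the
    field maximum) where PNP >= P_INT is measured: axial length, full
    radial width (mirrored across the axis), and mirrored cross-section
    area.  A threshold above the field maximum yields an empty region.
    """
    z, r, pnp = fmap.z, fmap.r, fmap.pnp
    dz = float(z[1] - z[0])
    dr = float(r[1] - r[0])
    imax = np.unravel_index(np.argmax(pnp), pnp.shape)
    rows = []
    for diameter, level in thresholds:
        if level <= 0:
            raise ValueError("threshold must be positive")
        mask = pnp >= level
        if not mask[imax]:
            rows.append({"diameter_m": diameter, "P_INT_Pa": level,
                         "length_m": 0.0, "width_m": 0.0, "area_m2": 0.0})
            continue
        labels, _ = ndimage.label(mask)
        region = labels == labels[imax]
        zi, ri = np.nonzero(region)
        length = (zi.max() - zi.min() + 1) * dz
        width = 2.0 * (r[ri.max()] + 0.5 * dr)
        area = 2.0 * region.sum() * dz * dr
        rows.append({"diameter_m": diameter, "P_INT_Pa": level,
                     "length_m": length, "width_m": width, "area_m2": area})
    return pd.DataFrame(rows, columns=["diameter_m", "P_INT_Pa",
                                       "length_m", "width_m", "area_m2"])
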
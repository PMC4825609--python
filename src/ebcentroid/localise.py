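"""Sub-pixel localisation of photon events.

Five estimators, mirroring the method comparison the pipeline is built for:

- ``fit_gaussian_mle``  — Poisson maximum-likelihood, point-sampled 2D
  symmetric Gaussian PSF (ML-G);
- ``fit_gaussian_ls``   — least squares, same model (LS-G);
- ``fit_integrated_gaussian_wls`` — weighted least squares with the
  pixel-integrated (error-function) Gaussian (WLS-IG);
- ``localise_radial_symmetry``    — non-iterative gradient-line estimator;
- ``localise_local_centroid``     — background-subtracted centre of mass.

Plus multi-emitter fitting analysis (``fit_multi``): a 2-emitter model with
shared width and background competes against the single-emitter fit through
a likelihood-ratio test, so overlapping photon events can be separated.

All fitted models use parameters (x0, y0, I, sigma, b): sub-pixel centre in
pixel-span coordinates, integrated intensity (photoelectrons), symmetric PSF
SD (px, bounded to [0.3, 3] and fitted unless frozen), constant background
per pixel. Optimisation is L-BFGS-B with analytic gradients.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .camera import CameraCalibration
from .detect import Candidate
from .errors import DegenerateInputError, OutOfBoundsError

__all__ = [
    "Localisation",
    "FitRegion",
    "extract_region",
    "fit_gaussian_mle",
    "fit_gaussian_ls",
    "fit_integrated_gaussian_wls",
    "localise_radial_symmetry",
    "localise_local_centroid",
    "fit_multi",
    "remove_duplicates",
    "filter_intensity",
    "localisations_to_dataframe",
    "write_localisations",
]

log = logging.getLogger(__name__)

SIGMA_BOUNDS = (0.3, 3.0)
_MODEL_FLOOR = 1e-12  # Poisson model floor, keeps log finite


@dataclass(frozen=True)
class Localisation:
    """One sub-pixel event record."""

    x_px: float
    y_px: float
    intensity_pe: float
    sigma_px: float
    background_pe: float
    frame: int = 0
    method: str = ""
    loglik_or_sse: float = math.nan
    n_emitters: int = 1
    pixel_size_nm: float = 80.0

    @property
    def x_nm(self) -> float:
        return self.x_px * self.pixel_size_nm

    @property
    def y_nm(self) -> float:
        return self.y_px * self.pixel_size_nm

    @property
    def sigma_nm(self) -> float:
        return self.sigma_px * self.pixel_size_nm


@dataclass(frozen=True)
class FitRegion:
    """Square fitting window cut from a photoelectron frame.

    ``patch[py, px]`` corresponds to frame pixel ``(ox + px, oy + py)``;
    a patch-local coordinate c maps to the frame as ``c + origin``.
    """

    patch: np.ndarray
    origin: tuple[int, int]  # (ox, oy) top-left pixel indices
    radius: int
    frame: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.patch, dtype=np.float64)
        if p.ndim != 2 or p.size == 0:
            raise DegenerateInputError("fit region patch must be a non-empty 2D array")
        object.__setattr__(self, "patch", p)


def extract_region(
    frame_pe: np.ndarray, candidate: Candidate, radius: int
) -> FitRegion:
    """Cut a (2r+1)-square window centred on a candidate, clipped at borders."""
    h, w = frame_pe.shape
    if not (0 <= candidate.cx < w and 0 <= candidate.cy < h):
        raise OutOfBoundsError(
            f"candidate ({candidate.cx}, {candidate.cy}) outside {w}x{h} frame"
        )
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    x0 = max(candidate.cx - radius, 0)
    x1 = min(candidate.cx + radius + 1, w)
    y0 = max(candidate.cy - radius, 0)
    y1 = min(candidate.cy + radius + 1, h)
    return FitRegion(
        patch=frame_pe[y0:y1, x0:x1].copy(),
        origin=(x0, y0),
        radius=radius,
        frame=candidate.frame,
    )


# ---------------------------------------------------------------------------
# Gaussian models: per-axis profile and its derivatives

def _sampled_axis(coords: np.ndarray, c: float, s: float):
    """Point-sampled normalised Gaussian on pixel centres: value, d/dc, d/ds."""
    z = (coords - c) / s
    g = np.exp(-0.5 * z * z) / (math.sqrt(2 * math.pi) * s)
    dg_dc = g * z / s
    dg_ds = g * (z * z - 1.0) / s
    return g, dg_dc, dg_ds


def _integrated_axis(edges_lo: np.ndarray, c: float, s: float):
    """Pixel-integrated Gaussian (difference of error functions): value and
    derivatives with respect to centre and SD."""
    a = (edges_lo - c) / s
    b = (edges_lo + 1.0 - c) / s
    g = stats.norm.cdf(b) - stats.norm.cdf(a)
    pa = stats.norm.pdf(a)
    pb = stats.norm.pdf(b)
    dg_dc = (pa - pb) / s
    dg_ds = (a * pa - b * pb) / s
    return g, dg_dc, dg_ds


def _axis_profiles(nx: int, ny: int, x0: float, y0: float, s: float, model: str):
    if model == "sampled":
        gx, dgx_dc, dgx_ds = _sampled_axis(np.arange(nx) + 0.5, x0, s)
        gy, dgy_dc, dgy_ds = _sampled_axis(np.arange(ny) + 0.5, y0, s)
    else:
        gx, dgx_dc, dgx_ds = _integrated_axis(np.arange(nx, dtype=float), x0, s)
        gy, dgy_dc, dgy_ds = _integrated_axis(np.arange(ny, dtype=float), y0, s)
    return (gx, dgx_dc, dgx_ds), (gy, dgy_dc, dgy_ds)


def _init_centroid(patch: np.ndarray) -> tuple[float, float]:
    """Min-subtracted centroid for initialisation; patch centre if flat."""
    w = patch - patch.min()
    t = w.sum()
    ny, nx = patch.shape
    if t <= 0:
        return nx / 2.0, ny / 2.0
    xs = np.arange(nx) + 0.5
    ys = np.arange(ny) + 0.5
    return float((w.sum(axis=0) * xs).sum() / t), float((w.sum(axis=1) * ys).sum() / t)


def _fit_single(
    patch: np.ndarray,
    model: Literal["sampled", "integrated"],
    objective: Literal["poisson", "ls", "wls"],
    init_sd: float,
    fix_sd: bool = False,
):
    """Shared 5-parameter single-emitter fit core.

    Returns (x0, y0, I, sigma, b, objective_value) or None when the fit is
    rejected (non-convergence or degenerate intensity).
    """
    d = np.maximum(np.asarray(patch, dtype=np.float64), 0.0)
    ny, nx = d.shape
    if objective == "wls":
        wts = 1.0 / np.maximum(d, 1.0)
    x_init, y_init = _init_centroid(d)
    b0 = float(d.min())
    i0 = max(float(d.sum() - b0 * d.size), 1.0)

    def objective_fn(p):
        x0, y0, intensity, s, b = p
        (gx, dgx, dsx), (gy, dgy, dsy) = _axis_profiles(nx, ny, x0, y0, s, model)
        m = b + intensity * np.outer(gy, gx)
        dm_dx = intensity * np.outer(gy, dgx)
        dm_dy = intensity * np.outer(dgy, gx)
        dm_di = np.outer(gy, gx)
        dm_ds = intensity * (np.outer(gy, dsx) + np.outer(dsy, gx))
        if objective == "poisson":
            m = np.maximum(m, _MODEL_FLOOR)
            f = float(np.sum(m - d * np.log(m)))
            w = 1.0 - d / m
        elif objective == "ls":
            r = d - m
            f = float(np.sum(r * r))
            w = -2.0 * r
        else:  # wls
            r = d - m
            f = float(np.sum(wts * r * r))
            w = -2.0 * wts * r
        grad = np.array(
            [
                np.sum(w * dm_dx),
                np.sum(w * dm_dy),
                np.sum(w * dm_di),
                np.sum(w * dm_ds),
                np.sum(w),
            ]
        )
        return f, grad

    p0 = np.array([x_init, y_init, i0, init_sd, max(b0, 1e-6)])
    sd_lo, sd_hi = (init_sd, init_sd) if fix_sd else SIGMA_BOUNDS
    bounds = [(0.0, nx), (0.0, ny), (1e-6, None), (sd_lo, sd_hi), (0.0, None)]
    res = optimize.minimize(
        objective_fn,
        p0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
    )
    x0, y0, intensity, s, b = res.x
    if not np.isfinite(res.fun) or intensity < 1.0:
        return None
    return float(x0), float(y0), float(intensity), float(s), float(b), float(res.fun)


def _make_localisation(
    region: FitRegion,
    fit: tuple,
    method: str,
    pixel_size_nm: float,
    n_emitters: int = 1,
) -> Localisation:
    x0, y0, intensity, s, b, obj = fit
    ox, oy = region.origin
    return Localisation(
        x_px=x0 + ox,
        y_px=y0 + oy,
        intensity_pe=intensity,
        sigma_px=s,
        background_pe=b,
        frame=region.frame,
        method=method,
        loglik_or_sse=obj,
        n_emitters=n_emitters,
        pixel_size_nm=pixel_size_nm,
    )


def fit_gaussian_mle(
    region: FitRegion,
    init_sd: float = 1.0,
    pixel_size_nm: float = 80.0,
    fix_sd: bool = False,
) -> Localisation | None:
    """Poisson maximum-likelihood fit of a point-sampled symmetric Gaussian.

    Maximises sum(d ln m - m) over the model m = b + I G(x0, y0, sigma).
    ``init_sd`` seeds the fitted width (the "SD = 1.0 px" setting); pass
    ``fix_sd=True`` to freeze it. Returns None for rejected fits.
    """
    fit = _fit_single(region.patch, "sampled", "poisson", init_sd, fix_sd)
    if fit is None:
        return None
    return _make_localisation(region, fit, "ml_gaussian", pixel_size_nm)


def fit_gaussian_ls(
    region: FitRegion,
    init_sd: float = 1.0,
    pixel_size_nm: float = 80.0,
    fix_sd: bool = False,
) -> Localisation | None:
    """Least-squares fit of the point-sampled Gaussian (same parameterisation
    as the MLE, minimising the sum of squared residuals)."""
    fit = _fit_single(region.patch, "sampled", "ls", init_sd, fix_sd)
    if fit is None:
        return None
    return _make_localisation(region, fit, "ls_gaussian", pixel_size_nm)


def fit_integrated_gaussian_wls(
    region: FitRegion,
    init_sd: float = 1.6,
    pixel_size_nm: float = 80.0,
    fix_sd: bool = False,
) -> Localisation | None:
    """Weighted least squares with the pixel-integrated Gaussian PSF.

    The model integrates the Gaussian over each pixel's area (per-axis
    difference of error functions); weights are 1/max(d, 1), the inverse
    Poisson variance estimate.
    """
    fit = _fit_single(region.patch, "integrated", "wls", init_sd, fix_sd)
    if fit is None:
        return None
    return _make_localisation(region, fit, "wls_integrated_gaussian", pixel_size_nm)


def localise_radial_symmetry(region: FitRegion) -> tuple[float, float]:
    """Non-iterative radial-symmetry centre estimate (frame coordinates).

    Intensity gradients are computed on the half-pixel corner lattice; the
    centre is the least-squares point minimising the perpendicular distance
    to the lines through each lattice point along its gradient, weighted by
    squared gradient magnitude. Falls back to the patch centre (with a
    warning) when the gradient field vanishes.
    """
    p = region.patch
    if p.shape[0] < 3 or p.shape[1] < 3:
        raise DegenerateInputError("radial symmetry needs at least a 3x3 patch")
    # corner lattice point (k+1, l+1) sits between rows k,k+1 and cols l,l+1
    gx = 0.5 * ((p[:-1, 1:] + p[1:, 1:]) - (p[:-1, :-1] + p[1:, :-1]))
    gy = 0.5 * ((p[1:, :-1] + p[1:, 1:]) - (p[:-1, :-1] + p[:-1, 1:]))
    w = gx * gx + gy * gy
    ox, oy = region.origin
    if w.sum() <= 0:
        warnings.warn("zero gradient field in radial-symmetry patch")
        return (ox + p.shape[1] / 2.0, oy + p.shape[0] / 2.0)
    ny, nx = gx.shape
    px = np.arange(1, nx + 1, dtype=float)[None, :] * np.ones((ny, 1))
    py = np.arange(1, ny + 1, dtype=float)[:, None] * np.ones((1, nx))
    # accumulate A c = rhs with A = sum w (I - g g^T), projector per point
    norm = np.maximum(w, 1e-300)
    nxx = gx * gx / norm  # unit-gradient outer products
    nyy = gy * gy / norm
    nxy = gx * gy / norm
    a11 = np.sum(w * (1.0 - nxx))
    a22 = np.sum(w * (1.0 - nyy))
    a12 = np.sum(w * (-nxy))
    r1 = np.sum(w * ((1.0 - nxx) * px - nxy * py))
    r2 = np.sum(w * (-nxy * px + (1.0 - nyy) * py))
    det = a11 * a22 - a12 * a12
    if abs(det) < 1e-12 * max(a11, a22, 1e-300):
        warnings.warn("degenerate gradient geometry in radial-symmetry patch")
        return (ox + p.shape[1] / 2.0, oy + p.shape[0] / 2.0)
    cx = (a22 * r1 - a12 * r2) / det
    cy = (a11 * r2 - a12 * r1) / det
    return (float(cx + ox), float(cy + oy))


def localise_local_centroid(region: FitRegion) -> tuple[float, float]:
    """Background-subtracted centre of mass of the patch (frame coordinates).

    The background estimate is the patch minimum; weights are the values
    above it. An all-equal patch is degenerate.
    """
    p = region.patch
    if p.sum() <= 0:
        raise DegenerateInputError("local centroid needs a positive patch sum")
    w = p - p.min()
    t = w.sum()
    if t <= 0:
        raise DegenerateInputError("all-equal patch: centroid undefined")
    ny, nx = p.shape
    xs = np.arange(nx) + 0.5
    ys = np.arange(ny) + 0.5
    ox, oy = region.origin
    return (
        float((w.sum(axis=0) * xs).sum() / t + ox),
        float((w.sum(axis=1) * ys).sum() / t + oy),
    )


# ---------------------------------------------------------------------------
# Multi-emitter fitting analysis

def _fit_two_emitters(patch: np.ndarray, seed_fit: tuple, init_sd: float):
    """8-parameter Poisson MLE: two sampled Gaussians sharing sigma and b.

    Parameters (x1, y1, I1, x2, y2, I2, sigma, b); the second emitter starts
    at the brightest residual pixel of the single-emitter fit.
    """
    d = np.maximum(np.asarray(patch, dtype=np.float64), 0.0)
    ny, nx = d.shape
    x1, y1, i1, s1, b1, _ = seed_fit
    (gx, _, _), (gy, _, _) = _axis_profiles(nx, ny, x1, y1, s1, "sampled")
    resid = d - (b1 + i1 * np.outer(gy, gx))
    ry, rx = np.unravel_index(np.argmax(resid), resid.shape)
    x2, y2 = rx + 0.5, ry + 0.5
    i2 = max(float(np.clip(resid, 0.0, None).sum()), 1.0)

    def objective_fn(p):
        xa, ya, ia, xb, yb, ib, s, b = p
        (gxa, dgxa, dsxa), (gya, dgya, dsya) = _axis_profiles(nx, ny, xa, ya, s, "sampled")
        (gxb, dgxb, dsxb), (gyb, dgyb, dsyb) = _axis_profiles(nx, ny, xb, yb, s, "sampled")
        ga = np.outer(gya, gxa)
        gb = np.outer(gyb, gxb)
        m = np.maximum(b + ia * ga + ib * gb, _MODEL_FLOOR)
        f = float(np.sum(m - d * np.log(m)))
        w = 1.0 - d / m
        grad = np.array(
            [
                np.sum(w * ia * np.outer(gya, dgxa)),
                np.sum(w * ia * np.outer(dgya, gxa)),
                np.sum(w * ga),
                np.sum(w * ib * np.outer(gyb, dgxb)),
                np.sum(w * ib * np.outer(dgyb, gxb)),
                np.sum(w * gb),
                np.sum(
                    w
                    * (
                        ia * (np.outer(gya, dsxa) + np.outer(dsya, gxa))
                        + ib * (np.outer(gyb, dsxb) + np.outer(dsyb, gxb))
                    )
                ),
                np.sum(w),
            ]
        )
        return f, grad

    p0 = np.array([x1, y1, max(i1, 1.0), x2, y2, i2, s1, max(b1, 1e-6)])
    bounds = [
        (0.0, nx), (0.0, ny), (1e-6, None),
        (0.0, nx), (0.0, ny), (1e-6, None),
        SIGMA_BOUNDS, (0.0, None),
    ]
    res = optimize.minimize(
        objective_fn, p0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not (res.success or res.status == 1) or not np.isfinite(res.fun):
        return None
    return res.x, float(res.fun)


def fit_multi(
    region: FitRegion,
    max_emitters: int = 2,
    p_threshold: float = 1e-6,
    init_sd: float = 1.0,
    pixel_size_nm: float = 80.0,
) -> list[Localisation]:
    """Multi-emitter fitting analysis for one region.

    Fits the single-emitter Poisson MLE and, when ``max_emitters == 2``, a
    two-emitter model with shared width and background. The richer model is
    selected iff the likelihood-ratio statistic 2*(logL2 - logL1) exceeds
    the chi-square quantile for 3 degrees of freedom (the added x2, y2, I2)
    at ``p_threshold``. A non-convergent two-emitter fit falls back to the
    single fit. With ``max_emitters == 1`` the result is exactly the
    single-emitter MLE.
    """
    if max_emitters not in (1, 2):
        raise ValueError(f"max_emitters must be 1 or 2, got {max_emitters}")
    single = _fit_single(region.patch, "sampled", "poisson", init_sd)
    if single is None:
        return []
    loc1 = _make_localisation(region, single, "ml_gaussian", pixel_size_nm)
    if max_emitters == 1:
        return [loc1]
    two = _fit_two_emitters(region.patch, single, init_sd)
    if two is None:
        return [loc1]
    params, nll2 = two
    nll1 = single[5]
    lrt = 2.0 * (nll1 - nll2)  # = 2 (logL2 - logL1); data-only terms cancel
    crit = stats.chi2.ppf(1.0 - p_threshold, df=3)
    if lrt <= crit:
        return [loc1]
    xa, ya, ia, xb, yb, ib, s, b = params
    ox, oy = region.origin
    out = []
    for (xx, yy, ii) in ((xa, ya, ia), (xb, yb, ib)):
        out.append(
            Localisation(
                x_px=float(xx + ox),
                y_px=float(yy + oy),
                intensity_pe=float(ii),
                sigma_px=float(s),
                background_pe=float(b),
                frame=region.frame,
                method="ml_gaussian_mfa",
                loglik_or_sse=nll2,
                n_emitters=2,
                pixel_size_nm=pixel_size_nm,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Post-processing

def remove_duplicates(
    locs: Sequence[Localisation], distance_nm: float = 160.0
) -> list[Localisation]:
    """Greedy per-frame duplicate removal, keeping the brighter record.

    Localisations are visited in descending intensity (ties broken by frame,
    x, y for determinism); each is kept iff no already-kept localisation of
    the same frame lies closer than ``distance_nm``.
    """
    order = sorted(
        range(len(locs)),
        key=lambda i: (-locs[i].intensity_pe, locs[i].frame, locs[i].x_px, locs[i].y_px),
    )
    kept_by_frame: dict[int, list[tuple[float, float]]] = {}
    kept_ids: set[int] = set()
    for i in order:
        loc = locs[i]
        pts = kept_by_frame.setdefault(loc.frame, [])
        x, y = loc.x_nm, loc.y_nm
        if all((x - px) ** 2 + (y - py) ** 2 >= distance_nm**2 for px, py in pts):
            pts.append((x, y))
            kept_ids.add(i)
    return [loc for i, loc in enumerate(locs) if i in kept_ids]


def filter_intensity(
    locs: Sequence[Localisation], min_pe: float
) -> list[Localisation]:
    """Keep localisations with intensity strictly greater than ``min_pe``."""
    return [loc for loc in locs if loc.intensity_pe > min_pe]


# ---------------------------------------------------------------------------
# Tables

_COLUMNS = [
    "frame", "x_nm", "y_nm", "sigma_nm", "intensity_pe",
    "background_pe", "method", "n_emitters", "objective",
]


def localisations_to_dataframe(locs: Sequence[Localisation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": [l.frame for l in locs],
            "x_nm": [l.x_nm for l in locs],
            "y_nm": [l.y_nm for l in locs],
            "sigma_nm": [l.sigma_nm for l in locs],
            "intensity_pe": [l.intensity_pe for l in locs],
            "background_pe": [l.background_pe for l in locs],
            "method": [l.method for l in locs],
            "n_emitters": [l.n_emitters for l in locs],
            "objective": [l.loglik_or_sse for l in locs],
        },
        columns=_COLUMNS,
    )


def write_localisations(path: str | Path, locs: Sequence[Localisation]) -> None:
    localisations_to_dataframe(locs).to_csv(path, index=False)


def read_localisations(
    path: str | Path, calibration: CameraCalibration | None = None
) -> list[Localisation]:
    """Read a localisation table back; positions are converted from nm using
    the table's own pixel size if a calibration is given, else 80 nm/px."""
    pixel = (calibration or CameraCalibration()).pixel_size_nm
    df = pd.read_csv(path)
    return [
        Localisation(
            x_px=float(r.x_nm) / pixel,
            y_px=float(r.y_nm) / pixel,
            intensity_pe=float(r.intensity_pe),
            sigma_px=float(r.sigma_nm) / pixel,
            background_pe=float(r.background_pe),
            frame=int(r.frame),
            method=str(r.method),
            loglik_or_sse=float(r.objective),
            n_emitters=int(r.n_emitters),
            pixel_size_nm=pixel,
        )
        for r in df.itertuples()
    ]
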
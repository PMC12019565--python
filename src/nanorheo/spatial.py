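"""Diffusivity maps, lipid-phase classification and spatial statistics.

Builds gridded diffusion-coefficient and topography maps from processed
force curves, labels liquid-ordered (L_O, taller and slower) versus
liquid-disordered (L_D) phases from the height histogram, and quantifies
spatial structure of the diffusivity with the spatial lag

    Y_SL,i = sum_j w_ij * v_j

over a contiguity neighbourhood, and the global Moran autocorrelation
statistic

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = v - mean(v),

with one-sided permutation inference (E[I] = -1/(n-1) under the null).
Values are z-scored within each lipid phase before lag/Moran analysis, so
that the between-phase mean difference does not masquerade as short-range
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, sparse

__all__ = [
    "DiffusivityMap",
    "SpatialWeights",
    "MoranResult",
    "SpatialError",
    "build_map",
    "classify_phases",
    "contiguity_weights",
    "spatial_lag",
    "morans_I",
    "per_phase_moran",
    "sigmoid_profile_fit",
    "SigmoidFit",
]

LO, LD, EXCLUDED = "LO", "LD", "excluded"


class SpatialError(RuntimeError):
    """Raised for undefined spatial statistics or malformed maps."""


@dataclass
class DiffusivityMap:
    """Gridded diffusion coefficient with topography and phase labels."""

    d: np.ndarray                  # (rows, cols), m^2/s, NaN where invalid
    height: np.ndarray             # (rows, cols), m
    pixel_size: float              # m
    phase: np.ndarray | None = None  # (rows, cols) of {"LO","LD","excluded"}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if self.d.shape != self.height.shape:
            raise ValueError("D and height grids must be congruent")
        if self.phase is not None and np.asarray(self.phase).shape != self.d.shape:
            raise ValueError("phase grid must be congruent with D")

    @property
    def valid(self) -> np.ndarray:
        v = np.isfinite(self.d) & (self.d > 0)
        if self.phase is not None:
            v &= np.asarray(self.phase) != EXCLUDED
        return v

    @property
    def d_um2_s(self) -> np.ndarray:
        """Diffusivity in reporting units (um^2/s)."""
        return self.d * 1e12


@dataclass
class SpatialWeights:
    """Row-standardized contiguity weights on a pixel grid.

    ``w`` is sparse with w_ii = 0 and rows summing to 1 for pixels with at
    least one neighbour; ``adjacency`` is the symmetric binary graph before
    standardization; ``isolated`` flags valid pixels with no neighbours;
    ``pixel_index`` maps matrix rows back to flat grid positions.
    """

    w: sparse.csr_matrix
    adjacency: sparse.csr_matrix
    isolated: np.ndarray
    pixel_index: np.ndarray
    scheme: str
    within_phase: bool


@dataclass
class MoranResult:
    """Moran's I with permutation inference."""

    i: float
    expected_i: float              # -1/(n-1)
    p_value: float                 # one-sided (greater) unless noted
    n: int                         # non-isolated observations
    y_sl: np.ndarray               # spatial lag per non-isolated pixel
    pixel_index: np.ndarray        # flat grid index per entry of y_sl
    permutations: int
    seed: int | None
    alternative: str = "greater"
    perm_mean: float = float("nan")
    perm_sd: float = float("nan")


# ---------------------------------------------------------------------------
# map building and phase labels
# ---------------------------------------------------------------------------


def build_map(
    processed_grid,
    pixel_size: float,
    mode: Literal["band", "plateau"] = "band",
    band: tuple[float, float] = (1.5e-9, 2.5e-9),
    height: np.ndarray | None = None,
) -> DiffusivityMap:
    """Assemble a DiffusivityMap from a rectangular grid of processed curves.

    Per-pixel D is either the mean of the valid D(dh) points with
    indentation inside ``band`` (default 2.0 +/- 0.5 nm) or the plateau
    estimate.  Pixels whose curve failed (no valid points in band, or no
    plateau) are masked NaN.  ``height`` defaults to the contact height
    ``z_contact`` per pixel (topography up to the scanner frame).
    """
    grid = np.asarray(processed_grid, dtype=object)
    if grid.ndim != 2:
        raise SpatialError("processed curves must form a rectangular 2-D grid")
    rows, cols = grid.shape
    d = np.full((rows, cols), np.nan)
    h = np.zeros((rows, cols))
    n_failed = 0
    for r in range(rows):
        for c in range(cols):
            p = grid[r, c]
            if p is None:
                n_failed += 1
                continue
            h[r, c] = p.z_contact
            if mode == "plateau":
                val = p.d_plateau
                if np.isfinite(val):
                    d[r, c] = val
                else:
                    n_failed += 1
                continue
            sel = p.d_mask & (p.dh >= band[0]) & (p.dh <= band[1]) & np.isfinite(p.d)
            if sel.any():
                d[r, c] = float(np.mean(p.d[sel]))
            else:
                n_failed += 1
    if n_failed > 0.5 * rows * cols:
        warnings.warn(
            f"{n_failed}/{rows * cols} map pixels failed and are masked", stacklevel=2
        )
    if height is not None:
        h = np.asarray(height, dtype=float)
    return DiffusivityMap(d=d, height=h, pixel_size=pixel_size,
                          meta={"mode": mode, "band": band, "n_failed": n_failed})


def classify_phases(
    height: np.ndarray,
    threshold: float | None = None,
    min_separation_sigmas: float = 2.0,
) -> np.ndarray:
    """Label pixels L_O / L_D from the topography histogram.

    Splits the height distribution at the Otsu (between-class variance
    maximizing) threshold; the higher mode is the liquid-ordered phase.  A
    manual ``threshold`` overrides.  If the two classes are separated by
    less than ``min_separation_sigmas`` pooled within-class standard
    deviations the histogram is treated as unimodal: everything is labelled
    L_D with a warning.
    """
    from skimage.filters import threshold_otsu

    h = np.asarray(height, dtype=float)
    finite = np.isfinite(h)
    labels = np.full(h.shape, LD, dtype=object)
    labels[~finite] = EXCLUDED
    vals = h[finite]
    if vals.size == 0:
        return labels
    if np.ptp(vals) == 0:
        warnings.warn("constant height map: single-phase labelling", stacklevel=2)
        return labels
    thr = float(threshold) if threshold is not None else float(threshold_otsu(vals))
    hi = finite & (h > thr)
    lo = finite & (h <= thr)
    if threshold is None:
        mu_hi, mu_lo = h[hi].mean() if hi.any() else np.nan, h[lo].mean() if lo.any() else np.nan
        sd = np.sqrt(
            np.nanmean([
                np.var(h[hi]) if hi.sum() > 1 else np.nan,
                np.var(h[lo]) if lo.sum() > 1 else np.nan,
            ])
        )
        if not hi.any() or not lo.any() or (
            sd > 0 and (mu_hi - mu_lo) < min_separation_sigmas * sd
        ):
            warnings.warn(
                "height histogram not resolvably bimodal: single-phase labelling",
                stacklevel=2,
            )
            return labels
    labels[hi] = LO
    return labels


# ---------------------------------------------------------------------------
# weights, lag, Moran
# ---------------------------------------------------------------------------

_ROOK = ((-1, 0), (1, 0), (0, -1), (0, 1))
_QUEEN = _ROOK + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def contiguity_weights(
    shape: tuple[int, int],
    scheme: Literal["rook", "queen"] = "queen",
    valid: np.ndarray | None = None,
    phase: np.ndarray | None = None,
    within_phase: bool = False,
) -> SpatialWeights:
    """Row-standardized contiguity weights on a grid.

    ``valid`` masks pixels out of the graph entirely; with
    ``within_phase=True`` edges crossing a phase boundary are removed.
    Pixels left without neighbours are flagged isolated (and excluded from
    downstream statistics).
    """
    rows, cols = shape
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    offsets = _ROOK if scheme == "rook" else _QUEEN
    if scheme not in ("rook", "queen"):
        raise ValueError(f"unknown scheme {scheme!r}")
    flat = np.arange(rows * cols).reshape(shape)
    src, dst = [], []
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        a = flat[r0:r1, c0:c1]
        b = flat[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = valid[r0:r1, c0:c1] & valid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        if within_phase and phase is not None:
            ph = np.asarray(phase)
            ok &= ph[r0:r1, c0:c1] == ph[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        src.append(a[ok])
        dst.append(b[ok])
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    pixel_index = np.flatnonzero(valid.ravel())
    remap = -np.ones(rows * cols, dtype=int)
    remap[pixel_index] = np.arange(len(pixel_index))
    n = len(pixel_index)
    adj = sparse.csr_matrix(
        (np.ones(len(src)), (remap[src], remap[dst])), shape=(n, n)
    )
    adj.data[:] = 1.0  # duplicate-proof binary adjacency
    degree = np.asarray(adj.sum(axis=1)).ravel()
    isolated = degree == 0
    inv = np.where(degree > 0, 1.0 / np.maximum(degree, 1), 0.0)
    w = sparse.diags(inv) @ adj
    return SpatialWeights(
        w=w.tocsr(), adjacency=adj, isolated=isolated, pixel_index=pixel_index,
        scheme=scheme, within_phase=within_phase,
    )


def spatial_lag(values: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Spatial lag Y_SL,i = sum_j w_ij v_j for non-isolated pixels (NaN on
    isolated rows)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.shape[0] == weights.w.shape[0]:
        vv = v
    else:
        vv = v[weights.pixel_index]
    if weights.isolated.all():
        raise SpatialError("all pixels are isolated: spatial lag undefined")
    lag = weights.w @ vv
    lag[weights.isolated] = np.nan
    return lag


def _moran_stat(z: np.ndarray, w: sparse.csr_matrix, s0: float) -> float:
    return float(len(z) / s0 * (z @ (w @ z)) / (z @ z))


def morans_I(
    values: np.ndarray,
    weights: SpatialWeights,
    permutations: int = 9999,
    seed: int | None = 0,
    alternative: Literal["greater", "two-sided"] = "greater",
) -> MoranResult:
    """Global Moran's I with permutation inference.

    Isolated pixels are dropped; the permutation null randomly relabels the
    remaining values over the remaining locations,
    p = (#{I_perm >= I_obs} + 1)/(N + 1) for the one-sided (greater)
    alternative.
    """
    v = np.asarray(values, dtype=float).ravel()
    vv = v if v.shape[0] == weights.w.shape[0] else v[weights.pixel_index]
    keep = ~weights.isolated & np.isfinite(vv)
    n = int(keep.sum())
    if n < 10:
        raise SpatialError(f"only {n} non-isolated pixels; need >= 10")
    w = weights.w[keep][:, keep]
    # re-standardize rows in case finite-masking removed neighbours
    deg = np.asarray(w.sum(axis=1)).ravel()
    inner = deg > 0
    if not inner.all():
        w = w[inner][:, inner]
        keep_idx = np.flatnonzero(keep)[inner]
        keep = np.zeros_like(keep)
        keep[keep_idx] = True
        n = int(inner.sum())
        if n < 10:
            raise SpatialError(f"only {n} connected pixels after masking; need >= 10")
        deg = np.asarray(w.sum(axis=1)).ravel()
    w = sparse.diags(1.0 / deg) @ w
    w = w.tocsr()
    x = vv[keep]
    if np.ptp(x) == 0:
        raise SpatialError("zero variance: Moran's I undefined")
    z = x - x.mean()
    s0 = float(w.sum())
    i_obs = _moran_stat(z, w, s0)
    lag = np.asarray(w @ x)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    if permutations > 0:
        perm = np.empty(permutations)
        batch = max(1, min(permutations, int(2e7 // max(n, 1))))
        done = 0
        while done < permutations:
            b = min(batch, permutations - done)
            zp = rng.permuted(np.broadcast_to(z, (b, n)).copy(), axis=1)
            num = np.einsum("bi,bi->b", zp, (w @ zp.T).T)
            perm[done:done + b] = n / s0 * num / (z @ z)
            done += b
        if alternative == "greater":
            p = (np.sum(perm >= i_obs) + 1.0) / (permutations + 1.0)
        else:
            dev = np.abs(perm - expected)
            p = (np.sum(dev >= abs(i_obs - expected)) + 1.0) / (permutations + 1.0)
        pm, ps = float(perm.mean()), float(perm.std())
    else:
        p, pm, ps = float("nan"), float("nan"), float("nan")
    return MoranResult(
        i=i_obs, expected_i=expected, p_value=float(p), n=n, y_sl=lag,
        pixel_index=weights.pixel_index[keep], permutations=permutations,
        seed=seed, alternative=alternative, perm_mean=pm, perm_sd=ps,
    )


def _zscore_within_phase(dmap: DiffusivityMap) -> np.ndarray:
    """Z-score the diffusivity within each lipid phase (the 'normalised
    diffusion coefficient'); returns a flat array aligned with the grid."""
    v = dmap.d.ravel().astype(float).copy()
    phase = (np.asarray(dmap.phase) if dmap.phase is not None
             else np.full(dmap.d.shape, LD, dtype=object)).ravel()
    valid = dmap.valid.ravel()
    out = np.full_like(v, np.nan)
    for ph in (LO, LD):
        sel = valid & (phase == ph)
        if sel.sum() < 2:
            continue
        mu, sd = v[sel].mean(), v[sel].std()
        out[sel] = (v[sel] - mu) / sd if sd > 0 else 0.0
    return out


def per_phase_moran(
    dmap: DiffusivityMap,
    scheme: Literal["rook", "queen"] = "queen",
    permutations: int = 9999,
    seed: int | None = 0,
    min_pixels: int = 10,
) -> dict[str, MoranResult]:
    """Moran analysis per lipid phase plus the whole map.

    Diffusivities are z-scored within phase throughout.  Per-phase results
    use within-phase weights (edges across domain boundaries removed);
    the whole-map result keeps all edges between valid pixels.  Phases with
    fewer than ``min_pixels`` connected pixels are skipped with a warning.
    """
    if dmap.phase is None:
        raise SpatialError("phase labels required; run classify_phases first")
    phase = np.asarray(dmap.phase)
    zv = _zscore_within_phase(dmap)
    results: dict[str, MoranResult] = {}
    valid_all = dmap.valid & np.isfinite(zv.reshape(dmap.d.shape))
    w_all = contiguity_weights(dmap.d.shape, scheme, valid=valid_all)
    results["all"] = morans_I(zv[w_all.pixel_index], w_all,
                              permutations=permutations, seed=seed)
    for ph in (LO, LD):
        sel = valid_all & (phase == ph)
        if sel.sum() < min_pixels:
            warnings.warn(f"phase {ph}: fewer than {min_pixels} pixels, skipped",
                          stacklevel=2)
            continue
        w_ph = contiguity_weights(dmap.d.shape, scheme, valid=sel,
                                  phase=phase, within_phase=True)
        try:
            results[ph] = morans_I(zv[w_ph.pixel_index], w_ph,
                                   permutations=permutations, seed=seed)
        except SpatialError as exc:
            warnings.warn(f"phase {ph} skipped: {exc}", stacklevel=2)
    return results


# ---------------------------------------------------------------------------
# transect sigmoid fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmoidFit:
    """Four-parameter logistic fit D(x) = a + (b-a)/(1+exp(-(x-x0)/w))."""

    lower: float
    upper: float
    midpoint: float
    width: float
    stderr: dict[str, float]
    residual_sd: float
    degenerate: bool = False

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.lower + (self.upper - self.lower) / (
            1.0 + np.exp(-(x - self.midpoint) / self.width)
        )


def sigmoid_profile_fit(positions, d_values, sigma=None) -> SigmoidFit:
    """Fit a four-parameter logistic to diffusivity along a transect.

    Positions in metres (or any consistent unit), D in m^2/s.  When
    per-point measurement uncertainties ``sigma`` are supplied (e.g. the sd
    over repeat curves at each location) they weight the fit and the
    parameter covariance is taken at face value; otherwise the covariance
    is scaled by the residual variance.  Raises SpatialError on
    non-convergence; warns and flags ``degenerate`` when the fitted step is
    indistinguishable from flat data.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(d_values, dtype=float)
    if len(x) < 5:
        raise SpatialError("need >= 5 points spanning the transition")
    span = float(np.ptp(x))
    yspan = float(np.ptp(y))
    if yspan == 0:
        warnings.warn("constant transect: degenerate sigmoid fit", stacklevel=2)
        return SigmoidFit(float(y[0]), float(y[0]), float(np.median(x)), span / 4,
                          {k: float("nan") for k in ("lower", "upper", "midpoint", "width")},
                          0.0, degenerate=True)

    def logistic(x, a, b, x0, w):
        return a + (b - a) / (1.0 + np.exp(-np.clip((x - x0) / w, -500, 500)))

    # fit in normalized coordinates: nm-scale positions and 1e-12-scale
    # diffusivities defeat the optimizer's default step control otherwise
    yscale = float(np.max(np.abs(y))) or 1.0
    xn = (x - x.min()) / span
    yn = y / yscale
    increasing = np.polyfit(xn, yn, 1)[0] >= 0
    p0 = [float(yn.min()), float(yn.max()), 0.5, 1 / 8]
    if not increasing:
        p0[0], p0[1] = p0[1], p0[0]
    sig = None if sigma is None else np.asarray(sigma, dtype=float) / yscale
    try:
        popt, pcov = optimize.curve_fit(
            logistic, xn, yn, p0=p0, maxfev=20000,
            sigma=sig, absolute_sigma=sigma is not None,
            bounds=([-np.inf, -np.inf, -1.0, 1e-6], [np.inf, np.inf, 2.0, np.inf]),
        )
    except RuntimeError as exc:
        raise SpatialError(f"sigmoid fit did not converge: {exc}") from exc
    perr = np.sqrt(np.abs(np.diag(pcov)))
    resid = (yn - logistic(xn, *popt)) * yscale
    rsd = float(np.std(resid))
    a, b = float(popt[0] * yscale), float(popt[1] * yscale)
    x0 = float(x.min() + popt[2] * span)
    w = float(popt[3] * span)
    perr = perr * np.array([yscale, yscale, span, span])
    degenerate = abs(b - a) < 2.0 * rsd
    if degenerate:
        warnings.warn("sigmoid fit is degenerate (step below residual noise)",
                      stacklevel=2)
    return SigmoidFit(
        lower=a, upper=b, midpoint=x0, width=w,
        stderr=dict(zip(("lower", "upper", "midpoint", "width"), map(float, perr))),
        residual_sd=rsd, degenerate=degenerate,
    )
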
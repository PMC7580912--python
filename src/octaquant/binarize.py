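"""Binarization thresholding for en-face angiograms.

The central routine is :func:`compute_vld_threshold`, which picks a single
binarization value for an eye from its deep-plexus slab: sweep integer
thresholds, count skeletonized vessel pixels at each, and locate where the
count curve transitions from a steep decline (noise being removed) to a
shallow plateau (true vessel signal).  The transition is found by an
exhaustive two-segment least-squares fit over the declining limb of the
curve, and the threshold is the crossing point of the two fitted lines.
The same value is then used to binarize all plexus slabs of that eye.

Two classical histogram thresholders (arithmetic-mean and Huang's fuzzy
minimization) are provided as comparators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import (
    FitDegenerateError,
    FitInvalidError,
    NoThresholdError,
    ParameterError,
)
from .image_io import EnFaceImage

__all__ = [
    "ThresholdCurve",
    "PiecewiseFit",
    "ThresholdResult",
    "binarize",
    "skeletonize",
    "sweep_vld_curve",
    "fit_two_segment",
    "compute_vld_threshold",
    "mean_threshold",
    "huang_threshold",
]

#: Default fraction of the sweep's upper bound past which the curve is not
#: fitted (beyond it, vessels themselves vanish and the curve falls again).
DEFAULT_FIT_UPPER_FRAC = 0.9

#: Default minimum number of points each fitted segment must contain.
DEFAULT_MIN_SEGMENT = 10


@dataclass(frozen=True)
class ThresholdCurve:
    """Skeleton pixel count as a function of candidate threshold."""

    thresholds: np.ndarray  # ascending integers
    vld_counts: np.ndarray  # skeleton pixel counts, same length

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds)
        c = np.asarray(self.vld_counts)
        if t.shape != c.shape or t.ndim != 1:
            raise ParameterError("thresholds and counts must be equal-length 1D")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ParameterError("thresholds must be strictly ascending")
        if np.any(c < 0):
            raise ParameterError("counts must be non-negative")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "vld_counts", c)


@dataclass(frozen=True)
class PiecewiseFit:
    """Two-segment least-squares fit of the declining curve limb.

    ``noise_line`` is the steep segment (noise removal), ``signal_line``
    the shallow plateau segment; ``intersection_x`` is where they cross.
    """

    breakpoint: int
    noise_line: Tuple[float, float]  # (slope, intercept)
    signal_line: Tuple[float, float]
    intersection_x: float
    total_sse: float
    fit_range: Tuple[int, int] = (0, 0)  # thresholds actually fitted


@dataclass(frozen=True)
class ThresholdResult:
    threshold: int
    curve: ThresholdCurve
    fit: PiecewiseFit


def binarize(img: EnFaceImage, t: int) -> np.ndarray:
    """Foreground iff raw intensity >= t."""
    if not (0 <= t <= img.intensity_max):
        raise ParameterError(
            f"threshold {t} outside intensity range [0, {img.intensity_max}]"
        )
    return img.pixels >= t


def _simple_point_lut() -> np.ndarray:
    """256-entry table: neighborhood bit pattern -> centre pixel is simple.

    A foreground pixel is simple (deletable without changing topology) iff
    its 8-neighborhood foreground forms exactly one 8-connected component
    and its 4-adjacent background forms exactly one 4-connected background
    component.  Neighbor bit order: (dy, dx) scanned row-major around the
    centre, i.e. NW, N, NE, W, E, SW, S, SE.
    """
    from scipy import ndimage as _ndi

    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    lut = np.zeros(256, dtype=bool)
    for code in range(256):
        patch = np.zeros((3, 3), dtype=bool)
        for i, (dy, dx) in enumerate(offsets):
            patch[dy + 1, dx + 1] = bool((code >> i) & 1)
        n_nb = int(patch.sum())
        if n_nb == 0 or n_nb == 8:
            continue  # isolated or interior point: never deletable
        _, n_fg = _ndi.label(patch, structure=np.ones((3, 3)))
        bg = ~patch
        bg[1, 1] = False  # centre is not part of its own background
        bg_labels, _ = _ndi.label(bg, structure=cross)
        touching = {bg_labels[0, 1], bg_labels[1, 0], bg_labels[1, 2], bg_labels[2, 1]}
        touching.discard(0)
        lut[code] = n_fg == 1 and len(touching) == 1
    return lut


_SIMPLE_LUT = _simple_point_lut()
_NB_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_code(padded: np.ndarray, r: int, c: int) -> int:
    code = 0
    for i, (dy, dx) in enumerate(_NB_OFFSETS):
        if padded[r + dy, c + dx]:
            code |= 1 << i
    return code


def _has_block(skel: np.ndarray) -> bool:
    return bool((skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]).any())


def _block_members(skel: np.ndarray) -> np.ndarray:
    """Mask of pixels belonging to at least one fully-foreground 2x2 block."""
    blk = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
    members = np.zeros_like(skel)
    members[:-1, :-1] |= blk
    members[1:, :-1] |= blk
    members[:-1, 1:] |= blk
    members[1:, 1:] |= blk
    return members


def _simple_deletion_pass(skel: np.ndarray) -> bool:
    """Delete simple points out of 2x2 blocks, one 4-subfield sweep.

    Candidates in the same subfield are never 8-adjacent, so none of them
    sits in another's neighborhood: deleting them together equals
    deleting them one by one, each still simple at its turn, which
    preserves topology.  Returns True if anything was deleted.
    """
    changed = False
    for pr in (0, 1):
        for pc in (0, 1):
            rs, cs = np.nonzero(_block_members(skel))
            if rs.size == 0:
                return changed
            sel = (rs % 2 == pr) & (cs % 2 == pc)
            rs, cs = rs[sel], cs[sel]
            if rs.size == 0:
                continue
            padded = np.pad(skel, 1)
            codes = np.zeros(rs.size, dtype=np.uint16)
            for i, (dy, dx) in enumerate(_NB_OFFSETS):
                codes |= padded[rs + 1 + dy, cs + 1 + dx].astype(np.uint16) << i
            simple = _SIMPLE_LUT[codes]
            if simple.any():
                skel[rs[simple], cs[simple]] = False
                changed = True
    return changed


_EIGHT = np.ones((3, 3), dtype=int)
_WINDOW_RADIUS = 3


def _fg_neighbors(skel: np.ndarray, r: int, c: int):
    h, w = skel.shape
    return [
        (r + dy, c + dx)
        for dy, dx in _NB_OFFSETS
        if 0 <= r + dy < h and 0 <= c + dx < w and skel[r + dy, c + dx]
    ]


def _window_connected(skel: np.ndarray, points, clear=(), set_=()) -> bool:
    """True if all ``points`` share one component in a local window.

    The window spans ``_WINDOW_RADIUS`` around the points' bounding box;
    ``clear``/``set_`` are applied to the window copy first.  A local
    path is also a global path, so a True answer certifies global
    connectivity; False is merely inconclusive (conservative).
    """
    from scipy import ndimage as _ndi

    pts = list(points)
    if len(pts) <= 1:
        return True
    h, w = skel.shape
    rs = [p[0] for p in pts] + [p[0] for p in clear] + [p[0] for p in set_]
    cs = [p[1] for p in pts] + [p[1] for p in clear] + [p[1] for p in set_]
    r0, r1 = max(min(rs) - _WINDOW_RADIUS, 0), min(max(rs) + _WINDOW_RADIUS + 1, h)
    c0, c1 = max(min(cs) - _WINDOW_RADIUS, 0), min(max(cs) + _WINDOW_RADIUS + 1, w)
    win = skel[r0:r1, c0:c1].copy()
    for r, c in clear:
        win[r - r0, c - c0] = False
    for r, c in set_:
        win[r - r0, c - c0] = True
    labels, _ = _ndi.label(win, structure=_EIGHT)
    ids = {labels[r - r0, c - c0] for r, c in pts}
    return 0 not in ids and len(ids) == 1


def _rewrite_stuck_blocks(skel: np.ndarray, support: np.ndarray) -> bool:
    """Resolve blocks whose pixels all fail the 3x3 simple-point test.

    Two window-verified moves are tried for each block corner ``p``:
    plain deletion (valid when p's neighbors re-connect within a local
    window — the 3x3 test is conservative), and shifting ``p`` onto an
    adjacent ``support`` pixel ``q`` that re-routes a diagonal branch
    around the block (the X-crossing case).  A move is kept only when
    the local window proves the foreground component structure is
    unchanged.  Returns True if anything was rewritten.
    """
    changed = False
    blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
    h, w = skel.shape
    for r, c in zip(*np.nonzero(blocks)):
        if not (skel[r, c] and skel[r + 1, c] and skel[r, c + 1] and skel[r + 1, c + 1]):
            continue  # already altered by an earlier rewrite
        done = False
        for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
            rr, cc = r + dr, c + dc
            nbrs = _fg_neighbors(skel, rr, cc)
            # window-verified plain deletion
            if _window_connected(skel, nbrs, clear=[(rr, cc)]):
                skel[rr, cc] = False
                changed = done = True
                break
            # window-verified shift toward the outward diagonal branch
            dy, dx = (1 if dr else -1), (1 if dc else -1)
            for qr, qc in ((rr + dy, cc), (rr, cc + dx)):
                if not (0 <= qr < h and 0 <= qc < w):
                    continue
                if skel[qr, qc] or not support[qr, qc]:
                    continue
                q_nbrs = [p for p in _fg_neighbors(skel, qr, qc) if p != (rr, cc)]
                no_merge = _window_connected(skel, q_nbrs, clear=[(rr, cc)])
                reroute = _window_connected(
                    skel, nbrs + [(qr, qc)], clear=[(rr, cc)], set_=[(qr, qc)]
                )
                if no_merge and reroute:
                    skel[rr, cc] = False
                    skel[qr, qc] = True
                    changed = done = True
                    break
            if done:
                break
    return changed


def _rewrite_stuck_blocks_global(skel: np.ndarray, support: np.ndarray) -> bool:
    """Last-resort rewrite verified by a global component count.

    Same moves as :func:`_rewrite_stuck_blocks`, but a candidate move is
    validated by relabelling the whole image, which accepts re-routes
    whose connectivity runs outside the local window.  Expensive, so
    only reached for blocks the window-verified pass could not resolve.
    """
    from scipy import ndimage as _ndi

    n_before = _ndi.label(skel, structure=_EIGHT)[1]
    changed = False
    blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
    h, w = skel.shape
    for r, c in zip(*np.nonzero(blocks)):
        if not (skel[r, c] and skel[r + 1, c] and skel[r, c + 1] and skel[r + 1, c + 1]):
            continue
        done = False
        for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
            rr, cc = r + dr, c + dc
            skel[rr, cc] = False  # plain deletion attempt
            if _ndi.label(skel, structure=_EIGHT)[1] == n_before:
                changed = done = True
                break
            skel[rr, cc] = True
            dy, dx = (1 if dr else -1), (1 if dc else -1)
            for qr, qc in ((rr + dy, cc), (rr, cc + dx)):
                if not (0 <= qr < h and 0 <= qc < w):
                    continue
                if skel[qr, qc] or not support[qr, qc]:
                    continue
                skel[rr, cc] = False
                skel[qr, qc] = True
                if _ndi.label(skel, structure=_EIGHT)[1] == n_before:
                    changed = done = True
                    break
                skel[rr, cc] = True
                skel[qr, qc] = False
            if done:
                break
    return changed


def _remove_2x2_blocks(skel: np.ndarray, support: Optional[np.ndarray] = None) -> np.ndarray:
    """Eliminate fully-foreground 2x2 blocks without changing topology.

    Simple-point deletion handles almost every block; irreducible
    X-crossings are re-routed through ``support`` (the binary map being
    skeletonized), first with cheap window-local verification, then with
    a global fallback.  A block that admits no topology-preserving move
    at all is left in place: removing it would necessarily split a
    component.
    """
    skel = skel.copy()
    for _ in range(16):  # blocks are rare; a few passes always suffice
        if not _has_block(skel):
            return skel
        if _simple_deletion_pass(skel):
            continue
        if support is None:
            break
        if _rewrite_stuck_blocks(skel, support):
            continue
        if not _rewrite_stuck_blocks_global(skel, support):
            break
    return skel


def skeletonize(binary: np.ndarray) -> np.ndarray:
    """Topology-preserving 2D thinning to 1-pixel-wide centerlines.

    Zhang-Suen-class thinning followed by a simple-point cleanup that
    guarantees no fully-foreground 2x2 block survives while leaving the
    connected-component structure untouched.
    """
    binary = np.asarray(binary, dtype=bool)
    return _remove_2x2_blocks(_sk_skeletonize(binary), support=binary)


def sweep_vld_curve(
    dcp: EnFaceImage, t_min: int = 1, t_max: Optional[int] = None
) -> ThresholdCurve:
    """Skeleton pixel count of ``binarize(dcp, t)`` for every integer t.

    Counts are taken over the full image extent (not the parafovea).  The
    default sweep runs from 1 to the intensity maximum minus one in unit
    steps, the finest grid available.
    """
    if t_max is None:
        t_max = dcp.intensity_max - 1
    if not (0 <= t_min < t_max <= dcp.intensity_max):
        raise ParameterError(f"degenerate sweep range [{t_min}, {t_max}]")
    thresholds = np.arange(t_min, t_max + 1, dtype=int)
    counts = np.empty(len(thresholds), dtype=int)
    px = dcp.pixels
    # Successive binary maps are nested, so two thresholds with the same
    # foreground count yield identical maps; reuse the skeleton count.
    hist = np.bincount(px.ravel(), minlength=dcp.intensity_max + 1)
    fg_from = np.concatenate([np.cumsum(hist[::-1])[::-1], [0]])
    prev_fg = -1
    prev_count = 0
    for i, t in enumerate(thresholds):
        n_fg = int(fg_from[t])
        if n_fg != prev_fg:
            prev_count = int(skeletonize(px >= t).sum())
            prev_fg = n_fg
        counts[i] = prev_count
    return ThresholdCurve(thresholds=thresholds, vld_counts=counts)


def _ols_line(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, sse)."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        # vertical stack of points; treat as flat line through the mean
        return 0.0, float(ym), float(((y - ym) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (slope * x + intercept)
    return slope, intercept, float((resid**2).sum())


def _smooth(y: np.ndarray, width: int = 5) -> np.ndarray:
    half = width // 2
    padded = np.pad(y, half, mode="edge")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


def _find_fit_window(
    y: np.ndarray, min_decline: float = 0.05, rise_tol: float = 0.08
) -> Tuple[int, int]:
    """Locate the declining limb [start, end) of the count-vs-threshold curve.

    The curve is non-monotone at both extremes: a fully-foreground image
    thins to almost nothing, and once the threshold erodes the vessels
    themselves the fragmenting remnants can spike the count again.  The
    limb of interest is therefore the FIRST peak of the smoothed curve
    that declines by at least ``min_decline`` before being exceeded, and
    it ends just before the first sustained rise (more than ``rise_tol``
    above the running minimum) after that peak.
    """
    ys = _smooth(y)
    n = len(ys)
    peaks = [
        i
        for i in range(n)
        if (i == 0 or ys[i] >= ys[i - 1]) and (i == n - 1 or ys[i] >= ys[i + 1])
    ]
    start = None
    for i in peaks:
        run_min = ys[i]
        for j in range(i + 1, n):
            if ys[j] > ys[i]:
                break
            run_min = min(run_min, ys[j])
            if run_min <= (1.0 - min_decline) * ys[i]:
                start = i
                break
        if start is not None:
            break
    if start is None:
        start = int(np.argmax(ys))

    end = n
    run_min = ys[start]
    for j in range(start + 1, n):
        if ys[j] > run_min * (1.0 + rise_tol):
            end = j
            break
        run_min = min(run_min, ys[j])
    return start, end


def fit_two_segment(
    curve: ThresholdCurve,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    fit_upper_frac: float = DEFAULT_FIT_UPPER_FRAC,
    parallel_rtol: float = 1e-6,
) -> PiecewiseFit:
    """Exhaustive two-segment least-squares fit of the declining limb.

    The fitted domain is the declining limb located by
    :func:`_find_fit_window` (first substantial peak up to the first
    sustained rise), additionally capped at ``fit_upper_frac`` times the
    top of the sweep, past which vessels themselves disappear.  Every
    admissible breakpoint ``b`` (each side holding at least
    ``min_segment`` points) splits the domain into [start, b] and
    (b, end]; ordinary least squares is fitted to each side and the
    breakpoint minimizing the summed SSE is returned, ties resolved
    toward the larger breakpoint.

    Raises
    ------
    ParameterError
        If the fitting window holds fewer than ``2 * min_segment`` points.
    FitDegenerateError
        If the two best-fit lines are (near-)parallel.
    FitInvalidError
        If the crossing abscissa falls outside the fitted range.
    """
    if min_segment < 2:
        raise ParameterError("min_segment must be at least 2")
    x_all = curve.thresholds.astype(float)
    y_all = curve.vld_counts.astype(float)

    start, end = _find_fit_window(y_all)
    upper = fit_upper_frac * x_all[-1]
    end = min(end, int(np.searchsorted(x_all, upper, side="right")))
    x = x_all[start:end]
    y = y_all[start:end]
    if len(x) < 2 * min_segment:
        raise ParameterError(
            f"fitting window has {len(x)} points; need >= {2 * min_segment}"
        )

    best: Optional[tuple] = None  # (sse, break_idx, line1, line2)
    for ib in range(min_segment - 1, len(x) - min_segment):
        m1, c1, sse1 = _ols_line(x[: ib + 1], y[: ib + 1])
        m2, c2, sse2 = _ols_line(x[ib + 1 :], y[ib + 1 :])
        sse = sse1 + sse2
        if best is None or sse < best[0] - 1e-12 or (
            abs(sse - best[0]) <= 1e-12 and ib > best[1]
        ):
            best = (sse, ib, (m1, c1), (m2, c2))

    sse, ib, noise_line, signal_line = best
    m1, c1 = noise_line
    m2, c2 = signal_line
    scale = max(abs(m1), abs(m2), 1.0)
    if abs(m1 - m2) <= parallel_rtol * scale:
        raise FitDegenerateError(
            f"segments near-parallel (slopes {m1:.4g}, {m2:.4g})"
        )
    ix = (c2 - c1) / (m1 - m2)
    if not (x[0] <= ix <= x[-1]):
        raise FitInvalidError(
            f"intersection {ix:.2f} outside fitted range [{x[0]:.0f}, {x[-1]:.0f}]"
        )
    return PiecewiseFit(
        breakpoint=int(x[ib]),
        noise_line=noise_line,
        signal_line=signal_line,
        intersection_x=float(ix),
        total_sse=float(sse),
        fit_range=(int(x[0]), int(x[-1])),
    )


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else int(math.ceil(v - 0.5))


def compute_vld_threshold(
    dcp: EnFaceImage,
    t_min: int = 1,
    t_max: Optional[int] = None,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    fit_upper_frac: float = DEFAULT_FIT_UPPER_FRAC,
) -> ThresholdResult:
    """Derive the eye's binarization threshold from its deep-plexus slab.

    The returned threshold is the two-line crossing abscissa rounded to
    the nearest integer (ties away from zero) and clamped to the sweep
    bounds; it is intended to binarize all layers of the same eye.
    """
    if dcp.plexus is not None and dcp.plexus.value != "DCP":
        warnings.warn(
            f"threshold derivation is defined on the DCP slab; got {dcp.plexus.value}",
            stacklevel=2,
        )
    curve = sweep_vld_curve(dcp, t_min=t_min, t_max=t_max)
    fit = fit_two_segment(curve, min_segment=min_segment, fit_upper_frac=fit_upper_frac)
    t = _round_half_away(fit.intersection_x)
    lo, hi = int(curve.thresholds[0]), int(curve.thresholds[-1])
    if t < lo or t > hi:
        warnings.warn(f"threshold {t} clamped to sweep bounds [{lo}, {hi}]", stacklevel=2)
        t = min(max(t, lo), hi)
    return ThresholdResult(threshold=t, curve=curve, fit=fit)


def mean_threshold(img: EnFaceImage) -> int:
    """Arithmetic mean of all intensities, rounded to the nearest integer."""
    return _round_half_away(float(img.pixels.mean()))


def huang_threshold(img: EnFaceImage) -> int:
    """Huang-Wang fuzzy thresholding: minimize histogram fuzziness.

    For each candidate t the image is split into background (< t) and
    foreground (>= t); each pixel's membership to its side's mean grey
    level is u = 1 / (1 + |g - mu| / C) with C the grey-level range, and
    the Shannon entropy of the memberships, summed over the histogram, is
    the fuzziness.  The candidate minimizing it is returned (exhaustive
    search; first minimum on ties).
    """
    hist = np.bincount(img.pixels.ravel(), minlength=img.intensity_max + 1).astype(float)
    nz = np.nonzero(hist)[0]
    if len(nz) < 2:
        raise NoThresholdError("constant image has no Huang threshold")
    first, last = int(nz[0]), int(nz[-1])
    c_range = float(last - first)
    g = np.arange(len(hist), dtype=float)

    cum_n = np.cumsum(hist)
    cum_g = np.cumsum(hist * g)
    tot_n, tot_g = cum_n[-1], cum_g[-1]

    best_t, best_e = None, np.inf
    for t in range(first + 1, last + 1):
        n0, g0 = cum_n[t - 1], cum_g[t - 1]
        n1, g1 = tot_n - n0, tot_g - g0
        mu0 = g0 / n0
        mu1 = g1 / n1
        u = np.empty_like(g)
        u[:t] = 1.0 / (1.0 + np.abs(g[:t] - mu0) / c_range)
        u[t:] = 1.0 / (1.0 + np.abs(g[t:] - mu1) / c_range)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        s[~np.isfinite(s)] = 0.0  # u == 1 contributes zero entropy
        e = float((hist * s).sum())
        if e < best_e - 1e-15:
            best_e, best_t = e, t
    return int(best_t)
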
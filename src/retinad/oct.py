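"""Graph-based OCT retinal segmentation and thickness measurement.

The segmentation follows the classic graph formulation for layered
tissue: each pixel is a node, adjacent columns are connected with
8-neighbourhood edges whose weights favour strong vertical intensity
gradients of a given polarity, and a boundary is the minimum-cumulative-
weight path crossing the image from the left margin to the right margin
(zero-cost phantom start/end columns, so the end rows are free).  Edge
weights use

    w(a, b) = 2 - (g_a + g_b) + w_min

with ``g`` the column-normalized vertical gradient in [0, 1] and
``w_min = 1e-5`` a small positive stabilizer.

Three interfaces are traced sequentially — ILM (dark-to-light), RPE base
(light-to-dark, searched below the ILM), and the INL/OPL interface
(light-to-dark, restricted strictly between them) — and the retina is
split into the inner (ILM to INL/OPL) and outer (INL/OPL to RPE base)
compound layers.  Per-eye thickness is the mean over five B-scans, with
the optic-nerve-head columns excluded; layer reflectance is normalized
to an RPE band to cancel per-scan gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    CorrectionBudgetWarning,
    InvalidParameterError,
    LowContrastWarning,
    PartialSummaryWarning,
    SegmentationError,
)
from .types import BoundarySet, BScan, ThicknessResult

W_MIN = 1e-5
#: Rows to skip below/above an already-found boundary when searching the next.
DEFAULT_GUARD_PX = 2
#: Fraction of central columns excluded from thickness averaging when the
#: B-scan does not carry an explicit ONH interval.
DEFAULT_ONH_FRAC = 0.10
#: Height (px) of the RPE reference band used for intensity normalization.
DEFAULT_RPE_BAND_PX = 3
#: Manual-correction budget: fraction of columns above which a warning fires.
CORRECTION_BUDGET = 0.05


def _vertical_gradient(image: np.ndarray) -> np.ndarray:
    """Signed derivative along the axial (row) axis, central differences."""
    return np.gradient(image.astype(float), axis=0)


def gradient_map(
    bscan: BScan | np.ndarray,
    polarity: str = "dark-to-light",
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Column-normalized vertical gradient in [0, 1] for one polarity.

    ``dark-to-light`` responds to intensity increasing with depth (e.g.
    the vitreous/ILM transition), ``light-to-dark`` to the opposite
    (e.g. the RPE base).  ``mask`` optionally restricts normalization to
    a search region; pixels outside it get gradient 0.
    """
    image = bscan.image if isinstance(bscan, BScan) else np.asarray(bscan, float)
    if polarity not in ("dark-to-light", "light-to-dark"):
        raise InvalidParameterError(f"unknown polarity {polarity!r}")
    g = _vertical_gradient(image)
    if polarity == "light-to-dark":
        g = -g
    if mask is not None:
        g = np.where(mask, g, np.nan)
    with np.errstate(invalid="ignore"):
        lo = np.nanmin(g, axis=0, keepdims=True)
        hi = np.nanmax(g, axis=0, keepdims=True)
        span = hi - lo
        flat = ~np.isfinite(span) | (span <= 0)
        norm = np.where(flat, 0.0, (g - lo) / np.where(span > 0, span, 1.0))
    norm = np.nan_to_num(norm, nan=0.0)
    if np.all(flat):
        warnings.warn(
            "image has no vertical contrast; gradient map is uniform",
            LowContrastWarning,
            stacklevel=2,
        )
    return norm


def trace_boundary(
    weights: np.ndarray, allowed: np.ndarray | None = None
) -> np.ndarray:
    """Minimum-weight left-to-right boundary through a gradient map.

    ``weights`` is the column-normalized gradient map (higher = more
    boundary-like).  The path visits exactly one row per column, moving
    at most one row between adjacent columns (8-connectivity), with
    free choice of start and end rows (phantom zero-cost margins).  Edge
    cost between consecutive pixels a, b is ``2 - (g_a + g_b) + w_min``.
    Ties prefer the smaller row index; the result is deterministic.

    ``allowed`` optionally masks rows available to the path (per pixel);
    a column with no allowed row raises :class:`SegmentationError`.
    """
    g = np.asarray(weights, dtype=float)
    if g.ndim != 2 or min(g.shape) < 2:
        raise InvalidParameterError("weight matrix must be 2-D, at least 2x2")
    H, W = g.shape
    if allowed is not None:
        allowed = np.asarray(allowed, bool)
        if allowed.shape != g.shape:
            raise InvalidParameterError("allowed mask shape mismatch")
        if not np.all(allowed.any(axis=0)):
            raise SegmentationError("search region empty in some column")
    INF = np.inf
    # f[r] = best cost of reaching row r in the previous column, minus the
    # previous column's own gradient term (factored edge weight).
    cost = np.zeros(H) if allowed is None else np.where(allowed[:, 0], 0.0, INF)
    pred = np.zeros((H, W), dtype=np.int32)
    for cidx in range(1, W):
        f = cost - g[:, cidx - 1]
        up = np.full(H, INF)
        down = np.full(H, INF)
        up[1:] = f[:-1]  # predecessor r-1
        down[:-1] = f[1:]  # predecessor r+1
        stacked = np.vstack([up, f, down])  # order encodes the row tie-break
        choice = np.argmin(stacked, axis=0)
        best = stacked[choice, np.arange(H)]
        cost = best + 2.0 + W_MIN - g[:, cidx]
        pred[:, cidx] = np.arange(H) + (choice - 1)
        if allowed is not None:
            cost = np.where(allowed[:, cidx], cost, INF)
    end = int(np.argmin(cost))  # argmin takes the smallest row on ties
    if not np.isfinite(cost[end]):
        raise SegmentationError("no admissible path through the search region")
    path = np.empty(W, dtype=np.int64)
    path[-1] = end
    for cidx in range(W - 1, 0, -1):
        path[cidx - 1] = pred[path[cidx], cidx]
    return path


def _subpixel_refine(path: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Parabolic vertex through the gradient at (r-1, r, r+1), clipped to ±0.5."""
    H = grad.shape[0]
    out = path.astype(float)
    for c, r in enumerate(path):
        if 0 < r < H - 1:
            gm, g0, gp = grad[r - 1, c], grad[r, c], grad[r + 1, c]
            denom = gm - 2.0 * g0 + gp
            if denom < 0:
                out[c] = r + float(np.clip(0.5 * (gm - gp) / denom, -0.5, 0.5))
    return out


def segment_retina(
    bscan: BScan,
    guard_px: int = DEFAULT_GUARD_PX,
    subpixel: bool = False,
) -> BoundarySet:
    """Trace ILM, RPE base and the INL/OPL interface of one B-scan.

    Sequential search: the ILM over the whole image (dark-to-light),
    then the RPE base below it (light-to-dark; on a retinal B-scan the
    brightest light-to-dark transition), then the INL/OPL interface in
    the region strictly between the two, each with a ``guard_px`` band.
    """
    image = bscan.image
    if np.ptp(image) <= 0:
        raise SegmentationError("constant image cannot be segmented")
    H, W = image.shape
    rows = np.arange(H)[:, None]

    g_ilm = gradient_map(bscan, "dark-to-light")
    ilm = trace_boundary(g_ilm)

    below_ilm = rows > (ilm[None, :] + guard_px)
    if not np.all(below_ilm.any(axis=0)):
        raise SegmentationError("no room below ILM to search for the RPE base")
    g_rpe = gradient_map(bscan, "light-to-dark", mask=below_ilm)
    rpe = trace_boundary(g_rpe, allowed=below_ilm)

    between = (rows > ilm[None, :] + guard_px) & (rows < rpe[None, :] - guard_px)
    if not np.all(between.any(axis=0)):
        raise SegmentationError(
            "no room between ILM and RPE base to search for the INL/OPL interface"
        )
    g_inl = gradient_map(bscan, "light-to-dark", mask=between)
    inl = trace_boundary(g_inl, allowed=between)

    if subpixel:
        ilm_f = _subpixel_refine(ilm, g_ilm)
        rpe_f = _subpixel_refine(rpe, g_rpe)
        inl_f = _subpixel_refine(inl, g_inl)
    else:
        ilm_f, inl_f, rpe_f = ilm.astype(float), inl.astype(float), rpe.astype(float)

    try:
        return BoundarySet(ilm=ilm_f, inl_opl=inl_f, rpe_base=rpe_f)
    except InvalidParameterError as exc:
        raise SegmentationError(f"boundary ordering violated: {exc}") from exc


def apply_corrections(
    boundaries: BoundarySet,
    corrections: list[tuple[str, slice | tuple[int, int], np.ndarray | float]],
    image_height: int | None = None,
) -> BoundarySet:
    """Overwrite boundary positions with manual corrections.

    Each correction is ``(boundary_name, column range, new positions)``
    with boundary_name one of ``ilm``, ``inl_opl``, ``rpe_base`` and the
    column range a slice or ``(start, stop)`` pair.  The corrected
    fraction (unique columns touched / width) is recorded; exceeding the
    5 % error budget raises a warning.  Corrections that break boundary
    ordering (or leave the image) are rejected with an explanation.
    """
    new = {
        "ilm": boundaries.ilm.copy(),
        "inl_opl": boundaries.inl_opl.copy(),
        "rpe_base": boundaries.rpe_base.copy(),
    }
    touched: set[int] = set()
    width = boundaries.width
    for name, cols, values in corrections:
        if name not in new:
            raise InvalidParameterError(f"unknown boundary {name!r}")
        sl = slice(*cols) if isinstance(cols, tuple) else cols
        idx = range(*sl.indices(width))
        vals = np.broadcast_to(np.asarray(values, float), (len(idx),))
        if np.any(vals < 0) or (
            image_height is not None and np.any(vals > image_height - 1)
        ):
            raise InvalidParameterError(
                f"correction of {name} at columns {sl} leaves the image"
            )
        new[name][sl] = vals
        touched.update(idx)
    try:
        result = BoundarySet(
            ilm=new["ilm"],
            inl_opl=new["inl_opl"],
            rpe_base=new["rpe_base"],
            corrected_fraction=len(touched) / width,
        )
    except InvalidParameterError as exc:
        raise InvalidParameterError(
            f"correction rejected, boundary ordering would break: {exc}"
        ) from exc
    if result.corrected_fraction > CORRECTION_BUDGET:
        warnings.warn(
            f"corrected fraction {result.corrected_fraction:.2%} exceeds the "
            f"{CORRECTION_BUDGET:.0%} segmentation error budget",
            CorrectionBudgetWarning,
            stacklevel=2,
        )
    return result


def _included_columns(bscan: BScan, onh_frac: float) -> np.ndarray:
    W = bscan.width
    keep = np.ones(W, dtype=bool)
    if bscan.onh_cols is not None:
        lo, hi = bscan.onh_cols
        keep[max(0, lo):min(W, hi)] = False
    elif onh_frac > 0:
        half = int(round(0.5 * onh_frac * W))
        centre = W // 2
        keep[max(0, centre - half):min(W, centre + half)] = False
    return keep


def thickness(
    boundaries: BoundarySet,
    bscan: BScan,
    onh_frac: float = DEFAULT_ONH_FRAC,
) -> tuple[float, float]:
    """(inner_um, outer_um): column-mean layer thickness × axial scale.

    Inner retina spans ILM→INL/OPL, outer retina INL/OPL→RPE base.
    Optic-nerve-head columns (``bscan.onh_cols`` or the central
    ``onh_frac`` of columns) are excluded from the averages.
    """
    keep = _included_columns(bscan, onh_frac)
    if not keep.any():
        raise InvalidParameterError("all columns excluded from thickness averaging")
    inner_px = boundaries.inl_opl[keep] - boundaries.ilm[keep]
    outer_px = boundaries.rpe_base[keep] - boundaries.inl_opl[keep]
    return (
        float(np.mean(inner_px) * bscan.axial_px_um),
        float(np.mean(outer_px) * bscan.axial_px_um),
    )


def normalize_intensity(
    bscan: BScan,
    boundaries: BoundarySet,
    rpe_band_px: int = DEFAULT_RPE_BAND_PX,
    onh_frac: float = DEFAULT_ONH_FRAC,
) -> tuple[float, float]:
    """Layer reflectance relative to the RPE band (unitless).

    Mean intensity of the inner (ILM→INL/OPL) and outer (INL/OPL→top of
    RPE band) layers divided by the mean intensity of a fixed-height
    strip directly above the RPE base, cancelling per-scan gain.
    """
    keep = _included_columns(bscan, onh_frac)
    rows = np.arange(bscan.height)[:, None]
    inner_m = (rows >= boundaries.ilm[None, :]) & (rows < boundaries.inl_opl[None, :])
    rpe_top = boundaries.rpe_base - rpe_band_px
    outer_m = (rows >= boundaries.inl_opl[None, :]) & (rows < rpe_top[None, :])
    rpe_m = (rows >= rpe_top[None, :]) & (rows < boundaries.rpe_base[None, :])
    for m in (inner_m, outer_m, rpe_m):
        m[:, ~keep] = False
    if not rpe_m.any() or not inner_m.any() or not outer_m.any():
        raise InvalidParameterError("empty layer band during intensity normalization")
    rpe_mean = float(bscan.image[rpe_m].mean())
    if rpe_mean <= 0:
        raise InvalidParameterError("RPE band intensity is zero; cannot normalize")
    return (
        float(bscan.image[inner_m].mean()) / rpe_mean,
        float(bscan.image[outer_m].mean()) / rpe_mean,
    )


@dataclass
class EyeOptions:
    guard_px: int = DEFAULT_GUARD_PX
    onh_frac: float = DEFAULT_ONH_FRAC
    rpe_band_px: int = DEFAULT_RPE_BAND_PX
    subpixel: bool = False


def summarize_eye(
    bscans: list[BScan], options: EyeOptions | None = None
) -> ThicknessResult:
    """Segment every B-scan of one eye and average the measurements.

    Nominally five scans 125 μm apart; any scan failing segmentation is
    dropped with a warning and the mean is taken over the successes.
    """
    if not bscans:
        raise InvalidParameterError("no B-scans supplied")
    opt = options or EyeOptions()
    inner, outer, n_in, n_out = [], [], [], []
    failures = 0
    for scan in bscans:
        try:
            bounds = segment_retina(scan, guard_px=opt.guard_px, subpixel=opt.subpixel)
            t_in, t_out = thickness(bounds, scan, onh_frac=opt.onh_frac)
            i_norm, o_norm = normalize_intensity(
                scan, bounds, rpe_band_px=opt.rpe_band_px, onh_frac=opt.onh_frac
            )
        except (SegmentationError, InvalidParameterError):
            failures += 1
            continue
        inner.append(t_in)
        outer.append(t_out)
        n_in.append(i_norm)
        n_out.append(o_norm)
    if not inner:
        raise SegmentationError("all B-scans of the eye failed segmentation")
    if failures:
        warnings.warn(
            f"{failures} of {len(bscans)} B-scans failed segmentation; "
            f"mean over {len(inner)}",
            PartialSummaryWarning,
            stacklevel=2,
        )
    return ThicknessResult(
        inner_um=float(np.mean(inner)),
        outer_um=float(np.mean(outer)),
        inner_norm_intensity=float(np.mean(n_in)),
        outer_norm_intensity=float(np.mean(n_out)),
        n_scans_used=len(inner),
    )
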
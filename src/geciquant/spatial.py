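"""ROI-level spatial quantification.

Trace extraction from movies, annulus neuropil estimation and the standard
``F - 0.7 * F_neuropil`` subtraction, neurite expression-decay fitting,
soma-to-neuropil ratio, IOU-based ROI matching across channels, labeling
density against a reference stain, and a minimal threshold segmenter used
where a full segmentation tool is not warranted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.optimize import curve_fit
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from geciquant.transients import Trace
from geciquant.scenes import Movie

__all__ = [
    "RoiMask",
    "MatchResult",
    "NeuriteProfile",
    "masks_from_label_image",
    "extract_trace",
    "neuropil_annulus_trace",
    "neuropil_correct",
    "fit_neurite_decay",
    "soma_neuropil_ratio",
    "iou",
    "match_rois",
    "labeling_density",
    "simple_segment",
]


@dataclass(frozen=True)
class RoiMask:
    """A labelled pixel mask for one ROI."""

    label: int
    pixels: frozenset[tuple[int, int]]  # (row, col)

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("RoiMask must be non-empty")
        object.__setattr__(self, "pixels", frozenset(self.pixels))

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid in pixel units (col, row order)."""
        arr = np.array(sorted(self.pixels), dtype=float)
        return float(arr[:, 1].mean()), float(arr[:, 0].mean())

    def centroid_um(self, pixel_size: float) -> tuple[float, float]:
        cx, cy = self.centroid
        return (cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size

    def to_bool(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        rc = np.array(sorted(self.pixels), dtype=int)
        out[rc[:, 0], rc[:, 1]] = True
        return out

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class MatchResult:
    """Cross-channel ROI matching outcome."""

    pairs: list[tuple[int, int, float]]  # (id_A, id_B, iou)
    unmatched_a: list[int]
    unmatched_b: list[int]


@dataclass(frozen=True)
class NeuriteProfile:
    """Fluorescence along a neurite, normalised to the soma value."""

    arclength: np.ndarray  # um from the soma edge
    intensity: np.ndarray  # a.u., ~1 at arclength 0

    def __post_init__(self) -> None:
        d = np.asarray(self.arclength, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "arclength", d)
        object.__setattr__(self, "intensity", i)
        if d.size != i.size:
            raise ValueError("arclength and intensity must match")
        if np.any(np.diff(d) <= 0):
            raise ValueError("arclength must be increasing")


def masks_from_label_image(labels: np.ndarray) -> list[RoiMask]:
    """Split a label image (0 = background) into RoiMask objects."""
    labels = np.asarray(labels)
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        out.append(RoiMask(label=int(lab), pixels=frozenset(zip(rows.tolist(), cols.tolist()))))
    return out


def _mask_index(mask: RoiMask) -> tuple[np.ndarray, np.ndarray]:
    rc = np.array(sorted(mask.pixels), dtype=int)
    return rc[:, 0], rc[:, 1]


def extract_trace(movie: Movie, mask: RoiMask, statistic: str = "mean") -> Trace:
    """Per-frame mean (or median) of the pixels within the mask."""
    rows, cols = _mask_index(mask)
    h, w = movie.frames.shape[1:]
    if rows.max() >= h or cols.max() >= w or rows.min() < 0 or cols.min() < 0:
        raise ValueError("mask exceeds frame bounds")
    px = movie.frames[:, rows, cols]
    if statistic == "mean":
        vals = px.mean(axis=1)
    elif statistic == "median":
        vals = np.median(px, axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return Trace(values=vals, frame_rate=movie.frame_rate)


def annulus_pixels(
    mask: RoiMask,
    shape: tuple[int, int],
    inner: float = 5.0,
    outer: float = 15.0,
    exclude: list[RoiMask] | None = None,
) -> np.ndarray:
    """Boolean image of the annulus around a ROI.

    The annulus is the set of pixels whose Euclidean distance to the nearest
    ROI pixel lies in ``(inner, outer]`` (pixels); pixels belonging to any
    mask in ``exclude`` (or to the ROI itself) are removed.
    """
    if inner >= outer:
        raise ValueError("annulus requires inner < outer")
    m = mask.to_bool(shape)
    dist = distance_transform_edt(~m)
    ring = (dist > inner) & (dist <= outer)
    if exclude:
        for other in exclude:
            if other.label == mask.label and other.pixels == mask.pixels:
                continue
            ring &= ~other.to_bool(shape)
    return ring


def neuropil_annulus_trace(
    movie: Movie,
    mask: RoiMask,
    inner: float = 5.0,
    outer: float = 15.0,
    exclude: list[RoiMask] | None = None,
) -> Trace:
    """Per-frame median over the neuropil annulus around a ROI.

    Standard neuropil estimate: a ring with inner radius 5 px and outer
    radius 15 px around the ROI, excluding pixels that belong to any other
    ROI.
    """
    ring = annulus_pixels(mask, movie.frames.shape[1:], inner, outer, exclude)
    if not ring.any():
        raise ValueError(
            "annulus empty after exclusions; increase the outer radius"
        )
    rows, cols = np.nonzero(ring)
    vals = np.median(movie.frames[:, rows, cols], axis=1)
    return Trace(values=vals, frame_rate=movie.frame_rate)


def neuropil_correct(f: Trace, f_neu: Trace, r: float = 0.7) -> Trace:
    """F_corrected = F_soma - r * F_neuropil (r = 0.7 by convention)."""
    if len(f) != len(f_neu):
        raise ValueError("trace length mismatch")
    return Trace(values=f.values - r * f_neu.values, frame_rate=f.frame_rate, t0=f.t0)


def fit_neurite_decay(profile: NeuriteProfile) -> tuple[float, float, float, bool]:
    """Fit I(d) = exp(-d/lambda) to a soma-normalised neurite profile.

    Returns ``(lambda_um, d_e_inv_um, r2, converged)`` where ``d_e_inv`` is
    the distance at which intensity drops to e^-1 (36.8%) of the soma value —
    identical to lambda for the exponential model. A non-decaying profile
    returns ``converged=False``.
    """
    d, y = profile.arclength, profile.intensity
    if d.size < 4:
        raise ValueError("need >= 4 profile points")
    if np.any(y <= 0):
        raise ValueError("intensities must be > 0")
    if y[-1] >= y[0] * (1.0 - 1e-9):
        return float("nan"), float("nan"), float("nan"), False

    def model(dd, lam):
        return np.exp(-dd / lam)

    lam0 = float(np.interp(np.exp(-1.0), y[::-1], d[::-1]))
    if not np.isfinite(lam0) or lam0 <= 0:
        lam0 = float(d[-1]) / 3.0
    try:
        popt, _ = curve_fit(model, d, y, p0=[lam0], bounds=(1e-9, np.inf), maxfev=10000)
    except RuntimeError:
        return float("nan"), float("nan"), float("nan"), False
    lam = float(popt[0])
    yfit = model(d, lam)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yfit) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return lam, lam, r2, True


def soma_neuropil_ratio(
    image: np.ndarray,
    soma_masks: list[RoiMask],
    neuropil_masks: list[RoiMask],
) -> float:
    """Mean intensity over soma pixels / mean intensity over neuropil pixels."""
    if not soma_masks or not neuropil_masks:
        raise ValueError("need non-empty soma and neuropil mask sets")
    image = np.asarray(image, dtype=float)
    soma_vals = np.concatenate([image[_mask_index(m)] for m in soma_masks])
    npil_vals = np.concatenate([image[_mask_index(m)] for m in neuropil_masks])
    npil_mean = float(np.mean(npil_vals))
    if npil_mean == 0.0:
        warnings.warn("zero neuropil mean; returning infinite ratio sentinel")
        return float("inf")
    return float(np.mean(soma_vals)) / npil_mean


def iou(a: RoiMask, b: RoiMask) -> float:
    """Intersection-over-union of two pixel masks, in [0, 1]."""
    inter = len(a.pixels & b.pixels)
    union = len(a.pixels | b.pixels)
    return inter / union


def match_rois(
    set_a: list[RoiMask],
    set_b: list[RoiMask],
    threshold: float = 0.5,
    strategy: str = "greedy",
) -> MatchResult:
    """Match ROIs across channels on IOU.

    Pairs with IOU >= ``threshold`` are candidates; ``greedy`` (default)
    repeatedly takes the highest-IOU available pair (ties broken by lower
    id_A then lower id_B), so each ROI joins at most one pair. ``optimal``
    instead maximises the summed IOU over a one-to-one assignment.
    """
    for name, s in (("A", set_a), ("B", set_b)):
        labs = [m.label for m in s]
        if len(labs) != len(set(labs)):
            raise ValueError(f"duplicate labels in set {name}")
    cands = []
    for ma in set_a:
        for mb in set_b:
            v = iou(ma, mb)
            if v >= threshold:
                cands.append((ma.label, mb.label, v))

    pairs: list[tuple[int, int, float]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    if strategy == "greedy":
        cands.sort(key=lambda c: (-c[2], c[0], c[1]))
        for a_id, b_id, v in cands:
            if a_id in used_a or b_id in used_b:
                continue
            pairs.append((a_id, b_id, v))
            used_a.add(a_id)
            used_b.add(b_id)
    elif strategy == "optimal":
        from scipy.optimize import linear_sum_assignment

        a_ids = sorted({c[0] for c in cands})
        b_ids = sorted({c[1] for c in cands})
        cost = np.zeros((len(a_ids), len(b_ids)))
        lut = {(c[0], c[1]): c[2] for c in cands}
        for i, ai in enumerate(a_ids):
            for j, bj in enumerate(b_ids):
                cost[i, j] = -lut.get((ai, bj), 0.0)
        ri, cj = linear_sum_assignment(cost)
        for i, j in zip(ri, cj):
            v = -cost[i, j]
            if v >= threshold:
                pairs.append((a_ids[i], b_ids[j], v))
                used_a.add(a_ids[i])
                used_b.add(b_ids[j])
        pairs.sort(key=lambda c: (-c[2], c[0], c[1]))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    return MatchResult(
        pairs=pairs,
        unmatched_a=[m.label for m in set_a if m.label not in used_a],
        unmatched_b=[m.label for m in set_b if m.label not in used_b],
    )


def labeling_density(
    geci_masks: list[RoiMask],
    reference_masks: list[RoiMask],
    image_shape: tuple[int, int] | None = None,
    iou_threshold: float = 0.25,
    edge_margin: int = 0,
) -> float:
    """Fraction of reference (e.g. Nissl-positive) ROIs with a GECI ROI.

    A reference ROI counts as labelled when some GECI ROI has IOU >=
    ``iou_threshold`` with it or has its centroid inside it. Reference ROIs
    touching the image edge (within ``edge_margin`` pixels, when
    ``image_shape`` is given) are removed before the ratio is computed.
    """
    refs = reference_masks
    if image_shape is not None and edge_margin >= 0:
        h, w = image_shape
        refs = [
            m
            for m in refs
            if all(
                edge_margin <= r < h - edge_margin and edge_margin <= c < w - edge_margin
                for r, c in m.pixels
            )
        ]
    if not refs:
        raise ValueError("reference mask set empty (after edge removal)")
    n_hit = 0
    for ref in refs:
        hit = False
        for g in geci_masks:
            if iou(ref, g) >= iou_threshold:
                hit = True
                break
            cx, cy = g.centroid
            if (int(round(cy)), int(round(cx))) in ref.pixels:
                hit = True
                break
        n_hit += hit
    return n_hit / len(refs)


def simple_segment(
    image: np.ndarray,
    smoothing_sigma: float = 1.0,
    threshold_rule: str | float = "otsu",
    min_area: int = 10,
    max_area: int | None = None,
) -> list[RoiMask]:
    """Minimal deterministic segmenter: smooth, threshold, label, area-filter.

    Intended for synthetic scenes and quick quality checks, not as a general
    cell-segmentation method.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("simple_segment expects a 2-D image")
    sm = gaussian(img, sigma=smoothing_sigma, preserve_range=True) if smoothing_sigma > 0 else img
    if threshold_rule == "otsu":
        if np.ptp(sm) == 0:
            return []
        thr = threshold_otsu(sm)
    else:
        thr = float(threshold_rule)
    binary = sm > thr
    labels = cc_label(binary)
    out = []
    next_id = 1
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        if max_area is not None and region.area > max_area:
            continue
        pixels = frozenset((int(r), int(c)) for r, c in region.coords)
        out.append(RoiMask(label=next_id, pixels=pixels))
        next_id += 1
    return out
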
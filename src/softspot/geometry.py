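"""Fruit geometry: segmentation, contour distance, H(r,d), sampling windows.

The apex-side view of a fruit on a black background segments trivially by
luminance.  Every in-fruit pixel gets a normalized contour distance
d = EDT(pixel) / max EDT, so d = 0 on the outer contour and d = 1 at the
deepest interior point (the apex for a disk).  Pooling per-pixel relevance
r against d over a cohort of fruits gives the 2-D histogram H(r, d), whose
high-r mass localises where in the fruit the classifier's evidence lives:
the apex band d in [0.75, 1] or the peripheral band d in [0, 0.1].

Sampling windows emulate tissue excision: the featured window is the
fully-interior square maximising mean relevance; the non-featured window
minimises it subject to a minimum separation from the featured one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "FruitMask",
    "DistanceMap",
    "RelevanceHistogram",
    "SampleRegion",
    "segment_fruit",
    "normalized_contour_distance",
    "relevance_histogram",
    "band_relevance_summary",
    "extract_featured_region",
    "extract_nonfeatured_region",
]

BANDS = {"periphery": (0.0, 0.1), "mid": (0.1, 0.75), "apex": (0.75, 1.0)}


@dataclass
class FruitMask:
    mask: np.ndarray  # H x W bool, single connected component
    contour: np.ndarray  # (n, 2) ordered (row, col) boundary pixels


@dataclass
class DistanceMap:
    d: np.ndarray  # H x W float; in [0, 1] on the mask, 0 elsewhere
    normalization: float  # max interior distance, px


@dataclass
class RelevanceHistogram:
    counts: np.ndarray  # n_r x n_d
    r_edges: np.ndarray
    d_edges: np.ndarray
    n_pixels: int


@dataclass
class SampleRegion:
    category: str  # RS-F / C-F / RS-NF
    row0: int
    col0: int
    side: int
    mean_relevance: float
    mean_d: float
    fruit_id: str = ""


def segment_fruit(image: np.ndarray, threshold: float = 0.1,
                  min_area: int = 64) -> FruitMask:
    """Luminance threshold -> morphological closing -> hole fill -> largest
    connected component."""
    lum = np.asarray(image, dtype=float).mean(axis=2) if image.ndim == 3 else np.asarray(image, dtype=float)
    raw = lum > threshold
    if not raw.any():
        raise ValueError("no fruit found: nothing above the luminance threshold")
    closed = ndimage.binary_closing(raw, structure=morphology.disk(3))
    filled = ndimage.binary_fill_holes(closed)
    lab, n = ndimage.label(filled)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    if sizes.max() < min_area:
        raise ValueError("no fruit found: largest component below minimum area")
    mask = lab == (1 + int(np.argmax(sizes)))
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    return FruitMask(mask, np.round(contour).astype(int))


def normalized_contour_distance(fruit: FruitMask) -> DistanceMap:
    """Euclidean distance transform to the background, scaled so the deepest
    interior pixel has d = 1."""
    mask = fruit.mask
    if not mask.any():
        raise ValueError("empty mask")
    edt = ndimage.distance_transform_edt(mask)
    dmax = float(edt.max())
    return DistanceMap(np.where(mask, edt / dmax, 0.0), dmax)


def relevance_histogram(maps, dmaps, masks, n_r: int = 20, n_d: int = 20) -> RelevanceHistogram:
    """Pool (r, d) over all mask pixels of all fruits into an n_r x n_d
    histogram on [0,1]^2; the final bin in each axis is right-inclusive so
    r = 1 and d = 1 are counted."""
    r_edges = np.linspace(0.0, 1.0, n_r + 1)
    d_edges = np.linspace(0.0, 1.0, n_d + 1)
    counts = np.zeros((n_r, n_d))
    total = 0
    for m, dm, fm in zip(maps, dmaps, masks):
        values = m.values if hasattr(m, "values") else np.asarray(m)
        dvals = dm.d if hasattr(dm, "d") else np.asarray(dm)
        mask = fm.mask if hasattr(fm, "mask") else np.asarray(fm)
        if values.shape != dvals.shape or values.shape != mask.shape:
            raise ValueError("relevance map, distance map and mask misaligned")
        h, _, _ = np.histogram2d(values[mask], dvals[mask], bins=(r_edges, d_edges))
        counts += h
        total += int(mask.sum())
    return RelevanceHistogram(counts, r_edges, d_edges, total)


def band_relevance_summary(hist: RelevanceHistogram, r_min: float = 0.8) -> dict[str, float]:
    """High-relevance (r >= r_min) pixel mass per contour-distance band."""
    r_sel = hist.r_edges[:-1] >= r_min - 1e-12
    out = {}
    for band, (lo, hi) in BANDS.items():
        lo_ok = np.isclose(hist.d_edges, lo).any()
        hi_ok = np.isclose(hist.d_edges, hi).any()
        if not (lo_ok and hi_ok):
            raise ValueError(f"histogram d-edges do not align with band {band}")
        d_sel = (hist.d_edges[:-1] >= lo - 1e-12) & (hist.d_edges[1:] <= hi + 1e-12)
        out[band] = float(hist.counts[np.ix_(r_sel, d_sel)].sum())
    return out


def _window_stats(values: np.ndarray, mask: np.ndarray, side: int):
    """Mean of ``values`` over every side x side window fully inside ``mask``.

    Returns (means, valid) on the (H-side+1, W-side+1) grid of top-left
    corners, via summed-area tables.
    """
    h, w = mask.shape
    if side > min(h, w):
        raise ValueError("window exceeds image extent")

    def sat_sum(a):
        s = np.cumsum(np.cumsum(np.asarray(a, dtype=float), axis=0), axis=1)
        s = np.pad(s, ((1, 0), (1, 0)))
        return (s[side:, side:] - s[:-side, side:] - s[side:, :-side]
                + s[:-side, :-side])

    area = side * side
    valid = np.isclose(sat_sum(mask), area)
    means = sat_sum(values) / area
    return means, valid


def extract_featured_region(rel_map, fruit: FruitMask, window_side: int,
                            dmap: DistanceMap | None = None,
                            category: str = "RS-F", fruit_id: str = "") -> SampleRegion:
    """Fully-interior square window maximising mean relevance; ties break to
    the smallest row, then column."""
    values = rel_map.values if hasattr(rel_map, "values") else np.asarray(rel_map)
    means, valid = _window_stats(values, fruit.mask, window_side)
    if not valid.any():
        raise ValueError("no window fits fully inside the mask")
    score = np.where(valid, means, -np.inf)
    flat = int(np.argmax(score))  # row-major first occurrence = tie rule
    r0, c0 = np.unravel_index(flat, score.shape)
    return _make_region(values, fruit, dmap, int(r0), int(c0), window_side,
                        category, fruit_id)


def extract_nonfeatured_region(rel_map, fruit: FruitMask, window_side: int,
                               featured: SampleRegion, min_separation: float | None = None,
                               dmap: DistanceMap | None = None,
                               fruit_id: str = "") -> SampleRegion:
    """Fully-interior window minimising mean relevance, with its centre at
    least ``min_separation`` px from the featured window's centre."""
    if min_separation is None:
        min_separation = 2.0 * window_side
    values = rel_map.values if hasattr(rel_map, "values") else np.asarray(rel_map)
    means, valid = _window_stats(values, fruit.mask, window_side)
    gh, gw = means.shape
    rr, cc = np.mgrid[0:gh, 0:gw]
    fr = featured.row0 + (featured.side - 1) / 2.0
    fc = featured.col0 + (featured.side - 1) / 2.0
    centre_dist = np.hypot(rr + (window_side - 1) / 2.0 - fr,
                           cc + (window_side - 1) / 2.0 - fc)
    ok = valid & (centre_dist >= min_separation)
    if not ok.any():
        raise ValueError("non-featured window constraint infeasible")
    score = np.where(ok, means, np.inf)
    r0, c0 = np.unravel_index(int(np.argmin(score)), score.shape)
    return _make_region(values, fruit, dmap, int(r0), int(c0), window_side,
                        "RS-NF", fruit_id)


def _make_region(values, fruit, dmap, r0, c0, side, category, fruit_id):
    sl = (slice(r0, r0 + side), slice(c0, c0 + side))
    mean_rel = float(values[sl].mean())
    mean_d = float(dmap.d[sl].mean()) if dmap is not None else float("nan")
    return SampleRegion(category, r0, c0, side, mean_rel, mean_d, fruit_id)
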
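"""Receptor-noise-limited color discrimination and perceptual image
segmentation.

Plumage color complexity is measured in the viewer's perceptual space:
each pixel of a calibrated multispectral photograph carries the quantum
catch of every cone class plus a luminance (double-cone) catch.  Distances
between colors are Just Noticeable Distances (JNDs) from the
receptor-noise-limited model in its log form — differences of
log quantum catches weighted by per-channel noise — so 1 JND sits at the
discrimination threshold under ideal viewing.

A custom agglomerative clustering then merges neighboring image regions
whose chromatic and achromatic JNDs both fall below threshold, with a
spatial search radius that grows each pass, reducing the image to the set
of perceptually distinct color patches.  Cluster count and the numbers
equivalent of the Shannon entropy of patch areas give color richness and
diversity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .diversity import ComplexityScore, WeightedCounts, complexity_score

logger = logging.getLogger(__name__)

__all__ = [
    "VisualModel",
    "ConeCatchImage",
    "ClusterParams",
    "ClusterMap",
    "median_blur",
    "chromatic_jnd",
    "achromatic_jnd",
    "composite_distance",
    "cluster_image",
    "color_complexity",
    "specimen_score",
]


@dataclass(frozen=True)
class VisualModel:
    """Receptor-noise-limited visual model.

    Channel noise follows the standard relative-abundance scaling
    ``omega_i = nu * sqrt(n_ref) / sqrt(n_i)`` where ``nu`` is the Weber
    fraction of the most abundant cone class and ``n_i`` the relative
    density of class ``i``.  Defaults are a violet-sensitive (VS)
    pigeon-like tetrachromat: densities (1, 2, 2, 4) for
    (vs, sws, mws, lws) and a 0.1 Weber fraction on the most abundant
    channel, with luminance Weber fraction 0.1.
    """

    relative_densities: tuple = (1.0, 2.0, 2.0, 4.0)
    weber_fraction: float = 0.1
    weber_achromatic: float = 0.1
    channel_names: tuple | None = None

    def __post_init__(self):
        dens = tuple(float(d) for d in self.relative_densities)
        if len(dens) < 2 or len(dens) > 4:
            raise ValueError("need 2-4 chromatic receptor classes")
        if any(d <= 0 for d in dens):
            raise ValueError("relative densities must be positive")
        if not (0 < self.weber_fraction < 1) or not (0 < self.weber_achromatic < 1):
            raise ValueError("Weber fractions must lie in (0, 1)")
        object.__setattr__(self, "relative_densities", dens)

    @property
    def n_channels(self) -> int:
        return len(self.relative_densities)

    @property
    def channel_noise(self) -> np.ndarray:
        """Per-channel noise omega_i."""
        dens = np.asarray(self.relative_densities)
        n_ref = dens.max()
        return self.weber_fraction * np.sqrt(n_ref) / np.sqrt(dens)


@dataclass
class ConeCatchImage:
    """Per-pixel cone quantum catches, luminance and a foreground mask.

    ``catches`` has shape (H, W, n_channels); ``luminance`` and ``mask``
    are (H, W).  Catches must be strictly positive on the foreground so
    the log model is defined; background pixels are ignored everywhere.
    """

    catches: np.ndarray
    luminance: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.catches = np.asarray(self.catches, dtype=float)
        self.luminance = np.asarray(self.luminance, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.catches.ndim != 3:
            raise ValueError("catches must be (H, W, n_channels)")
        if self.luminance.shape != self.catches.shape[:2]:
            raise ValueError("luminance shape mismatch")
        if self.mask.shape != self.catches.shape[:2]:
            raise ValueError("mask shape mismatch")
        if not self.mask.any():
            raise ValueError("mask selects no foreground pixels")
        if np.any(self.catches[self.mask] <= 0) or np.any(self.luminance[self.mask] <= 0):
            raise ValueError("foreground catches must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    @property
    def n_channels(self) -> int:
        return self.catches.shape[2]


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds and schedule for the spatial-chromatic clustering.

    ``chrom_threshold`` / ``lum_threshold`` are in JND; 3 JND is a
    conventional supra-threshold cut for discriminability under
    uncontrolled viewing.  The spatial search radius starts at
    ``initial_radius`` pixels and grows ``radius_increment`` per pass.
    """

    chrom_threshold: float = 3.0
    lum_threshold: float = 3.0
    initial_radius: int = 1
    radius_increment: int = 1
    max_passes: int = 200
    min_area_fraction: float = 0.0

    def __post_init__(self):
        if self.chrom_threshold <= 0 or self.lum_threshold <= 0:
            raise ValueError("JND thresholds must be positive")
        if self.initial_radius < 1:
            raise ValueError("initial radius must be >= 1 pixel")


@dataclass
class ClusterMap:
    """Partition of the foreground into perceptual color clusters.

    ``labels`` is (H, W) int with -1 on background; cluster ``i`` has
    ``areas[i]`` pixels, mean chromatic catches ``mean_catches[i]`` and
    mean luminance ``mean_luminance[i]``.
    """

    labels: np.ndarray
    mean_catches: np.ndarray
    mean_luminance: np.ndarray
    areas: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.areas)


def median_blur(img: ConeCatchImage, radius: int = 1) -> ConeCatchImage:
    """Channel-wise median over the (2r+1)^2 neighborhood, restricted to
    foreground pixels, to remove aberrant pixel values (dust, dead
    pixels).  The mask is unchanged."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    h, w = img.shape
    planes = np.dstack([img.catches, img.luminance[:, :, None]])
    n = planes.shape[2]
    pad = radius
    padded = np.full((h + 2 * pad, w + 2 * pad, n), np.nan)
    padded[pad : pad + h, pad : pad + w] = np.where(
        img.mask[:, :, None], planes, np.nan
    )
    # stack all (2r+1)^2 shifted copies and take the nanmedian
    stack = np.empty((h, w, n, (2 * radius + 1) ** 2))
    idx = 0
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            stack[:, :, :, idx] = padded[
                pad + dy : pad + dy + h, pad + dx : pad + dx + w
            ]
            idx += 1
    with np.errstate(all="ignore"):
        med = np.nanmedian(stack, axis=3)
    med = np.where(img.mask[:, :, None], med, planes)
    return ConeCatchImage(med[:, :, :-1], med[:, :, -1], img.mask)


def _rnl_weights(omega: np.ndarray) -> tuple[np.ndarray, float, list]:
    """Numerator weights and denominator of the receptor-noise formula.

    For n channels the squared chromatic distance is
    ``sum_{i<j} (prod_{k not in {i,j}} w_k)^2 (df_i - df_j)^2`` over
    ``sum_i (prod_{k != i} w_k)^2`` — which reduces to the familiar di-,
    tri- and tetrachromatic quotients.
    """
    n = len(omega)
    pairs = list(combinations(range(n), 2))
    num_w = np.array(
        [np.prod([omega[k] for k in range(n) if k not in (i, j)]) ** 2 for i, j in pairs]
    )
    den = float(
        sum(np.prod([omega[k] for k in range(n) if k != i]) ** 2 for i in range(n))
    )
    return num_w, den, pairs


def _chromatic_jnd_logspace(fa: np.ndarray, fb: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Vectorized chromatic JND between log-catch vectors (..., n)."""
    num_w, den, pairs = _rnl_weights(omega)
    df = np.asarray(fa) - np.asarray(fb)
    s = np.zeros(df.shape[:-1])
    for w, (i, j) in zip(num_w, pairs):
        s = s + w * (df[..., i] - df[..., j]) ** 2
    return np.sqrt(s / den)


def chromatic_jnd(qa, qb, m: VisualModel) -> float:
    """Chromatic JND between two catch vectors under the log
    receptor-noise-limited model.

    Zero for identical stimuli and for any uniform intensity scaling
    ``qb = c * qa`` (only pairwise differences of log catches enter).
    """
    qa = np.asarray(qa, dtype=float)
    qb = np.asarray(qb, dtype=float)
    if qa.shape != (m.n_channels,) or qb.shape != (m.n_channels,):
        raise ValueError("catch vectors must match the model's channel count")
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ValueError("quantum catches must be strictly positive")
    return float(_chromatic_jnd_logspace(np.log(qa), np.log(qb), m.channel_noise))


def achromatic_jnd(qLa: float, qLb: float, m: VisualModel) -> float:
    """Achromatic (luminance) JND: |ln qLa - ln qLb| / omega_L."""
    if qLa <= 0 or qLb <= 0:
        raise ValueError("luminance catches must be strictly positive")
    return abs(math.log(qLa) - math.log(qLb)) / m.weber_achromatic


def composite_distance(dS: float, dL: float, p: ClusterParams) -> float:
    """Euclidean norm of the threshold-scaled chromatic and achromatic
    distances, weighting the two channels equally at their thresholds."""
    if dS < 0 or dL < 0:
        raise ValueError("JND distances are nonnegative")
    return math.hypot(dS / p.chrom_threshold, dL / p.lum_threshold)


def _neighbor_pairs(labels: np.ndarray, r: int, n_ids: int) -> set:
    """Cluster pairs having any two pixels within Chebyshev distance r.

    Found by comparing the label image with all its shifts in the
    (2r+1)^2 window; background is -1 and never pairs.  Pairs are encoded
    as lo * n_ids + hi and deduplicated once per pass.
    """
    h, w = labels.shape
    # half-window of offsets (the rest follow by symmetry)
    offsets = [
        (dy, dx)
        for dy in range(0, min(r, h - 1) + 1)
        for dx in range(-min(r, w - 1), min(r, w - 1) + 1)
        if (dy, dx) != (0, 0) and (dy > 0 or dx > 0)
    ]
    codes = []
    for dy, dx in offsets:
        a = labels[max(0, dy) : h + min(0, dy), max(0, dx) : w + min(0, dx)]
        b = labels[
            max(0, -dy) : h + min(0, -dy), max(0, -dx) : w + min(0, -dx)
        ]
        sel = (a >= 0) & (b >= 0) & (a != b)
        if sel.any():
            lo = np.minimum(a[sel], b[sel]).astype(np.int64)
            hi = np.maximum(a[sel], b[sel]).astype(np.int64)
            codes.append(lo * n_ids + hi)
    if not codes:
        return set()
    u = np.unique(np.concatenate(codes))
    return set(zip((u // n_ids).tolist(), (u % n_ids).tolist()))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the lowest index as representative for determinism
            lo, hi = (ra, rb) if ra < rb else (rb, ra)
            self.parent[hi] = lo


def cluster_image(
    img: ConeCatchImage, m: VisualModel, p: ClusterParams | None = None
) -> ClusterMap:
    """Agglomerate foreground pixels into perceptually homogeneous color
    clusters.

    Every foreground pixel starts as its own cluster.  Each pass: (1)
    clusters with any two pixels within the current Chebyshev search
    radius are neighbors; (2) each cluster selects its nearest neighbor
    by the composite (threshold-scaled) JND distance between cluster mean
    catches; (3) the merge is accepted only if both the chromatic and the
    achromatic component distances are below their thresholds; (4)
    accepted merges chain transitively within the pass (if A joins B and
    B joins C, all three fuse); (5) cluster means are recomputed as
    area-weighted means and the search radius grows.  Clustering thus
    operates over n + 2 dimensions — n receptor channels plus x and y.
    Terminates when a pass merges nothing while the radius already spans
    the image, or at ``max_passes`` (logged as a warning, partial result
    returned).
    """
    if p is None:
        p = ClusterParams()
    if img.n_channels != m.n_channels:
        raise ValueError("image channel count does not match visual model")
    h, w = img.shape
    omega = m.channel_noise

    labels = np.full((h, w), -1, dtype=np.int64)
    fg = np.flatnonzero(img.mask.ravel())
    labels.ravel()[fg] = np.arange(fg.size)
    n0 = fg.size

    # running sums per cluster; means derived on demand
    cat_flat = img.catches.reshape(-1, img.n_channels)[fg]
    lum_flat = img.luminance.ravel()[fg]
    sums = cat_flat.astype(float).copy()
    lsums = lum_flat.astype(float).copy()
    areas = np.ones(n0, dtype=np.int64)

    r = p.initial_radius
    max_dim = max(h, w)
    for pass_no in range(p.max_passes):
        pairs = _neighbor_pairs(labels, r, n0)
        merged_any = False
        if pairs:
            active = np.unique(labels[labels >= 0])
            log_mean = np.full((n0, img.n_channels), np.nan)
            log_lum = np.full(n0, np.nan)
            log_mean[active] = np.log(sums[active] / areas[active, None])
            log_lum[active] = np.log(lsums[active] / areas[active])

            neighbors: dict[int, list] = {}
            for a, b in pairs:
                neighbors.setdefault(a, []).append(b)
                neighbors.setdefault(b, []).append(a)

            uf = _UnionFind(n0)
            for a in sorted(neighbors):
                nb = np.array(sorted(neighbors[a]))
                dS = _chromatic_jnd_logspace(
                    log_mean[nb], log_mean[a][None, :], omega
                )
                dL = np.abs(log_lum[nb] - log_lum[a]) / m.weber_achromatic
                comp = np.sqrt(
                    (dS / p.chrom_threshold) ** 2 + (dL / p.lum_threshold) ** 2
                )
                j = int(np.argmin(comp))  # ties -> lowest cluster index
                if dS[j] < p.chrom_threshold and dL[j] < p.lum_threshold:
                    uf.union(a, int(nb[j]))
                    merged_any = True
            if merged_any:
                roots = np.array([uf.find(i) for i in range(n0)])
                new_sums = np.zeros_like(sums)
                new_lsums = np.zeros_like(lsums)
                new_areas = np.zeros_like(areas)
                np.add.at(new_sums, roots, sums)
                np.add.at(new_lsums, roots, lsums)
                np.add.at(new_areas, roots, areas)
                sums, lsums, areas = new_sums, new_lsums, new_areas
                mask_fg = labels >= 0
                labels[mask_fg] = roots[labels[mask_fg]]
        if not merged_any and r >= max_dim:
            break
        r += p.radius_increment
    else:
        logger.warning(
            "cluster_image hit max_passes=%d before quiescence; partial result",
            p.max_passes,
        )

    active = np.unique(labels[labels >= 0])
    remap = np.full(n0, -1, dtype=np.int64)
    remap[active] = np.arange(active.size)
    out_labels = labels.copy()
    out_labels[labels >= 0] = remap[labels[labels >= 0]]
    return ClusterMap(
        labels=out_labels,
        mean_catches=sums[active] / areas[active, None],
        mean_luminance=lsums[active] / areas[active],
        areas=areas[active].astype(float),
    )


def color_complexity(cm: ClusterMap, min_area_fraction: float = 0.0) -> ComplexityScore:
    """Color richness (cluster count) and diversity (numbers equivalent of
    the Shannon entropy of cluster area proportions), optionally dropping
    specks below ``min_area_fraction`` of the foreground first."""
    areas = np.asarray(cm.areas, dtype=float)
    if min_area_fraction > 0:
        keep = areas >= min_area_fraction * areas.sum()
        areas = areas[keep]
    w = WeightedCounts(tuple(range(len(areas))), areas)
    return complexity_score(w)


def specimen_score(views: list[ComplexityScore]) -> ComplexityScore:
    """Average the available views (dorsal, ventral, angled) per metric to
    one specimen-level score."""
    if not views:
        raise ValueError("no scored views for this specimen")
    return ComplexityScore(
        richness=float(np.mean([v.richness for v in views])),
        diversity=float(np.mean([v.diversity for v in views])),
    )
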
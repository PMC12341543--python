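"""Skeletonization and branch statistics of striated fields.

The α-actinin channel is thresholded (Otsu by default), thinned to a
1-pixel skeleton, and decomposed into branches at junction pixels. The
branch count per unit area is the *breakage* score (more branches = more
fragmented striations); the mean branch length is the *continuity* score
(longer uninterrupted striations = higher continuity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .errors import UnscoreableFieldError
from .images import StriatedImage

_NEIGHBOURS = [
    (dr, dc)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if (dr, dc) != (0, 0)
]


@dataclass
class Branch:
    """One skeleton branch: an ordered pixel polyline and its length."""

    polyline: np.ndarray  # (n, 2) row/col pixel coordinates
    length_um: float


@dataclass
class SkeletonGraph:
    """Branch decomposition of a 1-pixel-wide skeleton."""

    branches: list[Branch]
    n_junctions: int
    n_endpoints: int
    pixel_size_um: float
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def branch_lengths_um(self) -> np.ndarray:
        return np.array([b.length_um for b in self.branches])

    @property
    def total_length_um(self) -> float:
        return float(self.branch_lengths_um.sum()) if self.branches else 0.0


def _polyline_length(poly: np.ndarray) -> float:
    """Euclidean length of a pixel polyline (in pixels)."""
    if len(poly) < 2:
        return 0.0
    steps = np.diff(poly.astype(float), axis=0)
    return float(np.sqrt((steps**2).sum(axis=1)).sum())


def _pixel_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    g.add_nodes_from(pixels)
    for r, c in pixels:
        for dr, dc in _NEIGHBOURS:
            nb = (r + dr, c + dc)
            if nb in pixels:
                g.add_edge((r, c), nb)
    return g


def _trace_branches(g: nx.Graph) -> tuple[list[np.ndarray], int, int]:
    """Decompose a skeleton pixel graph into maximal degree-2 paths."""
    branches: list[np.ndarray] = []
    node_pixels = [n for n in g.nodes if g.degree(n) != 2]
    n_endpoints = sum(1 for n in node_pixels if g.degree(n) == 1)
    n_junctions = sum(1 for n in node_pixels if g.degree(n) >= 3)
    visited_edges: set[frozenset] = set()

    for start in node_pixels:
        for nbr in g.neighbors(start):
            edge = frozenset((start, nbr))
            if edge in visited_edges:
                continue
            path = [start, nbr]
            visited_edges.add(edge)
            prev, cur = start, nbr
            while g.degree(cur) == 2:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                visited_edges.add(frozenset((cur, nxt)))
                path.append(nxt)
                prev, cur = cur, nxt
            branches.append(np.array(path))

    # pure cycles (every node degree 2) remain untraced
    for comp in nx.connected_components(g):
        comp = list(comp)
        if all(g.degree(n) == 2 for n in comp):
            cycle = nx.cycle_basis(g.subgraph(comp))[0]
            cycle.append(cycle[0])
            branches.append(np.array(cycle))
    return branches, n_junctions, n_endpoints


def binarize_and_skeletonize(
    img: StriatedImage,
    threshold: float | None = None,
    min_branch_um: float = 0.0,
    smooth_sigma_px: float = 1.0,
    min_object_um2: float = 0.25,
) -> SkeletonGraph:
    """Threshold, thin to 1-px skeleton, and decompose into branches.

    The image is lightly Gaussian-smoothed before thresholding and
    connected foreground objects smaller than ``min_object_um2`` are
    dropped, so the skeleton traces striations rather than shot-noise
    speckle (the denoise step of any practical skeletonization workflow).

    Parameters
    ----------
    threshold : float, optional
        Global intensity threshold; Otsu's method when omitted.
    min_branch_um : float
        Discard branches shorter than this (spur suppression); default
        keeps everything.
    smooth_sigma_px : float
        Pre-threshold Gaussian smoothing, pixels; 0 disables.
    min_object_um2 : float
        Minimum area of a foreground object kept, um^2; 0 disables.

    Raises
    ------
    UnscoreableFieldError
        If the field is degenerate (zero intensity variance) or the
        threshold yields an all-background / all-foreground mask.
    """
    pixels = img.pixels
    if pixels.std() == 0:
        raise UnscoreableFieldError("image has zero intensity variance")
    if smooth_sigma_px > 0:
        pixels = ndimage.gaussian_filter(pixels, smooth_sigma_px)
    if threshold is None:
        threshold = threshold_otsu(pixels)
    mask = pixels > threshold
    if min_object_um2 > 0:
        min_px = max(1, int(round(min_object_um2 / img.pixel_size_um**2)))
        labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3)))
        if n_lab:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0  # background never counts as an object
            mask = sizes[labels] >= min_px
    if not mask.any() or mask.all():
        raise UnscoreableFieldError(
            "thresholding produced an all-background or all-foreground field"
        )
    skel = skeletonize(mask)
    if not skel.any():
        raise UnscoreableFieldError("empty skeleton after thinning")

    g = _pixel_graph(skel)
    # isolated single pixels carry no length information
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    paths, n_junctions, n_endpoints = _trace_branches(g)

    branches = []
    for poly in paths:
        length = _polyline_length(poly) * img.pixel_size_um
        if length >= min_branch_um:
            branches.append(Branch(polyline=poly, length_um=length))
    if not branches:
        raise UnscoreableFieldError("no branches above min_branch_um")
    return SkeletonGraph(
        branches=branches,
        n_junctions=n_junctions,
        n_endpoints=n_endpoints,
        pixel_size_um=img.pixel_size_um,
        mask=mask,
    )


def breakage_score(sk: SkeletonGraph, field_area_um2: float) -> float:
    """Branches per 1000 um^2 of field; higher = more fragmented."""
    if not field_area_um2 > 0:
        raise ValueError("field area must be positive")
    return sk.n_branches / field_area_um2 * 1000.0


def continuity_score(sk: SkeletonGraph) -> float:
    """Mean branch length in um; higher = longer uninterrupted striations."""
    if sk.n_branches == 0:
        raise UnscoreableFieldError("empty skeleton: no branches to average")
    return float(sk.branch_lengths_um.mean())
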
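"""Diploid purity→VAF model and purity inference from VAF cluster centers.

For a clonal somatic mutation in a diploid tumor genome, a sample of purity
``p`` (tumor-cell fraction) yields an expected variant allele fraction of

    E[VAF] = p * m / 2

with allelic multiplicity ``m`` = 1 for heterozygous and 2 for homozygous
mutations (total copy number fixed at two; no CNV adjustment).  A
heterozygous VAF cluster centered at 0.25 therefore implies purity 0.5, and
a homozygous cluster at 1.0 implies a pure sample.  Cluster centers are
located as modes of a kernel-smoothed histogram — robust to a secondary
homozygous cluster, unlike a global mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

MULTIPLICITY = {"het": 1, "hom": 2}


def expected_vaf(purity: float, zygosity: str = "het") -> float:
    """Expected VAF of a clonal mutation: purity x multiplicity / 2."""
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity {purity} outside [0, 1]")
    try:
        m = MULTIPLICITY[zygosity]
    except KeyError:
        raise ValueError(f"zygosity must be het or hom, got {zygosity!r}")
    return purity * m / 2.0


def infer_purity(het_center: float, tol: float = 0.02) -> float:
    """Invert the het model: purity = 2 x cluster center, clamped to [0, 1].

    Centers in (0.5, 0.5 + tol] are treated as sampling noise around a pure
    sample and clamp to 1.0; larger centers violate the heterozygous-diploid
    assumption and raise.
    """
    if het_center <= 0:
        raise ValueError("het cluster center must be positive")
    if het_center > 0.5 + tol:
        raise ValueError(
            f"het cluster center {het_center:.3f} > 0.5: heterozygous diploid "
            "assumption violated (homozygous cluster or CNV?)"
        )
    return min(2.0 * het_center, 1.0)


@dataclass
class ClusterMode:
    center: Tuple[float, ...]  # (primary VAF, PDX VAF) or (VAF,) in 1D
    mass: float  # fraction of points within the mode's neighborhood
    density: float
    clear: bool  # mass above the dominance threshold


def _smooth_hist(
    values: np.ndarray, grid: float, bandwidth: float
) -> Tuple[np.ndarray, np.ndarray]:
    edges = np.arange(0.0, 1.0 + grid, grid)
    centers = (edges[:-1] + edges[1:]) / 2
    if values.ndim == 1:
        hist, _ = np.histogram(values, bins=edges)
        smooth = ndimage.gaussian_filter1d(hist.astype(float), bandwidth / grid,
                                           mode="nearest")
    else:
        hist, _, _ = np.histogram2d(values[:, 0], values[:, 1], bins=[edges, edges])
        smooth = ndimage.gaussian_filter(hist, bandwidth / grid, mode="nearest")
    return smooth, centers


def _mass_near(values: np.ndarray, center: np.ndarray, radius: float) -> float:
    if values.ndim == 1:
        inside = np.abs(values - center[0]) <= radius
    else:
        inside = np.all(np.abs(values - center) <= radius, axis=1)
    return float(inside.mean())


def estimate_cluster_centers(
    vaf_pairs: Sequence[Tuple[float, float]],
    n_clusters: int = 2,
    bandwidth: float = 0.03,
    grid: float = 0.01,
    min_pairs: int = 20,
    dominance: float = 0.05,
    mass_radius: float = 0.05,
) -> List[ClusterMode]:
    """Top density modes of the (primary VAF, PDX VAF) cloud.

    The joint density is a 2D histogram at ``grid`` resolution smoothed with
    a Gaussian kernel of ``bandwidth``; local maxima are ranked by density
    and each mode's mass is the fraction of points within ``mass_radius`` in
    both coordinates.  Modes with mass below ``dominance`` are flagged as
    "no clear cluster".  Deterministic for fixed inputs and resolution.
    """
    pts = np.asarray(list(vaf_pairs), dtype=float)
    if pts.ndim != 2 or len(pts) < min_pairs:
        raise ValueError(f"need at least {min_pairs} defined VAF pairs")
    smooth, centers = _smooth_hist(pts, grid, bandwidth)
    local_max = smooth == ndimage.maximum_filter(smooth, size=5, mode="nearest")
    local_max &= smooth > 0
    ij = np.argwhere(local_max)
    order = np.argsort(smooth[local_max])[::-1]
    modes: List[ClusterMode] = []
    for k in order[:n_clusters]:
        i, j = ij[k]
        center = np.array([centers[i], centers[j]])
        mass = _mass_near(pts, center, mass_radius)
        modes.append(
            ClusterMode(
                center=(float(center[0]), float(center[1])),
                mass=mass,
                density=float(smooth[i, j]),
                clear=mass >= dominance,
            )
        )
    return modes


def estimate_vaf_mode(
    vafs: Sequence[float],
    bandwidth: float = 0.03,
    grid: float = 0.01,
    min_sites: int = 20,
    dominance: float = 0.05,
    mass_radius: float = 0.05,
) -> ClusterMode:
    """1D analogue of :func:`estimate_cluster_centers` for one sample."""
    vals = np.asarray(list(vafs), dtype=float)
    if len(vals) < min_sites:
        raise ValueError(f"need at least {min_sites} defined VAFs")
    smooth, centers = _smooth_hist(vals, grid, bandwidth)
    i = int(np.argmax(smooth))
    center = np.array([centers[i]])
    mass = _mass_near(vals, center, mass_radius)
    return ClusterMode(
        center=(float(centers[i]),),
        mass=mass,
        density=float(smooth[i]),
        clear=mass >= dominance,
    )


def purity_from_vafs(
    vafs: Sequence[float],
    bandwidth: float = 0.03,
    grid: float = 0.01,
    tol: float = 0.02,
) -> Tuple[float, ClusterMode]:
    """Estimate sample purity from heterozygous-site VAFs via the density
    mode (assumes the het cluster dominates)."""
    mode = estimate_vaf_mode(vafs, bandwidth=bandwidth, grid=grid)
    return infer_purity(mode.center[0], tol=tol), mode
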
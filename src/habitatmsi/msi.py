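"""Multi-region spatial interaction (MSI) matrix and its feature set.

The MSI matrix is a symmetric (k+1) x (k+1) table of adjacent-voxel pair
counts over a habitat map: index 0 is the "boundary" label (in-grid
background voxels touching the ROI) and 1..k are the habitat subregions.
Each unordered neighboring pair with at least one in-ROI voxel is
counted once and mirrored across the diagonal; background-background
pairs are never counted, and neighbors falling outside the grid are
ignored.

From the matrix (plus the habitat map itself) a fixed, ordered feature
vector is extracted: four GLCM texture statistics of the subregion
block, per-subregion absolute volumes, absolute boundary interactions,
lower-triangular between-subregion interactions, and normalized variants
of those three groups.  For k subregions the vector has

    4 + 4k + k(k-1)

entries - 58 for the six-subregion scheme used by default, 32 at k=4 and
92 at k=8.  Volumes are voxel counts (not diagonal adjacency counts);
the normalizing denominator for every normalized interaction is the
total number of counted pairs (boundary + within + between), and volume
proportions are normalized by the ROI voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .habitat import HabitatMap

_OFFSETS_6 = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


class MSIError(ValueError):
    pass


@dataclass
class MSIMatrix:
    counts: np.ndarray  # (k+1) x (k+1), symmetric, counts[0,0] == 0
    k: int
    connectivity: int = 6

    @property
    def total_pairs(self) -> int:
        """Number of unordered counted pairs."""
        c = self.counts
        return int((c.sum() + np.trace(c)) // 2)


@dataclass
class MSIFeatureVector:
    values: np.ndarray
    names: list[str]
    k: int


@dataclass
class CombinedFeatureVector:
    values: np.ndarray
    names: list[str]
    k: int


def _half_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    if connectivity == 6:
        return _OFFSETS_6
    if connectivity == 26:
        return _OFFSETS_26
    raise ValueError("connectivity must be 6 or 26")


def build_msi_matrix(hmap: HabitatMap, connectivity: int = 6) -> MSIMatrix:
    """Count adjacent-voxel label pairs on the habitat map."""
    L = np.asarray(hmap.labels)
    k = hmap.k
    if L.max(initial=0) > k:
        raise MSIError(f"habitat map contains labels > k={k}")
    acc = np.zeros((k + 1, k + 1), dtype=np.int64)
    for off in _half_offsets(connectivity):
        sl_a = tuple(
            slice(None, -o) if o > 0 else slice(-o, None) for o in off
        )
        sl_b = tuple(
            slice(o, None) if o > 0 else slice(None, o) if o < 0 else slice(None)
            for o in off
        )
        a = L[sl_a].ravel()
        b = L[sl_b].ravel()
        keep = (a > 0) | (b > 0)
        lo = np.minimum(a[keep], b[keep]).astype(np.int64)
        hi = np.maximum(a[keep], b[keep]).astype(np.int64)
        np.add.at(acc, (lo, hi), 1)
    counts = acc + acc.T - np.diag(np.diag(acc))
    counts[0, 0] = 0
    return MSIMatrix(counts=counts, k=k, connectivity=connectivity)


def glcm_stats(msi: MSIMatrix) -> tuple[float, float, float, float]:
    """GLCM-style (contrast, homogeneity, correlation, energy) of the
    normalized k x k subregion block (boundary row/column excluded).

    Correlation is defined as 0 when either marginal SD vanishes.
    """
    block = msi.counts[1:, 1:].astype(float)
    total = block.sum()
    if total <= 0:
        raise MSIError("subregion block of the MSI matrix is all zero")
    p = block / total
    k = p.shape[0]
    i = np.arange(k)[:, None] * np.ones((1, k))
    j = i.T
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    energy = float((p**2).sum())
    mu_r = float((i * p).sum())
    mu_c = float((j * p).sum())
    var_r = float(((i - mu_r) ** 2 * p).sum())
    var_c = float(((j - mu_c) ** 2 * p).sum())
    if var_r <= 0 or var_c <= 0:
        correlation = 0.0
    else:
        correlation = float(
            ((i - mu_r) * (j - mu_c) * p).sum() / np.sqrt(var_r * var_c)
        )
    return contrast, homogeneity, correlation, energy


def feature_dimension(k: int) -> int:
    """Length of the MSI feature vector for k subregions."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return 4 + 4 * k + k * (k - 1)


def msi_feature_names(k: int) -> list[str]:
    return [f"MSI {i}" for i in range(1, feature_dimension(k) + 1)]


def _lower_triangular_pairs(k: int) -> list[tuple[int, int]]:
    """Between-subregion pairs in the enumeration order 1-2, 1-3, ...,
    1-k, 2-3, ..., (k-1)-k."""
    return [(a, b) for a in range(1, k + 1) for b in range(a + 1, k + 1)]


def extract_msi_features(
    msi: MSIMatrix, hmap: HabitatMap, k: int | None = None
) -> MSIFeatureVector:
    """Ordered MSI feature vector for one region.

    Order: 4 GLCM statistics; k absolute subregion volumes (voxel
    counts); k absolute boundary interactions; k(k-1)/2 between-subregion
    interactions; then volume proportions, normalized boundary
    interactions and normalized between-subregion interactions.  Absent
    subregions contribute zeros throughout.
    """
    if k is None:
        k = msi.k
    if k != msi.k or k != hmap.k:
        raise MSIError(f"k mismatch: matrix k={msi.k}, map k={hmap.k}, asked {k}")
    counts = msi.counts
    labels = hmap.labels
    volumes = np.bincount(labels[labels > 0].ravel(), minlength=k + 1)[1:].astype(
        float
    )
    roi_vox = volumes.sum()
    if roi_vox == 0:
        raise MSIError("habitat map has no in-ROI voxels")
    boundary = counts[0, 1:].astype(float)
    pairs = _lower_triangular_pairs(k)
    between = np.array([counts[a, b] for a, b in pairs], dtype=float)
    total_pairs = float(msi.total_pairs)
    if total_pairs == 0:
        raise MSIError("MSI matrix has no counted pairs")
    glcm = np.array(glcm_stats(msi))
    values = np.concatenate(
        [
            glcm,
            volumes,
            boundary,
            between,
            volumes / roi_vox,
            boundary / total_pairs,
            between / total_pairs,
        ]
    )
    return MSIFeatureVector(values=values, names=msi_feature_names(k), k=k)


def combine_regions(
    gtvp: MSIFeatureVector, mln: MSIFeatureVector
) -> CombinedFeatureVector:
    """Concatenate GTVp then MLN feature vectors with prefixed names."""
    if gtvp.k != mln.k:
        raise MSIError(f"k mismatch between regions: {gtvp.k} vs {mln.k}")
    values = np.concatenate([gtvp.values, mln.values])
    names = [f"GTVp_{n}" for n in gtvp.names] + [f"MLN_{n}" for n in mln.names]
    return CombinedFeatureVector(values=values, names=names, k=gtvp.k)


def features_for_map(
    hmap: HabitatMap, connectivity: int = 6
) -> MSIFeatureVector:
    """Convenience: MSI matrix plus feature extraction in one call."""
    msi = build_msi_matrix(hmap, connectivity=connectivity)
    return extract_msi_features(msi, hmap)
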
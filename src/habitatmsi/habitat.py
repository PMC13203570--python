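"""Habitat subregion construction.

Each region of interest is divided into spatially contiguous superpixels
(masked 3D SLIC on the entropy-fused image), each superpixel is
summarized by an 8-descriptor feature vector, the descriptors of all
training superpixels in the cohort are pooled, embedded to 2D with
Barnes-Hut t-SNE, and clustered with k-means.  Cluster labels are mapped
back through the superpixels to produce a per-patient habitat map with
labels 1..k inside the ROI and 0 outside.

Out-of-sample superpixels (e.g. test patients) inherit the habitat label
of their nearest training superpixel in standardized descriptor space;
the embedding itself has no native out-of-sample transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage.segmentation import slic as _skimage_slic
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .preprocess import FusedImage, RegionMask

SUPERPIXEL_FEATURE_NAMES = [
    "mean",
    "sd",
    "median",
    "min",
    "max",
    "skewness",
    "kurtosis",
    "entropy",
]


@dataclass
class SuperpixelMap:
    labels: np.ndarray  # 0 outside ROI, 1..n_sp inside
    n_sp: int


@dataclass
class SuperpixelFeatures:
    """n_sp x 8 descriptor matrix with provenance bookkeeping."""

    matrix: np.ndarray
    feature_names: list[str] = field(
        default_factory=lambda: list(SUPERPIXEL_FEATURE_NAMES)
    )
    provenance: pd.DataFrame | None = None  # patient, region, channel, sp id


@dataclass
class HabitatModel:
    k: int
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    embedding: np.ndarray  # n_train x 2
    centers: np.ndarray  # k x 2, in embedding space
    train_labels: np.ndarray  # habitat labels 1..k of training superpixels
    train_features_std: np.ndarray
    random_seed: int


def choose_superpixel_count(
    roi_voxels: int, voxels_per_sp: int = 300, lo: int = 30, hi: int = 100
) -> int:
    """Adaptive superpixel count: round(volume / target size), clamped to
    the [30, 100] operating range."""
    if roi_voxels < 1:
        raise ValueError("roi_voxels must be >= 1")
    n = int(round(roi_voxels / voxels_per_sp))
    return int(min(max(n, lo), hi))


def slic_segment(
    fused: FusedImage,
    mask: RegionMask,
    n_sp: int,
    compactness: float = 1e-2,
) -> SuperpixelMap:
    """Masked 3D SLIC over the fused intensities.

    With the very low compactness used here SLIC follows intensity
    structure closely; small fragments produced by the connectivity
    enforcement are merged (min_size_factor=0.2), which keeps the
    achieved count within about +-50% of the request.
    """
    m = mask.values
    n_roi = int(m.sum())
    if n_roi == 0:
        raise ValueError("empty mask")
    if n_sp < 1:
        raise ValueError("n_sp must be >= 1")
    if n_roi <= n_sp:
        warnings.warn(
            f"ROI has {n_roi} voxels <= requested {n_sp} superpixels; "
            "assigning one voxel per superpixel",
            stacklevel=2,
        )
        labels = np.zeros(m.shape, dtype=np.int32)
        labels[m] = np.arange(1, n_roi + 1)
        return SuperpixelMap(labels=labels, n_sp=n_roi)
    labels = _skimage_slic(
        fused.values.astype(float),
        n_segments=n_sp,
        compactness=compactness,
        mask=m,
        channel_axis=None,
        start_label=1,
        min_size_factor=0.2,
    )
    labels = labels.astype(np.int32)
    labels[~m] = 0
    # relabel to a dense 1..n range (SLIC can skip ids after merging)
    ids = np.unique(labels[m])
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    labels = lut[labels]
    return SuperpixelMap(labels=labels, n_sp=len(ids))


def _descriptor(vals: np.ndarray, entropy_bins: int = 16) -> np.ndarray:
    """Fixed 8-descriptor summary of one superpixel's intensities."""
    mu = vals.mean()
    sd = vals.std()  # population SD
    if sd == 0:
        skew = kurt = ent = 0.0
    else:
        skew = float(sstats.skew(vals, bias=True))
        kurt = float(sstats.kurtosis(vals, bias=True))  # excess
        hist, _ = np.histogram(vals, bins=entropy_bins)
        p = hist[hist > 0] / hist.sum()
        ent = float(-(p * np.log2(p)).sum())
    return np.array(
        [mu, sd, np.median(vals), vals.min(), vals.max(), skew, kurt, ent]
    )


def superpixel_features(
    fused: FusedImage,
    spmap: SuperpixelMap,
    provenance: dict | None = None,
) -> SuperpixelFeatures:
    """Per-superpixel descriptors; empty superpixel ids are dropped with
    relabeling so the matrix has one row per realized superpixel."""
    labels = spmap.labels
    rows = []
    kept = []
    for sp in range(1, spmap.n_sp + 1):
        vals = fused.values[labels == sp]
        if vals.size == 0:
            continue
        kept.append(sp)
        rows.append(_descriptor(vals.astype(float)))
    matrix = np.vstack(rows)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite superpixel descriptors")
    prov = None
    if provenance is not None:
        prov = pd.DataFrame(
            {
                "patient_id": provenance.get("patient_id", ""),
                "region": provenance.get("region", fused.region),
                "channel": provenance.get("channel", fused.source_channel),
                "superpixel": kept,
            }
        )
    return SuperpixelFeatures(matrix=matrix, provenance=prov)


def pool_features(parts: list[SuperpixelFeatures]) -> SuperpixelFeatures:
    """Stack per-patient superpixel feature blocks into one cohort matrix."""
    matrix = np.vstack([p.matrix for p in parts])
    provs = [p.provenance for p in parts if p.provenance is not None]
    prov = pd.concat(provs, ignore_index=True) if provs else None
    return SuperpixelFeatures(matrix=matrix, provenance=prov)


def fit_habitat_model(
    cohort_features: SuperpixelFeatures,
    k: int,
    seed: int,
    perplexity: float = 30.0,
    tsne_max_iter: int = 1000,
    kmeans_max_iter: int = 100,
    kmeans_replicates: int = 10,
) -> HabitatModel:
    """Standardize pooled descriptors, embed with Barnes-Hut t-SNE
    (2D, perplexity 30, 1000 iterations) and cluster the embedding with
    k-means (k-means++ seeding, 100 iterations, best of 10 replicates)."""
    X = np.asarray(cohort_features.matrix, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"{n} superpixels < k={k}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mean) / sd
    if n < 3 * perplexity:
        new_p = max(1.0, np.floor(n / 3))
        warnings.warn(
            f"{n} rows < 3*perplexity; lowering perplexity to {new_p}",
            stacklevel=2,
        )
        perplexity = new_p
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=tsne_max_iter,
        method="barnes_hut",
        init="pca",
        random_state=seed,
    ).fit_transform(Xs)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=kmeans_replicates,
        max_iter=kmeans_max_iter,
        random_state=seed,
    ).fit(emb)
    return HabitatModel(
        k=k,
        scaler_mean=mean,
        scaler_sd=sd,
        embedding=emb,
        centers=km.cluster_centers_,
        train_labels=km.labels_.astype(np.int32) + 1,
        train_features_std=Xs,
        random_seed=seed,
    )


def assign_habitats(
    model: HabitatModel, new_features: SuperpixelFeatures
) -> np.ndarray:
    """Nearest-training-superpixel habitat assignment in standardized
    descriptor space; exact distance ties go to the lower habitat label."""
    X = np.asarray(new_features.matrix, dtype=float)
    if X.shape[1] != model.scaler_mean.shape[0]:
        raise ValueError("feature dimension mismatch")
    Xs = (X - model.scaler_mean) / model.scaler_sd
    train = model.train_features_std
    out = np.empty(Xs.shape[0], dtype=np.int32)
    chunk = max(1, int(2e7) // max(train.shape[0], 1))
    for start in range(0, Xs.shape[0], chunk):
        block = Xs[start : start + chunk]
        d2 = (
            (block**2).sum(axis=1)[:, None]
            - 2.0 * block @ train.T
            + (train**2).sum(axis=1)[None, :]
        )
        dmin = d2.min(axis=1)
        for i in range(block.shape[0]):
            ties = np.isclose(d2[i], dmin[i], rtol=0, atol=1e-12)
            out[start + i] = model.train_labels[ties].min()
    return out


@dataclass
class HabitatMap:
    labels: np.ndarray  # 0 outside ROI, 1..k inside
    k: int
    region: str = "GTVp"
    crop_offset: tuple[int, int, int] = (0, 0, 0)


def build_habitat_map(
    spmap: SuperpixelMap,
    sp_labels: np.ndarray,
    k: int,
    region: str = "GTVp",
    crop_offset: tuple[int, int, int] = (0, 0, 0),
) -> HabitatMap:
    """Replace each superpixel id by its habitat label (0 stays 0)."""
    sp_labels = np.asarray(sp_labels)
    if sp_labels.shape[0] != spmap.n_sp:
        raise ValueError(
            f"got {sp_labels.shape[0]} labels for {spmap.n_sp} superpixels"
        )
    lut = np.zeros(spmap.n_sp + 1, dtype=np.int32)
    lut[1:] = sp_labels
    return HabitatMap(
        labels=lut[spmap.labels], k=k, region=region, crop_offset=crop_offset
    )


def evaluate_habitat_k(
    embedding: np.ndarray,
    k_candidates: tuple[int, ...] = (4, 6, 8),
    seed: int = 0,
    kmeans_max_iter: int = 100,
    kmeans_replicates: int = 10,
) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Cluster the embedding at each candidate k and score the labeling
    with the silhouette coefficient and Calinski-Harabasz index.

    Returns the per-k metric table and the labels per k (1-based).
    """
    rows = []
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_candidates:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=kmeans_replicates,
            max_iter=kmeans_max_iter,
            random_state=seed,
        ).fit(embedding)
        lab = km.labels_
        if len(np.unique(lab)) < 2:
            raise ValueError(f"degenerate clustering at k={k}")
        rows.append(
            {
                "k": k,
                "silhouette": float(silhouette_score(embedding, lab)),
                "ch_score": float(calinski_harabasz_score(embedding, lab)),
            }
        )
        labels_by_k[k] = lab.astype(np.int32) + 1
    return pd.DataFrame(rows), labels_by_k


def select_habitat_k(metrics: pd.DataFrame) -> int:
    """argmax silhouette; exact ties broken by the larger CH score."""
    t = metrics.sort_values(
        ["silhouette", "ch_score"], ascending=False, kind="stable"
    )
    return int(t.iloc[0]["k"])
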
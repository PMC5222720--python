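"""Quantification of RNA-FISH cloud images.

Per-nucleus, per-channel measurements on two-channel 3D stacks:

* a computed intensity threshold (Otsu's between-class-variance criterion
  on a 256-bin histogram of the nucleus);
* cloud segmentation as 26-connected components of the above-threshold
  voxel set, with a minimum-size filter;
* per-cloud volume (µm³), intensity-weighted centroid (µm) and a unitless
  *dispersion*: the intensity-weighted mean distance of the cloud's voxels
  from its centroid, divided by the radius of the sphere of equal volume.
  A uniform solid ball scores 3/4 regardless of size, a compact shell or
  scattered signal scores higher, a single voxel scores 0;
* channel co-localization: the Spearman correlation of the two channels'
  intensities over the voxels above either channel's threshold — positive
  when the signals occupy the same territory, negative when each channel
  is bright where the other is background;
* population summaries: cloud-count patterns (0/1/2+ clouds), positive
  fractions per group with a rank trend across ordered groups, and exact
  contingency comparisons of pattern counts between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

from xaquant.stats import RankSumResult, compare_contingency, rank_sum_test, spearman
from xaquant.synth_fish import NucleusImage

N_HIST_BINS = 256
PATTERN_CATEGORIES = ("0", "1", "2+")


@dataclass
class CloudMeasurement:
    """One segmented cloud: size, position and shape summary."""

    channel: int
    label: int
    n_voxels: int
    volume_um3: float
    centroid_um: tuple[float, float, float]
    dispersion: float
    integrated_intensity: float


@dataclass
class ColocResult:
    """Per-nucleus co-localization of the two channels."""

    threshold_ch1: float
    threshold_ch2: float
    n_voxels_used: int
    spearman_r: float  # NaN when undefined


def compute_threshold(channel_image: np.ndarray) -> float:
    """Otsu threshold of a channel: 256 bins between min and max.

    The returned threshold is the histogram bin edge that maximizes the
    between-class variance of the below/above split (ties broken toward
    the lowest edge), so it always lies strictly between the image minimum
    and maximum.  Raises on a constant image.
    """
    data = np.asarray(channel_image, dtype=float).ravel()
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("no threshold separable: image is constant")
    hist, edges = np.histogram(data, bins=N_HIST_BINS, range=(lo, hi))
    w = hist.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(w)[:-1]                      # class sizes for splits after bin t
    w1 = w.sum() - w0
    m = np.cumsum(w * centers)[:-1]
    m_total = (w * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m / w0
        mu1 = (m_total - m) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where((w0 > 0) & (w1 > 0), between, -np.inf)
    # plateaus happen (empty bins between modes leave the split free):
    # take the lowest edge within relative 1e-9 of the maximum
    vmax = between.max()
    t = int(np.argmax(between >= vmax - 1e-9 * abs(vmax)))
    return float(edges[t + 1])


def segment_clouds(
    channel_image: np.ndarray,
    threshold: float,
    voxel_size: tuple[float, float, float],
    min_voxels: int = 27,
    channel: int = 0,
) -> list[CloudMeasurement]:
    """26-connected components of the above-threshold voxel set.

    Components smaller than ``min_voxels`` are discarded; the rest are
    returned ordered by integrated intensity, brightest first, each with
    volume, intensity-weighted centroid and dispersion.
    """
    img = np.asarray(channel_image, dtype=float)
    mask = img >= threshold
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n_labels = scipy.ndimage.label(mask, structure=structure)
    voxel_volume = float(np.prod(voxel_size))
    out = []
    for lab in range(1, n_labels + 1):
        comp = labels == lab
        n_vox = int(comp.sum())
        if n_vox < min_voxels:
            continue
        out.append(
            CloudMeasurement(
                channel=channel,
                label=lab,
                n_voxels=n_vox,
                volume_um3=n_vox * voxel_volume,
                centroid_um=tuple(_weighted_centroid(img, comp, voxel_size)),
                dispersion=dispersion(img, comp, voxel_size),
                integrated_intensity=float(img[comp].sum()),
            )
        )
    out.sort(key=lambda c: -c.integrated_intensity)
    return out


def _weighted_centroid(img, mask, voxel_size) -> np.ndarray:
    coords = np.argwhere(mask) * np.asarray(voxel_size, dtype=float)
    weights = img[mask]
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    return (coords * weights[:, None]).sum(axis=0) / weights.sum()


def dispersion(
    channel_image: np.ndarray,
    cloud_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> float:
    """Unitless spread of a signal about its intensity-weighted centroid.

    D = (intensity-weighted mean Euclidean distance, in µm, of the mask's
    voxels from the intensity-weighted centroid) / r_eq, with r_eq the
    radius of the sphere whose volume equals the mask volume.  D = 0 for a
    single voxel; D -> 3/4 for a uniform solid ball; larger values mean a
    more scattered signal.  Invariant under voxel-grid translation and
    (up to discretization) under isotropic rescaling of the voxel size.
    """
    mask = np.asarray(cloud_mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("empty cloud mask")
    img = np.asarray(channel_image, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    coords = np.argwhere(mask) * vs
    weights = img[mask]
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    centroid = (coords * weights[:, None]).sum(axis=0) / weights.sum()
    dist = np.linalg.norm(coords - centroid, axis=1)
    mean_dist = float((dist * weights).sum() / weights.sum())
    volume = n_vox * float(np.prod(vs))
    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return mean_dist / r_eq


def colocalize(
    ch1: np.ndarray,
    ch2: np.ndarray,
    thr1: float,
    thr2: float,
    voxel_set: str = "union",
) -> ColocResult:
    """Spearman correlation of two channels over their signal voxels.

    The voxel set is the union (default) of the two above-threshold sets —
    keeping voxels that are signal in either channel preserves the
    anti-correlated regime where each channel is bright over the other's
    background — or their intersection (``voxel_set="intersection"``).
    Fewer than 3 usable voxels, or zero variance in either channel over
    the set, flag the correlation as undefined (NaN).
    """
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if voxel_set == "union":
        mask = (a >= thr1) | (b >= thr2)
    elif voxel_set == "intersection":
        mask = (a >= thr1) & (b >= thr2)
    else:
        raise ValueError("voxel_set must be 'union' or 'intersection'")
    x, y = a[mask], b[mask]
    n = int(mask.sum())
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return ColocResult(float(thr1), float(thr2), n, float("nan"))
    r = float(scipy.stats.spearmanr(x, y).statistic)
    return ColocResult(float(thr1), float(thr2), n, r)


def colocalize_nucleus(
    nucleus: NucleusImage,
    thresholds: tuple[float, float] | None = None,
    voxel_set: str = "union",
    max_project: bool = False,
) -> ColocResult:
    """Co-localization of one nucleus, thresholds computed if not given."""
    ch1, ch2 = nucleus.channels[0], nucleus.channels[1]
    if max_project:
        ch1, ch2 = ch1.max(axis=0), ch2.max(axis=0)
    if thresholds is None:
        thresholds = (compute_threshold(ch1), compute_threshold(ch2))
    return colocalize(ch1, ch2, thresholds[0], thresholds[1], voxel_set=voxel_set)


def coloc_population(
    nuclei: Sequence[NucleusImage],
    thresholds: tuple[float, float] | None = None,
    voxel_set: str = "union",
) -> dict:
    """Per-nucleus correlation list and its median over a population."""
    rs = [
        colocalize_nucleus(nuc, thresholds=thresholds, voxel_set=voxel_set).spearman_r
        for nuc in nuclei
    ]
    defined = [r for r in rs if not np.isnan(r)]
    return {
        "r_values": rs,
        "median_r": float(np.median(defined)) if defined else float("nan"),
        "n_defined": len(defined),
    }


def count_clouds_patterns(
    nuclei: Sequence[Mapping],
    thresholds: tuple[float, float],
    voxel_size: tuple[float, float, float] | None = None,
    min_voxels: int = 27,
) -> dict:
    """Cloud-count patterns (0/1/2+ per channel) and positive fractions.

    ``nuclei`` is a sequence of dicts with keys ``group`` and ``image``
    (as produced by :func:`xaquant.synth_fish.simulate_population`).
    Cloud counts are clipped to the categories 0, 1, 2+.  Returns per-group
    category counts per channel and the positive fraction (count >= 1).
    """
    rows = []
    for entry in nuclei:
        img: NucleusImage = entry["image"]
        vs = voxel_size or img.voxel_size
        for ch in (0, 1):
            clouds = segment_clouds(
                img.channels[ch], thresholds[ch], vs, min_voxels=min_voxels, channel=ch
            )
            count = min(len(clouds), 2)
            rows.append(
                {
                    "group": entry["group"],
                    "nucleus_id": entry.get("nucleus_id", ""),
                    "channel": ch,
                    "n_clouds": len(clouds),
                    "category": PATTERN_CATEGORIES[count],
                    "positive": len(clouds) >= 1,
                }
            )
    per_nucleus = pd.DataFrame(rows)
    counts = (
        per_nucleus.groupby(["group", "channel", "category"], sort=True)
        .size()
        .unstack("category", fill_value=0)
        .reindex(columns=list(PATTERN_CATEGORIES), fill_value=0)
    )
    fractions = (
        per_nucleus.groupby(["group", "channel"], sort=True)["positive"].mean().rename("positive_fraction")
    )
    return {"per_nucleus": per_nucleus, "pattern_counts": counts, "positive_fractions": fractions}


def fraction_trend(fractions: Sequence[float], group_order: Sequence[str] | None = None) -> float:
    """Spearman correlation of positive fraction against group rank.

    ``fractions`` ordered to match ``group_order`` (earliest group first);
    at least 3 groups required; constant fractions give NaN (flagged
    undefined) rather than an error.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) < 3:
        raise ValueError("need >= 3 groups for a trend")
    if group_order is not None and len(group_order) != len(fractions):
        raise ValueError("group_order length must match fractions")
    r = spearman(np.arange(len(fractions), dtype=float), fractions)
    if np.isnan(r):
        warnings.warn("constant fractions: trend undefined", stacklevel=2)
    return r


def compare_patterns(counts_a: Sequence[int], counts_b: Sequence[int]) -> dict:
    """Exact contingency comparison of two groups' pattern counts.

    Rows are groups, columns the shared pattern categories.  2×2 tables
    use Fisher's exact test; larger tables are exact (Freeman-Halton full
    enumeration) when the total count is <= 30 and chi-square with a
    warning otherwise; zero-margin tables give p = 1 with a warning.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("pattern categories must match between groups")
    return compare_contingency(np.vstack([a, b]))


def compare_measurements(values_a, values_b) -> RankSumResult:
    """Wilcoxon rank-sum comparison of two measurement distributions.

    Same contract as :func:`xaquant.allelic.compare_score_groups` (shared
    implementation): two-sided, exact for combined n <= 20.
    """
    return rank_sum_test(values_a, values_b)


def measure_nucleus(
    nucleus: NucleusImage,
    thresholds: tuple[float, float] | None = None,
    min_voxels: int = 27,
) -> list[CloudMeasurement]:
    """Segment and measure both channels of one nucleus."""
    out = []
    for ch in (0, 1):
        img = nucleus.channels[ch]
        thr = thresholds[ch] if thresholds is not None else compute_threshold(img)
        out.extend(
            segment_clouds(img, thr, nucleus.voxel_size, min_voxels=min_voxels, channel=ch)
        )
    return out
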
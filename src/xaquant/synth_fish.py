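"""Synthetic two-channel 3D RNA-FISH nuclei with ground truth.

Each nucleus is a two-channel voxel stack emulating XIST-like (channel 0)
and XACT-like (channel 1) lncRNA clouds.  A cloud is a sum of ``n_puncta``
isotropic Gaussian puncta whose centers scatter normally (sd
``cloud_spread``, in µm) about the cloud center — the particulate texture
of real RNA-FISH accumulations — so ``cloud_spread`` is the ground truth
for the dispersion metric of :mod:`xaquant.fishquant`.  Paired clouds in
the two channels are displaced by ``inter_channel_offset`` µm, steering
channel overlap from complete (offset 0) to none (offset far beyond the
punctum size and spread).  Geometry is isotropic in µm over an anisotropic
voxel grid; Gaussian background noise is added and clipped at zero.

Images round-trip through multi-page TIFF (z-planes interleaved by
channel) plus a plain-text JSON sidecar holding voxel size, channel order
and ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass
class ChannelConfig:
    """One channel's cloud model.

    ``n_clouds`` is 0, 1 or 2; each cloud is ``n_puncta`` Gaussian puncta
    of width ``punctum_sigma`` µm and peak amplitude ``peak_intensity``,
    scattered with sd ``cloud_spread`` µm about the cloud center.
    """

    n_clouds: int = 1
    n_puncta: int = 150
    punctum_sigma: float = 0.25
    cloud_spread: float = 0.5
    peak_intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.n_clouds not in (0, 1, 2):
            raise ValueError("n_clouds must be 0, 1 or 2")
        if self.n_puncta < 1 or self.punctum_sigma <= 0 or self.cloud_spread < 0:
            raise ValueError("invalid punctum parameters")


@dataclass
class FishSimConfig:
    """Geometry, noise and per-channel cloud parameters of one nucleus.

    ``shape`` is (z, y, x) voxels and ``voxel_size`` µm per axis in the
    same order; the nucleus is a sphere of ``nucleus_radius`` µm centered
    in the stack, and all cloud centers are kept inside it.
    """

    shape: tuple[int, int, int] = (16, 64, 64)
    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1)
    nucleus_radius: float = 2.0
    channels: tuple[ChannelConfig, ChannelConfig] = field(
        default_factory=lambda: (ChannelConfig(), ChannelConfig())
    )
    inter_channel_offset: float = 0.0
    background_mean: float = 10.0
    background_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError("shape must be three positive voxel counts")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.nucleus_radius <= 0 or self.inter_channel_offset < 0:
            raise ValueError("nucleus_radius must be positive, offset nonnegative")
        if len(self.channels) != 2:
            raise ValueError("exactly two channels are modeled")

    @classmethod
    def from_dict(cls, d: Mapping) -> "FishSimConfig":
        d = dict(d)
        for key in ("shape", "voxel_size"):
            if key in d:
                d[key] = tuple(d[key])
        if "channels" in d:
            d["channels"] = tuple(
                ch if isinstance(ch, ChannelConfig) else ChannelConfig(**ch)
                for ch in d["channels"]
            )
        return cls(**d)


@dataclass
class NucleusImage:
    """Two-channel 3D intensity stack with voxel size and ground truth."""

    channels: np.ndarray  # (2, z, y, x), nonnegative
    voxel_size: tuple[float, float, float]
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != 2:
            raise ValueError("channels must have shape (2, z, y, x)")
        if (self.channels < 0).any():
            raise ValueError("intensities must be nonnegative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")


def _image_center_um(shape, voxel_size) -> np.ndarray:
    return np.array([(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size)])


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        p = rng.uniform(-radius, radius, size=3)
        if np.dot(p, p) <= radius * radius:
            return p
    raise RuntimeError("could not place a point inside the nucleus")


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _add_punctum(
    img: np.ndarray,
    axes_um: Sequence[np.ndarray],
    center: np.ndarray,
    sigma: float,
    amplitude: float,
) -> None:
    """Add an isotropic Gaussian punctum within a ±4σ bounding box."""
    slices, local = [], []
    for ax, c in zip(axes_um, center):
        lo = int(np.searchsorted(ax, c - 4 * sigma, side="left"))
        hi = int(np.searchsorted(ax, c + 4 * sigma, side="right"))
        if lo >= hi:
            return
        slices.append(slice(lo, hi))
        local.append(ax[lo:hi] - c)
    dz, dy, dx = local
    d2 = (
        dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
    )
    img[tuple(slices)] += amplitude * np.exp(-d2 / (2.0 * sigma * sigma))


def simulate_nucleus(config: FishSimConfig) -> NucleusImage:
    """Render one two-channel nucleus from the configured cloud model.

    Channel-0 cloud centers are uniform within the nucleus (kept away from
    its surface by the cloud's own extent); each channel-1 cloud that has a
    channel-0 counterpart sits at that counterpart's center displaced by
    ``inter_channel_offset`` µm in a random direction, surplus clouds are
    placed independently.  Identical configs (and seeds) give identical
    voxel arrays.
    """
    rng = np.random.default_rng(config.seed)
    center_um = _image_center_um(config.shape, config.voxel_size)
    axes_um = [
        np.arange(n) * v for n, v in zip(config.shape, config.voxel_size)
    ]

    def margin(ch: ChannelConfig) -> float:
        # keep cloud centers away from the nuclear surface by roughly one
        # cloud extent, but never so far that placement becomes infeasible
        return min(ch.punctum_sigma + ch.cloud_spread, config.nucleus_radius * 0.45)

    ch0, ch1 = config.channels
    centers0 = [
        center_um + _uniform_in_sphere(rng, config.nucleus_radius - margin(ch0))
        for _ in range(ch0.n_clouds)
    ]
    centers1 = []
    inner1 = config.nucleus_radius - margin(ch1)
    for i in range(ch1.n_clouds):
        if i < len(centers0):
            placed = False
            for _ in range(_MAX_PLACEMENT_ATTEMPTS):
                cand = centers0[i] + config.inter_channel_offset * _random_unit_vector(rng)
                if np.linalg.norm(cand - center_um) <= max(inner1, 0.0) + 1e-9:
                    centers1.append(cand)
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    "could not place an offset channel-1 cloud inside the nucleus; "
                    "reduce inter_channel_offset or enlarge the nucleus"
                )
        else:
            centers1.append(center_um + _uniform_in_sphere(rng, max(inner1, 0.0)))

    stack = np.zeros((2,) + tuple(config.shape), dtype=np.float64)
    truth_clouds = []
    for ci, (ch, centers) in enumerate(((ch0, centers0), (ch1, centers1))):
        ch_truth = []
        for cloud_center in centers:
            puncta = cloud_center + rng.normal(0.0, ch.cloud_spread, size=(ch.n_puncta, 3))
            for p in puncta:
                _add_punctum(stack[ci], axes_um, p, ch.punctum_sigma, ch.peak_intensity)
            ch_truth.append(
                {
                    "center_um": [float(x) for x in cloud_center],
                    "spread_um": ch.cloud_spread,
                    "n_puncta": ch.n_puncta,
                }
            )
        truth_clouds.append(ch_truth)

    noise = rng.normal(config.background_mean, config.background_sd, size=stack.shape)
    stack = np.clip(stack + noise, 0.0, None)

    truth = {
        "clouds_by_channel": truth_clouds,
        "inter_channel_offset_um": config.inter_channel_offset,
        "n_clouds_by_channel": [ch0.n_clouds, ch1.n_clouds],
    }
    return NucleusImage(stack.astype(np.float32), tuple(config.voxel_size), truth)


def simulate_population(
    config: FishSimConfig,
    n_nuclei_by_group: Mapping[str, int],
    positive_fraction_by_group: Mapping[str, float],
) -> list[dict]:
    """A labelled population of nuclei with known positive fractions.

    Per group, each nucleus is independently *positive* (rendered with the
    configured clouds) with the group's probability, and otherwise pure
    background (zero clouds in both channels).  Returns a list of dicts
    ``{"group", "nucleus_id", "image", "true_positive"}``.
    """
    for g, f in positive_fraction_by_group.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"positive fraction for group {g!r} must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        sum(int(n) for n in n_nuclei_by_group.values()), dtype=np.uint32
    )
    negative_channels = tuple(
        dataclasses.replace(ch, n_clouds=0) for ch in config.channels
    )
    out, k = [], 0
    for group, n in n_nuclei_by_group.items():
        frac = positive_fraction_by_group[group]
        for i in range(int(n)):
            positive = bool(rng.random() < frac)
            cfg = dataclasses.replace(
                config,
                seed=int(seeds[k]),
                channels=config.channels if positive else negative_channels,
            )
            img = simulate_nucleus(cfg)
            img.ground_truth["positive"] = positive
            out.append(
                {
                    "group": group,
                    "nucleus_id": f"{group}_n{i:03d}",
                    "image": img,
                    "true_positive": positive,
                }
            )
            k += 1
    return out


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar round trip
# ---------------------------------------------------------------------------

def write_nucleus(nucleus: NucleusImage, path: str | Path) -> Path:
    """Write one nucleus as multi-page TIFF with a JSON sidecar.

    Pages are z-planes interleaved by channel (z-major: ch0/z0, ch1/z0,
    ch0/z1, ...); the sidecar carries voxel size, channel order and ground
    truth, so the TIFF itself stays bit-exact and reader-agnostic.
    """
    path = Path(path)
    z = nucleus.channels.shape[1]
    pages = np.transpose(nucleus.channels, (1, 0, 2, 3)).reshape(
        (2 * z,) + nucleus.channels.shape[2:]
    )
    tifffile.imwrite(path, pages)
    sidecar = {
        "voxel_size_um": list(nucleus.voxel_size),
        "n_channels": 2,
        "shape_zyx": list(nucleus.channels.shape[1:]),
        "page_order": "z_major_channel_interleaved",
        "ground_truth": nucleus.ground_truth,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_nucleus(path: str | Path) -> NucleusImage:
    """Inverse of :func:`write_nucleus`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    pages = tifffile.imread(path)
    z, y, x = sidecar["shape_zyx"]
    channels = np.transpose(pages.reshape(z, 2, y, x), (1, 0, 2, 3))
    return NucleusImage(
        channels, tuple(sidecar["voxel_size_um"]), sidecar.get("ground_truth")
    )
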
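"""Ground-truth scene generation and microscope forward model.

Downstream quantification is validated against simulated fields of
liposome clusters with known ground truth.  A scene holds clusters whose
per-cluster monomer counts follow a configurable size law (geometric
with a growing mean, as produced by constant-kernel aggregation, or a
fixed size), whose morphologies are compact (hexagonally packed),
chain-like, or fractal (hit-and-stick growth), and whose two fluorescence
channels (liposome dye, RNA dye) carry controllable per-monomer photon
fluxes.  Rendering convolves each monomer with an isotropic 2-D Gaussian
point-spread function, adds a slowly varying background plane, and
applies Poisson shot noise followed by Gaussian read noise.

Everything is deterministic for a fixed seed; time-lapse stacks are
written as multi-page TIFF with a plain-CSV ground-truth table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .image_quant import ImageFrame
from .smoluchowski import ClusterStateVector

__all__ = [
    "ClusterTruth",
    "GroundTruthScene",
    "NoiseModel",
    "PlacementError",
    "generate_fractal_cluster",
    "generate_ground_truth",
    "scene_from_sizes",
    "render_frame",
    "generate_timelapse",
    "scene_table",
    "match_features_to_truth",
]

MORPHOLOGIES = ("compact", "chain", "fractal")


class PlacementError(RuntimeError):
    """Raised when non-overlapping cluster placement fails."""


@dataclass
class ClusterTruth:
    """One simulated cluster: identity, size, morphology and fluxes."""

    cluster_id: int
    monomer_count: int
    monomer_offsets: np.ndarray          # (k, 2) µm relative to centroid
    centroid: tuple[float, float]        # (x, y) µm in the field
    flux_liposome: float = 1000.0        # photons per monomer
    flux_rna: float = 0.0
    morphology: str = "fractal"

    def __post_init__(self) -> None:
        self.monomer_offsets = np.asarray(self.monomer_offsets, dtype=float)
        if self.monomer_count < 1:
            raise ValueError("monomer_count must be >= 1")
        if self.monomer_offsets.shape != (self.monomer_count, 2):
            raise ValueError("monomer_offsets must have shape (k, 2)")
        if self.flux_liposome < 0 or self.flux_rna < 0:
            raise ValueError("fluxes must be non-negative")
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"morphology must be one of {MORPHOLOGIES}")

    @property
    def rg_true(self) -> float:
        """Radius of gyration of the monomer point set (µm), PSF-free."""
        off = self.monomer_offsets - self.monomer_offsets.mean(axis=0)
        return float(np.sqrt((off ** 2).sum(axis=1).mean()))

    @property
    def extent(self) -> float:
        """Bounding radius around the centroid (µm)."""
        return float(np.sqrt((self.monomer_offsets ** 2).sum(axis=1)).max())


@dataclass
class GroundTruthScene:
    """The simulated truth behind one rendered field of view."""

    scene_id: str
    pixel_size: float                    # µm per pixel
    field_shape: tuple[int, int]         # (rows, cols)
    clusters: list[ClusterTruth] = field(default_factory=list)
    timestamp: float = 0.0               # minutes since mixing

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.field_shape) < 1:
            raise ValueError("field_shape must be strictly positive")
        h = self.field_shape[0] * self.pixel_size
        w = self.field_shape[1] * self.pixel_size
        for c in self.clusters:
            x, y = c.centroid
            if not (0.0 <= x <= w and 0.0 <= y <= h):
                raise ValueError(f"cluster {c.cluster_id} centroid outside the field")

    @property
    def total_monomers(self) -> int:
        return sum(c.monomer_count for c in self.clusters)


@dataclass
class NoiseModel:
    """Camera and optics model for rendering.

    Defaults put segmentation in a regime where thresholding is
    nontrivial but solvable: Poisson shot noise on, 2-photon read noise,
    100-photon background.
    """

    background_level: float = 100.0      # photons per pixel
    background_gradient: tuple[float, float] = (0.0, 0.0)  # photons/px along (row, col)
    gaussian_read_noise_sd: float = 2.0  # photons
    poisson_shot_noise: bool = True
    psf_sigma: float = 0.3               # µm

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.gaussian_read_noise_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")

    @classmethod
    def noiseless(cls, background: float = 0.0, psf_sigma: float = 0.3) -> "NoiseModel":
        return cls(background_level=background, background_gradient=(0.0, 0.0),
                   gaussian_read_noise_sd=0.0, poisson_shot_noise=False,
                   psf_sigma=psf_sigma)


# --------------------------------------------------------------------------
# cluster morphologies
# --------------------------------------------------------------------------

def generate_fractal_cluster(k: int, target_df: float = 1.6,
                             monomer_radius: float = 0.25,
                             seed: int | np.random.Generator = 0,
                             max_steps: int = 400_000) -> np.ndarray:
    """Monomer offsets for a k-monomer cluster with tunable openness.

    target_df = 1 gives a straight chain (monomers spaced one diameter);
    target_df = 2 gives hexagonal close packing (compact disk);
    intermediate values use hit-and-stick growth (each new monomer
    random-walks from afar until it touches the existing cluster), which
    empirically yields mass-size exponents around 1.4-1.7 in 2-D.
    Offsets are returned centered on the centroid, in µm.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (1.0 <= target_df <= 2.0):
        raise ValueError("target_df must lie in [1, 2] for 2-D scenes")
    if monomer_radius <= 0:
        raise ValueError("monomer_radius must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = 2.0 * monomer_radius
    if k == 1:
        return np.zeros((1, 2))
    if target_df <= 1.0 + 1e-9:
        xs = d * np.arange(k, dtype=float)
        pts = np.column_stack([xs, np.zeros(k)])
    elif target_df >= 2.0 - 1e-9:
        pts = _hex_packing(k, d)
    else:
        pts = _hit_and_stick(k, d, rng, max_steps)
    return pts - pts.mean(axis=0)


def _hex_packing(k: int, d: float) -> np.ndarray:
    """k sites of a triangular lattice, closest to the origin first."""
    m = int(np.ceil(np.sqrt(k))) + 2
    i, j = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    x = d * (i + 0.5 * (j % 2))
    y = d * (np.sqrt(3) / 2.0) * j
    pts = np.column_stack([x.ravel(), y.ravel()])
    order = np.argsort((pts ** 2).sum(axis=1), kind="stable")
    return pts[order[:k]].astype(float)


def _hit_and_stick(k: int, d: float, rng: np.random.Generator,
                   max_steps: int) -> np.ndarray:
    pts = np.zeros((k, 2))
    n = 1
    steps = 0
    while n < k:
        occupied = pts[:n]
        r_max = np.sqrt((occupied ** 2).sum(axis=1)).max()
        launch = r_max + 5.0 * d
        kill = launch + 10.0 * d
        theta = rng.uniform(0, 2 * np.pi)
        pos = launch * np.array([np.cos(theta), np.sin(theta)])
        while True:
            steps += 1
            if steps > max_steps:
                raise RuntimeError("hit-and-stick walk exceeded the step budget")
            delta = occupied - pos
            dist = np.sqrt((delta ** 2).sum(axis=1))
            i_near = int(dist.argmin())
            if dist[i_near] <= d * (1.0 + 1e-9):
                # stick at exact contact along the approach direction
                u = (pos - occupied[i_near])
                norm = np.sqrt((u ** 2).sum())
                u = u / norm if norm > 0 else np.array([1.0, 0.0])
                cand = occupied[i_near] + d * u
                cand_d = np.sqrt(((occupied - cand) ** 2).sum(axis=1))
                if cand_d.min() < d * (1.0 - 1e-9):
                    # contact point overlaps a third monomer: relaunch
                    theta = rng.uniform(0, 2 * np.pi)
                    pos = launch * np.array([np.cos(theta), np.sin(theta)])
                    continue
                pts[n] = cand
                n += 1
                break
            if np.sqrt((pos ** 2).sum()) > kill:
                theta = rng.uniform(0, 2 * np.pi)
                pos = launch * np.array([np.cos(theta), np.sin(theta)])
                continue
            step = max(0.5 * d, dist[i_near] - d)
            phi = rng.uniform(0, 2 * np.pi)
            pos = pos + step * np.array([np.cos(phi), np.sin(phi)])
    return pts


# --------------------------------------------------------------------------
# scene generation
# --------------------------------------------------------------------------

def generate_ground_truth(n_clusters: int,
                          size_law: tuple[str, float] = ("geometric", 4.0),
                          morphology: str = "fractal",
                          target_df: float = 1.6,
                          coloc_fraction: float = 1.0,
                          field_shape: tuple[int, int] = (512, 512),
                          pixel_size: float = 0.325,
                          monomer_radius: float = 0.25,
                          flux_liposome: float = 1000.0,
                          flux_rna: float = 600.0,
                          border_margin: float = 2.0,
                          seed: int | np.random.Generator = 0,
                          timestamp: float = 0.0,
                          scene_id: str = "scene",
                          max_retries: int = 1000) -> GroundTruthScene:
    """Random non-overlapping scene with a prescribed cluster-size law.

    ``size_law`` is ("geometric", mean) -- geometric on {1, 2, ...} with
    the given mean, the scaled cluster-size law of constant-kernel
    aggregation -- or ("fixed", k).  A fraction ``coloc_fraction`` of
    clusters carries RNA flux; the rest render dark in the RNA channel.
    Placement is uniform with bounded rejection against overlap; an
    over-packed field raises :class:`PlacementError` rather than
    silently corrupting the ground truth.
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    if not (0.0 <= coloc_fraction <= 1.0):
        raise ValueError("coloc_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kind, param = size_law
    if kind == "geometric":
        if param < 1.0:
            raise ValueError("geometric size law needs mean >= 1")
        ks = (rng.geometric(1.0 / param, size=n_clusters) if n_clusters else
              np.array([], dtype=int))
    elif kind == "fixed":
        if int(param) < 1:
            raise ValueError("fixed size law needs k >= 1")
        ks = np.full(n_clusters, int(param))
    else:
        raise ValueError("size_law kind must be 'geometric' or 'fixed'")

    h_um = field_shape[0] * pixel_size
    w_um = field_shape[1] * pixel_size
    n_rna = int(round(coloc_fraction * n_clusters))
    rna_flags = np.zeros(n_clusters, dtype=bool)
    rna_flags[rng.permutation(n_clusters)[:n_rna]] = True

    clusters: list[ClusterTruth] = []
    placed_xy = np.empty((0, 2))
    placed_r = np.empty(0)
    for cid, k in enumerate(ks):
        offsets = _offsets_for(morphology, int(k), target_df, monomer_radius, rng)
        extent = float(np.sqrt((offsets ** 2).sum(axis=1)).max()) + monomer_radius
        lo = border_margin + extent
        if lo >= w_um - lo or lo >= h_um - lo:
            raise PlacementError(f"cluster {cid} (extent {extent:.2f} µm) "
                                 "does not fit inside the field")
        xy = _place_one(rng, lo, w_um, h_um, extent, placed_xy, placed_r,
                        max_retries, cid)
        placed_xy = np.vstack([placed_xy, xy])
        placed_r = np.append(placed_r, extent)
        clusters.append(ClusterTruth(
            cluster_id=cid, monomer_count=int(k), monomer_offsets=offsets,
            centroid=(float(xy[0]), float(xy[1])),
            flux_liposome=flux_liposome,
            flux_rna=flux_rna if rna_flags[cid] else 0.0,
            morphology=morphology))
    return GroundTruthScene(scene_id=scene_id, pixel_size=pixel_size,
                            field_shape=tuple(field_shape), clusters=clusters,
                            timestamp=timestamp)


def _place_one(rng: np.random.Generator, lo: float, w_um: float, h_um: float,
               extent: float, placed_xy: np.ndarray, placed_r: np.ndarray,
               max_retries: int, cid: int) -> np.ndarray:
    """Uniform rejection placement against already-placed bounding circles."""
    for _ in range(max_retries):
        xy = np.array([rng.uniform(lo, w_um - lo), rng.uniform(lo, h_um - lo)])
        if placed_xy.size == 0:
            return xy
        d = np.hypot(placed_xy[:, 0] - xy[0], placed_xy[:, 1] - xy[1])
        if np.all(d > placed_r + extent):
            return xy
    raise PlacementError(f"could not place cluster {cid} after {max_retries} "
                         "retries; field too crowded")


def _offsets_for(morphology: str, k: int, target_df: float,
                 monomer_radius: float, rng: np.random.Generator) -> np.ndarray:
    if morphology == "chain":
        df = 1.0
    elif morphology == "compact":
        df = 2.0
    elif morphology == "fractal":
        df = target_df
    else:
        raise ValueError(f"morphology must be one of {MORPHOLOGIES}")
    offsets = generate_fractal_cluster(k, target_df=df,
                                       monomer_radius=monomer_radius, seed=rng)
    # random orientation so chains do not align with the pixel grid
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return offsets @ rot.T


def scene_from_sizes(ks: Sequence[int],
                     field_shape: tuple[int, int] = (512, 512),
                     pixel_size: float = 0.325,
                     morphology: str = "fractal", target_df: float = 1.6,
                     monomer_radius: float = 0.25,
                     coloc_fraction: float = 1.0,
                     flux_liposome: float = 1000.0, flux_rna: float = 600.0,
                     seed: int | np.random.Generator = 0,
                     scene_id: str = "scene", timestamp: float = 0.0
                     ) -> GroundTruthScene:
    """Scene with explicitly prescribed cluster sizes (calibration fields)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _scene_with_sizes(list(ks), field_shape, pixel_size, morphology,
                             target_df, monomer_radius, coloc_fraction,
                             flux_liposome, flux_rna, rng, scene_id, timestamp)


def match_features_to_truth(features, scene: GroundTruthScene,
                            max_dist_um: float = 1.5) -> pd.DataFrame:
    """Pair measured features with ground-truth clusters by centroid distance.

    ``features`` is a sequence of measured feature records (from the
    quantification stage).  Returns one row per valid, non-border feature
    whose intensity-weighted centroid lies within ``max_dist_um`` of a
    true cluster centroid: columns k (true monomer count), rg_true_um,
    total_intensity, rg_um, circularity, feature_id, cluster_id, dist_um.
    """
    rows = []
    for f in features:
        if not f.valid or f.border_flag:
            continue
        r, c = f.centroid_rc
        x_um = c * scene.pixel_size
        y_um = r * scene.pixel_size
        best, best_d = None, np.inf
        for cl in scene.clusters:
            d = np.hypot(cl.centroid[0] - x_um, cl.centroid[1] - y_um)
            if d < best_d:
                best, best_d = cl, d
        if best is not None and best_d <= max_dist_um:
            rows.append({"feature_id": f.feature_id, "cluster_id": best.cluster_id,
                         "k": best.monomer_count, "rg_true_um": best.rg_true,
                         "total_intensity": f.total_intensity, "rg_um": f.rg_um,
                         "circularity": f.circularity, "dist_um": best_d})
    return pd.DataFrame(rows, columns=["feature_id", "cluster_id", "k",
                                       "rg_true_um", "total_intensity",
                                       "rg_um", "circularity", "dist_um"])


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_frame(scene: GroundTruthScene, channel: str,
                 noise: NoiseModel | None = None,
                 seed: int | np.random.Generator = 0) -> ImageFrame:
    """Render one channel of a scene into a raster (photons per pixel).

    Each monomer contributes an isotropic Gaussian spot whose integrated
    flux equals its per-channel photon flux; a background plane is added,
    then Poisson shot noise and Gaussian read noise, and the result is
    clipped at zero.  Deterministic per seed.
    """
    if channel not in ("liposome", "rna"):
        raise ValueError("channel must be 'liposome' or 'rna'")
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = scene.field_shape
    img = np.zeros((rows, cols))
    sigma_px = noise.psf_sigma / scene.pixel_size
    half = int(np.ceil(5.0 * sigma_px)) + 1
    for c in scene.clusters:
        flux = c.flux_liposome if channel == "liposome" else c.flux_rna
        if flux <= 0:
            continue
        for off in c.monomer_offsets:
            x_um = c.centroid[0] + off[0]
            y_um = c.centroid[1] + off[1]
            col_c = x_um / scene.pixel_size
            row_c = y_um / scene.pixel_size
            r0 = max(0, int(np.floor(row_c)) - half)
            r1 = min(rows, int(np.ceil(row_c)) + half + 1)
            c0 = max(0, int(np.floor(col_c)) - half)
            c1 = min(cols, int(np.ceil(col_c)) + half + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            rr = np.arange(r0, r1)[:, None]
            cc = np.arange(c0, c1)[None, :]
            g = np.exp(-((rr - row_c) ** 2 + (cc - col_c) ** 2)
                       / (2.0 * sigma_px ** 2))
            img[r0:r1, c0:c1] += flux * g / (2.0 * np.pi * sigma_px ** 2)
    gr, gc = noise.background_gradient
    bg = (noise.background_level
          + gr * np.arange(rows)[:, None] + gc * np.arange(cols)[None, :])
    img = img + bg
    if noise.poisson_shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if noise.gaussian_read_noise_sd > 0:
        img = img + rng.normal(0.0, noise.gaussian_read_noise_sd, img.shape)
    img = np.clip(img, 0.0, None)
    return ImageFrame(raster=img, channel=channel, frame_index=0,
                      pixel_size=scene.pixel_size, timestamp=scene.timestamp)


# --------------------------------------------------------------------------
# time lapse
# --------------------------------------------------------------------------

def scene_table(scene: GroundTruthScene, frame: int = 0) -> pd.DataFrame:
    """Ground-truth table for one scene (one row per cluster)."""
    rows = [{
        "scene_id": scene.scene_id, "frame": frame,
        "cluster_id": c.cluster_id, "k": c.monomer_count,
        "x_um": c.centroid[0], "y_um": c.centroid[1],
        "rg_true_um": c.rg_true, "flux_lipo": c.flux_liposome,
        "flux_rna": c.flux_rna, "morphology": c.morphology,
    } for c in scene.clusters]
    return pd.DataFrame(rows, columns=["scene_id", "frame", "cluster_id", "k",
                                       "x_um", "y_um", "rg_true_um",
                                       "flux_lipo", "flux_rna", "morphology"])


def scenes_from_trajectory(trajectory: Sequence[ClusterStateVector],
                           field_shape: tuple[int, int] = (512, 512),
                           pixel_size: float = 0.325,
                           morphology: str = "fractal", target_df: float = 1.6,
                           monomer_radius: float = 0.25,
                           coloc_fraction: float = 1.0,
                           flux_liposome: float = 1000.0, flux_rna: float = 600.0,
                           seed: int | np.random.Generator = 0,
                           scene_id: str = "traj") -> list[GroundTruthScene]:
    """Instantiate scenes from simulated cluster-size censuses.

    Counts must be (near-)integer -- stochastic-simulation snapshots
    qualify -- so that each k-mer count materializes exactly and the
    per-frame total monomer mass is conserved in the ground truth.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    times = [s.t for s in trajectory]
    if np.any(np.diff(times) <= 0):
        raise ValueError("trajectory times must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scenes = []
    for state in trajectory:
        counts = np.rint(state.counts).astype(int)
        if np.max(np.abs(state.counts - counts)) > 1e-6:
            raise ValueError("trajectory counts must be integer-valued for rendering")
        ks = np.repeat(np.arange(1, counts.size + 1), counts)
        # place the prescribed sizes with the same non-overlap machinery
        scene = _scene_with_sizes(ks, field_shape, pixel_size, morphology,
                                  target_df, monomer_radius, coloc_fraction,
                                  flux_liposome, flux_rna, rng,
                                  scene_id, float(state.t))
        scenes.append(scene)
    return scenes


def _scene_with_sizes(ks, field_shape, pixel_size, morphology, target_df,
                      monomer_radius, coloc_fraction, flux_liposome, flux_rna,
                      rng, scene_id, timestamp) -> GroundTruthScene:
    h_um = field_shape[0] * pixel_size
    w_um = field_shape[1] * pixel_size
    n = len(ks)
    n_rna = int(round(coloc_fraction * n))
    rna_flags = np.zeros(n, dtype=bool)
    rna_flags[rng.permutation(n)[:n_rna]] = True
    clusters = []
    placed_xy = np.empty((0, 2))
    placed_r = np.empty(0)
    for cid, k in enumerate(ks):
        offsets = _offsets_for(morphology, int(k), target_df, monomer_radius, rng)
        extent = float(np.sqrt((offsets ** 2).sum(axis=1)).max()) + monomer_radius
        lo = 2.0 + extent
        xy = _place_one(rng, lo, w_um, h_um, extent, placed_xy, placed_r, 1000, cid)
        placed_xy = np.vstack([placed_xy, xy])
        placed_r = np.append(placed_r, extent)
        clusters.append(ClusterTruth(
            cluster_id=cid, monomer_count=int(k), monomer_offsets=offsets,
            centroid=(float(xy[0]), float(xy[1])),
            flux_liposome=flux_liposome,
            flux_rna=flux_rna if rna_flags[cid] else 0.0,
            morphology=morphology))
    return GroundTruthScene(scene_id=scene_id, pixel_size=pixel_size,
                            field_shape=tuple(field_shape), clusters=clusters,
                            timestamp=timestamp)


def generate_timelapse(trajectory: Sequence[GroundTruthScene] | Sequence[ClusterStateVector],
                       noise: NoiseModel | None = None,
                       seed: int | np.random.Generator = 0,
                       out_dir: str | Path | None = None,
                       stack_name: str = "stack.tif",
                       scene_kwargs: dict | None = None
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a two-channel time-lapse stack with its ground-truth table.

    ``trajectory`` is either explicit scenes or cluster-size censuses
    (converted via :func:`scenes_from_trajectory`).  Returns the stack as
    a (frames, 2, rows, cols) array (channel order liposome, rna) and the
    concatenated truth table; when ``out_dir`` is given, writes the stack
    as 16-bit multi-page TIFF plus truth CSV and a JSON config echo.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(trajectory[0], ClusterStateVector):
        scenes = scenes_from_trajectory(trajectory, seed=rng, **(scene_kwargs or {}))
    else:
        scenes = list(trajectory)
        times = [s.timestamp for s in scenes]
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("scene timestamps must be strictly increasing")

    frames = []
    tables = []
    for fi, scene in enumerate(scenes):
        lipo = render_frame(scene, "liposome", noise, rng)
        rna = render_frame(scene, "rna", noise, rng)
        frames.append(np.stack([lipo.raster, rna.raster]))
        tbl = scene_table(scene, frame=fi)
        tbl["time_min"] = scene.timestamp
        tables.append(tbl)
    stack = np.stack(frames)  # (T, C, rows, cols)
    truth = pd.concat(tables, ignore_index=True)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / stack_name,
                         np.clip(np.rint(stack), 0, 65535).astype(np.uint16),
                         metadata={"axes": "TCYX"})
        truth.to_csv(out / "truth.csv", index=False)
        cfg = {"n_frames": len(scenes), "channels": ["liposome", "rna"],
               "pixel_size_um": scenes[0].pixel_size,
               "field_shape": list(scenes[0].field_shape),
               "psf_sigma_um": noise.psf_sigma,
               "background_level": noise.background_level,
               "poisson_shot_noise": noise.poisson_shot_noise,
               "gaussian_read_noise_sd": noise.gaussian_read_noise_sd}
        (out / "generate_config.json").write_text(json.dumps(cfg, indent=2))
    return stack, truth
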
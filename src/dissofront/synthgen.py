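"""Synthetic immersion stacks and dissolution datasets with known truth.

Renders a disk-shaped tablet in a dyed medium: an inward dye front, an
outward translucent halo, a receding rough outer boundary, optional gas
bubbles and pixel noise.  Kinematics are prescribed (constant velocities),
not simulated from physics, so every stack ships with an exact sidecar of
ground-truth radii.  All randomness is driven by the spec seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .dissolution import KineticModelSpec, eval_model
from .errors import BadTimeAxisError, SceneSpecError
from .imaging import ImageStack

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "simulate_immersion_stack",
    "simulate_dissolution",
    "make_study_fixture",
    "MEDIUM_RGB",
    "TABLET_RGB",
]

# scene palette (float RGB in [0, 1]); appearance only, thresholds in the
# tracker are derived from the image itself
MEDIUM_RGB = np.array([0.10, 0.15, 0.85])
TABLET_RGB = np.array([0.80, 0.78, 0.55])
BUBBLE_RGB = np.array([0.98, 0.98, 0.98])
STAIN_ALPHA = 0.65  # dye-penetrated tablet blended toward medium colour
GEL_ALPHA = 0.5  # translucent halo: 50% tablet / 50% medium

_N_ROUGH = 360  # control angles for boundary roughness


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic immersion stack."""

    image_size: tuple[int, int] = (512, 512)
    radius_px: float = 127.0
    center: tuple[float, float] | None = None
    pixel_size_mm: float = 0.05
    frame_interval_min: float = 1.0
    n_frames: int = 31
    wetting_velocity: float = 0.0  # mm/min, inward
    gel_velocity: float = 0.0  # mm/min, outward
    erosion_velocity: float = 0.0  # mm/min, inward
    gel_max_thickness_mm: float | None = None
    roughness_sd_px: float = 0.0
    bubble_count: int = 0
    bubble_radius_px: tuple[float, float] = (4.0, 9.0)
    pixel_noise_sd: float = 0.0  # fraction of dynamic range
    seed: int = 0
    replicate_id: str = "rep1"
    medium: str = "water"

    def validate(self) -> None:
        if self.n_frames < 2:
            raise SceneSpecError("need at least 2 frames")
        if self.radius_px <= 0 or self.pixel_size_mm <= 0:
            raise SceneSpecError("radius and pixel size must be positive")
        if min(self.wetting_velocity, self.gel_velocity, self.erosion_velocity) < 0:
            raise SceneSpecError("velocities must be >= 0")
        t_end = (self.n_frames - 1) * self.frame_interval_min
        v_in = max(self.wetting_velocity, self.erosion_velocity)
        if v_in * t_end >= self.radius_px * self.pixel_size_mm:
            raise SceneSpecError("tablet consumed before last frame")
        cy, cx = self._center()
        margin = min(cy, cx, self.image_size[0] - 1 - cy, self.image_size[1] - 1 - cx)
        gel_growth = self.gel_velocity * t_end / self.pixel_size_mm
        if self.gel_max_thickness_mm is not None:
            gel_growth = min(gel_growth, self.gel_max_thickness_mm / self.pixel_size_mm)
        if self.radius_px + gel_growth + 4 >= margin:
            raise SceneSpecError("scene exceeds field of view")

    def _center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)


@dataclass
class GroundTruth:
    """True kinematics behind a rendered stack."""

    times_min: np.ndarray
    wetting_radius_px: np.ndarray
    gel_radius_px: np.ndarray
    erosion_radius_px: np.ndarray  # mean (pre-roughness) outer radius
    roughness_px: np.ndarray  # (T, n_ctrl) per-frame per-angle offsets
    bubbles: np.ndarray  # (k, 3) rows: row, col, radius_px
    center: tuple[float, float] = (0.0, 0.0)
    pixel_size_mm: float = 1.0

    def velocity_mm_per_min(self, kind: str) -> float:
        """Least-squares slope of the true front distance, in mm/min."""
        r = {
            "wetting": self.wetting_radius_px,
            "gel": self.gel_radius_px,
            "erosion": self.erosion_radius_px,
        }[kind]
        d = np.abs(r - r[0]) * self.pixel_size_mm
        return float(np.polyfit(self.times_min, d, 1)[0])


def _periodic_interp(theta: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Linear interpolation of per-control-angle values, periodic in 2*pi."""
    n = values.size
    pos = (theta % (2 * np.pi)) / (2 * np.pi) * n
    i0 = np.floor(pos).astype(int) % n
    i1 = (i0 + 1) % n
    frac = pos - np.floor(pos)
    return values[i0] * (1 - frac) + values[i1] * frac


def simulate_immersion_stack(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render the stack described by ``spec``; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cy, cx = spec._center()
    times = np.arange(spec.n_frames) * spec.frame_interval_min
    px = spec.pixel_size_mm
    r0 = spec.radius_px

    yy, xx = np.mgrid[0:h, 0:w]
    dr = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)

    r_wet = r0 - spec.wetting_velocity * times / px
    gel_growth = spec.gel_velocity * times / px
    if spec.gel_max_thickness_mm is not None:
        gel_growth = np.minimum(gel_growth, spec.gel_max_thickness_mm / px)
    r_gel = r0 + gel_growth
    r_ero = r0 - spec.erosion_velocity * times / px

    rough = (
        rng.normal(0.0, spec.roughness_sd_px, (spec.n_frames, _N_ROUGH))
        if spec.roughness_sd_px > 0
        else np.zeros((spec.n_frames, _N_ROUGH))
    )
    rough[0] = 0.0  # frame 0 defines the reference border

    bubbles = np.empty((spec.bubble_count, 3))
    for k in range(spec.bubble_count):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(*spec.bubble_radius_px)
        # park bubbles on/near the (final) outer boundary where they disturb
        # the erosion measurement
        rr = rng.uniform(min(r_ero[-1], r0) - rad / 2, r0 + rad / 2)
        bubbles[k] = (cy + rr * np.sin(ang), cx + rr * np.cos(ang), rad)

    stain = (1 - STAIN_ALPHA) * TABLET_RGB + STAIN_ALPHA * MEDIUM_RGB
    gel = (1 - GEL_ALPHA) * TABLET_RGB + GEL_ALPHA * MEDIUM_RGB

    frames = np.empty((spec.n_frames, h, w, 3), dtype=np.uint8)
    for t in range(spec.n_frames):
        img = np.empty((h, w, 3))
        img[:] = MEDIUM_RGB
        if spec.gel_velocity > 0 and r_gel[t] > r0:
            cov = np.clip(r_gel[t] - dr + 0.5, 0, 1) * np.clip(dr - r0 + 0.5, 0, 1)
            img += cov[..., None] * (gel - img)
        edge = r_ero[t] + _periodic_interp(theta, rough[t])
        core_cov = np.clip(edge - dr + 0.5, 0, 1)
        stain_frac = np.clip(dr - r_wet[t] + 0.5, 0, 1)
        core = TABLET_RGB + stain_frac[..., None] * (stain - TABLET_RGB)
        img += core_cov[..., None] * (core - img)
        for row, col, rad in bubbles:
            if t == 0:
                continue  # bubbles appear only after immersion
            bcov = np.clip(rad - np.hypot(yy - row, xx - col) + 0.5, 0, 1)
            img += bcov[..., None] * (BUBBLE_RGB - img)
        if spec.pixel_noise_sd > 0:
            img = img + rng.normal(0.0, spec.pixel_noise_sd, img.shape)
        frames[t] = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)

    stack = ImageStack(
        frames=frames,
        timestamps=times,
        pixel_size=px,
        replicate_id=spec.replicate_id,
        medium=spec.medium,
    )
    truth = GroundTruth(
        times_min=times,
        wetting_radius_px=np.maximum(r_wet, 0.0),
        gel_radius_px=r_gel,
        erosion_radius_px=np.maximum(r_ero, 0.0),
        roughness_px=rough,
        bubbles=bubbles,
        center=(cy, cx),
        pixel_size_mm=px,
    )
    return stack, truth


def simulate_dissolution(
    spec: KineticModelSpec,
    parameters: dict[str, float],
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    clip: bool = True,
):
    """Evaluate a kinetic model and add seeded Gaussian noise, clipped to [0, 100].

    ``clip=False`` keeps the raw model values (a two-term curve with a
    negative coefficient can undershoot 0 slightly at early times), which
    is what exact round-trip recovery tests need.
    """
    from .dissolution import DissolutionProfile

    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise BadTimeAxisError("bad time axis")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    released = eval_model(spec, parameters, times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        released = released + rng.normal(0.0, noise_sd, released.shape)
    if clip:
        released = np.clip(released, 0.0, 100.0)
    return DissolutionProfile(times=times, released=released)


# --- study fixture ---------------------------------------------------------


def _load_catalogue() -> dict:
    """Per-formulation generator parameters from the packaged reference CSVs."""
    from .data import load_reference_kinetics, load_reference_rates

    rates = load_reference_rates()
    kin = load_reference_kinetics()
    cat: dict[str, dict] = {}
    for fid in rates["formulation_id"].unique():
        sub = rates[rates["formulation_id"] == fid]
        vel = {}
        for _, row in sub.iterrows():
            vel[(row["medium"], row["kind"])] = (
                None if np.isnan(row["mean_rate"]) else float(row["mean_rate"])
            )
        ps = kin[(kin["formulation_id"] == fid) & (kin["model_id"] == "PS")]
        cat[fid] = {
            "velocities": vel,
            "ps_params": {
                "k1": float(ps["k1"].iloc[0]),
                "k2": float(ps["k2"].iloc[0]),
                "m": float(ps["m"].iloc[0]),
            },
        }
    return cat


#: disintegration times (minutes) for the fixture DT table; synthetic
#: placeholders, not measured values
_FIXTURE_DT_MIN = {
    "IBU": {"water": 62.0, "HCl_pH1.2": 75.0},
    "IP": {"water": 48.0, "HCl_pH1.2": 55.0},
    "IP5E": {"water": 30.0, "HCl_pH1.2": 34.0},
    "IP10E": {"water": 19.0, "HCl_pH1.2": 22.0},
    "IP20E": {"water": 11.0, "HCl_pH1.2": 12.5},
    "IP25E": {"water": 8.0, "HCl_pH1.2": 9.0},
    "IP30E": {"water": 5.5, "HCl_pH1.2": 6.0},
}

_FIXTURE_TIMES_H = np.array([0.25, 0.5, 1, 2, 4, 6, 8, 12, 24], dtype=float)


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration for :func:`make_study_fixture`."""

    out_dir: str | Path = "fixture"
    formulations: tuple[str, ...] = (
        "IBU",
        "IP",
        "IP5E",
        "IP10E",
        "IP20E",
        "IP25E",
        "IP30E",
    )
    media: tuple[str, ...] = ("water", "HCl_pH1.2")
    n_replicates: int = 5
    image_size: tuple[int, int] = (512, 512)
    radius_px: float = 127.0
    pixel_size_mm: float = 0.05
    frame_interval_min: float = 1.0
    n_frames: int = 31
    roughness_sd_px: float = 0.0
    pixel_noise_sd: float = 0.0
    dissolution_noise_sd: float = 0.0
    seed: int = 0


def _valid_frame_plan(cfg: FixtureConfig, v_in: float, v_out: float) -> tuple[int, float]:
    """(n_frames, interval) keeping fronts inside tablet and field of view.

    Prefers trimming frames at the requested interval; when fast fronts
    leave fewer than 4 valid frames, the interval is shrunk instead so the
    regression still has the requested frame count.
    """
    t_max = np.inf
    if v_in > 0:
        t_max = min(t_max, 0.9 * cfg.radius_px * cfg.pixel_size_mm / v_in)
    if v_out > 0:
        margin_px = min(cfg.image_size) / 2 - cfg.radius_px - 6
        t_max = min(t_max, 0.9 * margin_px * cfg.pixel_size_mm / v_out)
    if not np.isfinite(t_max):
        return cfg.n_frames, cfg.frame_interval_min
    n = min(cfg.n_frames, int(t_max / cfg.frame_interval_min) + 1)
    if n >= 4:
        return n, cfg.frame_interval_min
    return cfg.n_frames, t_max / (cfg.n_frames - 1)


def make_study_fixture(config: FixtureConfig) -> Path:
    """Write an end-to-end test dataset: stacks, dissolution CSV, DT CSV.

    Generator velocities and kinetic parameters default to the packaged
    reference values per formulation.  Stacks whose fronts would leave the
    tablet (or the field of view) before the last requested frame are
    trimmed to a valid frame count.
    """
    catalogue = _load_catalogue()
    unknown = set(config.formulations) - set(catalogue)
    if unknown:
        raise KeyError(f"not in fixture catalogue: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    manifest: dict = {"stacks": [], "dissolution": "dissolution.csv", "dt": "dt.csv"}
    for fid in config.formulations:
        entry = catalogue[fid]
        for medium in config.media:
            vel = entry["velocities"]
            v_w = vel.get((medium, "wetting")) or 0.0
            v_g = vel.get((medium, "gel")) or 0.0
            v_e = vel.get((medium, "erosion")) or 0.0
            n_frames, interval = _valid_frame_plan(config, max(v_w, v_e), v_g)
            for rep in range(1, config.n_replicates + 1):
                spec = SceneSpec(
                    image_size=config.image_size,
                    radius_px=config.radius_px,
                    pixel_size_mm=config.pixel_size_mm,
                    frame_interval_min=interval,
                    n_frames=n_frames,
                    wetting_velocity=v_w,
                    gel_velocity=v_g,
                    erosion_velocity=v_e,
                    roughness_sd_px=config.roughness_sd_px,
                    pixel_noise_sd=config.pixel_noise_sd,
                    seed=int(rng.integers(0, 2**31)),
                    replicate_id=f"{fid}_{medium}_r{rep}",
                    medium=medium,
                )
                stack, truth = simulate_immersion_stack(spec)
                rel = f"stacks/{fid}/{medium}/rep{rep}"
                write_stack(stack, out / rel, truth=truth)
                manifest["stacks"].append(
                    {"formulation_id": fid, "medium": medium, "replicate": rep, "path": rel}
                )

    from .dissolution import PS_MODEL

    with open(out / "dissolution.csv", "w", newline="") as fh:
        wcsv = csv.writer(fh)
        wcsv.writerow(["formulation_id", "time_h", "pct_dissolved"])
        for i, fid in enumerate(config.formulations):
            prof = simulate_dissolution(
                PS_MODEL,
                catalogue[fid]["ps_params"],
                _FIXTURE_TIMES_H,
                noise_sd=config.dissolution_noise_sd,
                seed=config.seed + 1000 + i,
            )
            for t, f in zip(prof.times, prof.released):
                wcsv.writerow([fid, f"{t:g}", f"{f:.6f}"])

    with open(out / "dt.csv", "w", newline="") as fh:
        wcsv = csv.writer(fh)
        wcsv.writerow(["formulation_id", "medium", "disintegration_time_min"])
        for fid in config.formulations:
            for medium in config.media:
                wcsv.writerow([fid, medium, _FIXTURE_DT_MIN[fid][medium]])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


# --- stack I/O -------------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path, truth: GroundTruth | None = None) -> Path:
    """Write a stack as numbered PNG frames plus a YAML metadata sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = stack.frames
    if frames.dtype != np.uint8:
        frames = (np.clip(frames, 0, 1) * 255).round().astype(np.uint8)
    for t in range(stack.n_frames):
        iio.imwrite(path / f"frame_{t:04d}.png", frames[t])
    meta = {
        "pixel_size_mm": float(stack.pixel_size),
        "timestamps_min": [float(t) for t in stack.timestamps],
        "replicate_id": stack.replicate_id,
        "medium": stack.medium,
    }
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    if truth is not None:
        gt = {
            "times_min": truth.times_min.tolist(),
            "wetting_radius_px": truth.wetting_radius_px.tolist(),
            "gel_radius_px": truth.gel_radius_px.tolist(),
            "erosion_radius_px": truth.erosion_radius_px.tolist(),
            "bubbles": truth.bubbles.tolist(),
            "center": list(truth.center),
            "pixel_size_mm": truth.pixel_size_mm,
        }
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(gt, fh)
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack` (PNG/TIFF frames + meta.yaml)."""
    path = Path(path)
    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    frame_files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not frame_files:
        raise FileNotFoundError(f"no frames in {path}")
    frames = np.stack([iio.imread(p) for p in frame_files])
    if "timestamps_min" in meta:
        ts = np.asarray(meta["timestamps_min"], dtype=float)
    else:
        ts = np.arange(len(frame_files)) * float(meta["frame_interval_min"])
    return ImageStack(
        frames=frames,
        timestamps=ts,
        pixel_size=float(meta["pixel_size_mm"]),
        replicate_id=str(meta.get("replicate_id", "")),
        medium=str(meta.get("medium", "")),
    )
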
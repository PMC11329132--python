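"""Procedural paired thin/thick CT phantoms.

Emulates the geometry the slice-enhancement method assumes: a wrist-like
scene of closed cortical-bone shells (bright annuli) over a soft-tissue
ellipse on an air background, with band-limited trabecular texture inside
the shells, an optional oblique fracture plane, and additive acquisition
noise.  Shell centres and radii drift smoothly along the slice axis at
fixed rates, so consecutive thin slices differ systematically — the
through-plane structure that slice interpolation must recover.

Thick slices are synthesised from thin ones by unweighted averaging of k
consecutive slices with stride k (the standard partial-volume model for
"virtually generated" thick images); trailing thin slices that do not
fill a group of k are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import STORED_MAX, CTVolume, round_half_away
from .pairing import MappingTable, build_mapping


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the procedural phantom.

    All intensities are 12-bit stored values.  With the default rescale
    intercept of -1024, soft tissue at 1064 sits at ~+40 HU and cortical
    bone at 2824 at ~+1800 HU.
    """

    shape: tuple[int, int, int] = (30, 64, 64)  # (slices, rows, cols)
    voxel_size: tuple[float, float, float] = (1.0, 0.5, 0.5)  # (slice, row, col) mm
    n_shells: int = 2
    cortical_value: int = 2824
    soft_tissue_value: int = 1064
    marrow_value: int = 1400
    air_value: int = 0
    texture_amplitude: float = 150.0
    texture_corr_length: float = 2.0  # voxels
    fracture: bool = False
    fracture_orientation: float = 30.0  # degrees from the slice plane
    noise_sigma: float = 5.0
    # fixed through-plane dynamics, shared across cases of a family
    drift_per_slice: tuple[float, float] = (0.3, 0.2)  # (row, col) voxels/slice
    growth_per_slice: float = 0.25  # shell radius voxels/slice
    edge_width: float = 1.0  # soft (partial-volume) edge width, voxels
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if self.n_shells < 0:
            raise ValueError("n_shells must be >= 0")
        if self.texture_corr_length >= min(self.shape[1:]):
            raise ValueError("texture correlation length must be smaller than the grid")
        for v in (self.cortical_value, self.soft_tissue_value, self.marrow_value,
                  self.air_value):
            if not (0 <= v <= STORED_MAX):
                raise ValueError(f"stored value {v} outside [0, {STORED_MAX}]")


@dataclass(frozen=True)
class PairedCase:
    """A thin volume, its degraded thick counterpart, and their mapping."""

    thin: CTVolume
    thick: CTVolume
    mapping: MappingTable
    case_id: str

    def __post_init__(self):
        k = self.mapping.k
        if self.thick.n_slices != self.thin.n_slices // k:
            raise ValueError("thick slice count must be floor(thin count / k)")
        if self.thin.shape[1:] != self.thick.shape[1:]:
            raise ValueError("thin and thick must share in-plane dimensions")


def _soft_disk(rr: np.ndarray, cc: np.ndarray, center: tuple[float, float],
               radius: float, edge: float) -> np.ndarray:
    """Anti-aliased disk indicator in [0, 1] with a linear edge ramp."""
    d = np.hypot(rr - center[0], cc - center[1])
    if edge <= 0:
        return (d <= radius).astype(np.float64)
    return np.clip((radius + edge / 2.0 - d) / edge, 0.0, 1.0)


def generate_phantom_volume(config: PhantomConfig) -> CTVolume:
    """Render a thin-slice phantom volume from a :class:`PhantomConfig`.

    Identical config (including seed) yields a bit-identical volume.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ns, nr, nc = config.shape
    rr, cc = np.meshgrid(np.arange(nr, dtype=np.float64),
                         np.arange(nc, dtype=np.float64), indexing="ij")

    # case-specific geometry (drawn once per volume)
    ell_center = (nr / 2.0 + rng.uniform(-2, 2), nc / 2.0 + rng.uniform(-2, 2))
    ell_semi = (nr * rng.uniform(0.36, 0.42), nc * rng.uniform(0.36, 0.42))
    shells = []
    for s in range(config.n_shells):
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0.15, 0.3) * min(ell_semi)
        shells.append({
            "center0": (ell_center[0] + off * np.sin(ang),
                        ell_center[1] + off * np.cos(ang)),
            "outer0": rng.uniform(0.16, 0.22) * min(nr, nc),
            "cortex": rng.uniform(2.0, 3.0),  # cortical wall thickness, voxels
        })

    # band-limited trabecular texture, correlated in 3D
    if config.texture_amplitude > 0:
        white = rng.standard_normal(size=(ns, nr, nc))
        tex = gaussian_filter(white, sigma=config.texture_corr_length, mode="nearest")
        tex *= config.texture_amplitude / max(tex.std(), 1e-12)
    else:
        tex = np.zeros((ns, nr, nc))

    vol = np.empty((ns, nr, nc), dtype=np.float64)
    ew = config.edge_width
    theta = np.deg2rad(config.fracture_orientation)
    frac_normal = np.array([np.sin(theta), np.cos(theta) * 0.6, np.cos(theta) * 0.8])
    frac_normal /= np.linalg.norm(frac_normal)

    for z in range(ns):
        img = np.full((nr, nc), float(config.air_value))
        soft = _soft_disk(rr / ell_semi[0], cc / ell_semi[1],
                          (ell_center[0] / ell_semi[0], ell_center[1] / ell_semi[1]),
                          1.0, ew / min(ell_semi))
        img += (config.soft_tissue_value - config.air_value) * soft
        for sh in shells:
            center = (sh["center0"][0] + config.drift_per_slice[0] * z,
                      sh["center0"][1] + config.drift_per_slice[1] * z)
            outer = sh["outer0"] + config.growth_per_slice * z
            inner = max(outer - sh["cortex"], 0.5)
            disk_o = _soft_disk(rr, cc, center, outer, ew)
            disk_i = _soft_disk(rr, cc, center, inner, ew)
            # cortical ring over whatever is underneath
            img += (config.cortical_value - img) * (disk_o - disk_i).clip(0, 1)
            # textured marrow interior
            marrow = config.marrow_value + tex[z]
            img += (marrow - img) * disk_i
            if config.fracture and sh is shells[0]:
                # 1-voxel oblique sheet at soft-tissue intensity through the shell
                dist = (frac_normal[0] * (z - ns / 2.0)
                        + frac_normal[1] * (rr - center[0])
                        + frac_normal[2] * (cc - center[1]))
                sheet = (np.abs(dist) < 0.5) & (disk_o > 0.5)
                img[sheet] = config.soft_tissue_value
        vol[z] = img

    if config.noise_sigma > 0:
        vol += rng.normal(0.0, config.noise_sigma, size=vol.shape)

    voxels = round_half_away(np.clip(vol, 0, STORED_MAX)).astype(np.uint16)
    sz, sr, sc = config.voxel_size
    return CTVolume(voxels=voxels, thickness=sz, interval=sz,
                    pixel_spacing=(sr, sc), source_id=f"phantom-seed{config.seed}")


def degrade_to_thick(thin: CTVolume, k: int) -> CTVolume:
    """Average groups of ``k`` consecutive thin slices into thick slices.

    Thick slice j is the rounded arithmetic mean of thin slices
    [k*j, k*j + k); trailing thin slices that do not fill a group are
    dropped.  Output thickness = interval = k * thin thickness.
    """
    if k < 2:
        raise ValueError(f"thickness ratio k must be >= 2, got {k}")
    n = thin.n_slices
    if n < k:
        raise ValueError(f"need at least k={k} thin slices, got {n}")
    m = n // k
    groups = thin.voxels[: m * k].astype(np.float64).reshape(m, k, *thin.shape[1:])
    thick = round_half_away(groups.mean(axis=1)).astype(np.uint16)
    return CTVolume(
        voxels=thick,
        thickness=k * thin.thickness,
        interval=k * thin.thickness,
        pixel_spacing=thin.pixel_spacing,
        rescale_intercept=thin.rescale_intercept,
        source_id=f"{thin.source_id}|thick-x{k}",
    )


def make_paired_case(config: PhantomConfig, k: int = 3,
                     case_id: str | None = None) -> PairedCase:
    """Generate a thin phantom, degrade it, and build the slice mapping."""
    thin = generate_phantom_volume(config)
    thick = degrade_to_thick(thin, k)
    mapping = build_mapping(thin.n_slices, k)
    return PairedCase(thin=thin, thick=thick, mapping=mapping,
                      case_id=case_id or f"case-seed{config.seed}")


def phantom_suite(n_cases: int, base_seed: int, *,
                  shape: tuple[int, int, int] = (30, 64, 64),
                  k: int = 3, fracture_every: int = 2,
                  **overrides) -> list[PairedCase]:
    """A family of paired cases sharing through-plane dynamics.

    Case geometry (shell placement, texture, noise) varies with the
    per-case seed; the drift/growth rates stay at the family defaults so
    the through-plane motion is learnable across cases.
    """
    cases = []
    for i in range(n_cases):
        cfg = PhantomConfig(shape=shape, seed=base_seed + i,
                            fracture=(fracture_every > 0 and i % fracture_every == 0),
                            **overrides)
        cases.append(make_paired_case(cfg, k=k, case_id=f"case{i:02d}"))
    return cases
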
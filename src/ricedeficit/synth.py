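"""Synthetic leaf/sheath scan generator with analytic ground truth.

The greenhouse scan collections behind the diagnostic method are not
publicly deposited, so this module emulates their statistical structure:
four nutrition classes (Normal, N-, P- and K-deficient) whose leaf and
sheath images differ in exactly the symptom dimensions the diagnosis
exploits —

* N deficiency: light, lemon-yellowish leaves and sheaths, chlorosis
  spreading from the leaf tip, a whitish basal sheath region, shorter
  organs;
* P deficiency: narrow, short, dark ("dirty" green, low lightness) leaves,
  red/purple sheath (R > G);
* K deficiency: dark-green leaves with yellowish-brown tips;
* Normal: dark green, no tip gradient, no white sheath base, the longest
  leaves and the widest leaf spacing.

Because nutrients are remobilized from old to young tissue, symptoms are
rendered strongest on the oldest (3rd) leaf and attenuated on younger
positions via a per-position strength multiplier.

Leaves are lanceolate polygons (two mirrored quadratic Bézier arcs from the
truncated base through the widest point at 40 % of the length to the tip),
sheaths are stadium shapes (rectangle with semicircular caps).  Shapes are
built analytically in centimetres (shapely polygons), so the generator can
record exact ground-truth lengths, widths and areas next to every raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, box

from .segment import LeafScan

CLASSES = ("Normal", "Ndef", "Pdef", "Kdef")

#: reference healthy tissue colors that deficiency shifts are expressed against
HEALTHY_LEAF_RGB = (60.0, 110.0, 45.0)
HEALTHY_SHEATH_RGB = (120.0, 150.0, 90.0)

#: half base width as a fraction of the maximum half width
BASE_WIDTH_FRACTION = 0.45
#: axial location of the widest point, as a fraction of leaf length
PEAK_POSITION = 0.4

_BG_LEVEL = 250.0
_BG_MIN = 245
_WHITE_MIN = 230
_MARGIN_PX = 8


class DegenerateGeometry(ValueError):
    """Requested organ too small to rasterize at the given dpi."""


def _check_rgb(c, name):
    c = tuple(float(v) for v in c)
    if len(c) != 3 or any(v < 0 or v > 255 for v in c):
        raise ValueError(f"{name} must be an RGB triple in [0,255], got {c}")
    return c


def _check_triple(t, name):
    t = tuple(float(v) for v in t)
    if len(t) != 3 or any(v <= 0 for v in t):
        raise ValueError(f"{name} must be three positive values, got {t}")
    return t


@dataclass
class SymptomProfile:
    """Rendering parameters of one nutrition class.

    Colors are the *full-symptom* values; on younger leaf positions they are
    attenuated toward the healthy reference by ``position_strength``.
    Geometry is given per leaf position 1..3 (youngest to oldest of the top
    three fully expanded leaves).
    """

    class_label: str
    leaf_base_rgb: tuple[float, float, float]
    tip_fraction: float  # fraction of leaf length affected from the tip
    tip_rgb: tuple[float, float, float]
    length_cm: tuple[float, float, float]
    width_cm: tuple[float, float, float]
    sheath_rgb: tuple[float, float, float]
    sheath_length_cm: tuple[float, float, float]
    sheath_width_cm: float = 0.7
    white_region_fraction: float = 0.0
    noise_sd: float = 8.0
    geometry_jitter: float = 0.06
    color_jitter_sd: float = 3.0
    position_strength: tuple[float, float, float] = (0.6, 0.8, 1.0)

    def __post_init__(self):
        self.leaf_base_rgb = _check_rgb(self.leaf_base_rgb, "leaf_base_rgb")
        self.tip_rgb = _check_rgb(self.tip_rgb, "tip_rgb")
        self.sheath_rgb = _check_rgb(self.sheath_rgb, "sheath_rgb")
        self.length_cm = _check_triple(self.length_cm, "length_cm")
        self.width_cm = _check_triple(self.width_cm, "width_cm")
        self.sheath_length_cm = _check_triple(self.sheath_length_cm, "sheath_length_cm")
        for name in ("tip_fraction", "white_region_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.noise_sd < 0 or self.geometry_jitter < 0:
            raise ValueError("noise_sd and geometry_jitter must be non-negative")

    @property
    def tip_gradient(self) -> tuple[float, tuple[float, float, float]]:
        return (self.tip_fraction, self.tip_rgb)

    def strength(self, position: int) -> float:
        return float(self.position_strength[position - 1])


def default_profiles() -> dict[str, SymptomProfile]:
    """The four default nutrition-class profiles.

    Values are qualitative reconstructions of the documented symptoms
    (no quantitative colors are published for the classes); treat them as
    tunable configuration, not as ground truth about real rice.
    """
    return {
        "Normal": SymptomProfile(
            class_label="Normal",
            leaf_base_rgb=HEALTHY_LEAF_RGB,
            tip_fraction=0.0,
            tip_rgb=HEALTHY_LEAF_RGB,
            length_cm=(25.0, 32.0, 30.0),
            width_cm=(1.2, 1.4, 1.3),
            sheath_rgb=HEALTHY_SHEATH_RGB,
            sheath_length_cm=(18.0, 14.0, 11.0),
            white_region_fraction=0.0,
            position_strength=(1.0, 1.0, 1.0),
        ),
        "Ndef": SymptomProfile(
            class_label="Ndef",
            leaf_base_rgb=(140.0, 170.0, 70.0),
            tip_fraction=0.35,
            tip_rgb=(185.0, 190.0, 95.0),
            length_cm=(22.0, 28.0, 26.0),
            width_cm=(1.0, 1.15, 1.05),
            sheath_rgb=(170.0, 180.0, 95.0),
            sheath_length_cm=(15.0, 12.5, 10.5),
            white_region_fraction=0.25,
        ),
        "Pdef": SymptomProfile(
            class_label="Pdef",
            leaf_base_rgb=(45.0, 75.0, 40.0),
            tip_fraction=0.2,
            tip_rgb=(120.0, 90.0, 50.0),
            length_cm=(19.0, 25.0, 23.0),
            width_cm=(0.85, 1.0, 0.95),
            sheath_rgb=(135.0, 75.0, 95.0),
            sheath_length_cm=(14.0, 11.5, 9.5),
            white_region_fraction=0.0,
        ),
        "Kdef": SymptomProfile(
            class_label="Kdef",
            leaf_base_rgb=(55.0, 95.0, 45.0),
            tip_fraction=0.3,
            tip_rgb=(150.0, 120.0, 45.0),
            length_cm=(22.0, 29.0, 27.0),
            width_cm=(1.05, 1.25, 1.15),
            sheath_rgb=(110.0, 135.0, 85.0),
            sheath_length_cm=(15.5, 12.5, 10.2),
            white_region_fraction=0.0,
        ),
    }


# ---------------------------------------------------------------------------
# analytic outlines


def _leaf_profile(length_cm: float, width_cm: float, n: int = 800):
    """Half-width profile (x, h) of the lanceolate outline, in cm.

    Each side is a quadratic Bézier arc from the truncated base
    (half-width ``BASE_WIDTH_FRACTION * W/2``) to the tip, with the control
    point solved in closed form so that the maximum half-width is exactly
    W/2 and occurs at ``PEAK_POSITION * L``.
    """
    L, m = float(length_cm), float(width_cm) / 2.0
    h0 = BASE_WIDTH_FRACTION * m
    # max of h(t) = (1-t)^2 h0 + 2 t (1-t) h1 equals h1^2/(2 h1 - h0)
    h1 = m + np.sqrt(m * m - m * h0)
    t_star = (h1 - h0) / (2 * h1 - h0)
    x1 = (PEAK_POSITION * L - t_star**2 * L) / (2 * t_star * (1 - t_star))
    t = np.linspace(0.0, 1.0, n)
    x = 2 * t * (1 - t) * x1 + t**2 * L
    h = (1 - t) ** 2 * h0 + 2 * t * (1 - t) * h1
    return x, h


def _profile_polygon(x: np.ndarray, h: np.ndarray) -> Polygon:
    top = np.column_stack([x, h])
    bottom = np.column_stack([x[::-1], -h[::-1]])
    return Polygon(np.vstack([top, bottom[1:]]))


def leaf_outline(length_cm: float, width_cm: float, n: int = 800) -> Polygon:
    """Lanceolate leaf polygon in cm coordinates, base at x=0, tip at (L, 0)."""
    return _profile_polygon(*_leaf_profile(length_cm, width_cm, n))


def _sheath_profile(length_cm: float, width_cm: float, n: int = 800):
    """Half-width profile (x, h) of the stadium outline, in cm."""
    L, r = float(length_cm), float(width_cm) / 2.0
    if L <= 2 * r:
        raise DegenerateGeometry("sheath length must exceed its width")
    x = np.linspace(0.0, L, n)
    h = np.full(n, r)
    left = x < r
    h[left] = np.sqrt(np.maximum(r**2 - (x[left] - r) ** 2, 0.0))
    right = x > L - r
    h[right] = np.sqrt(np.maximum(r**2 - (x[right] - (L - r)) ** 2, 0.0))
    return x, h


def sheath_outline(length_cm: float, width_cm: float, n: int = 800) -> Polygon:
    """Stadium-shaped sheath polygon: rectangle with semicircular caps."""
    return _profile_polygon(*_sheath_profile(length_cm, width_cm, n))


def white_region_truth(
    length_cm: float, width_cm: float, fraction: float, n: int = 400
) -> float:
    """Exact area (cm^2) of the basal sheath segment x <= fraction * length."""
    if fraction <= 0:
        return 0.0
    poly = sheath_outline(length_cm, width_cm, n=n)
    clip = box(-1.0, -width_cm, fraction * length_cm, width_cm)
    return float(poly.intersection(clip).area)


# ---------------------------------------------------------------------------
# rasterization


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _blend(color, ref, strength) -> np.ndarray:
    c = np.asarray(ref) + strength * (np.asarray(color) - np.asarray(ref))
    return np.clip(c, 0.0, 255.0)


def _rasterize(x: np.ndarray, h: np.ndarray, dpi: int) -> tuple[np.ndarray, float]:
    """Boolean mask of a symmetric half-width profile at ``dpi``.

    Pixel centers at integer coordinates; a pixel (r, c) is foreground when
    its x lies inside the profile support and |r - midline| <= h(x).
    Returns the mask and the px-per-cm scale.
    """
    scale = dpi / 2.54
    hmax = float(h.max())
    width = int(np.ceil(x[-1] * scale)) + 2 * _MARGIN_PX + 1
    height = int(np.ceil(2 * hmax * scale)) + 2 * _MARGIN_PX + 1
    cy = (height - 1) / 2.0
    cols = np.arange(width)
    x_cm = (cols - _MARGIN_PX) / scale
    h_px = np.interp(x_cm, x, h, left=-1.0, right=-1.0) * scale
    rows = np.arange(height)
    mask = np.abs(rows[:, None] - cy) <= h_px[None, :]
    return mask, scale


def _apply_noise(img, fg_mask, white_mask, noise_sd, rng):
    """Add channel noise and clip background/white/foreground bands."""
    bg_sd = min(2.0, noise_sd)
    sd = np.where(fg_mask, noise_sd, bg_sd)[..., None]
    img = img + rng.standard_normal(img.shape) * sd
    bg = ~fg_mask
    img[bg] = np.clip(img[bg], _BG_MIN + 1, 255)
    img[fg_mask] = np.clip(img[fg_mask], 0, 255)
    if white_mask is not None and white_mask.any():
        img[white_mask] = np.clip(img[white_mask], _WHITE_MIN, 255)
    return np.round(img).astype(np.uint8)


def render_leaf(
    profile: SymptomProfile,
    position: int,
    dpi: int,
    rng,
    sample_id: str = "",
    length_cm: float | None = None,
    width_cm: float | None = None,
    color_offset=(0.0, 0.0, 0.0),
) -> LeafScan:
    """Rasterize one leaf of ``profile`` at leaf ``position`` (1..3).

    ``length_cm``/``width_cm`` override the profile geometry (used for
    per-plant jitter); ``color_offset`` is an additive per-plant RGB shift.
    The scan's ``meta`` records the exact generating geometry: polygon
    length, maximum width and shoelace area in cm.
    """
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    rng = _as_rng(rng)
    L = float(length_cm if length_cm is not None else profile.length_cm[position - 1])
    W = float(width_cm if width_cm is not None else profile.width_cm[position - 1])
    if L * dpi / 2.54 < 10:
        raise DegenerateGeometry(f"leaf of {L} cm is under 10 px at {dpi} dpi")

    xs, hs = _leaf_profile(L, W)
    poly = _profile_polygon(xs, hs)
    mask, scale = _rasterize(xs, hs, dpi)
    s = profile.strength(position)
    base = _blend(profile.leaf_base_rgb, HEALTHY_LEAF_RGB, s) + color_offset
    tip = _blend(profile.tip_rgb, HEALTHY_LEAF_RGB, s) + color_offset
    base, tip = np.clip(base, 0, 255), np.clip(tip, 0, 255)

    img = np.full(mask.shape + (3,), _BG_LEVEL)
    rr, cc = np.nonzero(mask)
    colors = np.tile(base, (len(rr), 1))
    f = profile.tip_fraction * s  # chlorosis extent scales with symptom strength
    if f > 0:
        u = (cc - cc.min()) / max(cc.max() - cc.min(), 1)  # 0 at base, 1 at tip
        w = np.clip((u - (1 - f)) / f, 0.0, 1.0)[:, None]
        colors = (1 - w) * base + w * tip
    img[rr, cc] = colors
    img = _apply_noise(img, mask, None, profile.noise_sd, rng)

    meta = {
        "class": profile.class_label,
        "length_cm": L,
        "width_cm": W,
        "area_cm2": float(poly.area),
        "white_area_cm2": 0.0,
        "tip_fraction": f,
    }
    return LeafScan(img, dpi=dpi, kind="leaf", position=position,
                    sample_id=sample_id, meta=meta)


def render_sheath(
    profile: SymptomProfile,
    position: int,
    dpi: int,
    rng,
    sample_id: str = "",
    length_cm: float | None = None,
    color_offset=(0.0, 0.0, 0.0),
) -> LeafScan:
    """Rasterize one sheath: a stadium with an optional near-white basal segment."""
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    rng = _as_rng(rng)
    L = float(
        length_cm if length_cm is not None else profile.sheath_length_cm[position - 1]
    )
    W = float(profile.sheath_width_cm)
    if L * dpi / 2.54 < 10:
        raise DegenerateGeometry(f"sheath of {L} cm is under 10 px at {dpi} dpi")

    xs, hs = _sheath_profile(L, W)
    poly = _profile_polygon(xs, hs)
    mask, scale = _rasterize(xs, hs, dpi)
    s = profile.strength(position)
    base = np.clip(
        _blend(profile.sheath_rgb, HEALTHY_SHEATH_RGB, s) + color_offset, 0, 255
    )
    wf = profile.white_region_fraction * s

    img = np.full(mask.shape + (3,), _BG_LEVEL)
    img[mask] = base
    white_mask = None
    if wf > 0:
        cols = np.nonzero(mask.any(axis=0))[0]
        cut = cols.min() + wf * (cols.max() - cols.min() + 1)
        white_mask = mask & (np.arange(mask.shape[1])[None, :] < cut)
        # near-white but below the scanner-background level, so the white
        # base stays inside the segmented foreground
        img[white_mask] = (233.0, 233.0, 230.0)

    img = _apply_noise(img, mask, white_mask, profile.noise_sd, rng)
    meta = {
        "class": profile.class_label,
        "length_cm": L,
        "width_cm": W,
        "area_cm2": float(poly.area),
        "white_area_cm2": white_region_truth(L, W, wf),
        "white_fraction": wf,
    }
    return LeafScan(img, dpi=dpi, kind="sheath", position=position,
                    sample_id=sample_id, meta=meta)


# ---------------------------------------------------------------------------
# datasets


@dataclass
class PlantSample:
    """The top three leaves and sheaths of one plant, with its class label."""

    sample_id: str
    class_label: str
    leaves: dict[int, LeafScan]
    sheaths: dict[int, LeafScan]

    def organs(self):
        for pos in (1, 2, 3):
            yield self.leaves[pos]
        for pos in (1, 2, 3):
            yield self.sheaths[pos]


@dataclass
class SyntheticDataset:
    """A class-balanced collection of PlantSamples plus their ground truth."""

    samples: list[PlantSample]
    truth_table: pd.DataFrame
    rng_seed: int
    dpi: int
    profiles: dict[str, SymptomProfile] = field(default_factory=dict)

    def write(self, out_dir) -> Path:
        """Write PNG images, the truth CSV and the profile YAML to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample in self.samples:
            for organ in sample.organs():
                organ.save(out / f"{sample.sample_id}_{organ.kind}{organ.position}.png")
        self.truth_table.to_csv(out / "truth.csv", index=False)
        with open(out / "profiles.yaml", "w") as fh:
            yaml.safe_dump(profiles_to_dict(self.profiles), fh, sort_keys=True)
        return out

    @classmethod
    def load(cls, in_dir, dpi: int) -> "SyntheticDataset":
        """Reload a written dataset (images + truth CSV) from disk."""
        in_dir = Path(in_dir)
        truth = pd.read_csv(in_dir / "truth.csv")
        profiles = {}
        pf = in_dir / "profiles.yaml"
        if pf.exists():
            with open(pf) as fh:
                profiles = profiles_from_dict(yaml.safe_load(fh))
        samples = []
        for sid, grp in truth.groupby("sample_id", sort=False):
            label = grp["class"].iloc[0]
            leaves, sheaths = {}, {}
            for pos in (1, 2, 3):
                leaves[pos] = LeafScan.from_file(
                    in_dir / f"{sid}_leaf{pos}.png", dpi, "leaf", pos, sid
                )
                sheaths[pos] = LeafScan.from_file(
                    in_dir / f"{sid}_sheath{pos}.png", dpi, "sheath", pos, sid
                )
            samples.append(PlantSample(sid, label, leaves, sheaths))
        return cls(samples, truth, rng_seed=-1, dpi=dpi, profiles=profiles)


def profiles_to_dict(profiles: dict[str, SymptomProfile]) -> dict:
    return {k: asdict(v) for k, v in profiles.items()}


def profiles_from_dict(d: dict) -> dict[str, SymptomProfile]:
    out = {}
    for k, v in d.items():
        v = dict(v)
        for key in ("leaf_base_rgb", "tip_rgb", "sheath_rgb", "length_cm",
                    "width_cm", "sheath_length_cm", "position_strength"):
            if key in v:
                v[key] = tuple(v[key])
        out[k] = SymptomProfile(**v)
    return out


def generate_dataset(
    n_per_class: int,
    profiles: dict[str, SymptomProfile] | None = None,
    dpi: int = 300,
    seed: int = 0,
    out_dir=None,
) -> SyntheticDataset:
    """Generate ``4 * n_per_class`` plants (three leaves + three sheaths each).

    Per-plant randomness: multiplicative Gaussian jitter on every organ's
    length and width (sd = ``geometry_jitter``) and an additive per-plant
    RGB offset (sd = ``color_jitter_sd``) shared by all of the plant's
    organs.  Identical (profiles, n, dpi, seed) regenerate bit-identical
    images and truth tables.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    samples, rows = [], []
    for label in CLASSES:
        if label not in profiles:
            raise KeyError(f"missing profile for class {label!r}")
    for label in CLASSES:
        prof = profiles[label]
        for i in range(n_per_class):
            sid = f"{label}_{i:04d}"
            offset = rng.normal(0.0, prof.color_jitter_sd, 3)
            leaves, sheaths = {}, {}
            for pos in (1, 2, 3):
                jl = max(1.0 + prof.geometry_jitter * rng.standard_normal(), 0.5)
                jw = max(1.0 + prof.geometry_jitter * rng.standard_normal(), 0.5)
                leaf = render_leaf(
                    prof, pos, dpi, rng, sample_id=sid,
                    length_cm=prof.length_cm[pos - 1] * jl,
                    width_cm=prof.width_cm[pos - 1] * jw,
                    color_offset=offset,
                )
                js = max(1.0 + prof.geometry_jitter * rng.standard_normal(), 0.5)
                sheath = render_sheath(
                    prof, pos, dpi, rng, sample_id=sid,
                    length_cm=prof.sheath_length_cm[pos - 1] * js,
                    color_offset=offset,
                )
                leaves[pos], sheaths[pos] = leaf, sheath
                for organ in (leaf, sheath):
                    rows.append({
                        "sample_id": sid,
                        "class": label,
                        "pos": pos,
                        "kind": organ.kind,
                        "length_cm": round(organ.meta["length_cm"], 6),
                        "width_cm": round(organ.meta["width_cm"], 6),
                        "area_cm2": round(organ.meta["area_cm2"], 6),
                        "white_area_cm2": round(organ.meta["white_area_cm2"], 6),
                    })
            samples.append(PlantSample(sid, label, leaves, sheaths))
    truth = pd.DataFrame(rows)
    ds = SyntheticDataset(samples, truth, rng_seed=seed, dpi=dpi, profiles=profiles)
    if out_dir is not None:
        ds.write(out_dir)
    return ds
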
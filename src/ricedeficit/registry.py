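"""Canonical registry of the 32 leaf/sheath characteristics.

Indices 1–28 are leaf characteristics (color means, shape descriptors,
cross-leaf differences, tip color); 29–32 are the sheath color means and
the white-region area.  The registry fixes the order, the column names
used in feature tables, and the physical units, so every downstream module
(selection, discriminants, cascade) addresses features by index.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureDef:
    """One registered characteristic."""

    index: int
    name: str
    unit: str  # "" for dimensionless / 0-255 color scale
    description: str

    @property
    def column(self) -> str:
        safe = (
            self.name.replace("/", "_")
            .replace("-", "_")
            .replace("–", "_")
        )
        return f"f{self.index:02d}_{safe}"


_DEFS = [
    FeatureDef(1, "LR", "", "leaf mean red channel"),
    FeatureDef(2, "LG", "", "leaf mean green channel"),
    FeatureDef(3, "LB", "", "leaf mean blue channel"),
    FeatureDef(4, "LL", "cm", "leaf length (skeleton geodesic)"),
    FeatureDef(5, "LW", "cm", "leaf width (widest zone)"),
    FeatureDef(6, "LA", "cm2", "leaf area"),
    FeatureDef(7, "LP", "cm", "leaf perimeter"),
    FeatureDef(8, "EC", "", "eccentricity: length/width"),
    FeatureDef(9, "RE", "", "rectangularity: area / min-area bounding box"),
    FeatureDef(10, "AC", "", "area convexity: area / convex-hull area"),
    FeatureDef(11, "CI", "", "circularity: inscribed / circumscribed radius"),
    FeatureDef(12, "FF", "", "form factor 4*pi*A/P^2"),
    FeatureDef(13, "LI", "", "leaf lightness"),
    FeatureDef(14, "LSL", "cm", "leaf sheath length"),
    FeatureDef(15, "L/LS", "", "leaf length / sheath length"),
    FeatureDef(16, "A/L", "cm", "leaf area / leaf length"),
    FeatureDef(17, "A/P", "cm", "leaf area / leaf perimeter"),
    FeatureDef(18, "L23", "cm", "2nd minus 3rd leaf length"),
    FeatureDef(19, "L1/3", "", "1st / 3rd leaf length"),
    FeatureDef(20, "R23", "", "2nd minus 3rd leaf mean R"),
    FeatureDef(21, "G23", "", "2nd minus 3rd leaf mean G"),
    FeatureDef(22, "B23", "", "2nd minus 3rd leaf mean B"),
    FeatureDef(23, "LS12", "cm", "1st minus 2nd sheath length (leaf spacing)"),
    FeatureDef(24, "LS23", "cm", "2nd minus 3rd sheath length (leaf spacing)"),
    FeatureDef(25, "LS12-LS23", "cm", "difference in leaf spacing"),
    FeatureDef(26, "LTR", "", "leaf tip mean R (distal 1/5 of length)"),
    FeatureDef(27, "LTG", "", "leaf tip mean G"),
    FeatureDef(28, "LTB", "", "leaf tip mean B"),
    FeatureDef(29, "LSR", "", "sheath mean R"),
    FeatureDef(30, "LSG", "", "sheath mean G"),
    FeatureDef(31, "LSB", "", "sheath mean B"),
    FeatureDef(32, "WRA", "cm2", "white-region area of the sheath"),
]

REGISTRY: dict[int, FeatureDef] = {d.index: d for d in _DEFS}

#: All feature column names in registry order.
COLUMNS: list[str] = [d.column for d in _DEFS]

#: Column name -> registry index.
INDEX_OF: dict[str, int] = {d.column: d.index for d in _DEFS}

#: Short name (e.g. "LG") -> registry index.
INDEX_OF_NAME: dict[str, int] = {d.name: d.index for d in _DEFS}

N_FEATURES = len(_DEFS)

# indices of color-mean characteristics, used by selection sanity checks
LEAF_COLOR_INDICES = frozenset({1, 2, 3, 13, 20, 21, 22, 26, 27, 28})
SHEATH_COLOR_INDICES = frozenset({29, 30, 31, 32})


def columns_for(indices) -> list[str]:
    """Map registry indices to feature-table column names, keeping order."""
    return [REGISTRY[int(i)].column for i in indices]


def indices_for(columns) -> list[int]:
    return [INDEX_OF[c] for c in columns]


def validate_indices(indices) -> None:
    bad = [i for i in indices if int(i) not in REGISTRY]
    if bad:
        raise KeyError(f"unknown registry indices: {bad}")
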
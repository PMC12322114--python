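"""Crop catalogues and source-to-output reclassification.

The output product distinguishes 16 crop types, keyed by Eurostat-style
codes (``LMAIZ`` maize, ``PARI`` rice, ``CERE`` other cereals, ...).  The
1-km crop-type source map uses a finer 28-class legend that is collapsed
onto the 16 output classes: all cereals except maize and rice merge into
``CERE`` and 8 minor classes (root/forage crops, soya, tobacco, other
industrial crops, flowers, forage plants, nurseries, other permanent
crops) merge into ``OTHER``.  A coarser 12-class legend is used when
comparing against products with cruder crop typing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CROP_CODES",
    "DGPCM_TO_OUTPUT",
    "OUTPUT_TO_AGGREGATED",
    "AGGREGATED_CODES",
    "ReclassMap",
    "reclassify_areas",
    "reclassify_codes",
]

#: The 16 output crop classes.
CROP_CODES: tuple[str, ...] = (
    "LMAIZ",      # maize
    "PARI",       # rice
    "CERE",       # other cereals (all cereals except maize and rice)
    "PULS",       # pulses
    "POTA",       # potato
    "SUGB",       # sugar beet
    "LRAPE",      # rape and turnip rape
    "SUNF",       # sunflower
    "TEXT",       # textile crops
    "TOMA_OVEG",  # fresh vegetable, melon, strawberry - open field
    "GRAS",       # grassland
    "APPL_OFRU",  # fruit and berry
    "CITR",       # citrus
    "OLIVGR",     # olive
    "VINY",       # vineyards
    "OTHER",      # other crops
)

#: 28-class source legend -> 16 output classes.
DGPCM_TO_OUTPUT: dict[str, str] = {
    # cereals other than maize and rice
    "SWHE": "CERE", "DWHE": "CERE", "BARL": "CERE",
    "RYEM": "CERE", "OATS": "CERE", "OCER": "CERE",
    # one-to-one classes
    "LMAIZ": "LMAIZ", "PARI": "PARI", "PULS": "PULS", "POTA": "POTA",
    "SUGB": "SUGB", "SUNF": "SUNF", "LRAPE": "LRAPE", "TEXT": "TEXT",
    "GRAS": "GRAS", "TOMA_OVEG": "TOMA_OVEG", "APPL_OFRU": "APPL_OFRU",
    "CITR": "CITR", "OLIVGR": "OLIVGR", "VINY": "VINY",
    # minor classes merged into OTHER
    "ROOF": "OTHER", "SOYA": "OTHER", "TOBA": "OTHER", "OIND": "OTHER",
    "FLOW": "OTHER", "OFAR": "OTHER", "NURS": "OTHER", "OCRO": "OTHER",
}

#: 12-class aggregated legend for cross-product comparison.
AGGREGATED_CODES: tuple[str, ...] = (
    "CERE", "LMAIZ", "PARI", "PULS", "POTA", "SUGB", "SUNF", "LRAPE",
    "COTTON", "GRAS", "VEGFRU", "OTHER",
)

#: 16 output classes -> 12 aggregated classes.
OUTPUT_TO_AGGREGATED: dict[str, str] = {
    "CERE": "CERE", "LMAIZ": "LMAIZ", "PARI": "PARI", "PULS": "PULS",
    "POTA": "POTA", "SUGB": "SUGB", "SUNF": "SUNF", "LRAPE": "LRAPE",
    "TEXT": "COTTON", "GRAS": "GRAS",
    "TOMA_OVEG": "VEGFRU", "APPL_OFRU": "VEGFRU", "CITR": "VEGFRU",
    "OLIVGR": "VEGFRU", "VINY": "VEGFRU",
    "OTHER": "OTHER",
}


@dataclass(frozen=True)
class ReclassMap:
    """A total mapping from a source crop legend onto a target catalogue."""

    mapping: dict[str, str]
    scheme: str
    target_catalog: tuple[str, ...] = CROP_CODES

    def __post_init__(self) -> None:
        bad = sorted(set(self.mapping.values()) - set(self.target_catalog))
        if bad:
            raise ValueError(
                f"reclass scheme {self.scheme!r} maps onto codes outside the "
                f"target catalogue: {bad}"
            )

    def __getitem__(self, source_code: str) -> str:
        try:
            return self.mapping[source_code]
        except KeyError:
            raise KeyError(
                f"source code {source_code!r} not in reclass scheme {self.scheme!r}"
            ) from None

    def target_codes(self) -> list[str]:
        """Distinct target codes actually reached by the mapping."""
        return sorted(set(self.mapping.values()))

    def sources_of(self, target_code: str) -> list[str]:
        return sorted(k for k, v in self.mapping.items() if v == target_code)


DGPCM_SCHEME = ReclassMap(DGPCM_TO_OUTPUT, "DGPCM->output")
AGGREGATED_SCHEME = ReclassMap(
    OUTPUT_TO_AGGREGATED, "output->aggregated", AGGREGATED_CODES
)


def reclassify_areas(areas: pd.DataFrame, rmap: ReclassMap,
                     code_col: str = "crop_code",
                     value_col: str = "aai_ha") -> pd.DataFrame:
    """Sum a keyed area table into target crop codes.

    Any other columns (region_id, year, ...) are kept as grouping keys, so
    total area is conserved exactly within every group.
    """
    out = areas.copy()
    out[code_col] = [rmap[c] for c in out[code_col]]
    keys = [c for c in out.columns if c != value_col]
    return out.groupby(keys, as_index=False, sort=True)[value_col].sum()


def reclassify_codes(codes: pd.Series | list[str], rmap: ReclassMap) -> list[str]:
    """Re-key a sequence of source crop codes (e.g. survey points)."""
    return [rmap[c] for c in codes]
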
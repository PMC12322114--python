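"""Hierarchical and crop-wise disaggregation of regional irrigated area.

The annual survey series reports the total area actually irrigated (AAI)
per region, mostly at NUTS2 but for some countries only at NUTS1.  A
fixed reference-year census provides crop-specific AAI per NUTS2 region.
Two constancy assumptions carry that structure through time:

* the share of each NUTS2 region in its NUTS1 parent's total AAI is fixed
  at its reference-year value, so NUTS1 annual totals can be split to
  NUTS2 (``compute_region_shares`` / ``disaggregate_total_aai``);
* the crop composition of each NUTS2 region's AAI is fixed at its
  reference-year value, so annual totals can be split across crops
  (``compute_crop_proportions`` / ``crop_aai_series``).

Because the reference census does not always reconcile its reported
regional total with the sum of its crop-specific entries, all proportions
here are computed from the crop-specific sums, never from the reported
totals.  Regions whose reference crop data are entirely missing or zero
fall back to even splits and are flagged; their annual totals are carried
as *unallocated* in diagnostics rather than invented as a crop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "validate_region_table",
    "compute_region_shares",
    "disaggregate_total_aai",
    "compute_crop_proportions",
    "crop_aai_series",
    "unallocated_totals",
]

_REL_TOL = 1e-9


def validate_region_table(regions: pd.DataFrame) -> pd.DataFrame:
    """Check the NUTS1/NUTS2 hierarchy table (region_id, parent_id, level)."""
    if regions["region_id"].duplicated().any():
        dupes = regions.loc[regions["region_id"].duplicated(), "region_id"]
        raise ValueError(f"duplicate region identifiers: {sorted(set(dupes))}")
    levels = set(regions["level"])
    if not levels <= {"NUTS1", "NUTS2"}:
        raise ValueError(f"unknown region levels: {sorted(levels - {'NUTS1', 'NUTS2'})}")
    nuts1 = set(regions.loc[regions["level"] == "NUTS1", "region_id"])
    nuts2 = regions[regions["level"] == "NUTS2"]
    orphans = nuts2.loc[~nuts2["parent_id"].isin(nuts1), "region_id"]
    if len(orphans):
        raise ValueError(f"NUTS2 regions without a NUTS1 parent: {sorted(orphans)}")
    return regions


def compute_region_shares(ref: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Reference-year share of each NUTS2 region in its NUTS1 parent.

    Parameters
    ----------
    ref
        Reference crop-specific AAI table (region_id, crop_code, aai_ha),
        keyed by NUTS2 region.
    regions
        Hierarchy table.

    Returns
    -------
    DataFrame with columns (region_id, parent_id, share_pct, flagged).
    share = 100 * region crop-sum / parent crop-sum.  When the parent's
    crop-sum is zero or no child has reference data, each of the parent's
    N children receives 100/N and the rows are flagged.
    """
    validate_region_table(regions)
    if (ref["aai_ha"] < 0).any():
        raise ValueError("negative reference irrigated area")
    nuts2 = regions[regions["level"] == "NUTS2"]
    crop_sum = ref.groupby("region_id")["aai_ha"].sum()

    rows = []
    for parent_id, children in nuts2.groupby("parent_id"):
        sums = crop_sum.reindex(children["region_id"]).astype(float)
        total = float(sums.fillna(0.0).sum())
        have_data = sums.notna().any()
        if total > 0 and have_data:
            for rid, s in zip(children["region_id"], sums.fillna(0.0)):
                rows.append((rid, parent_id, 100.0 * s / total, False))
        else:
            # even split: stated fallback for missing data, extended to the
            # all-zero case so hierarchy conservation always holds
            n = len(children)
            for rid in children["region_id"]:
                rows.append((rid, parent_id, 100.0 / n, True))
    out = pd.DataFrame(rows, columns=["region_id", "parent_id", "share_pct", "flagged"])

    sums = out.groupby("parent_id")["share_pct"].sum()
    assert np.allclose(sums, 100.0, rtol=_REL_TOL), "shares must sum to 100 per parent"
    return out


def disaggregate_total_aai(series: pd.DataFrame, shares: pd.DataFrame,
                           regions: pd.DataFrame) -> pd.DataFrame:
    """Split NUTS1-level annual totals to NUTS2 using fixed shares.

    Rows of ``series`` (region_id, year, taai_ha) already keyed at NUTS2
    pass through unchanged.  For every NUTS1 row, each child receives
    ``share_pct / 100 * taai_ha``; the children's sum equals the parent
    total by construction.
    """
    validate_region_table(regions)
    if (series["taai_ha"] < 0).any():
        raise ValueError("negative annual irrigated area")
    if series.duplicated(["region_id", "year"]).any():
        raise ValueError("duplicate (region, year) rows in annual series")
    level = regions.set_index("region_id")["level"]
    share_by_parent = dict(tuple(shares.groupby("parent_id")))

    rows = []
    for rec in series.itertuples(index=False):
        lvl = level.get(rec.region_id)
        if lvl is None:
            raise ValueError(f"series region {rec.region_id!r} not in region table")
        if lvl == "NUTS2":
            rows.append((rec.region_id, rec.year, float(rec.taai_ha)))
        else:
            child_shares = share_by_parent.get(rec.region_id)
            if child_shares is None:
                raise ValueError(
                    f"no NUTS2 shares available for NUTS1 region {rec.region_id!r}"
                )
            for child in child_shares.itertuples(index=False):
                rows.append((child.region_id, rec.year,
                             child.share_pct / 100.0 * float(rec.taai_ha)))
    return pd.DataFrame(rows, columns=["region_id", "year", "taai_ha"])


def compute_crop_proportions(ref: pd.DataFrame) -> pd.DataFrame:
    """Per-NUTS2 crop composition of reference-year AAI, in percent.

    Returns (region_id, crop_code, share_pct, flagged); for regions whose
    crop entries sum to zero all shares are 0 and the rows are flagged.
    """
    if ref.duplicated(["region_id", "crop_code"]).any():
        raise ValueError("duplicate (region, crop) rows in reference table")
    if (ref["aai_ha"] < 0).any():
        raise ValueError("negative reference irrigated area")
    out = ref.copy()
    totals = out.groupby("region_id")["aai_ha"].transform("sum")
    with np.errstate(invalid="ignore"):
        out["share_pct"] = np.where(totals > 0, 100.0 * out["aai_ha"] / totals, 0.0)
    out["flagged"] = totals.to_numpy() == 0
    return out[["region_id", "crop_code", "share_pct", "flagged"]]


def crop_aai_series(nuts2_series: pd.DataFrame,
                    crop_shares: pd.DataFrame) -> pd.DataFrame:
    """Annual crop-specific AAI targets: fixed crop shares times annual totals.

    Returns (region_id, crop_code, year, aai_ha).  For non-flagged regions
    the crop sum equals the annual total exactly; flagged (zero-share)
    regions yield all-zero rows and their totals are reported separately by
    :func:`unallocated_totals`.
    """
    missing = set(nuts2_series["region_id"]) - set(crop_shares["region_id"])
    if missing:
        raise ValueError(f"regions without crop shares: {sorted(missing)}")
    merged = nuts2_series.merge(crop_shares, on="region_id", how="inner")
    merged["aai_ha"] = merged["share_pct"] / 100.0 * merged["taai_ha"]
    return merged[["region_id", "crop_code", "year", "aai_ha"]]


def unallocated_totals(nuts2_series: pd.DataFrame,
                       crop_shares: pd.DataFrame) -> pd.DataFrame:
    """Annual totals of flagged regions that no crop split can absorb."""
    flagged = crop_shares.loc[crop_shares["flagged"], "region_id"].unique()
    out = nuts2_series[nuts2_series["region_id"].isin(flagged)
                       & (nuts2_series["taai_ha"] > 0)].copy()
    return out.rename(columns={"taai_ha": "unallocated_ha"}).reset_index(drop=True)
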
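"""Summary reports: a per-region model table (community counts, trait
ranges, and model R² for temperature and precipitation) and the paleo
reconstruction table."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_region_table", "export_report"]


def _region_row(region: str, g: pd.DataFrame, r2_mat, r2_ap) -> dict:
    return {
        "region": region,
        "n_communities": len(g),
        "min_trait_mean": float(g["trait_mean"].min()),
        "max_trait_mean": float(g["trait_mean"].max()),
        "mean_trait_mean": float(g["trait_mean"].mean()),
        "sd_trait_mean": float(g["trait_mean"].std(ddof=1)) if len(g) > 1 else 0.0,
        "r2_mat": np.nan if r2_mat is None else float(r2_mat),
        "r2_ap": np.nan if r2_ap is None else float(r2_ap),
    }


def build_region_table(
    summaries: pd.DataFrame, r2_by_region: dict[str, dict] | None = None
) -> pd.DataFrame:
    """One row per region (plus a leading global row when several regions
    exist): community count N, min/max/mean/SD of community trait means,
    and the R² of the regional MAT and AP models where supplied.

    Regions come from an optional ``region`` column; without one the table
    is a single global row. Per-region N sums to the global N.
    """
    r2_by_region = r2_by_region or {}
    rows = []
    if "region" in summaries.columns and summaries["region"].nunique() > 1:
        g2 = r2_by_region.get("global", {})
        rows.append(_region_row("global", summaries, g2.get("mat"), g2.get("ap")))
        for region, g in summaries.groupby("region", sort=True):
            r2 = r2_by_region.get(str(region), {})
            rows.append(_region_row(str(region), g, r2.get("mat"), r2.get("ap")))
    else:
        region = (
            str(summaries["region"].iloc[0])
            if "region" in summaries.columns
            else "global"
        )
        r2 = r2_by_region.get(region, r2_by_region.get("global", {}))
        rows.append(_region_row(region, summaries, r2.get("mat"), r2.get("ap")))
    return pd.DataFrame(rows)


def export_report(
    summaries: pd.DataFrame,
    r2_by_region: dict[str, dict] | None = None,
    reconstruction: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the report tables. The paleo section is omitted (with no
    error) when no reconstruction results exist."""
    out = {"regions": build_region_table(summaries, r2_by_region)}
    if reconstruction is not None and len(reconstruction):
        out["paleo"] = reconstruction
    return out
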
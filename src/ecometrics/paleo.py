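"""Paleoclimate hindcasting from fossil assemblages.

A fossil assemblage's trait mean and standard deviation (same estimator as
for modern communities) are passed through the modern-calibrated ecometric
models to estimate the paleotemperature (degC) and paleoprecipitation
(back-transformed to mm). Each reconstruction is paired with the modern
community at (or nearest to) the site location, yielding the
predicted-minus-modern climate differences and the displacement of the
community through ecometric space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import EcometricResults

__all__ = [
    "FossilAssemblage",
    "ReconstructionResult",
    "summarize_fossil",
    "hindcast",
    "modern_comparison",
    "reconstruct_sites",
]


@dataclass(frozen=True)
class FossilAssemblage:
    """One fossil site: metadata plus the species trait list."""

    site: str
    x: float
    y: float
    species: tuple[str, ...]
    rbl: tuple[float, ...]
    age_min_kya: float = float("nan")
    age_max_kya: float = float("nan")
    habitat: str = ""

    def __post_init__(self):
        if len(self.species) != len(self.rbl):
            raise ValueError(f"{self.site}: species and RBL lists differ in length")
        if len(self.rbl) < 3:
            raise ValueError(
                f"{self.site}: needs >= 3 species with trait values, has {len(self.rbl)}"
            )
        if any(not (0.0 <= v <= 1.0) for v in self.rbl):
            raise ValueError(f"{self.site}: RBL values must lie in [0, 1]")


def summarize_fossil(assemblage: FossilAssemblage) -> tuple[float, float]:
    """Trait mean and sample standard deviation (n-1) of the assemblage —
    the same estimator applied to modern communities."""
    v = np.asarray(assemblage.rbl, dtype=float)
    return float(v.mean()), float(v.std(ddof=1))


def hindcast(
    mat_results: EcometricResults,
    ap_results: EcometricResults,
    trait_mean: float,
    trait_sd: float,
) -> dict:
    """Estimate (MAT degC, AP mm) for a trait summary through the fitted
    models. Summaries outside the calibrated trait space are clamped to
    edge bins and flagged; empty bins borrow the nearest nonempty bin.
    """
    if mat_results.model.env != "MAT" or ap_results.model.env != "AP":
        raise ValueError("pass (MAT results, AP results) in that order")
    mat_est, mat_clamped, mat_borrowed = mat_results.predict(
        trait_mean, trait_sd, return_flags=True
    )
    lap_est, ap_clamped, ap_borrowed = ap_results.predict(
        trait_mean, trait_sd, return_flags=True
    )
    return {
        "mat_c": float(mat_est),
        "ap_mm": float(math.exp(lap_est)),
        "clamped": bool(mat_clamped or ap_clamped),
        "borrowed_bin": bool(mat_borrowed or ap_borrowed),
    }


@dataclass(frozen=True)
class ReconstructionResult:
    """Fossil-vs-modern comparison at one site (the shape of a paleo
    reconstruction table row)."""

    site: str
    fossil_mean: float
    fossil_sd: float
    modern_mean: float
    modern_sd: float
    predicted_mat_c: float
    predicted_ap_mm: float
    modern_mat_c: float
    modern_ap_mm: float
    clamped: bool = False
    habitat: str = ""

    @property
    def mat_difference_c(self) -> float:
        """Predicted minus modern MAT; positive = site predicted hotter."""
        return self.predicted_mat_c - self.modern_mat_c

    @property
    def ap_difference_mm(self) -> float:
        """Predicted minus modern AP; positive = site predicted wetter."""
        return self.predicted_ap_mm - self.modern_ap_mm

    @property
    def displacement(self) -> tuple[float, float]:
        """Ecometric-space displacement modern minus fossil: (dmean, dsd)."""
        return (self.modern_mean - self.fossil_mean, self.modern_sd - self.fossil_sd)

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "fossil_mean": self.fossil_mean,
            "fossil_sd": self.fossil_sd,
            "modern_mean": self.modern_mean,
            "modern_sd": self.modern_sd,
            "predicted_mat_c": self.predicted_mat_c,
            "predicted_ap_mm": self.predicted_ap_mm,
            "modern_mat_c": self.modern_mat_c,
            "modern_ap_mm": self.modern_ap_mm,
            "mat_difference_c": self.mat_difference_c,
            "ap_difference_mm": self.ap_difference_mm,
            "delta_mean": self.displacement[0],
            "delta_sd": self.displacement[1],
            "clamped": self.clamped,
            "habitat": self.habitat,
        }


def modern_comparison(
    site: str,
    fossil_mean: float,
    fossil_sd: float,
    modern_mean: float,
    modern_sd: float,
    predicted_mat_c: float,
    predicted_ap_mm: float,
    modern_mat_c: float,
    modern_ap_mm: float,
    clamped: bool = False,
    habitat: str = "",
) -> ReconstructionResult:
    """Assemble a :class:`ReconstructionResult`; the climate differences
    (predicted - modern) and the ecometric displacement are derived
    properties, always recomputable from the stored fields."""
    return ReconstructionResult(
        site=site,
        fossil_mean=float(fossil_mean),
        fossil_sd=float(fossil_sd),
        modern_mean=float(modern_mean),
        modern_sd=float(modern_sd),
        predicted_mat_c=float(predicted_mat_c),
        predicted_ap_mm=float(predicted_ap_mm),
        modern_mat_c=float(modern_mat_c),
        modern_ap_mm=float(modern_ap_mm),
        clamped=clamped,
        habitat=habitat,
    )


def _nearest_modern(
    x: float, y: float, summaries: pd.DataFrame, max_radius: float
) -> pd.Series:
    d = np.hypot(summaries["x"] - x, summaries["y"] - y)
    k = d.idxmin()
    if d.loc[k] > max_radius:
        raise ValueError(
            f"no modern community within {max_radius} of site ({x}, {y}); "
            f"closest is {d.loc[k]:.1f} away"
        )
    return summaries.loc[k]


def reconstruct_sites(
    assemblages,
    mat_results: EcometricResults,
    ap_results: EcometricResults,
    modern_summaries: pd.DataFrame,
    max_radius: float | None = None,
    grid_spacing: float | None = None,
) -> pd.DataFrame:
    """Hindcast every fossil assemblage and compare against the nearest
    modern community (default search radius: two grid spacings).

    ``modern_summaries`` must carry x, y, trait_mean, trait_sd, mat, ap.
    Returns one row per site in reconstruction-table shape.
    """
    if max_radius is None:
        if grid_spacing is None:
            dx = np.diff(np.unique(modern_summaries["x"].round(9)))
            grid_spacing = float(dx.min()) if dx.size else 1.0
        max_radius = 2.0 * grid_spacing
    rows = []
    for asm in assemblages:
        fmean, fsd = summarize_fossil(asm)
        est = hindcast(mat_results, ap_results, fmean, fsd)
        modern = _nearest_modern(asm.x, asm.y, modern_summaries, max_radius)
        rows.append(
            modern_comparison(
                site=asm.site,
                fossil_mean=fmean,
                fossil_sd=fsd,
                modern_mean=float(modern["trait_mean"]),
                modern_sd=float(modern["trait_sd"]),
                predicted_mat_c=est["mat_c"],
                predicted_ap_mm=est["ap_mm"],
                modern_mat_c=float(modern["mat"]),
                modern_ap_mm=float(modern["ap"]),
                clamped=est["clamped"],
                habitat=asm.habitat,
            ).to_dict()
        )
    return pd.DataFrame(rows)
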
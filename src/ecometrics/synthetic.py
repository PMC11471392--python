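"""Synthetic study system for the ecometric pipeline.

Generates spatially autocorrelated temperature / precipitation surfaces, a
species pool whose dietary trait values couple to climatic niche position,
Bernoulli-thinned climatic-envelope ranges, and fossil assemblages drawn
under a designated paleoclimate. The generator's defaults emulate the
statistical structure the analysis assumes in real data: community trait
standard deviation rises toward hot and wet climates, the lowest community
trait means occur only under wet conditions, species trait values are
bounded in [0.41, 1.0], and communities of three or more trait-bearing
species exist over most of the domain.

Every generator is a pure function of ``(config, seed)``: a single master
seed deterministically derives independent substreams per stage, so any
stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .communities import ClimateSurface, CommunityMatrix, TraitTable, build_summaries

__all__ = [
    "WorldConfig",
    "SimulatedWorld",
    "FossilDraw",
    "generate_climate",
    "generate_species_pool",
    "generate_ranges",
    "generate_fossil_assemblage",
    "simulate_world",
]

# trait bounds observed across extant carnivorans (skunk .. felids)
TRAIT_MIN = 0.41
TRAIT_MAX = 1.0

# substream indices off the master seed
_STAGE_CLIMATE = 0
_STAGE_POOL = 1
_STAGE_RANGES = 2
_STAGE_FOSSIL = 3


def _rng(seed: int, stage: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(stage, *map(int, extra)))
    )


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world.

    Climate: MAT runs a south-north linear gradient over ``mat_range``
    (degC) plus Gaussian-smoothed noise with correlation length
    ``autocorr_length`` (cells); precipitation is generated on the natural
    log scale over ``log_ap_range`` (ln mm) with a west-east gradient and
    the same smoothing, then exponentiated (AP > 0 by construction).

    Species: niche centers are placed at the climates of randomly chosen
    cells (jittered), niche breadths are ``breadth_frac`` of each climate
    axis range, and occupancy inside the (hard, 2-breadth-unit) envelope is
    Bernoulli. Trait values draw from a normal whose mean decreases with
    niche wetness (strength ``coupling_mean``) and whose spread increases
    with niche hot-wetness (strength ``coupling_sd``), clipped to
    [0.41, 1.0]. Both couplings live in [0, 1]; at 0 traits are independent
    of niche position.
    """

    seed: int = 0
    nx: int = 60
    ny: int = 50
    cell_size: float = 50.0  # nominal km
    n_species: int = 60
    coupling_mean: float = 1.0
    coupling_sd: float = 1.0
    autocorr_length: float = 5.0  # cells
    richness_target: int = 12
    occupancy: float = 0.85
    breadth_frac: float = 0.125
    noise_amplitude: float = 1.0  # scales both climate noise fields
    mat_range: tuple[float, float] = (-15.0, 30.0)
    log_ap_range: tuple[float, float] = (4.7, 7.9)  # ~110 .. 2700 mm
    mat_noise_sd: float = 3.0  # degC
    log_ap_noise_sd: float = 0.35
    trait_mean_high: float = 0.88
    trait_mean_drop: float = 0.25
    trait_sd_base: float = 0.04
    trait_sd_gain: float = 0.15

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid dimensions must be >= 2")
        if self.autocorr_length <= 0:
            raise ValueError("autocorrelation length must be positive")
        if not (0.0 <= self.coupling_mean <= 1.0 and 0.0 <= self.coupling_sd <= 1.0):
            raise ValueError("coupling strengths must lie in [0, 1]")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError("occupancy must be in (0, 1]")
        if self.n_species < 3:
            raise ValueError("need at least 3 species")


def _smooth_noise(rng: np.random.Generator, ny: int, nx: int, length: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ~length cells."""
    z = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma=length, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_climate(config: WorldConfig) -> ClimateSurface:
    """South-north MAT gradient and west-east log-AP gradient, each plus
    spatially autocorrelated noise. With ``noise_amplitude=0`` the layers
    are exact linear gradients."""
    rng = _rng(config.seed, _STAGE_CLIMATE)
    ny, nx = config.ny, config.nx
    lat = np.linspace(1.0, 0.0, ny)[:, None]  # row 0 = south = hot
    lon = np.linspace(0.0, 1.0, nx)[None, :]  # col nx-1 = east = wet
    m0, m1 = config.mat_range
    p0, p1 = config.log_ap_range
    mat = m0 + (m1 - m0) * lat + np.zeros((ny, nx))
    log_ap = p0 + (p1 - p0) * lon + np.zeros((ny, nx))
    if config.noise_amplitude > 0:
        amp = config.noise_amplitude
        mat = mat + amp * config.mat_noise_sd * _smooth_noise(rng, ny, nx, config.autocorr_length)
        log_ap = log_ap + amp * config.log_ap_noise_sd * _smooth_noise(
            rng, ny, nx, config.autocorr_length
        )
    return ClimateSurface(mat=mat, ap=np.exp(log_ap), cell_size=config.cell_size)


def generate_species_pool(config: WorldConfig, surface: ClimateSurface) -> pd.DataFrame:
    """Species pool with niche-conditional trait distribution.

    Returns a DataFrame (one row per species): ``species``, ``rbl``,
    ``niche_mat``, ``niche_log_ap``, ``breadth_mat``, ``breadth_log_ap``,
    ``occupancy``. Species in hot/wet climate space draw traits from a
    wider distribution reaching low values; cold/dry species draw from a
    narrow, high-trait distribution. All traits clip to [0.41, 1.0].
    """
    rng = _rng(config.seed, _STAGE_POOL)
    mat = surface.mat.ravel()
    log_ap = np.log(surface.ap).ravel()
    mat_lo, mat_hi = mat.min(), mat.max()
    lap_lo, lap_hi = log_ap.min(), log_ap.max()
    mat_rng = mat_hi - mat_lo or 1.0
    lap_rng = lap_hi - lap_lo or 1.0

    n = config.n_species
    cells = rng.integers(0, mat.size, size=n)
    niche_mat = mat[cells] + rng.normal(0, 0.05 * mat_rng, size=n)
    niche_lap = log_ap[cells] + rng.normal(0, 0.05 * lap_rng, size=n)

    w_hot = np.clip((niche_mat - mat_lo) / mat_rng, 0.0, 1.0)
    w_wet = np.clip((niche_lap - lap_lo) / lap_rng, 0.0, 1.0)
    mu = config.trait_mean_high - config.trait_mean_drop * config.coupling_mean * w_wet
    sigma = config.trait_sd_base + config.trait_sd_gain * config.coupling_sd * 0.5 * (
        w_hot + w_wet
    )
    rbl = np.clip(rng.normal(mu, sigma), TRAIT_MIN, TRAIT_MAX)

    return pd.DataFrame(
        {
            "species": [f"sp{i:03d}" for i in range(n)],
            "rbl": rbl,
            "niche_mat": niche_mat,
            "niche_log_ap": niche_lap,
            "breadth_mat": config.breadth_frac * mat_rng,
            "breadth_log_ap": config.breadth_frac * lap_rng,
            "occupancy": config.occupancy,
        }
    )


def _envelope_mask(
    pool: pd.DataFrame, mat: np.ndarray, log_ap: np.ndarray
) -> np.ndarray:
    """(n_cells, n_species) boolean: climate inside each species' hard
    envelope (elliptical cutoff at 2 niche-breadth units)."""
    dm = (mat[:, None] - pool["niche_mat"].to_numpy()[None, :]) / pool[
        "breadth_mat"
    ].to_numpy()[None, :]
    dp = (log_ap[:, None] - pool["niche_log_ap"].to_numpy()[None, :]) / pool[
        "breadth_log_ap"
    ].to_numpy()[None, :]
    return dm * dm + dp * dp <= 4.0


def generate_ranges(
    pool: pd.DataFrame, surface: ClimateSurface, config: WorldConfig
) -> CommunityMatrix:
    """Occupancy-thinned climatic-envelope ranges on the surface's cell
    centers. Species whose envelope excludes every cell simply end with
    empty ranges (they are retained as all-False columns)."""
    if len(pool) == 0:
        raise ValueError("species pool is empty")
    rng = _rng(config.seed, _STAGE_RANGES)
    points = surface.cell_centers()
    mat = surface.mat.ravel()
    log_ap = np.log(surface.ap).ravel()
    inside = _envelope_mask(pool, mat, log_ap)
    occ = rng.random(inside.shape) < pool["occupancy"].to_numpy()[None, :]
    presence = pd.DataFrame(
        inside & occ, index=points.index, columns=list(pool["species"])
    )
    return CommunityMatrix(points=points, presence=presence)


@dataclass(frozen=True)
class FossilDraw:
    """A synthetic fossil assemblage at one site cell."""

    site_cell: int
    paleo_mat: float
    paleo_log_ap: float
    species: list[str]
    rbl: np.ndarray

    @property
    def trait_mean(self) -> float:
        return float(np.mean(self.rbl))

    @property
    def trait_sd(self) -> float:
        return float(np.std(self.rbl, ddof=1))


def generate_fossil_assemblage(
    pool: pd.DataFrame,
    surface: ClimateSurface,
    site_cell: int,
    config: WorldConfig,
    paleo_mat: float | None = None,
    paleo_log_ap: float | None = None,
    matrix: CommunityMatrix | None = None,
) -> FossilDraw:
    """Draw a fossil assemblage at ``site_cell`` under a designated
    paleoclimate (defaults to the cell's modern climate).

    Candidates are species whose climatic envelope contains the
    paleoclimate. When the modern ``matrix`` is supplied, species whose
    envelope also contains the cell's *modern* climate are conditioned on
    their observed modern presence (their absence at the cell is treated as
    a real range hole), so an assemblage drawn under the modern climate is
    a subsample of the modern community. Membership is Bernoulli at each
    candidate's occupancy, topped up deterministically (nearest niche
    first) to the three-species minimum. Fewer than three candidates is a
    generation error.
    """
    n_cells = surface.mat.size
    if not (0 <= site_cell < n_cells):
        raise ValueError(f"site_cell {site_cell} outside the surface (0..{n_cells - 1})")
    mat_cell = float(surface.mat.ravel()[site_cell])
    lap_cell = float(np.log(surface.ap.ravel()[site_cell]))
    pm = mat_cell if paleo_mat is None else float(paleo_mat)
    pl = lap_cell if paleo_log_ap is None else float(paleo_log_ap)

    in_paleo = _envelope_mask(pool, np.array([pm]), np.array([pl]))[0]
    eligible = np.flatnonzero(in_paleo)
    if matrix is not None:
        in_modern = _envelope_mask(pool, np.array([mat_cell]), np.array([lap_cell]))[0]
        present = matrix.presence.iloc[site_cell].reindex(pool["species"]).to_numpy()
        keep = in_paleo & (~in_modern | present)
        eligible = np.flatnonzero(keep)
    if eligible.size < 3:
        raise ValueError(
            f"only {eligible.size} species have envelopes containing the "
            f"paleoclimate (MAT={pm:.1f} degC, logAP={pl:.2f}) at cell "
            f"{site_cell}; need >= 3"
        )
    rng = _rng(config.seed, _STAGE_FOSSIL, site_cell)
    occ = pool["occupancy"].to_numpy()[eligible]
    drawn = eligible[rng.random(eligible.size) < occ]
    if drawn.size < 3:
        # top up with the closest-niche eligible species, deterministically
        d2 = (
            (pool["niche_mat"].to_numpy()[eligible] - pm)
            / pool["breadth_mat"].to_numpy()[eligible]
        ) ** 2 + (
            (pool["niche_log_ap"].to_numpy()[eligible] - pl)
            / pool["breadth_log_ap"].to_numpy()[eligible]
        ) ** 2
        for k in eligible[np.argsort(d2, kind="stable")]:
            if k not in drawn:
                drawn = np.append(drawn, k)
            if drawn.size >= 3:
                break
    drawn = np.sort(drawn)
    return FossilDraw(
        site_cell=site_cell,
        paleo_mat=pm,
        paleo_log_ap=pl,
        species=list(pool["species"].to_numpy()[drawn]),
        rbl=pool["rbl"].to_numpy()[drawn].astype(float),
    )


@dataclass
class SimulatedWorld:
    """Bundle of one synthetic study system: climate surface, species pool,
    trait table, presence matrix, and filtered community summaries."""

    config: WorldConfig
    surface: ClimateSurface
    pool: pd.DataFrame
    traits: TraitTable
    matrix: CommunityMatrix
    summaries: pd.DataFrame


def simulate_world(config: WorldConfig | None = None, min_richness: int = 3) -> SimulatedWorld:
    """Run every generation stage and assemble filtered community
    summaries ready for :class:`~ecometrics.model.EcometricModel`."""
    config = config or WorldConfig()
    surface = generate_climate(config)
    pool = generate_species_pool(config, surface)
    traits = TraitTable(pool[["species", "rbl"]].assign(source="measured"))
    matrix = generate_ranges(pool, surface, config)
    summaries = build_summaries(matrix, traits, surface, min_n=min_richness)
    return SimulatedWorld(
        config=config,
        surface=surface,
        pool=pool,
        traits=traits,
        matrix=matrix,
        summaries=summaries,
    )
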
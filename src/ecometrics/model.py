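"""Binned maximum-likelihood ecometric model.

Communities are placed in a 2-D "ecometric space" spanned by their trait
mean (x) and trait standard deviation (y), discretised into an ``n_bins`` x
``n_bins`` grid of equal-width bins. Within each bin the distribution of an
environmental variable (mean annual temperature in degC, or annual
precipitation on a natural-log mm scale) over the member communities is
smoothed with a Gaussian kernel, and the peak of that likelihood surface is
the bin's maximum-likelihood environment estimate. A community's estimated
environment is the peak of its bin; model fit is summarised by the squared
Pearson correlation between estimated and observed environments.

The public surface follows the Model/Results convention: build an
:class:`EcometricModel` from a community-summary table, call :meth:`fit`,
and work with the returned :class:`EcometricResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EcometricSpace",
    "EcometricModel",
    "EcometricResults",
    "bin_communities",
    "fit_bin_likelihood",
    "evaluate_fit",
    "silverman_bandwidth",
]

DEFAULT_N_BINS = 25
DEFAULT_GRID_SIZE = 512
#: bandwidth floor, as a fraction of the full environmental range, applied
#: to near-degenerate bins (single community, or zero spread)
BANDWIDTH_FLOOR_FRAC = 0.01
#: two likelihood-surface modes whose densities agree to this relative
#: tolerance are treated as tied (the smaller environmental value wins)
PEAK_TIE_TOL = 1e-5


class DegenerateAxisError(ValueError):
    """Raised when an ecometric axis has zero spread (all communities share
    one trait mean or one trait SD); equal-width binning is undefined.
    Aggregate more heterogeneous communities or reduce ``n_bins``."""


@dataclass(frozen=True)
class EcometricSpace:
    """The binned trait space: equal-width bins over the observed ranges.

    Bins are half-open ``[edge_k, edge_{k+1})`` with the last bin closed, so
    a value on an interior edge belongs to the higher bin and the axis
    maximum belongs to the top bin.
    """

    n_bins: int
    mean_edges: np.ndarray  # length n_bins + 1
    sd_edges: np.ndarray  # length n_bins + 1

    @property
    def n_total_bins(self) -> int:
        return self.n_bins * self.n_bins

    def bin_index(self, trait_mean, trait_sd, clamp: bool = False):
        """Map (mean, SD) pairs to integer bin indices ``(i, j)``.

        With ``clamp=True`` out-of-range values are assigned to the nearest
        edge bin and flagged (needed for fossil summaries that fall outside
        the modern calibration range); otherwise they raise ``ValueError``.

        Returns ``(i, j, clamped)`` arrays of identical shape to the input.
        """
        m = np.asarray(trait_mean, dtype=float)
        s = np.asarray(trait_sd, dtype=float)
        i = self._axis_index(m, self.mean_edges)
        j = self._axis_index(s, self.sd_edges)
        below_i = m < self.mean_edges[0]
        above_i = m > self.mean_edges[-1]
        below_j = s < self.sd_edges[0]
        above_j = s > self.sd_edges[-1]
        clamped = below_i | above_i | below_j | above_j
        if np.any(clamped) and not clamp:
            raise ValueError(
                "trait summaries outside the calibrated ecometric space; "
                "pass clamp=True to assign them to edge bins"
            )
        return i, j, clamped

    def _axis_index(self, v: np.ndarray, edges: np.ndarray) -> np.ndarray:
        lo, hi = edges[0], edges[-1]
        width = (hi - lo) / self.n_bins
        idx = np.floor((v - lo) / width).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)

    @property
    def mean_centers(self) -> np.ndarray:
        return 0.5 * (self.mean_edges[:-1] + self.mean_edges[1:])

    @property
    def sd_centers(self) -> np.ndarray:
        return 0.5 * (self.sd_edges[:-1] + self.sd_edges[1:])


def bin_communities(
    trait_mean, trait_sd, n_bins: int = DEFAULT_N_BINS
) -> tuple[EcometricSpace, np.ndarray, np.ndarray]:
    """Construct the ecometric space from community summaries and assign
    every community to exactly one bin.

    Returns ``(space, i, j)`` where ``i``/``j`` index the mean/SD axes.
    """
    m = np.asarray(trait_mean, dtype=float)
    s = np.asarray(trait_sd, dtype=float)
    if m.size < 1:
        raise ValueError("at least one community is required")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    for name, v in (("trait mean", m), ("trait SD", s)):
        if np.ptp(v) == 0.0:
            raise DegenerateAxisError(
                f"all communities share a single {name} value "
                f"({v[0]!r}); the {name} axis has zero width"
            )
    space = EcometricSpace(
        n_bins=n_bins,
        mean_edges=np.linspace(m.min(), m.max(), n_bins + 1),
        sd_edges=np.linspace(s.min(), s.max(), n_bins + 1),
    )
    i, j, _ = space.bin_index(m, s)
    return space, i, j


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, robust variant:
    ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``. Returns 0 for degenerate
    samples (n < 2 or zero spread); callers apply a floor."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        return 0.0
    sd = v.std(ddof=1)
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def fit_bin_likelihood(
    env_values,
    bandwidth="auto",
    bandwidth_floor: float = 0.0,
    grid_size: int = DEFAULT_GRID_SIZE,
    return_surface: bool = True,
):
    """Gaussian-kernel likelihood surface for one bin's environment values.

    The kernel density is evaluated on ``grid_size`` equally spaced points
    spanning ``[min - 3h, max + 3h]``; the maximum-likelihood environment is
    the argmax, with ties broken toward the smallest environmental value.

    Parameters
    ----------
    env_values : array-like
        Observed environment of the communities in the bin (>= 1 value).
    bandwidth : float or "auto"
        Kernel bandwidth ``h`` in environment units; "auto" applies
        Silverman's rule to the bin members.
    bandwidth_floor : float
        Lower bound on ``h`` (e.g. 1% of the global environmental range) so
        single-community and zero-spread bins still have a defined surface.
    return_surface : bool
        When False, only the peak is computed (fast path used by the
        randomization null, which refits hundreds of near-singleton bins).

    Returns
    -------
    (grid, density, peak, h) — grid/density are None if not requested.
    """
    v = np.asarray(env_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty bin: no environmental values to fit")
    if bandwidth == "auto":
        h = silverman_bandwidth(v)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    h = max(h, bandwidth_floor)
    vmin, vmax = v.min(), v.max()
    if vmin == vmax:
        # all mass at one point: the peak is that value regardless of h
        if not return_surface:
            return None, None, float(vmin), h
        if h <= 0:
            h = max(bandwidth_floor, 1.0)  # arbitrary positive width
    if h <= 0:
        # spread but no usable bandwidth: fall back to the data SD
        h = float(np.std(v)) or 1.0
    if not return_surface:
        # peak only, still on the documented evaluation grid
        grid = np.linspace(vmin - 3 * h, vmax + 3 * h, grid_size)
        dens = _kde(grid, v, h)
        return None, None, _peak_of(grid, dens, v, h), h
    grid = np.linspace(vmin - 3 * h, vmax + 3 * h, grid_size)
    dens = _kde(grid, v, h)
    return grid, dens, _peak_of(grid, dens, v, h), h


def _peak_of(grid: np.ndarray, dens: np.ndarray, values: np.ndarray, h: float) -> float:
    """Continuous argmax of the kernel density.

    The coarse evaluation grid can rank two nearly equal modes in the wrong
    order (its density error is quadratic in the grid step), so every grid
    point within a conservative margin of the sampled maximum is refined by
    a dense local evaluation; the refined maximum wins, with ties broken
    toward the smallest environmental value.
    """
    dmax = dens.max()
    candidates = np.flatnonzero(dens >= dmax * (1.0 - 1e-3))
    refined: list[tuple[float, float]] = []
    for i in candidates:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        xs = np.linspace(lo, hi, 201)
        ds = _kde(xs, values, h)
        k = int(np.argmax(ds))
        refined.append((float(xs[k]), float(ds[k])))
    best_d = max(d for _, d in refined)
    # modes within PEAK_TIE_TOL relative density are equally likely at the
    # working resolution; the convention picks the smallest value
    return min(x for x, d in refined if d >= best_d * (1.0 - PEAK_TIE_TOL))


def _kde(grid: np.ndarray, values: np.ndarray, h: float) -> np.ndarray:
    z = (grid[:, None] - values[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (values.size * h * math.sqrt(2 * math.pi))


def evaluate_fit(estimates, observations) -> float:
    """Coefficient of determination between estimated and observed
    environments: the squared Pearson correlation. Constant estimate
    vectors (zero variance) yield 0 by convention."""
    e = np.asarray(estimates, dtype=float)
    o = np.asarray(observations, dtype=float)
    if e.shape != o.shape:
        raise ValueError("estimates and observations must be paired vectors")
    if e.size < 3:
        raise ValueError("at least 3 paired values are required for R^2")
    if np.ptp(e) == 0.0 or np.ptp(o) == 0.0:
        return 0.0
    r = np.corrcoef(e, o)[0, 1]
    return float(r * r)


def _r2_regression(estimates: np.ndarray, observations: np.ndarray) -> float:
    """1 - SSres/SStot of observations about the estimates (logged as a
    secondary diagnostic; may be negative for a poorly located estimator)."""
    ss_res = float(np.sum((observations - estimates) ** 2))
    ss_tot = float(np.sum((observations - observations.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


class EcometricModel:
    """Trait-environment model over binned community ecometric space.

    Parameters
    ----------
    summaries : pandas.DataFrame
        One row per community, with columns ``trait_mean``, ``trait_sd``
        and the environment column for ``env`` (``mat`` in degC, or
        ``log_ap`` / ``ap`` for precipitation; precipitation is modelled on
        the natural-log mm scale throughout and back-transformed only for
        reporting).
    env : {"MAT", "AP"}
    n_bins : int
        Bins per axis (default 25, i.e. 625 bins).
    """

    def __init__(
        self,
        summaries: pd.DataFrame,
        env: str = "MAT",
        n_bins: int = DEFAULT_N_BINS,
        grid_size: int = DEFAULT_GRID_SIZE,
    ):
        env = env.upper()
        if env not in ("MAT", "AP"):
            raise ValueError("env must be 'MAT' or 'AP'")
        required = {"trait_mean", "trait_sd"}
        missing = required - set(summaries.columns)
        if missing:
            raise ValueError(f"summaries missing columns: {sorted(missing)}")
        if env == "MAT":
            if "mat" not in summaries.columns:
                raise ValueError("summaries missing 'mat' column")
            env_values = summaries["mat"].to_numpy(dtype=float)
        else:
            if "log_ap" in summaries.columns:
                env_values = summaries["log_ap"].to_numpy(dtype=float)
            elif "ap" in summaries.columns:
                ap = summaries["ap"].to_numpy(dtype=float)
                if np.any(ap <= 0):
                    raise ValueError("ap must be strictly positive to log-transform")
                env_values = np.log(ap)
            else:
                raise ValueError("summaries missing 'log_ap' (or 'ap') column")
        if np.any(~np.isfinite(env_values)):
            bad = summaries.index[~np.isfinite(env_values)].tolist()[:10]
            raise ValueError(f"non-finite environment values at rows {bad}")
        self.summaries = summaries
        self.env = env
        self.n_bins = int(n_bins)
        self.grid_size = int(grid_size)
        self.env_values = env_values
        self.trait_mean = summaries["trait_mean"].to_numpy(dtype=float)
        self.trait_sd = summaries["trait_sd"].to_numpy(dtype=float)
        self.nobs = len(summaries)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, env: str = "MAT", **kwargs) -> "EcometricModel":
        return cls(data, env=env, **kwargs)

    def fit(self, bandwidth="silverman", compute_surfaces: bool = False) -> "EcometricResults":
        """Bin the communities and fit the per-bin Gaussian-kernel
        likelihood peaks.

        ``bandwidth`` is "silverman" (per-bin rule of thumb, floored at 1%
        of the environmental range) or a fixed float in environment units.
        """
        space, bi, bj = bin_communities(self.trait_mean, self.trait_sd, self.n_bins)
        env_range = float(np.ptp(self.env_values))
        floor = BANDWIDTH_FLOOR_FRAC * env_range if env_range > 0 else 1.0
        bw_arg = "auto" if bandwidth == "silverman" else bandwidth

        n = self.n_bins
        peaks = np.full((n, n), np.nan)
        bandwidths = np.full((n, n), np.nan)
        counts = np.zeros((n, n), dtype=int)
        surfaces: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        flat = bi * n + bj
        order = np.argsort(flat, kind="stable")
        sorted_flat = flat[order]
        boundaries = np.flatnonzero(np.diff(sorted_flat)) + 1
        for group in np.split(order, boundaries):
            i, j = divmod(int(flat[group[0]]), n)
            vals = self.env_values[group]
            counts[i, j] = vals.size
            grid, dens, peak, h = fit_bin_likelihood(
                vals,
                bandwidth=bw_arg,
                bandwidth_floor=floor,
                grid_size=self.grid_size,
                return_surface=compute_surfaces,
            )
            peaks[i, j] = peak
            bandwidths[i, j] = h
            if compute_surfaces:
                surfaces[(i, j)] = (grid, dens)

        estimates = peaks[bi, bj]
        return EcometricResults(
            model=self,
            space=space,
            bin_i=bi,
            bin_j=bj,
            peaks=peaks,
            bandwidths=bandwidths,
            counts=counts,
            estimates=estimates,
            surfaces=surfaces,
            bandwidth_rule=str(bandwidth),
            bandwidth_floor=floor,
        )


@dataclass
class EcometricResults:
    """Fitted ecometric model: per-bin ML environment estimates plus
    per-community estimates, anomalies and fit statistics.

    Environmental scale: for MAT everything is degC; for AP the internal
    scale is ln(mm) — :attr:`estimates_natural` and :attr:`anomalies`
    back-transform to mm.
    """

    model: EcometricModel
    space: EcometricSpace
    bin_i: np.ndarray
    bin_j: np.ndarray
    peaks: np.ndarray  # (n_bins, n_bins), NaN where empty
    bandwidths: np.ndarray
    counts: np.ndarray
    estimates: np.ndarray  # per community, model scale
    surfaces: dict = field(default_factory=dict, repr=False)
    bandwidth_rule: str = "silverman"
    bandwidth_floor: float = 0.0

    def __post_init__(self):
        self._nonempty = np.argwhere(~np.isnan(self.peaks))

    # -- fit statistics ---------------------------------------------------
    @property
    def r_squared(self) -> float:
        """Squared Pearson correlation of estimated vs observed environment."""
        return evaluate_fit(self.estimates, self.model.env_values)

    @property
    def r_squared_regression(self) -> float:
        """Secondary diagnostic: 1 - SSres/SStot."""
        return _r2_regression(self.estimates, self.model.env_values)

    @property
    def estimates_natural(self) -> np.ndarray:
        """Per-community estimates in natural units (mm for AP, degC for MAT)."""
        return np.exp(self.estimates) if self.model.env == "AP" else self.estimates

    @property
    def observations_natural(self) -> np.ndarray:
        v = self.model.env_values
        return np.exp(v) if self.model.env == "AP" else v

    @property
    def anomalies(self) -> np.ndarray:
        """Estimate minus observation in natural units; positive means the
        model overestimates (wetter / warmer than observed)."""
        return self.estimates_natural - self.observations_natural

    # -- prediction -------------------------------------------------------
    def predict(self, trait_mean, trait_sd, return_flags: bool = False):
        """Estimate the environment for arbitrary (mean, SD) summaries.

        Summaries outside the calibrated axis ranges are clamped to the
        nearest edge bin; summaries landing in an empty bin borrow the
        nearest nonempty bin's estimate (Euclidean distance in bin-index
        units, ties to the lower indices). Both situations are flagged.

        Returns the estimate on the model scale (ln mm for AP); with
        ``return_flags=True`` also a boolean ``clamped`` and ``borrowed``
        array pair.
        """
        m = np.atleast_1d(np.asarray(trait_mean, dtype=float))
        s = np.atleast_1d(np.asarray(trait_sd, dtype=float))
        i, j, clamped = self.space.bin_index(m, s, clamp=True)
        est = self.peaks[i, j]
        borrowed = np.isnan(est)
        if np.any(borrowed):
            if self._nonempty.size == 0:
                raise ValueError("model has no fitted bins")
            for k in np.flatnonzero(borrowed):
                ni, nj = self._nearest_nonempty(i[k], j[k])
                est[k] = self.peaks[ni, nj]
        scalar = np.isscalar(trait_mean) and np.isscalar(trait_sd)
        if return_flags:
            if scalar:
                return float(est[0]), bool(clamped[0]), bool(borrowed[0])
            return est, clamped, borrowed
        return float(est[0]) if scalar else est

    def _nearest_nonempty(self, i: int, j: int) -> tuple[int, int]:
        d2 = (self._nonempty[:, 0] - i) ** 2 + (self._nonempty[:, 1] - j) ** 2
        # ties resolved toward lower (i, j) via lexicographic key
        key = d2 * self.space.n_bins**2 * 4 + self._nonempty[:, 0] * self.space.n_bins * 2 + self._nonempty[:, 1]
        best = self._nonempty[np.argmin(key)]
        return int(best[0]), int(best[1])

    # -- presentation -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Per-community table: bin indices, estimate, observation, anomaly
        (natural units)."""
        return pd.DataFrame(
            {
                "bin_i": self.bin_i,
                "bin_j": self.bin_j,
                "estimate": self.estimates_natural,
                "observed": self.observations_natural,
                "anomaly": self.anomalies,
            },
            index=self.model.summaries.index,
        )

    def summary(self) -> str:
        env = self.model.env
        unit = "degC" if env == "MAT" else "mm"
        n_nonempty = int(np.sum(~np.isnan(self.peaks)))
        lines = [
            "Ecometric model results",
            "=" * 47,
            f"Environment:            {env} ({unit}"
            + (", fitted on ln scale)" if env == "AP" else ")"),
            f"Communities:            {self.model.nobs}",
            f"Ecometric bins:         {self.space.n_bins} x {self.space.n_bins}"
            f" = {self.space.n_total_bins} ({n_nonempty} occupied)",
            f"Bandwidth rule:         {self.bandwidth_rule}"
            f" (floor {self.bandwidth_floor:.4g})",
            f"R^2 (Pearson^2):        {self.r_squared:.4f}",
            f"R^2 (1 - SSres/SStot):  {self.r_squared_regression:.4f}",
            f"Mean anomaly ({unit}):".ljust(24)
            + f"{float(np.mean(self.anomalies)):.4g}",
            f"Trait mean range:       [{self.space.mean_edges[0]:.4g},"
            f" {self.space.mean_edges[-1]:.4g}]",
            f"Trait SD range:         [{self.space.sd_edges[0]:.4g},"
            f" {self.space.sd_edges[-1]:.4g}]",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EcometricResults env={self.model.env} nobs={self.model.nobs} "
            f"R2={self.r_squared:.3f}>"
        )
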
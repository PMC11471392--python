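"""Randomization nulls and down-sampling sensitivity analysis.

Two null procedures probe whether the estimated-to-observed environment
correlation could be spurious: (1) shuffling the estimated environments
against the observations, and (2) reassigning every community to a uniform
random ecometric bin, refitting all bin peaks, and re-estimating. Both are
repeated ``reps`` times (default 100) and summarised against the observed
R². The sensitivity analysis down-samples the communities over a ladder of
sample sizes, splits each draw 80/20 into train/test, fits on the training
set (re-binning its own ecometric space) and scores R² on the test set.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .model import (
    EcometricModel,
    EcometricResults,
    evaluate_fit,
    fit_bin_likelihood,
)

__all__ = [
    "NullDistribution",
    "SensitivityResult",
    "shuffle_test",
    "bin_randomization_test",
    "downsample_sensitivity",
]


@dataclass(frozen=True)
class NullDistribution:
    """Replicate R² values from one randomization procedure."""

    procedure: str  # "shuffle" | "bin-randomize"
    null_r2: np.ndarray
    observed_r2: float

    @property
    def exceedance(self) -> float:
        """Bias-avoiding empirical exceedance probability:
        ``(1 + #{null >= observed}) / (1 + reps)``."""
        return float(
            (1 + np.sum(self.null_r2 >= self.observed_r2)) / (1 + self.null_r2.size)
        )

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.null_r2, q)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"procedure": self.procedure, "replicate": np.arange(self.null_r2.size),
             "null_r2": self.null_r2, "observed_r2": self.observed_r2}
        )


def shuffle_test(results: EcometricResults, reps: int = 100, seed: int = 0) -> NullDistribution:
    """Permutation null: shuffle the estimate vector against the
    observations and recompute R² per replicate."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if results.model.nobs < 10:
        raise ValueError("shuffle test needs at least 10 communities")
    rng = np.random.default_rng(seed)
    obs = results.model.env_values
    est = results.estimates
    null = np.empty(reps)
    for r in range(reps):
        null[r] = evaluate_fit(rng.permutation(est), obs)
    return NullDistribution("shuffle", null, evaluate_fit(est, obs))


def bin_randomization_test(
    results: EcometricResults, reps: int = 100, seed: int = 0
) -> NullDistribution:
    """Structural null: assign every community to a uniformly random bin,
    refit all bin likelihood peaks from the reassigned memberships,
    re-estimate each community from its random bin, and recompute R²."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    model = results.model
    if model.nobs < 3:
        raise ValueError("bin-randomization needs at least 3 communities")
    rng = np.random.default_rng(seed)
    obs = model.env_values
    n_total = results.space.n_total_bins
    floor = results.bandwidth_floor
    bw = "auto" if results.bandwidth_rule == "silverman" else float(results.bandwidth_rule)
    null = np.empty(reps)
    for r in range(reps):
        assignment = rng.integers(0, n_total, size=model.nobs)
        est = np.empty(model.nobs)
        order = np.argsort(assignment, kind="stable")
        sorted_bins = assignment[order]
        cuts = np.flatnonzero(np.diff(sorted_bins)) + 1
        for group in np.split(order, cuts):
            vals = obs[group]
            if vals.size == 1 or np.ptp(vals) == 0.0:
                est[group] = vals[0]
                continue
            _, _, peak, _ = fit_bin_likelihood(
                vals, bandwidth=bw, bandwidth_floor=floor,
                grid_size=model.grid_size, return_surface=False,
            )
            est[group] = peak
        null[r] = evaluate_fit(est, obs)
    return NullDistribution("bin-randomize", null, results.r_squared)


@dataclass(frozen=True)
class SensitivityResult:
    """Test-set R² per (sample size, repeat)."""

    table: pd.DataFrame  # columns: size, repeat, r2_test, n_train, n_test

    @property
    def sizes(self) -> np.ndarray:
        return np.unique(self.table["size"].to_numpy())

    def median_by_size(self) -> pd.Series:
        return self.table.groupby("size")["r2_test"].median()


def downsample_sensitivity(
    summaries: pd.DataFrame,
    env: str = "MAT",
    sizes=None,
    repeats: int = 20,
    train_frac: float = 0.8,
    seed: int = 0,
    n_bins: int = 25,
) -> SensitivityResult:
    """Down-sampling transferability analysis.

    For each size in ``sizes`` (default 100..9100 step 1000) and each of
    ``repeats`` repeats: draw that many communities without replacement,
    split ``train_frac``/rest into train/test, fit an ecometric model on
    the training communities (with its own re-binned space), estimate the
    test communities through it (empty bins borrow the nearest nonempty
    bin), and record the test-set R². Sizes exceeding the available
    community count are dropped with a warning.
    """
    if sizes is None:
        sizes = list(range(100, 9101, 1000))
    sizes = sorted(int(s) for s in sizes)
    n = len(summaries)
    usable = [s for s in sizes if s <= n]
    if len(usable) < len(sizes):
        warnings.warn(
            f"sizes {sorted(set(sizes) - set(usable))} exceed the {n} available "
            "communities; size list truncated"
        )
    if not usable:
        raise ValueError("no requested size fits the available communities")
    rng = np.random.default_rng(seed)
    rows = []
    for size in usable:
        for rep in range(repeats):
            idx = rng.choice(n, size=size, replace=False)
            n_train = int(round(train_frac * size))
            train, test = idx[:n_train], idx[n_train:]
            tr = summaries.iloc[train]
            te = summaries.iloc[test]
            res = EcometricModel(tr, env=env, n_bins=n_bins).fit()
            est = res.predict(
                te["trait_mean"].to_numpy(), te["trait_sd"].to_numpy()
            )
            obs = (
                te["mat"].to_numpy()
                if env.upper() == "MAT"
                else te["log_ap"].to_numpy()
            )
            rows.append(
                {
                    "size": size,
                    "repeat": rep,
                    "r2_test": evaluate_fit(est, obs),
                    "n_train": len(train),
                    "n_test": len(test),
                }
            )
    return SensitivityResult(pd.DataFrame(rows))
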
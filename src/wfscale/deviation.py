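"""Divergence measures between scaled and unscaled replicate sets.

Scalar outcomes (per-replicate means of fixation time, allele frequency,
r^2, and the corrected fixed fraction) are compared by mean percent error;
binned outcomes (fixation-time histograms, SFS) by Kullback-Leibler
divergence between the replicate-averaged, normalized distributions; the
binned LD profile by RMSE over distance bins.  Uncertainty comes from
resampling whole replicates with replacement (1000 bootstrap resamples by
default) and recomputing every measure end-to-end.

Two sign conventions for the percent error are exposed.
:func:`mean_percent_error` is the directional error
``100 * (mean_unscaled - mean_scaled) / mean_unscaled`` (positive when
rescaling lowers the outcome's mean).  The report tables instead carry
:func:`percent_change` — ``100 * (mean_scaled - mean_unscaled) /
mean_unscaled``, positive when rescaling raises the mean — which is the
orientation the published comparison tables in this literature use
(e.g. a mean fixation time rising from 600 to 615 generations is reported
as +2.5%).  The two are negatives of each other; reports record which one
they carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .summaries import ReplicateSummary, N_LD_BINS

__all__ = [
    "AveragedOutcomeDistribution",
    "DeviationReport",
    "mean_percent_error",
    "percent_change",
    "kl_divergence",
    "ld_rmse",
    "bootstrap_deviation",
    "point_deviation",
    "subsample_stability",
    "SCALAR_OUTCOMES",
    "BINNED_OUTCOMES",
]

# scalar outcomes: ReplicateSummary attribute holding a per-class dict of means
SCALAR_OUTCOMES = {
    "fixation_times": "mean_fixation_time",
    "allele_frequencies": "mean_allele_frequency",
    "fraction_fixed": "fixed_fraction",
}
# binned outcomes compared by KL divergence
BINNED_OUTCOMES = ("fixation_time_distribution", "sfs")

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class AveragedOutcomeDistribution:
    """A binned outcome averaged across replicates and normalized to sum 1."""

    bin_values: np.ndarray    # per-bin replicate-averaged values
    probabilities: np.ndarray
    n_replicates: int

    @classmethod
    def from_stack(cls, stack: np.ndarray,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "AveragedOutcomeDistribution":
        """Average a (replicates x bins) stack and normalize.

        ``pseudocount`` is added to every bin of the averaged histogram
        before normalization so that the KL divergence stays finite when one
        side has an empty bin; 0 disables regularization.
        """
        stack = np.asarray(stack, dtype=np.float64)
        means = stack.mean(axis=0)
        reg = means + pseudocount
        total = reg.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero distribution without pseudocount")
        return cls(bin_values=means, probabilities=reg / total, n_replicates=stack.shape[0])


def mean_percent_error(mean_unscaled: float, mean_scaled: float) -> float:
    """Directional percent error 100*(unscaled - scaled)/unscaled.

    Positive when the scaled mean falls below the unscaled mean.  Undefined
    (NaN) when the unscaled mean is 0.
    """
    if mean_unscaled == 0 or not np.isfinite(mean_unscaled) or not np.isfinite(mean_scaled):
        return float("nan")
    return 100.0 * (mean_unscaled - mean_scaled) / mean_unscaled


def percent_change(mean_unscaled: float, mean_scaled: float) -> float:
    """Signed percent change of the scaled mean relative to the unscaled
    baseline: 100*(scaled - unscaled)/unscaled, positive when rescaling
    raises the mean.  The negation of :func:`mean_percent_error`; this is
    the orientation used in the summary tables."""
    return -mean_percent_error(mean_unscaled, mean_scaled)


def kl_divergence(unscaled: AveragedOutcomeDistribution,
                  scaled: AveragedOutcomeDistribution) -> float:
    """D_KL(unscaled || scaled) = sum p_u * ln(p_u / p_s), in nats."""
    p = unscaled.probabilities
    q = scaled.probabilities
    if p.shape != q.shape:
        raise ValueError(f"mismatched bin counts: {p.shape} vs {q.shape}")
    mask = p > 0
    if np.any(q[mask] == 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def ld_rmse(unscaled_profile: np.ndarray, scaled_profile: np.ndarray) -> float:
    """RMSE between two replicate-averaged LD profiles over the 50 distance
    bins.  Bins empty (NaN) on either side are excluded from both the sum
    and the denominator; with all 50 bins populated this is the plain
    sqrt(sum((r2_s - r2_u)^2) / 50)."""
    u = np.asarray(unscaled_profile, dtype=np.float64)
    s = np.asarray(scaled_profile, dtype=np.float64)
    if u.shape != s.shape:
        raise ValueError(f"mismatched LD bin counts: {u.shape} vs {s.shape}")
    good = np.isfinite(u) & np.isfinite(s)
    if not good.any():
        return float("nan")
    return float(np.sqrt(np.mean((s[good] - u[good]) ** 2)))


# ---------------------------------------------------------------------------
# Stacking replicate summaries for vectorized resampling
# ---------------------------------------------------------------------------

class _SummaryStack:
    """Dense per-outcome arrays over a replicate set (for fast resampling)."""

    def __init__(self, summaries: Sequence[ReplicateSummary]):
        if not summaries:
            raise ValueError("need at least one replicate summary")
        self.n = len(summaries)
        self.classes = summaries[0].classes
        self.scalars = {}  # (outcome, class) -> (n,) array
        for outcome, attr in SCALAR_OUTCOMES.items():
            for cls_name in self.classes:
                vals = np.array([getattr(s, attr)[cls_name] for s in summaries], dtype=np.float64)
                self.scalars[(outcome, cls_name)] = vals
        self.mean_r2 = np.array([s.mean_r2 for s in summaries], dtype=np.float64)
        self.hist = {c: np.stack([s.fixation_hist[c] for s in summaries]).astype(np.float64)
                     for c in self.classes}
        self.sfs = {c: np.stack([s.sfs[c] for s in summaries]).astype(np.float64)
                    for c in self.classes}
        self.ld = np.stack([s.ld_bin_means for s in summaries]).astype(np.float64)

    def scalar_mean(self, outcome, cls_name, idx) -> float:
        vals = self.scalars[(outcome, cls_name)][idx]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if len(vals) else float("nan")

    def r2_mean(self, idx) -> float:
        vals = self.mean_r2[idx]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if len(vals) else float("nan")

    def ld_profile(self, idx) -> np.ndarray:
        sub = self.ld[idx]
        counts = np.isfinite(sub).sum(axis=0)
        sums = np.nansum(sub, axis=0)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


@dataclass
class DeviationReport:
    """Bootstrap mean and SD of each deviation measure for one scaled-vs-
    unscaled comparison (one Q)."""

    label: str
    Q: float
    baseline_Q: float
    B: int
    pseudocount: float
    mpe_orientation: str  # "percent_change" (tables) or "mean_percent_error"
    rows: pd.DataFrame = field(repr=False)
    # columns: outcome, mclass, measure, mean, sd, n_defined

    def value(self, outcome: str, mclass: str, measure: str = "mpe") -> tuple[float, float]:
        sel = self.rows[(self.rows.outcome == outcome)
                        & (self.rows.mclass == mclass)
                        & (self.rows.measure == measure)]
        if len(sel) != 1:
            raise KeyError(f"no unique row for ({outcome}, {mclass}, {measure})")
        return float(sel["mean"].iloc[0]), float(sel["sd"].iloc[0])


def _one_pass(unscaled: _SummaryStack, scaled: _SummaryStack,
              idx_u: np.ndarray, idx_s: np.ndarray,
              pseudocount: float, orientation: str) -> dict:
    sign = 1.0 if orientation == "mean_percent_error" else -1.0
    out = {}
    for outcome in SCALAR_OUTCOMES:
        for cls_name in unscaled.classes:
            mu = unscaled.scalar_mean(outcome, cls_name, idx_u)
            ms = scaled.scalar_mean(outcome, cls_name, idx_s)
            out[(outcome, cls_name, "mpe")] = sign * mean_percent_error(mu, ms)
    mu = unscaled.r2_mean(idx_u)
    ms = scaled.r2_mean(idx_s)
    out[("ld", "all", "mpe")] = sign * mean_percent_error(mu, ms)
    for cls_name in unscaled.classes:
        du = AveragedOutcomeDistribution.from_stack(unscaled.hist[cls_name][idx_u], pseudocount)
        ds = AveragedOutcomeDistribution.from_stack(scaled.hist[cls_name][idx_s], pseudocount)
        out[("fixation_time_distribution", cls_name, "kld")] = kl_divergence(du, ds)
        du = AveragedOutcomeDistribution.from_stack(unscaled.sfs[cls_name][idx_u], pseudocount)
        ds = AveragedOutcomeDistribution.from_stack(scaled.sfs[cls_name][idx_s], pseudocount)
        out[("sfs", cls_name, "kld")] = kl_divergence(du, ds)
    out[("ld", "all", "rmse")] = ld_rmse(unscaled.ld_profile(idx_u), scaled.ld_profile(idx_s))
    return out


def bootstrap_deviation(unscaled: Sequence[ReplicateSummary],
                        scaled: Sequence[ReplicateSummary],
                        B: int = 1000,
                        seed=None,
                        pseudocount: float = DEFAULT_PSEUDOCOUNT,
                        mpe_orientation: str = "percent_change") -> DeviationReport:
    """Bootstrap the deviation measures between two replicate sets.

    Each of the ``B`` resamples redraws both sets with replacement at their
    original sizes and recomputes MPE, KL divergence, and LD RMSE end-to-end
    (re-averaging the binned distributions per resample).  Reported are the
    mean and SD over resamples; measures undefined in every resample stay
    NaN.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if mpe_orientation not in ("percent_change", "mean_percent_error"):
        raise ValueError("mpe_orientation must be 'percent_change' or 'mean_percent_error'")
    su = _SummaryStack(list(unscaled))
    ss = _SummaryStack(list(scaled))
    if su.classes != ss.classes:
        raise ValueError(f"class sets differ: {su.classes} vs {ss.classes}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    samples: dict = {}
    for _ in range(B):
        idx_u = rng.integers(0, su.n, size=su.n)
        idx_s = rng.integers(0, ss.n, size=ss.n)
        vals = _one_pass(su, ss, idx_u, idx_s, pseudocount, mpe_orientation)
        for key, v in vals.items():
            samples.setdefault(key, []).append(v)

    rows = []
    for (outcome, cls_name, measure), vals in samples.items():
        arr = np.asarray(vals, dtype=np.float64)
        finite = arr[np.isfinite(arr)]
        rows.append({
            "outcome": outcome, "mclass": cls_name, "measure": measure,
            "mean": float(finite.mean()) if len(finite) else float("nan"),
            "sd": float(finite.std(ddof=0)) if len(finite) else float("nan"),
            "n_defined": int(len(finite)),
        })
    first_u = list(unscaled)[0]
    first_s = list(scaled)[0]
    return DeviationReport(label=first_s.label, Q=first_s.Q, baseline_Q=first_u.Q,
                           B=B, pseudocount=pseudocount, mpe_orientation=mpe_orientation,
                           rows=pd.DataFrame(rows))


def point_deviation(unscaled: Sequence[ReplicateSummary],
                    scaled: Sequence[ReplicateSummary],
                    pseudocount: float = DEFAULT_PSEUDOCOUNT,
                    mpe_orientation: str = "percent_change") -> dict:
    """Single-pass (no resampling) deviation measures on the full sets."""
    su = _SummaryStack(list(unscaled))
    ss = _SummaryStack(list(scaled))
    return _one_pass(su, ss, np.arange(su.n), np.arange(ss.n), pseudocount, mpe_orientation)


def subsample_stability(unscaled: Sequence[ReplicateSummary],
                        scaled: Sequence[ReplicateSummary],
                        sizes: Sequence[int] = (100, 10),
                        repeats: int = 1000,
                        seed=None,
                        pseudocount: float = DEFAULT_PSEUDOCOUNT,
                        mpe_orientation: str = "percent_change") -> pd.DataFrame:
    """Distribution of each deviation measure when only ``size`` replicates
    per side are available.

    For each repeat, ``size`` replicates are drawn per side without
    replacement and all deviation measures recomputed.  Returns a tidy frame
    with mean, SD and quantiles of each measure per size.
    """
    su = _SummaryStack(list(unscaled))
    ss = _SummaryStack(list(scaled))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for size in sizes:
        if size > su.n or size > ss.n:
            raise ValueError(f"requested subsample size {size} exceeds available replicates")
        samples: dict = {}
        for _ in range(repeats):
            idx_u = rng.choice(su.n, size=size, replace=False)
            idx_s = rng.choice(ss.n, size=size, replace=False)
            for key, v in _one_pass(su, ss, idx_u, idx_s, pseudocount, mpe_orientation).items():
                samples.setdefault(key, []).append(v)
        for (outcome, cls_name, measure), vals in samples.items():
            arr = np.asarray(vals, dtype=np.float64)
            finite = arr[np.isfinite(arr)]
            rec = {"size": size, "outcome": outcome, "mclass": cls_name, "measure": measure,
                   "mean": float(finite.mean()) if len(finite) else float("nan"),
                   "sd": float(finite.std(ddof=0)) if len(finite) else float("nan"),
                   "n_defined": int(len(finite))}
            for q in (0.025, 0.5, 0.975):
                rec[f"q{q}"] = float(np.quantile(finite, q)) if len(finite) else float("nan")
            records.append(rec)
    return pd.DataFrame(records)
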
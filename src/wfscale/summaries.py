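"""Per-replicate outcome statistics.

Four summaries are computed from each replicate, with the Q-corrections that
make scaled and unscaled runs directly comparable:

* the unfolded site frequency spectrum (SFS) per mutation class, from a
  sample of n individuals (2n-1 entries; 199 for n=100);
* linkage disequilibrium (r^2 between pairs of segregating mutations, all
  classes pooled) averaged within 50 equal genomic-distance bins;
* the fraction of post-burn-in mutations of each class that fixed, divided
  by Q (recovering the unscaled 1/2N scale for neutral mutations);
* histograms of fixation times (already multiplied by Q) on a common bin
  width chosen from a reference unscaled replicate (20 bins + overflow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .engine import MCLASS_NAMES, MCLASS_CODES, ReplicateResult, SampleHaplotypes

__all__ = [
    "SiteFrequencySpectrum",
    "LDProfile",
    "FixationTimeHistogram",
    "FixedFractionEstimate",
    "ReplicateSummary",
    "compute_sfs",
    "compute_r2",
    "compute_ld_profile",
    "fraction_fixed",
    "reference_bin_width",
    "fixation_time_histogram",
    "summarize_replicate",
    "N_LD_BINS",
    "N_TIME_BINS",
    "LD_SUBSAMPLE_CAP",
]

N_LD_BINS = 50
N_TIME_BINS = 20
LD_SUBSAMPLE_CAP = 5000


@dataclass
class SiteFrequencySpectrum:
    mclass: str
    counts: np.ndarray  # length 2n-1; entry k-1 = mutations at derived count k

    @property
    def n_segregating(self) -> int:
        return int(self.counts.sum())


@dataclass
class LDProfile:
    bin_means: np.ndarray   # length 50; NaN where no pairs fell in a bin
    bin_width: float        # L / 50, in bp
    pair_counts: np.ndarray  # pairs per bin

    @property
    def weighted_mean_r2(self) -> float:
        """Mean r^2 over all bins weighted by pair count (NaN if no pairs)."""
        total = self.pair_counts.sum()
        if total == 0:
            return float("nan")
        good = self.pair_counts > 0
        return float((self.bin_means[good] * self.pair_counts[good]).sum() / total)


@dataclass
class FixationTimeHistogram:
    mclass: str
    bin_width: float        # unscaled generations
    counts: np.ndarray      # length N_TIME_BINS + 1; last entry = overflow


@dataclass
class FixedFractionEstimate:
    mclass: str
    corrected_fraction: float  # (#fixed / #arisen) / Q; NaN when undefined
    n_arisen: int
    n_fixed: int

    @property
    def defined(self) -> bool:
        return self.n_arisen > 0


def compute_sfs(sample: SampleHaplotypes, mclass: str) -> SiteFrequencySpectrum:
    """Unfolded SFS of one mutation class over derived-allele counts 1..2n-1.

    Mutations absent from the sample or carried by every sampled haplotype
    contribute nothing.
    """
    two_n = sample.matrix.shape[0]
    counts = np.zeros(two_n - 1, dtype=np.int64)
    code = MCLASS_CODES[mclass]
    cols = sample.mclass == code
    if cols.any():
        dac = sample.matrix[:, cols].sum(axis=0)
        seg = (dac > 0) & (dac < two_n)
        np.add.at(counts, dac[seg].astype(np.int64) - 1, 1)
    return SiteFrequencySpectrum(mclass=mclass, counts=counts)


def compute_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Haplotypic r^2 = D^2 / (pA(1-pA) pB(1-pB)), D = pAB - pA*pB.

    Both columns must be segregating; a monomorphic column is a caller error
    (such pairs are excluded upstream, not scored 0).
    """
    a = np.asarray(col_a, dtype=np.float64)
    b = np.asarray(col_b, dtype=np.float64)
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("r2 is undefined for a monomorphic column; exclude the pair")
    d = (a * b).mean() - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def _pairwise_r2_and_dist(matrix: np.ndarray, positions: np.ndarray):
    """r^2 and |distance| for all pairs of columns (vectorized)."""
    x = matrix.astype(np.float64)
    n, m = x.shape
    p = x.mean(axis=0)
    cov = x.T @ x / n - np.outer(p, p)
    var = p * (1 - p)
    denom = np.outer(var, var)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = cov * cov / denom
    iu, ju = np.triu_indices(m, k=1)
    dist = np.abs(positions[iu] - positions[ju])
    return r2[iu, ju], dist


def compute_ld_profile(sample: SampleHaplotypes,
                       rng: Optional[np.random.Generator] = None) -> LDProfile:
    """Binned mean r^2 over all pairs of sample-segregating mutations.

    All mutation classes are pooled.  If more than 5000 mutations segregate
    in the sample, 5000 are subsampled at random before pairing.  Pairs are
    assigned to bin floor(distance / (L/50)).
    """
    two_n = sample.matrix.shape[0]
    dac = sample.matrix.sum(axis=0)
    seg = (dac > 0) & (dac < two_n)
    matrix = sample.matrix[:, seg]
    positions = sample.positions[seg].astype(np.float64)
    m = matrix.shape[1]
    if m > LD_SUBSAMPLE_CAP:
        if rng is None:
            rng = np.random.default_rng()
        keep = rng.choice(m, size=LD_SUBSAMPLE_CAP, replace=False)
        matrix = matrix[:, keep]
        positions = positions[keep]
        m = LD_SUBSAMPLE_CAP

    bin_width = sample.L / N_LD_BINS
    sums = np.zeros(N_LD_BINS)
    counts = np.zeros(N_LD_BINS, dtype=np.int64)
    if m >= 2:
        r2, dist = _pairwise_r2_and_dist(matrix, positions)
        bins = np.minimum((dist // bin_width).astype(np.int64), N_LD_BINS - 1)
        np.add.at(sums, bins, r2)
        np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDProfile(bin_means=means, bin_width=bin_width, pair_counts=counts)


def fraction_fixed(result: ReplicateResult) -> dict[str, FixedFractionEstimate]:
    """Per-class Q-corrected fixed fraction: (#fixed / #arisen, post-burn-in) / Q.

    The denominator counts every post-burn-in mutation of the class
    regardless of fate.  Classes with no arisen mutations are flagged
    undefined (NaN), never coerced to 0.
    """
    out = {}
    for code, name in enumerate(MCLASS_NAMES):
        n_arisen = int(result.arisen[code])
        n_fixed = int(result.fixed[code])
        if n_arisen == 0:
            frac = float("nan")
        else:
            frac = (n_fixed / n_arisen) / result.Q
        out[name] = FixedFractionEstimate(mclass=name, corrected_fraction=frac,
                                          n_arisen=n_arisen, n_fixed=n_fixed)
    return out


def reference_bin_width(reference: ReplicateResult, mclass: str) -> float:
    """Fixation-time bin width from a reference replicate: max corrected
    fixation time of the class divided by 20.  Propagate this width to every
    replicate and Q of the experiment so bins map to the same time ranges."""
    times = reference.fixation_times_for(mclass)
    if len(times) == 0:
        raise ValueError(
            f"reference replicate has no {mclass} fixations; choose another reference")
    return float(times.max()) / N_TIME_BINS


def fixation_time_histogram(result: ReplicateResult, mclass: str,
                            bin_width: float) -> FixationTimeHistogram:
    """Histogram of Q-corrected fixation times on half-open bins
    [k*w, (k+1)*w); times at or beyond 20*w land in the overflow bin."""
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    times = result.fixation_times_for(mclass)
    counts = np.zeros(N_TIME_BINS + 1, dtype=np.int64)
    if len(times):
        bins = np.minimum((times // bin_width).astype(np.int64), N_TIME_BINS)
        np.add.at(counts, bins, 1)
    return FixationTimeHistogram(mclass=mclass, bin_width=float(bin_width), counts=counts)


@dataclass
class ReplicateSummary:
    """All four outcome statistics (plus the scalar per-replicate means used
    by the percent-error measures) for one replicate."""

    label: str
    Q: float
    seed: int
    n_sample: int
    L: int
    classes: tuple
    sfs: dict                  # class -> np.ndarray
    ld_bin_means: np.ndarray
    ld_pair_counts: np.ndarray
    fixed_fraction: dict       # class -> float (NaN when undefined)
    fixation_hist: dict        # class -> np.ndarray (21 entries)
    time_bin_width: dict       # class -> float
    mean_fixation_time: dict   # class -> float (corrected; NaN if no fixations)
    mean_allele_frequency: dict  # class -> float (sample frequency; NaN if none segregating)
    mean_r2: float

    def to_json_dict(self) -> dict:
        d = asdict(self)
        for key in ("sfs", "fixation_hist"):
            d[key] = {k: np.asarray(v).tolist() for k, v in d[key].items()}
        d["ld_bin_means"] = np.asarray(self.ld_bin_means).tolist()
        d["ld_pair_counts"] = np.asarray(self.ld_pair_counts).tolist()
        d["classes"] = list(self.classes)
        return d

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)

    @classmethod
    def from_json_dict(cls, d: dict) -> "ReplicateSummary":
        d = dict(d)
        d["classes"] = tuple(d["classes"])
        d["sfs"] = {k: np.asarray(v, dtype=np.int64) for k, v in d["sfs"].items()}
        d["fixation_hist"] = {k: np.asarray(v, dtype=np.int64)
                              for k, v in d["fixation_hist"].items()}
        d["ld_bin_means"] = np.asarray(d["ld_bin_means"], dtype=np.float64)
        d["ld_pair_counts"] = np.asarray(d["ld_pair_counts"], dtype=np.int64)
        return cls(**d)

    @classmethod
    def load_json(cls, path) -> "ReplicateSummary":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def _classes_of(result: ReplicateResult) -> tuple:
    present = list(result.model.mix.classes_present)
    if result.model.sweep.enabled:
        present.append("sweep")
    return tuple(present)


def summarize_replicate(result: ReplicateResult,
                        time_bin_width: dict,
                        rng: Optional[np.random.Generator] = None) -> ReplicateSummary:
    """Compute the four outcome statistics for one replicate.

    ``time_bin_width`` maps class name -> bin width (from
    :func:`reference_bin_width` on a baseline replicate); classes without an
    entry get an all-zero histogram with width NaN.
    """
    classes = _classes_of(result)
    sample = result.sample
    two_n = sample.matrix.shape[0]
    dac = sample.matrix.sum(axis=0)

    sfs = {}
    mean_freq = {}
    for name in classes:
        sfs[name] = compute_sfs(sample, name).counts
        code = MCLASS_CODES[name]
        seg = (sample.mclass == code) & (dac > 0) & (dac < two_n)
        mean_freq[name] = float(dac[seg].mean() / two_n) if seg.any() else float("nan")

    ld = compute_ld_profile(sample, rng=rng)
    frac = fraction_fixed(result)

    hists = {}
    widths = {}
    mean_time = {}
    for name in classes:
        times = result.fixation_times_for(name)
        mean_time[name] = float(times.mean()) if len(times) else float("nan")
        w = time_bin_width.get(name)
        if w is not None and w > 0:
            hists[name] = fixation_time_histogram(result, name, w).counts
            widths[name] = float(w)
        else:
            hists[name] = np.zeros(N_TIME_BINS + 1, dtype=np.int64)
            widths[name] = float("nan")

    return ReplicateSummary(
        label=result.model.label, Q=result.Q, seed=result.seed,
        n_sample=sample.n_individuals, L=sample.L, classes=classes,
        sfs=sfs, ld_bin_means=ld.bin_means, ld_pair_counts=ld.pair_counts,
        fixed_fraction={name: frac[name].corrected_fraction for name in classes},
        fixation_hist=hists, time_bin_width=widths,
        mean_fixation_time=mean_time, mean_allele_frequency=mean_freq,
        mean_r2=ld.weighted_mean_r2)
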
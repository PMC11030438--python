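"""Synthetic single-class replicate summaries with controllable means."""

import numpy as np

from wfscale.summaries import N_LD_BINS, N_TIME_BINS, ReplicateSummary


def make_summary(seed=0, Q=1.0, mean_time=100.0, mean_freq=0.1, frac=1e-4,
                 mean_r2=0.2, hist=None, sfs=None, ld=None, noise=0.0,
                 rng=None) -> ReplicateSummary:
    if rng is not None and noise > 0:
        def jitter(x):
            return x * (1 + noise * rng.standard_normal())
    else:
        def jitter(x):
            return x
    hist = np.asarray(hist if hist is not None else [5] * (N_TIME_BINS + 1), dtype=np.int64)
    sfs = np.asarray(sfs if sfs is not None else [3, 2, 1] + [0] * 16, dtype=np.int64)
    ld = np.asarray(ld if ld is not None else np.full(N_LD_BINS, 0.2))
    return ReplicateSummary(
        label="synthetic", Q=Q, seed=seed, n_sample=10, L=10_000,
        classes=("neutral",), sfs={"neutral": sfs},
        ld_bin_means=ld, ld_pair_counts=np.full(N_LD_BINS, 10, dtype=np.int64),
        fixed_fraction={"neutral": jitter(frac)},
        fixation_hist={"neutral": hist}, time_bin_width={"neutral": 10.0},
        mean_fixation_time={"neutral": jitter(mean_time)},
        mean_allele_frequency={"neutral": jitter(mean_freq)},
        mean_r2=jitter(mean_r2))
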
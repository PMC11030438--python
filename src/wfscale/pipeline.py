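"""End-to-end experiments: simulate -> summarize -> deviation -> discriminate.

An experiment simulates ``replicates`` runs of one model at each scaling
factor in ``Q_list``, summarizes every replicate, compares each Q against
the baseline Q (per-outcome deviation with bootstrap uncertainty), and
optionally trains scaled-vs-unscaled classifiers per feature set.  All
randomness derives from a single root seed; every replicate gets its own
counter-derived stream, so results are independent of execution order and a
re-run with the same config reproduces all outputs byte-for-byte.
Replicate summaries are stored as one JSON per replicate and reloaded on
resume instead of re-simulating.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import deviation as dev
from . import discriminate as disc
from .engine import FitnessError, run_replicate
from .models import ModelSpec, build_catalog_model, rescale_model
from .summaries import ReplicateSummary, reference_bin_width, summarize_replicate

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "compare_runs"]

logger = logging.getLogger("wfscale")


@dataclass
class ExperimentConfig:
    """Everything needed to run one experiment.

    ``model`` is a catalog name or an inline (unscaled) :class:`ModelSpec`;
    ``baseline_Q`` defaults to the smallest entry of ``Q_list`` (1 for
    models whose unscaled form is feasible; larger for models where the
    baseline itself must be scaled).
    """

    model: Union[str, ModelSpec]
    Q_list: Sequence[float] = (1, 2, 5, 10, 20)
    replicates: int = 1000
    seed: int = 0
    L: Optional[int] = None
    baseline_Q: Optional[float] = None
    bootstrap_B: int = 1000
    subsample_sizes: Sequence[int] = ()
    subsample_repeats: int = 1000
    classifiers: Sequence[str] = disc.CLASSIFIERS
    feature_sets: Sequence[str] = disc.FEATURE_SETS
    sample_n: int = 100
    mpe_orientation: str = "percent_change"
    output_dir: Optional[Union[str, Path]] = None

    def resolve_model(self) -> ModelSpec:
        if isinstance(self.model, ModelSpec):
            return self.model
        return build_catalog_model(self.model, L=self.L)

    def resolved_baseline(self) -> float:
        return float(min(self.Q_list) if self.baseline_Q is None else self.baseline_Q)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.Q_list:
            raise ValueError("Q_list must not be empty")
        if self.resolved_baseline() not in [float(q) for q in self.Q_list]:
            raise ValueError("Q_list must include the baseline Q")

    @classmethod
    def from_json_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("model"), dict):
            d["model"] = ModelSpec.from_dict(d["model"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))

    def to_json_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "Q_list", "replicates", "seed", "L", "baseline_Q", "bootstrap_B",
            "subsample_sizes", "subsample_repeats", "classifiers", "feature_sets",
            "sample_n", "mpe_orientation")}
        d["Q_list"] = list(self.Q_list)
        d["subsample_sizes"] = list(self.subsample_sizes)
        d["classifiers"] = list(self.classifiers)
        d["feature_sets"] = list(self.feature_sets)
        d["model"] = self.model if isinstance(self.model, str) else self.model.to_dict()
        return d


def _replicate_seed(root_seed: int, q_index: int, rep_index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(q_index, rep_index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _analysis_rng(root_seed: int, purpose: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(0xA0 + purpose,))
    return np.random.default_rng(ss)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    summaries: dict                     # Q -> list[ReplicateSummary]
    time_bin_width: dict                # class -> float
    deviation_reports: dict             # Q -> DeviationReport (non-baseline Q)
    discrimination: pd.DataFrame
    subsample: Optional[pd.DataFrame]
    failed_replicates: list = field(default_factory=list)  # (Q, seed, message)

    def deviation_table(self) -> pd.DataFrame:
        frames = []
        for q, rep in sorted(self.deviation_reports.items()):
            t = rep.rows.copy()
            t.insert(0, "Q", q)
            t.insert(0, "model", rep.label)
            t["B"] = rep.B
            frames.append(t)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)

    def summary_text_table(self) -> str:
        """Plain-text MPE table: one row per (class, outcome), one column per Q."""
        tab = self.deviation_table()
        if tab.empty:
            return "(no scaled-vs-baseline comparisons)"
        tab = tab[tab.measure == "mpe"]
        lines = [f"Mean percent error vs baseline (orientation: "
                 f"{self.config.mpe_orientation})"]
        qs = sorted(tab.Q.unique())
        header = f"{'class':<12} {'outcome':<22}" + "".join(f" Q={q:<8g}" for q in qs)
        lines.append(header)
        for (mclass, outcome), grp in tab.groupby(["mclass", "outcome"], sort=True):
            cells = []
            for q in qs:
                sel = grp[grp.Q == q]
                cells.append(f" {sel['mean'].iloc[0]:<9.3g}" if len(sel) else " " * 10)
            lines.append(f"{mclass:<12} {outcome:<22}" + "".join(cells))
        return "\n".join(lines)


def _simulate_set(model_scaled: ModelSpec, config: ExperimentConfig, q_index: int,
                  out_dir: Optional[Path], failed: list):
    """Run (or reload) all replicates at one Q; returns list of ReplicateResult
    or (on resume) preloaded ReplicateSummary."""
    results = []
    for i in range(config.replicates):
        seed = _replicate_seed(config.seed, q_index, i)
        cache = None
        if out_dir is not None:
            cache = out_dir / f"rep{i:05d}.json"
            if cache.exists():
                results.append(ReplicateSummary.load_json(cache))
                continue
        try:
            res = run_replicate(model_scaled, seed, sample_n=config.sample_n)
        except FitnessError as exc:
            logger.warning("replicate failed (Q=%s, seed=%d): %s",
                           model_scaled.Q_applied, seed, exc)
            failed.append((model_scaled.Q_applied, seed, str(exc)))
            continue
        results.append(res)
    return results


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full pipeline for one config; see module docstring."""
    base_model = config.resolve_model()
    baseline_Q = config.resolved_baseline()
    q_values = [float(q) for q in config.Q_list]
    out_root = Path(config.output_dir) if config.output_dir is not None else None
    if out_root is not None:
        out_root.mkdir(parents=True, exist_ok=True)

    failed: list = []
    t0 = time.time()

    # a common sample size across every Q keeps the SFS/LD feature lengths
    # comparable (the smallest scaled population bounds it)
    scaled_models = {q: (rescale_model(base_model, q) if q != 1 else base_model)
                     for q in q_values}
    n_common = min([config.sample_n]
                   + [min(m.demography.N_anc, m.demography.N_post)
                      for m in scaled_models.values()])
    if n_common < config.sample_n:
        logger.info("sample size reduced to %d (smallest scaled population)", n_common)
    config = _replace_sample_n(config, n_common)

    raw: dict = {}
    for j, q in enumerate(q_values):
        scaled = scaled_models[q]
        sum_dir = None
        if out_root is not None:
            sum_dir = out_root / "summaries" / f"Q{q:g}"
            sum_dir.mkdir(parents=True, exist_ok=True)
        logger.info("simulating %d replicates at Q=%g", config.replicates, q)
        raw[q] = _simulate_set(scaled, config, j, sum_dir, failed)
        logger.info("Q=%g done (%.1fs elapsed)", q, time.time() - t0)

    # fixation-time bin widths: first baseline replicate (by seed order) that
    # has fixations of the class; deterministic and recorded in the manifest
    widths: dict = {}
    width_source: dict = {}
    for i, item in enumerate(raw[baseline_Q]):
        if isinstance(item, ReplicateSummary):
            # resumed run: widths come from the stored summaries
            for c, w in item.time_bin_width.items():
                if c not in widths and np.isfinite(w):
                    widths[c] = w
                    width_source[c] = f"stored:Q{baseline_Q:g}/rep{i}"
            continue
        for c in _summary_classes(item):
            if c not in widths:
                try:
                    widths[c] = reference_bin_width(item, c)
                    width_source[c] = f"Q{baseline_Q:g}/rep{i}"
                except ValueError:
                    pass  # no fixations of this class in this replicate; try the next
    # classes with no baseline fixations at all keep all-zero histograms

    summaries: dict = {}
    for j, q in enumerate(q_values):
        items = []
        for i, item in enumerate(raw[q]):
            if isinstance(item, ReplicateSummary):
                items.append(item)
                continue
            rng = _analysis_rng(config.seed, 1 + j * config.replicates + i)
            s = summarize_replicate(item, widths, rng=rng)
            if out_root is not None:
                s.save_json(out_root / "summaries" / f"Q{q:g}" / f"rep{i:05d}.json")
            items.append(s)
        summaries[q] = items

    # deviation per non-baseline Q
    reports = {}
    for j, q in enumerate(q_values):
        if q == baseline_Q:
            continue
        reports[q] = dev.bootstrap_deviation(
            summaries[baseline_Q], summaries[q],
            B=config.bootstrap_B, seed=_analysis_rng(config.seed, 2_000 + j),
            mpe_orientation=config.mpe_orientation)

    # classifiers
    disc_rows = []
    for j, q in enumerate(q_values):
        if q == baseline_Q:
            continue
        for fi, fs in enumerate(config.feature_sets):
            fm_u = disc.build_features(summaries[baseline_Q], fs)
            fm_s = disc.build_features(summaries[q], fs)
            width = max(fm_u.rows.shape[1], fm_s.rows.shape[1])
            ru = _pad(fm_u.rows, width)
            rs = _pad(fm_s.rows, width)
            for ci, clf in enumerate(config.classifiers):
                seed = _replicate_seed(config.seed, 9_000 + j, 10 * fi + ci)
                rep = disc.train_and_score(ru, rs, clf, seed, feature_set=fs,
                                           Q=q, baseline_Q=baseline_Q)
                disc_rows.append({
                    "model": base_model.label, "Q": q, "feature_set": fs,
                    "classifier": clf, "accuracy": rep.test_accuracy,
                    "n_train": rep.n_train, "n_test": rep.n_test, "seed": rep.seed})
    disc_df = pd.DataFrame(disc_rows)

    sub_df = None
    if config.subsample_sizes:
        frames = []
        for j, q in enumerate(q_values):
            if q == baseline_Q:
                continue
            f = dev.subsample_stability(
                summaries[baseline_Q], summaries[q],
                sizes=config.subsample_sizes, repeats=config.subsample_repeats,
                seed=_analysis_rng(config.seed, 3_000 + j),
                mpe_orientation=config.mpe_orientation)
            f.insert(0, "Q", q)
            frames.append(f)
        sub_df = pd.concat(frames, ignore_index=True) if frames else None

    result = ExperimentResult(
        config=config, summaries=summaries, time_bin_width=widths,
        deviation_reports=reports, discrimination=disc_df, subsample=sub_df,
        failed_replicates=failed)

    if out_root is not None:
        _write_outputs(result, out_root, width_source, t0)
    if failed:
        logger.warning("%d replicate(s) failed and were excluded", len(failed))
    return result


def _replace_sample_n(config: ExperimentConfig, n: int) -> ExperimentConfig:
    if config.sample_n == n:
        return config
    import dataclasses
    return dataclasses.replace(config, sample_n=n)


def _summary_classes(result) -> tuple:
    present = list(result.model.mix.classes_present)
    if result.model.sweep.enabled:
        present.append("sweep")
    return tuple(present)


def _pad(rows: np.ndarray, width: int) -> np.ndarray:
    if rows.shape[1] == width:
        return rows
    out = np.zeros((rows.shape[0], width))
    out[:, :rows.shape[1]] = rows
    return out


def _write_outputs(result: ExperimentResult, out_root: Path, width_source: dict,
                   t0: float) -> None:
    config = result.config
    dev_table = result.deviation_table()
    dev_table.to_csv(out_root / "deviation.csv", index=False)
    with open(out_root / "deviation.json", "w") as fh:
        json.dump({
            "mpe_orientation": config.mpe_orientation,
            "bootstrap_B": config.bootstrap_B,
            "rows": dev_table.to_dict(orient="records"),
        }, fh, indent=2)
    result.discrimination.to_csv(out_root / "discrimination.csv", index=False)
    if result.subsample is not None:
        result.subsample.to_csv(out_root / "subsample_stability.csv", index=False)
    (out_root / "deviation_summary.txt").write_text(result.summary_text_table() + "\n")

    # aggregate per-replicate scalar table (one row per replicate)
    rows = []
    for q, items in sorted(result.summaries.items()):
        for s in items:
            row = {"Q": q, "seed": s.seed, "mean_r2": s.mean_r2}
            for c in s.classes:
                row[f"mean_fixation_time_{c}"] = s.mean_fixation_time[c]
                row[f"mean_allele_frequency_{c}"] = s.mean_allele_frequency[c]
                row[f"fixed_fraction_{c}"] = s.fixed_fraction[c]
            rows.append(row)
    pd.DataFrame(rows).to_csv(out_root / "replicate_scalars.tsv", sep="\t", index=False)

    cfg_json = json.dumps(config.to_json_dict(), sort_keys=True)
    manifest = {
        "config": config.to_json_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "software_version": _version(),
        "time_bin_width": {k: float(v) for k, v in result.time_bin_width.items()},
        "time_bin_width_source": width_source,
        "replicate_seeds": {
            f"Q{q:g}": [_replicate_seed(config.seed, j, i)
                        for i in range(config.replicates)]
            for j, q in enumerate(float(q) for q in config.Q_list)},
        "failed_replicates": [
            {"Q": q, "seed": s, "error": m} for q, s, m in result.failed_replicates],
        "files": sorted(str(p.relative_to(out_root))
                        for p in out_root.rglob("*") if p.is_file()),
        "wall_seconds": round(time.time() - t0, 1),
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _version() -> str:
    from . import __version__
    return __version__


def compare_runs(baseline_dir, scaled_dir, B: int = 1000, seed=None,
                 mpe_orientation: str = "percent_change"):
    """Deviation report across two separately executed runs.

    Both directories must contain ``summaries/Q*/rep*.json`` written by
    :func:`run_experiment` (or externally produced files in the same
    schema).  Binning (sample size, genome length, fixation-time bin
    widths) must agree.
    """
    def load(d):
        d = Path(d)
        files = sorted(d.glob("summaries/Q*/rep*.json"))
        if not files:
            files = sorted(d.glob("rep*.json"))
        if not files:
            raise ValueError(f"no replicate summaries under {d}")
        return [ReplicateSummary.load_json(f) for f in files]

    base = load(baseline_dir)
    scaled = load(scaled_dir)
    for attr in ("n_sample", "L"):
        a, b = getattr(base[0], attr), getattr(scaled[0], attr)
        if a != b:
            raise ValueError(
                f"binning mismatch: {attr} differs ({a} vs {b}); re-summarize both "
                f"runs with a common sample size and genome length")
    for c, w in base[0].time_bin_width.items():
        w2 = scaled[0].time_bin_width.get(c, float("nan"))
        if np.isfinite(w) and np.isfinite(w2) and abs(w - w2) > 1e-9:
            raise ValueError(
                f"binning mismatch: fixation-time bin width for class {c!r} differs "
                f"({w} vs {w2}); recompute the scaled run's histograms with the "
                f"baseline reference width")
    return dev.bootstrap_deviation(base, scaled, B=B, seed=seed,
                                   mpe_orientation=mpe_orientation)
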
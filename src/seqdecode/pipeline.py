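"""End-to-end orchestration: seeded runs, serialization, and reporting.

`run_pipeline` executes the full chain on synthetic data — schedule
generation, EEG simulation, artifact rejection, wavelet power, decoding of
the four control codes, cluster statistics, generalization, RSA, chaining,
and behavior — and writes a results bundle (HDF5 arrays with axis metadata,
delimited text tables, JSON statistics, and a manifest).  `report` turns a
bundle into frequency x time heat maps with significant-cluster outlines and
summary tables.

Every stochastic stage derives its stream from the single master seed, so a
run is reproducible from its config alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import apply_exclusions, structure_contrasts, within_subject_ci
from .cluster_stats import cluster_permutation
from .decode import DecodeConfig, decode_map, summarize_period
from .represent import build_model_matrix, chaining_asymmetry, chaining_test, cross_classify, fit_rsa
from .spectral import build_wavelet_bank, reject_artifacts, tf_power
from .synth_eeg import (ALPHA, PREP, PROBE, THETA, BehaviorParams, CodePatternSpec,
                        NoiseSpec, simulate_behavior, simulate_dataset)
from .task_model import ExperimentDesign, assign_probes, build_schedule, cowans_k, median_split_wm

logger = logging.getLogger(__name__)

CODES = ("element", "within_chunk_position", "chunk_identity", "chunk_position")

#: Band/window in which each control code is injected by default: content
#: codes (elements, chunk identity) ride on alpha, order codes on theta;
#: chunk identity is a preparation-period signal, chunk position peaks around
#: the probe.
DEFAULT_CODE_BANDS = {
    "element": {"band": ALPHA, "window": (-600.0, 300.0)},
    "within_chunk_position": {"band": THETA, "window": (-600.0, 300.0)},
    "chunk_identity": {"band": ALPHA, "window": (-600.0, 0.0)},
    "chunk_position": {"band": THETA, "window": (0.0, 300.0)},
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    out_dir: str
    variant: str = "exp1"
    n_subjects: int = 4
    n_blocks: int = 6
    codes: tuple = CODES
    amplitude: float = 6.0
    noise_sd: float = 10.0
    one_over_f_exponent: float = 1.0
    p_match: float = 0.5
    n_freqs: int = 8
    f_min: float = 4.0
    f_max: float = 35.0
    n_folds: int = 4
    n_iterations: int = 3
    window_step: int = 25
    n_permutations: int = 500
    behavior: dict = field(default_factory=dict)
    analysis_window: tuple = (-700.0, 400.0)
    pad_ms: float = 400.0

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("config must specify a seed")
        if self.n_subjects < 1 or self.n_blocks < 1:
            raise ConfigError("n_subjects and n_blocks must be positive")
        unknown = set(self.codes) - set(CODES)
        if unknown:
            raise ConfigError(f"unknown codes: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError("config must specify a seed")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _subject_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> preprocess -> decode -> stats stages; write bundle.

    Returns a dict of output paths.  The manifest records package version,
    per-stage seeds, trial counts before/after rejection, and runtimes.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = ExperimentDesign.from_variant(config.variant, n_blocks=config.n_blocks)
    seeds = _subject_seeds(config.seed, config.n_subjects)
    bank = build_wavelet_bank(config.f_min, config.f_max, config.n_freqs)
    beh_params = BehaviorParams(**config.behavior)

    subject_maps = {code: [] for code in config.codes}
    confusions_prep, confusions_probe = [], []
    gen_scores, chain_diffs = [], []
    behavior_tables = []
    wm_ks = []
    manifest_subjects = []
    freqs = times = None

    for s, seed_s in enumerate(seeds):
        # decoupled streams: schedule, probes, EEG noise, behavior, and fold
        # partitions each get their own offset of the subject seed
        rng = np.random.default_rng(seed_s)
        dec_cfg = DecodeConfig(
            n_folds=config.n_folds, n_iterations=config.n_iterations,
            window_step=config.window_step, seed=seed_s + 40031,
        )
        schedule = build_schedule(design, seed=seed_s, subject=s,
                                  allow_unbalanced=True)
        schedule = assign_probes(schedule, config.p_match, seed=seed_s + 10007)

        patterns = [
            CodePatternSpec(code=c, amplitude=config.amplitude,
                            **DEFAULT_CODE_BANDS[c])
            for c in config.codes
        ]
        eeg = simulate_dataset(
            schedule, patterns,
            NoiseSpec(one_over_f_exponent=config.one_over_f_exponent,
                      noise_sd=config.noise_sd),
            seed=seed_s + 20011, analysis_window=config.analysis_window,
            pad_ms=config.pad_ms,
        )
        rejection = reject_artifacts(eeg)
        keep = ~rejection["rejected"].to_numpy()

        beh = simulate_behavior(schedule, beh_params, seed=seed_s + 30013,
                                variant=config.variant)
        beh = apply_exclusions(beh, config.variant)
        behavior_tables.append(beh)
        usable = keep & ~beh["excluded"].to_numpy()

        eeg.data = eeg.data[usable]
        eeg.schedule = schedule.loc[usable].reset_index(drop=True)
        tf = tf_power(eeg, bank)
        freqs, times = tf.freqs, None

        labels_all = eeg.schedule
        for code in config.codes:
            res = decode_map(tf, labels_all[code].to_numpy(), dec_cfg)
            subject_maps[code].append(res.accuracy)
            times = res.times
            if code == "within_chunk_position":
                confusions_prep.append(res.mean_confusion(THETA, PREP))
                confusions_probe.append(res.mean_confusion(THETA, PROBE))

        if "within_chunk_position" in config.codes:
            gen = cross_classify(tf, labels_all["within_chunk_position"].to_numpy(),
                                 labels_all["element"].to_numpy(), dec_cfg,
                                 band=THETA, period=PREP)
            gen_scores.append(gen)
        chain_diffs.append(chaining_asymmetry(tf, labels_all, band=ALPHA, period=PREP))

        h = rng.uniform(0.6, 0.95)
        f = rng.uniform(0.05, 0.3)
        wm_ks.append(cowans_k(4, h, f))
        manifest_subjects.append({
            "subject": s, "seed": seed_s, "n_trials": int(len(schedule)),
            "n_rejected": int((~keep).sum()), "n_usable": int(usable.sum()),
        })
        logger.info("subject %d: %d/%d usable trials", s, usable.sum(), len(schedule))

    # -- persist arrays ------------------------------------------------------
    maps_path = out / "maps.h5"
    with h5py.File(maps_path, "w") as fh:
        fh.create_dataset("freqs", data=freqs)
        fh.create_dataset("times", data=times)
        for code in config.codes:
            fh.create_dataset(f"accuracy/{code}", data=np.stack(subject_maps[code]))

    behavior_path = out / "behavior.csv"
    pd.concat(behavior_tables, ignore_index=True).to_csv(behavior_path, index=False)

    # -- group statistics ----------------------------------------------------
    stats: dict = {"cluster": {}, "behavior": {}, "rsa": {}, "chance": 1 / 3}
    for code in config.codes:
        maps = np.stack(subject_maps[code])
        if maps.shape[0] >= 2:
            cres = cluster_permutation(maps, chance=1 / 3,
                                       n_permutations=config.n_permutations,
                                       seed=config.seed)
            stats["cluster"][code] = {
                "n_clusters": len(cres.clusters),
                "min_p": min((c.p_value for c in cres.clusters), default=None),
                "masks": [c.mask.tolist() for c in cres.clusters if c.p_value < 0.05],
            }

    if len(confusions_prep) >= 2:
        models = [build_model_matrix("discrete"), build_model_matrix("unique_position_1")]
        for period_name, confs in (("prep", confusions_prep), ("probe", confusions_probe)):
            fit = fit_rsa(np.stack(confs), models)
            stats["rsa"][period_name] = {"method": fit.method, **fit.coefficients}

    if gen_scores:
        stats["generalization"] = {
            "generalized": float(np.mean([g["generalized"] for g in gen_scores])),
            "reference": float(np.mean([g["reference"] for g in gen_scores])),
        }
    if len(chain_diffs) >= 2:
        chain = chaining_test(chain_diffs)
        stats["chaining"] = {"mean_diff": chain.mean_diff, "t": chain.t, "p": chain.p}

    all_beh = pd.concat(behavior_tables, ignore_index=True)
    if all_beh["subject"].nunique() >= 2:
        wm = dict(zip(range(config.n_subjects),
                      median_split_wm([k.K for k in wm_ks])))
        for c in structure_contrasts(all_beh, wm_groups=wm):
            stats["behavior"][f"{c.measure}:{c.contrast}"] = {
                "estimate": c.estimate, "se": c.se, "t": c.t, "F": c.F, "p": c.p,
            }

    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(stats, indent=2, default=float))

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "subjects": manifest_subjects,
        "runtime_s": time.time() - t_start,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    return {"maps": str(maps_path), "behavior": str(behavior_path),
            "stats": str(stats_path), "manifest": str(manifest_path)}


def report(results_dir) -> dict:
    """Summary figures and tables from a results bundle.

    Produces one frequency x time accuracy heat map per decoded code (with
    outlines around cluster-significant regions when present), a band/period
    summary table recomputed from the stored maps, and a behavior plot with
    within-subject CIs.  Missing stage outputs yield a partial report.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = Path(results_dir)
    outputs: dict = {"figures": [], "notices": []}
    maps_path = res / "maps.h5"
    stats = json.loads((res / "stats.json").read_text()) if (res / "stats.json").exists() else {}
    if not maps_path.exists():
        outputs["notices"].append("maps.h5 missing; no heat maps produced")
        return outputs

    rows = []
    with h5py.File(maps_path) as fh:
        freqs = fh["freqs"][()]
        times = fh["times"][()]
        for code in fh["accuracy"]:
            maps = fh[f"accuracy/{code}"][()]
            mean_map = maps.mean(axis=0)
            fig, ax = plt.subplots(figsize=(5, 3.2))
            im = ax.pcolormesh(times, freqs, mean_map, shading="nearest",
                               cmap="viridis")
            masks = stats.get("cluster", {}).get(code, {}).get("masks", [])
            for mask in masks:
                ax.contour(times, freqs, np.asarray(mask, dtype=float),
                           levels=[0.5], colors="white", linewidths=1.2)
            ax.set(xlabel="time (ms)", ylabel="frequency (Hz)",
                   title=f"{code} decoding accuracy")
            fig.colorbar(im, ax=ax, label="accuracy")
            fig.tight_layout()
            fig_path = res / f"map_{code}.png"
            fig.savefig(fig_path, dpi=110)
            plt.close(fig)
            outputs["figures"].append(str(fig_path))

            for band_name, band in (("theta", THETA), ("alpha", ALPHA)):
                for period_name, period in (("prep", PREP), ("probe", PROBE)):
                    try:
                        val = summarize_period(mean_map, freqs, times, band, period)
                    except ValueError:
                        continue
                    rows.append({"code": code, "band": band_name,
                                 "period": period_name, "accuracy": val})
    summary = pd.DataFrame(rows)
    summary_path = res / "summary.csv"
    summary.to_csv(summary_path, index=False)
    outputs["summary"] = str(summary_path)

    beh_path = res / "behavior.csv"
    if beh_path.exists():
        beh = pd.read_csv(beh_path)
        means = beh[~beh.get("excluded", False)].pivot_table(
            index="subject", columns="within_chunk_position", values="rt")
        ci = within_subject_ci(means)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.errorbar(means.columns, means.mean(), yerr=ci, marker="o")
        ax.set(xlabel="within-chunk position", ylabel="RT (ms)",
               xticks=list(means.columns))
        fig.tight_layout()
        fig_path = res / "behavior_rt.png"
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        outputs["figures"].append(str(fig_path))
    else:
        outputs["notices"].append("behavior.csv missing; behavior plot skipped")
    return outputs
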
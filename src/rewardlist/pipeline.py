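"""End-to-end orchestration: simulate -> analyze -> report.

``run_full_pipeline`` chains design generation, recall simulation, the
behavioral statistics and their permutation nulls, EEG simulation, amplitude
epoch rejection, the focal ssVEP spectrum, the global time-frequency +
cluster tests, and the notch-filtered ERP cluster tests, and writes a JSON
report (plus tidy TSVs and figures) with every p-value accompanied by its
n_perm and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .core_data import CONDITIONS, reject_epochs_amplitude
from .synthetic_data import (
    BehaviorSimParams,
    EEGSimParams,
    generate_design,
    simulate_eeg,
    simulate_recall,
)
from .recall_dynamics import (
    organization_score,
    prob_first_recall_high,
    recall_proportion,
)
from .permutation_inference import (
    compare_observed_to_null,
    interaction_signflip_test,
    permute_output_orders,
    rm_anova_oneway,
)
from .eeg_spectral import (
    baseline_subtract,
    bandstop_fir,
    db_baseline,
    erp_average,
    extract_ssvep,
    find_ssvep_peak,
    psd_hanning,
    tfr_hanning,
)
from .cluster_permutation import (
    build_neighbor_graph,
    cluster_test,
    interaction_contrast,
)

__all__ = ["RunConfig", "run_full_pipeline"]

logger = logging.getLogger("rewardlist")


@dataclass
class RunConfig:
    """Configuration of a full simulated study run."""

    out_dir: str = "rewardlist_run"
    seed_behavior: int = 101
    seed_eeg: int = 202
    seed_perm: int = 303
    behavior: BehaviorSimParams = field(default_factory=BehaviorSimParams)
    eeg: EEGSimParams = field(default_factory=EEGSimParams)
    n_eeg_subjects: int = 20
    n_perm_recall: int = 10_000
    n_perm_interaction: int = 10_000
    n_perm_cluster: int = 1000
    ssvep_band_hz: tuple[float, float] = (14.0, 15.0)
    ssvep_window_ms: tuple[float, float] = (1000.0, 2000.0)
    analysis_window_ms: tuple[float, float] = (0.0, 2000.0)
    tfr_baseline_ms: tuple[float, float] = (-700.0, -200.0)
    erp_stopbands: tuple = ((14.0, 15.0), (28.0, 29.0))
    reject_threshold_uv: float = 100.0
    make_figures: bool = True

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = dict(raw)
        if "behavior" in kwargs:
            kwargs["behavior"] = BehaviorSimParams(**kwargs["behavior"])
        if "eeg" in kwargs:
            eeg = dict(kwargs["eeg"])
            for key in ("ssvep_amp", "erp_amp"):
                if key in eeg:
                    eeg[key] = dict(eeg[key])
            kwargs["eeg"] = EEGSimParams(**eeg)
        for key in (
            "ssvep_band_hz",
            "ssvep_window_ms",
            "analysis_window_ms",
            "tfr_baseline_ms",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "erp_stopbands" in kwargs:
            kwargs["erp_stopbands"] = tuple(tuple(b) for b in kwargs["erp_stopbands"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _wilcoxon_dict(res, n_perm, seed):
    return {
        "V": res.V,
        "n": res.n_used,
        "p": res.p_two_sided,
        "method": res.method,
        "n_perm": n_perm,
        "seed": seed,
    }


def _cluster_dict(res, times_ms=None):
    def extent(c):
        lo, hi = c.time_extent
        if times_ms is None:
            return [lo, hi]
        return [float(times_ms[lo]), float(times_ms[hi])]

    return {
        "n_perm": res.n_perm,
        "seed": res.seed,
        "alpha_cluster": res.alpha_cluster,
        "clusters": [
            {
                "sign": c.sign,
                "mass": c.mass,
                "n_samples": len(c.members),
                "n_channels": len(c.channels),
                "time_extent_ms": extent(c),
                "p": c.p,
            }
            for c in sorted(res.clusters, key=lambda c: c.p or 1.0)
        ],
        "n_significant": len(res.significant()),
    }


def _stage(name, t_start):
    elapsed = time.perf_counter() - t_start
    logger.info("stage=%s elapsed=%.1fs", name, elapsed)
    return time.perf_counter()


def _condition_features(tfr_band, subjects, n_ch, times_mask):
    """Stack a band-averaged TFR dict into condition -> (subjects, ch, T)."""
    feats = {}
    for cond in CONDITIONS:
        feats[cond] = np.stack(
            [tfr_band[(s, cond)][:, times_mask] for s in subjects]
        )
    return feats


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the full simulated study; returns the report dictionary."""
    os.makedirs(config.out_dir, exist_ok=True)
    t0 = time.perf_counter()
    report: dict = {
        "software": {"package": "rewardlist", "version": __version__},
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }

    # ---------------- behavior ----------------
    behavior = dataclasses.replace(config.behavior, seed=config.seed_behavior)
    designs = generate_design(behavior.n_subjects, config.seed_behavior)
    log = simulate_recall(designs, behavior)
    t0 = _stage("simulate_behavior", t0)

    props = recall_proportion(log)
    inter = interaction_signflip_test(
        props, n_perm=config.n_perm_interaction, seed=config.seed_perm
    )
    pfr_obs = prob_first_recall_high(log)
    pfr_null = permute_output_orders(
        log, "pfr_high", n_perm=config.n_perm_recall, seed=config.seed_perm + 1
    )
    pfr_test = compare_observed_to_null(pfr_obs, pfr_null)
    clus_obs = organization_score(log, "reward", "mixed")["value"]
    clus_null = permute_output_orders(
        log, "reward_clustering", n_perm=config.n_perm_recall, seed=config.seed_perm + 2
    )
    clus_test = compare_observed_to_null(clus_obs, clus_null)
    temporal = pd.DataFrame(
        {
            lt: organization_score(log, "temporal", lt)["value"]
            for lt in ("mixed", "pure_high", "pure_low")
        }
    ).dropna()
    anova = rm_anova_oneway(temporal.to_numpy())
    t0 = _stage("recall_statistics", t0)

    mean_props = props.mean()
    report["behavior"] = {
        "n_subjects": behavior.n_subjects,
        "recall_proportion_mean": {c: float(mean_props[c]) for c in CONDITIONS},
        "interaction_signflip": {
            "statistic": inter.statistic,
            "p": inter.p,
            "n_perm": inter.n_perm,
            "seed": inter.seed,
        },
        "pfr_high": {
            "observed_mean": float(pfr_obs.mean()),
            "permuted_mean": pfr_null.group_mean,
            "wilcoxon": _wilcoxon_dict(pfr_test, config.n_perm_recall, pfr_null.seed),
        },
        "reward_clustering": {
            "observed_mean": float(clus_obs.mean()),
            "permuted_mean": clus_null.group_mean,
            "wilcoxon": _wilcoxon_dict(clus_test, config.n_perm_recall, clus_null.seed),
        },
        "temporal_organization": {
            "means": {lt: float(temporal[lt].mean()) for lt in temporal.columns},
            "rm_anova": {
                "F": anova.F,
                "df1": anova.df1,
                "df2": anova.df2,
                "p": anova.p,
                "partial_eta_sq": anova.partial_eta_sq,
            },
        },
    }
    props.data.to_csv(os.path.join(config.out_dir, "recall_proportions.tsv"), sep="\t")
    temporal.to_csv(os.path.join(config.out_dir, "temporal_organization.tsv"), sep="\t")

    # ---------------- EEG ----------------
    eeg_params = dataclasses.replace(config.eeg, seed=config.seed_eeg)
    eeg = simulate_eeg(config.n_eeg_subjects, eeg_params)
    n_before = eeg.n_trials
    eeg = reject_epochs_amplitude(eeg, config.reject_threshold_uv)
    eeg = baseline_subtract(eeg, (-500.0, 0.0))
    t0 = _stage("simulate_eeg", t0)

    subjects = sorted(set(eeg.trial_subject))
    spectrum = psd_hanning(eeg, window_ms=config.ssvep_window_ms)
    focal = extract_ssvep(spectrum, band_hz=config.ssvep_band_hz, channel="Oz")
    focal.data.to_csv(os.path.join(config.out_dir, "focal_ssvep.tsv"), sep="\t")
    t0 = _stage("focal_ssvep", t0)

    band_freqs = np.arange(
        np.ceil(config.ssvep_band_hz[0]), np.floor(config.ssvep_band_hz[1]) + 1
    )
    tfr = tfr_hanning(eeg, freqs=band_freqs)
    tfr_db = db_baseline(tfr, config.tfr_baseline_ms)
    peak_channel, peak_window = find_ssvep_peak(tfr_db, config.ssvep_band_hz)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge columns
        band = {k: np.nanmean(P, axis=1) for k, P in tfr_db.power.items()}  # (ch, T)
    tmask = (tfr_db.times >= config.analysis_window_ms[0]) & (
        tfr_db.times < config.analysis_window_ms[1]
    )
    # drop time points missing anywhere (window partly outside the epoch)
    valid = ~np.any(
        np.stack([np.isnan(b).any(axis=0) for b in band.values()]), axis=0
    )
    tmask &= valid
    feats = _condition_features(band, subjects, eeg.data.shape[1], tmask)
    graph = build_neighbor_graph(eeg.channel_xyz)
    ssvep_clusters = {}
    for contrast in ("reward", "list", "interaction"):
        a, b = interaction_contrast(feats, contrast)
        res = cluster_test(
            a, b, graph, n_perm=config.n_perm_cluster, seed=config.seed_perm + 10
        )
        ssvep_clusters[contrast] = _cluster_dict(res, tfr_db.times[tmask])
    t0 = _stage("global_ssvep", t0)

    report["ssvep"] = {
        "n_eeg_subjects": config.n_eeg_subjects,
        "n_trials_rejected": int(n_before - eeg.n_trials),
        "focal_mean_amplitude": {
            c: float(focal.data[c].mean()) for c in CONDITIONS
        },
        "peak_channel": peak_channel,
        "peak_window_ms": list(peak_window),
        "cluster_tests": ssvep_clusters,
    }

    # ---------------- ERP ----------------
    erp_eeg = bandstop_fir(eeg, stopbands=config.erp_stopbands)
    erps = erp_average(erp_eeg, (-200.0, 0.0))
    emask = (erps.times >= config.analysis_window_ms[0]) & (
        erps.times < config.analysis_window_ms[1]
    )
    erp_feats = {
        cond: np.stack([erps.erp[(s, cond)][:, emask] for s in subjects])
        for cond in CONDITIONS
    }
    erp_clusters = {}
    for contrast in (
        "reward",
        "list",
        "interaction",
        "reward_within_mixed",
        "reward_within_pure",
    ):
        a, b = interaction_contrast(erp_feats, contrast)
        res = cluster_test(
            a, b, graph, n_perm=config.n_perm_cluster, seed=config.seed_perm + 20
        )
        erp_clusters[contrast] = _cluster_dict(res, erps.times[emask])
    t0 = _stage("global_erp", t0)

    report["erp"] = {"cluster_tests": erp_clusters}

    # qualitative flags mirroring the study's headline pattern
    def _sig(block, sign=None):
        return any(
            c["p"] < block["alpha_cluster"] and (sign is None or c["sign"] == sign)
            for c in block["clusters"]
        )

    report["flags"] = {
        "mixed_reward_recall_effect": bool(
            report["behavior"]["interaction_signflip"]["p"] < 0.05
            and mean_props["mixed_high"] > mean_props["mixed_low"]
        ),
        "pfr_above_chance": bool(
            pfr_test.p_two_sided < 0.05 and float(pfr_obs.mean()) > pfr_null.group_mean
        ),
        "reward_clustering_above_chance": bool(
            clus_test.p_two_sided < 0.05
            and float(clus_obs.mean()) > clus_null.group_mean
        ),
        "temporal_anova_significant": bool(anova.p < 0.05),
        "ssvep_negative_reward_cluster": _sig(ssvep_clusters["reward"], sign=-1),
        "erp_reward_cluster_mixed": _sig(erp_clusters["reward_within_mixed"], sign=1),
        "erp_reward_cluster_pure": _sig(erp_clusters["reward_within_pure"]),
    }

    if config.make_figures:
        _make_figures(config, report, props, spectrum, tfr_db, eeg)
        t0 = _stage("figures", t0)

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    return report


def _make_figures(config, report, props, spectrum, tfr_db, eeg):
    """Regenerated analogs of the study figures (cosmetic fidelity out of scope)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = config.out_dir
    # recall proportions: bars + per-subject points
    fig, ax = plt.subplots(figsize=(5, 4))
    means = props.mean()
    ax.bar(range(len(CONDITIONS)), [means[c] for c in CONDITIONS], color="lightgray")
    for i, c in enumerate(CONDITIONS):
        y = props.data[c].dropna()
        ax.plot(np.full(len(y), i) + np.linspace(-0.15, 0.15, len(y)), y, "k.", ms=3)
    ax.set_xticks(range(len(CONDITIONS)), CONDITIONS, rotation=20)
    ax.set_ylabel("proportion recalled")
    fig.tight_layout()
    fig.savefig(os.path.join(out, "fig_recall.png"), dpi=100)
    plt.close(fig)

    # grand-average Oz spectrum
    fig, ax = plt.subplots(figsize=(5, 4))
    oz = spectrum.channel_names.index("Oz")
    ga = np.mean([p[oz] for p in spectrum.power.values()], axis=0)
    ax.plot(spectrum.freqs, ga)
    ax.set_xlim(0, 40)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (µV²)")
    fig.tight_layout()
    fig.savefig(os.path.join(out, "fig_spectrum.png"), dpi=100)
    plt.close(fig)

    # stimulation-band dB time course at Oz + topography
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge columns
        band = np.nanmean(
        np.stack([np.nanmean(P[oz], axis=0) for P in tfr_db.power.values()]), axis=0
    )
    axes[0].plot(tfr_db.times, band)
    axes[0].set_xlabel("time (ms)")
    axes[0].set_ylabel("power (dB)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        topo = np.nanmean(
        np.stack(
            [
                np.nanmean(P[:, :, (tfr_db.times >= 0) & (tfr_db.times < 2000)], axis=(1, 2))
                for P in tfr_db.power.values()
            ]
        ),
        axis=0,
    )
    sc = axes[1].scatter(
        eeg.channel_xyz[:, 0], eeg.channel_xyz[:, 1], c=topo, cmap="RdBu_r", s=60
    )
    fig.colorbar(sc, ax=axes[1], label="dB")
    axes[1].set_aspect("equal")
    fig.tight_layout()
    fig.savefig(os.path.join(out, "fig_tfr.png"), dpi=100)
    plt.close(fig)
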
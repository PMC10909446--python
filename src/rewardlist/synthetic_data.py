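"""Synthetic study designs, recall logs and epoched EEG.

The generators emulate a 2 (reward: high/low) x 2 (list composition:
mixed/pure) free-recall EEG experiment: 9 blocks of 16 pictures (1 practice
mixed block + 4 mixed + 2 pure-high + 2 pure-low experimental blocks, 144
distinct stimuli per subject), pictures flickered at 85/6 Hz (≈14.17 Hz) for
2047 ms, EEG epoched -2000..+3000 ms at 500 Hz.

Recall is generated by a two-stage process: each item is recalled with a
condition-dependent probability, then the output order of the recalled set is
sampled sequentially from a softmax over a first-recall reward bias, a
same-reward transition bonus, and a temporal-proximity transition bonus.
This is deliberately the simplest process whose three weights independently
tune the three behavioral statistics (probability of first recall, reward
clustering, temporal clustering); it is not a retrieved-context model.

EEG trials are 1/f^chi pink noise plus (i) a flicker-locked sinusoid with an
occipital topography and an envelope maximal between 1000 and 2000 ms, and
(ii) a late slow-wave ERP (590-1450 ms, raised-cosine edges) over
centroparietal and frontal channel groups, with per-condition amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import (
    BLOCK_COMPOSITION,
    CONDITIONS,
    ITEMS_PER_BLOCK,
    N_BLOCKS,
    EpochedEEG,
    RecallEvent,
    RecallLog,
    StudyDesign,
    StudyItem,
)

__all__ = [
    "BehaviorSimParams",
    "EEGSimParams",
    "generate_design",
    "simulate_recall",
    "simulate_eeg",
    "fibonacci_hemisphere",
    "SSVEP_FREQ_HZ",
    "FLICKER_DURATION_MS",
]

#: exact stimulation frequency; the printed 14.17 Hz is this ratio rounded
SSVEP_FREQ_HZ = 85.0 / 6.0
#: flicker (stimulus) duration in ms
FLICKER_DURATION_MS = 2047.0


@dataclass
class BehaviorSimParams:
    """Generative parameters of the recall simulator.

    Probabilities are per-item recall probabilities; the betas are log-odds
    weights of the sequential output-order softmax.
    """

    p_low: float = 0.35  # P(recall) for low-reward items (and practice)
    boost_mixed: float = 0.20  # added for high-reward items in mixed lists
    boost_pure: float = 0.0  # added for high-reward items in pure lists
    beta_first: float = 1.0  # first-recall reward bias (mixed lists)
    beta_reward: float = 0.6  # same-reward transition bonus
    beta_temporal: float = 1.5  # temporal-proximity transition bonus
    n_subjects: int = 43
    seed: int = 0

    def validate(self) -> "BehaviorSimParams":
        for name in ("p_low", "boost_mixed", "boost_pure"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        for p in (self.p_low, self.p_low + self.boost_mixed, self.p_low + self.boost_pure):
            if not 0.0 <= p <= 1.0:
                raise ValueError("recall probabilities must lie in [0, 1]")
        for name in ("beta_first", "beta_reward", "beta_temporal"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        return self


def _default_ssvep_amp() -> dict[str, float]:
    # power lower for high reward, regardless of list composition; a strong
    # occipital flicker response, sized so the reward contrast stands clear of
    # the ~1 µV²/bin pink-noise floor in a 29-trial average
    return {"mixed_high": 2.8, "mixed_low": 3.5, "pure_high": 2.8, "pure_low": 3.5}


def _default_erp_amp() -> dict[str, float]:
    # late slow wave confined to high-reward items in mixed lists
    return {"mixed_high": 3.0, "mixed_low": 0.0, "pure_high": 0.0, "pure_low": 0.0}


@dataclass
class EEGSimParams:
    """Generative parameters of the EEG simulator (amplitudes in µV)."""

    n_channels: int = 32  # 113 reproduces the full-scale montage
    trials_per_condition: int = 29  # analyzable trials out of 32 per condition
    srate: float = 500.0
    t0_offset_ms: float = -2000.0
    n_samples: int = 2500  # -2000..+3000 ms
    ssvep_freq: float = SSVEP_FREQ_HZ
    ssvep_amp: dict[str, float] = field(default_factory=_default_ssvep_amp)
    ssvep_ramp_ms: float = 1000.0  # envelope reaches maximum at this latency
    erp_amp: dict[str, float] = field(default_factory=_default_erp_amp)
    erp_window_ms: tuple[float, float] = (590.0, 1450.0)
    erp_edge_ms: float = 150.0  # raised-cosine edge width
    noise_exponent: float = 1.0  # chi of the 1/f^chi noise
    noise_scale: float = 10.0  # noise standard deviation, µV
    subject_gain_sd: float = 0.2  # lognormal sigma of per-subject signal gain
    seed: int = 0

    def validate(self) -> "EEGSimParams":
        if not 0 < self.ssvep_freq < self.srate / 2:
            raise ValueError("ssvep_freq must lie in (0, srate/2)")
        if any(a < 0 for a in self.ssvep_amp.values()):
            raise ValueError("ssVEP amplitudes must be >= 0")
        if self.n_channels < 2 or self.trials_per_condition < 1:
            raise ValueError("need >= 2 channels and >= 1 trial per condition")
        return self


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


def generate_design(n_subjects: int, seed: int = 0) -> list[StudyDesign]:
    """Generate per-subject designs: 1 practice mixed block + 8 experimental
    blocks (4 mixed, 2 pure-high, 2 pure-low) of 16 items each, block order
    randomized by ``seed``; 144 distinct item ids per subject."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    designs = []
    for s in range(n_subjects):
        subject_id = f"sub{s + 1:03d}"
        exp_types = [lt for lt, n in BLOCK_COMPOSITION.items() for _ in range(n)]
        order = rng.permutation(len(exp_types))
        block_types = ["mixed"] + [exp_types[i] for i in order]  # block 1 = practice
        items: list[StudyItem] = []
        item_counter = 0
        for block, lt in enumerate(block_types, start=1):
            if lt == "mixed":
                rewards = np.array(["high"] * 8 + ["low"] * 8, dtype=object)
                rng.shuffle(rewards)
            elif lt == "pure_high":
                rewards = np.array(["high"] * ITEMS_PER_BLOCK, dtype=object)
            else:
                rewards = np.array(["low"] * ITEMS_PER_BLOCK, dtype=object)
            for pos in range(1, ITEMS_PER_BLOCK + 1):
                item_counter += 1
                items.append(
                    StudyItem(
                        item_id=f"{subject_id}_item{item_counter:03d}",
                        serial_position=pos,
                        reward=str(rewards[pos - 1]),
                        block=block,
                        list_type=lt,
                        is_practice=(block == 1),
                    )
                )
        designs.append(StudyDesign(subject_id, items).validate())
    return designs


# ---------------------------------------------------------------------------
# recall simulation
# ---------------------------------------------------------------------------


def _sample_output_order(
    rng: np.random.Generator,
    serial: np.ndarray,
    is_high: np.ndarray,
    mixed: bool,
    params: BehaviorSimParams,
) -> np.ndarray:
    """Sequentially sample an output order over the recalled set (indices)."""
    k = serial.size
    order = np.empty(k, dtype=int)
    remaining = list(range(k))
    # first recall: reward bias in mixed lists only
    if mixed and params.beta_first != 0.0:
        logw = params.beta_first * is_high[remaining].astype(float)
    else:
        logw = np.zeros(len(remaining))
    w = np.exp(logw - logw.max())
    choice = rng.choice(len(remaining), p=w / w.sum())
    order[0] = remaining.pop(choice)
    for j in range(1, k):
        prev = order[j - 1]
        rem = np.array(remaining)
        logw = (
            params.beta_reward * (is_high[rem] == is_high[prev]).astype(float)
            - params.beta_temporal * np.abs(serial[rem] - serial[prev]) / ITEMS_PER_BLOCK
        )
        if not np.all(np.isfinite(logw)):
            raise ValueError("non-finite transition weights")
        w = np.exp(logw - logw.max())
        choice = rng.choice(len(rem), p=w / w.sum())
        order[j] = remaining.pop(choice)
    return order


def simulate_recall(
    designs: list[StudyDesign] | StudyDesign,
    params: BehaviorSimParams | None = None,
) -> RecallLog:
    """Simulate free recall for every list of every design.

    All simulated recalls are correct (no intrusions or repetitions); output
    positions are 1..k per list. Deterministic given ``params.seed``.
    """
    if isinstance(designs, StudyDesign):
        designs = [designs]
    params = (params or BehaviorSimParams()).validate()
    rng = np.random.default_rng(params.seed)
    events: list[RecallEvent] = []
    for design in designs:
        for block, items in design.blocks().items():
            lt = items[0].list_type
            is_high = np.array([it.reward == "high" for it in items])
            boost = params.boost_mixed if lt == "mixed" else params.boost_pure
            p = np.where(is_high, np.clip(params.p_low + boost, 0, 1), params.p_low)
            recalled = np.flatnonzero(rng.random(ITEMS_PER_BLOCK) < p)
            if recalled.size == 0:
                continue
            serial = np.array([items[i].serial_position for i in recalled])
            order = _sample_output_order(
                rng, serial, is_high[recalled], lt == "mixed", params
            )
            for out_pos, idx in enumerate(order, start=1):
                events.append(
                    RecallEvent(
                        subject_id=design.subject_id,
                        block=block,
                        output_position=out_pos,
                        item_id=items[recalled[idx]].item_id,
                    )
                )
    return RecallLog(events=events, designs={d.subject_id: d for d in designs}).validate()


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n points on the upper unit hemisphere via a Fibonacci lattice.

    Coordinates follow the +x right / +y nose / +z up convention.
    """
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = (i + 0.5) / n  # uniform in z over (0, 1): upper hemisphere
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


# anchor directions for the named channels (unit vectors; +y = nose, +z = up)
_ANCHORS = {
    "Oz": np.array([0.0, -0.95, 0.31]),
    "CPz": np.array([0.0, -0.37, 0.93]),
    "Fz": np.array([0.0, 0.71, 0.71]),
}


def _angular_distance(xyz: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    anchor = anchor / np.linalg.norm(anchor)
    return np.arccos(np.clip(xyz @ anchor, -1.0, 1.0))


def channel_layout(n_channels: int) -> tuple[list[str], np.ndarray, dict[str, int]]:
    """Fibonacci layout with Oz-like, CPz-like and Fz-like channels named.

    Returns (names, xyz, anchors) where ``anchors`` maps the three anatomical
    labels to channel indices (nearest lattice point by polar angle).
    """
    xyz = fibonacci_hemisphere(n_channels)
    names = [f"ch{i + 1:03d}" for i in range(n_channels)]
    anchors: dict[str, int] = {}
    taken: set[int] = set()
    for label, vec in _ANCHORS.items():
        d = _angular_distance(xyz, vec)
        for idx in np.argsort(d):
            if int(idx) not in taken:
                anchors[label] = int(idx)
                taken.add(int(idx))
                break
        names[anchors[label]] = label
    return names, xyz, anchors


def _raised_cosine_window(times_ms, start, stop, edge):
    """1 inside [start+edge, stop-edge], raised-cosine edges, 0 outside."""
    t = np.asarray(times_ms, dtype=float)
    w = np.zeros_like(t)
    core = (t >= start + edge) & (t <= stop - edge)
    w[core] = 1.0
    rise = (t >= start) & (t < start + edge)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - start) / edge))
    fall = (t > stop - edge) & (t <= stop)
    w[fall] = 0.5 * (1 - np.cos(np.pi * (stop - t[fall]) / edge))
    return w


def _pink_noise(rng, shape, n_samples, exponent, srate):
    """1/f^chi noise via frequency-domain shaping, unit variance per trace."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((*shape, freqs.size))
        + 1j * rng.standard_normal((*shape, freqs.size))
    ) * gain
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_eeg(
    designs: list[StudyDesign] | StudyDesign | list[str] | int,
    params: EEGSimParams | None = None,
) -> EpochedEEG:
    """Simulate epoched EEG for the subjects of ``designs``.

    ``designs`` may be StudyDesign objects, subject-id strings, or an integer
    subject count. Each subject contributes ``trials_per_condition`` trials in
    each of the four design cells. Deterministic given ``params.seed``.
    """
    params = (params or EEGSimParams()).validate()
    if isinstance(designs, int):
        subjects = [f"sub{i + 1:03d}" for i in range(designs)]
    else:
        if isinstance(designs, StudyDesign):
            designs = [designs]
        subjects = [d.subject_id if isinstance(d, StudyDesign) else str(d) for d in designs]

    names, xyz, anchors = channel_layout(params.n_channels)
    times = params.t0_offset_ms + np.arange(params.n_samples) * 1000.0 / params.srate

    # spatial gain profiles (Gaussian in angular distance to the anchors)
    occ_gain = np.exp(-0.5 * (_angular_distance(xyz, _ANCHORS["Oz"]) / 0.6) ** 2)
    lpp_gain = np.exp(-0.5 * (_angular_distance(xyz, _ANCHORS["CPz"]) / 0.6) ** 2)
    fsw_gain = np.exp(-0.5 * (_angular_distance(xyz, _ANCHORS["Fz"]) / 0.6) ** 2)
    erp_gain = np.maximum(lpp_gain, fsw_gain)

    # flicker envelope: raised-cosine rise to 1 by ssvep_ramp_ms, off at 2047 ms
    env = np.zeros_like(times)
    on = (times >= 0) & (times <= FLICKER_DURATION_MS)
    ramp = np.clip(times / params.ssvep_ramp_ms, 0, 1)
    env[on] = 0.5 * (1 - np.cos(np.pi * ramp[on]))
    carrier = env * np.sin(2 * np.pi * params.ssvep_freq * times / 1000.0)

    erp_shape = _raised_cosine_window(
        times, params.erp_window_ms[0], params.erp_window_ms[1], params.erp_edge_ms
    )

    rng = np.random.default_rng(params.seed)
    n_cond_trials = params.trials_per_condition
    n_trials_per_subject = n_cond_trials * len(CONDITIONS)
    n_total = n_trials_per_subject * len(subjects)
    data = np.empty((n_total, params.n_channels, params.n_samples), dtype=np.float32)
    trial_condition = np.empty(n_total, dtype=object)
    trial_subject = np.empty(n_total, dtype=object)

    row = 0
    for subj in subjects:
        gain = float(np.exp(rng.normal(0.0, params.subject_gain_sd)))
        for cond in CONDITIONS:
            noise = _pink_noise(
                rng,
                (n_cond_trials, params.n_channels),
                params.n_samples,
                params.noise_exponent,
                params.srate,
            ) * params.noise_scale
            signal = (
                gain * params.ssvep_amp[cond] * occ_gain[:, None] * carrier[None, :]
                + gain * params.erp_amp[cond] * erp_gain[:, None] * erp_shape[None, :]
            )
            data[row : row + n_cond_trials] = (noise + signal[None]).astype(np.float32)
            trial_condition[row : row + n_cond_trials] = cond
            trial_subject[row : row + n_cond_trials] = subj
            row += n_cond_trials

    return EpochedEEG(
        data=data,
        srate=params.srate,
        t0_offset_ms=params.t0_offset_ms,
        channel_names=names,
        channel_xyz=xyz,
        trial_condition=trial_condition,
        trial_subject=trial_subject,
    ).validate()
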
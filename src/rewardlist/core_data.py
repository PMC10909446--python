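"""Domain containers and file I/O for the behavioral tables and epoched EEG.

Conventions used throughout the package:

* serial positions, output positions and block indices are 1-based;
* time is in milliseconds relative to stimulus onset;
* analysis windows are inclusive-start / exclusive-end;
* EEG voltages are in microvolts (µV), stored as little-endian float32.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LIST_TYPES",
    "CONDITIONS",
    "REWARDS",
    "ValidationError",
    "ParseError",
    "StudyItem",
    "StudyDesign",
    "RecallEvent",
    "RecallLog",
    "EpochedEEG",
    "SubjectConditionTable",
    "read_recall_tables",
    "write_recall_tables",
    "read_eeg_container",
    "write_eeg_container",
    "reject_epochs_amplitude",
    "time_window_mask",
]

REWARDS = ("high", "low")
LIST_TYPES = ("mixed", "pure_high", "pure_low")
#: the four cells of the 2 (reward) x 2 (list composition) design
CONDITIONS = ("mixed_high", "mixed_low", "pure_high", "pure_low")

N_BLOCKS = 9
ITEMS_PER_BLOCK = 16
N_ITEMS = N_BLOCKS * ITEMS_PER_BLOCK  # 144 distinct stimuli per subject

#: experimental (non-practice) block composition: list_type -> number of blocks
BLOCK_COMPOSITION = {"mixed": 4, "pure_high": 2, "pure_low": 2}


class ValidationError(ValueError):
    """An object violates a design or schema invariant."""


class ParseError(ValueError):
    """A file row could not be parsed."""


def condition_of(list_type: str, reward: str) -> str:
    """Map (list_type, reward) to the 2x2 design cell name."""
    if list_type == "mixed":
        return f"mixed_{reward}"
    return list_type


# ---------------------------------------------------------------------------
# behavioral containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyItem:
    item_id: str
    serial_position: int
    reward: str
    block: int
    list_type: str
    is_practice: bool = False

    def __post_init__(self):
        if self.reward not in REWARDS:
            raise ValidationError(f"unknown reward {self.reward!r}")
        if self.list_type not in LIST_TYPES:
            raise ValidationError(f"unknown list_type {self.list_type!r}")
        if not 1 <= self.serial_position <= ITEMS_PER_BLOCK:
            raise ValidationError(
                f"serial_position {self.serial_position} outside 1..{ITEMS_PER_BLOCK}"
            )

    @property
    def condition(self) -> str:
        return condition_of(self.list_type, self.reward)


@dataclass
class StudyDesign:
    """All studied items of one subject: 1 practice + 8 experimental blocks."""

    subject_id: str
    items: list[StudyItem]

    def validate(self) -> "StudyDesign":
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"subject {self.subject_id}: duplicate item ids")
        if len(ids) != N_ITEMS:
            raise ValidationError(
                f"subject {self.subject_id}: expected {N_ITEMS} items, got {len(ids)}"
            )
        by_block = self.blocks()
        if sorted(by_block) != list(range(1, N_BLOCKS + 1)):
            raise ValidationError(
                f"subject {self.subject_id}: blocks must be 1..{N_BLOCKS}"
            )
        comp: dict[str, int] = {}
        for block, items in by_block.items():
            positions = sorted(it.serial_position for it in items)
            if positions != list(range(1, ITEMS_PER_BLOCK + 1)):
                raise ValidationError(
                    f"subject {self.subject_id} block {block}: serial positions "
                    f"must be a permutation of 1..{ITEMS_PER_BLOCK}"
                )
            ltypes = {it.list_type for it in items}
            if len(ltypes) != 1:
                raise ValidationError(
                    f"subject {self.subject_id} block {block}: mixed list_type labels"
                )
            practice = {it.is_practice for it in items}
            if len(practice) != 1:
                raise ValidationError(
                    f"subject {self.subject_id} block {block}: inconsistent is_practice"
                )
            lt = ltypes.pop()
            n_high = sum(it.reward == "high" for it in items)
            if lt == "pure_high" and n_high != ITEMS_PER_BLOCK:
                raise ValidationError(
                    f"subject {self.subject_id} block {block}: pure_high with low items"
                )
            if lt == "pure_low" and n_high != 0:
                raise ValidationError(
                    f"subject {self.subject_id} block {block}: pure_low with high items"
                )
            if lt == "mixed" and n_high != ITEMS_PER_BLOCK // 2:
                raise ValidationError(
                    f"subject {self.subject_id} block {block}: mixed list needs "
                    f"8 high + 8 low, got {n_high} high"
                )
            if not items[0].is_practice:
                comp[lt] = comp.get(lt, 0) + 1
        if comp != BLOCK_COMPOSITION:
            raise ValidationError(
                f"subject {self.subject_id}: experimental block composition {comp} "
                f"!= {BLOCK_COMPOSITION}"
            )
        n_practice = sum(its[0].is_practice for its in by_block.values())
        if n_practice != 1:
            raise ValidationError(
                f"subject {self.subject_id}: expected exactly 1 practice block, "
                f"got {n_practice}"
            )
        return self

    def blocks(self) -> dict[int, list[StudyItem]]:
        out: dict[int, list[StudyItem]] = {}
        for it in self.items:
            out.setdefault(it.block, []).append(it)
        for items in out.values():
            items.sort(key=lambda it: it.serial_position)
        return out

    def experimental_blocks(self) -> dict[int, list[StudyItem]]:
        return {b: its for b, its in self.blocks().items() if not its[0].is_practice}

    def item_lookup(self) -> dict[tuple[int, str], StudyItem]:
        return {(it.block, it.item_id): it for it in self.items}


@dataclass(frozen=True)
class RecallEvent:
    subject_id: str
    block: int
    output_position: int
    item_id: str | None  # None for unidentifiable intrusions
    intrusion: bool = False
    repetition: bool = False

    @property
    def correct(self) -> bool:
        return not self.intrusion and not self.repetition


@dataclass
class RecallLog:
    """Recall events plus the study designs they refer to (possibly many subjects)."""

    events: list[RecallEvent]
    designs: dict[str, StudyDesign]

    def validate(self) -> "RecallLog":
        for design in self.designs.values():
            design.validate()
        by_list: dict[tuple[str, int], list[RecallEvent]] = {}
        for ev in self.events:
            if ev.subject_id not in self.designs:
                raise ValidationError(f"recall for unknown subject {ev.subject_id}")
            design = self.designs[ev.subject_id]
            if ev.block not in design.blocks():
                raise ValidationError(
                    f"subject {ev.subject_id}: recall in unknown block {ev.block}"
                )
            by_list.setdefault((ev.subject_id, ev.block), []).append(ev)
        for (subj, block), evs in by_list.items():
            positions = sorted(e.output_position for e in evs)
            if positions != list(range(1, len(evs) + 1)):
                raise ValidationError(
                    f"subject {subj} block {block}: output positions must be a "
                    f"permutation of 1..{len(evs)}"
                )
            studied = {it.item_id for it in self.designs[subj].blocks()[block]}
            seen: set[str] = set()
            for ev in sorted(evs, key=lambda e: e.output_position):
                if ev.correct:
                    if ev.item_id is None or ev.item_id not in studied:
                        raise ValidationError(
                            f"subject {subj} block {block}: correct recall of "
                            f"unstudied item {ev.item_id!r}"
                        )
                    if ev.item_id in seen:
                        raise ValidationError(
                            f"subject {subj} block {block}: item {ev.item_id!r} "
                            "recalled twice but not flagged as repetition"
                        )
                    seen.add(ev.item_id)
        return self

    def subjects(self) -> list[str]:
        return sorted(self.designs)

    def events_by_list(self) -> dict[tuple[str, int], list[RecallEvent]]:
        out: dict[tuple[str, int], list[RecallEvent]] = {}
        for ev in self.events:
            out.setdefault((ev.subject_id, ev.block), []).append(ev)
        for evs in out.values():
            evs.sort(key=lambda e: e.output_position)
        return out


# ---------------------------------------------------------------------------
# behavioral table I/O (TSV)
# ---------------------------------------------------------------------------

STUDY_COLUMNS = [
    "subject_id",
    "block",
    "list_type",
    "serial_position",
    "item_id",
    "reward",
    "is_practice",
]
RECALL_COLUMNS = [
    "subject_id",
    "block",
    "output_position",
    "item_id",
    "intrusion",
    "repetition",
]


def _to_bool(value, path, line) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true"):
        return True
    if s in ("0", "false"):
        return False
    raise ParseError(f"{path}:{line}: cannot parse boolean {value!r}")


def read_recall_tables(study_path, recall_path) -> RecallLog:
    """Read the study/recall TSV pair and return a validated :class:`RecallLog`."""
    study = pd.read_csv(study_path, sep="\t", dtype=str, keep_default_na=False)
    recall = pd.read_csv(recall_path, sep="\t", dtype=str, keep_default_na=False)
    for cols, df, path in ((STUDY_COLUMNS, study, study_path), (RECALL_COLUMNS, recall, recall_path)):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")

    designs: dict[str, list[StudyItem]] = {}
    for i, row in enumerate(study.itertuples(index=False), start=2):
        try:
            item = StudyItem(
                item_id=row.item_id,
                serial_position=int(row.serial_position),
                reward=row.reward,
                block=int(row.block),
                list_type=row.list_type,
                is_practice=_to_bool(row.is_practice, study_path, i),
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{study_path}:{i}: {exc}") from exc
        designs.setdefault(row.subject_id, []).append(item)

    events: list[RecallEvent] = []
    for i, row in enumerate(recall.itertuples(index=False), start=2):
        try:
            events.append(
                RecallEvent(
                    subject_id=row.subject_id,
                    block=int(row.block),
                    output_position=int(row.output_position),
                    item_id=row.item_id or None,
                    intrusion=_to_bool(row.intrusion, recall_path, i),
                    repetition=_to_bool(row.repetition, recall_path, i),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{recall_path}:{i}: {exc}") from exc

    log = RecallLog(
        events=events,
        designs={s: StudyDesign(s, items) for s, items in designs.items()},
    )
    return log.validate()


def write_recall_tables(log: RecallLog, study_path, recall_path) -> None:
    """Write the study/recall TSV pair; byte-stable for a fixed log."""
    study_rows = []
    for subj in log.subjects():
        for it in sorted(
            log.designs[subj].items, key=lambda it: (it.block, it.serial_position)
        ):
            study_rows.append(
                (subj, it.block, it.list_type, it.serial_position, it.item_id,
                 it.reward, int(it.is_practice))
            )
    recall_rows = [
        (ev.subject_id, ev.block, ev.output_position, ev.item_id or "",
         int(ev.intrusion), int(ev.repetition))
        for ev in sorted(log.events, key=lambda e: (e.subject_id, e.block, e.output_position))
    ]
    pd.DataFrame(study_rows, columns=STUDY_COLUMNS).to_csv(
        study_path, sep="\t", index=False, lineterminator="\n"
    )
    pd.DataFrame(recall_rows, columns=RECALL_COLUMNS).to_csv(
        recall_path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# epoched EEG
# ---------------------------------------------------------------------------


@dataclass
class EpochedEEG:
    """Epoched multichannel EEG: trials x channels x samples, in µV.

    The default epoch spans -2000..+3000 ms around stimulus onset at 500 Hz
    (2500 samples).
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples) float32, µV
    srate: float
    t0_offset_ms: float
    channel_names: list[str]
    channel_xyz: np.ndarray  # (n_channels, 3) unit-sphere coordinates
    trial_condition: np.ndarray  # (n_trials,) str, drawn from CONDITIONS
    trial_subject: np.ndarray  # (n_trials,) str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.channel_xyz = np.asarray(self.channel_xyz, dtype=float)
        self.trial_condition = np.asarray(self.trial_condition, dtype=object)
        self.trial_subject = np.asarray(self.trial_subject, dtype=object)

    def validate(self) -> "EpochedEEG":
        n_tr, n_ch, _ = self.data.shape
        if len(self.channel_names) != n_ch or self.channel_xyz.shape != (n_ch, 3):
            raise ValidationError("channel names/coordinates do not match data shape")
        if self.trial_condition.shape != (n_tr,) or self.trial_subject.shape != (n_tr,):
            raise ValidationError("per-trial labels do not match trial count")
        bad = set(self.trial_condition) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels {sorted(bad)}")
        return self

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        n = self.data.shape[2]
        return self.t0_offset_ms + np.arange(n) * 1000.0 / self.srate

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select_trials(self, mask: np.ndarray) -> "EpochedEEG":
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            trial_condition=self.trial_condition[mask],
            trial_subject=self.trial_subject[mask],
        )

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


def time_window_mask(times: np.ndarray, start_ms: float, stop_ms: float) -> np.ndarray:
    """Boolean mask for the inclusive-start / exclusive-end window [start, stop)."""
    times = np.asarray(times)
    mask = (times >= start_ms) & (times < stop_ms)
    if not mask.any():
        raise ValueError(f"window [{start_ms}, {stop_ms}) ms contains no samples")
    return mask


def write_eeg_container(eeg: EpochedEEG, dir_path) -> None:
    """Write header.json + data.f32 (row-major little-endian float32)."""
    eeg.validate()
    os.makedirs(dir_path, exist_ok=True)
    header = {
        "format": "rewardlist-epoched-eeg-v1",
        "units": "uV",
        "srate": eeg.srate,
        "t0_offset_ms": eeg.t0_offset_ms,
        "shape": list(eeg.data.shape),
        "channel_names": list(eeg.channel_names),
        "channel_xyz": eeg.channel_xyz.tolist(),
        "trial_condition": [str(c) for c in eeg.trial_condition],
        "trial_subject": [str(s) for s in eeg.trial_subject],
    }
    with open(os.path.join(dir_path, "header.json"), "w") as fh:
        json.dump(header, fh, indent=1, sort_keys=True)
        fh.write("\n")
    eeg.data.astype("<f4").tofile(os.path.join(dir_path, "data.f32"))


def read_eeg_container(dir_path) -> EpochedEEG:
    """Read an EEG container written by :func:`write_eeg_container`."""
    with open(os.path.join(dir_path, "header.json")) as fh:
        header = json.load(fh)
    shape = tuple(header["shape"])
    data = np.fromfile(os.path.join(dir_path, "data.f32"), dtype="<f4")
    if data.size != int(np.prod(shape)):
        raise ValidationError(
            f"{dir_path}: data.f32 holds {data.size} values, header shape {shape} "
            f"needs {int(np.prod(shape))}"
        )
    eeg = EpochedEEG(
        data=data.reshape(shape),
        srate=header["srate"],
        t0_offset_ms=header["t0_offset_ms"],
        channel_names=list(header["channel_names"]),
        channel_xyz=np.asarray(header["channel_xyz"], dtype=float),
        trial_condition=np.asarray(header["trial_condition"], dtype=object),
        trial_subject=np.asarray(header["trial_subject"], dtype=object),
    )
    return eeg.validate()


def reject_epochs_amplitude(eeg: EpochedEEG, threshold_uv: float = 100.0) -> EpochedEEG:
    """Drop trials in which any sample of any channel exceeds ±threshold µV.

    The final artifact-rejection step of the preprocessing chain; idempotent,
    order preserving, and may return zero trials.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    keep = np.all(np.abs(eeg.data) <= threshold_uv, axis=(1, 2))
    return eeg.select_trials(keep)


# ---------------------------------------------------------------------------
# subject x condition tables
# ---------------------------------------------------------------------------


@dataclass
class SubjectConditionTable:
    """A named subject x condition matrix of one scalar statistic.

    ``data`` is a DataFrame indexed by subject with one column per condition
    (or list type); missing cells are NaN.
    """

    name: str
    units: str
    data: pd.DataFrame

    def validate(self, proportions: bool = False) -> "SubjectConditionTable":
        if proportions:
            vals = self.data.to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
            if not ok.all():
                raise ValidationError(f"{self.name}: proportions outside [0, 1]")
        return self

    def mean(self) -> pd.Series:
        return self.data.mean(axis=0)
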
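import numpy as np
import pytest

from rewardlist.core_data import RecallEvent, RecallLog, StudyDesign, StudyItem
from rewardlist.synthetic_data import (
    BehaviorSimParams,
    EEGSimParams,
    generate_design,
    simulate_eeg,
    simulate_recall,
)


@pytest.fixture(scope="session")
def one_design():
    return generate_design(1, seed=11)[0]


@pytest.fixture(scope="session")
def small_log():
    designs = generate_design(6, seed=21)
    return simulate_recall(designs, BehaviorSimParams(n_subjects=6, seed=22))


@pytest.fixture(scope="session")
def tiny_eeg():
    """2 subjects x 4 conditions x 3 trials, 16 channels; fast to analyze."""
    params = EEGSimParams(n_channels=16, trials_per_condition=3, seed=31)
    return simulate_eeg(2, params)


def make_list_design(rewards, subject_id="s1", block=2, list_type=None):
    """A single 16-item experimental list embedded in a valid design shell.

    ``rewards`` gives the first len(rewards) item rewards; the helper builds
    only the one block and bypasses whole-design validation (tests that need
    a full design use generate_design).
    """
    items = [
        StudyItem(
            item_id=f"it{i + 1:02d}",
            serial_position=i + 1,
            reward=r,
            block=block,
            list_type=list_type
            or ("mixed" if len(set(rewards)) > 1 else f"pure_{rewards[0]}"),
        )
        for i, r in enumerate(rewards)
    ]
    return items


def single_list_log(rewards, recall_serials, list_type=None):
    """RecallLog with one artificial list (no full-design validation).

    ``recall_serials`` are 1-based serial positions in output order.
    """
    items = make_list_design(rewards, list_type=list_type)
    design = StudyDesign("s1", items)
    events = [
        RecallEvent("s1", 2, pos, f"it{serial:02d}")
        for pos, serial in enumerate(recall_serials, start=1)
    ]
    return RecallLog(events=events, designs={"s1": design})
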
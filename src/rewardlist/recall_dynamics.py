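"""Recall-dynamics statistics: recall proportions, probability of first
recall by reward, and percentile-rank organization (clustering) scores.

The organization score of a recall transition is the percentile rank (with
ties counted half) of the actually-recalled item among all studied,
not-yet-recalled candidates, under a distance defined by the metric:

* ``temporal``: absolute serial-position lag to the previously recalled item
  (smaller lag = "closer", so the rank counts candidates with *larger* lag);
* ``reward``: indicator of a reward-category mismatch with the previous item
  (a same-reward transition outranks a different-reward candidate).

Scores lie in [0, 1] with expectation 0.5 under a uniformly random output
order. Transitions are pooled across lists within subject before averaging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import (
    CONDITIONS,
    ITEMS_PER_BLOCK,
    RecallLog,
    StudyItem,
    SubjectConditionTable,
)

__all__ = [
    "recall_proportion",
    "prob_first_recall_high",
    "organization_score",
    "list_arrays",
    "transition_scores",
]

SCOPES = ("mixed", "pure_high", "pure_low", "all")
METRICS = ("reward", "temporal")


def list_arrays(log: RecallLog, include_practice: bool = False):
    """Yield (subject, block, list_type, serial, is_high, recall_idx) per list.

    ``serial``/``is_high`` describe all 16 studied items (index = serial-1);
    ``recall_idx`` gives the 0-based studied-item indices of correct recalls
    in output order.
    """
    by_list = log.events_by_list()
    for subj in log.subjects():
        design = log.designs[subj]
        for block, items in design.blocks().items():
            if items[0].is_practice and not include_practice:
                continue
            serial = np.array([it.serial_position for it in items])
            is_high = np.array([it.reward == "high" for it in items])
            id_to_idx = {it.item_id: i for i, it in enumerate(items)}
            evs = by_list.get((subj, block), [])
            recall_idx = np.array(
                [id_to_idx[e.item_id] for e in evs if e.correct], dtype=int
            )
            yield subj, block, items[0].list_type, serial, is_high, recall_idx


def distance_matrix(serial: np.ndarray, is_high: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise transition distances between studied items."""
    if metric == "temporal":
        return np.abs(serial[:, None] - serial[None, :]).astype(float)
    if metric == "reward":
        return (is_high[:, None] != is_high[None, :]).astype(float)
    raise ValueError(f"unknown metric {metric!r}")


def transition_scores(orders: np.ndarray, dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Summed percentile-rank scores for a batch of output orders of one list.

    Parameters
    ----------
    orders : (P, k) int array
        P candidate output orders over the recalled set, as 0-based indices
        into the studied list (k >= 2).
    dist : (n_items, n_items) array
        Transition distance matrix over the studied items.

    Returns
    -------
    (score_sum, n_used) : two (P,) arrays
        Sum of per-transition scores and count of usable transitions per
        order. A transition whose candidate set (studied, not yet recalled)
        contains only the actually-recalled item is skipped.
    """
    orders = np.atleast_2d(orders)
    P, k = orders.shape
    n_items = dist.shape[0]
    recalled = np.zeros((P, n_items), dtype=bool)
    rows = np.arange(P)
    score_sum = np.zeros(P)
    n_used = np.zeros(P)
    recalled[rows, orders[:, 0]] = True
    for j in range(k - 1):
        prev = orders[:, j]
        nxt = orders[:, j + 1]
        cand = ~recalled  # studied and not yet recalled (includes nxt)
        d_all = dist[prev]  # (P, n_items)
        d_next = dist[prev, nxt]
        in_play = cand.copy()
        in_play[rows, nxt] = False  # compare against the other candidates
        greater = (in_play & (d_all > d_next[:, None])).sum(axis=1)
        ties = (in_play & (d_all == d_next[:, None])).sum(axis=1)
        denom = cand.sum(axis=1) - 1
        usable = denom >= 1
        score_sum[usable] += (greater[usable] + 0.5 * ties[usable]) / denom[usable]
        n_used += usable
        recalled[rows, nxt] = True
    return score_sum, n_used


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def recall_proportion(log: RecallLog) -> SubjectConditionTable:
    """Per subject x design cell: correct recalls / items studied in the cell.

    Mixed cells hold 32 items over 4 lists, pure cells 32 over 2 lists;
    the practice block is excluded.
    """
    counts = {s: {c: [0, 0] for c in CONDITIONS} for s in log.subjects()}
    for subj, _block, lt, _serial, is_high, recall_idx in list_arrays(log):
        hi_cond = "mixed_high" if lt == "mixed" else lt
        lo_cond = "mixed_low" if lt == "mixed" else lt
        n_high = int(is_high.sum())
        counts[subj][hi_cond][1] += n_high
        if lt != "pure_high":
            counts[subj][lo_cond][1] += ITEMS_PER_BLOCK - n_high
        rec_high = int(is_high[recall_idx].sum())
        counts[subj][hi_cond][0] += rec_high
        if lt != "pure_high":
            counts[subj][lo_cond][0] += recall_idx.size - rec_high
    data = pd.DataFrame(
        {
            c: {
                s: counts[s][c][0] / counts[s][c][1] if counts[s][c][1] else np.nan
                for s in counts
            }
            for c in CONDITIONS
        }
    )
    data.index.name = "subject_id"
    return SubjectConditionTable("recall_proportion", "proportion", data).validate(True)


def prob_first_recall_high(log: RecallLog) -> pd.Series:
    """Per subject: fraction of mixed lists whose first correct recall is a
    high-reward item (lists with no correct recall do not contribute)."""
    num = {s: 0 for s in log.subjects()}
    den = {s: 0 for s in log.subjects()}
    for subj, _block, lt, _serial, is_high, recall_idx in list_arrays(log):
        if lt != "mixed" or recall_idx.size == 0:
            continue
        den[subj] += 1
        num[subj] += bool(is_high[recall_idx[0]])
    out = pd.Series(
        {s: num[s] / den[s] if den[s] else np.nan for s in log.subjects()},
        name="prob_first_recall_high",
    )
    out.index.name = "subject_id"
    return out


def _scope_match(list_type: str, scope: str) -> bool:
    return scope == "all" or list_type == scope


def organization_score(
    log: RecallLog, metric: str, scope: str = "mixed"
) -> pd.DataFrame:
    """Per-subject organization score, transitions pooled across lists.

    Returns a DataFrame indexed by subject with columns ``value`` (NaN when
    no usable transition exists) and ``n_transitions``.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    sums = {s: 0.0 for s in log.subjects()}
    counts = {s: 0 for s in log.subjects()}
    for subj, _block, lt, serial, is_high, recall_idx in list_arrays(log):
        if not _scope_match(lt, scope) or recall_idx.size < 2:
            continue
        dist = distance_matrix(serial, is_high, metric)
        ssum, n = transition_scores(recall_idx[None, :], dist)
        sums[subj] += float(ssum[0])
        counts[subj] += int(n[0])
    out = pd.DataFrame(
        {
            "value": {
                s: sums[s] / counts[s] if counts[s] else np.nan for s in sums
            },
            "n_transitions": counts,
        }
    )
    out.index.name = "subject_id"
    out.attrs.update({"metric": metric, "scope": scope})
    return out
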
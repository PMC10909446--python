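"""Recall-rate-controlled permutation nulls and scalar inference tests.

The permutation null fixes which items were recalled in each list and
permutes only their output order (uniformly over the k! orders), so the
chance level of order-sensitive statistics — probability of first recall of
a high-reward item, reward clustering — is estimated while controlling for
condition differences in recall rate. Observed values are then compared to
the per-subject permuted means with a one-sample Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_data import CONDITIONS, RecallLog, SubjectConditionTable
from .recall_dynamics import distance_matrix, list_arrays, transition_scores

__all__ = [
    "PermutationNull",
    "WilcoxonResult",
    "RmAnovaResult",
    "PowerSpec",
    "permute_output_orders",
    "wilcoxon_signed_rank",
    "compare_observed_to_null",
    "rm_anova_oneway",
    "interaction_signflip_test",
    "SignFlipResult",
    "required_sample_size",
    "power_paired_t",
]

STATISTICS = ("pfr_high", "reward_clustering")


@dataclass
class PermutationNull:
    """Per-subject permuted means of an output-order statistic."""

    statistic: str
    n_perm: int
    seed: int
    per_subject_mean: pd.Series  # NaN where the statistic is undefined
    distribution: pd.DataFrame | None = None  # subjects x n_perm, optional

    @property
    def group_mean(self) -> float:
        return float(self.per_subject_mean.mean())


def _random_orders(rng: np.random.Generator, n_perm: int, k: int) -> np.ndarray:
    """(n_perm, k) uniformly random permutations of range(k)."""
    return np.argsort(rng.random((n_perm, k)), axis=1)


def permute_output_orders(
    log: RecallLog,
    statistic: str = "pfr_high",
    n_perm: int = 10_000,
    seed: int = 0,
    keep_distribution: bool = False,
) -> PermutationNull:
    """Estimate the chance level of an output-order statistic.

    For each mixed list, the output order of the correctly recalled items is
    permuted ``n_perm`` times (recalled set fixed) and the statistic is
    recomputed per permutation; the per-subject mean over permutations is
    returned. Subjects for whom the statistic is undefined get NaN.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    rng = np.random.default_rng(seed)
    subjects = log.subjects()
    if statistic == "pfr_high":
        # per permutation: fraction of contributing lists with high first recall
        num = {s: np.zeros(n_perm) for s in subjects}
        den = {s: 0 for s in subjects}
        for subj, _b, lt, _serial, is_high, recall_idx in list_arrays(log):
            if lt != "mixed" or recall_idx.size == 0:
                continue
            first = recall_idx[rng.integers(recall_idx.size, size=n_perm)]
            num[subj] += is_high[first]
            den[subj] += 1
        dist = {
            s: num[s] / den[s] if den[s] else np.full(n_perm, np.nan)
            for s in subjects
        }
    else:  # reward clustering: pooled transitions per subject per permutation
        ssum = {s: np.zeros(n_perm) for s in subjects}
        count = {s: np.zeros(n_perm) for s in subjects}
        for subj, _b, lt, serial, is_high, recall_idx in list_arrays(log):
            if lt != "mixed" or recall_idx.size < 2:
                continue
            dmat = distance_matrix(serial, is_high, "reward")
            orders = recall_idx[_random_orders(rng, n_perm, recall_idx.size)]
            sc, n = transition_scores(orders, dmat)
            ssum[subj] += sc
            count[subj] += n
        dist = {}
        for s in subjects:
            with np.errstate(invalid="ignore", divide="ignore"):
                dist[s] = np.where(count[s] > 0, ssum[s] / np.maximum(count[s], 1), np.nan)
    per_subject = pd.Series(
        {s: float(np.nanmean(dist[s])) if not np.all(np.isnan(dist[s])) else np.nan
         for s in subjects},
        name=f"permuted_{statistic}",
    )
    per_subject.index.name = "subject_id"
    table = pd.DataFrame(dist).T if keep_distribution else None
    return PermutationNull(statistic, n_perm, seed, per_subject, table)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


@dataclass
class WilcoxonResult:
    """One-sample / paired Wilcoxon signed-rank test.

    ``V`` is the sum of the ranks of the positive differences (the statistic
    R prints); ``method`` is ``exact`` (full 2^n sign enumeration) or
    ``normal_approx`` (tie- and continuity-corrected).
    """

    V: float
    n_used: int
    p_two_sided: float
    method: str

    def summary(self) -> str:
        return (
            f"Wilcoxon signed-rank: V = {self.V:g}, n = {self.n_used}, "
            f"p = {self.p_two_sided:.4g} ({self.method})"
        )


def _exact_v_distribution(ranks: np.ndarray) -> np.ndarray:
    """Counts of each value of V over all 2^n sign assignments (integer ranks)."""
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(diffs, exact_max_n: int = 25) -> WilcoxonResult:
    """Wilcoxon signed-rank test of the differences against zero.

    Zeros are dropped; |diffs| are ranked with average ties. The exact
    two-sided p comes from full sign enumeration when n <= ``exact_max_n``
    and the ranks are untied; otherwise a normal approximation with tie and
    continuity corrections is used.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: Wilcoxon test undefined")
    ranks = stats.rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= exact_max_n and not has_ties:
        counts = _exact_v_distribution(ranks)
        total = counts.sum()
        v_int = int(round(V))
        p_le = counts[: v_int + 1].sum() / total
        p_ge = counts[v_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(V, n, float(p), "exact")
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return WilcoxonResult(V, n, 1.0, "normal_approx")
    delta = V - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)  # continuity correction
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(V, n, p, "normal_approx")


def compare_observed_to_null(
    observed: pd.Series,
    null: PermutationNull,
    target: str = "per_subject",
) -> WilcoxonResult:
    """Wilcoxon test of observed values against the permutation chance level.

    ``target='per_subject'`` pairs each subject with their own permuted mean;
    ``target='group'`` tests everyone against the group-level permuted mean.
    """
    permuted = null.per_subject_mean
    joined = pd.concat([observed.rename("obs"), permuted.rename("perm")], axis=1).dropna()
    if target == "per_subject":
        diffs = joined["obs"] - joined["perm"]
    elif target == "group":
        diffs = joined["obs"] - null.group_mean
    else:
        raise ValueError("target must be 'per_subject' or 'group'")
    return wilcoxon_signed_rank(diffs.to_numpy())


# ---------------------------------------------------------------------------
# one-way repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class RmAnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float

    def summary(self) -> str:
        return (
            f"RM-ANOVA: F({self.df1}, {self.df2}) = {self.F:.3f}, "
            f"p = {self.p:.4g}, partial eta^2 = {self.partial_eta_sq:.3f}"
        )


def rm_anova_oneway(scores) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a complete subject x condition matrix.

    F = MS_condition / MS_(condition x subject); partial eta squared =
    SS_condition / (SS_condition + SS_error). No sphericity correction.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValueError("scores must be a 2-D subject x condition matrix")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.isnan(X).any():
        raise ValueError("missing cells are not allowed (no imputation)")
    grand = X.mean()
    ss_cond = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ms_cond == 0 else np.inf)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return RmAnovaResult(float(F), df1, df2, p, float(eta))


# ---------------------------------------------------------------------------
# sign-flip interaction test
# ---------------------------------------------------------------------------


@dataclass
class SignFlipResult:
    statistic: float
    p: float
    n_perm: int
    seed: int
    n_subjects: int


def interaction_signflip_test(
    props: SubjectConditionTable | pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> SignFlipResult:
    """Nonparametric reward x list-composition interaction test.

    The per-subject statistic is (mixed_high - mixed_low) - (pure_high -
    pure_low); its group mean is compared to a null built by independent
    random sign flips of each subject's statistic. Two-sided Monte-Carlo p
    with the +1 correction.
    """
    data = props.data if isinstance(props, SubjectConditionTable) else props
    data = data[list(CONDITIONS)].dropna()
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 subjects with complete cells")
    per_subj = (
        (data["mixed_high"] - data["mixed_low"])
        - (data["pure_high"] - data["pure_low"])
    ).to_numpy()
    obs = per_subj.mean()
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    perm = (signs * per_subj).mean(axis=1)
    p = (np.count_nonzero(np.abs(perm) >= abs(obs)) + 1) / (n_perm + 1)
    return SignFlipResult(float(obs), float(p), n_perm, seed, n)


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------


@dataclass
class PowerSpec:
    eta_p_sq: float | None = None
    dz: float | None = None
    alpha: float = 0.05
    power: float = 0.90

    def effect_dz(self) -> float:
        if self.dz is not None:
            return float(self.dz)
        if self.eta_p_sq is None or not 0 < self.eta_p_sq < 1:
            raise ValueError("eta_p_sq must lie in (0, 1) when dz is not given")
        return float(np.sqrt(self.eta_p_sq / (1.0 - self.eta_p_sq)))


def power_paired_t(n: float, dz: float, alpha: float = 0.05) -> float:
    """Two-sided power of a paired/one-sample t-test at effect size dz."""
    df = n - 1
    ncp = dz * np.sqrt(n)
    tc = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))


def required_sample_size(
    spec: PowerSpec | None = None,
    *,
    eta_p_sq: float | None = None,
    dz: float | None = None,
    power: float = 0.90,
    alpha: float = 0.05,
    conservative: bool = False,
) -> int:
    """Sample size for a two-sided within-subject (paired-t) contrast.

    The effect is dz = sqrt(eta_p_sq / (1 - eta_p_sq)) when given as a
    partial eta squared. By default the continuous solution of
    power(n) = target is rounded to the nearest integer, matching the
    convention of the standard power calculators whose reported n users
    round; ``conservative=True`` instead returns the smallest integer n whose
    achieved power is at least the target.
    """
    if spec is None:
        spec = PowerSpec(eta_p_sq=eta_p_sq, dz=dz, alpha=alpha, power=power)
    d = spec.effect_dz()
    if not 0 < spec.power < 1:
        raise ValueError("power must lie in (0, 1)")
    if d <= 0:
        raise ValueError("effect size must be positive")
    lo, hi = 2.0, 10.0
    if power_paired_t(lo, d, spec.alpha) >= spec.power:
        return 2
    while power_paired_t(hi, d, spec.alpha) < spec.power:
        hi *= 2
        if hi > 1e7:
            raise ValueError("requested power unattainable at this effect size")
    n_cont = optimize.brentq(
        lambda n: power_paired_t(n, d, spec.alpha) - spec.power, lo, hi, xtol=1e-6
    )
    if conservative:
        n_int = int(np.ceil(n_cont - 1e-9))
        while power_paired_t(n_int, d, spec.alpha) < spec.power:
            n_int += 1
        return max(n_int, 2)
    return max(int(round(n_cont)), 2)
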
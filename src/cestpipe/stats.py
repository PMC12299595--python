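"""ROI summarization and group-level statistics for APTw maps.

The statistical unit is the per-subject hippocampal average: the mean of
the left- and right-ROI mean APTw values.  Group differences are assessed
with a one-way ANOVA followed by Tukey HSD pairwise comparisons
(studentized-range based); per-group normality is checked with a
Lilliefors-corrected Kolmogorov-Smirnov test (parameters are estimated
from the data, so the uncorrected KS null distribution would be wrong);
left/right laterality is checked per group with independent two-sample
t-tests (pooled variance by default, Welch by flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .aptw import APTwMap
from .errors import DataError, StatsError
from .io import PipelineConfig, ROIMaskSet

__all__ = [
    "SubjectROISummary",
    "GroupComparison",
    "summarize_roi",
    "summaries_to_frame",
    "compare_groups",
    "power_experiment",
]

log = logging.getLogger(__name__)

AVG_LABEL = "avg"
DEFAULT_ROI_LABELS = ("left_hippocampus", "right_hippocampus")


@dataclass(frozen=True)
class SubjectROISummary:
    """Mean APTw over the valid voxels of one ROI of one subject."""

    subject_id: str
    group: str
    roi: str
    mean_aptw_percent: float
    n_valid_voxels: int


@dataclass
class GroupComparison:
    """The full statistical battery over one cohort."""

    groups: tuple[str, ...]
    anova_F: float
    anova_p: float
    pairwise: dict[tuple[str, str], float]  # Tukey-adjusted p per pair
    normality_p: dict[str, float]  # Lilliefors KS p per group
    lr_tests: dict[str, float]  # left-vs-right t-test p per group
    alpha: float = 0.05
    group_means: dict[str, float] = field(default_factory=dict)
    group_sds: dict[str, float] = field(default_factory=dict)

    @property
    def significant_pairs(self) -> dict[tuple[str, str], bool]:
        return {pair: p < self.alpha for pair, p in self.pairwise.items()}

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "anova_F": self.anova_F,
            "anova_p": self.anova_p,
            "alpha": self.alpha,
            "pairwise_tukey_p": {
                f"{a}|{b}": p for (a, b), p in self.pairwise.items()
            },
            "significant_pairs": {
                f"{a}|{b}": bool(s)
                for (a, b), s in self.significant_pairs.items()
            },
            "normality_lilliefors_p": self.normality_p,
            "left_right_ttest_p": self.lr_tests,
            "group_means": self.group_means,
            "group_sds": self.group_sds,
        }


def summarize_roi(
    aptw: APTwMap,
    masks: ROIMaskSet,
    subject_id: str,
    group: str,
    roi_labels: Sequence[str] = DEFAULT_ROI_LABELS,
) -> list[SubjectROISummary]:
    """Per-ROI mean APTw over valid voxels, plus the left/right average.

    The average entry (roi = "avg") is the mean of the ROI means, the
    per-subject statistic used for group comparisons.  An ROI with no valid
    voxels is recorded as missing (skipped) with a warning.
    """
    if masks.shape != aptw.shape:
        raise DataError("mask shape does not match map shape")
    out: list[SubjectROISummary] = []
    roi_means = []
    for label in roi_labels:
        if label not in masks:
            raise DataError(f"mask set lacks ROI '{label}'")
        vals = aptw.values(masks[label])
        if vals.size == 0:
            log.warning(
                "subject %s ROI %s has no valid voxels; recorded as missing",
                subject_id, label,
            )
            continue
        out.append(
            SubjectROISummary(
                subject_id, group, label, float(vals.mean()), int(vals.size)
            )
        )
        roi_means.append((float(vals.mean()), int(vals.size)))
    if roi_means:
        out.append(
            SubjectROISummary(
                subject_id,
                group,
                AVG_LABEL,
                float(np.mean([m for m, _ in roi_means])),
                int(sum(n for _, n in roi_means)),
            )
        )
    return out


def summaries_to_frame(
    summaries: Iterable[SubjectROISummary],
) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "roi": s.roi,
            "mean_aptw_percent": s.mean_aptw_percent,
            "n_valid_voxels": s.n_valid_voxels,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def _avg_by_group(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    avg = frame[frame["roi"] == AVG_LABEL]
    return {
        g: sub["mean_aptw_percent"].to_numpy()
        for g, sub in avg.groupby("group", sort=True)
    }


def compare_groups(
    summaries: Iterable[SubjectROISummary] | pd.DataFrame,
    alpha: float = 0.05,
    welch: bool = False,
) -> GroupComparison:
    """One-way ANOVA + Tukey HSD + normality + laterality tests.

    Requires at least two groups with at least two subjects each.
    """
    frame = (
        summaries
        if isinstance(summaries, pd.DataFrame)
        else summaries_to_frame(summaries)
    )
    by_group = _avg_by_group(frame)
    if len(by_group) < 2:
        raise StatsError("need at least two groups")
    for g, vals in by_group.items():
        if vals.size < 2:
            raise StatsError(f"group '{g}' has fewer than two subjects")

    names = tuple(sorted(by_group))
    samples = [by_group[g] for g in names]
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        # identical, constant groups: no variance anywhere -> no evidence
        anova_F, anova_p = 0.0, 1.0
    else:
        anova = sps.f_oneway(*samples)
        anova_F, anova_p = float(anova.statistic), float(anova.pvalue)

    tukey = sps.tukey_hsd(*samples)
    pairwise: dict[tuple[str, str], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise[(names[i], names[j])] = float(tukey.pvalue[i, j])

    normality: dict[str, float] = {}
    for g in names:
        vals = by_group[g]
        if vals.size >= 4 and np.ptp(vals) > 0:
            _, p = lilliefors(vals, dist="norm", pvalmethod="table")
            normality[g] = float(p)
        else:
            normality[g] = float("nan")

    lr: dict[str, float] = {}
    left = frame[frame["roi"] == "left_hippocampus"]
    right = frame[frame["roi"] == "right_hippocampus"]
    for g in names:
        lv = left[left["group"] == g]["mean_aptw_percent"].to_numpy()
        rv = right[right["group"] == g]["mean_aptw_percent"].to_numpy()
        if lv.size >= 2 and rv.size >= 2:
            res = sps.ttest_ind(lv, rv, equal_var=not welch)
            lr[g] = float(res.pvalue)
        else:
            lr[g] = float("nan")

    return GroupComparison(
        groups=names,
        anova_F=anova_F,
        anova_p=anova_p,
        pairwise=pairwise,
        normality_p=normality,
        lr_tests=lr,
        alpha=alpha,
        group_means={g: float(by_group[g].mean()) for g in names},
        group_sds={
            g: float(by_group[g].std(ddof=1)) for g in names
        },
    )


def power_experiment(
    group_specs: Mapping[str, "PhantomSpec"],  # noqa: F821 - forward ref
    n_per_group: int = 7,
    replicates: int = 200,
    base_seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Monte-Carlo rejection rates of the full simulate->process->test chain.

    Each replicate simulates a fresh cohort, runs the complete B0-corrected
    APTw pipeline on every subject, and applies :func:`compare_groups`.
    Returns the ANOVA rejection rate and, per group pair, the fraction of
    replicates with Tukey-adjusted p below alpha.
    """
    from .pipeline import analyze_cohort  # local import: avoids a cycle

    config = config or PipelineConfig()
    seeds = np.random.default_rng(base_seed).integers(
        0, 2**31 - 1, size=replicates
    )
    anova_rejects = 0
    pair_rejects: dict[tuple[str, str], int] = {}
    for seed in seeds:
        comparison = analyze_cohort(
            group_specs, n_per_group, int(seed), config
        ).comparison
        if comparison.anova_p < config.alpha:
            anova_rejects += 1
        for pair, p in comparison.pairwise.items():
            pair_rejects[pair] = pair_rejects.get(pair, 0) + (p < config.alpha)
    return {
        "replicates": replicates,
        "alpha": config.alpha,
        "anova_rejection_rate": anova_rejects / replicates,
        "pairwise_rejection_rate": {
            pair: count / replicates for pair, count in pair_rejects.items()
        },
    }


def effect_pattern_rate(
    group_specs: Mapping[str, "PhantomSpec"],  # noqa: F821 - forward ref
    significant_pairs: set[tuple[str, str]],
    n_per_group: int = 7,
    replicates: int = 200,
    base_seed: int = 0,
    config: PipelineConfig | None = None,
) -> float:
    """Fraction of simulated cohorts reproducing an exact significance pattern.

    A replicate counts as a success when the set of group pairs with
    Tukey-adjusted p below alpha equals ``significant_pairs`` exactly
    (pairs given as sorted label tuples).
    """
    from .pipeline import analyze_cohort

    config = config or PipelineConfig()
    expected = {tuple(sorted(p)) for p in significant_pairs}
    seeds = np.random.default_rng(base_seed).integers(
        0, 2**31 - 1, size=replicates
    )
    hits = 0
    for seed in seeds:
        comparison = analyze_cohort(
            group_specs, n_per_group, int(seed), config
        ).comparison
        observed = {
            pair for pair, p in comparison.pairwise.items()
            if p < config.alpha
        }
        hits += observed == expected
    return hits / replicates
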
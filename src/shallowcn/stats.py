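"""Rank-based cohort statistics and ROC/AUC.

Tests are two-sided throughout. Exact null enumeration is used at small
sample sizes without ties (rank-sum: min group size <= 8; signed-rank:
<= 12 non-zero pairs); midrank normal approximations with continuity
correction otherwise. AUC is the probability that a random positive
outranks a random negative, with half credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_RANKSUM_MAX_N = 8
EXACT_SIGNRANK_MAX_N = 12


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    group_summaries: list[GroupSummary] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0,1]")


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


def _summarize(*groups) -> list[GroupSummary]:
    out = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        out.append(
            GroupSummary(
                n=len(g),
                mean=float(np.mean(g)),
                sd=float(np.std(g, ddof=1)) if len(g) > 1 else 0.0,
                median=float(np.median(g)),
            )
        )
    return out


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def rank_sum_test(a, b) -> TestResult:
    """Two-sided Mann-Whitney / Wilcoxon rank-sum test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not len(a) or not len(b):
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        u = len(a) * len(b) / 2.0
        return TestResult("mann_whitney_u", u, 1.0, _summarize(a, b))
    exact = min(len(a), len(b)) <= EXACT_RANKSUM_MAX_N and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        "mann_whitney_u",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        _summarize(a, b),
        extra={"method": method},
    )


def paired_signed_rank(pre, post) -> TestResult:
    """Two-sided Wilcoxon signed-rank on paired samples; zero diffs dropped."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post):
        raise ValueError("paired test requires equal-length inputs")
    diff = post - pre
    n_zero = int(np.sum(diff == 0))
    nz = diff[diff != 0]
    if len(nz) == 0:
        return TestResult(
            "wilcoxon_signed_rank", 0.0, 1.0, _summarize(pre, post), extra={"n_zero": n_zero}
        )
    exact = len(nz) <= EXACT_SIGNRANK_MAX_N and not _has_ties(np.abs(nz))
    method = "exact" if exact else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method, correction=True)
    return TestResult(
        "wilcoxon_signed_rank",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        _summarize(pre, post),
        extra={"n_zero": n_zero, "method": method},
    )


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal-Wallis H with midrank ties correction; chi-square p, k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    if np.ptp(np.concatenate(arrays)) == 0:
        return TestResult("kruskal_wallis", 0.0, 1.0, _summarize(*arrays))
    h, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), float(p), _summarize(*arrays))


def roc_auc(scores, labels) -> RocResult:
    """AUC by pair counting (ties get half credit) plus the threshold curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if not len(pos) or not len(neg):
        raise ValueError("both classes must be present")
    # rank identity: AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg)
    ranks = sps.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    auc = (r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg))
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocResult(auc=float(auc), thresholds=thresholds, sensitivity=sens, specificity=spec)


def load_cohort_table(path) -> pd.DataFrame:
    """Read the cohort table: dog_id, sample_id, group, timepoint, tumor_fraction."""
    df = pd.read_csv(path, sep="\t")
    required = {"dog_id", "sample_id", "group", "timepoint", "tumor_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


def cohort_report(df: pd.DataFrame) -> dict:
    """Group comparison, paired pre/post test and ROC on a cohort table.

    Uses the earliest pre-surgery sample per dog for the between-group and
    ROC analyses (rows are assumed in collection order within a dog).
    """
    pre = df[df["timepoint"] == "pre"].groupby("dog_id", sort=False).first().reset_index()
    benign = pre.loc[pre["group"] == "benign", "tumor_fraction"].to_numpy()
    malignant = pre.loc[pre["group"] == "malignant", "tumor_fraction"].to_numpy()
    report: dict = {}
    if len(benign) and len(malignant):
        rs = rank_sum_test(benign, malignant)
        roc = roc_auc(
            np.concatenate([benign, malignant]),
            np.concatenate([np.zeros(len(benign), int), np.ones(len(malignant), int)]),
        )
        report["benign_vs_malignant"] = {
            "p_value": rs.p_value,
            "statistic": rs.statistic,
            "mean_benign": float(np.mean(benign)),
            "mean_malignant": float(np.mean(malignant)),
        }
        report["roc_auc"] = roc.auc
    mal = df[df["group"] == "malignant"]
    pre_post = mal.pivot_table(
        index="dog_id", columns="timepoint", values="tumor_fraction", aggfunc="first"
    )
    if {"pre", "post"} <= set(pre_post.columns):
        paired = pre_post.dropna(subset=["pre", "post"])
        if len(paired):
            sr = paired_signed_rank(paired["pre"].to_numpy(), paired["post"].to_numpy())
            report["pre_vs_post_surgery"] = {
                "p_value": sr.p_value,
                "statistic": sr.statistic,
                "mean_pre": float(paired["pre"].mean()),
                "mean_post": float(paired["post"].mean()),
                "n_pairs": int(len(paired)),
            }
    return report
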
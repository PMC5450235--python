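"""Descriptive statistics and significance tests across location groups.

Reproduces the study-style group comparison: per-group mean ± s.e.m.
and five-number summary (box-and-whisker convention: box = 25th–75th
percentile, whiskers = sample range, linear-interpolation quantiles),
plus pairwise two-tailed unpaired Student t-tests with star annotation
(* p<0.05, ** p<0.01, *** p<0.001).  Pooled-variance Student is the
default, matching the Prism-style "unpaired t-test"; Welch is available
behind a flag.  No multiple-testing correction is applied — pairs are
reported individually, as in the source analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "GROUP_ORDER",
    "stars_for",
    "group_summary",
    "unpaired_t_test",
    "compare_groups",
    "summaries_frame",
]

#: Deterministic presentation order of localization groups.
GROUP_ORDER = ("PO", "PO_MITO", "MITO", "ER")


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float | None  # undefined for n = 1
    min: float
    q1: float
    median: float
    q3: float
    max: float


@dataclass(frozen=True)
class TestResult:
    t: float
    df: float
    p: float
    stars: str


def stars_for(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_summary(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean, s.e.m. and five-number summary of one group (n >= 1)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty group")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in group")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    sem = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size >= 2 else None
    return GroupSummary(
        label=label,
        n=int(x.size),
        mean=float(x.mean()),
        sem=sem,
        min=float(x.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(x.max()),
    )


def unpaired_t_test(
    a: Sequence[float], b: Sequence[float], *, welch: bool = False
) -> TestResult:
    """Two-tailed unpaired t-test (pooled-variance Student by default).

    Degenerate case: zero pooled variance with equal means gives
    t = 0, p = 1; zero pooled variance with unequal means is an error
    (the statistic is undefined).
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = xa.size, xb.size
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    diff = xa.mean() - xb.mean()
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0.0:
            if diff == 0.0:
                return TestResult(t=0.0, df=float(na + nb - 2), p=1.0, stars="ns")
            raise ValueError("zero variance with unequal means: t undefined")
        t = diff / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0.0:
            if diff == 0.0:
                return TestResult(t=0.0, df=df, p=1.0, stars="ns")
            raise ValueError("zero pooled variance with unequal means: t undefined")
        t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(t=float(t), df=float(df), p=p, stars=stars_for(p))


def _ordered_groups(labels: Sequence[str]) -> list[str]:
    present = list(dict.fromkeys(labels))
    ordered = [g for g in GROUP_ORDER if g in present]
    ordered += sorted(g for g in present if g not in GROUP_ORDER)
    return ordered


def compare_groups(
    features: pd.DataFrame,
    feature_name: str,
    *,
    label_col: str = "location",
    welch: bool = False,
) -> tuple[list[GroupSummary], pd.DataFrame]:
    """Per-group summaries plus all pairwise t-tests for one feature.

    *features* is a DataFrame with a label column and the feature
    column; groups are ordered PO, PO_MITO, MITO, ER (then any others
    alphabetically).  Returns ``(summaries, pairwise)`` where *pairwise*
    has columns ``group_a, group_b, t, df, p, stars``.
    """
    if feature_name not in features.columns:
        raise KeyError(f"unknown feature {feature_name!r}")
    if label_col not in features.columns:
        raise KeyError(f"missing label column {label_col!r}")
    clean = features.dropna(subset=[feature_name])
    groups = _ordered_groups(clean[label_col])
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    by_group = {
        g: clean.loc[clean[label_col] == g, feature_name].to_numpy(dtype=float)
        for g in groups
    }
    summaries = [group_summary(by_group[g], g) for g in groups]
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            if len(by_group[ga]) < 2 or len(by_group[gb]) < 2:
                continue
            res = unpaired_t_test(by_group[ga], by_group[gb], welch=welch)
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "stars": res.stars,
                }
            )
    return summaries, pd.DataFrame(rows, columns=["group_a", "group_b", "t", "df", "p", "stars"])


def summaries_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Plot-ready table of group summaries (one row per group)."""
    return pd.DataFrame(
        [
            {
                "group": s.label,
                "n": s.n,
                "mean": s.mean,
                "sem": s.sem if s.sem is not None else "",
                "min": s.min,
                "q1": s.q1,
                "median": s.median,
                "q3": s.q3,
                "max": s.max,
            }
            for s in summaries
        ]
    )
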
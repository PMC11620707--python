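"""ROI-mean follow-up ANOVA and behavioral condition summaries.

The 2x2 within-subject ANOVA (Semantic Category x Priming) is computed from
per-subject 1-df contrasts tested with one-sample t statistics (F = t^2,
df (1, n-1)), which is exact for this design; post hoc paired comparisons
are Benjamini-Hochberg corrected within the requested family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import PatternMatrix
from .similarity import fdr_adjust
from .synth import CONDITIONS

#: Default post hoc family: the four simple effects.
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("ToolUnprimed", "ToolPrimed"),
    ("AnimalUnprimed", "AnimalPrimed"),
    ("ToolUnprimed", "AnimalUnprimed"),
    ("ToolPrimed", "AnimalPrimed"),
)

#: Per-subject contrast weights over (TP, TU, AP, AU) defining each 1-df effect.
EFFECT_CONTRASTS: dict[str, dict[str, float]] = {
    "SemanticCategory": {"ToolPrimed": 0.5, "ToolUnprimed": 0.5,
                         "AnimalPrimed": -0.5, "AnimalUnprimed": -0.5},
    "Priming": {"ToolUnprimed": 0.5, "AnimalUnprimed": 0.5,
                "ToolPrimed": -0.5, "AnimalPrimed": -0.5},
    "Interaction": {"ToolUnprimed": 1.0, "ToolPrimed": -1.0,
                    "AnimalUnprimed": -1.0, "AnimalPrimed": 1.0},
}


def roi_means(patterns: PatternMatrix | np.ndarray,
              condition_order: Sequence[str] = CONDITIONS,
              subjects: Sequence | None = None) -> pd.DataFrame:
    """Per subject/condition arithmetic mean of the pattern values over the
    ROI voxels; returns a subjects x conditions table."""
    if isinstance(patterns, PatternMatrix):
        data = patterns.data
        condition_order = patterns.condition_order
        subjects = patterns.subjects
    else:
        data = np.asarray(patterns, dtype=float)
        if subjects is None:
            subjects = list(range(data.shape[0]))
    return pd.DataFrame(data.mean(axis=2), index=list(subjects),
                        columns=list(condition_order))


@dataclass
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    condition_means: pd.DataFrame  # condition -> mean, sem
    posthoc: pd.DataFrame | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"effect": name, "F": e.F, "df_num": e.df_num,
                 "df_den": e.df_den, "p": e.p}
                for name, e in self.effects.items()]
        return pd.DataFrame(rows)


def _one_sample(values: np.ndarray) -> tuple[float, float]:
    """(t, two-sided p) for a one-sample test against zero; degenerate
    zero-variance input yields t = 0 / p = 1 when all values are zero and
    NaN (flagged undefined) otherwise."""
    n = values.size
    sd = values.std(ddof=1)
    if sd == 0:
        if np.allclose(values, 0):
            return 0.0, 1.0
        return float("nan"), float("nan")
    t = values.mean() / (sd / np.sqrt(n))
    return float(t), float(2 * stats.t.sf(abs(t), df=n - 1))


def rm_anova_2x2(table: pd.DataFrame) -> AnovaResult:
    """2x2 repeated-measures ANOVA via per-subject 1-df contrasts.

    Each effect (SemanticCategory, Priming, Interaction) is the one-sample t
    of the corresponding subject contrast; F = t^2 with df (1, n-1) and a
    two-sided p.
    """
    missing = [c for c in CONDITIONS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing conditions: {missing}")
    n = len(table)
    if n < 2:
        raise ValueError("ANOVA requires >= 2 subjects")
    effects = {}
    for name, weights in EFFECT_CONTRASTS.items():
        v = sum(w * table[c].to_numpy() for c, w in weights.items())
        t, p = _one_sample(np.asarray(v, dtype=float))
        effects[name] = EffectResult(F=t * t, df_num=1, df_den=n - 1, p=p)
    means = pd.DataFrame({
        "mean": table[list(CONDITIONS)].mean(),
        "sem": table[list(CONDITIONS)].std(ddof=1) / np.sqrt(n),
    })
    return AnovaResult(effects=effects, condition_means=means)


def posthoc_paired(table: pd.DataFrame,
                   comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
                   ) -> pd.DataFrame:
    """Paired t tests for the requested condition pairs with BH-FDR
    adjustment across the supplied comparison family."""
    rows = []
    for a, b in comparisons:
        for c in (a, b):
            if c not in table.columns:
                raise ValueError(f"unknown condition label {c!r}")
        diff = table[a].to_numpy(dtype=float) - table[b].to_numpy(dtype=float)
        t, p = _one_sample(diff)
        rows.append({"condition_a": a, "condition_b": b,
                     "mean_difference": float(diff.mean()), "t": t, "p_raw": p})
    df = pd.DataFrame(rows)
    valid = df["p_raw"].notna()
    adjusted = np.full(len(df), np.nan)
    if valid.any():
        adjusted[valid.to_numpy()] = fdr_adjust(df.loc[valid, "p_raw"].to_numpy())
    df["p_fdr"] = adjusted
    return df


def summarize_behavior(records: pd.DataFrame) -> pd.DataFrame:
    """Condition summaries: mean RT over correct trials and accuracy %,
    both as means +/- SEM over per-subject values.

    Conditions without any analyzable data are reported with missing values
    rather than dropped.
    """
    if records.empty:
        raise ValueError("no behavioral records supplied")
    rows = []
    for cond, sub in records.groupby("condition", sort=False):
        correct = sub[(sub["accuracy"] == 1) & sub["rt_ms"].notna()]
        rt_by_subject = correct.groupby("subject")["rt_ms"].mean()
        acc_by_subject = sub.groupby("subject")["accuracy"].mean() * 100.0
        n_rt = len(rt_by_subject)
        rows.append({
            "condition": cond,
            "n_subjects": sub["subject"].nunique(),
            "rt_mean_ms": rt_by_subject.mean() if n_rt else np.nan,
            "rt_sem_ms": (rt_by_subject.std(ddof=1) / np.sqrt(n_rt)
                          if n_rt > 1 else np.nan),
            "accuracy_pct": acc_by_subject.mean(),
            "accuracy_sem_pct": (acc_by_subject.std(ddof=1)
                                 / np.sqrt(len(acc_by_subject))
                                 if len(acc_by_subject) > 1 else np.nan),
        })
    return pd.DataFrame(rows)


def priming_differences(records: pd.DataFrame) -> pd.DataFrame:
    """Within-subject unprimed-minus-primed RT difference per category."""
    correct = records[(records["accuracy"] == 1) & records["rt_ms"].notna()]
    pivot = correct.pivot_table(index="subject", columns="condition",
                                values="rt_ms", aggfunc="mean")
    rows = []
    for category, (unprimed, primed) in (
            ("tool", ("ToolUnprimed", "ToolPrimed")),
            ("animal", ("AnimalUnprimed", "AnimalPrimed"))):
        if unprimed in pivot.columns and primed in pivot.columns:
            diff = (pivot[unprimed] - pivot[primed]).dropna()
            rows.append({
                "category": category,
                "n_subjects": len(diff),
                "priming_effect_ms": diff.mean(),
                "sem_ms": diff.std(ddof=1) / np.sqrt(len(diff)) if len(diff) > 1
                          else np.nan,
            })
        else:
            rows.append({"category": category, "n_subjects": 0,
                         "priming_effect_ms": np.nan, "sem_ms": np.nan})
    return pd.DataFrame(rows)
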
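"""Cosine-similarity category decoding with sign-flip permutation inference.

For each subject, the six condition-pair cosine similarities are reduced to
within- minus across-category contrast scores; the group mean score is
tested against zero with a right-tailed sign-flip permutation test and
Benjamini-Hochberg FDR correction across ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .patterns import PatternMatrix
from .synth import CONDITIONS

#: The six unordered condition pairs, in the fixed reporting order.
PAIRS: tuple[tuple[str, str], ...] = (
    ("ToolPrimed", "ToolUnprimed"),
    ("AnimalPrimed", "AnimalUnprimed"),
    ("ToolPrimed", "AnimalPrimed"),
    ("AnimalUnprimed", "ToolUnprimed"),
    ("ToolPrimed", "AnimalUnprimed"),
    ("AnimalPrimed", "ToolUnprimed"),
)
PAIR_LABELS: tuple[str, ...] = tuple(f"{a}/{b}" for a, b in PAIRS)
WITHIN_PAIRS: tuple[str, ...] = PAIR_LABELS[:2]
ACROSS_PAIRS: tuple[str, ...] = PAIR_LABELS[2:]

EXHAUSTIVE_LIMIT = 20  # 2^n null assignments beyond this is refused


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Sum(x_i y_i) / (||x|| ||y||), in [-1, 1]; symmetric in x and y."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 1:
        raise ValueError("inputs must be equal-length vectors of length >= 1")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm input to cosine similarity")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def pairwise_similarities(patterns: PatternMatrix | np.ndarray,
                          condition_order: Sequence[str] = CONDITIONS,
                          subjects: Sequence | None = None) -> pd.DataFrame:
    """Per-subject cosine similarities for the six condition pairs.

    Returns a DataFrame indexed by subject with one column per pair label.
    """
    if isinstance(patterns, PatternMatrix):
        data = patterns.data
        condition_order = patterns.condition_order
        subjects = patterns.subjects
    else:
        data = np.asarray(patterns, dtype=float)
        if subjects is None:
            subjects = list(range(data.shape[0]))
    pos = {c: i for i, c in enumerate(condition_order)}
    table = np.empty((data.shape[0], len(PAIRS)))
    for s in range(data.shape[0]):
        for k, (a, b) in enumerate(PAIRS):
            try:
                table[s, k] = cosine_similarity(data[s, pos[a]], data[s, pos[b]])
            except ValueError as err:
                raise ValueError(
                    f"subject {subjects[s]!r}, pair {a}/{b}: {err}") from err
    return pd.DataFrame(table, index=list(subjects), columns=list(PAIR_LABELS))


def contrast_weights(contrast_id: int, literal_three: bool = False,
                     ) -> dict[str, float]:
    """Weight vector over the six pair similarities for contrasts 1-3.

    Contrast 1: mean within-category minus mean across-category similarity.
    Contrast 2: tool within-pair minus the mean of the five other pairs.
    Contrast 3: animal within-pair minus the five other pairs; the
    ``literal_three`` variant subtracts only four pairs (omitting
    AnimalPrimed/ToolUnprimed) while keeping the divisor of 5, and its
    weights do not sum to zero.
    """
    tp_tu, ap_au = WITHIN_PAIRS
    if contrast_id == 1:
        w = {p: -0.25 for p in ACROSS_PAIRS}
        w[tp_tu] = 0.5
        w[ap_au] = 0.5
    elif contrast_id == 2:
        w = {p: -0.2 for p in ACROSS_PAIRS}
        w[ap_au] = -0.2
        w[tp_tu] = 1.0
    elif contrast_id == 3:
        if literal_three:
            w = {p: -0.2 for p in ACROSS_PAIRS if p != "AnimalPrimed/ToolUnprimed"}
            w[tp_tu] = -0.2
            w[ap_au] = 1.0
        else:
            w = {p: -0.2 for p in ACROSS_PAIRS}
            w[tp_tu] = -0.2
            w[ap_au] = 1.0
    else:
        raise ValueError(f"unknown contrast id {contrast_id!r} (expected 1, 2 or 3)")
    if not literal_three:
        assert abs(sum(w.values())) < 1e-12, "contrast weights must sum to zero"
    return w


def contrast_score(table: pd.DataFrame, contrast_id: int,
                   literal_three: bool = False) -> np.ndarray:
    """Per-subject contrast scores from a six-pair similarity table."""
    missing = [p for p in PAIR_LABELS if p not in table.columns]
    if missing:
        raise ValueError(f"similarity table is missing pairs: {missing}")
    w = contrast_weights(contrast_id, literal_three=literal_three)
    vec = np.array([w.get(p, 0.0) for p in PAIR_LABELS])
    return table[list(PAIR_LABELS)].to_numpy() @ vec


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_uncorrected: float
    n_permutations: int
    seed: int
    p_fdr: float | None = None


def sign_flip_test(scores: Sequence[float], n_permutations: int = 10000,
                   seed: int = 0, exhaustive: bool = False) -> PermutationResult:
    """Right-tailed group-level sign-flip permutation test.

    The statistic is the unweighted group mean of subject scores; the null
    is the distribution of that mean under random (or, when ``exhaustive``,
    all 2^n) sign assignments. p = (1 + #{null >= observed}) / (1 + N), so
    p is always in (0, 1] and ties count against significance.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 2:
        raise ValueError("sign-flip test requires >= 2 subjects")
    observed = float(scores.mean())
    if exhaustive:
        if n > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration of 2^{n} sign assignments refused "
                f"(limit n <= {EXHAUSTIVE_LIMIT})")
        codes = np.arange(2 ** n, dtype=np.int64)
        signs = 1 - 2 * ((codes[:, None] >> np.arange(n)) & 1)
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1, 1), size=(n_permutations, n))
    null = (signs * scores).mean(axis=1)
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + null.size)
    return PermutationResult(observed=observed, null=null, p_uncorrected=float(p),
                             n_permutations=int(null.size), seed=seed)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, >= raw, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_mvpa(patterns_by_roi: Mapping[str, PatternMatrix | np.ndarray],
             contrasts: Sequence[int] = (1, 2, 3),
             n_permutations: int = 10000, seed: int = 0,
             literal_three: bool = False,
             return_results: bool = False):
    """Similarity contrasts with sign-flip inference for every ROI.

    FDR correction is applied across the ROIs tested within each contrast
    family. Returns a tidy DataFrame (and, when ``return_results``, the
    underlying PermutationResult objects keyed by (roi, contrast)).
    """
    if not patterns_by_roi:
        raise ValueError("at least one ROI is required")
    roi_names = list(patterns_by_roi)
    tables = {name: pairwise_similarities(patterns_by_roi[name])
              for name in roi_names}
    children = iter(np.random.SeedSequence(seed).spawn(len(roi_names) * len(contrasts)))
    rows = []
    results: dict[tuple[str, int], PermutationResult] = {}
    for contrast_id in contrasts:
        per_roi = []
        for name in roi_names:
            scores = contrast_score(tables[name], contrast_id,
                                    literal_three=literal_three)
            child_seed = int(next(children).generate_state(1)[0] & 0x7FFFFFFF)
            res = sign_flip_test(scores, n_permutations=n_permutations,
                                 seed=child_seed)
            results[(name, contrast_id)] = res
            per_roi.append((name, scores, res))
        adj = fdr_adjust([res.p_uncorrected for _, _, res in per_roi])
        for (name, scores, res), p_fdr in zip(per_roi, adj):
            res.p_fdr = float(p_fdr)
            rows.append({
                "roi": name, "contrast": contrast_id,
                "n_subjects": len(scores),
                "observed_mean": res.observed,
                "sem": float(np.std(scores, ddof=1) / np.sqrt(len(scores))),
                "p_uncorrected": res.p_uncorrected,
                "p_fdr": res.p_fdr,
                "n_permutations": res.n_permutations,
                "seed": res.seed,
            })
    df = pd.DataFrame(rows)
    return (df, results) if return_results else df
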
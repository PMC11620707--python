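"""Seeded synthetic semantic-priming fMRI experiments.

This module generates every input the analysis chain consumes: a rated
lexicon of tool and animal nouns partitioned into matched prime/target
lists, randomized semantic-priming trial sequences, blocked tool-use /
free-hand motor designs, 4D BOLD volumes produced by the same
boxcar-times-HRF forward model the GLM assumes (plus AR(1) noise), voxel
pattern templates with a controllable within- versus across-category
correlation structure, and lexical-decision behavior (RT and accuracy)
with priming and category effects.

Everything is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

# --------------------------------------------------------------------------
# Constants of the experimental design
# --------------------------------------------------------------------------

#: The four word conditions whose voxel patterns enter the similarity analysis,
#: in the fixed order used throughout the package.
CONDITIONS: tuple[str, ...] = (
    "ToolPrimed",
    "ToolUnprimed",
    "AnimalPrimed",
    "AnimalUnprimed",
)
PSEUDOWORD = "Pseudoword"
ALL_CONDITIONS: tuple[str, ...] = CONDITIONS + (PSEUDOWORD,)

PRIME_S = 0.3          # prime display, uppercase
TARGET_S = 0.5         # target display, lowercase
MODELED_S = 0.8        # prime-target association modeled in the GLM
RESPONSE_REMAINDER_S = 1.5  # remaining response window, nuisance regressor
FIXATION_S = 0.5       # fixation dot preceding the prime
DEADLINE_MS = 2000.0   # response deadline from target onset
TR_S = 2.4

#: One motor repetition: planning/execution alternation followed by rest.
MOTOR_TEMPLATE: tuple[tuple[str, float], ...] = (
    ("planning", 4.0),
    ("execution", 4.0),
    ("planning", 4.0),
    ("execution", 4.0),
    ("rest", 10.0),
)
MOTOR_REPETITION_S = sum(d for _, d in MOTOR_TEMPLATE)

N_LISTS_PER_CATEGORY = 5
#: Per category: lists feeding targets vs. primes (2 target + 3 prime lists
#: cover 28 unique targets and 42 prime tokens under the default design).
N_TARGET_LISTS = 2

#: Psycholinguistic variables the lists are matched on.
MATCH_VARIABLES = ("log_frequency", "n_letters", "n_syllables", "n_neighbors")


class LexiconError(ValueError):
    """Raised when a matched lexicon cannot be constructed."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WordItem:
    """A rated (pseudo)word with its psycholinguistic covariates."""

    label: str
    category: str  # tool | animal | pseudoword
    imageability: float | None
    manipulability: float | None
    written_frequency: float
    n_letters: int
    n_syllables: int
    n_neighbors: int


@dataclass
class Lexicon:
    """Words partitioned into matched lists with a prime/target role each."""

    lists: dict[int, tuple[WordItem, ...]]
    roles: dict[int, str]  # list id -> "prime" | "target"

    @property
    def words(self) -> tuple[WordItem, ...]:
        return tuple(w for lid in sorted(self.lists) for w in self.lists[lid])

    def category_words(self, category: str, role: str | None = None) -> list[WordItem]:
        out: list[WordItem] = []
        for lid in sorted(self.lists):
            if role is not None and self.roles[lid] != role:
                continue
            out.extend(w for w in self.lists[lid] if w.category == category)
        return out


@dataclass(frozen=True)
class PrimingTrial:
    index: int
    prime: WordItem
    target: WordItem
    condition: str
    prime_onset: float
    iti: float

    @property
    def target_onset(self) -> float:
        return self.prime_onset + PRIME_S


@dataclass(frozen=True)
class MotorEvent:
    onset: float
    duration: float
    phase: str      # planning | execution | rest
    effector: str   # tool | hand
    missed: bool = False


@dataclass
class BehaviorParams:
    """Lognormal RT model with subject random intercepts.

    ``rt_mean_ms`` are the marginal condition means the generator reproduces
    in expectation; ``sigma_subject``/``sigma_trial`` are log-scale SDs of
    the subject intercept and trial noise; ``error_rate`` are per-condition
    Bernoulli error probabilities. Responses slower than ``deadline_ms``
    are recorded as omissions.
    """

    rt_mean_ms: dict[str, float] = field(default_factory=lambda: {
        "ToolPrimed": 945.0,
        "ToolUnprimed": 1017.0,
        "AnimalPrimed": 901.0,
        "AnimalUnprimed": 962.0,
        PSEUDOWORD: 1050.0,
    })
    sigma_subject: float = 0.195
    sigma_trial: float = 0.15
    error_rate: dict[str, float] = field(default_factory=lambda: {
        "ToolPrimed": 0.037,
        "ToolUnprimed": 0.037,
        "AnimalPrimed": 0.009,
        "AnimalUnprimed": 0.009,
        PSEUDOWORD: 0.05,
    })
    deadline_ms: float = DEADLINE_MS


@dataclass
class GroundTruth:
    """Generating parameters of one synthetic subject/experiment.

    ``condition_amplitude_maps`` maps ROI name -> condition label -> per-voxel
    response amplitudes (a vector over that ROI's voxels, or a scalar applied
    uniformly). ``rho_within``/``rho_across`` record the target correlations
    of the semantic pattern templates; ``mean_offsets`` the per-condition
    uniform activation offsets baked into the maps.
    """

    condition_amplitude_maps: dict[str, dict[str, np.ndarray | float]] = field(
        default_factory=dict)
    rho_within: float = 0.6
    rho_across: float = 0.0
    mean_offsets: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    ar1: float = 0.3
    baseline: float = 100.0
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    #: optional whole-grid, per-condition amplitude fields (3D arrays) on top
    #: of the ROI maps — used for subject-idiosyncratic background activation
    background_amplitude_maps: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho_across <= 1.0 and -1.0 <= self.rho_within <= 1.0):
            raise ValueError("rho_within and rho_across must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SubjectRun:
    """One simulated 4D acquisition (X x Y x Z x T) with its event table."""

    data: np.ndarray
    affine: np.ndarray
    tr: float
    events: pd.DataFrame
    run_type: str  # semantic | motor_tool | motor_hand

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


# --------------------------------------------------------------------------
# Lexicon generation
# --------------------------------------------------------------------------


def _draw_covariates(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {
        "written_frequency": rng.lognormal(mean=1.0, sigma=0.8, size=n),
        "n_letters": 3 + rng.poisson(3.0, size=n),
        "n_syllables": 1 + rng.poisson(1.2, size=n),
        "n_neighbors": rng.poisson(2.5, size=n),
    }


def _draw_category(rng: np.random.Generator, category: str, n: int,
                   threshold: float) -> list[WordItem]:
    """Draw rated candidates and keep the first ``n`` passing the filter."""
    items: list[WordItem] = []
    guard = 0
    while len(items) < n:
        guard += 1
        if guard > 1000:  # pragma: no cover - filter pass rate is ~8-30%
            raise LexiconError(f"could not draw {n} {category} nouns passing "
                               f"the rating filter at threshold {threshold}")
        block = max(4 * n, 64)
        imag = rng.uniform(1.0, 7.0, size=block)
        manip = rng.uniform(1.0, 7.0, size=block)
        cov = _draw_covariates(rng, block)
        for j in range(block):
            if imag[j] < threshold:
                continue
            if category == "tool" and manip[j] < threshold:
                continue
            i = len(items)
            items.append(WordItem(
                label=f"{category}{i:03d}",
                category=category,
                imageability=float(imag[j]),
                manipulability=float(manip[j]),
                written_frequency=float(cov["written_frequency"][j]),
                n_letters=int(cov["n_letters"][j]),
                n_syllables=int(cov["n_syllables"][j]),
                n_neighbors=int(cov["n_neighbors"][j]),
            ))
            if len(items) == n:
                break
    return items


def _match_matrix(items: Sequence[WordItem]) -> np.ndarray:
    return np.array([
        [math.log10(w.written_frequency), w.n_letters, w.n_syllables, w.n_neighbors]
        for w in items
    ], dtype=float)


def _partition_matched(tools: list[WordItem], animals: list[WordItem],
                       rng: np.random.Generator, tol: float,
                       max_swaps: int = 20000) -> tuple[dict[int, tuple[WordItem, ...]], float, int]:
    """Partition each category into 5 lists whose means are matched on every
    psycholinguistic variable to within ``tol`` pooled SDs.

    Starts from a serpentine deal over a randomized composite ordering, then
    hill-climbs within-category item swaps on a blended spread objective.
    Returns (lists, worst spread in pooled-SD units, worst variable index).
    """
    values = np.vstack([_match_matrix(tools), _match_matrix(animals)])
    pooled_sd = values.std(axis=0, ddof=1)
    pooled_sd[pooled_sd == 0] = 1.0
    z = (values - values.mean(axis=0)) / pooled_sd
    n_t = len(tools)
    per_list = n_t // N_LISTS_PER_CATEGORY
    n_lists = 2 * N_LISTS_PER_CATEGORY
    n_vars = values.shape[1]

    # serpentine deal by composite z-score (small random tie-breaker) gives
    # a nearly balanced start for all positively weighted variables at once
    members: list[list[int]] = [[] for _ in range(n_lists)]
    for cat0, idx0, count in ((0, 0, n_t), (N_LISTS_PER_CATEGORY, n_t, len(animals))):
        composite = z[idx0:idx0 + count].sum(axis=1) + 0.05 * rng.standard_normal(count)
        order = np.argsort(composite) + idx0
        for k, item in enumerate(order):
            row = k // N_LISTS_PER_CATEGORY
            col = k % N_LISTS_PER_CATEGORY
            if row % 2:
                col = N_LISTS_PER_CATEGORY - 1 - col
            members[cat0 + col].append(int(item))

    vals = [tuple(float(v) for v in row) for row in (values / pooled_sd)]
    sums = [[sum(vals[i][k] for i in lst) for k in range(n_vars)]
            for lst in members]

    def objective() -> tuple[float, float, int]:
        worst, worst_var, total = 0.0, 0, 0.0
        for k in range(n_vars):
            col = [s[k] for s in sums]
            spread = (max(col) - min(col)) / per_list
            total += spread
            if spread > worst:
                worst, worst_var = spread, k
        # blended score lets swaps improve other variables while the worst
        # one is tied, avoiding plateaus of the pure max objective
        return worst, worst + 0.2 * total / n_vars, worst_var

    obj, score, worst = objective()
    la_lb = rng.integers(0, N_LISTS_PER_CATEGORY, size=(max_swaps, 2))
    picks = rng.integers(0, per_list, size=(max_swaps, 2))
    cats = rng.integers(0, 2, size=max_swaps)
    targeted = rng.random(max_swaps) < 0.5
    for step in range(max_swaps):
        if obj < tol:
            break
        cat0 = int(cats[step]) * N_LISTS_PER_CATEGORY
        ia, ib = int(picks[step, 0]), int(picks[step, 1])
        if targeted[step]:
            # move the worst variable's extreme lists (within one category)
            # toward each other by swapping a high item for a low item
            cat_lists = range(cat0, cat0 + N_LISTS_PER_CATEGORY)
            la = max(cat_lists, key=lambda l: sums[l][worst])
            lb = min(cat_lists, key=lambda l: sums[l][worst])
            if la == lb:
                continue
            ia = max(range(per_list), key=lambda i: vals[members[la][i]][worst])
            ib = min(range(per_list), key=lambda i: vals[members[lb][i]][worst])
        else:
            la, lb = la_lb[step]
            if la == lb:
                continue
            la, lb = int(la) + cat0, int(lb) + cat0
        a, b = members[la][ia], members[lb][ib]
        va, vb = vals[a], vals[b]
        sa, sb = sums[la], sums[lb]
        for k in range(n_vars):
            d = vb[k] - va[k]
            sa[k] += d
            sb[k] -= d
        new_obj, new_score, new_worst = objective()
        if new_score <= score:
            members[la][ia], members[lb][ib] = b, a
            obj, score, worst = new_obj, new_score, new_worst
        else:
            for k in range(n_vars):
                d = vb[k] - va[k]
                sa[k] -= d
                sb[k] += d

    items = tools + animals
    lists = {lid + 1: tuple(items[i] for i in sorted(members[lid]))
             for lid in range(n_lists)}
    return lists, obj, worst


def generate_lexicon(n_per_category: int = 70, rating_threshold: float = 5.0,
                     seed: int = 0, match_tol: float = 0.25,
                     max_resample: int = 20) -> Lexicon:
    """Generate tool and animal nouns passing the rating filter, partitioned
    into 2 x 5 lists matched on the psycholinguistic covariates.

    Tool nouns require imageability and manipulability >= ``rating_threshold``
    (on the 1-7 scale); animal nouns require imageability only. Lists are
    re-randomized (with bounded local swaps) until, for every matching
    variable, the spread of list means is below ``match_tol`` pooled SDs.
    Within each category, 2 lists are assigned the target role and 3 the
    prime role.
    """
    if n_per_category <= 0:
        raise LexiconError("empty category: n_per_category must be positive")
    if n_per_category % N_LISTS_PER_CATEGORY:
        raise LexiconError(
            f"n_per_category={n_per_category} is not divisible by "
            f"{N_LISTS_PER_CATEGORY} lists")
    rng = np.random.default_rng(seed)
    # match_tol is calibrated to the default 14-item lists; smaller lists
    # cannot be balanced as finely (a single item moves a list mean by
    # ~1/per_list pooled SDs), so the bound scales with 14/per_list
    per_list = n_per_category // N_LISTS_PER_CATEGORY
    tol = match_tol * 14.0 / per_list
    last_obj, last_worst = np.inf, 0
    for _ in range(max_resample):
        tools = _draw_category(rng, "tool", n_per_category, rating_threshold)
        animals = _draw_category(rng, "animal", n_per_category, rating_threshold)
        lists, obj, worst = _partition_matched(tools, animals, rng, tol)
        if obj < tol:
            roles: dict[int, str] = {}
            for cat0 in (0, N_LISTS_PER_CATEGORY):
                ids = rng.permutation(N_LISTS_PER_CATEGORY) + cat0 + 1
                for k, lid in enumerate(ids):
                    roles[int(lid)] = "target" if k < N_TARGET_LISTS else "prime"
            return Lexicon(lists=lists, roles=roles)
        last_obj, last_worst = min(last_obj, obj), worst
    raise LexiconError(
        f"could not match lists within {tol:.3f} pooled SD after "
        f"{max_resample} resamples; worst variable: "
        f"{MATCH_VARIABLES[last_worst]} (spread {last_obj:.3f} SD)")


# --------------------------------------------------------------------------
# Trial sequences
# --------------------------------------------------------------------------


def _make_pseudowords(rng: np.random.Generator, n: int) -> list[WordItem]:
    cov = _draw_covariates(rng, n)
    return [WordItem(
        label=f"pseudo{i:03d}", category="pseudoword",
        imageability=None, manipulability=None,
        written_frequency=float(cov["written_frequency"][i]),
        n_letters=int(cov["n_letters"][i]),
        n_syllables=int(cov["n_syllables"][i]),
        n_neighbors=int(cov["n_neighbors"][i]),
    ) for i in range(n)]


def build_priming_design(lexicon: Lexicon, n_word_pairs_per_condition: int = 14,
                         n_pseudo_pairs: int = 28,
                         iti_range: tuple[float, float] = (5.0, 7.0),
                         seed: int = 0) -> list[PrimingTrial]:
    """Build the randomized prime-target trial sequence.

    Four word conditions with ``n_word_pairs_per_condition`` pairs each
    (primed pairs use two different words of the same category; unprimed
    pairs cross categories) plus ``n_pseudo_pairs`` pseudoword-target pairs
    whose primes alternate between tool and animal nouns. Target words are
    never reused across conditions. Onsets are strictly increasing with the
    trial timing fixation(0.5) + prime(0.3) + target(0.5) + response
    remainder(1.5) + a uniform ITI from ``iti_range``.
    """
    n = n_word_pairs_per_condition
    if n < 0 or n_pseudo_pairs < 0:
        raise ValueError("pair counts must be non-negative")
    if iti_range[0] > iti_range[1]:
        raise ValueError("iti_range must be (low, high) with low <= high")
    rng = np.random.default_rng(seed)
    if n == 0 and n_pseudo_pairs == 0:
        return []

    tool_targets = lexicon.category_words("tool", role="target")
    animal_targets = lexicon.category_words("animal", role="target")
    tool_primes = lexicon.category_words("tool", role="prime")
    animal_primes = lexicon.category_words("animal", role="prime")

    need_t_targets, need_a_targets = 2 * n, 2 * n
    need_t_primes = n + n + (n_pseudo_pairs + 1) // 2  # TP + AnimalUnprimed + pseudo
    need_a_primes = n + n + n_pseudo_pairs // 2        # AP + ToolUnprimed + pseudo
    shortfalls = []
    if len(tool_targets) < need_t_targets:
        shortfalls.append(f"tool targets ({len(tool_targets)} < {need_t_targets})")
    if len(animal_targets) < need_a_targets:
        shortfalls.append(f"animal targets ({len(animal_targets)} < {need_a_targets})")
    if len(tool_primes) < need_t_primes:
        shortfalls.append(f"tool primes ({len(tool_primes)} < {need_t_primes})")
    if len(animal_primes) < need_a_primes:
        shortfalls.append(f"animal primes ({len(animal_primes)} < {need_a_primes})")
    if shortfalls:
        raise ValueError("lexicon too small: " + "; ".join(shortfalls))

    tool_targets = [tool_targets[i] for i in rng.permutation(len(tool_targets))]
    animal_targets = [animal_targets[i] for i in rng.permutation(len(animal_targets))]
    tool_primes = [tool_primes[i] for i in rng.permutation(len(tool_primes))]
    animal_primes = [animal_primes[i] for i in rng.permutation(len(animal_primes))]

    pairs: list[tuple[str, WordItem, WordItem]] = []
    for k in range(n):
        pairs.append(("ToolPrimed", tool_primes.pop(), tool_targets.pop()))
    for k in range(n):
        pairs.append(("ToolUnprimed", animal_primes.pop(), tool_targets.pop()))
    for k in range(n):
        pairs.append(("AnimalPrimed", animal_primes.pop(), animal_targets.pop()))
    for k in range(n):
        pairs.append(("AnimalUnprimed", tool_primes.pop(), animal_targets.pop()))
    for k, pseudo in enumerate(_make_pseudowords(rng, n_pseudo_pairs)):
        prime = tool_primes.pop() if k % 2 == 0 else animal_primes.pop()
        pairs.append((PSEUDOWORD, prime, pseudo))

    order = rng.permutation(len(pairs))
    trials: list[PrimingTrial] = []
    t = FIXATION_S
    for idx, k in enumerate(order):
        cond, prime, target = pairs[k]
        iti = float(rng.uniform(*iti_range))
        trials.append(PrimingTrial(index=idx, prime=prime, target=target,
                                   condition=cond, prime_onset=t, iti=iti))
        t += MODELED_S + RESPONSE_REMAINDER_S + iti + FIXATION_S
    return trials


def design_duration(trials: Sequence[PrimingTrial]) -> float:
    """Total scan time of a priming design including the final ITI."""
    if not trials:
        return 0.0
    last = trials[-1]
    return last.prime_onset + MODELED_S + RESPONSE_REMAINDER_S + last.iti


def priming_events(trials: Sequence[PrimingTrial],
                   include_response_window: bool = True) -> pd.DataFrame:
    """BIDS-style event table (onset, duration, trial_type) for a design.

    The modeled event spans 0.8 s from prime onset; when requested, the
    remaining 1.5 s response window is emitted as a ``response_window``
    nuisance event per trial.
    """
    rows = [{"onset": tr.prime_onset, "duration": MODELED_S,
             "trial_type": tr.condition} for tr in trials]
    if include_response_window:
        rows += [{"onset": tr.prime_onset + MODELED_S,
                  "duration": RESPONSE_REMAINDER_S,
                  "trial_type": "response_window"} for tr in trials]
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    return df.sort_values("onset", kind="stable").reset_index(drop=True)


def build_motor_design(effector: str, n_repetitions: int = 15,
                       missed_rate: float = 0.0,
                       seed: int = 0) -> list[MotorEvent]:
    """Blocked motor design: (4 s planning - 4 s execution) x2 + 10 s rest,
    repeated ``n_repetitions`` times with a single effector per run."""
    if effector not in ("tool", "hand"):
        raise ValueError(f"unknown effector {effector!r}")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    events: list[MotorEvent] = []
    t = 0.0
    for _ in range(n_repetitions):
        for phase, dur in MOTOR_TEMPLATE:
            missed = bool(phase == "execution" and rng.random() < missed_rate)
            events.append(MotorEvent(onset=t, duration=dur, phase=phase,
                                     effector=effector, missed=missed))
            t += dur
    return events


def motor_duration(n_repetitions: int) -> float:
    return MOTOR_REPETITION_S * n_repetitions


def motor_events(events: Sequence[MotorEvent]) -> pd.DataFrame:
    """Event table with trial_type ``{phase}_{effector}`` (missed trials get
    their own ``missed`` regressor label)."""
    rows = []
    for ev in events:
        label = "missed" if ev.missed else f"{ev.phase}_{ev.effector}"
        rows.append({"onset": ev.onset, "duration": ev.duration,
                     "trial_type": label})
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


# --------------------------------------------------------------------------
# Pattern templates
# --------------------------------------------------------------------------


def make_pattern_templates(n_voxels: int, rho_within: float, rho_across: float,
                           seed: int = 0) -> dict[str, np.ndarray]:
    """Draw four voxel-amplitude templates (one per word condition) whose
    pairwise correlations target ``rho_within`` for same-category pairs and
    ``rho_across`` for different-category pairs.

    Templates are generated from the Cholesky-type square root of the 4x4
    target correlation matrix applied to iid normal voxel loadings, then
    de-meaned across voxels (so template means cannot masquerade as
    condition activation offsets). Raises ``ValueError`` if the target
    matrix is not positive semidefinite.
    """
    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2")
    if not (-1.0 <= rho_across <= rho_within <= 1.0):
        raise ValueError("require -1 <= rho_across <= rho_within <= 1")
    target = np.full((4, 4), rho_across)
    target[0, 1] = target[1, 0] = rho_within  # tool pair
    target[2, 3] = target[3, 2] = rho_within  # animal pair
    np.fill_diagonal(target, 1.0)
    eigval, eigvec = np.linalg.eigh(target)
    if eigval.min() < -1e-10:
        raise ValueError(
            f"infeasible correlation structure (rho_within={rho_within}, "
            f"rho_across={rho_across}): target matrix is not PSD")
    root = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    rng = np.random.default_rng(seed)
    raw = root @ rng.standard_normal((4, n_voxels))
    raw -= raw.mean(axis=1, keepdims=True)
    return {cond: raw[i] for i, cond in enumerate(CONDITIONS)}


def simulate_patterns(n_subjects: int, n_voxels: int, rho_within: float,
                      rho_across: float, noise_sd: float = 1.0,
                      mean_offsets: Mapping[str, float] | None = None,
                      seed: int = 0) -> np.ndarray:
    """Directly simulate per-subject condition patterns (no BOLD forward
    model): each subject gets its own correlated templates plus condition
    offsets plus iid voxel noise. Returns (n_subjects, 4, n_voxels)."""
    offsets = np.array([(mean_offsets or {}).get(c, 0.0) for c in CONDITIONS])
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    out = np.empty((n_subjects, 4, n_voxels))
    for s, child in enumerate(children):
        t_seed, n_seed = child.spawn(2)
        tmpl = make_pattern_templates(
            n_voxels, rho_within, rho_across,
            seed=int(t_seed.generate_state(1)[0] & 0x7FFFFFFF))
        rng = np.random.default_rng(n_seed)
        out[s] = (np.stack([tmpl[c] for c in CONDITIONS])
                  + offsets[:, None]
                  + noise_sd * rng.standard_normal((4, n_voxels)))
    return out


# --------------------------------------------------------------------------
# BOLD simulation
# --------------------------------------------------------------------------


def _ar1_noise(rng: np.random.Generator, shape_tv: tuple[int, int],
               sd: float, ar1: float, burn: int = 50) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` along axis 0 (time)."""
    t, v = shape_tv
    if sd == 0:
        return np.zeros((t, v))
    if ar1 == 0:
        return sd * rng.standard_normal((t, v))
    w = rng.standard_normal((t + burn, v)) * sd * math.sqrt(1.0 - ar1 ** 2)
    x = _signal.lfilter([1.0], [1.0, -ar1], w, axis=0)
    return x[burn:]


def default_affine(voxel_size_mm: Sequence[float] = (3.0, 3.0, 3.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def simulate_bold(events: pd.DataFrame, truth: GroundTruth,
                  grid: tuple[int, int, int],
                  roi_layout: Mapping[str, np.ndarray],
                  tr: float = TR_S, seed: int = 0,
                  duration: float | None = None,
                  run_type: str = "semantic",
                  voxel_size_mm: Sequence[float] = (3.0, 3.0, 3.0)) -> SubjectRun:
    """Simulate one 4D run with the boxcar x canonical-HRF forward model.

    Voxel time series = baseline + sum over conditions of amplitude x
    (boxcar convolved with the canonical HRF) + AR(1) Gaussian noise.
    Amplitudes are nonzero only inside ``roi_layout`` voxels, where they
    follow ``truth.condition_amplitude_maps``; ``duration`` defaults to the
    end of the last event, rounded up to whole volumes.
    """
    from . import glm  # local import: glm owns the shared forward model

    if duration is None:
        duration = float((events["onset"] + events["duration"]).max()) if len(events) else tr
    n_volumes = int(math.ceil(duration / tr))
    end = events["onset"] + events["duration"]
    if len(events) and (end.max() > n_volumes * tr + 1e-9 or events["onset"].min() < 0):
        raise ValueError("event beyond run end: events must fall within the run")

    names = sorted({c for roi in truth.condition_amplitude_maps.values() for c in roi}
                   | set(truth.background_amplitude_maps))
    active = [c for c in names if c in set(events["trial_type"])]
    nv = int(np.prod(grid))
    t_len = n_volumes
    signal = np.zeros((t_len, nv))
    if active:
        regs, _ = glm.condition_regressors(
            events[events["trial_type"].isin(active)], tr, n_volumes,
            conditions=active)
        flat = {}
        for roi_name, coords in roi_layout.items():
            coords = np.asarray(coords)
            flat[roi_name] = np.ravel_multi_index(coords.T, grid)
        for roi_name, cond_maps in truth.condition_amplitude_maps.items():
            if roi_name not in flat:
                raise KeyError(f"ROI {roi_name!r} missing from roi_layout")
            idx = flat[roi_name]
            for cond, amp in cond_maps.items():
                if cond not in active:
                    continue
                amp_vec = np.broadcast_to(np.asarray(amp, dtype=float), idx.shape)
                j = active.index(cond)
                signal[:, idx] += np.outer(regs[:, j], amp_vec)
        for cond, bg in truth.background_amplitude_maps.items():
            if cond not in active:
                continue
            bg = np.asarray(bg, dtype=float)
            if bg.shape != tuple(grid):
                raise ValueError(f"background map for {cond!r} must match the grid")
            signal += np.outer(regs[:, active.index(cond)], bg.ravel())

    rng = np.random.default_rng(seed)
    noise = _ar1_noise(rng, (t_len, nv), truth.noise_sd, truth.ar1)
    data = (truth.baseline + signal + noise).T.reshape(*grid, t_len)
    return SubjectRun(data=data, affine=default_affine(voxel_size_mm), tr=tr,
                      events=events.reset_index(drop=True), run_type=run_type)


# --------------------------------------------------------------------------
# Behavior
# --------------------------------------------------------------------------


def simulate_behavior(trials: Sequence[PrimingTrial], truth: GroundTruth,
                      n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Simulate lexical-decision RT/accuracy records for ``n_subjects``.

    RTs are lognormal with subject random intercepts and condition means set
    by ``truth.behavior``; the lognormal is mean-corrected so each condition
    mean equals its target in expectation. Responses exceeding the 2 s
    deadline are recorded as omissions (missing RT, accuracy 0).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    bp = truth.behavior
    conds = [tr.condition for tr in trials]
    means = np.array([bp.rt_mean_ms[c] for c in conds])
    errs = np.array([bp.error_rate.get(c, 0.0) for c in conds])
    correction = 0.5 * (bp.sigma_subject ** 2 + bp.sigma_trial ** 2)
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_subjects):
        b_s = rng.normal(0.0, bp.sigma_subject)
        z = rng.standard_normal(len(trials))
        rt = means * np.exp(b_s + bp.sigma_trial * z - correction)
        omitted = rt > bp.deadline_ms
        acc = (rng.random(len(trials)) >= errs).astype(int)
        acc[omitted] = 0
        frames.append(pd.DataFrame({
            "subject": s,
            "trial": np.arange(len(trials)),
            "condition": conds,
            "rt_ms": np.where(omitted, np.nan, rt),
            "accuracy": acc,
        }))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# External interfaces
# --------------------------------------------------------------------------


def events_with_behavior(trials: Sequence[PrimingTrial],
                         records: pd.DataFrame, subject: int) -> pd.DataFrame:
    """BIDS-style events (onset, duration, trial_type, response_time,
    accuracy) for one subject, merging the design with behavioral records."""
    sub = records[records["subject"] == subject].set_index("trial")
    rows = []
    for tr in trials:
        rec = sub.loc[tr.index]
        rows.append({
            "onset": tr.prime_onset, "duration": MODELED_S,
            "trial_type": tr.condition,
            "response_time": rec["rt_ms"] / 1000.0,
            "accuracy": int(rec["accuracy"]),
        })
    return pd.DataFrame(rows)


def write_events_tsv(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def truth_to_json(truth: GroundTruth) -> str:
    """Serialize a GroundTruth (amplitude arrays as lists) to JSON."""
    d = dataclasses.asdict(truth)
    for roi, conds in d["condition_amplitude_maps"].items():
        for cond, amp in conds.items():
            conds[cond] = np.asarray(amp).tolist()
    for cond, bg in d["background_amplitude_maps"].items():
        d["background_amplitude_maps"][cond] = np.asarray(bg).tolist()
    return json.dumps(d, indent=2, sort_keys=True)


def truth_from_json(text: str) -> GroundTruth:
    d = json.loads(text)
    maps = {roi: {c: np.asarray(a, dtype=float) for c, a in conds.items()}
            for roi, conds in d["condition_amplitude_maps"].items()}
    return GroundTruth(
        condition_amplitude_maps=maps,
        rho_within=d["rho_within"], rho_across=d["rho_across"],
        mean_offsets=d["mean_offsets"], noise_sd=d["noise_sd"],
        ar1=d["ar1"], baseline=d["baseline"],
        behavior=BehaviorParams(**d["behavior"]),
        background_amplitude_maps={
            c: np.asarray(b, dtype=float)
            for c, b in d.get("background_amplitude_maps", {}).items()},
    )
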
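"""End-to-end orchestration: simulate -> first-level GLM -> second-level
clusters -> ROI masks -> similarity MVPA -> follow-up ANOVA -> behavior.

A master seed fans out to per-stage seeds through a fixed
``numpy.random.SeedSequence`` splitting rule, so e.g. changing the number
of permutations never perturbs data generation. Every stage can also be run
standalone from the on-disk artifacts of the previous stage (see cli).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import glm, patterns, similarity, synth, univariate
from .synth import ALL_CONDITIONS, CONDITIONS, BehaviorParams, GroundTruth

RESPONSE_WINDOW = "response_window"
SEMANTIC_DESIGN_CONDITIONS = list(ALL_CONDITIONS) + [RESPONSE_WINDOW]

#: Motor response amplitudes (per phase_effector regressor) giving a
#: tool-planning-specific interaction of +0.75 amplitude units inside ROIs.
DEFAULT_MOTOR_AMPLITUDES: dict[str, float] = {
    "planning_tool": 1.5,
    "planning_hand": 0.75,
    "execution_tool": 1.0,
    "execution_hand": 1.0,
}


class ConfigError(ValueError):
    """Aggregated configuration violations."""


@dataclass
class RoiSpec:
    """A planted ROI: location, size and generating pattern structure.

    ``position_jitter`` shifts each subject's ROI by an integer offset drawn
    uniformly from [-j, j] per axis (clamped to the grid), emulating the
    between-subject variability in functional anatomy that keeps group
    cluster maps from ballooning around every active region.
    """

    name: str
    center: tuple[int, int, int]
    n_voxels: int
    rho_within: float = 0.0
    rho_across: float = 0.0
    amplitude_scale: float = 1.5
    mean_offsets: dict[str, float] = field(default_factory=dict)
    motor_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTOR_AMPLITUDES))
    position_jitter: int = 1


def default_rois() -> list[RoiSpec]:
    """Three tool-use planning ROIs on the default 20x20x12 grid, sized like
    the group clusters the analysis targets (IPL 150, OTC 76, IFG 28 voxels);
    semantic category structure and an unprimed-tool offset are planted in
    the OTC only."""
    return [
        RoiSpec(name="ipl", center=(5, 5, 6), n_voxels=150),
        RoiSpec(name="otc", center=(16, 16, 6), n_voxels=76,
                rho_within=0.6, rho_across=0.0,
                mean_offsets={"ToolUnprimed": 0.5}),
        RoiSpec(name="ifg", center=(16, 5, 6), n_voxels=28),
    ]


@dataclass
class PipelineConfig:
    n_subjects: int = 20
    grid: tuple[int, int, int] = (22, 22, 12)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr: float = synth.TR_S
    rois: list[RoiSpec] = field(default_factory=default_rois)
    # design
    n_word_pairs: int = 14
    n_pseudo_pairs: int = 28
    iti_range: tuple[float, float] = (5.0, 7.0)
    motor_repetitions: int = 15
    n_per_category: int = 70
    rating_threshold: float = 5.0
    # noise model
    noise_sd: float = 1.0
    ar1: float = 0.3
    baseline: float = 100.0
    #: between-subject SD of the smooth background amplitude field added to
    #: every motor regressor grid-wide (idiosyncratic activation topography;
    #: this variance floor keeps group motor clusters compact)
    motor_background_sd: float = 0.15
    background_fwhm_mm: float = 8.0
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    # GLM options (univariate path smooths; the MVPA path never does)
    smooth_fwhm_mm: float = 8.0
    # inference
    n_permutations: int = 10000
    alpha: float = 0.05
    cluster_p: float = 0.001
    cluster_extent: int = 10
    mask_p: float = 0.05
    connectivity: int = 18
    literal_three: bool = False
    seed: int = 0


def _merge_dataclass(cls, defaults, overrides: Mapping, errors: list[str],
                     prefix: str = ""):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in overrides.items():
        if key not in known:
            errors.append(f"unknown config field {prefix}{key!r}")
            continue
        current = getattr(defaults, key)
        if key == "rois" and isinstance(value, list):
            value = [v if isinstance(v, RoiSpec)
                     else _merge_dataclass(RoiSpec, RoiSpec(name="", center=(0, 0, 0), n_voxels=1),
                                           v, errors, prefix="rois.")
                     for v in value]
        elif key == "behavior" and isinstance(value, Mapping):
            value = _merge_dataclass(BehaviorParams, BehaviorParams(), value,
                                     errors, prefix="behavior.")
        elif dataclasses.is_dataclass(current) and isinstance(value, Mapping):
            value = _merge_dataclass(type(current), current, value, errors,
                                     prefix=f"{key}.")
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    merged = dataclasses.replace(defaults, **{k: v for k, v in kwargs.items()
                                              if k in known})
    return merged


def validate_config(config: PipelineConfig | Mapping | None = None,
                    ) -> PipelineConfig:
    """Fill defaults, enforce invariants and report every violation at once."""
    errors: list[str] = []
    if config is None:
        cfg = PipelineConfig()
    elif isinstance(config, PipelineConfig):
        cfg = config
    elif isinstance(config, Mapping):
        cfg = _merge_dataclass(PipelineConfig, PipelineConfig(), config, errors)
    else:
        raise ConfigError(f"cannot interpret config of type {type(config)!r}")

    if cfg.n_subjects < 2:
        errors.append(f"n_subjects must be >= 2 (got {cfg.n_subjects})")
    for name in ("alpha", "cluster_p", "mask_p"):
        val = getattr(cfg, name)
        if not (0.0 < val < 1.0):
            errors.append(f"{name} must lie in (0, 1) (got {val})")
    if cfg.n_permutations < 1:
        errors.append("n_permutations must be >= 1")
    if len(cfg.grid) != 3 or any(g < 1 for g in cfg.grid):
        errors.append(f"grid must be three positive dimensions (got {cfg.grid})")
    if cfg.tr <= 0:
        errors.append("tr must be positive")
    if cfg.iti_range[0] > cfg.iti_range[1]:
        errors.append(f"iti_range must be ordered (got {cfg.iti_range})")
    if cfg.connectivity not in (6, 18, 26):
        errors.append("connectivity must be 6, 18 or 26")
    if not cfg.rois:
        errors.append("at least one ROI must be configured")
    nv = int(np.prod(cfg.grid))
    seen = set()
    for roi in cfg.rois:
        if not roi.name:
            errors.append("every ROI needs a name")
        if roi.name in seen:
            errors.append(f"duplicate ROI name {roi.name!r}")
        seen.add(roi.name)
        if roi.n_voxels < 1 or roi.n_voxels > nv:
            errors.append(f"ROI {roi.name!r}: n_voxels {roi.n_voxels} does not "
                          f"fit the grid ({nv} voxels)")
        if len(roi.center) == 3 and not all(
                0 <= c < g for c, g in zip(roi.center, cfg.grid)):
            errors.append(f"ROI {roi.name!r}: center {roi.center} outside grid")
        if not (-1.0 <= roi.rho_across <= roi.rho_within <= 1.0):
            errors.append(f"ROI {roi.name!r}: require -1 <= rho_across <= "
                          "rho_within <= 1")
    if not errors:
        layout = roi_layout(cfg)
        total = sum(len(v) for v in layout.values())
        flat = np.concatenate([np.ravel_multi_index(np.asarray(v).T, cfg.grid)
                               for v in layout.values()])
        if len(np.unique(flat)) != total:
            errors.append("ROIs overlap; the layout must be disjoint")
    if errors:
        raise ConfigError("invalid configuration:\n- " + "\n- ".join(errors))
    return cfg


def sphere_roi(center: Sequence[int], n_voxels: int,
               grid: tuple[int, int, int]) -> np.ndarray:
    """The ``n_voxels`` grid voxels nearest to ``center`` (ties broken
    lexicographically), i.e. a sphere trimmed to an exact voxel count."""
    coords = np.indices(grid).reshape(3, -1).T
    d2 = ((coords - np.asarray(center)) ** 2).sum(axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
    return coords[order[:n_voxels]]


def roi_layout(config: PipelineConfig) -> dict[str, np.ndarray]:
    return {roi.name: sphere_roi(roi.center, roi.n_voxels, config.grid)
            for roi in config.rois}


# --------------------------------------------------------------------------
# Seed fan-out
# --------------------------------------------------------------------------


def validation_config(seed: int = 0) -> PipelineConfig:
    """Reduced-scale configuration for repeated end-to-end recovery studies.

    Two ROIs on a 16x16x8 grid: a 76-voxel region with planted semantic
    category structure (rho_within 0.6, rho_across 0) plus the
    unprimed-tool activation offset, and a 48-voxel region with motor
    activation but null semantic structure. 2,000 permutations. All other
    conditions (20 subjects, full trial counts, 15 motor repetitions) match
    the default configuration.
    """
    return validate_config({
        "grid": (16, 16, 8),
        "n_permutations": 2000,
        "rois": [
            {"name": "planted", "center": (4, 4, 4), "n_voxels": 76,
             "rho_within": 0.6, "rho_across": 0.0,
             "mean_offsets": {"ToolUnprimed": 0.5}},
            {"name": "null", "center": (11, 11, 4), "n_voxels": 48},
        ],
        "seed": seed,
    })


def _stage_seeds(config: PipelineConfig) -> dict[str, np.random.SeedSequence]:
    names = ("lexicon", "design", "truth", "bold", "behavior", "permutations")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return dict(zip(names, children))


def _as_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# --------------------------------------------------------------------------
# Subject-level simulation and fitting
# --------------------------------------------------------------------------


def subject_truth(config: PipelineConfig, seed: int,
                  ) -> tuple[GroundTruth, dict[str, np.ndarray]]:
    """Draw one subject's generating parameters and ROI placement.

    Returns the GroundTruth (per-ROI semantic templates with the configured
    correlation structure, scaled and offset, plus the motor amplitude
    profile) and this subject's ROI layout, i.e. the planted layout shifted
    by the subject's anatomical jitter.
    """
    maps: dict[str, dict[str, np.ndarray | float]] = {}
    layout: dict[str, np.ndarray] = {}
    children = np.random.SeedSequence(seed).spawn(len(config.rois) + 1)
    background: dict[str, np.ndarray] = {}
    if config.motor_background_sd > 0:
        rng = np.random.default_rng(children[-1])
        for label in sorted(DEFAULT_MOTOR_AMPLITUDES):
            white = rng.standard_normal(config.grid)
            smooth = glm.smooth_volume(white, config.background_fwhm_mm,
                                       config.voxel_size_mm)
            sd = smooth.std()
            background[label] = (config.motor_background_sd / sd) * smooth
    for roi, child in zip(config.rois, children):
        tmpl_child, jitter_child = child.spawn(2)
        cond_maps: dict[str, np.ndarray | float] = {}
        if roi.amplitude_scale != 0:
            tmpl = synth.make_pattern_templates(
                roi.n_voxels, roi.rho_within, roi.rho_across,
                seed=_as_int(tmpl_child))
            for cond in CONDITIONS:
                cond_maps[cond] = (roi.amplitude_scale * tmpl[cond]
                                   + roi.mean_offsets.get(cond, 0.0))
        for label, amp in roi.motor_amplitudes.items():
            cond_maps[label] = amp
        maps[roi.name] = cond_maps
        coords = sphere_roi(roi.center, roi.n_voxels, config.grid)
        if roi.position_jitter > 0:
            rng = np.random.default_rng(jitter_child)
            shift = rng.integers(-roi.position_jitter,
                                 roi.position_jitter + 1, size=3)
            lo = -coords.min(axis=0)
            hi = np.asarray(config.grid) - 1 - coords.max(axis=0)
            coords = coords + np.clip(shift, lo, hi)
        layout[roi.name] = coords
    truth = GroundTruth(condition_amplitude_maps=maps,
                        mean_offsets={}, noise_sd=config.noise_sd,
                        ar1=config.ar1, baseline=config.baseline,
                        behavior=config.behavior,
                        background_amplitude_maps=background)
    return truth, layout


def simulate_subject(config: PipelineConfig, lexicon: synth.Lexicon,
                     design_seed: int, truth_seed: int, bold_seed: int,
                     ) -> tuple[dict[str, synth.SubjectRun], list[synth.PrimingTrial]]:
    """Simulate one subject's semantic run and both motor runs."""
    truth, layout = subject_truth(config, truth_seed)
    trials = synth.build_priming_design(
        lexicon, config.n_word_pairs, config.n_pseudo_pairs,
        config.iti_range, seed=design_seed)
    run_seeds = np.random.SeedSequence(bold_seed).spawn(3)
    runs: dict[str, synth.SubjectRun] = {}
    runs["semantic"] = synth.simulate_bold(
        synth.priming_events(trials), truth, config.grid, layout,
        tr=config.tr, seed=_as_int(run_seeds[0]),
        duration=synth.design_duration(trials), run_type="semantic",
        voxel_size_mm=config.voxel_size_mm)
    for k, effector in enumerate(("tool", "hand"), start=1):
        events = synth.motor_events(
            synth.build_motor_design(effector, config.motor_repetitions))
        runs[f"motor_{effector}"] = synth.simulate_bold(
            events, truth, config.grid, layout, tr=config.tr,
            seed=_as_int(run_seeds[k]),
            duration=synth.motor_duration(config.motor_repetitions),
            run_type=f"motor_{effector}", voxel_size_mm=config.voxel_size_mm)
    return runs, trials


def motor_first_level(runs: Mapping[str, synth.SubjectRun],
                      config: PipelineConfig,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed first-level motor fits for one subject.

    Returns the tool-use planning interaction map
    (planning_tool - planning_hand) - (execution_tool - execution_hand)
    and the exclusive-mask component map (execution_hand - execution_tool).
    The rest phase is the implicit baseline.
    """
    betas: dict[str, np.ndarray] = {}
    for effector in ("tool", "hand"):
        run = runs[f"motor_{effector}"]
        events = run.events[~run.events["trial_type"].str.startswith("rest")]
        design = glm.build_design_matrix(
            events, run.tr, run.n_volumes,
            conditions=sorted(events["trial_type"].unique()))
        smoothed = glm.smooth_volume(run.data, config.smooth_fwhm_mm,
                                     config.voxel_size_mm)
        fit = glm.fit_glm(smoothed, design)
        for phase in ("planning", "execution"):
            betas[f"{phase}_{effector}"] = fit.beta_map(f"{phase}_{effector}")
    interaction = ((betas["planning_tool"] - betas["planning_hand"])
                   - (betas["execution_tool"] - betas["execution_hand"]))
    component = betas["execution_hand"] - betas["execution_tool"]
    return interaction, component


def semantic_first_level(run: synth.SubjectRun) -> glm.GLMResult:
    """Non-smoothed first-level fit of the semantic run (five condition
    regressors, response-window nuisance, intercept)."""
    present = [c for c in SEMANTIC_DESIGN_CONDITIONS
               if c in set(run.events["trial_type"])]
    design = glm.build_design_matrix(run.events, run.tr, run.n_volumes,
                                     conditions=present)
    return glm.fit_glm(run, design)


def match_clusters_to_layout(table: glm.ClusterTable,
                             layout: Mapping[str, np.ndarray],
                             grid: tuple[int, int, int],
                             ) -> dict[int, tuple[str | None, float]]:
    """For each cluster id, the planted ROI with the largest voxel overlap
    (fraction of the planted ROI covered), or None. Larger clusters claim
    first; a planted ROI is claimed at most once."""
    flat_layout = {name: set(np.ravel_multi_index(np.asarray(v).T, grid))
                   for name, v in layout.items()}
    claimed: set[str] = set()
    out: dict[int, tuple[str | None, float]] = {}
    for cluster in table:
        flat = set(np.ravel_multi_index(cluster.voxels.T, grid))
        best, best_frac = None, 0.0
        for name, roi_flat in flat_layout.items():
            if name in claimed:
                continue
            frac = len(flat & roi_flat) / len(roi_flat)
            if frac > best_frac:
                best, best_frac = name, frac
        if best is not None and best_frac > 0:
            claimed.add(best)
            out[cluster.id] = (best, best_frac)
        else:
            out[cluster.id] = (None, 0.0)
    return out


# --------------------------------------------------------------------------
# run_all
# --------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: PipelineConfig
    cluster_table: glm.ClusterTable
    group_t: np.ndarray
    group_p: np.ndarray
    roi_masks: dict[str, patterns.ROIMask]
    roi_overlap: dict[str, float]
    pattern_matrices: dict[str, patterns.PatternMatrix]
    mvpa: pd.DataFrame
    followup: dict[str, univariate.AnovaResult]
    behavior_records: pd.DataFrame
    behavior_summary: pd.DataFrame
    priming_effects: pd.DataFrame
    manifest: dict


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_all(config: PipelineConfig | Mapping | None = None,
            out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full chain deterministically under the master seed."""
    config = validate_config(config)
    seeds = _stage_seeds(config)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    lexicon = synth.generate_lexicon(config.n_per_category,
                                     config.rating_threshold,
                                     seed=_as_int(seeds["lexicon"]))
    timings["lexicon"] = time.perf_counter() - t0

    design_seeds = seeds["design"].spawn(config.n_subjects)
    truth_seeds = seeds["truth"].spawn(config.n_subjects)
    bold_seeds = seeds["bold"].spawn(config.n_subjects)

    t0 = time.perf_counter()
    interaction_maps: list[np.ndarray] = []
    component_maps: list[np.ndarray] = []
    semantic_fits: dict[int, glm.GLMResult] = {}
    first_trials: list[synth.PrimingTrial] | None = None
    for s in range(config.n_subjects):
        runs, trials = simulate_subject(
            config, lexicon, _as_int(design_seeds[s]), _as_int(truth_seeds[s]),
            _as_int(bold_seeds[s]))
        if first_trials is None:
            first_trials = trials
        inter, comp = motor_first_level(runs, config)
        interaction_maps.append(inter)
        component_maps.append(comp)
        semantic_fits[s] = semantic_first_level(runs["semantic"])
    timings["simulate_and_first_level"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    group_t, group_p = glm.second_level_contrast(interaction_maps)
    _, excl_p = glm.second_level_contrast(component_maps)
    table = glm.extract_clusters(group_t, group_p, config.cluster_p,
                                 config.cluster_extent,
                                 exclusive_mask=(excl_p, config.mask_p),
                                 connectivity=config.connectivity)
    layout = roi_layout(config)
    matches = match_clusters_to_layout(table, layout, config.grid)
    affine = synth.default_affine(config.voxel_size_mm)
    roi_masks: dict[str, patterns.ROIMask] = {}
    roi_overlap: dict[str, float] = {}
    for cluster in table:
        matched, frac = matches[cluster.id]
        name = matched if matched is not None else f"cluster{cluster.id}"
        roi_masks[name] = patterns.mask_from_cluster(cluster, config.grid,
                                                     affine, name)
        roi_overlap[name] = frac
    timings["second_level"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pattern_matrices = {name: patterns.extract_patterns(semantic_fits, mask)
                        for name, mask in roi_masks.items()}
    if pattern_matrices:
        mvpa = similarity.run_mvpa(pattern_matrices,
                                   n_permutations=config.n_permutations,
                                   seed=_as_int(seeds["permutations"]),
                                   literal_three=config.literal_three)
    else:
        mvpa = pd.DataFrame(columns=["roi", "contrast", "n_subjects",
                                     "observed_mean", "sem", "p_uncorrected",
                                     "p_fdr", "n_permutations", "seed"])
    timings["mvpa"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    followup: dict[str, univariate.AnovaResult] = {}
    sig = mvpa[(mvpa["contrast"] == 1) & (mvpa["p_fdr"] < config.alpha)]
    for name in sig["roi"]:
        means = univariate.roi_means(pattern_matrices[name])
        result = univariate.rm_anova_2x2(means)
        result.posthoc = univariate.posthoc_paired(means)
        followup[name] = result
    timings["followup"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    truth0, _ = subject_truth(config, _as_int(truth_seeds[0]))
    records = synth.simulate_behavior(first_trials, truth0, config.n_subjects,
                                      seed=_as_int(seeds["behavior"]))
    behavior_summary = univariate.summarize_behavior(records)
    priming = univariate.priming_differences(records)
    timings["behavior"] = time.perf_counter() - t0

    manifest = {
        "package_version": _pkg_version,
        "config": dataclasses.asdict(config),
        "config_sha256": config_hash(config),
        "stage_seeds": {k: _as_int(v) for k, v in _stage_seeds(config).items()},
        "stage_timings_s": {k: round(v, 4) for k, v in timings.items()},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "roi_overlap": roi_overlap,
        "outputs": [],
    }
    result = PipelineResult(
        config=config, cluster_table=table, group_t=group_t, group_p=group_p,
        roi_masks=roi_masks, roi_overlap=roi_overlap,
        pattern_matrices=pattern_matrices, mvpa=mvpa, followup=followup,
        behavior_records=records, behavior_summary=behavior_summary,
        priming_effects=priming, manifest=manifest)
    if out_dir is not None:
        write_results(result, Path(out_dir))
    return result


def write_results(result: PipelineResult, out_dir: Path) -> None:
    """Write the result bundle (TSV tables, NIfTI masks, JSON manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def _write_tsv(df: pd.DataFrame, rel: str) -> None:
        path = out_dir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False, na_rep="n/a")
        outputs.append(rel)

    _write_tsv(result.cluster_table.to_dataframe(), "group/clusters.tsv")
    patterns.save_map(result.group_t, synth.default_affine(result.config.voxel_size_mm),
                      out_dir / "group" / "tool_planning_tstat.nii.gz")
    outputs.append("group/tool_planning_tstat.nii.gz")
    for name, mask in result.roi_masks.items():
        rel = f"rois/{name}_mask.nii.gz"
        (out_dir / "rois").mkdir(parents=True, exist_ok=True)
        patterns.save_mask(mask, out_dir / rel)
        outputs.append(rel)
    _write_tsv(result.mvpa, "mvpa/mvpa_results.tsv")
    for name, anova in result.followup.items():
        _write_tsv(anova.to_dataframe(), f"followup/{name}_anova.tsv")
        if anova.posthoc is not None:
            _write_tsv(anova.posthoc, f"followup/{name}_posthoc.tsv")
    _write_tsv(result.behavior_summary, "behavior/behavior_summary.tsv")
    _write_tsv(result.priming_effects, "behavior/priming_effects.tsv")
    result.manifest["outputs"] = outputs
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))


# --------------------------------------------------------------------------
# Stage-wise disk pipeline (used by the CLI; reproduces run_all exactly
# because both derive their per-stage seeds from the same fan-out)
# --------------------------------------------------------------------------


def _load_config(out_dir: Path) -> PipelineConfig:
    path = Path(out_dir) / "config.json"
    if not path.exists():
        raise FileNotFoundError(f"{path} not found; run the simulate stage first")
    return validate_config(json.loads(path.read_text()))


def stage_simulate(config: PipelineConfig, out_dir: Path) -> None:
    """Simulate all subjects and write volumes, events, behavior and config."""
    config = validate_config(config)
    out_dir = Path(out_dir)
    sim = out_dir / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True))
    seeds = _stage_seeds(config)
    lexicon = synth.generate_lexicon(config.n_per_category,
                                     config.rating_threshold,
                                     seed=_as_int(seeds["lexicon"]))
    design_seeds = seeds["design"].spawn(config.n_subjects)
    truth_seeds = seeds["truth"].spawn(config.n_subjects)
    bold_seeds = seeds["bold"].spawn(config.n_subjects)
    first_trials = None
    for s in range(config.n_subjects):
        runs, trials = simulate_subject(
            config, lexicon, _as_int(design_seeds[s]), _as_int(truth_seeds[s]),
            _as_int(bold_seeds[s]))
        if first_trials is None:
            first_trials = trials
        for run_type, run in runs.items():
            stem = sim / f"sub-{s:02d}_task-{run_type}"
            patterns.save_map(run.data, run.affine, f"{stem}_bold.nii.gz")
            synth.write_events_tsv(f"{stem}_events.tsv", run.events)
    truth0, _ = subject_truth(config, _as_int(truth_seeds[0]))
    records = synth.simulate_behavior(first_trials, truth0, config.n_subjects,
                                      seed=_as_int(seeds["behavior"]))
    records.to_csv(sim / "behavior.tsv", sep="\t", index=False, na_rep="n/a")


def stage_glm(out_dir: Path) -> None:
    """First-level fits from on-disk runs: per-subject motor contrast maps
    (smoothed) and semantic condition t-maps (non-smoothed)."""
    out_dir = Path(out_dir)
    config = _load_config(out_dir)
    sim = out_dir / "sim"
    gdir = out_dir / "glm"
    gdir.mkdir(parents=True, exist_ok=True)
    for s in range(config.n_subjects):
        runs = {}
        for run_type in ("semantic", "motor_tool", "motor_hand"):
            stem = sim / f"sub-{s:02d}_task-{run_type}"
            data, affine = patterns.load_map(f"{stem}_bold.nii.gz")
            events = synth.read_events_tsv(f"{stem}_events.tsv")
            runs[run_type] = synth.SubjectRun(data=data, affine=affine,
                                              tr=config.tr, events=events,
                                              run_type=run_type)
        inter, comp = motor_first_level(runs, config)
        affine = runs["semantic"].affine
        patterns.save_map(inter, affine, gdir / f"sub-{s:02d}_interaction.nii.gz")
        patterns.save_map(comp, affine, gdir / f"sub-{s:02d}_component.nii.gz")
        fit = semantic_first_level(runs["semantic"])
        tmaps = np.stack([fit.t_map(c) for c in CONDITIONS], axis=-1)
        patterns.save_map(tmaps, affine, gdir / f"sub-{s:02d}_semantic_tstat.nii.gz")
    (gdir / "conditions.json").write_text(json.dumps(list(CONDITIONS)))


def stage_cluster(out_dir: Path) -> glm.ClusterTable:
    """Second-level one-sample t on the interaction maps, cluster extraction
    with the exclusive mask, cluster table and label map."""
    out_dir = Path(out_dir)
    config = _load_config(out_dir)
    gdir = out_dir / "glm"
    group = out_dir / "group"
    group.mkdir(parents=True, exist_ok=True)
    inters, comps = [], []
    affine = synth.default_affine(config.voxel_size_mm)
    for s in range(config.n_subjects):
        arr, affine = patterns.load_map(gdir / f"sub-{s:02d}_interaction.nii.gz")
        inters.append(arr)
        comps.append(patterns.load_map(gdir / f"sub-{s:02d}_component.nii.gz")[0])
    group_t, group_p = glm.second_level_contrast(inters)
    _, excl_p = glm.second_level_contrast(comps)
    table = glm.extract_clusters(group_t, group_p, config.cluster_p,
                                 config.cluster_extent,
                                 exclusive_mask=(excl_p, config.mask_p),
                                 connectivity=config.connectivity)
    patterns.save_map(group_t, affine, group / "tool_planning_tstat.nii.gz")
    patterns.save_map(group_p, affine, group / "tool_planning_p.nii.gz")
    labels = np.zeros(config.grid, dtype=float)
    for cluster in table:
        labels[tuple(cluster.voxels.T)] = cluster.id
    patterns.save_map(labels, affine, group / "cluster_labels.nii.gz")
    table.to_dataframe().to_csv(group / "clusters.tsv", sep="\t", index=False)
    return table


def stage_roi(out_dir: Path) -> dict[str, patterns.ROIMask]:
    """ROI masks from the cluster label map, named by overlap with the
    configured (planted) layout."""
    out_dir = Path(out_dir)
    config = _load_config(out_dir)
    labels, affine = patterns.load_map(out_dir / "group" / "cluster_labels.nii.gz")
    rdir = out_dir / "rois"
    rdir.mkdir(parents=True, exist_ok=True)
    clusters = []
    for lab in sorted(set(np.unique(labels)) - {0.0}):
        voxels = np.argwhere(labels == lab)
        clusters.append(glm.Cluster(id=int(lab), size=len(voxels), voxels=voxels,
                                    peak_coordinate=tuple(int(v) for v in voxels[0]),
                                    peak_stat=0.0))
    table = glm.ClusterTable(sorted(clusters, key=lambda c: -c.size))
    matches = match_clusters_to_layout(table, roi_layout(config), config.grid)
    masks: dict[str, patterns.ROIMask] = {}
    for cluster in table:
        matched, _ = matches[cluster.id]
        name = matched if matched is not None else f"cluster{cluster.id}"
        mask = patterns.mask_from_cluster(cluster, config.grid, affine, name)
        masks[name] = mask
        patterns.save_mask(mask, rdir / f"{name}_mask.nii.gz")
    return masks


def _load_patterns(out_dir: Path, config: PipelineConfig,
                   ) -> dict[str, patterns.PatternMatrix]:
    gdir = out_dir / "glm"
    conditions = tuple(json.loads((gdir / "conditions.json").read_text()))
    tstack = [patterns.load_map(gdir / f"sub-{s:02d}_semantic_tstat.nii.gz")[0]
              for s in range(config.n_subjects)]
    out: dict[str, patterns.PatternMatrix] = {}
    for mask_path in sorted((out_dir / "rois").glob("*_mask.nii.gz")):
        name = mask_path.name[:-len("_mask.nii.gz")]
        mask = patterns.load_mask(mask_path, name=name)
        idx = tuple(mask.voxel_indices.T)
        data = np.stack([np.stack([t[..., c][idx] for c in range(len(conditions))])
                         for t in tstack])
        out[name] = patterns.PatternMatrix(data=data,
                                           subjects=list(range(config.n_subjects)),
                                           condition_order=conditions, roi=mask)
    return out


def stage_mvpa(out_dir: Path) -> pd.DataFrame:
    out_dir = Path(out_dir)
    config = _load_config(out_dir)
    mats = _load_patterns(out_dir, config)
    seeds = _stage_seeds(config)
    mdir = out_dir / "mvpa"
    mdir.mkdir(parents=True, exist_ok=True)
    if mats:
        df = similarity.run_mvpa(mats, n_permutations=config.n_permutations,
                                 seed=_as_int(seeds["permutations"]),
                                 literal_three=config.literal_three)
    else:
        df = pd.DataFrame(columns=["roi", "contrast", "n_subjects",
                                   "observed_mean", "sem", "p_uncorrected",
                                   "p_fdr", "n_permutations", "seed"])
    df.to_csv(mdir / "mvpa_results.tsv", sep="\t", index=False)
    return df


def stage_followup(out_dir: Path) -> dict[str, univariate.AnovaResult]:
    out_dir = Path(out_dir)
    config = _load_config(out_dir)
    df = pd.read_csv(out_dir / "mvpa" / "mvpa_results.tsv", sep="\t")
    mats = _load_patterns(out_dir, config)
    fdir = out_dir / "followup"
    fdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, univariate.AnovaResult] = {}
    sig = df[(df["contrast"] == 1) & (df["p_fdr"] < config.alpha)]
    for name in sig["roi"]:
        means = univariate.roi_means(mats[name])
        result = univariate.rm_anova_2x2(means)
        result.posthoc = univariate.posthoc_paired(means)
        result.to_dataframe().to_csv(fdir / f"{name}_anova.tsv", sep="\t",
                                     index=False)
        result.posthoc.to_csv(fdir / f"{name}_posthoc.tsv", sep="\t", index=False)
        out[name] = result
    return out


def stage_behavior(out_dir: Path) -> pd.DataFrame:
    out_dir = Path(out_dir)
    records = pd.read_csv(out_dir / "sim" / "behavior.tsv", sep="\t",
                          na_values=["n/a"])
    bdir = out_dir / "behavior"
    bdir.mkdir(parents=True, exist_ok=True)
    summary = univariate.summarize_behavior(records)
    summary.to_csv(bdir / "behavior_summary.tsv", sep="\t", index=False,
                   na_rep="n/a")
    univariate.priming_differences(records).to_csv(
        bdir / "priming_effects.tsv", sep="\t", index=False, na_rep="n/a")
    return summary
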
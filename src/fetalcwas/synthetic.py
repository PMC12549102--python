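"""Synthetic resting-state cohorts with planted network structure.

Emulates the statistical structure the downstream analysis assumes: a
cohort of ~59 scans, 100 ROIs sampled at TR 3 s with ~110 volumes each,
BOLD series drawn from a zero-mean multivariate normal whose correlation
matrix has modular block structure (14 equal communities by default),
questionnaire scores drawn from truncated normals matching the reported
cohort means/SDs, motion traces with Bernoulli spikes, and optionally a
sparse set of edges whose population correlation varies linearly with a
behavior score — the ground truth that recovery tests target.

Everything is driven by a single integer seed; fixed seed means
bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from fetalcwas.exceptions import SpecError
from fetalcwas.motion import SubjectScan

#: eigenvalue floor used when repairing an indefinite correlation matrix
_PD_EPS = 1e-8

#: planted effects keep target correlations inside this band
EFFECT_CLIP = 0.9


@dataclass(frozen=True)
class BehaviorSpec:
    """Truncated-normal questionnaire score distribution.

    floor/ceiling are the instrument bounds (the scale cannot leave them),
    not the observed sample range.
    """

    name: str
    mean: float
    sd: float
    floor: float
    ceiling: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise SpecError(f"{self.name}: sd must be nonnegative, got {self.sd}")
        if not self.floor <= self.mean <= self.ceiling:
            raise SpecError(
                f"{self.name}: mean {self.mean} outside [{self.floor}, {self.ceiling}]"
            )


#: cohort questionnaire distributions: reported mean (SD) on each
#: instrument's own bounds (SSAI/STAI 20-80, PSS 0-40, EPDS 0-30)
DEFAULT_BEHAVIORS = (
    BehaviorSpec("ssai", mean=26.66, sd=6.72, floor=20, ceiling=80),
    BehaviorSpec("stai", mean=28.09, sd=6.62, floor=20, ceiling=80),
    BehaviorSpec("pss", mean=9.27, sd=5.13, floor=0, ceiling=40),
    BehaviorSpec("epds", mean=3.24, sd=2.84, floor=0, ceiling=30),
)


@dataclass(frozen=True)
class EffectSpec:
    """A planted linear brain-behavior effect on a set of edges.

    For subject i with score s_i, each edge in ``edge_set`` has population
    correlation base_r + slope_per_unit * (s_i - mean(s)), clipped to
    [-EFFECT_CLIP, EFFECT_CLIP].
    """

    behavior_name: str
    edge_set: tuple[tuple[int, int], ...]
    slope_per_unit: float
    base_r: float = 0.05

    def __post_init__(self) -> None:
        seen = set()
        for i, j in self.edge_set:
            if i == j:
                raise SpecError(f"self-edge ({i},{i}) in effect edge set")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise SpecError(f"duplicate edge {key} in effect edge set")
            seen.add(key)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort."""

    n_subjects: int = 59
    n_rois: int = 100
    n_modules: int = 14
    n_volumes: int = 110
    tr_seconds: float = 3.0
    within_module_r: float = 0.4
    between_module_r: float = 0.05
    behavior_specs: tuple[BehaviorSpec, ...] = DEFAULT_BEHAVIORS
    effect_specs: tuple[EffectSpec, ...] = ()
    motion_spike_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise SpecError("n_subjects must be nonnegative")
        if not 1 <= self.n_modules <= self.n_rois:
            raise SpecError("need 1 <= n_modules <= n_rois")
        if abs(self.within_module_r) >= 1 or abs(self.between_module_r) >= 1:
            raise SpecError("block correlations must satisfy |r| < 1")
        if not 0 <= self.motion_spike_prob <= 1:
            raise SpecError("motion_spike_prob must lie in [0, 1]")
        for eff in self.effect_specs:
            if any(
                not (0 <= i < self.n_rois and 0 <= j < self.n_rois)
                for i, j in eff.edge_set
            ):
                raise SpecError("effect edge outside ROI range")
            if eff.behavior_name not in {b.name for b in self.behavior_specs}:
                raise SpecError(
                    f"effect refers to unknown behavior {eff.behavior_name!r}"
                )


@dataclass
class Cohort:
    """Generated scans plus covariates and the generating ground truth."""

    spec: CohortSpec
    scans: list[SubjectScan]
    covariates: pd.DataFrame  # one row per scan
    module_assignment: np.ndarray  # planted module id per ROI, 1-based
    behaviors: dict[str, np.ndarray] = field(default_factory=dict)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def module_assignment(n_rois: int, n_modules: int) -> np.ndarray:
    """Planted partition: equal-size contiguous blocks, 1-based ids.

    Remainder ROIs are assigned to the last module.
    """
    size = n_rois // n_modules
    assignment = np.minimum(np.arange(n_rois) // size, n_modules - 1) + 1
    return assignment


def block_correlation(
    assignment: np.ndarray, within_r: float, between_r: float
) -> np.ndarray:
    """Block correlation matrix from a module assignment."""
    same = assignment[:, None] == assignment[None, :]
    corr = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(corr, 1.0)
    return corr


def nearest_positive_definite(corr: np.ndarray, eps: float = _PD_EPS) -> np.ndarray:
    """Eigenvalue-clipped repair to the nearest positive-definite matrix.

    Eigenvalues below ``eps`` are raised to it and the diagonal is rescaled
    back to 1 so the result is still a correlation matrix.
    """
    corr = np.asarray(corr, dtype=float)
    if not np.all(np.isfinite(corr)):
        raise SpecError("correlation matrix contains non-finite entries")
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2.0)
    if vals[0] >= eps:
        return corr
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@lru_cache(maxsize=64)
def _truncnorm_params(
    mean: float, sd: float, floor: float, ceiling: float
) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [floor, ceiling]-truncation has the
    requested mean and sd (moment matching).

    Without this, truncating N(mean, sd) at an instrument floor close to
    the mean shifts the realised mean upward by a sizeable fraction of sd.
    Some reported (mean, sd) pairs sit at the boundary of what a truncated
    normal can realise (sd close to mean - floor); the least-squares
    solution then lands on the nearest attainable moments.
    """

    def residual(p):
        mu, log_s = p
        s = np.exp(log_s)
        a, b = (floor - mu) / s, (ceiling - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.least_squares(residual, x0=[mean, np.log(sd)], xtol=1e-12)
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    achieved = np.asarray(residual(sol.x))
    naive = np.asarray(residual([mean, np.log(sd)]))
    if np.abs(achieved).sum() >= np.abs(naive).sum():
        return mean, sd
    return mu, sigma


def generate_behavior(spec: BehaviorSpec, n: int, seed: int) -> np.ndarray:
    """Draw n scores from a truncated normal on [floor, ceiling].

    The underlying normal is moment-matched so the *truncated* distribution
    has mean ~= spec.mean and sd ~= spec.sd.
    """
    if n < 0:
        raise SpecError("n must be nonnegative")
    if n == 0:
        return np.array([])
    if spec.sd == 0:
        return np.full(n, float(spec.mean))
    mu, sigma = _truncnorm_params(spec.mean, spec.sd, spec.floor, spec.ceiling)
    a = (spec.floor - mu) / sigma
    b = (spec.ceiling - mu) / sigma
    rng = _rng(seed)
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def sample_timeseries(
    corr: np.ndarray, n_volumes: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean multivariate normal series with the given correlation."""
    corr = nearest_positive_definite(corr)
    chol = np.linalg.cholesky(corr)
    white = rng.standard_normal((corr.shape[0], n_volumes))
    return chol @ white


def generate_timeseries(spec: CohortSpec, subject_index: int) -> SubjectScan:
    """One subject's scan under the pure block model (no planted effect)."""
    assignment = module_assignment(spec.n_rois, spec.n_modules)
    corr = block_correlation(
        assignment, spec.within_module_r, spec.between_module_r
    )
    return _assemble_scan(spec, subject_index, corr)


def _assemble_scan(
    spec: CohortSpec, subject_index: int, corr: np.ndarray
) -> SubjectScan:
    ts = sample_timeseries(corr, spec.n_volumes, _rng(spec.seed, 1, subject_index))
    trans, rot = generate_motion_trace(
        spec.n_volumes,
        spec.motion_spike_prob,
        seed=spec.seed,
        _stream=(2, subject_index),
    )
    return SubjectScan(
        scan_id=f"sub-{subject_index:03d}",
        timeseries=ts,
        translation_delta=trans,
        rotation_delta=rot,
        tr_seconds=spec.tr_seconds,
    )


def inject_behavior_effect(
    spec: CohortSpec, effect: EffectSpec, scores: np.ndarray
) -> list[SubjectScan]:
    """Cohort whose effect edges track the behavior score linearly.

    Subject i's correlation matrix is the block matrix with each edge in
    ``effect.edge_set`` replaced by base_r + slope * (score_i - mean score),
    clipped to [-EFFECT_CLIP, EFFECT_CLIP]; the matrix is then repaired to
    positive definite and sampled. The generating slope is therefore the
    direct target of recovery tests.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != spec.n_subjects:
        raise SpecError("need exactly one score per subject")
    assignment = module_assignment(spec.n_rois, spec.n_modules)
    base = block_correlation(assignment, spec.within_module_r, spec.between_module_r)
    centered = scores - scores.mean()
    scans = []
    for i in range(spec.n_subjects):
        corr = base.copy()
        target = np.clip(
            effect.base_r + effect.slope_per_unit * centered[i],
            -EFFECT_CLIP,
            EFFECT_CLIP,
        )
        for a, b in effect.edge_set:
            corr[a, b] = corr[b, a] = target
        scans.append(_assemble_scan(spec, i, corr))
    return scans


def generate_motion_trace(
    n_volumes: int,
    spike_prob: float,
    seed: int,
    _stream: tuple[int, ...] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-volume translation (mm) and rotation (deg) frame-to-frame deltas.

    Baseline deltas are small (well below the 1 mm / 1.5 deg censoring
    thresholds); each volume independently spikes with probability
    ``spike_prob``, in which case either its translation exceeds 1 mm or
    its rotation exceeds 1.5 deg.
    """
    if n_volumes < 0:
        raise SpecError("n_volumes must be nonnegative")
    if not 0 <= spike_prob <= 1:
        raise SpecError("spike_prob must lie in [0, 1]")
    rng = _rng(seed, *_stream)
    trans = np.clip(np.abs(rng.normal(0.0, 0.08, n_volumes)), 0.0, 0.5)
    rot = np.clip(np.abs(rng.normal(0.0, 0.1, n_volumes)), 0.0, 0.7)
    spikes = rng.random(n_volumes) < spike_prob
    which_rot = rng.random(n_volumes) < 0.5
    trans[spikes & ~which_rot] = rng.uniform(1.05, 2.5, int((spikes & ~which_rot).sum()))
    rot[spikes & which_rot] = rng.uniform(1.6, 3.5, int((spikes & which_rot).sum()))
    return trans, rot


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Full cohort: scans, questionnaire covariates, planted ground truth.

    Behavior scores are drawn per instrument; if effect specs are present
    the (single) effect's scored behavior modulates its edges. Multiple
    effects on disjoint edge sets are combined into one per-subject
    correlation matrix.
    """
    behaviors = {
        b.name: generate_behavior(b, spec.n_subjects, _seed_for(spec.seed, 3, k))
        for k, b in enumerate(spec.behavior_specs)
    }
    if spec.effect_specs:
        claimed: set[tuple[int, int]] = set()
        for eff in spec.effect_specs:
            edges = {(min(i, j), max(i, j)) for i, j in eff.edge_set}
            if claimed & edges:
                raise SpecError("effect specs share edges; edge sets must be disjoint")
            claimed |= edges
        scans = _generate_with_effects(spec, behaviors)
    else:
        scans = [generate_timeseries(spec, i) for i in range(spec.n_subjects)]
    cov = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(spec.n_subjects)],
            "scan_id": [s.scan_id for s in scans],
            **{name: vals for name, vals in behaviors.items()},
            "retained_volumes": [s.retained_volumes for s in scans],
        }
    )
    return Cohort(
        spec=spec,
        scans=scans,
        covariates=cov,
        module_assignment=module_assignment(spec.n_rois, spec.n_modules),
        behaviors=behaviors,
    )


def _seed_for(seed: int, *stream: int) -> int:
    # derive a small deterministic sub-seed for APIs that take a plain int
    return int(np.random.SeedSequence([int(seed), *stream]).generate_state(1)[0] % (2**31))


def _generate_with_effects(
    spec: CohortSpec, behaviors: dict[str, np.ndarray]
) -> list[SubjectScan]:
    assignment = module_assignment(spec.n_rois, spec.n_modules)
    base = block_correlation(assignment, spec.within_module_r, spec.between_module_r)
    centered = {
        name: vals - vals.mean() for name, vals in behaviors.items()
    }
    scans = []
    for i in range(spec.n_subjects):
        corr = base.copy()
        for eff in spec.effect_specs:
            target = np.clip(
                eff.base_r + eff.slope_per_unit * centered[eff.behavior_name][i],
                -EFFECT_CLIP,
                EFFECT_CLIP,
            )
            for a, b in eff.edge_set:
                corr[a, b] = corr[b, a] = target
        scans.append(_assemble_scan(spec, i, corr))
    return scans


def roi_labels(n_rois: int) -> list[str]:
    return [f"ROI{k + 1:03d}" for k in range(n_rois)]


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write the cohort to disk in the pipeline's plain-text formats.

    Per scan: a time-series TSV (rows = ROIs, columns = volumes) and a
    motion-trace TSV (volume, trans_delta_mm, rot_delta_deg). Cohort-level:
    covariates CSV and a ground-truth JSON (module assignment, effects).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = roi_labels(cohort.spec.n_rois)
    for scan in cohort.scans:
        ts = pd.DataFrame(scan.timeseries, index=labels)
        ts.to_csv(directory / f"{scan.scan_id}_timeseries.tsv", sep="\t")
        motion = pd.DataFrame(
            {
                "volume": np.arange(scan.n_volumes),
                "trans_delta_mm": scan.translation_delta,
                "rot_delta_deg": scan.rotation_delta,
            }
        )
        motion.to_csv(directory / f"{scan.scan_id}_motion.tsv", sep="\t", index=False)
    cohort.covariates.to_csv(directory / "covariates.csv", index=False)
    truth = {
        "module_assignment": cohort.module_assignment.tolist(),
        "effects": [
            {
                "behavior_name": e.behavior_name,
                "edge_set": [list(edge) for edge in e.edge_set],
                "slope_per_unit": e.slope_per_unit,
                "base_r": e.base_r,
            }
            for e in cohort.spec.effect_specs
        ],
        "seed": cohort.spec.seed,
    }
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return directory


def read_cohort(directory: str | Path, tr_seconds: float = 3.0) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    cov = pd.read_csv(directory / "covariates.csv")
    truth = json.loads((directory / "ground_truth.json").read_text())
    scans = []
    for scan_id in cov["scan_id"]:
        ts = pd.read_csv(directory / f"{scan_id}_timeseries.tsv", sep="\t", index_col=0)
        motion = pd.read_csv(directory / f"{scan_id}_motion.tsv", sep="\t")
        scans.append(
            SubjectScan(
                scan_id=scan_id,
                timeseries=ts.to_numpy(),
                translation_delta=motion["trans_delta_mm"].to_numpy(),
                rotation_delta=motion["rot_delta_deg"].to_numpy(),
                tr_seconds=tr_seconds,
            )
        )
    n_rois = scans[0].timeseries.shape[0]
    assignment = np.asarray(truth["module_assignment"])
    behaviors = {
        b.name: cov[b.name].to_numpy()
        for b in DEFAULT_BEHAVIORS
        if b.name in cov.columns
    }
    spec = CohortSpec(
        n_subjects=len(scans),
        n_rois=n_rois,
        n_modules=int(assignment.max()),
        n_volumes=scans[0].n_volumes,
        tr_seconds=tr_seconds,
        seed=int(truth.get("seed", 0)),
    )
    return Cohort(
        spec=spec,
        scans=scans,
        covariates=cov,
        module_assignment=assignment,
        behaviors=behaviors,
    )
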
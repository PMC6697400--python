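"""Synthetic cohort generator.

Emulates a case-control study of perceptual stability and cognitive
rigidity: a single latent "rigidity" trait per subject drives

* percept durations in a bistable (structure-from-motion) viewing test
  (gamma-distributed, long-tailed; higher trait -> longer percepts),
* run lengths of voluntarily repeated tasks in a spontaneous
  task-switching (TS) test (two-state persistence process -> geometric-like
  run lengths; higher trait -> higher persistence),
* the mean gray-matter volume (GMV) of a planted spherical cluster
  (negative loading for the default scenario), and
* ordinal restricted-repetitive-behavior (RRB) scores for the ASD group.

The two behavioral indices correlate only through the shared trait: each is
driven by ``u_k = T + e_k`` with ``Var(e_k) = 1/rho - 1`` so that the
subject-level correlation of the two indices equals ``trait_behavior_corr``.

Everything is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "RTParams",
    "DemographicCalibration",
    "CohortSpec",
    "GMVStack",
    "CohortDataset",
    "generate_cohort",
    "generate_percept_timeline",
    "generate_spontaneous_session",
    "yoke_instructed_session",
    "generate_gmv_images",
    "default_persistence_map",
]

SHAPES = ("circle", "square", "triangle", "pentagon")


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class RTParams:
    """Reaction-time model (milliseconds).

    Spontaneous switching is nearly free of switch cost while instructed
    switching carries a clear one; both modes share a common Gaussian noise.
    """

    spont_repeat_mean: float = 650.0
    spont_switch_cost: float = 15.0
    instr_repeat_mean: float = 700.0
    instr_switch_cost: float = 150.0
    sd: float = 150.0
    iti_s: float = 0.25
    min_rt_ms: float = 150.0
    timeout_ms: float = 3000.0


@dataclass(frozen=True)
class DemographicCalibration:
    """Group means/SDs for age and IQ plus ADOS score models (ASD only).

    Defaults reproduce the demographic table of the emulated study
    (SEM-to-SD conversion at n = 22 per group).
    """

    age_mean_td: float = 30.8
    age_mean_asd: float = 33.0
    age_sd_td: float = 7.5
    age_sd_asd: float = 9.4
    fiq_mean_td: float = 112.8
    fiq_mean_asd: float = 119.7
    fiq_sd_td: float = 14.1
    fiq_sd_asd: float = 12.2
    viq_mean_td: float = 114.5
    viq_mean_asd: float = 120.6
    viq_sd_td: float = 13.6
    viq_sd_asd: float = 14.5
    piq_mean_td: float = 108.0
    piq_mean_asd: float = 114.7
    piq_sd_td: float = 15.0
    piq_sd_asd: float = 12.2
    ados_social_mean: float = 2.7
    ados_social_sd: float = 1.4
    ados_comm_mean: float = 6.2
    ados_comm_sd: float = 2.3
    # RRB in {0,1,2}: fixed quantile cuts of the noisy ASD trait chosen so
    # P = (0.45, 0.30, 0.25) and the mean score is ~0.8.
    rrb_cut_quantiles: tuple[float, float] = (0.45, 0.75)
    rrb_trait_noise_sd: float = 0.75


def default_persistence_map(intercept: float = 0.70, slope: float = 0.35) -> Callable:
    """Monotone logistic map from the noisy rigidity trait to the per-trial
    task-persistence probability; sigma(0.70) ~ 0.668 gives a mean run
    length of ~3 trials for an average control subject."""

    def _map(u):
        return _sigmoid(intercept + slope * np.asarray(u, dtype=float))

    return _map


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the generator; defaults are the emulated study's
    conditions (22 subjects per group, 5 x 90 s percept runs, 5 x 3 min TS
    runs, behavioral inter-correlation 0.45, negatively loaded planted
    cluster, 8 mm FWHM spatial correlation)."""

    n_per_group: int = 22
    trait_mean_td: float = 0.0
    trait_mean_asd: float = 1.65
    trait_sd: float = 1.0
    trait_behavior_corr: float = 0.45
    # Finite-run median estimation attenuates the latent correlation by
    # the geometric mean of the two indices' reliabilities under the
    # default 5-run design (~0.90). The latent correlation is inflated by
    # 1/measurement_attenuation so the realized correlation of the scored
    # medians converges to trait_behavior_corr, as the generator contract
    # requires.
    measurement_attenuation: float = 0.90

    # bistable percept model
    percept_shape: float = 3.0
    percept_base_scale_s: float = 1.5
    percept_trait_gain: float = 0.18
    mixed_event_prob: float = 0.08
    mixed_mean_s: float = 1.0
    run_length_s: float = 90.0
    n_runs: int = 5

    # task-switching model
    persistence_map: Callable | None = None
    lapse_rate: float = 0.01
    timeout_rate: float = 0.002
    instructed_accuracy: float = 0.97
    trial_budget_s: float = 180.0
    rt_params: RTParams = field(default_factory=RTParams)

    # volumes
    include_volumes: bool = True
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 3.0
    cluster_center: tuple[int, int, int] = (21, 12, 20)
    cluster_radius_mm: float = 15.0
    cluster_effect: float = -0.06
    noise_sd: float = 0.015
    smooth_fwhm_mm: float = 8.0
    gmv_baseline: float = 0.5
    # global ASD surplus; sized so that, net of the planted cluster's
    # deficit, the whole-brain group difference is marginal (t ~ 2)
    asd_whole_brain_offset: float = 0.013
    # between-subject global (brain-size-like) GMV variation; makes the
    # group whole-brain difference marginal rather than trivially large
    subject_global_sd: float = 0.012
    brain_radii_mm: tuple[float, float, float] = (42.0, 46.0, 38.0)

    demo_calibration: DemographicCalibration = field(default_factory=DemographicCalibration)
    seed: int = 0

    def get_persistence_map(self) -> Callable:
        return self.persistence_map or default_persistence_map()

    def behavior_noise_sd(self) -> float:
        """SD of the index-specific noise e_k giving the target
        correlation between the two *scored* behavioral indices (the
        latent correlation is inflated to offset median-measurement
        attenuation)."""
        rho = min(self.trait_behavior_corr / self.measurement_attenuation, 0.99)
        return self.trait_sd * math.sqrt(1.0 / rho - 1.0)

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError(f"n_per_group must be positive, got {self.n_per_group}")
        if not (0.0 < self.measurement_attenuation <= 1.0):
            raise ValueError(
                f"measurement_attenuation must lie in (0,1], got {self.measurement_attenuation}"
            )
        if not (0.0 < self.trait_behavior_corr < 1.0):
            raise ValueError(
                f"trait_behavior_corr must lie in (0,1), got {self.trait_behavior_corr}"
            )
        if self.trait_sd <= 0:
            raise ValueError(f"trait_sd must be positive, got {self.trait_sd}")
        if self.percept_shape <= 0:
            raise ValueError(f"percept_shape must be positive, got {self.percept_shape}")
        if not (0.0 <= self.lapse_rate < 1.0):
            raise ValueError(f"lapse_rate must lie in [0,1), got {self.lapse_rate}")
        if not (0.0 <= self.timeout_rate < 1.0):
            raise ValueError(f"timeout_rate must lie in [0,1), got {self.timeout_rate}")
        if not (0.0 <= self.mixed_event_prob < 1.0):
            raise ValueError(
                f"mixed_event_prob must lie in [0,1), got {self.mixed_event_prob}"
            )
        if self.run_length_s <= 0 or self.trial_budget_s <= 0:
            raise ValueError("run_length_s and trial_budget_s must be positive")
        if self.n_runs <= 0:
            raise ValueError(f"n_runs must be positive, got {self.n_runs}")
        pmap = self.get_persistence_map()
        probe = pmap(np.array([-6.0, 0.0, 6.0]))
        if np.any(probe <= 0.0) or np.any(probe >= 1.0):
            raise ValueError("persistence_map must return probabilities in (0,1)")
        if self.include_volumes:
            center_mm = np.asarray(self.cluster_center, float) * self.voxel_size_mm
            hi_mm = (np.asarray(self.volume_shape, float) - 1) * self.voxel_size_mm
            if np.any(center_mm - self.cluster_radius_mm < 0) or np.any(
                center_mm + self.cluster_radius_mm > hi_mm
            ):
                raise ValueError("cluster_center/cluster_radius_mm: cluster outside volume")


@dataclass
class GMVStack:
    """Per-subject GMV volumes on a shared grid.

    values: (n_subjects, X, Y, Z) modulated-GMV units; mask: in-brain
    voxels; planted: the generator's spherical cluster (ground truth)."""

    values: np.ndarray
    mask: np.ndarray
    voxel_size_mm: float
    planted: np.ndarray
    affine: np.ndarray | None = None

    def subject_image(self, i: int) -> np.ndarray:
        return self.values[i]


@dataclass
class CohortDataset:
    """One simulated cohort.

    ``subjects`` carries demographics (ADOS columns are NaN for TD,
    mirroring how such scores exist only for the clinical group);
    ``latents`` carries the hidden traits for self-consistency checks and
    is never part of the on-disk cohort table."""

    spec: CohortSpec
    subjects: pd.DataFrame
    percept_events: pd.DataFrame
    trials: pd.DataFrame
    images: GMVStack | None
    latents: pd.DataFrame

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject"])

    def group_index(self, group: str) -> np.ndarray:
        return (self.subjects["group"] == group).to_numpy()


# ---------------------------------------------------------------------------
# percept timelines


def generate_percept_timeline(
    trait: float, spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """One 90 s run of percept reports.

    Clear up/down percepts alternate with gamma(shape, scale) durations,
    scale = base * exp(gain * trait) so the median duration grows
    monotonically with the trait. Brief mixed/unsure reports are inserted
    at a low rate (~1.7% of run time at defaults). Events beyond the run
    end are truncated away.
    """
    if not np.isfinite(trait):
        raise ValueError("trait must be finite")
    scale = spec.percept_base_scale_s * math.exp(spec.percept_trait_gain * trait)
    onsets: list[float] = []
    labels: list[str] = []
    t = float(rng.uniform(0.3, 1.0))  # latency of the first clear report
    label = "up" if rng.random() < 0.5 else "down"
    while t < spec.run_length_s:
        onsets.append(t)
        labels.append(label)
        t += float(rng.gamma(spec.percept_shape, scale))
        if spec.mixed_event_prob > 0 and rng.random() < spec.mixed_event_prob:
            if t < spec.run_length_s:
                onsets.append(t)
                labels.append("mixed")
                t += float(rng.exponential(spec.mixed_mean_s))
        label = "down" if label == "up" else "up"
    return pd.DataFrame({"onset_s": onsets, "label": labels})


# ---------------------------------------------------------------------------
# task-switching sessions


def _random_stimuli(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial stimulus layout: index of the designated shape (circle)
    and of the uniquely brightest figure; the circle is never the
    brightest so retrospective task inference is always well defined."""
    circle_idx = rng.integers(0, 4, size=n)
    bright_idx = (circle_idx + rng.integers(1, 4, size=n)) % 4
    return circle_idx, bright_idx


def generate_spontaneous_session(
    trait: float, spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """One 3-min spontaneous TS run as a trial table.

    Task choice follows a two-state persistence process (repeat with
    probability p(trait), else switch). Columns: task (hidden generating
    task), circle_index, bright_index, choice_index (-1 on timeout),
    rt_ms, timeout, cue ('none' in spontaneous mode).
    """
    if not np.isfinite(trait):
        raise ValueError("trait must be finite")
    rt = spec.rt_params
    p_persist = float(spec.get_persistence_map()(trait))
    n_max = int(spec.trial_budget_s / ((rt.min_rt_ms / 1000.0) + rt.iti_s)) + 8

    first = int(rng.random() < 0.5)
    switches = rng.random(n_max - 1) < (1.0 - p_persist)
    tasks = np.empty(n_max, dtype=np.int64)
    tasks[0] = first
    tasks[1:] = (first + np.cumsum(switches)) % 2

    is_switch = np.zeros(n_max, dtype=bool)
    is_switch[1:] = switches
    rts = rng.normal(
        rt.spont_repeat_mean + rt.spont_switch_cost * is_switch, rt.sd, size=n_max
    )
    rts = np.clip(rts, rt.min_rt_ms, rt.timeout_ms - 1.0)
    timeouts = rng.random(n_max) < spec.timeout_rate
    rts[timeouts] = rt.timeout_ms

    elapsed = np.cumsum(rts / 1000.0 + rt.iti_s)
    n = int(np.searchsorted(elapsed, spec.trial_budget_s, side="right"))
    n = max(n, 1)

    circle_idx, bright_idx = _random_stimuli(n, rng)
    tasks = tasks[:n]
    choice = np.where(tasks == 0, circle_idx, bright_idx)
    lapses = rng.random(n) < spec.lapse_rate
    if lapses.any():
        # choose a figure that is neither the circle nor the brightest
        others = rng.integers(0, 2, size=n)
        all_idx = np.arange(4)
        for i in np.flatnonzero(lapses):
            pool = np.setdiff1d(all_idx, [circle_idx[i], bright_idx[i]])
            choice[i] = pool[others[i] % len(pool)]
    choice = np.where(timeouts[:n], -1, choice)

    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "mode": "spontaneous",
            "cue": "none",
            "task": np.where(tasks == 0, "shape", "brightness"),
            "circle_index": circle_idx,
            "bright_index": bright_idx,
            "choice_index": choice,
            "rt_ms": rts[:n],
            "timeout": timeouts[:n],
        }
    )


def _classify_choices(trials: pd.DataFrame) -> np.ndarray:
    """Vectorized retrospective task inference (shape / brightness /
    unclassifiable); mirrors behavior.classify_trial."""
    choice = trials["choice_index"].to_numpy()
    circle = trials["circle_index"].to_numpy()
    bright = trials["bright_index"].to_numpy()
    if np.any(circle == bright):
        raise ValueError("stimulus invariant violated: circle is the brightest figure")
    out = np.full(len(trials), "unclassifiable", dtype=object)
    out[choice == circle] = "shape"
    out[choice == bright] = "brightness"
    out[choice < 0] = "unclassifiable"
    return out


def yoke_instructed_session(
    spontaneous: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Instructed-mode session yoked to a spontaneous one.

    The cue sequence is the spontaneous session's inferred task sequence
    with unclassifiable trials omitted; stimuli are regenerated and RTs
    redrawn with instructed-mode parameters (larger switch cost).
    """
    labels = _classify_choices(spontaneous)
    cues = labels[labels != "unclassifiable"]
    if len(cues) == 0:
        raise ValueError("cannot yoke an instructed session to an empty classified sequence")
    n = len(cues)
    rt = spec.rt_params

    is_switch = np.zeros(n, dtype=bool)
    is_switch[1:] = cues[1:] != cues[:-1]
    rts = rng.normal(
        rt.instr_repeat_mean + rt.instr_switch_cost * is_switch, rt.sd, size=n
    )
    rts = np.clip(rts, rt.min_rt_ms, rt.timeout_ms - 1.0)
    timeouts = rng.random(n) < spec.timeout_rate
    rts[timeouts] = rt.timeout_ms

    circle_idx, bright_idx = _random_stimuli(n, rng)
    target = np.where(cues == "shape", circle_idx, bright_idx)
    errors = rng.random(n) >= spec.instructed_accuracy
    choice = target.copy()
    if errors.any():
        for i in np.flatnonzero(errors):
            pool = np.setdiff1d(np.arange(4), [target[i]])
            choice[i] = pool[rng.integers(0, 3)]
    choice = np.where(timeouts, -1, choice)

    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "mode": "instructed",
            "cue": cues,
            "task": cues,
            "circle_index": circle_idx,
            "bright_index": bright_idx,
            "choice_index": choice,
            "rt_ms": rts,
            "timeout": timeouts,
        }
    )


# ---------------------------------------------------------------------------
# volumes


def _smooth_unit_noise(
    shape: tuple[int, int, int], sigma_vox: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit voxelwise SD.

    The rescaling factor is the l2 norm of the separable smoothing kernel,
    computed from the same truncated kernel scipy uses.
    """
    white = rng.standard_normal(shape)
    if sigma_vox <= 0:
        return white
    smoothed = gaussian_filter(white, sigma_vox, mode="constant", truncate=4.0)
    radius = int(4.0 * sigma_vox + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma_vox) ** 2)
    w /= w.sum()
    norm_1d = math.sqrt(float((w**2).sum()))
    return smoothed / (norm_1d ** len(shape))


def _brain_mask(spec: CohortSpec) -> np.ndarray:
    shape = np.asarray(spec.volume_shape, dtype=float)
    center = (shape - 1) / 2.0
    radii_vox = np.asarray(spec.brain_radii_mm, dtype=float) / spec.voxel_size_mm
    grids = np.ogrid[[slice(0, int(s)) for s in spec.volume_shape]]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    return d2 <= 1.0


def _planted_sphere(spec: CohortSpec) -> np.ndarray:
    grids = np.ogrid[[slice(0, int(s)) for s in spec.volume_shape]]
    d2 = sum(
        ((g - c) * spec.voxel_size_mm) ** 2 for g, c in zip(grids, spec.cluster_center)
    )
    return d2 <= spec.cluster_radius_mm**2


def generate_gmv_images(
    traits: np.ndarray,
    is_asd: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> GMVStack:
    """Per-subject GMV volumes: baseline + group whole-brain offset +
    cluster_effect * trait inside the planted sphere + smoothed noise with
    voxelwise SD ``noise_sd``. The smoothing models post-preprocessing
    spatial correlation, not any preprocessing step itself."""
    spec.validate()
    traits = np.asarray(traits, dtype=float)
    is_asd = np.asarray(is_asd, dtype=bool)
    mask = _brain_mask(spec)
    sphere = _planted_sphere(spec)
    if not np.all(mask[sphere]):
        raise ValueError("planted cluster must lie inside the in-brain mask")
    sigma_vox = spec.smooth_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / spec.voxel_size_mm
    n = len(traits)
    values = np.empty((n,) + tuple(spec.volume_shape), dtype=np.float32)
    for i in range(n):
        vol = np.full(spec.volume_shape, spec.gmv_baseline, dtype=float)
        if is_asd[i]:
            vol += spec.asd_whole_brain_offset
        if spec.subject_global_sd > 0:
            vol += rng.normal(0.0, spec.subject_global_sd)
        vol[sphere] += spec.cluster_effect * traits[i]
        vol += spec.noise_sd * _smooth_unit_noise(spec.volume_shape, sigma_vox, rng)
        vol[~mask] = 0.0
        values[i] = vol
    return GMVStack(
        values=values,
        mask=mask,
        voxel_size_mm=spec.voxel_size_mm,
        planted=sphere & mask,
    )


# ---------------------------------------------------------------------------
# demographics and the full cohort


def _demographics(
    spec: CohortSpec, trait_rrb: np.ndarray, is_asd: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    cal = spec.demo_calibration
    n = len(trait_rrb)
    td = ~is_asd

    def draw(mean_td, mean_asd, sd_td, sd_asd):
        out = np.where(
            is_asd,
            rng.normal(mean_asd, sd_asd, size=n),
            rng.normal(mean_td, sd_td, size=n),
        )
        return out

    age = np.round(np.clip(draw(cal.age_mean_td, cal.age_mean_asd, cal.age_sd_td, cal.age_sd_asd), 18, 65), 1)
    fiq = np.round(np.clip(draw(cal.fiq_mean_td, cal.fiq_mean_asd, cal.fiq_sd_td, cal.fiq_sd_asd), 85, 160))
    viq = np.round(np.clip(draw(cal.viq_mean_td, cal.viq_mean_asd, cal.viq_sd_td, cal.viq_sd_asd), 85, 160))
    piq = np.round(np.clip(draw(cal.piq_mean_td, cal.piq_mean_asd, cal.piq_sd_td, cal.piq_sd_asd), 85, 160))

    # ADOS scores only exist for the ASD group
    social = np.round(np.clip(rng.normal(cal.ados_social_mean, cal.ados_social_sd, size=n), 0, 14))
    comm = np.round(np.clip(rng.normal(cal.ados_comm_mean, cal.ados_comm_sd, size=n), 0, 14))

    # RRB in {0,1,2} by fixed quantile cuts of the noisy ASD trait
    from scipy.stats import norm

    asd_trait_sd = math.sqrt(spec.trait_sd**2 + cal.rrb_trait_noise_sd**2)
    q1, q2 = cal.rrb_cut_quantiles
    c1 = spec.trait_mean_asd + asd_trait_sd * norm.ppf(q1)
    c2 = spec.trait_mean_asd + asd_trait_sd * norm.ppf(q2)
    rrb = np.digitize(trait_rrb, [c1, c2]).astype(float)

    df = pd.DataFrame(
        {
            "subject": [f"{'asd' if a else 'td'}{i:03d}" for i, a in enumerate(is_asd)],
            "group": np.where(is_asd, "ASD", "TD"),
            "age": age,
            "full_iq": fiq,
            "verbal_iq": viq,
            "performance_iq": piq,
            "ados_social": np.where(is_asd, social, np.nan),
            "ados_communication": np.where(is_asd, comm, np.nan),
            "ados_rrb": np.where(is_asd, rrb, np.nan),
        }
    )
    df.loc[td, ["ados_social", "ados_communication", "ados_rrb"]] = np.nan
    return df


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate a full cohort (behavior + demographics + volumes).

    A latent rigidity trait ``T`` is drawn per subject; percept timelines,
    TS sessions, the planted GMV cluster, and RRB scores all derive from
    ``T`` plus independent noise, so the two behavioral medians correlate
    near ``trait_behavior_corr`` and the ROI loads on both.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_per_group
    is_asd = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
    means = np.where(is_asd, spec.trait_mean_asd, spec.trait_mean_td)
    trait = rng.normal(means, spec.trait_sd)

    noise_sd = spec.behavior_noise_sd()
    u_percept = trait + rng.normal(0.0, noise_sd, size=2 * n)
    u_switch = trait + rng.normal(0.0, noise_sd, size=2 * n)
    u_rrb = trait + rng.normal(0.0, spec.demo_calibration.rrb_trait_noise_sd, size=2 * n)

    subjects = _demographics(spec, u_rrb, is_asd, rng)
    ids = subjects["subject"].to_numpy()

    percept_frames = []
    trial_frames = []
    for i, sid in enumerate(ids):
        for run in range(1, spec.n_runs + 1):
            tl = generate_percept_timeline(u_percept[i], spec, rng)
            tl.insert(0, "run", run)
            tl.insert(0, "subject", sid)
            percept_frames.append(tl)

            spont = generate_spontaneous_session(u_switch[i], spec, rng)
            instr = yoke_instructed_session(spont, spec, rng)
            for frame in (spont, instr):
                frame.insert(0, "run", run)
                frame.insert(0, "subject", sid)
            trial_frames.append(spont)
            trial_frames.append(instr)

    percept_events = pd.concat(percept_frames, ignore_index=True)
    trials = pd.concat(trial_frames, ignore_index=True)

    images = None
    if spec.include_volumes:
        images = generate_gmv_images(trait, is_asd, spec, rng)

    latents = pd.DataFrame(
        {
            "subject": ids,
            "trait": trait,
            "u_percept": u_percept,
            "u_switch": u_switch,
            "u_rrb": u_rrb,
        }
    )
    return CohortDataset(
        spec=spec,
        subjects=subjects,
        percept_events=percept_events,
        trials=trials,
        images=images,
        latents=latents,
    )


def null_spec(base: CohortSpec | None = None, seed: int = 0) -> CohortSpec:
    """A no-effect scenario: identical group traits, uncorrelated planted
    cluster. Downstream analyses should detect nothing above nominal
    error rates on cohorts generated from this spec."""
    base = base or CohortSpec()
    return replace(
        base,
        trait_mean_asd=base.trait_mean_td,
        cluster_effect=0.0,
        asd_whole_brain_offset=0.0,
        seed=seed,
    )
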
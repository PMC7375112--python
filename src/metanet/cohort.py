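"""Synthetic multi-subject, multi-condition coupled-oscillator cohorts.

Downstream stages (preprocessing, phase metrics, permutation statistics,
PCA, behaviour association, classification) are validated against data
with *known* phase-coupling structure. Signals are generated from a
community-structured Kuramoto model: each region is a noisy phase
oscillator with an intrinsic frequency inside the analysis band, coupled
strongly to regions of its own network and weakly to the rest of the
brain. Observed "BOLD-like" series are sinusoidal read-outs of the
phases plus measurement noise and nuisance contamination; rigid-body
motion traces, block-structured event tables and behaviour scores that
depend linearly on ground-truth connection metastability complete the
cohort.

The oscillator model

    dtheta_k/dt = 2*pi*f_k + sum_j K_kj * sin(theta_j - theta_k) + noise

is integrated with the Euler-Maruyama scheme at dt = TR/10 and sampled
stroboscopically every 10 steps. K_kj = k_w/N within a network and
k_b/N between networks, N the total region count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    InteractionMatrix,
    NetworkAssignment,
    PhaseArray,
    RegionTimeSeries,
    wrap_phase,
)

__all__ = [
    "SimulationConfig",
    "BlockScheme",
    "BehaviorModel",
    "SyntheticCohort",
    "gordon_like_network_sizes",
    "small_network_sizes",
    "default_coupling",
    "simulate_phases",
    "render_bold",
    "simulate_confounds",
    "simulate_motion",
    "generate_events",
    "generate_behavior",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "synthetic_matrix_classes",
    "synthetic_paired_stacks",
]

#: The 12 large-scale networks of the parcellation, plus the residual
#: "none" label and the single-region thalamus (14 labels in total).
NETWORK_LABELS = [
    "default_mode",
    "visual",
    "fronto_parietal",
    "dorsal_attention",
    "ventral_attention",
    "cingulo_opercular",
    "salience",
    "motor_hand",
    "motor_mouth",
    "auditory",
    "medial_parietal",
    "parieto_occipital",
    "none",
    "thalamus",
]

#: Networks treated as cognitive-control-like vs unimodal sensory when
#: building default task couplings.
CONTROL_NETWORKS = [
    "fronto_parietal",
    "dorsal_attention",
    "cingulo_opercular",
    "thalamus",
]
SENSORY_NETWORKS = ["visual", "motor_hand", "motor_mouth", "auditory"]

TASK_CONDITIONS = [
    "emotion",
    "relational",
    "language",
    "working_memory",
    "gambling",
    "social",
    "motor",
]


def gordon_like_network_sizes() -> dict[str, int]:
    """Full-scale parcellation geometry: 333 cortical regions over 13
    labels plus a single-region thalamus (334 regions, 14 labels).

    Per-network counts are plausible inventions; only the totals and the
    single-region thalamus are constrained.
    """
    sizes = {
        "default_mode": 41,
        "visual": 39,
        "fronto_parietal": 24,
        "dorsal_attention": 32,
        "ventral_attention": 23,
        "cingulo_opercular": 40,
        "salience": 4,
        "motor_hand": 38,
        "motor_mouth": 8,
        "auditory": 24,
        "medial_parietal": 5,
        "parieto_occipital": 14,
        "none": 41,
        "thalamus": 1,
    }
    assert sum(sizes.values()) == 334
    return sizes


def small_network_sizes(regions_per_network: int = 4) -> dict[str, int]:
    """Desk-scale parcellation: the same 14 labels with few regions each
    (thalamus stays a single region)."""
    sizes = {lab: regions_per_network for lab in NETWORK_LABELS}
    sizes["thalamus"] = 1
    return sizes


def default_coupling(
    rest_kw: float = 4.0,
    rest_kb: float = 0.4,
    control_boost: float = 1.75,
    sensory_drop: float = 0.75,
    task_kb_boost: float = 1.25,
) -> dict[str, tuple[dict[str, float] | float, float]]:
    """Per-condition coupling map ``{condition: (k_w, k_b)}``.

    Rest sits just below the between-network synchronisation transition
    (global metastability ~0.12 at the default geometry). Each task
    raises the within-network coupling of cognitive-control networks
    and lowers it in unimodal sensory networks (with a small
    task-specific tilt) and nudges the between-network coupling up, so
    tasks show higher global and between-network metastability than
    rest with a planted control-up / sensory-down contrast structure.
    """
    coupling: dict[str, tuple[dict[str, float] | float, float]] = {
        "rest": (rest_kw, rest_kb)
    }
    for t, task in enumerate(TASK_CONDITIONS):
        tilt = 1.0 + 0.05 * (t - len(TASK_CONDITIONS) / 2) / len(TASK_CONDITIONS)
        kw = {}
        for lab in NETWORK_LABELS:
            if lab in CONTROL_NETWORKS:
                kw[lab] = rest_kw * control_boost * tilt
            elif lab in SENSORY_NETWORKS:
                kw[lab] = rest_kw * sensory_drop / tilt
            else:
                kw[lab] = rest_kw
        coupling[task] = (kw, rest_kb * task_kb_boost)
    return coupling


@dataclass
class BlockScheme:
    """Alternating cue/task/fixation block layout for one run."""

    cue_s: float = 2.88
    task_s: float = 25.92
    fixation_s: float = 10.08
    n_blocks: int = 8
    randomize: bool = False
    #: optional per-block task durations (seconds); overrides ``task_s``
    task_durations_s: list[float] | None = None


@dataclass
class BehaviorModel:
    """Linear behaviour model: score = a + b * m + eps.

    ``m`` is the subject's metastability on a single target connection
    (a pair of network labels) of the ``condition`` interaction matrix;
    by default the ground-truth value from the generator, so estimator
    error and model error can be separated.
    """

    intercept: float = 100.0
    slope: float = 0.5
    connection: tuple[str, str] = ("fronto_parietal", "dorsal_attention")
    # about half the between-subject signal sd (slope x sd of the target
    # connection's metastability) under the default coupling jitter
    noise_sd: float = 0.004
    condition: str = "rest"
    use_measured: bool = False


@dataclass
class SimulationConfig:
    n_subjects: int = 8
    network_sizes: dict[str, int] = field(default_factory=small_network_sizes)
    tr_s: float = 0.72
    n_frames: int = 400
    freq_band_hz: tuple[float, float] = (0.06, 0.125)
    coupling: dict = field(default_factory=default_coupling)
    phase_noise_sd: float = 0.8  # rad / sqrt(s)
    obs_noise_sd: float = 0.1
    motion_step_sd: float = 0.02  # mm (and rad) per frame
    motion_spike_rate: float = 0.005  # probability per frame
    spike_mm: float = 0.6
    n_confounds: int = 2
    confound_weight: float = 0.2
    coupling_jitter_sd: float = 0.25  # per-subject, per-network lognormal sd
    block_scheme: BlockScheme = field(default_factory=BlockScheme)
    behavior_model: BehaviorModel = field(default_factory=BehaviorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_frames <= 0:
            raise ValueError("counts must be positive")
        if any(n <= 0 for n in self.network_sizes.values()):
            raise ValueError("network sizes must be positive")
        lo, hi = self.freq_band_hz
        nyq = 0.5 / self.tr_s
        if not (0.0 < lo < hi < nyq):
            raise ValueError(f"freq band must lie inside (0, {nyq:.4f}) Hz")
        for cond, (kw, kb) in self.coupling.items():
            kws = list(kw.values()) if isinstance(kw, Mapping) else [kw]
            if any(not np.isfinite(k) or k < 0 for k in kws) or kb < 0:
                raise ValueError(f"non-finite or negative coupling for {cond!r}")
        if not np.isfinite(self.phase_noise_sd) or self.phase_noise_sd < 0:
            raise ValueError("phase_noise_sd must be finite and >= 0")

    @property
    def conditions(self) -> list[str]:
        return list(self.coupling)

    @property
    def n_regions(self) -> int:
        return int(sum(self.network_sizes.values()))

    @property
    def region_ids(self) -> list[str]:
        ids = []
        for lab, n in self.network_sizes.items():
            ids.extend(f"{lab}_{i:03d}" for i in range(n))
        return ids

    def assignment(self) -> NetworkAssignment:
        mapping = {}
        for lab, n in self.network_sizes.items():
            for i in range(n):
                mapping[f"{lab}_{i:03d}"] = lab
        return NetworkAssignment(mapping, label_order=list(self.network_sizes))


# ---------------------------------------------------------------------------
# random-stream helpers: every draw is keyed on (seed, purpose, subject,
# condition) so the cohort is reproducible element-wise, not only globally.

_TRAIT, _PHASE, _MOTION, _OBS, _CONF, _BEHAV, _EVENTS = range(7)


def _rng(config: SimulationConfig, purpose: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, purpose, *keys])


def _subject_traits(config: SimulationConfig, subject: int):
    """Trait-like quantities sampled once per subject: intrinsic
    frequencies and per-network coupling jitter (shared across
    conditions, as dynamics at rest should be trait-linked)."""
    rng = _rng(config, _TRAIT, subject)
    lo, hi = config.freq_band_hz
    freqs = rng.uniform(lo, hi, size=config.n_regions)
    n_lab = len(config.network_sizes)
    sd = config.coupling_jitter_sd
    # lognormal with unit mean so jitter does not shift the cohort average
    jitter = np.exp(rng.normal(-0.5 * sd * sd, sd, size=n_lab)) if sd > 0 else np.ones(n_lab)
    return freqs, jitter


def _condition_index(config: SimulationConfig, condition: str) -> int:
    try:
        return config.conditions.index(condition)
    except ValueError:
        raise KeyError(
            f"unknown condition {condition!r}; known: {config.conditions}"
        ) from None


def _coupling_vectors(config: SimulationConfig, condition: str, jitter: np.ndarray):
    """Per-network within-coupling (jittered) and scalar between-coupling."""
    kw, kb = config.coupling[condition]
    labels = list(config.network_sizes)
    if isinstance(kw, Mapping):
        kw_vec = np.array([float(kw[lab]) for lab in labels])
    else:
        kw_vec = np.full(len(labels), float(kw))
    return kw_vec * jitter, float(kb)


def _membership(config: SimulationConfig) -> np.ndarray:
    """(n_networks, n_regions) one-hot membership matrix."""
    labels = list(config.network_sizes)
    net_of = np.concatenate(
        [np.full(n, i) for i, (_, n) in enumerate(config.network_sizes.items())]
    )
    M = np.zeros((len(labels), config.n_regions))
    M[net_of, np.arange(config.n_regions)] = 1.0
    return M


def simulate_phases(
    config: SimulationConfig,
    condition: str,
    subject: int = 0,
    n_frames: int | None = None,
    steps_per_frame: int = 10,
    freqs: np.ndarray | None = None,
    init_phases: np.ndarray | None = None,
    burn_in: int = 0,
) -> PhaseArray:
    """Integrate the community Kuramoto model for one subject/condition.

    Returns wrapped phases of shape ``(n_frames, n_regions)``; frame 0
    is the random initial state and subsequent frames are stroboscopic
    samples every ``steps_per_frame`` Euler-Maruyama steps of size
    ``tr_s / steps_per_frame``. ``freqs`` and ``init_phases`` override
    the sampled intrinsic frequencies / initial state for controlled
    experiments. ``burn_in`` frames are integrated and discarded
    before recording starts (the relaxation from the random initial
    state to the attractor is a non-stationary transient).
    """
    theta = _simulate_phases_multi(
        config, condition, [subject], n_frames=n_frames,
        steps_per_frame=steps_per_frame, freqs=freqs, init_phases=init_phases,
        burn_in=burn_in,
    )[0]
    return PhaseArray(theta, tr_s=config.tr_s, region_ids=config.region_ids)


def _simulate_phases_multi(
    config: SimulationConfig,
    condition: str,
    subjects,
    n_frames: int | None = None,
    steps_per_frame: int = 10,
    freqs: np.ndarray | None = None,
    init_phases: np.ndarray | None = None,
    burn_in: int = 0,
) -> np.ndarray:
    """Vectorised integration across subjects -> (S, frames, regions)."""
    cond_ix = _condition_index(config, condition)
    n_frames = (config.n_frames if n_frames is None else int(n_frames)) + burn_in
    N = config.n_regions
    S = len(subjects)
    dt = config.tr_s / steps_per_frame

    M = _membership(config)  # (L, N)
    net_of = np.argmax(M, axis=0)

    freq_arr = np.empty((S, N))
    kw_eff = np.empty((S, M.shape[0]))
    kb = np.empty(S)
    theta = np.empty((S, N))
    noise_streams = []
    for s, subj in enumerate(subjects):
        f, jit = _subject_traits(config, subj)
        freq_arr[s] = f if freqs is None else np.broadcast_to(freqs, (N,))
        kw_eff[s], kb[s] = _coupling_vectors(config, condition, jit)
        rng = _rng(config, _PHASE, subj, cond_ix)
        init = rng.uniform(-np.pi, np.pi, size=N)
        theta[s] = init if init_phases is None else np.broadcast_to(init_phases, (N,))
        noise_streams.append(rng)
    freqs = freq_arr

    out = np.empty((S, n_frames, N))
    out[:, 0] = theta
    omega = 2.0 * np.pi * freqs
    sq = config.phase_noise_sd * np.sqrt(dt)
    kw_region = kw_eff[:, net_of]  # (S, N) within-coupling of each region's net
    for frame in range(1, n_frames):
        for _ in range(steps_per_frame):
            z = np.exp(1j * theta)  # (S, N)
            z_net = z @ M.T  # (S, L) phasor sum per network
            z_own = z_net[:, net_of]  # (S, N)
            field_c = (kw_region * z_own + kb[:, None] * (z_net.sum(axis=1, keepdims=True) - z_own)) / N
            drift = omega + np.imag(np.exp(-1j * theta) * field_c)
            theta = theta + drift * dt
            if sq > 0:
                for s in range(S):
                    theta[s] += sq * noise_streams[s].standard_normal(N)
        out[:, frame] = theta
    return wrap_phase(out[:, burn_in:])


def simulate_confounds(config: SimulationConfig, subject: int, condition: str) -> np.ndarray:
    """Slow nuisance series (e.g. synthetic white-matter / ventricle
    signals): smoothed Gaussian random walks, one column each."""
    cond_ix = _condition_index(config, condition)
    rng = _rng(config, _CONF, subject, cond_ix)
    steps = rng.standard_normal((config.n_frames, config.n_confounds))
    walk = np.cumsum(steps, axis=0)
    # moving-average smoothing to make them slow, then standardise
    k = 11
    kernel = np.ones(k) / k
    sm = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, walk)
    sm -= sm.mean(axis=0)
    sd = sm.std(axis=0)
    sd[sd == 0] = 1.0
    return sm / sd


def render_bold(
    phases: PhaseArray | np.ndarray,
    config: SimulationConfig,
    confounds: np.ndarray | None = None,
    confound_weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> RegionTimeSeries:
    """Observed signal: x_k(t) = sin(theta_k(t)) + noise + confound mix."""
    theta = phases.data if isinstance(phases, PhaseArray) else np.asarray(phases)
    if not np.all(np.isfinite(theta)):
        raise ValueError("phases must be finite")
    x = np.sin(theta)
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[0] != theta.shape[0]:
            raise ValueError(
                f"confounds have {confounds.shape[0]} frames, phases {theta.shape[0]}"
            )
        if confound_weights is None:
            confound_weights = np.full(confounds.shape[1], config.confound_weight)
        # every region receives the same weighted confound mixture
        x = x + (confounds * np.asarray(confound_weights, dtype=float)).sum(
            axis=1, keepdims=True
        )
    if rng is not None and config.obs_noise_sd > 0:
        x = x + config.obs_noise_sd * rng.standard_normal(x.shape)
    ids = phases.region_ids if isinstance(phases, PhaseArray) else config.region_ids[: theta.shape[1]]
    return RegionTimeSeries(x, tr_s=config.tr_s, region_ids=list(ids))


def simulate_motion(
    config: SimulationConfig, subject: int = 0, condition: str = "rest"
) -> np.ndarray:
    """Six-column rigid-body motion trace (3 translations mm, 3
    rotations rad): a random walk with occasional persistent single-axis
    translation steps of ``spike_mm``."""
    cond_ix = _condition_index(config, condition)
    rng = _rng(config, _MOTION, subject, cond_ix)
    steps = config.motion_step_sd * rng.standard_normal((config.n_frames, 6))
    # rotational steps are arc-length-equivalent: a 50 mm head radius
    # turns rad into mm downstream, so divide the step size back out
    steps[:, 3:] /= 50.0
    steps[0] = 0.0
    spikes = rng.random(config.n_frames) < config.motion_spike_rate
    spikes[0] = False
    for t in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)  # translation axes only
        steps[t, axis] += config.spike_mm * (1 if rng.random() < 0.5 else -1)
    return np.cumsum(steps, axis=0)


def generate_events(
    config: SimulationConfig, scheme: BlockScheme | None = None
) -> pd.DataFrame:
    """BIDS-style event table (onset, duration, trial_type) of
    alternating cue/task/fixation blocks fitting inside the run."""
    scheme = scheme or config.block_scheme
    run_s = config.n_frames * config.tr_s
    durations = (
        list(scheme.task_durations_s)
        if scheme.task_durations_s is not None
        else [scheme.task_s] * scheme.n_blocks
    )
    if scheme.randomize:
        rng = _rng(config, _EVENTS, 0)
        durations = list(rng.permutation(durations))
    rows = []
    t = 0.0
    for dur in durations:
        block = [("cue", scheme.cue_s), ("task", float(dur)), ("fixation", scheme.fixation_s)]
        total = sum(d for _, d in block if d > 0)
        if t + total > run_s + 1e-9:
            break
        for typ, d in block:
            if d > 0:
                rows.append({"onset": t, "duration": d, "trial_type": typ})
                t += d
    ev = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    ends = ev["onset"] + ev["duration"]
    if len(ev) > 1 and np.any(ev["onset"].values[1:] < ends.values[:-1] - 1e-9):
        raise ValueError("overlapping blocks in generated event table")
    return ev


@dataclass
class SubjectConditionData:
    ts: RegionTimeSeries
    motion: np.ndarray
    confounds: np.ndarray
    phases: PhaseArray  # ground-truth oscillator phases


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    assignment: NetworkAssignment
    data: dict  # (subject, condition) -> SubjectConditionData
    events: dict  # condition -> event table (None for rest)
    true_metastability: dict  # (subject, condition) -> InteractionMatrix
    true_synchrony: dict  # (subject, condition) -> InteractionMatrix
    behavior: pd.DataFrame

    @property
    def subjects(self) -> list[int]:
        return list(range(self.config.n_subjects))

    @property
    def conditions(self) -> list[str]:
        return self.config.conditions

    def metastability_stack(self, condition: str) -> np.ndarray:
        """(subjects, L, L) ground-truth metastability matrices."""
        return np.stack(
            [self.true_metastability[(s, condition)].values for s in self.subjects]
        )


def _true_interactions(theta: np.ndarray, config: SimulationConfig):
    """Interaction matrices computed directly from ground-truth phases."""
    from .phase import interaction_matrix  # local import avoids cycle

    pa = PhaseArray(theta, tr_s=config.tr_s, region_ids=config.region_ids)
    assignment = config.assignment()
    return (
        interaction_matrix(pa, assignment, kind="metastability"),
        interaction_matrix(pa, assignment, kind="synchrony"),
    )


def generate_behavior(
    cohort: "SyntheticCohort", model: BehaviorModel | None = None
) -> pd.DataFrame:
    """Behaviour scores linear in the target connection's metastability."""
    model = model or cohort.config.behavior_model
    labels = cohort.assignment.labels
    try:
        i = labels.index(model.connection[0])
        j = labels.index(model.connection[1])
    except ValueError:
        raise KeyError(f"behaviour target connection {model.connection} not in labels")
    rng = _rng(cohort.config, _BEHAV, 0)
    rows = []
    for s in cohort.subjects:
        m = cohort.true_metastability[(s, model.condition)].values[i, j]
        eps = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
        rows.append({"subject": s, "metastability_target": m,
                     "score": model.intercept + model.slope * m + eps})
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full cohort bundle for all subjects and conditions."""
    assignment = config.assignment()
    data: dict = {}
    true_meta: dict = {}
    true_sync: dict = {}
    events: dict = {}
    for cond in config.conditions:
        events[cond] = None if cond == "rest" else generate_events(config)
        theta_all = _simulate_phases_multi(config, cond, list(range(config.n_subjects)))
        for s in range(config.n_subjects):
            theta = theta_all[s]
            pa = PhaseArray(theta, tr_s=config.tr_s, region_ids=config.region_ids)
            conf = simulate_confounds(config, s, cond)
            obs_rng = _rng(config, _OBS, s, _condition_index(config, cond))
            ts = render_bold(pa, config, confounds=conf, rng=obs_rng)
            motion = simulate_motion(config, s, cond)
            data[(s, cond)] = SubjectConditionData(ts=ts, motion=motion, confounds=conf, phases=pa)
            true_meta[(s, cond)], true_sync[(s, cond)] = _true_interactions(theta, config)
    cohort = SyntheticCohort(
        config=config,
        assignment=assignment,
        data=data,
        events=events,
        true_metastability=true_meta,
        true_synchrony=true_sync,
        behavior=pd.DataFrame(),
    )
    cohort.behavior = generate_behavior(cohort)
    return cohort


# ---------------------------------------------------------------------------
# on-disk round trip

_FLOAT_FMT = "%.17g"


def _config_to_json(config: SimulationConfig) -> dict:
    d = {
        "n_subjects": config.n_subjects,
        "network_sizes": config.network_sizes,
        "tr_s": config.tr_s,
        "n_frames": config.n_frames,
        "freq_band_hz": list(config.freq_band_hz),
        "coupling": {
            c: [kw if not isinstance(kw, Mapping) else dict(kw), kb]
            for c, (kw, kb) in config.coupling.items()
        },
        "phase_noise_sd": config.phase_noise_sd,
        "obs_noise_sd": config.obs_noise_sd,
        "motion_step_sd": config.motion_step_sd,
        "motion_spike_rate": config.motion_spike_rate,
        "spike_mm": config.spike_mm,
        "n_confounds": config.n_confounds,
        "confound_weight": config.confound_weight,
        "coupling_jitter_sd": config.coupling_jitter_sd,
        "seed": config.seed,
    }
    return d


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the cohort as plain-text files; returns the manifest.

    Layout: per subject x condition a signals TSV (region-id header), a
    6-column whitespace ``.par`` motion file and a confounds TSV; one
    events TSV per task condition; plus four side tables
    (assignment.tsv, behavior.tsv, config.json, manifest.json).
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        files: list[str] = []
        for (s, cond), d in cohort.data.items():
            stem = f"sub-{s:03d}_{cond}"
            ts_path = directory / f"{stem}_ts.tsv"
            pd.DataFrame(d.ts.data, columns=d.ts.region_ids).to_csv(
                ts_path, sep="\t", index=False, float_format=_FLOAT_FMT
            )
            np.savetxt(directory / f"{stem}_motion.par", d.motion, fmt=_FLOAT_FMT)
            pd.DataFrame(
                d.confounds, columns=[f"confound_{i}" for i in range(d.confounds.shape[1])]
            ).to_csv(directory / f"{stem}_confounds.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
            files += [f"{stem}_ts.tsv", f"{stem}_motion.par", f"{stem}_confounds.tsv"]
        for cond, ev in cohort.events.items():
            if ev is not None:
                ev.to_csv(directory / f"events_{cond}.tsv", sep="\t", index=False,
                          float_format=_FLOAT_FMT)
                files.append(f"events_{cond}.tsv")
        cohort.assignment.to_frame().to_csv(directory / "assignment.tsv", sep="\t", index=False)
        cohort.behavior.to_csv(directory / "behavior.tsv", sep="\t", index=False,
                               float_format=_FLOAT_FMT)
        (directory / "config.json").write_text(
            json.dumps(_config_to_json(cohort.config), indent=2)
        )
        manifest = {
            "tr_s": cohort.config.tr_s,
            "subjects": cohort.subjects,
            "conditions": cohort.conditions,
            "files": files + ["assignment.tsv", "behavior.tsv", "config.json", "manifest.json"],
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except OSError as exc:
        raise OSError(f"failed writing cohort under {directory}: {exc}") from exc


def read_cohort_tables(directory: str | Path):
    """Read back the plain-text cohort: (signals, motion, confounds)
    dicts keyed by (subject, condition), events per condition,
    assignment, behaviour table and config echo."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    tr_s = manifest["tr_s"]
    signals, motion, confounds = {}, {}, {}
    for s in manifest["subjects"]:
        for cond in manifest["conditions"]:
            stem = f"sub-{s:03d}_{cond}"
            df = pd.read_csv(directory / f"{stem}_ts.tsv", sep="\t")
            signals[(s, cond)] = RegionTimeSeries(df.values, tr_s=tr_s,
                                                  region_ids=list(df.columns))
            motion[(s, cond)] = np.loadtxt(directory / f"{stem}_motion.par", ndmin=2)
            confounds[(s, cond)] = pd.read_csv(
                directory / f"{stem}_confounds.tsv", sep="\t"
            ).values
    events = {}
    for cond in manifest["conditions"]:
        p = directory / f"events_{cond}.tsv"
        events[cond] = pd.read_csv(p, sep="\t") if p.exists() else None
    assignment = NetworkAssignment.from_frame(
        pd.read_csv(directory / "assignment.tsv", sep="\t")
    )
    behavior = pd.read_csv(directory / "behavior.tsv", sep="\t")
    config_echo = json.loads((directory / "config.json").read_text())
    return signals, motion, confounds, events, assignment, behavior, config_echo


read_cohort = read_cohort_tables


# ---------------------------------------------------------------------------
# direct interaction-matrix generators (cheap fixtures for the NBS,
# decomposition and classifier stages, bypassing the oscillator model)


def _sym_noise(rng: np.random.Generator, n: int, d: int, sd: float) -> np.ndarray:
    a = rng.normal(0.0, sd, size=(n, d, d))
    return (a + a.transpose(0, 2, 1)) / np.sqrt(2.0)


def synthetic_paired_stacks(
    n_subjects: int,
    d: int = 14,
    effect_edges: list[tuple[int, int]] | None = None,
    effect_size: float = 0.0,
    noise_sd: float = 0.02,
    subject_sd: float = 0.03,
    base_level: float = 0.15,
    seed: int = 0,
):
    """Paired (task, rest) stacks of symmetric matrices with an optional
    additive effect planted on specific edges of the task condition.

    Each subject has a shared baseline matrix (between-subject sd
    ``subject_sd``); task and rest add independent symmetric noise of sd
    ``noise_sd``; ``effect_size`` is added on ``effect_edges`` (and
    their transposes) in the task stack only.
    """
    rng = np.random.default_rng(seed)
    base = base_level + _sym_noise(rng, n_subjects, d, subject_sd)
    rest = base + _sym_noise(rng, n_subjects, d, noise_sd)
    task = base + _sym_noise(rng, n_subjects, d, noise_sd)
    if effect_edges and effect_size != 0.0:
        for i, j in effect_edges:
            task[:, i, j] += effect_size
            if i != j:
                task[:, j, i] += effect_size
    return task, rest


def synthetic_matrix_classes(
    n_per_class: int,
    n_classes: int = 8,
    d: int = 14,
    separation: float = 5.0,
    noise_sd: float = 0.02,
    sparse_edges: int | None = None,
    seed: int = 0,
):
    """Labelled symmetric matrices with class-specific mean patterns.

    By default class means are dense symmetric patterns with entry sd
    ``separation * noise_sd`` (classes separated everywhere by
    ``separation`` noise units). With ``sparse_edges`` set, every class
    instead shares a common baseline and differs only on that many
    randomly chosen class-specific connections — emulating states that
    are identified by a small number of distinctive network changes.
    Returns ``(X, y)`` with X of shape (n_classes*n_per_class, d, d).
    """
    rng = np.random.default_rng(seed)
    if sparse_edges is None:
        means = _sym_noise(rng, n_classes, d, separation * noise_sd)
    else:
        base = _sym_noise(rng, 1, d, noise_sd)[0]
        iu = np.triu_indices(d)
        means = np.tile(base, (n_classes, 1, 1))
        for c in range(n_classes):
            pick = rng.choice(len(iu[0]), size=sparse_edges, replace=False)
            for e in pick:
                i, j = iu[0][e], iu[1][e]
                # class-evoked *increases*, mirroring task-evoked rises
                # in synchrony that saliency analysis then picks up
                delta = separation * noise_sd
                means[c, i, j] += delta
                if i != j:
                    means[c, j, i] += delta
    X = np.concatenate(
        [means[c] + _sym_noise(rng, n_per_class, d, noise_sd) for c in range(n_classes)]
    )
    y = np.repeat(np.arange(n_classes), n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]
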
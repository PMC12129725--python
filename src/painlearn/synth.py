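"""Synthetic task schedules, agents, cohorts, parcel time series and scores.

Everything the pipeline consumes can be generated here with known ground
truth: reflected Gaussian-random-walk win/loss probabilities for the four
cues, Bernoulli outcome sampling, forward-simulated RL agents, two-group
cohorts drawn from group-level parameter distributions, parcel time series
with a planted connectivity hub, and clinical scores with a planted
correlation to a centrality vector.

Named RNG streams (walks, outcomes, choices, ...) are derived from the
top-level seed so each component is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .models import (
    ChoiceDataset,
    ModelSpec,
    SubjectParams,
    InvalidParameterError,
    InvalidDataError,
    N_CUES,
    PROB_FLOOR,
)

__all__ = [
    "WalkConfig",
    "TaskSchedule",
    "CohortConfig",
    "GroupLevel",
    "ARTHRITIS_GROUP",
    "CONTROL_GROUP",
    "MODEL5_RECOVERY",
    "MODEL1_RECOVERY",
    "generate_schedule",
    "sample_outcomes",
    "simulate_agent",
    "simulate_cohort",
    "generate_parcel_timeseries",
    "generate_clinical_scores",
]


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child RNG stream."""
    tag = zlib.crc32(name.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkConfig:
    """Reflected Gaussian random walks for the cue payoff probabilities.

    Defaults emulate the task: 240 trials over 4 runs, 4 cues, win and loss
    probabilities drifting slowly and independently, reflected at
    [0.2, 0.8] so every arm stays stochastic yet learnable.
    """

    n_trials: int = 240
    n_runs: int = 4
    step_sd: float = 0.02
    bounds: tuple[float, float] = (0.2, 0.8)
    init: np.ndarray | None = None  # fixed (2, 4) init, else uniform in bounds
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (0.0 < lo < hi < 1.0):
            raise InvalidParameterError(f"bounds {self.bounds} must satisfy 0 < low < high < 1")
        if self.step_sd < 0:
            raise InvalidParameterError("step_sd must be >= 0")
        if self.n_trials <= 0 or self.n_runs <= 0 or self.n_trials % self.n_runs:
            raise InvalidParameterError("n_trials must be a positive multiple of n_runs")


@dataclass(frozen=True)
class TaskSchedule:
    """Win and loss probability trajectories, trials x 4 cues each."""

    p_win: np.ndarray
    p_loss: np.ndarray
    n_runs: int = 4

    @property
    def n_trials(self) -> int:
        return int(self.p_win.shape[0])


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values back into [lo, hi] (reflecting boundaries)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def generate_schedule(cfg: WalkConfig) -> TaskSchedule:
    """Eight independent reflected walks: 4 cues x {win, loss}."""
    rng = _stream(cfg.seed, "walks")
    lo, hi = cfg.bounds
    if cfg.init is not None:
        start = np.asarray(cfg.init, dtype=float).reshape(2, N_CUES)
    else:
        start = rng.uniform(lo, hi, size=(2, N_CUES))
    steps = rng.normal(0.0, cfg.step_sd, size=(cfg.n_trials - 1, 2, N_CUES))
    path = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)], axis=0)
    path = _reflect(path, lo, hi)
    return TaskSchedule(p_win=path[:, 0, :], p_loss=path[:, 1, :], n_runs=cfg.n_runs)


def sample_outcomes(
    schedule: TaskSchedule, trial: int, choice: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Bernoulli win/loss draw for one (trial, choice); loss coded {0, -1}.

    Win and loss tokens are independent, so both-token and no-token
    outcomes arise naturally.
    """
    if not (0 <= trial < schedule.n_trials):
        raise InvalidDataError(f"trial {trial} out of range")
    if choice not in (1, 2, 3, 4):
        raise InvalidDataError(f"choice {choice} out of range 1-4")
    c = choice - 1
    win = int(rng.random() < schedule.p_win[trial, c])
    loss = -int(rng.random() < schedule.p_loss[trial, c])
    return win, loss


# ---------------------------------------------------------------------------
# agents and cohorts
# ---------------------------------------------------------------------------

def simulate_agent(
    spec: ModelSpec,
    params: SubjectParams,
    schedule: TaskSchedule,
    seed: int,
    subject_id: str = "sim",
    group_label: str = "synthetic-A",
    trial_spacing: float = 6.0,
) -> ChoiceDataset:
    """Forward-simulate one agent through a schedule.

    Per trial: decay -> softmax(+lapse) choice sampling -> independent
    win/loss outcome sampling -> scaled prediction errors -> update.
    Onsets are synthesized on a fixed grid (one trial every
    ``trial_spacing`` seconds, outcome 2 s after cue) for regressor tests.
    """
    params.validate(spec)
    rng_choice = _stream(seed, "choices")
    rng_out = _stream(seed, "outcomes")
    T = schedule.n_trials
    lr_r, lr_p = params.learning_rates(spec)
    keep = 1.0 - params.d if spec.has_decay else 1.0
    xi = params.xi if spec.has_lapse else 0.0

    qr = np.zeros(N_CUES)
    qp = np.zeros(N_CUES)
    choice = np.empty(T, dtype=np.int64)
    win = np.empty(T, dtype=np.int64)
    loss = np.empty(T, dtype=np.int64)
    for t in range(T):
        qr *= keep
        qp *= keep
        tot = qr + qp
        tot = tot - tot.max()
        p = np.exp(tot)
        p /= p.sum()
        p = p * (1.0 - xi) + xi / N_CUES
        c = int(rng_choice.choice(N_CUES, p=p))
        w, l = sample_outcomes(schedule, t, c + 1, rng_out)
        choice[t], win[t], loss[t] = c + 1, w, l
        qr[c] += lr_r * params.R * (w - qr[c])
        qp[c] += lr_p * params.P * (l - qp[c])

    per_run = T // schedule.n_runs
    run = np.repeat(np.arange(1, schedule.n_runs + 1), per_run)
    within = np.tile(np.arange(per_run), schedule.n_runs)
    cue_onset = within * trial_spacing
    return ChoiceDataset(
        subject_id=subject_id, group_label=group_label,
        choice=choice, win=win, loss=loss, run=run,
        cue_onset=cue_onset,
        outcome_onset=cue_onset + 2.0,
        keypress_time=cue_onset + 0.8,
    )


@dataclass(frozen=True)
class GroupLevel:
    """Group-level mean and SD per parameter on the constrained scale."""

    mean: dict[str, float]
    sd: dict[str, float]


# Group-level defaults: the study conditions for two-group simulations.
# Constrained-scale means (SDs) per free parameter of the full model family.
ARTHRITIS_GROUP = GroupLevel(
    mean={"R": 12.750, "P": 9.953, "lr_r": 0.679, "lr_p": 0.547, "d": 0.603, "xi": 0.105},
    sd={"R": 5.911, "P": 2.577, "lr_r": 0.069, "lr_p": 0.074, "d": 0.311, "xi": 0.043},
)
CONTROL_GROUP = GroupLevel(
    mean={"R": 9.417, "P": 5.778, "lr_r": 0.590, "lr_p": 0.570, "d": 0.469, "xi": 0.026},
    sd={"R": 5.031, "P": 3.715, "lr_r": 0.043, "lr_p": 0.047, "d": 0.261, "xi": 0.003},
)

# Model-recovery conditions.  The scaled prediction error makes the value
# update relax toward the outcome at rate LR*R; these conditions keep
# LR*R <= ~1 so simulated choice behaviour stays stochastic and learnable
# rather than saturating into deterministic habits.
MODEL5_RECOVERY = GroupLevel(
    mean={"R": 4.0, "P": 3.5, "lr_r": 0.25, "lr_p": 0.20},
    sd={"R": 1.0, "P": 1.0, "lr_r": 0.05, "lr_p": 0.05},
)
MODEL1_RECOVERY = GroupLevel(
    # strong differential learning rate (beta = 0.15) and strong lapse
    mean={"R": 4.0, "P": 3.5, "lr_r": 0.45, "lr_p": 0.15, "d": 0.3, "xi": 0.25},
    sd={"R": 1.0, "P": 1.0, "lr_r": 0.05, "lr_p": 0.05, "d": 0.1, "xi": 0.05},
)


@dataclass(frozen=True)
class CohortConfig:
    """A simulated group of agents sharing group-level parameter distributions."""

    model_id: int = 1
    group: GroupLevel = field(default_factory=lambda: ARTHRITIS_GROUP)
    n_subjects: int = 12
    group_label: str = "synthetic-A"
    sensitivity_bound: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidParameterError("a cohort needs at least 2 subjects")


_PARAM_RANGE = {"lr_r": (0.0, 1.0), "lr_p": (0.0, 1.0), "d": (0.0, 1.0), "xi": (0.0, 1.0)}


def _draw_subject_params(
    spec: ModelSpec, cfg: CohortConfig, rng: np.random.Generator
) -> list[SubjectParams]:
    """Truncated-normal subject draws (rejection-resampled into range)."""
    bound = cfg.sensitivity_bound
    out = []
    for _ in range(cfg.n_subjects):
        vals = {}
        for name in spec.free_parameters:
            lo, hi = _PARAM_RANGE.get(name, (0.0, bound))
            m, s = cfg.group.mean[name], cfg.group.sd[name]
            v = rng.normal(m, s)
            while not (lo <= v <= hi):
                v = rng.normal(m, s)
            vals[name] = v
        out.append(SubjectParams.from_rates(
            spec, R=vals["R"], P=vals["P"], lr_r=vals["lr_r"], lr_p=vals["lr_p"],
            d=vals.get("d", 0.0), xi=vals.get("xi", 0.0), sensitivity_bound=bound))
    return out


def simulate_cohort(
    cfg: CohortConfig,
    walk: WalkConfig | None = None,
) -> tuple[list[ChoiceDataset], list[SubjectParams], GroupLevel]:
    """Simulate a cohort: per-subject schedule + agent, with ground truth.

    Returns the datasets, the true subject-level parameters, and the
    generating group-level distribution (the recovery target).
    """
    spec = ModelSpec.from_id(cfg.model_id)
    rng = _stream(cfg.seed, "cohort-params")
    params = _draw_subject_params(spec, cfg, rng)
    walk = walk or WalkConfig()
    datasets = []
    for i, p in enumerate(params):
        sched = generate_schedule(WalkConfig(
            n_trials=walk.n_trials, n_runs=walk.n_runs, step_sd=walk.step_sd,
            bounds=walk.bounds, init=walk.init, seed=int(_stream(cfg.seed, f"walk-{i}").integers(2**31))))
        datasets.append(simulate_agent(
            spec, p, sched, seed=int(_stream(cfg.seed, f"agent-{i}").integers(2**31)),
            subject_id=f"{cfg.group_label}-{i:03d}", group_label=cfg.group_label))
    return datasets, params, cfg.group


# ---------------------------------------------------------------------------
# connectivity-stage fixtures
# ---------------------------------------------------------------------------

def generate_parcel_timeseries(
    n_parcels: int,
    n_volumes: int,
    hub_node: int,
    hub_strength: float,
    seed: int,
    n_linked: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian parcel series with a planted hub.

    Each of ``n_linked`` parcels j shares a private signal s_j with the hub:
    x_j = noise + hub_strength * s_j, while the hub sums all the private
    signals (scaled by 1/sqrt(n_linked)) on top of its own noise.  The hub
    therefore correlates with every linked parcel, while linked parcels stay
    mutually near-independent, so the hub attains the highest degree after
    density thresholding.  Returns (series, linked_mask); the implied
    covariance is Sigma = I + hub_strength^2 * L L^T with L the (parcels x
    n_linked) loading matrix described above.
    """
    if hub_strength < 0:
        raise InvalidParameterError("hub_strength must be >= 0")
    if not (0 <= hub_node < n_parcels):
        raise InvalidParameterError(f"hub_node {hub_node} out of range")
    if n_linked >= n_parcels:
        raise InvalidParameterError("n_linked must be < n_parcels")
    rng = _stream(seed, "parcel-ts")
    others = np.array([i for i in range(n_parcels) if i != hub_node])
    linked = others[:n_linked]
    x = rng.normal(size=(n_parcels, n_volumes))
    s = rng.normal(size=(n_linked, n_volumes))
    x[linked] += hub_strength * s
    x[hub_node] += hub_strength * s.sum(axis=0) / np.sqrt(n_linked)
    mask = np.zeros(n_parcels, dtype=bool)
    mask[linked] = True
    return x, mask


def generate_clinical_scores(
    centrality: np.ndarray, target_r: float, seed: int
) -> np.ndarray:
    """Scores with expected correlation ``target_r`` to a centrality vector."""
    if not (-1.0 < target_r < 1.0):
        raise InvalidParameterError("target_r must be in (-1, 1)")
    c = np.asarray(centrality, dtype=float)
    if c.std() == 0:
        raise InvalidDataError("centrality vector is constant; correlation undefined")
    z = (c - c.mean()) / c.std()
    rng = _stream(seed, "clinical")
    noise = rng.normal(size=c.shape)
    return target_r * z + np.sqrt(1.0 - target_r**2) * noise
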
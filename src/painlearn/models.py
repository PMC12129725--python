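"""Reinforcement-learning models of the four-armed bandit task.

Five delta-rule variants track separate reward and punishment Q-values per
cue.  Prediction errors are scaled by sensitivity parameters (R for rewards,
P for punishments), learning rates are either coupled (alpha +/- beta,
Models 1-2) or independent (alpha_r / alpha_p, Models 3-5), and the softmax
policy over the summed Q-values may include a lapse mixture (xi) and a
per-trial decay of all tracked values (d).

Per-trial order of operations (fixed): decay all cues -> choice
probabilities from the current state -> log-likelihood of the observed
choice -> sensitivity-scaled prediction errors -> update of the chosen cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

N_CUES = 4
PROB_FLOOR = 1e-12

try:
    from . import _kernels as _KERNELS
except ImportError:  # pragma: no cover - numba always present in practice
    _KERNELS = None

__all__ = [
    "ModelSpec",
    "SubjectParams",
    "TrialObservation",
    "ChoiceDataset",
    "QState",
    "LatentTrace",
    "InvalidParameterError",
    "InvalidDataError",
    "scaled_prediction_errors",
    "update_values",
    "apply_decay",
    "choice_probabilities",
    "run_trials",
    "negative_log_likelihood",
    "export_regressors",
    "batch_log_likelihood",
]


class InvalidParameterError(ValueError):
    """A model parameter lies outside its admissible range."""


class InvalidDataError(ValueError):
    """Observed task data violate the bandit coding (choice 1-4, win {0,1}, loss {0,-1})."""


# ---------------------------------------------------------------------------
# model family
# ---------------------------------------------------------------------------

_MODEL_TABLE = {
    # model_id: (coupled_learning_rates, has_decay, has_lapse)
    1: (True, True, True),
    2: (True, False, True),
    3: (False, True, True),
    4: (False, False, True),
    5: (False, False, False),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which free parameters a model variant uses.

    The flags are a pure function of ``model_id``: Models 1-2 couple the
    learning rates as alpha +/- beta, Models 3-5 use independent alpha_r /
    alpha_p; Models 1 and 3 add decay; Models 1-4 add the lapse.
    """

    model_id: int
    coupled_learning_rates: bool
    has_decay: bool
    has_lapse: bool

    @classmethod
    def from_id(cls, model_id: int) -> "ModelSpec":
        try:
            coupled, decay, lapse = _MODEL_TABLE[int(model_id)]
        except KeyError:
            raise InvalidParameterError(f"model_id must be 1-5, got {model_id!r}")
        return cls(int(model_id), coupled, decay, lapse)

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of the free parameters on the fitting scale.

        Coupled models are parameterized by the learning rates themselves,
        (lr_r, lr_p) in [0,1]^2, which is algebraically identical to
        (alpha + beta, alpha - beta) and always admissible; alpha and beta
        are derived for reporting.
        """
        names = ["R", "P", "lr_r", "lr_p"]
        if self.has_decay:
            names.append("d")
        if self.has_lapse:
            names.append("xi")
        return tuple(names)

    def __post_init__(self) -> None:
        expect = _MODEL_TABLE.get(self.model_id)
        if expect != (self.coupled_learning_rates, self.has_decay, self.has_lapse):
            raise InvalidParameterError(
                f"flags {self!r} do not match the model table for id {self.model_id}"
            )


@dataclass(frozen=True)
class SubjectParams:
    """Subject-level free parameters; inactive ones stay at neutral values.

    ``alpha``/``beta`` parameterize the coupled learning rates
    (lr_r = alpha + beta, lr_p = alpha - beta, Models 1-2); ``alpha_r`` /
    ``alpha_p`` are the independent rates (Models 3-5).  ``d`` is the
    per-trial decay, ``xi`` the lapse probability, and R/P the reward and
    punishment sensitivities scaling the prediction errors.
    """

    R: float = 1.0
    P: float = 1.0
    alpha: float = 0.0
    beta: float = 0.0
    alpha_r: float = 0.0
    alpha_p: float = 0.0
    d: float = 0.0
    xi: float = 0.0
    sensitivity_bound: float = 30.0

    def learning_rates(self, spec: ModelSpec) -> tuple[float, float]:
        if spec.coupled_learning_rates:
            return self.alpha + self.beta, self.alpha - self.beta
        return self.alpha_r, self.alpha_p

    def validate(self, spec: ModelSpec) -> None:
        if not (0.0 <= self.R <= self.sensitivity_bound):
            raise InvalidParameterError(f"R={self.R} outside [0, {self.sensitivity_bound}]")
        if not (0.0 <= self.P <= self.sensitivity_bound):
            raise InvalidParameterError(f"P={self.P} outside [0, {self.sensitivity_bound}]")
        lr_r, lr_p = self.learning_rates(spec)
        for name, lr in (("reward", lr_r), ("punishment", lr_p)):
            if not (0.0 <= lr <= 1.0):
                raise InvalidParameterError(f"{name} learning rate {lr} outside [0, 1]")
        if not (0.0 <= self.d <= 1.0):
            raise InvalidParameterError(f"d={self.d} outside [0, 1]")
        if not (0.0 <= self.xi <= 1.0):
            raise InvalidParameterError(f"xi={self.xi} outside [0, 1]")
        if not spec.has_decay and self.d != 0.0:
            raise InvalidParameterError("decay inactive for this model; d must be 0")
        if not spec.has_lapse and self.xi != 0.0:
            raise InvalidParameterError("lapse inactive for this model; xi must be 0")

    @classmethod
    def from_rates(
        cls,
        spec: ModelSpec,
        R: float,
        P: float,
        lr_r: float,
        lr_p: float,
        d: float = 0.0,
        xi: float = 0.0,
        sensitivity_bound: float = 30.0,
    ) -> "SubjectParams":
        """Build params from fitting-scale values (learning rates directly)."""
        if spec.coupled_learning_rates:
            p = cls(R=R, P=P, alpha=(lr_r + lr_p) / 2.0, beta=(lr_r - lr_p) / 2.0,
                    d=d if spec.has_decay else 0.0, xi=xi if spec.has_lapse else 0.0,
                    sensitivity_bound=sensitivity_bound)
        else:
            p = cls(R=R, P=P, alpha_r=lr_r, alpha_p=lr_p,
                    d=d if spec.has_decay else 0.0, xi=xi if spec.has_lapse else 0.0,
                    sensitivity_bound=sensitivity_bound)
        p.validate(spec)
        return p


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialObservation:
    """One bandit trial: choice in 1-4, win in {0, 1}, loss in {0, -1}."""

    choice: int
    win: int
    loss: int
    cue_onset: float | None = None
    outcome_onset: float | None = None
    keypress_time: float | None = None

    def __post_init__(self) -> None:
        if self.choice not in (1, 2, 3, 4):
            raise InvalidDataError(f"choice must be in 1-4, got {self.choice}")
        if self.win not in (0, 1):
            raise InvalidDataError(f"win must be 0 or 1, got {self.win}")
        if self.loss not in (0, -1):
            raise InvalidDataError(f"loss must be 0 or -1, got {self.loss}")


@dataclass
class ChoiceDataset:
    """One subject's bandit session: ordered runs of ordered trials.

    Cues are coded 1-4 externally (the task coding); the likelihood engine
    converts to 0-based indices internally.
    """

    subject_id: str
    group_label: str
    choice: np.ndarray          # (T,) int, values 1-4
    win: np.ndarray             # (T,) int, values {0, 1}
    loss: np.ndarray            # (T,) int, values {0, -1}
    run: np.ndarray             # (T,) int run index, non-decreasing
    cue_onset: np.ndarray | None = None
    outcome_onset: np.ndarray | None = None
    keypress_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.choice = np.asarray(self.choice, dtype=np.int64)
        self.win = np.asarray(self.win, dtype=np.int64)
        self.loss = np.asarray(self.loss, dtype=np.int64)
        self.run = np.asarray(self.run, dtype=np.int64)
        n = self.choice.shape[0]
        if n == 0:
            raise InvalidDataError(f"subject {self.subject_id}: empty dataset")
        for name in ("win", "loss", "run"):
            if getattr(self, name).shape != (n,):
                raise InvalidDataError(f"subject {self.subject_id}: {name} length mismatch")
        bad = np.flatnonzero(~np.isin(self.choice, [1, 2, 3, 4]))
        if bad.size:
            raise InvalidDataError(
                f"subject {self.subject_id}: choice outside 1-4 at rows {bad[:10].tolist()}")
        bad = np.flatnonzero(~np.isin(self.win, [0, 1]))
        if bad.size:
            raise InvalidDataError(
                f"subject {self.subject_id}: win outside {{0,1}} at rows {bad[:10].tolist()}")
        bad = np.flatnonzero(~np.isin(self.loss, [0, -1]))
        if bad.size:
            raise InvalidDataError(
                f"subject {self.subject_id}: loss outside {{0,-1}} at rows {bad[:10].tolist()}")
        if np.any(np.diff(self.run) < 0):
            raise InvalidDataError(f"subject {self.subject_id}: run indices must be sorted")

    @property
    def n_trials(self) -> int:
        return int(self.choice.shape[0])

    @property
    def run_ids(self) -> np.ndarray:
        return np.unique(self.run)

    def run_slices(self) -> list[tuple[int, slice]]:
        out = []
        for r in self.run_ids:
            idx = np.flatnonzero(self.run == r)
            out.append((int(r), slice(int(idx[0]), int(idx[-1]) + 1)))
        return out

    @property
    def has_onsets(self) -> bool:
        return self.cue_onset is not None and self.outcome_onset is not None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject_id: str, group_label: str = "") -> "ChoiceDataset":
        df = df.sort_values(["run", "trial"]) if {"run", "trial"} <= set(df.columns) else df
        opt = {}
        for col, name in (("cue_onset", "cue_onset"), ("outcome_onset", "outcome_onset"),
                          ("keypress_time", "keypress_time")):
            if col in df.columns and df[col].notna().all():
                opt[name] = df[col].to_numpy(dtype=float)
        return cls(
            subject_id=subject_id,
            group_label=group_label,
            choice=df["choice"].to_numpy(),
            win=df["win"].to_numpy(),
            loss=df["loss"].to_numpy(),
            run=df["run"].to_numpy() if "run" in df.columns else np.zeros(len(df), dtype=int),
            **opt,
        )

    def to_dataframe(self) -> pd.DataFrame:
        trial = np.concatenate([np.arange(1, sl.stop - sl.start + 1) for _, sl in self.run_slices()])
        out = pd.DataFrame({
            "subject": self.subject_id,
            "group": self.group_label,
            "run": self.run,
            "trial": trial,
            "choice": self.choice,
            "win": self.win,
            "loss": self.loss,
        })
        for col in ("cue_onset", "outcome_onset", "keypress_time"):
            val = getattr(self, col)
            if val is not None:
                out[col] = val
        return out


@dataclass
class QState:
    """Tracked reward and punishment values per cue; starts at zero."""

    q_reward: np.ndarray = field(default_factory=lambda: np.zeros(N_CUES))
    q_punish: np.ndarray = field(default_factory=lambda: np.zeros(N_CUES))

    def total(self) -> np.ndarray:
        return self.q_reward + self.q_punish

    def copy(self) -> "QState":
        return QState(self.q_reward.copy(), self.q_punish.copy())

    def _check_finite(self) -> None:
        if not (np.all(np.isfinite(self.q_reward)) and np.all(np.isfinite(self.q_punish))):
            raise InvalidDataError("non-finite Q state")


@dataclass
class LatentTrace:
    """Per-trial latent quantities from a forward pass through a session.

    ``q_reward``/``q_punish`` hold the state entering the policy on each
    trial (after decay, before the update); ``delta_r``/``delta_p`` the
    sensitivity-scaled prediction errors of the chosen cue.
    """

    choice: np.ndarray         # (T,) 1-4
    q_reward: np.ndarray       # (T, 4)
    q_punish: np.ndarray       # (T, 4)
    delta_r: np.ndarray        # (T,)
    delta_p: np.ndarray        # (T,)
    choice_probs: np.ndarray   # (T, 4)
    log_lik: np.ndarray        # (T,)

    @property
    def n_trials(self) -> int:
        return int(self.choice.shape[0])

    @property
    def total_log_lik(self) -> float:
        return float(self.log_lik.sum())


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def scaled_prediction_errors(
    params: SubjectParams, q: QState, obs: TrialObservation
) -> tuple[float, float]:
    """Sensitivity-scaled prediction errors for the chosen cue.

    delta_r = R * (O_r - Qr_chosen), delta_p = P * (O_p - Qp_chosen).
    """
    q._check_finite()
    c = obs.choice - 1
    delta_r = params.R * (obs.win - q.q_reward[c])
    delta_p = params.P * (obs.loss - q.q_punish[c])
    return float(delta_r), float(delta_p)


def update_values(
    spec: ModelSpec,
    params: SubjectParams,
    q: QState,
    chosen: int,
    delta_r: float,
    delta_p: float,
) -> QState:
    """Delta-rule update of the chosen cue only: Q += LR * delta."""
    lr_r, lr_p = params.learning_rates(spec)
    for name, lr in (("reward", lr_r), ("punishment", lr_p)):
        if not (0.0 <= lr <= 1.0):
            raise InvalidParameterError(f"{name} learning rate {lr} outside [0, 1]")
    if chosen not in (1, 2, 3, 4):
        raise InvalidDataError(f"chosen cue must be 1-4, got {chosen}")
    out = q.copy()
    c = chosen - 1
    out.q_reward[c] += lr_r * delta_r
    out.q_punish[c] += lr_p * delta_p
    return out


def apply_decay(params: SubjectParams, q: QState) -> QState:
    """Multiply every tracked value (all four cues, both valences) by (1 - d)."""
    if not (0.0 <= params.d <= 1.0):
        raise InvalidParameterError(f"d={params.d} outside [0, 1]")
    return QState((1.0 - params.d) * q.q_reward, (1.0 - params.d) * q.q_punish)


def choice_probabilities(spec: ModelSpec, params: SubjectParams, q: QState) -> np.ndarray:
    """Softmax over summed Q-values, mixed with a uniform lapse if active."""
    q._check_finite()
    tot = q.total()
    tot = tot - tot.max()  # log-sum-exp stabilization
    p = np.exp(tot)
    p /= p.sum()
    if spec.has_lapse:
        p = p * (1.0 - params.xi) + params.xi / N_CUES
    return p


# ---------------------------------------------------------------------------
# session-level engine
# ---------------------------------------------------------------------------

def run_trials(
    spec: ModelSpec,
    params: SubjectParams,
    dataset: ChoiceDataset,
    reset_between_runs: bool = False,
) -> LatentTrace:
    """Forward pass through one subject's session, recording latent traces.

    Q-values start at zero and, by default, carry across run boundaries
    (the four runs are contiguous blocks of one 240-trial session);
    ``reset_between_runs=True`` re-zeroes them at each run start.
    """
    params.validate(spec)
    T = dataset.n_trials
    resets = np.zeros(T, dtype=bool)
    if reset_between_runs:
        resets[np.flatnonzero(np.diff(dataset.run, prepend=dataset.run[0]) != 0)] = True

    q = QState()
    qr_pre = np.empty((T, N_CUES))
    qp_pre = np.empty((T, N_CUES))
    probs = np.empty((T, N_CUES))
    dr = np.empty(T)
    dp = np.empty(T)
    ll = np.empty(T)
    for t in range(T):
        if resets[t]:
            q = QState()
        if spec.has_decay:
            q = apply_decay(params, q)
        qr_pre[t] = q.q_reward
        qp_pre[t] = q.q_punish
        p = choice_probabilities(spec, params, q)
        probs[t] = p
        c = dataset.choice[t]
        ll[t] = np.log(max(p[c - 1], PROB_FLOOR))
        obs = TrialObservation(choice=int(c), win=int(dataset.win[t]), loss=int(dataset.loss[t]))
        dr[t], dp[t] = scaled_prediction_errors(params, q, obs)
        q = update_values(spec, params, q, int(c), dr[t], dp[t])

    return LatentTrace(
        choice=dataset.choice.copy(),
        q_reward=qr_pre, q_punish=qp_pre,
        delta_r=dr, delta_p=dp,
        choice_probs=probs, log_lik=ll,
    )


def negative_log_likelihood(
    spec: ModelSpec,
    params: SubjectParams,
    dataset: ChoiceDataset,
    reset_between_runs: bool = False,
) -> tuple[float, np.ndarray]:
    """Negative total log-likelihood plus the pointwise per-trial vector."""
    trace = run_trials(spec, params, dataset, reset_between_runs=reset_between_runs)
    return -trace.total_log_lik, trace.log_lik


def batch_log_likelihood(
    spec: ModelSpec,
    choice0: np.ndarray,
    win: np.ndarray,
    loss: np.ndarray,
    R: np.ndarray,
    P: np.ndarray,
    lr_r: np.ndarray,
    lr_p: np.ndarray,
    d: np.ndarray | float = 0.0,
    xi: np.ndarray | float = 0.0,
    pointwise: bool = False,
) -> np.ndarray:
    """Vectorized session log-likelihood over batches of parameter sets.

    ``choice0``/``win``/``loss`` have shape (S, T) with 0-based choices;
    parameters broadcast to shape (..., S).  Returns total log-likelihood of
    shape (..., S), or (..., S, T) when ``pointwise``.  This is the hot path
    used by the hierarchical sampler; it must agree with :func:`run_trials`
    trial for trial.
    """
    choice0 = np.asarray(choice0)
    S, T = choice0.shape
    R, P, lr_r, lr_p, d, xi = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (R, P, lr_r, lr_p, d, xi)))
    if R.shape[-1] != S:
        raise InvalidDataError(f"parameter trailing dim {R.shape} must match {S} subjects")
    batch = R.shape
    d_eff = d if spec.has_decay else np.zeros_like(d)
    xi_eff = xi if spec.has_lapse else np.zeros_like(xi)

    if _KERNELS is not None:
        B = int(np.prod(batch[:-1], dtype=int)) if len(batch) > 1 else 1
        args = [np.ascontiguousarray(a.reshape(B, S))
                for a in (R, P, lr_r, lr_p, d_eff, xi_eff)]
        fn = _KERNELS.loglik_pointwise if pointwise else _KERNELS.loglik_total
        out = fn(np.ascontiguousarray(choice0.astype(np.int64)),
                 np.ascontiguousarray(win, dtype=np.float64),
                 np.ascontiguousarray(loss, dtype=np.float64), *args)
        return out.reshape(batch + ((T,) if pointwise else ()))

    keep = 1.0 - d_eff

    qr = np.zeros(batch + (N_CUES,))
    qp = np.zeros(batch + (N_CUES,))
    s_idx = np.arange(S)
    ll = np.zeros(batch + (T,)) if pointwise else np.zeros(batch)
    for t in range(T):
        qr *= keep[..., None]
        qp *= keep[..., None]
        tot = qr + qp
        tot = tot - tot.max(axis=-1, keepdims=True)
        p = np.exp(tot)
        p /= p.sum(axis=-1, keepdims=True)
        p = p * (1.0 - xi_eff[..., None]) + xi_eff[..., None] / N_CUES
        c = choice0[:, t]
        pc = p[..., s_idx, c]
        step = np.log(np.maximum(pc, PROB_FLOOR))
        if pointwise:
            ll[..., t] = step
        else:
            ll += step
        delta_r = R * (win[:, t] - qr[..., s_idx, c])
        delta_p = P * (loss[:, t] - qp[..., s_idx, c])
        qr[..., s_idx, c] += lr_r * delta_r
        qp[..., s_idx, c] += lr_p * delta_p
    return ll


# ---------------------------------------------------------------------------
# regressor export
# ---------------------------------------------------------------------------

_REGRESSOR_NAMES = ("reward_outcome", "punishment_outcome", "rpe", "ppe", "cue", "keypress")


def export_regressors(
    trace: LatentTrace,
    dataset: ChoiceDataset,
    duration: float = 0.0,
) -> dict[int, dict[str, np.ndarray]]:
    """Model-derived event tables for GLM analysis, one set per run.

    Four regressors of interest at the outcome onset (reward outcome,
    punishment outcome, reward and punishment prediction error) and two of
    no interest (cue onset, keypress; value 1).  Each table has three
    columns: onset, duration, value (FSL EV convention).
    """
    if not dataset.has_onsets:
        raise InvalidDataError(
            f"subject {dataset.subject_id}: cue/outcome onsets required for regressor export")
    if trace.n_trials != dataset.n_trials:
        raise InvalidDataError("trace and dataset length mismatch")
    keypress = dataset.keypress_time if dataset.keypress_time is not None else dataset.cue_onset

    out: dict[int, dict[str, np.ndarray]] = {}
    for run_id, sl in dataset.run_slices():
        onset = dataset.outcome_onset[sl]
        dur = np.full(onset.shape, duration)
        tables = {
            "reward_outcome": np.column_stack([onset, dur, dataset.win[sl].astype(float)]),
            "punishment_outcome": np.column_stack([onset, dur, dataset.loss[sl].astype(float)]),
            "rpe": np.column_stack([onset, dur, trace.delta_r[sl]]),
            "ppe": np.column_stack([onset, dur, trace.delta_p[sl]]),
            "cue": np.column_stack([dataset.cue_onset[sl], np.full(onset.shape, duration),
                                    np.ones(onset.shape)]),
            "keypress": np.column_stack([keypress[sl], np.full(onset.shape, duration),
                                         np.ones(onset.shape)]),
        }
        out[run_id] = tables
    return out
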
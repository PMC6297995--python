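"""QUEST Bayesian adaptive estimation of visually lossless thresholds.

The threshold of interest is the compression ratio (CR) at which a reader
can no longer distinguish a JPEG2000-compressed CT image from its
original. Each reader completes a fixed 25-trial forced-choice session:
the first trial presents CR 5:1, and every subsequent trial is placed at
the mode of the current posterior over log10(CR). After 25 trials the
threshold estimate is the posterior mean, mapped back to CR.

The stimulus domain is log10(CR): perceptual performance is scale-like in
CR, while QUEST's Gaussian-prior machinery assumes an additive intensity
scale. The assumed psychometric function is a Weibull-shaped sigmoid with
its half-way point at the threshold,

    P(distinguishable | x) = fa + (1 - fa - lapse) * (1 - 2**(-10**(slope*(x - T))))

so P = fa + 0.5*(1 - fa - lapse) exactly at x = T.

Simulated observers (:class:`ObserverModel`) stand in for the reader
panel: each has a true threshold, slope, false-alarm and lapse rate, and
answers each trial with a Bernoulli draw from its own psychometric
function. The panel threshold ``vlt_rad`` is the median of the
per-reader estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "N_TRIALS",
    "QUEST_DEFAULTS",
    "OBSERVER_DEFAULTS",
    "QuestState",
    "ObserverModel",
    "VLTRecord",
    "init_quest",
    "next_stimulus",
    "update",
    "psychometric",
    "final_estimate",
    "simulate_observer",
    "run_session",
    "measure_vlt_panel",
]

#: trials per session (fixed-length staircase)
N_TRIALS = 25

#: CR presented on the first trial
INITIAL_CR = 5.0

#: prior and grid defaults: Gaussian prior centred on the initial
#: stimulus with SD 0.5 log10 units, 200-point grid on [log10 2, log10 40]
QUEST_DEFAULTS = {
    "prior_mean_log": math.log10(5.0),
    "prior_sd_log": 0.5,
    "grid_lo": math.log10(2.0),
    "grid_hi": math.log10(40.0),
    "n_grid": 200,
}

#: assumed psychometric parameters, also the simulated-observer defaults.
#: Conventional psychophysics values; simulation parameters, not claims
#: about any particular reader panel.
OBSERVER_DEFAULTS = {"slope": 3.5, "false_alarm": 0.04, "lapse": 0.02}


@dataclass(frozen=True)
class QuestState:
    """Posterior over log10-threshold plus the trial history."""

    grid: np.ndarray
    posterior: np.ndarray
    history: tuple[tuple[float, bool], ...] = ()

    @property
    def trial_index(self) -> int:
        return len(self.history)

    @property
    def posterior_mean_log(self) -> float:
        return float(np.dot(self.grid, self.posterior))

    @property
    def posterior_mode_log(self) -> float:
        # argmax returns the first maximum: ties break toward the lower
        # grid point
        return float(self.grid[int(np.argmax(self.posterior))])


@dataclass(frozen=True)
class ObserverModel:
    """Simulated reader with a true threshold in log10(CR)."""

    true_vlt_log: float
    slope: float = OBSERVER_DEFAULTS["slope"]
    false_alarm: float = OBSERVER_DEFAULTS["false_alarm"]
    lapse: float = OBSERVER_DEFAULTS["lapse"]

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be > 0")
        if not (0 <= self.false_alarm <= 0.2 and 0 <= self.lapse <= 0.1):
            raise ValueError("false_alarm in [0,0.2], lapse in [0,0.1]")
        if self.false_alarm + self.lapse >= 1:
            raise ValueError("false_alarm + lapse must be < 1")


@dataclass(frozen=True)
class VLTRecord:
    """Panel result for one image: per-reader VLTs and their median."""

    image_id: str
    reader_vlts: tuple[float, ...]
    vlt_rad: float


def init_quest(
    prior_mean_log: float = QUEST_DEFAULTS["prior_mean_log"],
    prior_sd_log: float = QUEST_DEFAULTS["prior_sd_log"],
    grid_lo: float = QUEST_DEFAULTS["grid_lo"],
    grid_hi: float = QUEST_DEFAULTS["grid_hi"],
    n_grid: int = QUEST_DEFAULTS["n_grid"],
) -> QuestState:
    """Fresh session state: truncated-Gaussian prior on the grid."""
    if not grid_lo < grid_hi:
        raise ValueError("grid_lo must be < grid_hi")
    if n_grid < 50:
        raise ValueError("n_grid must be >= 50")
    if not prior_sd_log > 0:
        raise ValueError("prior_sd_log must be > 0")
    grid = np.linspace(grid_lo, grid_hi, n_grid)
    prior = np.exp(-0.5 * ((grid - prior_mean_log) / prior_sd_log) ** 2)
    prior /= prior.sum()
    return QuestState(grid=grid, posterior=prior)


def psychometric(
    x: float,
    threshold: float,
    slope: float = OBSERVER_DEFAULTS["slope"],
    false_alarm: float = OBSERVER_DEFAULTS["false_alarm"],
    lapse: float = OBSERVER_DEFAULTS["lapse"],
):
    """P("distinguishable") at log10-CR ``x`` for a given threshold.

    Vectorized over ``x`` and/or ``threshold``.
    """
    if not slope > 0:
        raise ValueError("slope must be > 0")
    d = np.asarray(x, dtype=np.float64) - np.asarray(threshold, dtype=np.float64)
    # 1 - 2**(-10**(slope*d)) : 0 at -inf, 0.5 at d=0, 1 at +inf
    w = -np.power(2.0, -np.power(10.0, np.clip(slope * d, -300, 300)))
    w += 1.0
    return false_alarm + (1.0 - false_alarm - lapse) * w


def next_stimulus(state: QuestState) -> float:
    """CR for the next trial: 5:1 first, then the posterior mode."""
    if state.trial_index >= N_TRIALS:
        raise ValueError(f"session already has {N_TRIALS} trials")
    if state.trial_index == 0:
        return INITIAL_CR
    return 10.0 ** state.posterior_mode_log


def update(
    state: QuestState,
    cr: float,
    response: bool,
    slope: float = OBSERVER_DEFAULTS["slope"],
    false_alarm: float = OBSERVER_DEFAULTS["false_alarm"],
    lapse: float = OBSERVER_DEFAULTS["lapse"],
) -> QuestState:
    """Bayes update after one trial at ``cr`` with the reader's response.

    ``response`` is True when the reader judged original and compressed
    images distinguishable.
    """
    if not cr > 1:
        raise ValueError("cr must be > 1")
    p = psychometric(math.log10(cr), state.grid, slope, false_alarm, lapse)
    lik = p if response else 1.0 - p
    post = state.posterior * lik
    total = post.sum()
    if total <= 0:
        raise RuntimeError("posterior vanished; likelihood floor too hard")
    return replace(
        state,
        posterior=post / total,
        history=state.history + ((float(cr), bool(response)),),
    )


def final_estimate(state: QuestState) -> float:
    """Threshold estimate after a complete session: 10**posterior mean."""
    if state.trial_index != N_TRIALS:
        raise ValueError(
            f"session incomplete: {state.trial_index}/{N_TRIALS} trials"
        )
    return 10.0 ** state.posterior_mean_log


def simulate_observer(
    observer: ObserverModel, cr: float, rng: np.random.Generator
) -> bool:
    """One Bernoulli response of a simulated reader at the given CR."""
    if not cr > 1:
        raise ValueError("cr must be > 1")
    p = float(
        psychometric(
            math.log10(cr),
            observer.true_vlt_log,
            observer.slope,
            observer.false_alarm,
            observer.lapse,
        )
    )
    return bool(rng.random() < p)


def run_session(
    observer: ObserverModel,
    rng: np.random.Generator,
    **quest_kwargs,
) -> tuple[float, QuestState]:
    """One full 25-trial QUEST session against a simulated observer."""
    state = init_quest(**quest_kwargs)
    for _ in range(N_TRIALS):
        cr = next_stimulus(state)
        response = simulate_observer(observer, cr, rng)
        state = update(state, cr, response)
    return final_estimate(state), state


def measure_vlt_panel(
    image_id: str,
    observers: list[ObserverModel],
    seed: int,
) -> VLTRecord:
    """Run an independent QUEST session per reader; pool by the median."""
    if len(observers) == 0:
        raise ValueError("observer panel must not be empty")
    streams = np.random.SeedSequence(seed).spawn(len(observers))
    vlts = tuple(
        run_session(obs, np.random.default_rng(ss))[0]
        for obs, ss in zip(observers, streams)
    )
    return VLTRecord(
        image_id=image_id, reader_vlts=vlts, vlt_rad=float(np.median(vlts))
    )
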
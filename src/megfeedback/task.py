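"""Probabilistic classification ("weather prediction") task simulator.

Four fractal stimuli each predict one of two outcomes (sun/rain) with a fixed
contingency (default 90/10).  Two stimuli are *positive-feedback cards*: an
optimal answer earns positive feedback, a non-optimal one earns nothing.  The
other two are *negative-feedback cards*: a non-optimal answer earns negative
feedback, an optimal one earns nothing.  This asymmetry dissociates learning
from reward and from punishment.

``generate_task_session`` lays out the trials and draws the outcomes;
``simulate_agent_responses`` fills in responses for an agent with a target
optimal-response rate and lognormal reaction times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TaskConfig", "generate_task_session", "simulate_agent_responses",
           "feedback_for", "TRIAL_COLUMNS"]

STIMULI = ("S1", "S2", "S3", "S4")
CARD_TYPE = {"S1": "positive", "S2": "positive", "S3": "negative", "S4": "negative"}

TRIAL_COLUMNS = [
    "subject_id", "block", "trial", "stimulus", "card_type",
    "dominant_outcome", "outcome", "response", "optimal",
    "feedback_shown", "rt_ms",
]


@dataclass
class TaskConfig:
    """Task structure parameters.

    n_blocks * trials_per_block trials in total (default 3 x 160 = 480);
    each stimulus's dominant outcome occurs with probability ``contingency``.
    Per card type exactly two stimuli exist; of the four stimuli two predict
    "sun" and two predict "rain" (the pairing is randomised per session).
    """

    n_blocks: int = 3
    trials_per_block: int = 160
    contingency: float = 0.9
    feedback_duration_ms: tuple = (900.0, 1000.0)

    def __post_init__(self):
        if not 0.5 <= self.contingency <= 1.0:
            raise ValueError("contingency must be in [0.5, 1]")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("block structure counts must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def feedback_for(card_type: str, optimal: bool) -> str:
    """Feedback contingency table of the task.

    positive card & optimal -> positive; positive card & non-optimal -> none;
    negative card & non-optimal -> negative; negative card & optimal -> none.
    """
    if card_type == "positive":
        return "positive" if optimal else "none"
    if card_type == "negative":
        return "none" if optimal else "negative"
    raise ValueError(f"unknown card type {card_type!r}")


def generate_task_session(
    cfg: TaskConfig, seed: int, subject_id: str = "S000"
) -> pd.DataFrame:
    """Generate one session's trial layout and outcomes (responses unset).

    Within each block the four stimuli appear in (near-)balanced shuffled
    order.  One stimulus per card type is sun-dominant and one rain-dominant,
    assigned at random per session.  Outcomes are independent draws: the
    dominant outcome with probability ``cfg.contingency``.
    """
    rng = np.random.default_rng(seed)

    # random sun/rain assignment: one dominant-sun and one dominant-rain
    # stimulus within each card-type pair
    dominant = {}
    for pair in (("S1", "S2"), ("S3", "S4")):
        sun_first = bool(rng.integers(2))
        dominant[pair[0]] = "sun" if sun_first else "rain"
        dominant[pair[1]] = "rain" if sun_first else "sun"

    blocks = []
    trials = []
    order = []
    reps = -(-cfg.trials_per_block // 4)  # ceil
    for block in range(cfg.n_blocks):
        o = np.tile(np.arange(4), reps)[: cfg.trials_per_block]
        rng.shuffle(o)
        order.append(o)
        blocks.append(np.full(cfg.trials_per_block, block))
        trials.append(np.arange(cfg.trials_per_block))
    order = np.concatenate(order)
    stim = np.asarray(STIMULI)[order]
    dom = np.asarray([dominant[s] for s in STIMULI])[order]
    other = np.where(dom == "sun", "rain", "sun")
    outcome = np.where(rng.random(len(order)) < cfg.contingency, dom, other)
    n = len(order)
    return pd.DataFrame({
        "subject_id": np.repeat(subject_id, n),
        "block": np.concatenate(blocks),
        "trial": np.concatenate(trials),
        "stimulus": stim,
        "card_type": np.asarray([CARD_TYPE[s] for s in STIMULI])[order],
        "dominant_outcome": dom,
        "outcome": outcome,
        "response": np.full(n, None, dtype=object),
        "optimal": np.full(n, None, dtype=object),
        "feedback_shown": np.full(n, None, dtype=object),
        "rt_ms": np.full(n, np.nan),
    })


@dataclass
class RTModel:
    """Lognormal reaction-time model (ms); positive-skewed like real RTs."""

    median_ms: float = 600.0
    sigma: float = 0.35

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(np.log(self.median_ms), self.sigma, size=n))


def simulate_agent_responses(
    session: pd.DataFrame,
    target_accuracy,
    seed: int,
    rt_model: RTModel | None = None,
) -> pd.DataFrame:
    """Fill in responses for an agent with a fixed optimal-response rate.

    ``target_accuracy`` is either a scalar or a ``{"positive": p, "negative":
    q}`` mapping giving the per-card-type probability of answering optimally
    (i.e. with the stimulus's dominant outcome).  Feedback follows the task's
    contingency table; reaction times are lognormal.
    """
    if np.isscalar(target_accuracy):
        target_accuracy = {"positive": float(target_accuracy),
                           "negative": float(target_accuracy)}
    for v in target_accuracy.values():
        if not 0.0 <= v <= 1.0:
            raise ValueError("target_accuracy must be in [0, 1]")
    rt_model = rt_model or RTModel()

    rng = np.random.default_rng(seed)
    out = session.copy()
    n = len(out)
    acc = out["card_type"].map(target_accuracy).to_numpy(dtype=float)
    optimal = rng.random(n) < acc
    dom = out["dominant_outcome"].to_numpy()
    other = np.where(dom == "sun", "rain", "sun")
    out["response"] = np.where(optimal, dom, other)
    out["optimal"] = optimal
    out["feedback_shown"] = [
        feedback_for(ct, bool(op)) for ct, op in zip(out["card_type"], optimal)
    ]
    out["rt_ms"] = rt_model.draw(rng, n)
    return out
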
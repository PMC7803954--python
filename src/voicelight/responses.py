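"""Behavioural response simulation.

Emulates the identification behaviour observed in the scanner: a subject
answers correctly with probability ``ability``; errors are routed through a
confusability kernel in which the two hardest-to-separate speakers (Betty
and Chloe) absorb most confusions; a small fraction of trials times out
(missing response); reaction times are lognormal truncated at the 5-s
answer window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Errors routed preferentially between speakers 2 and 3 (rows: presented
# speaker; columns: answered speaker; zero diagonal, rows sum to 1).
DEFAULT_ERROR_KERNEL = np.array(
    [
        [0.0, 0.5, 0.5],
        [0.3, 0.0, 0.7],
        [0.3, 0.7, 0.0],
    ]
)

# Per-speaker shifts around the scalar ability, in probability units,
# emulating the observed ordering (speaker 3 hardest).
DEFAULT_SPEAKER_ABILITY_DELTA = (0.039, 0.013, -0.059)


class BehaviorModelError(ValueError):
    pass


@dataclass
class BehaviorModel:
    """Generative model of single-trial identification responses.

    Parameters
    ----------
    ability : float
        Probability of a correct answer on an answered trial, in [0, 1].
    error_kernel : (n_speakers, n_speakers) array
        Row-stochastic answer distribution conditional on an error;
        zero diagonal.
    miss_rate : float
        Probability that no response occurs within the answer window.
    rt_lognormal_params : (float, float)
        (location, scale) of the response-time lognormal, in log-seconds.
    speaker_ability_delta : tuple or None
        Additive per-speaker shift of ``ability`` (clipped to [0, 1]);
        None disables speaker-difficulty structure.
    """

    ability: float = 0.62
    error_kernel: np.ndarray = field(
        default_factory=lambda: DEFAULT_ERROR_KERNEL.copy()
    )
    miss_rate: float = 0.02
    rt_lognormal_params: tuple = (np.log(1.2), 0.35)
    speaker_ability_delta: tuple | None = DEFAULT_SPEAKER_ABILITY_DELTA

    def __post_init__(self):
        if not 0.0 <= self.ability <= 1.0:
            raise BehaviorModelError("ability must lie in [0, 1]")
        if not 0.0 <= self.miss_rate < 1.0:
            raise BehaviorModelError("miss_rate must lie in [0, 1)")
        k = np.asarray(self.error_kernel, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise BehaviorModelError("error_kernel must be square")
        if np.any(np.diag(k) != 0):
            raise BehaviorModelError("error_kernel diagonal must be zero")
        if not np.allclose(k.sum(axis=1), 1.0):
            raise BehaviorModelError("error_kernel rows must sum to 1")
        self.error_kernel = k


def simulate_responses(
    design: pd.DataFrame,
    model: BehaviorModel,
    seed: int = 0,
    answer_window: float = 5.0,
) -> pd.DataFrame:
    """Fill the response columns of an event table.

    Each trial independently: with probability ``miss_rate`` no response
    (missing=True, response="n/a"); otherwise correct with the (per-speaker
    adjusted) ability, errors drawn from the presented speaker's
    ``error_kernel`` row, and an RT drawn lognormal truncated at
    ``answer_window``. Missingness is independent of correctness.
    """
    rng = np.random.default_rng(seed)
    events = design.copy()
    speakers = sorted(events["speaker"].unique())
    if len(speakers) > model.error_kernel.shape[0]:
        raise BehaviorModelError(
            "error_kernel smaller than the number of speakers in the design"
        )
    idx = {s: i for i, s in enumerate(speakers)}

    n = len(events)
    n_spk = len(speakers)
    presented = np.array([idx[s] for s in events["speaker"]])

    missing = rng.uniform(size=n) < model.miss_rate

    p_correct = np.full(n, model.ability)
    if model.speaker_ability_delta is not None:
        delta = np.asarray(model.speaker_ability_delta)[:n_spk]
        p_correct = np.clip(p_correct + delta[presented], 0.0, 1.0)
    correct = rng.uniform(size=n) < p_correct

    # errors: inverse-CDF draw from the presented speaker's kernel row
    kernel = model.error_kernel[:n_spk, :n_spk].copy()
    sums = kernel.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0  # degenerate single-speaker design: no error targets
    cdf = np.cumsum(kernel / sums, axis=1)
    u = rng.uniform(size=n)
    err_answer = np.minimum((u[:, None] > cdf[presented]).sum(axis=1), n_spk - 1)

    answer_idx = np.where(correct, presented, err_answer)
    answered = ~missing
    responses = np.full(n, "n/a", dtype=object)
    responses[answered] = np.array(speakers, dtype=object)[answer_idx[answered]]

    # truncated lognormal RTs: redraw any value past the answer window
    mu, sigma = model.rt_lognormal_params
    rts = np.full(n, np.nan)
    need = answered.copy()
    while need.any():
        draw = rng.lognormal(mu, sigma, size=int(need.sum()))
        rts[need] = draw
        need = answered & (rts > answer_window)

    events["response"] = responses
    events["response_time"] = rts
    events["missing"] = missing
    return events
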
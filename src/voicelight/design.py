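"""Trial-sequence generation for the speaker-identification experiment.

The scanner session comprises four runs of 36 trials (12 disyllabic words,
each spoken by 3 learned speakers, every word-speaker pair exactly once per
run). Trial order is pseudo-random with at most two consecutive trials from
the same speaker. Inter-stimulus intervals are drawn from an exponential
distribution truncated to [3, 5] s. Subjects answer within a 5-s window;
the generator spaces onsets conservatively by the full window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_COLUMNS = [
    "onset",
    "duration",
    "speaker",
    "word",
    "response",
    "response_time",
    "missing",
    "run",
]

DEFAULT_SPEAKERS = ("anne", "betty", "chloe")
DEFAULT_WORDS = tuple(f"w{i:02d}" for i in range(1, 13))


class DesignError(ValueError):
    """Raised when a design specification is invalid or infeasible."""


@dataclass
class DesignSpec:
    """Parameters of the scanning-session trial design.

    Defaults reproduce the study conditions: 4 runs x 36 trials
    (12 words x 3 speakers), ISIs in [3, 5] s, a 5-s answer window,
    TR = 0.955 s and 366 volumes per run.
    """

    n_runs: int = 4
    words: tuple = DEFAULT_WORDS
    speakers: tuple = DEFAULT_SPEAKERS
    isi_bounds: tuple = (3.0, 5.0)
    answer_window: float = 5.0
    tr: float = 0.955
    n_volumes_per_run: int = 366
    max_consecutive_same_speaker: int = 2
    stimulus_duration: float = 0.7
    response_slot: float = 3.0
    isi_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise DesignError("n_runs must be >= 1")
        if not self.words or not self.speakers:
            raise DesignError("words and speakers must be non-empty")
        if len(set(self.words)) != len(self.words):
            raise DesignError("word labels must be unique")
        if len(set(self.speakers)) != len(self.speakers):
            raise DesignError("speaker labels must be unique")
        lo, hi = self.isi_bounds
        if not lo < hi:
            raise DesignError("isi_bounds must satisfy lo < hi")
        if self.max_consecutive_same_speaker < 1:
            raise DesignError(
                "max_consecutive_same_speaker must be >= 1 "
                "(0 forbids every trial)"
            )
        if self.tr <= 0 or self.n_volumes_per_run < 1:
            raise DesignError("tr and n_volumes_per_run must be positive")

    @property
    def n_trials_per_run(self) -> int:
        return len(self.words) * len(self.speakers)

    @property
    def run_duration(self) -> float:
        return self.n_volumes_per_run * self.tr


def truncated_exponential(rng, n, bounds, rate=1.0):
    """Sample from Exp(rate) truncated to ``bounds`` by inverse-CDF."""
    lo, hi = bounds
    u = rng.uniform(size=n)
    c_lo = 1.0 - np.exp(-rate * lo)
    c_hi = 1.0 - np.exp(-rate * hi)
    return -np.log(1.0 - (c_lo + u * (c_hi - c_lo))) / rate


def _order_with_speaker_constraint(pairs, max_consecutive, rng, max_restarts=1000):
    """Sequentially sample an order of (word, speaker) pairs such that no
    more than ``max_consecutive`` same-speaker trials occur in a row.

    At each step, draws uniformly among admissible remaining pairs;
    restarts on dead ends. Infeasibility (e.g. a single speaker with more
    pairs than the allowed run length) raises :class:`DesignError`.
    """
    speakers = sorted({s for _, s in pairs})
    if len(speakers) == 1 and len(pairs) > max_consecutive:
        raise DesignError(
            "infeasible ordering: a single speaker cannot satisfy "
            f"max_consecutive_same_speaker={max_consecutive} "
            f"over {len(pairs)} trials"
        )
    for _ in range(max_restarts):
        remaining = list(pairs)
        order = []
        streak_speaker, streak = None, 0
        ok = True
        while remaining:
            if streak >= max_consecutive:
                admissible = [p for p in remaining if p[1] != streak_speaker]
            else:
                admissible = remaining
            if not admissible:
                ok = False
                break
            pick = admissible[rng.integers(len(admissible))]
            remaining.remove(pick)
            order.append(pick)
            if pick[1] == streak_speaker:
                streak += 1
            else:
                streak_speaker, streak = pick[1], 1
        if ok:
            return order
    raise DesignError("could not satisfy the speaker-ordering constraint")


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Generate the full event table for one subject's scanning session.

    Returns a BIDS-style event table with one row per trial. ``response``,
    ``response_time`` and ``missing`` are filled by
    :func:`voicelight.responses.simulate_responses`; here they are "n/a".

    The scanner task is self-paced (the ISI runs from the response
    instant); the generator approximates this with a fixed nominal
    response slot: onsets are spaced by stimulus duration + response_slot
    + a truncated-exponential ISI, so the 36 trials always fit the run
    and simulated responses (RT <= answer window) never overlap the next
    stimulus.
    """
    rng = np.random.default_rng(spec.seed)
    pairs = [(w, s) for w in spec.words for s in spec.speakers]
    frames = []
    for run in range(1, spec.n_runs + 1):
        order = _order_with_speaker_constraint(
            pairs, spec.max_consecutive_same_speaker, rng
        )
        n = len(order)
        isis = truncated_exponential(rng, n, spec.isi_bounds, spec.isi_rate)
        # first onset after an initial ISI-like delay; subsequent onsets
        # leave room for the stimulus and a nominal response slot
        gaps = spec.stimulus_duration + spec.response_slot + isis[1:]
        onsets = isis[0] + np.concatenate([[0.0], np.cumsum(gaps)])
        end = onsets[-1] + spec.stimulus_duration + spec.answer_window
        if end > spec.run_duration:
            raise DesignError(
                f"run {run} does not fit: needs {end:.1f}s, "
                f"run lasts {spec.run_duration:.1f}s"
            )
        frames.append(
            pd.DataFrame(
                {
                    "onset": onsets,
                    "duration": spec.stimulus_duration,
                    "speaker": [s for _, s in order],
                    "word": [w for w, _ in order],
                    "response": "n/a",
                    "response_time": np.nan,
                    "missing": True,
                    "run": run,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[EVENT_COLUMNS]


def generate_learning_design(spec: DesignSpec, n_sessions: int = 2) -> pd.DataFrame:
    """Generate the pre-scan learning-phase trial table.

    The learning phase repeats the word x speaker product once per session
    (2 sessions of 36 trials = 72 identification trials by default), with
    the same speaker-ordering constraint. Self-paced: onsets are trial
    indices, no scanner timing.
    """
    if n_sessions < 1:
        raise DesignError("n_sessions must be >= 1")
    rng = np.random.default_rng(spec.seed)
    pairs = [(w, s) for w in spec.words for s in spec.speakers]
    frames = []
    for sess in range(1, n_sessions + 1):
        order = _order_with_speaker_constraint(
            pairs, spec.max_consecutive_same_speaker, rng
        )
        frames.append(
            pd.DataFrame(
                {
                    "onset": np.arange(len(order), dtype=float),
                    "duration": spec.stimulus_duration,
                    "speaker": [s for _, s in order],
                    "word": [w for w, _ in order],
                    "response": "n/a",
                    "response_time": np.nan,
                    "missing": True,
                    "run": sess,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[EVENT_COLUMNS]


def max_speaker_run_length(events: pd.DataFrame) -> int:
    """Longest streak of consecutive same-speaker trials within any run."""
    longest = 0
    for _, g in events.groupby("run"):
        speakers = g.sort_values("onset")["speaker"].to_numpy()
        streak = 0
        prev = None
        for s in speakers:
            streak = streak + 1 if s == prev else 1
            prev = s
            longest = max(longest, streak)
    return longest
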
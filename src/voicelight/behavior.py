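"""Behavioural summaries and confusion-matrix analytics.

Percent-correct scores (overall, per speaker, per run), reaction-time
summaries over answered trials, and the 3x3 presented-vs-answered
confusion matrix normalised so that all nine cells sum to 100% (perfect
performance: 33.33% per diagonal cell; uniform guessing: 11.11% per cell).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .searchlight import ConfusionMatrix3


class BehaviorError(ValueError):
    pass


@dataclass
class BehaviorSummary:
    pc_overall: float  # percent correct over answered (or all) trials
    pc_per_speaker: dict
    rt_mean_overall: float
    rt_mean_per_speaker: dict
    missing_rate: float  # percent of all trials without a response
    pc_per_run: dict
    n_trials: int
    n_answered: int


def _answered(events: pd.DataFrame) -> pd.DataFrame:
    return events[~events["missing"].astype(bool)]


def percent_correct(events: pd.DataFrame,
                    missing_policy: str = "exclude") -> BehaviorSummary:
    """Percent-correct and RT summary of an event table.

    ``missing_policy`` "exclude" conditions PC on answered trials;
    "count_as_error" counts missing trials as incorrect. RT summaries
    always use answered trials only.
    """
    if missing_policy not in ("exclude", "count_as_error"):
        raise BehaviorError(f"unknown missing_policy {missing_policy!r}")
    answered = _answered(events)
    if not len(answered):
        raise BehaviorError("no answered trials")

    def _pc(sub):
        ans = _answered(sub)
        hits = float((ans["response"] == ans["speaker"]).sum())
        denom = len(sub) if missing_policy == "count_as_error" else len(ans)
        return 100.0 * hits / denom if denom else np.nan

    return BehaviorSummary(
        pc_overall=_pc(events),
        pc_per_speaker={s: _pc(g) for s, g in events.groupby("speaker")},
        rt_mean_overall=float(answered["response_time"].mean()),
        rt_mean_per_speaker={
            s: float(g["response_time"].mean())
            for s, g in answered.groupby("speaker")
        },
        missing_rate=100.0 * float(events["missing"].astype(bool).mean()),
        pc_per_run={int(r): _pc(g) for r, g in events.groupby("run")},
        n_trials=len(events),
        n_answered=len(answered),
    )


def confusion_matrix(events: pd.DataFrame,
                     labels=None) -> ConfusionMatrix3:
    """Presented x answered percentage matrix over answered trials.

    Missing responses carry no answer cell and are excluded (reported
    separately by :func:`percent_correct`). Cells sum to 100.
    """
    answered = _answered(events)
    if not len(answered):
        raise BehaviorError("no answered trials to tabulate")
    if labels is None:
        labels = sorted(events["speaker"].unique())
    index = {s: i for i, s in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for s, r in zip(answered["speaker"], answered["response"]):
        counts[index[s], index[r]] += 1
    return ConfusionMatrix3(
        cells=100.0 * counts / counts.sum(),
        n_trials=int(counts.sum()),
        labels=tuple(labels),
    )


def _cells_vector(cm: ConfusionMatrix3, cells: str) -> np.ndarray:
    m = np.asarray(cm.cells, dtype=float)
    if cells == "all9":
        return m.ravel()
    if cells == "offdiag6":
        mask = ~np.eye(m.shape[0], dtype=bool)
        return m[mask]
    raise BehaviorError(f"unknown cell selection {cells!r}")


def confusion_correlation(cm_a: ConfusionMatrix3, cm_b: ConfusionMatrix3,
                          cells: str = "all9"):
    """Spearman correlation between two confusion matrices.

    Correlates the selected cell vectors (all 9 cells by default, or the 6
    off-diagonal error cells) and returns (rho, one-tailed p for positive
    association). For vectors of length <= 9 the p-value is exact,
    obtained by enumerating all permutations of one rank vector.
    """
    a = _cells_vector(cm_a, cells)
    b = _cells_vector(cm_b, cells)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise BehaviorError("constant cell vector: correlation undefined")
    rho = float(stats.spearmanr(a, b).statistic)
    n = len(a)
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    if n <= 9:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_null = _pearson_many(ra[perms], rb)
        p = float(np.mean(rho_null >= rho - 1e-12))
    else:
        p = float(stats.spearmanr(a, b, alternative="greater").pvalue)
    return rho, p


def _pearson_many(rows, y):
    """Pearson correlation of each row of ``rows`` with ``y``."""
    rows = np.asarray(rows, dtype=float)
    y = np.asarray(y, dtype=float)
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = rc @ yc
    den = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    return num / den
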
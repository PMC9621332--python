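"""Behavioral summary measures: windowed performance and probing odds.

Performance is the odds of choosing the currently high-reward card and
probing the odds of choosing the informative explore option, both
estimated in a sliding window (default 201 trials, centered, truncated at
the edges).  The within-window proportion is clipped to
[1/(n+1), n/(n+1)] (n = valid trials in the window) before the odds
transform so that all-success or all-failure windows stay finite.
rmse_temporal scores the quality of the learned temporal representation
against the generative template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .templates import MU_GRID, NU_GRID

__all__ = [
    "TrialRecord",
    "windowed_odds",
    "performance_series",
    "probing_series",
    "summary_means",
    "rmse_temporal",
    "records_frame",
]

DEFAULT_WINDOW = 201


@dataclass
class TrialRecord:
    """One trial of one subject: choice, outcome, correctness label."""

    subject: str
    trial: int
    choice: int | None  # 1 left, 2 explore, 3 right; None = missing
    outcome: int | None
    correct: bool  # chosen card was the high-probability card


def records_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [r.subject for r in records],
            "trial": [r.trial for r in records],
            "choice": [r.choice for r in records],
            "outcome": [r.outcome for r in records],
            "correct": [r.correct for r in records],
        }
    )


def _clipped_odds(successes: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if np.any(valid < 1):
        raise ValueError("empty window")
    p = successes / valid
    lo = 1.0 / (valid + 1.0)
    p = np.clip(p, lo, 1.0 - lo)
    return p / (1.0 - p)


def windowed_odds(labels, center: int, window: int = DEFAULT_WINDOW) -> float:
    """Odds of a True label in a centered window around a 1-based trial."""
    if window % 2 != 1:
        raise ValueError("window length must be odd (centered window)")
    lab = np.asarray(labels, dtype=float)
    half = window // 2
    lo = max(0, center - 1 - half)
    hi = min(lab.size, center + half)
    seg = lab[lo:hi]
    valid = np.sum(~np.isnan(seg))
    if valid < 1:
        raise ValueError("empty window")
    succ = np.nansum(seg)
    return float(_clipped_odds(np.array([succ]), np.array([valid]))[0])


def _label_series(labels: np.ndarray, window: int) -> np.ndarray:
    """Vectorised windowed odds over every trial (NaN = missing, excluded)."""
    if window % 2 != 1:
        raise ValueError("window length must be odd (centered window)")
    lab = np.asarray(labels, dtype=float)
    kernel = np.ones(window)
    valid = np.convolve((~np.isnan(lab)).astype(float), kernel, mode="same")
    succ = np.convolve(np.nan_to_num(lab), kernel, mode="same")
    return _clipped_odds(succ, valid)


def _labels_from_records(records, column: str) -> np.ndarray:
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    df = df.sort_values("trial")
    missing = df["choice"].isna().to_numpy()
    if column == "correct":
        lab = df["correct"].to_numpy(dtype=float)
    elif column == "explore":
        lab = (df["choice"] == 2).to_numpy(dtype=float)
    else:  # pragma: no cover
        raise ValueError(column)
    lab[missing] = np.nan
    return lab


def performance_series(records, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Per-trial odds of a correct (high-reward-card) choice.

    Explore and missing responses count as not correct; missing trials are
    excluded from both numerator and denominator.
    """
    return _label_series(_labels_from_records(records, "correct"), window)


def probing_series(records, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Per-trial odds of choosing the explore option."""
    return _label_series(_labels_from_records(records, "explore"), window)


def summary_means(series: np.ndarray, from_trial: int = 400, to_trial: int = 800) -> float:
    """Mean odds over 1-based trials [from_trial, to_trial].

    The defaults drop the first 400 trials (task familiarisation) and
    everything after the trial-800 statistics switch.
    """
    series = np.asarray(series, dtype=float)
    if not (1 <= from_trial <= to_trial <= series.size):
        raise ValueError("summary bounds outside the series")
    return float(series[from_trial - 1 : to_trial].mean())


def rmse_from_marginals(
    q_mu: np.ndarray, q_nu: np.ndarray, true_mu: float, true_nu: float
) -> tuple[float, float]:
    """RMSE of (mu, nu) from already-marginalised template posteriors."""
    q_mu = np.asarray(q_mu) / np.sum(q_mu)
    q_nu = np.asarray(q_nu) / np.sum(q_nu)
    rmse_mu = float(np.sqrt(np.sum(q_mu * (MU_GRID - true_mu) ** 2)))
    rmse_nu = float(np.sqrt(np.sum(q_nu * (NU_GRID - true_nu) ** 2)))
    return rmse_mu, rmse_nu


def rmse_temporal(belief, true_mu: float, true_nu: float) -> tuple[float, float]:
    """Root-mean-square error of the template posterior about (mu, nu).

    RMSE_mu = sqrt(sum_m q(m) (mu_m - true_mu)^2), analogously for nu, so a
    posterior concentrated on the truth scores (0, 0).
    """
    from .beliefs import template_marginals

    q_mu, q_nu = template_marginals(belief)
    return rmse_from_marginals(q_mu, q_nu, true_mu, true_nu)
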
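"""Behavioral summaries and group statistics.

Per subject: optimal-response accuracy and reaction time, split by
positive-feedback and negative-feedback cards.  Group level: a one-way MANOVA
(Wilks' lambda) on the four dependent variables, learner classification
against a >65% accuracy criterion, and a chi-square comparison of learner
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA

__all__ = [
    "LearnerConfig", "compute_accuracy_rt", "behavioral_table",
    "classify_learner", "manova_group_effect", "chi_square_learners",
]

DEPENDENT_VARS = ["pos_accuracy", "neg_accuracy", "pos_rt", "neg_rt"]


@dataclass
class LearnerConfig:
    """Learner criterion: accuracy strictly greater than ``threshold``."""

    threshold: float = 0.65

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def compute_accuracy_rt(
    trials: pd.DataFrame, first_n: int | None = None, rt_stat: str = "mean"
) -> dict:
    """One behavioral-table row from a completed session.

    Accuracy is the fraction of optimal responses, separately for positive-
    and negative-feedback cards; RT is the mean (or median) reaction time per
    card type.  ``first_n`` restricts the computation to the session's first
    ``first_n`` trials (a prefix, never a sample).  A card type with zero
    trials yields NaN cells rather than zeros.
    """
    if trials.empty:
        raise ValueError("session has no trials")
    if first_n is not None:
        if first_n > len(trials):
            raise ValueError("first_n exceeds available trials")
        trials = trials.iloc[:first_n]
    if trials["optimal"].isna().any():
        raise ValueError("session contains unanswered trials")
    agg = {"mean": np.mean, "median": np.median}[rt_stat]

    row = {"subject_id": trials["subject_id"].iloc[0],
           "n_trials_completed": int(len(trials))}
    for card, tag in (("positive", "pos"), ("negative", "neg")):
        sub = trials[trials["card_type"] == card]
        if sub.empty:
            row[f"{tag}_accuracy"] = np.nan
            row[f"{tag}_rt"] = np.nan
        else:
            row[f"{tag}_accuracy"] = float(sub["optimal"].mean())
            row[f"{tag}_rt"] = float(agg(sub["rt_ms"].to_numpy(dtype=float)))
    return row


def behavioral_table(
    sessions, groups, first_n: int | None = None, rt_stat: str = "mean"
) -> pd.DataFrame:
    """Stack per-subject rows (see :func:`compute_accuracy_rt`) with groups."""
    rows = []
    for sess, grp in zip(sessions, groups):
        row = compute_accuracy_rt(sess, first_n=first_n, rt_stat=rt_stat)
        row["group"] = grp
        rows.append(row)
    return pd.DataFrame(rows)


def classify_learner(accuracy: float, cfg: LearnerConfig | None = None) -> bool:
    """True iff accuracy strictly exceeds the learner threshold."""
    cfg = cfg or LearnerConfig()
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    return bool(accuracy > cfg.threshold)


def manova_group_effect(table: pd.DataFrame) -> dict:
    """One-way MANOVA of group on the four behavioral dependent variables.

    Subjects with any missing dependent variable are dropped listwise.
    Returns the Wilks' lambda statistic with its exact-F conversion.
    """
    cols = DEPENDENT_VARS + ["group"]
    data = table[cols].dropna()
    counts = data["group"].value_counts()
    if len(counts) < 2:
        raise ValueError("MANOVA needs at least two groups")
    p = len(DEPENDENT_VARS)
    if (counts <= p).any():
        raise ValueError("each group must have more subjects than dependent variables")
    # explicit degenerate-input handling: statsmodels silently rank-reduces
    # collinear DVs and cannot form the test when the between-group scatter
    # is exactly zero
    groups = [data[data["group"] == g][DEPENDENT_VARS].to_numpy(dtype=float)
              for g in counts.index]
    within = sum(np.cov(g, rowvar=False) * (len(g) - 1) for g in groups)
    if np.linalg.matrix_rank(within, tol=1e-10 * np.trace(within)) < p:
        raise ValueError("singular within-group covariance")
    means = np.stack([g.mean(axis=0) for g in groups])
    n_total = int(len(data))
    if np.allclose(means, means[0], rtol=0, atol=1e-12):
        return {"wilks_lambda": 1.0, "F": 0.0, "df1": p,
                "df2": n_total - p - 1, "p": 1.0, "n": n_total}
    # standardise column names for the formula interface
    d = data.rename(columns={c: f"v{i}" for i, c in enumerate(DEPENDENT_VARS)})
    formula = " + ".join(f"v{i}" for i in range(p)) + " ~ group"
    try:
        res = MANOVA.from_formula(formula, data=d).mv_test()
    except np.linalg.LinAlgError as err:  # singular within-group covariance
        raise ValueError(f"singular covariance in MANOVA: {err}") from err
    stat = res.results["group"]["stat"].loc["Wilks' lambda"]
    return {
        "wilks_lambda": float(stat["Value"]),
        "F": float(stat["F Value"]),
        "df1": int(stat["Num DF"]),
        "df2": int(stat["Den DF"]),
        "p": float(stat["Pr > F"]),
        "n": int(len(data)),
    }


def chi_square_learners(counts, correction: bool = False) -> dict:
    """Chi-square test on a 2x2 learner/non-learner by group table.

    ``counts``: [[learners_A, nonlearners_A], [learners_B, nonlearners_B]].
    Yates continuity correction is off by default.
    """
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be a 2x2 table of non-negative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("chi-square requires positive margins")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=correction)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}
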
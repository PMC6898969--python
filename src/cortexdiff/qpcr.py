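"""Delta-Ct qPCR quantification and Mann-Whitney group comparisons.

Relative expression of a target against a housekeeping reference (GAPDH in
the motivating experiments) is quantified on the cycle-threshold scale:

    dCt = Ct_target - Ct_reference,      rel_expr = 2 ** (-dCt),

assuming perfect doubling per cycle (efficiency fixed at 2).  Group fold
changes default to the delta-delta-Ct-of-means convention,

    FC(a, b) = 2 ** -(mean dCt_a - mean dCt_b),

i.e. the ratio of geometric means of relative expression; the ratio of
arithmetic means is available behind the ``convention`` flag.  Group
differences are tested with the two-sided Mann-Whitney U test (exact for
small tie-free samples, normal approximation with tie correction otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ValidationError

__all__ = [
    "QpcrGroupResult",
    "delta_ct",
    "group_fold_change",
    "mann_whitney",
    "compare_groups",
]

#: Largest combined sample size for which the exact Mann-Whitney null is used.
EXACT_MAX_N = 20


@dataclass
class QpcrGroupResult:
    """Fold change and Mann-Whitney comparison for one target and group pair."""

    target: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    fold_change: float
    u_statistic: float
    p: float


def delta_ct(ct_target, ct_reference):
    """(dCt, relative expression 2**-dCt); vectorises over array input."""
    dct = np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float)
    rel = np.power(2.0, -dct)
    if dct.ndim == 0:
        return float(dct), float(rel)
    return dct, rel


def _group_dct(table: pd.DataFrame, target: str, group: str) -> np.ndarray:
    mask = (table["target"] == target) & (table["group"] == group)
    sub = table.loc[mask]
    if sub.empty:
        raise ValidationError(f"no measurements for target {target!r} in group {group!r}")
    dct, _ = delta_ct(sub["ct_target"].to_numpy(), sub["ct_reference"].to_numpy())
    return np.atleast_1d(dct)


def group_fold_change(
    table: pd.DataFrame,
    target: str,
    group_a: str,
    group_b: str,
    convention: str = "ddct-of-means",
) -> float:
    """Linear fold change of group_a relative to group_b for one target.

    ``convention`` selects ``"ddct-of-means"`` (default; 2**-(difference of
    group mean delta-Ct)) or ``"mean-of-ratios"`` (ratio of arithmetic group
    means of 2**-dCt).
    """
    dct_a = _group_dct(table, target, group_a)
    dct_b = _group_dct(table, target, group_b)
    for group, dct in ((group_a, dct_a), (group_b, dct_b)):
        if dct.size < 2:
            raise ValidationError(
                f"group {group!r} has {dct.size} measurement(s) for "
                f"{target!r}; need at least 2"
            )
    if convention == "ddct-of-means":
        return float(2.0 ** -(dct_a.mean() - dct_b.mean()))
    if convention == "mean-of-ratios":
        return float(np.mean(2.0 ** -dct_a) / np.mean(2.0 ** -dct_b))
    raise ValueError(f"unknown convention {convention!r}")


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample size is at most 20 and
    the data are tie-free; otherwise the normal approximation with tie
    correction.  Returns (U statistic of the first sample, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        warnings.warn(
            "all values identical across both groups; p set to 1",
            UserWarning,
            stacklevel=2,
        )
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    exact = (a.size + b.size) <= EXACT_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    table: pd.DataFrame,
    target: str,
    group_a: str,
    group_b: str,
    convention: str = "ddct-of-means",
) -> QpcrGroupResult:
    """Fold change plus Mann-Whitney comparison of relative expression."""
    dct_a = _group_dct(table, target, group_a)
    dct_b = _group_dct(table, target, group_b)
    fc = group_fold_change(table, target, group_a, group_b, convention)
    u, p = mann_whitney(2.0 ** -dct_a, 2.0 ** -dct_b)
    return QpcrGroupResult(
        target=target, group_a=group_a, group_b=group_b,
        n_a=int(dct_a.size), n_b=int(dct_b.size),
        fold_change=fc, u_statistic=u, p=p,
    )
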
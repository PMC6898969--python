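"""Balanced-permutation false-discovery-rate assessment and stringency scan.

The procedure estimates, for a class comparison run at given (p, fold-change)
thresholds, how many significant genes a matched null analysis would produce:
the samples of the two compared groups are split into two pseudo-groups, each
containing exactly half of the case arrays and half of the control arrays, so
any real group difference cancels; the full pipeline (variance-model refit
included) is rerun on the pseudo-labels and the resulting "significant" genes
counted.  With n_perm such balanced splits (10 by default),

    FDR% = 100 * median(null counts) / experimental count.

The stringency scan evaluates a grid of thresholds (default {0.05, 0.01} x
{1.5, 2.0}), reusing the same splits across grid points so the scan varies
thresholds, not labelings — which also makes null counts monotone
non-increasing in stringency within each permutation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ComparisonSpec, ExpressionMatrix, SampleSheet, ValidationError
from .rvm import (
    RvmFit,
    fit_rvm,
    moderated_t_from_arrays,
    pooled_variances,
    signed_fold_change,
)

__all__ = [
    "StringencyCell",
    "balanced_null_partition",
    "distinct_balanced_splits",
    "permutation_fdr",
    "stringency_scan",
    "pooled_fdr_pct",
]

DEFAULT_GRID: list[tuple[float, float]] = [
    (0.05, 1.5), (0.05, 2.0), (0.01, 1.5), (0.01, 2.0),
]


@dataclass
class StringencyCell:
    """FDR assessment at one (p, fold-change) threshold pair."""

    p_thr: float
    fc_thr: float
    experimental_count: int
    null_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.experimental_count == 0 and self.null_counts:
            warnings.warn(
                "no experimental discoveries at "
                f"(p<{self.p_thr}, FC {self.fc_thr}); FDR% undefined",
                UserWarning,
                stacklevel=2,
            )

    @property
    def median_null(self) -> float:
        return float(np.median(self.null_counts))

    @property
    def fdr_pct(self) -> float:
        """100 * median null count / experimental count (NaN when undefined)."""
        if self.experimental_count == 0:
            return float("nan")
        return 100.0 * self.median_null / self.experimental_count


def balanced_null_partition(
    sheet: SampleSheet,
    spec: ComparisonSpec,
    seed: int | np.random.Generator = 0,
    parity: int | None = None,
) -> tuple[list[str], list[str]]:
    """Split the two compared groups into two balanced pseudo-groups.

    Each pseudo-group receives exactly half of group_a's samples and half of
    group_b's, chosen uniformly at random without replacement; the two
    pseudo-groups are disjoint and together cover all samples of both
    groups.  Groups of odd size raise an error unless ``parity`` is given,
    in which case the extra sample joins pseudo-group ``parity`` (callers
    alternate parity across permutations).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pseudo_1: list[str] = []
    pseudo_2: list[str] = []
    for group in (spec.group_a, spec.group_b):
        ids = sheet.samples_in_group(group)
        if len(ids) % 2 and parity is None:
            raise ValidationError(
                f"balanced split requires even group sizes; group {group!r} "
                f"has {len(ids)} samples"
            )
        half = len(ids) // 2 + (len(ids) % 2 if parity == 0 else 0)
        chosen = rng.choice(len(ids), size=half, replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        mask[chosen] = True
        pseudo_1 += [ids[i] for i in range(len(ids)) if mask[i]]
        pseudo_2 += [ids[i] for i in range(len(ids)) if not mask[i]]
    return pseudo_1, pseudo_2


def _n_admissible_splits(na: int, nb: int) -> int:
    return math.comb(na, na // 2) * math.comb(nb, nb // 2) // 2


def distinct_balanced_splits(
    sheet: SampleSheet,
    spec: ComparisonSpec,
    n_perm: int,
    rng: np.random.Generator,
) -> list[tuple[list[str], list[str]]]:
    """Draw n_perm distinct balanced splits (rejection on collision)."""
    na = len(sheet.samples_in_group(spec.group_a))
    nb = len(sheet.samples_in_group(spec.group_b))
    total = _n_admissible_splits(na, nb)
    if n_perm > total:
        raise ValidationError(
            f"requested {n_perm} distinct splits but only {total} exist for "
            f"group sizes {na}+{nb}"
        )
    splits: list[tuple[list[str], list[str]]] = []
    seen: set[frozenset[frozenset[str]]] = set()
    attempts = 0
    while len(splits) < n_perm:
        attempts += 1
        if attempts > 1000 * n_perm:
            raise RuntimeError("could not draw distinct balanced splits")
        p1, p2 = balanced_null_partition(sheet, spec, rng)
        key = frozenset({frozenset(p1), frozenset(p2)})
        if key in seen:
            continue
        seen.add(key)
        splits.append((p1, p2))
    return splits


def _count_calls(
    t_p: np.ndarray, fc: np.ndarray, p_thr: float, fc_thr: float
) -> int:
    return int(((t_p < p_thr) & (np.abs(fc) >= fc_thr)).sum())


def _split_stats(
    matrix: ExpressionMatrix,
    ids_a: list[str],
    ids_b: list[str],
    refit: bool,
    base_fit: RvmFit | None,
) -> tuple[np.ndarray, np.ndarray]:
    """p-values and signed fold changes for an arbitrary two-group labelling."""
    xa = matrix.values_for(ids_a)
    xb = matrix.values_for(ids_b)
    s2, d = pooled_variances(xa, xb)
    fit = fit_rvm(s2, d) if (refit or base_fit is None) else base_fit
    _, _, p = moderated_t_from_arrays(xa, xb, fit)
    fc = signed_fold_change(xa.mean(axis=1) - xb.mean(axis=1))
    return p, fc


def stringency_scan(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    spec: ComparisonSpec,
    grid: list[tuple[float, float]] | None = None,
    n_perm: int = 10,
    seed: int = 0,
    refit: bool = True,
) -> list[StringencyCell]:
    """FDR assessment over a (p, fold-change) threshold grid.

    All grid points share the same experimental statistics and the same
    n_perm balanced splits; only the thresholds vary.  With ``refit`` false
    the variance hyperparameters fitted on the true labels are frozen and
    reused inside every permutation.
    """
    grid = list(grid) if grid else list(DEFAULT_GRID)
    if not grid:
        raise ValidationError("threshold grid must be non-empty")
    rng = np.random.default_rng(seed)

    ids_a = sheet.samples_in_group(spec.group_a)
    ids_b = sheet.samples_in_group(spec.group_b)
    xa, xb = matrix.values_for(ids_a), matrix.values_for(ids_b)
    s2, d = pooled_variances(xa, xb)
    base_fit = fit_rvm(s2, d)
    _, _, exp_p = moderated_t_from_arrays(xa, xb, base_fit)
    exp_fc = signed_fold_change(xa.mean(axis=1) - xb.mean(axis=1))

    splits = distinct_balanced_splits(sheet, spec, n_perm, rng)
    null_stats = [
        _split_stats(matrix, p1, p2, refit, base_fit) for p1, p2 in splits
    ]

    cells = []
    for p_thr, fc_thr in grid:
        experimental = _count_calls(exp_p, exp_fc, p_thr, fc_thr)
        null_counts = [_count_calls(p, fc, p_thr, fc_thr) for p, fc in null_stats]
        cells.append(StringencyCell(
            p_thr=p_thr, fc_thr=fc_thr,
            experimental_count=experimental, null_counts=null_counts,
        ))
    return cells


def permutation_fdr(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    spec: ComparisonSpec,
    p_thr: float | None = None,
    fc_thr: float | None = None,
    n_perm: int = 10,
    seed: int = 0,
    refit: bool = True,
) -> StringencyCell:
    """FDR assessment at a single threshold pair (defaults from the spec)."""
    p_thr = spec.p_threshold if p_thr is None else p_thr
    fc_thr = spec.fc_threshold if fc_thr is None else fc_thr
    (cell,) = stringency_scan(
        matrix, sheet, spec, grid=[(p_thr, fc_thr)],
        n_perm=n_perm, seed=seed, refit=refit,
    )
    return cell


def pooled_fdr_pct(cells: list[StringencyCell]) -> float:
    """Overall FDR across comparisons: ratio of summed medians to summed
    experimental counts (x100)."""
    total_exp = sum(c.experimental_count for c in cells)
    if total_exp == 0:
        return float("nan")
    return 100.0 * sum(c.median_null for c in cells) / total_exp


def scan_table(cells: list[StringencyCell]) -> pd.DataFrame:
    """Tabulate cells with Experimental / FDR# / FDR% columns."""
    return pd.DataFrame(
        [
            {
                "p_thr": c.p_thr,
                "fc_thr": c.fc_thr,
                "experimental": c.experimental_count,
                "median_null": c.median_null,
                "fdr_pct": c.fdr_pct,
            }
            for c in cells
        ]
    )
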
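"""Gene-set testing: LS and KS statistics under a random-set null, the
Efron-Tibshirani maxmean statistic under a sample-permutation null, and the
2-of-3 consensus rule.

For a set of k member genes with per-gene two-sided p-values p_1..p_k:

    LS = (1/k) * sum(-ln p_i)            (large when members have small p)
    KS = max_i (i/k - p_(i))             (max positive deviation of the
                                          ordered p-values below uniform)

Both are referred to an empirical null built from random gene sets of the
same size drawn from all genes in the dataset, with the add-one rule
p = (1 + #{null >= observed}) / (n_null + 1) so empirical p-values are never
zero.

The maxmean statistic scores a set by the larger of the mean positive part
and the mean negative part of its members' moderated t scores; its null
permutes sample labels (uniformly over assignments preserving group sizes).
With restandardization (on by default) the positive- and negative-part set
means are centred and scaled by the corresponding moments of the per-gene
scores over all genes in that same permutation before taking the max, which
protects the test against genome-wide shifts in the score distribution.

A gene set is reported as a consensus hit when at least 2 of the 3 tests are
significant at alpha (strict inequality, default 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    ComparisonSpec,
    ExpressionMatrix,
    GeneSetCollection,
    SampleSheet,
    ValidationError,
)
from .rvm import RvmFit, fit_rvm, moderated_t_from_arrays, pooled_variances

__all__ = [
    "GeneSetResult",
    "ls_statistic",
    "ks_statistic",
    "random_set_pvalue",
    "maxmean_scores",
    "maxmean_test",
    "consensus_call",
    "analyze_gene_sets",
]


@dataclass
class GeneSetResult:
    """All three test results plus the consensus verdict for one set."""

    name: str
    k: int
    ls_stat: float
    ls_p: float
    ks_stat: float
    ks_p: float
    maxmean_stat: float
    maxmean_direction: str
    maxmean_p: float
    n_significant_tests: int
    consensus: bool
    skipped: bool = False


def _validated_p(p_values: np.ndarray) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValidationError("need a 1-D array of at least one p-value")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn(
            "p-values of exactly 0 floored at the machine minimum",
            UserWarning,
            stacklevel=3,
        )
        p = np.maximum(p, np.finfo(float).tiny)
    return p


def ls_statistic(p_values: np.ndarray) -> float:
    """Mean negative log p-value of the set members (natural log)."""
    p = _validated_p(p_values)
    return float(np.mean(-np.log(p)))


def ks_statistic(p_values: np.ndarray) -> float:
    """Maximal positive deviation of ordered member p-values below uniform."""
    p = np.sort(_validated_p(p_values))
    k = p.size
    i = np.arange(1, k + 1) / k
    return float(np.max(i - p))


def _batch_random_sets(
    rng: np.random.Generator, n_sets: int, k: int, population: int
) -> np.ndarray:
    """Index matrix (n_sets, k): rows are uniform draws without replacement."""
    # random-key trick when the key matrix is affordable, else per-row choice
    if n_sets * population <= 50_000_000:
        keys = rng.random((n_sets, population))
        return np.argpartition(keys, k - 1, axis=1)[:, :k]
    return np.stack(
        [rng.choice(population, size=k, replace=False) for _ in range(n_sets)]
    )


def random_set_pvalue(
    statistic_fn,
    member_p: np.ndarray,
    all_p: np.ndarray,
    n_null: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Empirical p-value of a set statistic against random same-size sets.

    Returns (observed statistic, empirical p) where the empirical p uses the
    add-one rule (1 + #{null >= observed}) / (n_null + 1).
    """
    if n_null < 100:
        raise ValidationError("n_null must be at least 100")
    all_p = np.asarray(all_p, dtype=float)
    member_p = np.asarray(member_p, dtype=float)
    k = member_p.size
    if k > all_p.size:
        raise ValidationError(
            f"set size {k} exceeds the gene population {all_p.size}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = statistic_fn(member_p)
    idx = _batch_random_sets(rng, n_null, k, all_p.size)
    null = _batch_statistics(statistic_fn, all_p, idx)
    p = (1.0 + int((null >= observed).sum())) / (n_null + 1.0)
    return float(observed), float(p)


def _batch_statistics(statistic_fn, all_p: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorised null statistics for the two built-in set statistics."""
    sub = _validated_p_matrix(all_p[idx])
    if statistic_fn is ls_statistic:
        return np.mean(-np.log(sub), axis=1)
    if statistic_fn is ks_statistic:
        k = sub.shape[1]
        ordered = np.sort(sub, axis=1)
        grid = np.arange(1, k + 1) / k
        return np.max(grid[None, :] - ordered, axis=1)
    return np.apply_along_axis(statistic_fn, 1, sub)


def _validated_p_matrix(p: np.ndarray) -> np.ndarray:
    return np.maximum(p, np.finfo(float).tiny)


def maxmean_scores(z: np.ndarray) -> tuple[float, float]:
    """(mean positive part, mean negative part) of member gene scores."""
    z = np.asarray(z, dtype=float)
    return float(np.mean(np.maximum(z, 0.0))), float(np.mean(np.maximum(-z, 0.0)))


def _standardized_maxmean(
    z_all: np.ndarray, member_idx: np.ndarray, restandardize: bool
) -> tuple[float, str]:
    pos = np.maximum(z_all, 0.0)
    neg = np.maximum(-z_all, 0.0)
    sp = float(pos[member_idx].mean())
    sn = float(neg[member_idx].mean())
    if restandardize:
        sp_std = (sp - pos.mean()) / max(pos.std(), np.finfo(float).tiny)
        sn_std = (sn - neg.mean()) / max(neg.std(), np.finfo(float).tiny)
    else:
        sp_std, sn_std = sp, sn
    if sp_std >= sn_std:
        return sp_std, "up"
    return sn_std, "down"


def _permutation_zscores(
    values: np.ndarray, n_a: int, fit: RvmFit, rng: np.random.Generator,
    n_perm: int,
) -> np.ndarray:
    """Per-gene moderated t scores for n_perm label permutations.

    ``values`` holds the pooled samples of both groups (genes x (n_a+n_b)).
    Group-size-preserving label permutations are drawn uniformly; the fitted
    variance hyperparameters are reused across permutations.
    """
    n = values.shape[1]
    out = np.empty((n_perm, values.shape[0]))
    for j in range(n_perm):
        order = rng.permutation(n)
        t, _, _ = moderated_t_from_arrays(
            values[:, order[:n_a]], values[:, order[n_a:]], fit
        )
        out[j] = t
    return out


def maxmean_test(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    spec: ComparisonSpec,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    restandardize: bool = True,
    fit: RvmFit | None = None,
) -> tuple[float, str, float]:
    """Maxmean set test with a sample-permutation null.

    Returns (observed maxmean statistic on the raw score scale, direction,
    empirical p).  The empirical p compares restandardized scores (see
    module docstring) with the add-one rule.
    """
    ids_a = sheet.samples_in_group(spec.group_a)
    ids_b = sheet.samples_in_group(spec.group_b)
    for group, ids in ((spec.group_a, ids_a), (spec.group_b, ids_b)):
        if len(ids) < 2:
            raise ValidationError(f"group {group!r} needs at least 2 samples")
    n_distinct = math.comb(len(ids_a) + len(ids_b), len(ids_a))
    if n_distinct < 20:
        raise ValidationError(
            f"permutation space too small: only {n_distinct} distinct "
            "label assignments"
        )
    member_idx = np.array([matrix.gene_ids.index(g) for g in gene_set])
    if member_idx.size < 1:
        raise ValidationError("gene set resolves to no matrix rows")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    xa = matrix.values_for(ids_a)
    xb = matrix.values_for(ids_b)
    if fit is None:
        s2, d = pooled_variances(xa, xb)
        fit = fit_rvm(s2, d)
    z_obs, _, _ = moderated_t_from_arrays(xa, xb, fit)

    sp, sn = maxmean_scores(z_obs[member_idx])
    raw_stat = max(sp, sn)
    obs_std, direction = _standardized_maxmean(z_obs, member_idx, restandardize)

    pooled = np.concatenate([xa, xb], axis=1)
    z_perm = _permutation_zscores(pooled, xa.shape[1], fit, rng, n_perm)
    null_std = np.array([
        _standardized_maxmean(z_perm[j], member_idx, restandardize)[0]
        for j in range(n_perm)
    ])
    p = (1.0 + int((null_std >= obs_std).sum())) / (n_perm + 1.0)
    return float(raw_stat), direction, float(p)


def consensus_call(
    ls_p: float, ks_p: float, maxmean_p: float, alpha: float = 0.05
) -> tuple[int, bool]:
    """Count tests significant at alpha (strict) and apply the 2-of-3 rule."""
    for p in (ls_p, ks_p, maxmean_p):
        if not 0.0 <= p <= 1.0:
            raise ValidationError("p-values must lie in [0, 1]")
    n_sig = sum(p < alpha for p in (ls_p, ks_p, maxmean_p))
    return n_sig, n_sig >= 2


def analyze_gene_sets(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    spec: ComparisonSpec,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    n_null: int = 10_000,
    n_perm: int = 1000,
    seed: int = 0,
    min_set_size: int = 3,
    restandardize: bool = True,
) -> pd.DataFrame:
    """Score every set in a collection with LS, KS, maxmean and consensus.

    Per-gene p-values and moderated t scores come from a single
    variance-model fit on the true labels; the maxmean permutations and the
    per-size random-set nulls are shared across sets.  Sets that resolve to
    fewer than ``min_set_size`` members are reported with ``skipped=True``.
    """
    rng = np.random.default_rng(seed)
    ids_a = sheet.samples_in_group(spec.group_a)
    ids_b = sheet.samples_in_group(spec.group_b)
    xa, xb = matrix.values_for(ids_a), matrix.values_for(ids_b)
    s2, d = pooled_variances(xa, xb)
    fit = fit_rvm(s2, d)
    z_obs, _, gene_p = moderated_t_from_arrays(xa, xb, fit)

    pooled = np.concatenate([xa, xb], axis=1)
    z_perm = _permutation_zscores(pooled, xa.shape[1], fit, rng, n_perm)
    # positive/negative parts and their genome-wide moments, shared by sets
    pos_perm = np.maximum(z_perm, 0.0)
    neg_perm = np.maximum(-z_perm, 0.0)
    tiny = np.finfo(float).tiny
    pos_mom = (pos_perm.mean(axis=1), np.maximum(pos_perm.std(axis=1), tiny))
    neg_mom = (neg_perm.mean(axis=1), np.maximum(neg_perm.std(axis=1), tiny))

    report = collection.resolve(matrix.gene_ids)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}

    # shared random-set null statistics per distinct set size
    null_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _nulls_for(k: int) -> tuple[np.ndarray, np.ndarray]:
        if k not in null_cache:
            idx = _batch_random_sets(rng, n_null, k, gene_p.size)
            null_cache[k] = (
                _batch_statistics(ls_statistic, gene_p, idx),
                _batch_statistics(ks_statistic, gene_p, idx),
            )
        return null_cache[k]

    rows = []
    for name in collection.names():
        members = report.resolved[name]
        k = len(members)
        if k < min_set_size:
            rows.append(GeneSetResult(
                name=name, k=k, ls_stat=float("nan"), ls_p=float("nan"),
                ks_stat=float("nan"), ks_p=float("nan"),
                maxmean_stat=float("nan"), maxmean_direction="",
                maxmean_p=float("nan"), n_significant_tests=0,
                consensus=False, skipped=True,
            ))
            continue
        member_idx = np.array([gene_pos[g] for g in members])
        member_p = gene_p[member_idx]
        ls_obs = ls_statistic(member_p)
        ks_obs = ks_statistic(member_p)
        ls_null, ks_null = _nulls_for(k)
        ls_p = (1.0 + int((ls_null >= ls_obs).sum())) / (n_null + 1.0)
        ks_p = (1.0 + int((ks_null >= ks_obs).sum())) / (n_null + 1.0)

        sp, sn = maxmean_scores(z_obs[member_idx])
        raw_stat = max(sp, sn)
        obs_std, direction = _standardized_maxmean(z_obs, member_idx, restandardize)
        sp_null = pos_perm[:, member_idx].mean(axis=1)
        sn_null = neg_perm[:, member_idx].mean(axis=1)
        if restandardize:
            sp_null = (sp_null - pos_mom[0]) / pos_mom[1]
            sn_null = (sn_null - neg_mom[0]) / neg_mom[1]
        null_std = np.maximum(sp_null, sn_null)
        mm_p = (1.0 + int((null_std >= obs_std).sum())) / (n_perm + 1.0)

        n_sig, consensus = consensus_call(ls_p, ks_p, mm_p, alpha)
        rows.append(GeneSetResult(
            name=name, k=k, ls_stat=ls_obs, ls_p=ls_p,
            ks_stat=ks_obs, ks_p=ks_p,
            maxmean_stat=raw_stat, maxmean_direction=direction,
            maxmean_p=mm_p, n_significant_tests=n_sig, consensus=consensus,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
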
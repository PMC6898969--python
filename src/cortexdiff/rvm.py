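"""Random-variance moderated t-tests and differential-expression calls.

The random variance model (RVM) shares variance information across genes in
small-sample microarray designs: gene-specific inverse variances are modelled
as Gamma(a, scale b), so across genes the pooled residual variance satisfies

    s_g^2 * a * b  ~  F(d, 2a),     d = n_a + n_b - 2.

Maximum likelihood over that F marginal yields the hyperparameters (a, b).
The moderated test then replaces each gene's pooled variance with the
posterior-mean compromise

    sigma~_g^2 = (d * s_g^2 + 2 a tau) / (d + 2 a),   tau = 1 / (a b),

and refers t = (mean_a - mean_b) / sqrt(sigma~_g^2 (1/n_a + 1/n_b)) to a
t distribution with d + 2a degrees of freedom.  The null calibration of that
reference distribution is verified by simulation in the test suite.

Fold change is computed as 2**(difference of group means of log2 values) and
reported with the sign convention -2**|log2fc| for down-regulated genes, so a
"fold change +/- 1.5" rule applies to its magnitude.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data import ComparisonSpec, ExpressionMatrix, SampleSheet, ValidationError

__all__ = [
    "RvmFit",
    "DegSet",
    "fit_rvm",
    "rvm_ttest",
    "moderated_t_from_arrays",
    "call_degs",
    "overlap_accounting",
]

#: Cap applied to the shape hyperparameter when the variance distribution is
#: degenerate (all variances equal, likelihood unbounded in a).
A_MAX = 1e6


@dataclass
class RvmFit:
    """Fitted variance-model hyperparameters for one comparison."""

    a: float
    b: float
    d: int
    log_likelihood: float
    converged: bool
    n_genes: int = 0
    variance_floor: float = 0.0

    @property
    def tau(self) -> float:
        """Shrinkage target: reciprocal of the prior mean precision."""
        return 1.0 / (self.a * self.b)

    @property
    def extra_df(self) -> float:
        """Degrees of freedom contributed by the prior (2a)."""
        return 2.0 * self.a


@dataclass
class DegSet:
    """Significant genes for one comparison, split by direction."""

    comparison: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValidationError("a gene cannot be both up- and down-regulated")

    @property
    def genes(self) -> set[str]:
        return set(self.up) | set(self.down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def _f_logpdf(x: np.ndarray, d1: float, d2: float) -> np.ndarray:
    """Log density of the F(d1, d2) distribution, vectorised."""
    h1, h2 = d1 / 2.0, d2 / 2.0
    return (
        h1 * np.log(d1 / d2)
        + (h1 - 1.0) * np.log(x)
        - (h1 + h2) * np.log1p(d1 * x / d2)
        - special.betaln(h1, h2)
    )


def _neg_loglik(theta: np.ndarray, v: np.ndarray, d: int) -> float:
    a, b = np.exp(theta)
    u = a * b * v
    ll = v.size * np.log(a * b) + _f_logpdf(u, d, 2.0 * a).sum()
    return -ll


def fit_rvm(
    variances: np.ndarray,
    d: int,
    floor_zeros: bool = True,
    cap_degenerate: bool = False,
) -> RvmFit:
    """Fit the variance-model hyperparameters (a, b) by maximum likelihood.

    Parameters
    ----------
    variances:
        Per-gene pooled residual variances (non-negative).
    d:
        Residual degrees of freedom of each variance (n_a + n_b - 2).
    floor_zeros:
        Replace exact zeros by the 1st percentile of the positive variances
        before fitting (keeps the log-likelihood finite).
    cap_degenerate:
        When all variances are identical the likelihood is unbounded in a;
        with this flag the fit returns a capped a = 1e6 and the matching b
        instead of raising.
    """
    v = np.asarray(variances, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("need a 1-D array of at least 2 variances")
    if d < 1:
        raise ValidationError("residual degrees of freedom d must be >= 1")
    if (v < 0).any() or not np.isfinite(v).all():
        raise ValidationError("variances must be finite and non-negative")
    if v.size < 50:
        warnings.warn(
            f"fitting variance hyperparameters on only {v.size} genes; "
            "estimates will be unstable",
            UserWarning,
            stacklevel=2,
        )

    floor = 0.0
    if (v == 0).any():
        positive = v[v > 0]
        if positive.size == 0:
            raise ValidationError("all variances are zero")
        if not floor_zeros:
            raise ValidationError("zero variances present and floor_zeros disabled")
        floor = float(np.percentile(positive, 1.0))
        v = np.where(v == 0, floor, v)

    if np.allclose(v, v[0], rtol=1e-12, atol=0.0):
        if not cap_degenerate:
            raise ValidationError(
                "degenerate variance distribution: all variances identical "
                "(shape parameter unbounded); enable cap_degenerate for a "
                "capped fit"
            )
        a = A_MAX
        b = 1.0 / (a * float(v[0]))
        return RvmFit(a=a, b=b, d=int(d), log_likelihood=np.inf,
                      converged=True, n_genes=v.size, variance_floor=floor)

    # moment-flavoured start: a=2 puts the prior mean variance at 1/b
    mean_v = float(np.mean(v))
    x0 = np.log([2.0, 1.0 / mean_v])
    res = optimize.minimize(
        _neg_loglik,
        x0,
        args=(v, int(d)),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10000, "maxfev": 10000},
    )
    a, b = np.exp(res.x)
    return RvmFit(
        a=float(a),
        b=float(b),
        d=int(d),
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
        n_genes=int(v.size),
        variance_floor=floor,
    )


def pooled_variances(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, int]:
    """Pooled two-group residual variances per gene and their df."""
    na, nb = xa.shape[1], xb.shape[1]
    d = na + nb - 2
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / d
    return s2, d


def moderated_t_from_arrays(
    xa: np.ndarray, xb: np.ndarray, fit: RvmFit
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t statistics, df and p-values for arrays (genes x samples)."""
    na, nb = xa.shape[1], xb.shape[1]
    s2, d = pooled_variances(xa, xb)
    shrunk = (d * s2 + 2.0 * fit.a * fit.tau) / (d + 2.0 * fit.a)
    se = np.sqrt(shrunk * (1.0 / na + 1.0 / nb))
    t = (xa.mean(axis=1) - xb.mean(axis=1)) / se
    df = d + 2.0 * fit.a
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.full_like(t, df), p


def _group_arrays(
    matrix: ExpressionMatrix, sheet: SampleSheet, spec: ComparisonSpec
) -> tuple[np.ndarray, np.ndarray]:
    out = []
    for group in (spec.group_a, spec.group_b):
        ids = sheet.samples_in_group(group)
        if len(ids) < 2:
            raise ValidationError(
                f"group {group!r} has {len(ids)} sample(s); need at least 2"
            )
        out.append(matrix.values_for(ids))
    return out[0], out[1]


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: 2**log2fc up, -2**|log2fc| down."""
    mag = np.power(2.0, np.abs(log2fc))
    return np.where(log2fc >= 0, mag, -mag)


def rvm_ttest(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    spec: ComparisonSpec,
    fit: RvmFit | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test for spec.group_a vs spec.group_b.

    Returns a DataFrame indexed by gene with columns mean_a, mean_b, log2fc,
    fc (signed), s2, shrunk_s2, t_mod, df_mod, p, direction and significant
    (at the spec's thresholds).  When ``fit`` is None the variance
    hyperparameters are fitted on this comparison's pooled variances.
    """
    xa, xb = _group_arrays(matrix, sheet, spec)
    s2, d = pooled_variances(xa, xb)
    if fit is None:
        fit = fit_rvm(s2, d)
    t, df, p = moderated_t_from_arrays(xa, xb, fit)
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    log2fc = mean_a - mean_b
    fc = signed_fold_change(log2fc)
    shrunk = (d * s2 + 2.0 * fit.a * fit.tau) / (d + 2.0 * fit.a)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "fc": fc,
            "s2": s2,
            "shrunk_s2": shrunk,
            "t_mod": t,
            "df_mod": df,
            "p": p,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    out["significant"] = significance_mask(out, spec)
    return out


def significance_mask(
    stats_df: pd.DataFrame,
    spec: ComparisonSpec,
    p_threshold: float | None = None,
    fc_threshold: float | None = None,
) -> pd.Series:
    """Boolean mask: p below threshold AND |fold change| at/above threshold."""
    p_thr = spec.p_threshold if p_threshold is None else p_threshold
    fc_thr = spec.fc_threshold if fc_threshold is None else fc_threshold
    return (stats_df["p"] < p_thr) & (stats_df["fc"].abs() >= fc_thr)


def call_degs(stats_df: pd.DataFrame, spec: ComparisonSpec) -> DegSet:
    """Threshold per-gene statistics into an up/down differential gene set."""
    mask = significance_mask(stats_df, spec)
    sig = stats_df.loc[mask]
    up = list(sig.index[sig["log2fc"] > 0])
    down = list(sig.index[sig["log2fc"] < 0])
    return DegSet(comparison=spec.label, up=up, down=down)


def overlap_accounting(deg_sets: list[DegSet]) -> pd.DataFrame:
    """Exclusive-subset counts across comparisons (Venn-style accounting).

    For every non-empty subset of the supplied comparisons, counts the genes
    significant in exactly that subset.  Counts over all subsets sum to the
    size of the union of the DEG sets.
    """
    if len(deg_sets) < 2:
        raise ValidationError("need at least 2 DEG sets for overlap accounting")
    labels = [ds.comparison for ds in deg_sets]
    if len(set(labels)) != len(labels):
        raise ValidationError("comparison labels must be unique")
    membership: dict[str, tuple[bool, ...]] = {}
    for gene in set().union(*(ds.genes for ds in deg_sets)):
        membership[gene] = tuple(gene in ds.genes for ds in deg_sets)
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(range(len(labels)), r):
            pattern = tuple(i in combo for i in range(len(labels)))
            count = sum(1 for pat in membership.values() if pat == pattern)
            row = {lab: pattern[i] for i, lab in enumerate(labels)}
            row["count"] = count
            rows.append(row)
    return pd.DataFrame(rows)
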
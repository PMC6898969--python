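"""Shared domain containers for the expression-analysis pipeline.

The substrate of every statistical stage is a log2-scale expression matrix
(genes x samples) together with a sample sheet that assigns each array to one
of five design groups: non-neurological controls (``CTRL``) and, for each MS
case group (follicle-positive / follicle-negative SPMS), one grey matter
lesion array and one normal-appearing grey matter array per donor
(``FPOS_GML``, ``FPOS_NAGM``, ``FNEG_GML``, ``FNEG_NAGM``).

Containers are thin, validated wrappers around :class:`pandas.DataFrame`;
validation happens at construction so downstream code can rely on the
invariants (unique identifiers, finite values, closed group vocabulary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed vocabulary of design groups.
GROUPS = ("CTRL", "FPOS_GML", "FPOS_NAGM", "FNEG_GML", "FNEG_NAGM")

#: The four MS conditions, each compared against CTRL.
CONDITIONS = ("FPOS_GML", "FPOS_NAGM", "FNEG_GML", "FNEG_NAGM")


class ValidationError(ValueError):
    """Raised when a container or input file violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes in rows, samples in columns.

    Parameters
    ----------
    data:
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  Values must be finite floats; identifiers must be unique.
        Row identifiers are treated as opaque (probe- or gene-level).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite value at gene "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values_for(self, sample_ids: list[str]) -> np.ndarray:
        """Array of shape (n_genes, len(sample_ids)) in matrix gene order."""
        return self.data.loc[:, list(sample_ids)].to_numpy()

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def check_log2_scale(self, threshold: float = 30.0, frac: float = 0.01) -> bool:
        """Warn when the value range suggests linear-scale (un-logged) input.

        Returns True when the matrix looks like log2 data.
        """
        share = float((self.data.to_numpy() > threshold).mean())
        if share > frac:
            warnings.warn(
                f"{share:.1%} of expression values exceed {threshold}; input may "
                "be on the linear scale rather than log2",
                UserWarning,
                stacklevel=2,
            )
            return False
        return True


@dataclass
class SampleSheet:
    """Array-to-group and array-to-case assignments.

    The table must carry columns ``sample_id``, ``group`` and ``case_id``;
    additional covariate columns (age, post-mortem delay, ...) are carried
    through untouched.  A case may contribute at most one array per group
    (one GML and one NAGM array per MS donor).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"sample_id", "group", "case_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(
                f"unknown group label(s) {bad}; allowed groups are {list(GROUPS)}"
            )
        per_group = df.groupby("group", sort=False)["case_id"]
        if (per_group.nunique() != per_group.size()).any():
            raise ValidationError("a case_id appears more than once within a group")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(
                f"unknown group label {group!r}; allowed groups are {list(GROUPS)}"
            )
        mask = self.table["group"] == group
        return list(self.table.loc[mask, "sample_id"])

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.table["group"] == g).sum()) for g in GROUPS}

    def check_against(self, matrix: ExpressionMatrix) -> None:
        """Require the sheet's sample ids to match the matrix columns exactly."""
        sheet_ids = set(self.sample_ids)
        matrix_ids = set(matrix.sample_ids)
        if sheet_ids != matrix_ids:
            only_sheet = sorted(sheet_ids - matrix_ids)
            only_matrix = sorted(matrix_ids - sheet_ids)
            raise ValidationError(
                "sample sheet and expression matrix disagree: "
                f"only in sheet {only_sheet}, only in matrix {only_matrix}"
            )


@dataclass
class ComparisonSpec:
    """One class comparison: group_a vs group_b with significance thresholds.

    ``fc_threshold`` is on the linear scale; a gene is called when its
    two-sided p-value is below ``p_threshold`` and its absolute fold change
    reaches ``fc_threshold``.
    """

    group_a: str
    group_b: str = "CTRL"
    p_threshold: float = 0.01
    fc_threshold: float = 1.5

    def __post_init__(self) -> None:
        for g in (self.group_a, self.group_b):
            if g not in GROUPS:
                raise ValidationError(
                    f"unknown group label {g!r}; allowed groups are {list(GROUPS)}"
                )
        if self.group_a == self.group_b:
            raise ValidationError("group_a and group_b must differ")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValidationError("p_threshold must lie in (0, 1)")
        if not self.fc_threshold > 1.0:
            raise ValidationError("fc_threshold must exceed 1 (linear scale)")

    @property
    def label(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"


@dataclass
class ResolutionReport:
    """Outcome of resolving gene-set members against a matrix's gene ids."""

    resolved: dict[str, list[str]]
    missing: dict[str, list[str]]

    def n_missing(self, name: str) -> int:
        return len(self.missing.get(name, []))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member lists."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} lists a member twice")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def resolve(self, gene_ids: list[str] | pd.Index) -> ResolutionReport:
        """Match members against available gene ids.

        Unresolvable members are counted and reported, never silently
        dropped from the report.
        """
        universe = set(gene_ids)
        resolved: dict[str, list[str]] = {}
        missing: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            resolved[name] = [m for m in members if m in universe]
            absent = [m for m in members if m not in universe]
            if absent:
                missing[name] = absent
        return ResolutionReport(resolved=resolved, missing=missing)
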
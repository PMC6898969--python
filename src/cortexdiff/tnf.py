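"""Pro-death vs pro-survival TNF pathway balance scoring.

TNF signalling bifurcates downstream of its receptors: TNFR1 can drive
caspase-dependent apoptosis and, via RIPK1/RIPK3/MLKL, caspase-independent
necroptosis (the "pro-death" arm), while TNFR1/TNFR2 signalling through the
IKK/NFkB axis promotes cell survival (the "pro-survival" arm).  This module
formalises that dichotomy: given per-gene differential-expression results for
one condition, it averages log2 fold changes over each panel and reports the
balance index

    balance = mean(log2fc, death panel) - mean(log2fc, survival panel),

calling the condition death-shifted when the index exceeds +delta,
survival-shifted below -delta, and balanced otherwise.  The index weights
genes equally and is an artifact construct for summarising a qualitative
contrast, not a pathway-topology model.

Panel membership defaults to the genes named in the verification
experiments, recorded under their informal symbols (TNFR1, HSP70, NFKB,
IKK-B, ...).  Because such symbols may not match a platform's row
identifiers, panels are resolved through a user-editable alias mapping
rather than hard-coded official identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, ValidationError
from .cluster import hierarchical_cluster

__all__ = [
    "DEFAULT_DEATH_PANEL",
    "DEFAULT_SURVIVAL_PANEL",
    "PanelDefinition",
    "BalanceReport",
    "read_alias_map",
    "read_panel_tsv",
    "compute_balance",
    "panel_heatmap_order",
]

#: Pro-death (apoptotic/necroptotic) panel: necroptosis kinases, RIPK1
#: de-ubiquitinases, NFkB inhibitors, executioner caspases and TNFR1.
DEFAULT_DEATH_PANEL: list[str] = [
    "RIPK1", "RIPK3", "MLKL", "RNF11", "CYLD", "LOX", "HSP70",
    "TNFAIP3", "CASP3", "CASP7", "TNFR1",
]

#: Pro-survival (NFkB-mediated) panel: death-domain adaptors, caspase-8 and
#: its inhibitor cFLIP, IKK/NFkB components, survival factors and TNFR2.
DEFAULT_SURVIVAL_PANEL: list[str] = [
    "TNFR2", "CASP8", "TRADD", "FADD", "CFLAR", "IKK-B", "NFKB",
    "RELA", "AKT", "XIAP",
]


@dataclass
class PanelDefinition:
    """Two disjoint, non-empty gene panels (death first by convention)."""

    death: list[str] = field(default_factory=lambda: list(DEFAULT_DEATH_PANEL))
    survival: list[str] = field(default_factory=lambda: list(DEFAULT_SURVIVAL_PANEL))

    def __post_init__(self) -> None:
        if not self.death or not self.survival:
            raise ValidationError("both panels must be non-empty")
        overlap = set(self.death) & set(self.survival)
        if overlap:
            raise ValidationError(f"panels must be disjoint; shared: {sorted(overlap)}")

    def swapped(self) -> "PanelDefinition":
        return PanelDefinition(death=list(self.survival), survival=list(self.death))


@dataclass
class BalanceReport:
    """Panel summaries and the balance verdict for one condition."""

    condition: str
    mean_log2fc_death: float
    mean_log2fc_survival: float
    balance_index: float
    verdict: str  # death-shifted | survival-shifted | balanced
    per_gene: pd.DataFrame
    unresolved: dict[str, list[str]]


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping informal panel symbols to matrix row ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("alias map needs two columns: alias, gene_id")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_panel_tsv(path: str | Path) -> PanelDefinition:
    """Two-column TSV (gene, panel) with panel labels 'death'/'survival'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "panel"} <= set(df.columns):
        raise ValidationError("panel file needs columns 'gene' and 'panel'")
    bad = sorted(set(df["panel"]) - {"death", "survival"})
    if bad:
        raise ValidationError(f"unknown panel label(s): {bad}")
    return PanelDefinition(
        death=list(df.loc[df["panel"] == "death", "gene"]),
        survival=list(df.loc[df["panel"] == "survival", "gene"]),
    )


def _resolve_panel(
    members: list[str], available: set[str], aliases: dict[str, str] | None
) -> tuple[list[str], list[str]]:
    aliases = aliases or {}
    resolved, missing = [], []
    for gene in members:
        candidate = gene if gene in available else aliases.get(gene)
        if candidate in available:
            resolved.append(candidate)
        else:
            missing.append(gene)
    return resolved, missing


def compute_balance(
    stats_df: pd.DataFrame,
    panels: PanelDefinition | None = None,
    condition: str = "",
    delta: float = 0.2,
    aliases: dict[str, str] | None = None,
) -> BalanceReport:
    """Score the pro-death vs pro-survival balance for one condition.

    ``stats_df`` is a per-gene result table (as produced by
    :func:`cortexdiff.rvm.rvm_ttest`) indexed by gene with at least columns
    ``log2fc`` and ``p``.
    """
    panels = panels if panels is not None else PanelDefinition()
    if delta < 0:
        raise ValidationError("delta must be non-negative")
    available = set(stats_df.index)
    unresolved: dict[str, list[str]] = {}
    rows = []
    means = {}
    for panel_name, members in (("death", panels.death), ("survival", panels.survival)):
        resolved, missing = _resolve_panel(members, available, aliases)
        if missing:
            unresolved[panel_name] = missing
        if not resolved:
            raise ValidationError(
                f"{panel_name} panel fully unresolved; missing ids: {missing}"
            )
        sub = stats_df.loc[resolved]
        means[panel_name] = float(sub["log2fc"].mean())
        for gene in resolved:
            rows.append({
                "gene": gene,
                "panel": panel_name,
                "log2fc": float(stats_df.at[gene, "log2fc"]),
                "p": float(stats_df.at[gene, "p"]),
            })
    index = means["death"] - means["survival"]
    if index > delta:
        verdict = "death-shifted"
    elif index < -delta:
        verdict = "survival-shifted"
    else:
        verdict = "balanced"
    return BalanceReport(
        condition=condition,
        mean_log2fc_death=means["death"],
        mean_log2fc_survival=means["survival"],
        balance_index=index,
        verdict=verdict,
        per_gene=pd.DataFrame(rows),
        unresolved=unresolved,
    )


def panel_heatmap_order(
    matrix: ExpressionMatrix,
    panels: PanelDefinition | None = None,
    aliases: dict[str, str] | None = None,
) -> list[str]:
    """Row order for a panel heatmap: death panel first, each panel ordered
    by the average-linkage uncentered-Pearson dendrogram's leaf order."""
    panels = panels if panels is not None else PanelDefinition()
    available = set(matrix.gene_ids)
    order: list[str] = []
    for members in (panels.death, panels.survival):
        resolved, missing = _resolve_panel(members, available, aliases)
        if missing:
            raise ValidationError(f"panel genes absent from matrix: {missing}")
        if len(resolved) == 1:
            order.extend(resolved)
            continue
        rows = matrix.data.loc[resolved].to_numpy()
        dend = hierarchical_cluster(rows, labels=resolved)
        order.extend(dend.ordered_labels)
    return order
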
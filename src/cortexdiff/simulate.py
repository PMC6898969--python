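"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study design the analysis targets: 10 control
arrays plus 10 follicle-positive and 10 follicle-negative SPMS cases, each
case contributing one grey-matter-lesion (GML) and one normal-appearing
grey-matter (NAGM) array — 50 arrays in total.  Expression for gene g in
sample s is

    x_gs = mu_g + effect(g, group(s)) + case_effect(g, case(s)) + noise,

with per-gene baselines mu_g ~ N(8, 1) on the log2 scale, gene-specific
noise variances drawn from the hierarchical variance model (inverse
variances Gamma(a_true, scale b_true)), and a per-(gene, case) random effect
that correlates a donor's GML and NAGM arrays.  The case effect's standard
deviation is expressed relative to the gene's noise SD, so the marginal
per-gene variance remains inverse-gamma across genes (scaled by a constant)
and the variance model the moderated test assumes stays exactly satisfied.

Planted differential expression is supplied as a (gene, condition, log2
effect) table; the default table plants the two TNF panels — a pro-death
panel up-regulated in the follicle-positive lesion condition and a
pro-survival panel up-regulated in the follicle-negative lesion condition,
with effect sizes matching the percentage changes the verification
experiments report — plus, optionally, randomly placed extra effects per
condition with |log2FC| drawn uniformly from a configurable range.

Every planted effect is mirrored in a :class:`SyntheticTruth` table so each
downstream stage can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    CONDITIONS,
    ExpressionMatrix,
    GeneSetCollection,
    SampleSheet,
    ValidationError,
)
from .tnf import DEFAULT_DEATH_PANEL, DEFAULT_SURVIVAL_PANEL

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "sample_gene_variances",
    "default_panel_effects",
    "random_extra_effects",
    "generate_dataset",
    "generate_qpcr_table",
]

#: Planted log2 effects for the pro-death panel in the follicle-positive GML
#: condition, derived from the reported percentage increases vs controls
#: (log2(1 + pct/100)); TNFR1 uses its reported 4.50-fold change.
DEATH_PANEL_FPOS_GML: dict[str, float] = {
    "TNFR1": math.log2(4.50),
    "RIPK1": math.log2(1.88),
    "RIPK3": math.log2(2.60),
    "MLKL": math.log2(2.35),
    "RNF11": math.log2(2.21),
    "CYLD": math.log2(2.26),
    "LOX": math.log2(1.57),
    "HSP70": math.log2(2.51),
    "TNFAIP3": math.log2(1.55),
    "CASP3": math.log2(1.60),
    "CASP7": math.log2(1.66),
}

#: Planted log2 effects for the pro-survival panel in the follicle-negative
#: GML condition (reported percentage increases; TNFR2 its 4.61-fold change).
SURVIVAL_PANEL_FNEG_GML: dict[str, float] = {
    "TNFR2": math.log2(4.61),
    "CASP8": math.log2(1.60),
    "TRADD": math.log2(2.73),
    "FADD": math.log2(1.96),
    "CFLAR": math.log2(2.30),
    "IKK-B": math.log2(1.98),
    "NFKB": math.log2(3.50),
    "RELA": math.log2(1.85),
    "AKT": math.log2(2.25),
    "XIAP": math.log2(1.47),
    "RIPK1": math.log2(1.70),
}

#: CASP8 is reported halved in the follicle-positive lesions.
EXTRA_FPOS_GML: dict[str, float] = {"CASP8": -1.0}

#: NAGM shares the GML direction at reduced amplitude (the verification
#: experiments pool GML and NAGM; the attenuation factor is a generator
#: choice, configurable).
NAGM_ATTENUATION = 0.5

#: Default per-group true expression ratios vs CTRL for the qPCR simulator
#: (TNFR1/TNFR2 printed fold changes).
DEFAULT_QPCR_TARGETS: dict[str, dict[str, float]] = {
    "TNFR1": {"FPOS_GML": 4.50, "FPOS_NAGM": 2.53, "FNEG_GML": 3.17, "FNEG_NAGM": 2.30},
    "TNFR2": {"FPOS_GML": 1.20, "FPOS_NAGM": 1.10, "FNEG_GML": 4.61, "FNEG_NAGM": 4.03},
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Counts mirror the target design (10 controls, 10 cases per MS group,
    each MS case contributing a GML and a NAGM array).  ``case_effect_sd``
    is relative to each gene's noise SD (see module docstring).
    """

    n_genes: int = 8000
    n_ctrl: int = 10
    n_fpos_cases: int = 10
    n_fneg_cases: int = 10
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    a_true: float = 3.0
    b_true: float = 1.0
    case_effect_sd: float = 0.2
    effects: pd.DataFrame | None = None  # columns gene, condition, log2fc
    n_extra_degs: int = 0  # extra random effects planted per condition
    extra_effect_range: tuple[float, float] = (0.58, 2.0)
    n_decoy_sets: int = 20
    decoy_set_size: int = 15
    qpcr_targets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_QPCR_TARGETS.items()}
    )
    qpcr_noise_sd: float = 0.3
    qpcr_ref_noise_sd: float = 0.05
    qpcr_target_baseline_ct: float = 26.0
    qpcr_reference_baseline_ct: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_ctrl", "n_fpos_cases", "n_fneg_cases"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2")
        if self.a_true <= 1.0:
            raise ValidationError("a_true must exceed 1 (finite prior mean variance)")
        if self.b_true <= 0.0:
            raise ValidationError("b_true must be positive")
        if self.case_effect_sd < 0.0:
            raise ValidationError("case_effect_sd must be non-negative")
        if self.effects is not None:
            if not np.isfinite(self.effects["log2fc"].to_numpy(dtype=float)).all():
                raise ValidationError("planted effect sizes must be finite")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator.

    ``effects`` lists every planted (gene, condition, log2fc) triple;
    ``set_enrichment`` flags, per gene set and condition, whether at least
    half of the set's members carry a planted effect in that condition.
    """

    effects: pd.DataFrame
    set_enrichment: pd.DataFrame

    def effect_lookup(self) -> dict[tuple[str, str], float]:
        return {
            (r.gene, r.condition): float(r.log2fc)
            for r in self.effects.itertuples(index=False)
        }

    def genes_with_effect(self, condition: str) -> set[str]:
        mask = self.effects["condition"] == condition
        return set(self.effects.loc[mask, "gene"])


def sample_gene_variances(
    n_genes: int,
    a_true: float,
    b_true: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw gene noise variances from the hierarchical variance model.

    Inverse variances are Gamma(a_true, scale b_true); the returned variances
    are their reciprocals (inverse-gamma distributed, all strictly positive).
    """
    if a_true <= 0 or b_true <= 0:
        raise ValidationError("variance hyperparameters must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    precisions = rng.gamma(shape=a_true, scale=b_true, size=int(n_genes))
    return 1.0 / precisions


def default_panel_effects(nagm_attenuation: float = NAGM_ATTENUATION) -> pd.DataFrame:
    """Planted TNF panel effects: death panel up in FPOS, survival in FNEG.

    NAGM conditions receive the GML effect scaled by ``nagm_attenuation``.
    """
    rows: list[tuple[str, str, float]] = []
    for gene, eff in DEATH_PANEL_FPOS_GML.items():
        rows.append((gene, "FPOS_GML", eff))
        rows.append((gene, "FPOS_NAGM", eff * nagm_attenuation))
    for gene, eff in SURVIVAL_PANEL_FNEG_GML.items():
        rows.append((gene, "FNEG_GML", eff))
        rows.append((gene, "FNEG_NAGM", eff * nagm_attenuation))
    for gene, eff in EXTRA_FPOS_GML.items():
        rows.append((gene, "FPOS_GML", eff))
        rows.append((gene, "FPOS_NAGM", eff * nagm_attenuation))
    return pd.DataFrame(rows, columns=["gene", "condition", "log2fc"])


def random_extra_effects(
    gene_pool: list[str],
    n_per_condition: int,
    effect_range: tuple[float, float],
    rng: np.random.Generator,
    conditions: tuple[str, ...] = CONDITIONS,
) -> pd.DataFrame:
    """Plant n random effects per condition with |log2FC| uniform in a range."""
    lo, hi = effect_range
    rows: list[tuple[str, str, float]] = []
    for condition in conditions:
        genes = rng.choice(gene_pool, size=n_per_condition, replace=False)
        magnitudes = rng.uniform(lo, hi, size=n_per_condition)
        signs = rng.choice([-1.0, 1.0], size=n_per_condition)
        rows += [
            (g, condition, float(m * s))
            for g, m, s in zip(genes, magnitudes, signs)
        ]
    return pd.DataFrame(rows, columns=["gene", "condition", "log2fc"])


def _gene_ids(config: SimulationConfig) -> list[str]:
    panel = list(dict.fromkeys(DEFAULT_DEATH_PANEL + DEFAULT_SURVIVAL_PANEL))
    if config.n_genes < len(panel) + 10:
        raise ValidationError(
            f"n_genes must be at least {len(panel) + 10} to host the TNF panels"
        )
    filler = [f"G{i:05d}" for i in range(config.n_genes - len(panel))]
    return panel + filler


def _design_sheet(config: SimulationConfig) -> SampleSheet:
    rows: list[dict[str, str]] = []
    for i in range(config.n_ctrl):
        rows.append({"sample_id": f"CTRL_{i + 1:02d}", "group": "CTRL",
                     "case_id": f"C{i + 1:02d}"})
    for prefix, n, tag in (("FPOS", config.n_fpos_cases, "P"),
                           ("FNEG", config.n_fneg_cases, "N")):
        for i in range(n):
            case = f"{tag}{i + 1:02d}"
            for tissue in ("GML", "NAGM"):
                rows.append({
                    "sample_id": f"{prefix}_{tissue}_{case}",
                    "group": f"{prefix}_{tissue}",
                    "case_id": case,
                })
    return SampleSheet(pd.DataFrame(rows))


def _resolve_effects(
    config: SimulationConfig, gene_ids: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    if config.effects is not None:
        effects = config.effects.copy()
    else:
        effects = default_panel_effects()
        if config.n_extra_degs > 0:
            planted = set(effects["gene"])
            pool = [g for g in gene_ids if g not in planted]
            effects = pd.concat(
                [effects, random_extra_effects(pool, config.n_extra_degs,
                                               config.extra_effect_range, rng)],
                ignore_index=True,
            )
    unknown_genes = sorted(set(effects["gene"]) - set(gene_ids))
    if unknown_genes:
        raise ValidationError(f"effect table references unknown genes: {unknown_genes}")
    unknown_cond = sorted(set(effects["condition"]) - set(CONDITIONS))
    if unknown_cond:
        raise ValidationError(
            f"effect table references unknown conditions: {unknown_cond}"
        )
    if effects.duplicated(["gene", "condition"]).any():
        raise ValidationError("effect table repeats a (gene, condition) pair")
    return effects.reset_index(drop=True)


def _gene_sets(
    config: SimulationConfig,
    gene_ids: list[str],
    effects: pd.DataFrame,
    rng: np.random.Generator,
) -> GeneSetCollection:
    sets = {
        "TNF_PRO_DEATH": list(DEFAULT_DEATH_PANEL),
        "TNF_PRO_SURVIVAL": list(DEFAULT_SURVIVAL_PANEL),
    }
    descriptions = {
        "TNF_PRO_DEATH": "TNFR1-driven apoptotic/necroptotic signalling panel",
        "TNF_PRO_SURVIVAL": "TNFR1/TNFR2 NFkB-mediated survival signalling panel",
    }
    planted = set(effects["gene"])
    pool = np.array([g for g in gene_ids if g not in planted])
    for i in range(config.n_decoy_sets):
        name = f"DECOY_{i + 1:03d}"
        members = rng.choice(pool, size=config.decoy_set_size, replace=False)
        sets[name] = [str(m) for m in members]
        descriptions[name] = "decoy set drawn uniformly from non-planted genes"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def _set_enrichment(
    collection: GeneSetCollection, effects: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    for condition in CONDITIONS:
        hit = set(effects.loc[effects["condition"] == condition, "gene"])
        for name, members in collection.sets.items():
            frac = sum(m in hit for m in members) / len(members)
            rows.append({"set": name, "condition": condition,
                         "enriched": frac >= 0.5})
    return pd.DataFrame(rows)


def generate_dataset(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, SampleSheet, GeneSetCollection, SyntheticTruth]:
    """Generate a full synthetic dataset plus its ground truth.

    Returns (matrix, sheet, gene sets, truth).  Identical config and seed
    give byte-identical outputs.  ``seed`` overrides ``config.seed``.
    """
    config = config if config is not None else SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    gene_ids = _gene_ids(config)
    sheet = _design_sheet(config)
    effects = _resolve_effects(config, gene_ids, rng)

    n_genes = config.n_genes
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    variances = sample_gene_variances(n_genes, config.a_true, config.b_true, rng)
    noise_sd = np.sqrt(variances)

    cases = list(dict.fromkeys(sheet.table["case_id"]))
    case_index = {c: i for i, c in enumerate(cases)}
    # per-(gene, case) random effect, scaled by the gene's noise SD
    case_effects = rng.normal(0.0, 1.0, size=(n_genes, len(cases)))
    case_effects *= config.case_effect_sd * noise_sd[:, None]

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    effect_matrix = np.zeros((n_genes, len(CONDITIONS)))
    cond_index = {c: i for i, c in enumerate(CONDITIONS)}
    for row in effects.itertuples(index=False):
        effect_matrix[gene_index[row.gene], cond_index[row.condition]] = row.log2fc

    columns = {}
    for rec in sheet.table.itertuples(index=False):
        x = baselines.copy()
        if rec.group != "CTRL":
            x = x + effect_matrix[:, cond_index[rec.group]]
        x = x + case_effects[:, case_index[rec.case_id]]
        x = x + rng.normal(0.0, noise_sd)
        columns[rec.sample_id] = x
    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    )

    collection = _gene_sets(config, gene_ids, effects, rng)
    truth = SyntheticTruth(
        effects=effects, set_enrichment=_set_enrichment(collection, effects)
    )
    return matrix, sheet, collection, truth


def generate_qpcr_table(
    config: SimulationConfig | None = None,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for the configured targets.

    For each sample and target, Ct_target = baseline - log2(relative
    expression of the sample's group) + noise, against a near-constant
    GAPDH-like reference.  The planted group ratios are recoverable from the
    group mean delta-Ct differences.  ``truth`` is accepted for signature
    symmetry with the expression generator; target ratios come from the
    config.
    """
    config = config if config is not None else SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    for target, ratios in config.qpcr_targets.items():
        for group, ratio in ratios.items():
            if ratio <= 0:
                raise ValidationError(
                    f"qPCR target {target!r}: ratio for {group!r} must be positive"
                )
    sheet = _design_sheet(config)
    rows = []
    for target, ratios in config.qpcr_targets.items():
        for rec in sheet.table.itertuples(index=False):
            ratio = 1.0 if rec.group == "CTRL" else float(ratios.get(rec.group, 1.0))
            ct_t = (
                config.qpcr_target_baseline_ct
                - math.log2(ratio)
                + rng.normal(0.0, config.qpcr_noise_sd)
            )
            ct_r = config.qpcr_reference_baseline_ct + rng.normal(
                0.0, config.qpcr_ref_noise_sd
            )
            rows.append({
                "sample_id": rec.sample_id,
                "group": rec.group,
                "target": target,
                "ct_target": ct_t,
                "ct_reference": ct_r,
            })
    return pd.DataFrame(rows)
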
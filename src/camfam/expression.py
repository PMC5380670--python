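"""Organ-specificity calls over an expression atlas and 2^-ddCt qPCR analysis.

Atlas side: a genes x conditions matrix of non-negative expression values
(EST-atlas style, already normalized upstream). A gene is called specific
to an organ when that organ carries its maximum value over a chosen organ
subset; ties break by column order.

qPCR side: relative quantification by the ddCt method. Technical
replicates are averaged per biological replicate; the target Ct is
normalized by the reference gene within each biological replicate
(dCt = Ct_target - Ct_reference); treatment effect is
ddCt = mean dCt(treated) - mean dCt(control); fold change = 2^-ddCt.
Significance (optional) is a two-sided Welch t-test on the per-replicate
dCt sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionAtlas",
    "QPCRExperiment",
    "FoldChangeResult",
    "max_condition",
    "organ_specific_genes",
    "delta_delta_ct",
]


@dataclass
class ExpressionAtlas:
    """Complete genes x conditions matrix of non-negative values."""

    values: pd.DataFrame  # index = gene ids, columns = condition labels

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("atlas contains missing cells")
        if (self.values < 0).any().any():
            raise ValueError("atlas contains negative values")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("atlas gene ids and condition labels must be unique")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionAtlas":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


def max_condition(
    atlas: ExpressionAtlas, gene: str, condition_subset: Sequence[str]
) -> str:
    """Condition with the maximum value for ``gene`` within the subset.

    Ties break by subset order.
    """
    if gene not in atlas.values.index:
        raise KeyError(f"unknown gene {gene!r}")
    if not condition_subset:
        raise ValueError("condition subset must be non-empty")
    unknown = [c for c in condition_subset if c not in atlas.values.columns]
    if unknown:
        raise KeyError(f"unknown conditions {unknown}")
    row = atlas.values.loc[gene, list(condition_subset)]
    best = condition_subset[0]
    for cond in condition_subset:
        if row[cond] > row[best]:
            best = cond
    return best


def organ_specific_genes(
    atlas: ExpressionAtlas, organ: str, organ_set: Sequence[str]
) -> list[str]:
    """Genes whose maximum over ``organ_set`` falls in ``organ``, atlas order."""
    if organ not in organ_set:
        raise ValueError(f"organ {organ!r} not in the organ set")
    return [
        g for g in atlas.genes if max_condition(atlas, g, organ_set) == organ
    ]


@dataclass
class QPCRExperiment:
    """Replicate-level Ct values for one target gene and one reference gene.

    ``ct`` columns: gene, condition, bio_rep, tech_rep, ct — with gene one
    of {target, reference} roles resolved via ``target_gene_id`` /
    ``reference_gene_id`` and condition in {control, treated}.
    """

    ct: pd.DataFrame
    target_gene_id: str = "target"
    reference_gene_id: str = "reference"
    control_label: str = "control"
    treated_label: str = "treated"

    REQUIRED = ("gene", "condition", "bio_rep", "tech_rep", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.ct.columns]
        if missing:
            raise ValueError(f"Ct table missing columns {missing}")
        if (self.ct["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")

    @classmethod
    def from_tsv(
        cls, path: str | Path, target: str, reference: str, **kw
    ) -> "QPCRExperiment":
        return cls(
            pd.read_csv(path, sep="\t"),
            target_gene_id=target,
            reference_gene_id=reference,
            **kw,
        )


@dataclass(frozen=True)
class FoldChangeResult:
    """2^-ddCt fold change with its intermediate quantities."""

    fold_change: float
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    p_value: float | None = None
    per_rep_delta_ct: dict = field(default_factory=dict, compare=False)


def _bio_rep_delta_ct(exp: QPCRExperiment, condition: str) -> pd.Series:
    """dCt per biological replicate: target minus reference, techs averaged."""
    sub = exp.ct[exp.ct["condition"] == condition]
    means = sub.groupby(["gene", "bio_rep"])["ct"].mean()
    missing = [
        g for g in (exp.target_gene_id, exp.reference_gene_id)
        if g not in means.index.get_level_values("gene")
    ]
    if missing:
        raise ValueError(f"condition {condition!r}: no Ct values for {missing}")
    target = means[exp.target_gene_id]
    reference = means[exp.reference_gene_id]
    if set(target.index) != set(reference.index):
        raise ValueError(
            f"condition {condition!r}: target and reference biological "
            "replicates do not match"
        )
    return target - reference


def delta_delta_ct(exp: QPCRExperiment, significance: bool = True) -> FoldChangeResult:
    """Relative expression of the target in treated vs control, 2^-ddCt.

    With fewer than two biological replicates in either condition the
    p-value is omitted with a warning.
    """
    dct_control = _bio_rep_delta_ct(exp, exp.control_label)
    dct_treated = _bio_rep_delta_ct(exp, exp.treated_label)
    ddct = float(dct_treated.mean() - dct_control.mean())
    p_value: float | None = None
    if significance:
        if len(dct_control) < 2 or len(dct_treated) < 2:
            warnings.warn(
                "fewer than 2 biological replicates; p-value omitted",
                stacklevel=2,
            )
        else:
            p_value = float(
                stats.ttest_ind(dct_treated, dct_control, equal_var=False).pvalue
            )
    return FoldChangeResult(
        fold_change=math.exp2(-ddct),
        delta_ct_treated=float(dct_treated.mean()),
        delta_ct_control=float(dct_control.mean()),
        delta_delta_ct=ddct,
        p_value=p_value,
        per_rep_delta_ct={
            "control": dct_control.to_dict(),
            "treated": dct_treated.to_dict(),
        },
    )
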
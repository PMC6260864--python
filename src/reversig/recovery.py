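"""Parameter-recovery scoring of the pipeline against planted truth.

The simulator plants a category per gene; the pipeline calls a category per
signature gene. This module crosses the two into a confusion matrix and
derives per-category recall/precision, signature-level sensitivity and
specificity, and the empirical false discovery rate of the signature. It
also provides a null-calibration harness: repeated all-null simulations
summarising raw p-value behaviour and spurious signature membership.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classify import REVERSAL_ORDER
from .datatypes import ValidationError
from .pipeline import run_reversal_pipeline
from .simulate import SimulationConfig, generate_factorial_counts

#: planted categories collapsed over direction
PLANTED_ORDER = ("reversed", "partially_reversed", "exacerbated", "unaffected", "null")
CALLED_ORDER = REVERSAL_ORDER + ("not_in_signature",)

_COLLAPSE = {
    "null": "null",
    "up_reversed": "reversed", "down_reversed": "reversed",
    "up_partial": "partially_reversed", "down_partial": "partially_reversed",
    "up_exacerbated": "exacerbated", "down_exacerbated": "exacerbated",
    "up_unaffected": "unaffected", "down_unaffected": "unaffected",
}


@dataclass
class RecoveryReport:
    """Scorecard of one pipeline run against planted truth."""

    confusion: pd.DataFrame          # planted (rows) x called (columns)
    recall: pd.Series                # per planted non-null category
    precision: pd.Series             # per called category
    signature_sensitivity: float     # planted non-null genes recovered into the signature
    signature_specificity: float     # planted null genes kept out of the signature
    signature_fdr: float             # planted-null members / signature size
    signature_size: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": f"recall_{c}", "value": self.recall[c]} for c in self.recall.index
        ] + [
            {"metric": f"precision_{c}", "value": self.precision[c]}
            for c in self.precision.index
        ] + [
            {"metric": "signature_sensitivity", "value": self.signature_sensitivity},
            {"metric": "signature_specificity", "value": self.signature_specificity},
            {"metric": "signature_fdr", "value": self.signature_fdr},
            {"metric": "signature_size", "value": float(self.signature_size)},
        ]
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = ["Recovery report", "===============", "", "Confusion (planted x called):",
                 self.confusion.to_string(), ""]
        for _, row in self.to_frame().iterrows():
            lines.append(f"{row['metric']}: {row['value']:.4f}")
        return "\n".join(lines) + "\n"


def evaluate_recovery(
    truth: pd.DataFrame,
    classification: pd.DataFrame,
    signature: pd.DataFrame,
) -> RecoveryReport:
    """Score a reversal classification against the simulator's planted truth.

    ``truth`` and the pipeline outputs must share a gene universe. Genes
    planted non-null but absent from the signature are counted against
    recall under ``not_in_signature``; genes planted null but present in
    the signature are the signature's false discoveries.
    """
    if not signature.index.isin(truth.index).all() or not classification.index.isin(truth.index).all():
        raise ValidationError("classification covers genes absent from the truth table")
    planted = truth["category"].map(_COLLAPSE)
    if planted.isna().any():
        raise ValidationError("truth table contains unknown categories")

    called = pd.Series("not_in_signature", index=truth.index, dtype=object)
    called.loc[classification.index] = classification["category"]

    confusion = pd.DataFrame(0, index=list(PLANTED_ORDER), columns=list(CALLED_ORDER))
    for p_cat, c_cat in zip(planted, called):
        confusion.loc[p_cat, c_cat] += 1

    recall = pd.Series(
        {
            cat: (confusion.loc[cat, cat] / planted.eq(cat).sum()) if planted.eq(cat).any() else np.nan
            for cat in REVERSAL_ORDER
        },
        name="recall",
    )
    precision = pd.Series(
        {
            cat: (confusion.loc[cat, cat] / confusion[cat].sum()) if confusion[cat].sum() else np.nan
            for cat in REVERSAL_ORDER
        },
        name="precision",
    )
    nonnull = planted != "null"
    in_signature = truth.index.isin(signature.index)
    sensitivity = float(in_signature[nonnull].mean()) if nonnull.any() else np.nan
    specificity = float((~in_signature[~nonnull]).mean()) if (~nonnull).any() else np.nan
    false_members = int((in_signature & ~nonnull).sum())
    fdr = false_members / max(1, len(signature))
    return RecoveryReport(
        confusion=confusion,
        recall=recall,
        precision=precision,
        signature_sensitivity=sensitivity,
        signature_specificity=specificity,
        signature_fdr=float(fdr),
        signature_size=len(signature),
    )


def null_calibration(
    n_reps: int,
    config: SimulationConfig,
    alpha: float = 0.05,
    alpha_adj: float = 0.05,
    fc_threshold: float = 1.5,
    base_mean_min: float = 10.0,
) -> pd.DataFrame:
    """Repeated all-null simulations: raw p behaviour and spurious signature size.

    Every planted category must be null. Replicate ``r`` runs the full
    pipeline on a simulation seeded ``config.seed + r`` and records, per
    contrast, the fraction of tested genes with raw ``p < alpha`` plus the
    signature size. Returns one row per (replicate, contrast); empty for
    ``n_reps = 0``.
    """
    cats = config.resolved_categories(("null",))
    if set(cats) - {"null"}:
        raise ValidationError("null calibration requires all-null categories")
    rows = []
    for rep in range(n_reps):
        rep_config = replace(config, seed=config.seed + rep)
        counts, design, _ = generate_factorial_counts(rep_config)
        result = run_reversal_pipeline(
            counts, design, alpha_adj=alpha_adj, alpha=alpha,
            fc_threshold=fc_threshold, base_mean_min=base_mean_min,
        )
        for name, contrast in result.contrasts.items():
            p = contrast.loc[contrast["tested"], "pvalue"]
            rows.append(
                {
                    "replicate": rep,
                    "seed": rep_config.seed,
                    "contrast": name,
                    "n_tested": len(p),
                    "fraction_p_below_alpha": float((p < alpha).mean()),
                    "signature_size": len(result.signature),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["replicate", "seed", "contrast", "n_tested",
                 "fraction_p_below_alpha", "signature_size"],
    )


def reference_scenario(seed: int = 0, n_genes: int = 10_000) -> SimulationConfig:
    """The benchmark recovery scenario: ~500 signature genes planted in the
    127:53:19:307 reversed/partial/exacerbated/unaffected proportions
    (split into 455 up / 56 down as in the aged-microglia signature) among
    otherwise null genes, age effects of 1.5-2.5 log2 units, six samples
    per group, dispersion 0.05."""
    planted = {
        "up_reversed": 117, "down_reversed": 10,
        "up_partial": 53, "down_partial": 5,
        "up_exacerbated": 14, "down_exacerbated": 5,
        "up_unaffected": 271, "down_unaffected": 36,
    }
    n_planted = sum(planted.values())
    return SimulationConfig(
        n_genes=n_genes,
        n_per_group=6,
        dispersion=0.05,
        age_lfc_magnitude=(1.5, 2.5),
        category_counts={"null": n_genes - n_planted, **planted},
        seed=seed,
    )
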
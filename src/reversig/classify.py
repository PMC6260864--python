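"""Signature definition and multi-contrast classification taxonomies.

Two decision procedures operating on contrast result tables:

* the age signature (aged-control vs adult-control, adjusted P and fold
  change gates) and its four-way reversal taxonomy after forced microglial
  turnover — reversed, partially reversed, exacerbated, unaffected;
* the LPS-response taxonomy — exacerbated by age, unique to aged,
  adult-only, nonresponsive — with a flag for aged responses prevented in
  repopulated animals.

Classification contrasts are gated on nominal (unadjusted) p-values; only
the signature definition uses BH-adjusted p-values. All p-value gates use
strict ``<``: a p-value of exactly 0.05 fails ``P < 0.05`` and satisfies
``P >= 0.05``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ValidationError

logger = logging.getLogger(__name__)

REVERSAL_ORDER = ("reversed", "partially_reversed", "exacerbated", "unaffected")
LPS_ORDER = ("exacerbated_by_age", "unique_to_aged", "adult_only", "nonresponsive")


def define_age_signature(
    age_contrast: pd.DataFrame,
    alpha_adj: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Genes differentially expressed by age.

    Membership requires ``padj < alpha_adj`` and ``|log2fc| > log2(fc_threshold)``
    (both strict); untested genes never enter. Returns a DataFrame indexed
    by gene with columns ``direction`` (increased/decreased), ``log2fc``,
    ``pvalue`` and ``padj``, in the input gene order.
    """
    if not 0 < alpha_adj < 1:
        raise ValidationError("alpha_adj must lie in (0, 1)")
    if fc_threshold <= 1:
        raise ValidationError("fc_threshold must exceed 1")
    tested = age_contrast["tested"].fillna(False).astype(bool)
    member = (
        tested
        & (age_contrast["padj"] < alpha_adj)
        & (age_contrast["log2fc"].abs() > np.log2(fc_threshold))
    )
    sig = age_contrast.loc[member, ["log2fc", "pvalue", "padj"]].copy()
    sig["direction"] = np.where(sig["log2fc"] > 0, "increased", "decreased")
    return sig[["direction", "log2fc", "pvalue", "padj"]]


def classify_reversal(
    signature: pd.DataFrame,
    repop_vs_aged: pd.DataFrame,
    repop_vs_adult: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Four-way reversal taxonomy over the age-signature genes.

    Per gene, in order: no significant repopulation effect (repop-vs-aged
    ``P >= alpha``, or untested) -> ``unaffected``; a significant change in
    the same direction as the age effect (conserved directionality) ->
    ``exacerbated``; otherwise the gene moved toward adult levels and is
    ``reversed`` when repop-vs-adult ``P >= alpha`` (no longer different
    from adult controls) or ``partially_reversed`` when still different.

    A degenerate significant change with log2fc exactly 0 carries no
    direction and is classed ``unaffected``. Signature genes missing from a
    classification contrast are classed ``unaffected`` and logged.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    categories = []
    for gene, row in signature.iterrows():
        age_sign = 1.0 if row["direction"] == "increased" else -1.0
        cat = _classify_one(gene, age_sign, repop_vs_aged, repop_vs_adult, alpha)
        categories.append(cat)
    out = signature.copy()
    out = out.rename(columns={"log2fc": "age_log2fc", "pvalue": "age_pvalue", "padj": "age_padj"})
    out["category"] = categories
    out["repop_vs_aged_log2fc"] = repop_vs_aged["log2fc"].reindex(out.index)
    out["repop_vs_aged_pvalue"] = repop_vs_aged["pvalue"].reindex(out.index)
    out["repop_vs_adult_pvalue"] = repop_vs_adult["pvalue"].reindex(out.index)
    cols = ["direction", "category", "age_log2fc", "age_pvalue", "age_padj",
            "repop_vs_aged_log2fc", "repop_vs_aged_pvalue", "repop_vs_adult_pvalue"]
    return out[cols]


def _classify_one(gene, age_sign, repop_vs_aged, repop_vs_adult, alpha) -> str:
    if gene not in repop_vs_aged.index or not bool(repop_vs_aged.loc[gene, "tested"]):
        logger.warning("signature gene %s untested in repop-vs-aged contrast; unaffected", gene)
        return "unaffected"
    p_ra = repop_vs_aged.loc[gene, "pvalue"]
    lfc_ra = repop_vs_aged.loc[gene, "log2fc"]
    if not p_ra < alpha:
        return "unaffected"
    if lfc_ra == 0:
        return "unaffected"  # significant but directionless: no claim
    if np.sign(lfc_ra) == age_sign:
        return "exacerbated"
    if gene not in repop_vs_adult.index or not bool(repop_vs_adult.loc[gene, "tested"]):
        logger.warning("signature gene %s untested in repop-vs-adult contrast; reversed gate "
                       "defaults to no-difference", gene)
        return "reversed"
    return "reversed" if not repop_vs_adult.loc[gene, "pvalue"] < alpha else "partially_reversed"


def classify_lps_response(
    contrasts: dict,
    alpha: float = 0.05,
    fc_threshold: float | None = None,
) -> pd.DataFrame:
    """LPS-response taxonomy over all genes of the LPS panel.

    ``contrasts`` must contain the keys ``adult_lps_vs_saline``,
    ``aged_lps_vs_saline``, ``aged_lps_vs_adult_lps`` and
    ``aged_repop_lps_vs_saline``. A gene is "up" in a contrast when it is
    tested, ``pvalue < alpha`` and ``log2fc > 0`` (optionally also
    ``log2fc > log2(fc_threshold)``; off by default).

    Categories: ``exacerbated_by_age`` (up after LPS in adults and further
    increased in aged animals), ``unique_to_aged`` (up in aged, not in
    adults), ``adult_only`` (up in adults only), else ``nonresponsive``.
    ``prevented_by_repop`` flags aged-responsive genes whose LPS response is
    absent in aged-repopulation animals.
    """
    required = ("adult_lps_vs_saline", "aged_lps_vs_saline",
                "aged_lps_vs_adult_lps", "aged_repop_lps_vs_saline")
    for key in required:
        if key not in contrasts:
            raise ValidationError(f"missing LPS contrast {key!r}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    lfc_min = 0.0 if fc_threshold is None else np.log2(fc_threshold)

    genes = contrasts["adult_lps_vs_saline"].index

    def up(key):
        c = contrasts[key].reindex(genes)
        return (
            c["tested"].fillna(False).astype(bool)
            & (c["pvalue"] < alpha)
            & (c["log2fc"] > lfc_min)
        ).to_numpy()

    up_adult = up("adult_lps_vs_saline")
    up_aged = up("aged_lps_vs_saline")
    up_aged_vs_adult = up("aged_lps_vs_adult_lps")
    up_repop = up("aged_repop_lps_vs_saline")

    category = np.full(len(genes), "nonresponsive", dtype=object)
    category[up_adult & ~up_aged] = "adult_only"
    category[up_aged & ~up_adult] = "unique_to_aged"
    category[up_adult & up_aged_vs_adult] = "exacerbated_by_age"
    aged_responsive = np.isin(category, ("exacerbated_by_age", "unique_to_aged"))
    prevented = aged_responsive & ~up_repop

    out = pd.DataFrame(
        {
            "lps_category": category,
            "prevented_by_repop": prevented,
            "adult_lps_log2fc": contrasts["adult_lps_vs_saline"]["log2fc"].reindex(genes),
            "adult_lps_pvalue": contrasts["adult_lps_vs_saline"]["pvalue"].reindex(genes),
            "aged_lps_log2fc": contrasts["aged_lps_vs_saline"]["log2fc"].reindex(genes),
            "aged_lps_pvalue": contrasts["aged_lps_vs_saline"]["pvalue"].reindex(genes),
            "aged_vs_adult_lps_pvalue": contrasts["aged_lps_vs_adult_lps"]["pvalue"].reindex(genes),
            "aged_repop_lps_pvalue": contrasts["aged_repop_lps_vs_saline"]["pvalue"].reindex(genes),
        },
        index=genes,
    )
    return out


def summarize_categories(classification: pd.DataFrame) -> pd.DataFrame:
    """Deterministically ordered category counts.

    For a reversal classification, counts per (direction, category); for an
    LPS classification, counts per (lps_category, prevented_by_repop).
    Counts always sum to the number of classified genes.
    """
    if len(classification) == 0:
        raise ValidationError("empty classification")
    if "category" in classification.columns:
        rows = []
        for direction in ("increased", "decreased"):
            for cat in REVERSAL_ORDER:
                n = int(
                    (
                        (classification["direction"] == direction)
                        & (classification["category"] == cat)
                    ).sum()
                )
                rows.append({"direction": direction, "category": cat, "n_genes": n})
        return pd.DataFrame(rows)
    if "lps_category" in classification.columns:
        rows = []
        for cat in LPS_ORDER:
            in_cat = classification["lps_category"] == cat
            rows.append(
                {
                    "lps_category": cat,
                    "n_genes": int(in_cat.sum()),
                    "n_prevented_by_repop": int(
                        (in_cat & classification["prevented_by_repop"]).sum()
                    ),
                }
            )
        return pd.DataFrame(rows)
    raise ValidationError("unrecognized classification table")
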
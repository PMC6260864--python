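"""Synthetic factorial RNA-seq count generator with planted, recoverable truth.

Counts are negative-binomial (NB2, ``var = mu + alpha*mu**2``) around
group means ``baseline * 2**lfc * library_factor``, with log-normal
library-size variation and per-gene planted log2 fold changes realizing
each reversal-taxonomy category across a 2x2 age x treatment design
(optionally extended by a saline/LPS stimulus axis). The planted truth is
returned alongside the counts so every downstream stage can be scored by
parameter recovery.

One root seed drives everything; each arm (factorial, LPS panel, ddCT
fixture) draws from its own deterministic substream so arms can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, DdctTable, SampleDesign, ValidationError

#: canonical planting order of reversal categories
REVERSAL_CATEGORIES = (
    "null",
    "up_reversed", "up_partial", "up_exacerbated", "up_unaffected",
    "down_reversed", "down_partial", "down_exacerbated", "down_unaffected",
)

#: canonical planting order of LPS-panel categories
LPS_CATEGORIES = (
    "null", "lps_adult_up", "lps_age_exacerbated", "lps_aged_unique",
    "lps_prevented_by_repop",
)

_ARM_FACTORIAL = 0
_ARM_LPS = 1
_ARM_DDCT = 2


@dataclass
class SimulationConfig:
    """Parameters of the factorial count simulation.

    Defaults mirror the study design this generator emulates: four groups
    of six animals, moderate biological dispersion, library sizes varying
    by ~15% on the log scale, baseline expression log-uniform over
    [20, 2000] so an expression prefilter at baseMean 10 is non-vacuous,
    and age effects of 1.5-2.5 log2 units.
    """

    n_genes: int = 2000
    n_per_group: int = 6
    baseline_mean_range: tuple = (20.0, 2000.0)
    dispersion: float | np.ndarray = 0.1
    libsize_sd: float = 0.15
    category_counts: dict = field(default_factory=dict)
    age_lfc_magnitude: tuple = (1.5, 2.5)
    lps_lfc_magnitude: tuple | None = None
    partial_fraction: float = 0.5
    exacerbation_increment: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ValidationError("baseline_mean_range must be a positive interval")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ValidationError("dispersion must be nonnegative")
        if self.libsize_sd < 0:
            raise ValidationError("libsize_sd must be nonnegative")
        if not 0 < self.partial_fraction < 1:
            raise ValidationError("partial_fraction must lie in (0, 1)")
        if self.exacerbation_increment <= 0:
            raise ValidationError("exacerbation_increment must be positive")
        lo, hi = self.age_lfc_magnitude
        if not (0 < lo <= hi):
            raise ValidationError("age_lfc_magnitude must be a positive interval")

    def resolved_categories(self, allowed) -> dict:
        counts = dict(self.category_counts) if self.category_counts else {"null": self.n_genes}
        unknown = set(counts) - set(allowed)
        if unknown:
            raise ValidationError(f"unknown categories {sorted(unknown)}; allowed: {list(allowed)}")
        total = sum(counts.values())
        if total != self.n_genes:
            raise ValidationError(
                f"category counts sum to {total}, expected n_genes={self.n_genes}"
            )
        if any(v < 0 for v in counts.values()):
            raise ValidationError("category counts must be nonnegative")
        return counts


def _rng(seed: int, arm: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(arm,)))


def _sample_counts(rng, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 draws; Poisson where alpha == 0."""
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float)[:, None], mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / alpha[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def _gene_params(rng, config: SimulationConfig, n_genes: int):
    lo, hi = config.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    alpha = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (n_genes,)).copy()
    return baseline, alpha


def _assign_categories(counts: dict, order) -> list:
    labels = []
    for cat in order:
        labels.extend([cat] * counts.get(cat, 0))
    return labels


def generate_factorial_counts(config: SimulationConfig):
    """Simulate the 2x2 age x treatment design with planted reversal structure.

    Returns ``(CountMatrix, SampleDesign, truth)`` where ``truth`` is a
    DataFrame indexed by gene with columns ``category, lfc_age, lfc_repop,
    baseline_mean, dispersion``. ``lfc_age`` is the aged-control vs
    adult-control log2 fold change and ``lfc_repop`` the aged-repopulation
    vs aged-control one; adult groups are unaffected by repopulation.
    """
    counts_by_cat = config.resolved_categories(REVERSAL_CATEGORIES)
    rng = _rng(config.seed, _ARM_FACTORIAL)
    n = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    categories = _assign_categories(counts_by_cat, REVERSAL_CATEGORIES)
    baseline, alpha = _gene_params(rng, config, n)

    lo, hi = config.age_lfc_magnitude
    magnitude = rng.uniform(lo, hi, size=n)
    lfc_age = np.zeros(n)
    lfc_repop = np.zeros(n)
    for i, cat in enumerate(categories):
        if cat == "null":
            continue
        sign = 1.0 if cat.startswith("up_") else -1.0
        lfc_age[i] = sign * magnitude[i]
        kind = cat.split("_", 1)[1]
        if kind == "reversed":
            lfc_repop[i] = -lfc_age[i]
        elif kind == "partial":
            lfc_repop[i] = -config.partial_fraction * lfc_age[i]
        elif kind == "exacerbated":
            lfc_repop[i] = sign * config.exacerbation_increment
        # unaffected: stays 0

    groups = [("adult", "control"), ("adult", "repopulation"),
              ("aged", "control"), ("aged", "repopulation")]
    sample_ids, rows = [], []
    for age, treatment in groups:
        for k in range(config.n_per_group):
            sample_ids.append(f"{age}_{treatment}_{k + 1}")
            rows.append({"age": age, "treatment": treatment})
    design = SampleDesign(pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id")))

    lib = np.exp(rng.normal(0.0, config.libsize_sd, size=len(sample_ids)))
    # per-group log2 offsets: adult groups at baseline; aged-control carries
    # the age effect; aged-repop carries age + repopulation effects
    group_lfc = {
        ("adult", "control"): np.zeros(n),
        ("adult", "repopulation"): np.zeros(n),
        ("aged", "control"): lfc_age,
        ("aged", "repopulation"): lfc_age + lfc_repop,
    }
    mean = np.empty((n, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        age, treatment = design.table.loc[sid, "age"], design.table.loc[sid, "treatment"]
        mean[:, j] = baseline * np.power(2.0, group_lfc[(age, treatment)]) * lib[j]
    values = _sample_counts(rng, mean, alpha)

    matrix = CountMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        scale="raw",
    )
    truth = pd.DataFrame(
        {
            "category": categories,
            "lfc_age": lfc_age,
            "lfc_repop": lfc_repop,
            "baseline_mean": baseline,
            "dispersion": alpha,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return matrix, design, truth


def generate_lps_panel(config: SimulationConfig):
    """Simulate the LPS-challenge arm: 2x2x2 age x treatment x stimulus design.

    Planted categories control the LPS response per group: an adult-only
    response (``lps_adult_up``), a response present in adults and larger in
    aged mice (``lps_age_exacerbated``), a response present only in aged
    mice (``lps_aged_unique``), and an aged-only response abolished in
    aged-repopulation animals (``lps_prevented_by_repop``). Saline groups
    sit at baseline for every gene. Truth columns: ``category,
    lfc_lps_adult, lfc_lps_aged, lfc_lps_aged_repop, baseline_mean,
    dispersion``.
    """
    counts_by_cat = config.resolved_categories(LPS_CATEGORIES)
    rng = _rng(config.seed, _ARM_LPS)
    n = config.n_genes
    gene_ids = [f"L{i + 1:05d}" for i in range(n)]
    categories = _assign_categories(counts_by_cat, LPS_CATEGORIES)
    baseline, alpha = _gene_params(rng, config, n)

    lo, hi = config.lps_lfc_magnitude or config.age_lfc_magnitude
    magnitude = rng.uniform(lo, hi, size=n)
    lfc_adult = np.zeros(n)
    lfc_aged = np.zeros(n)
    lfc_aged_repop = np.zeros(n)
    for i, cat in enumerate(categories):
        if cat == "null":
            continue
        m = magnitude[i]
        if cat == "lps_adult_up":
            lfc_adult[i] = m
        elif cat == "lps_age_exacerbated":
            lfc_adult[i] = m
            lfc_aged[i] = m + config.exacerbation_increment
            lfc_aged_repop[i] = lfc_aged[i]
        elif cat == "lps_aged_unique":
            lfc_aged[i] = m
            lfc_aged_repop[i] = m
        elif cat == "lps_prevented_by_repop":
            lfc_aged[i] = m
            # response abolished in aged-repopulation animals

    groups = [(age, tr, st) for age in ("adult", "aged")
              for tr in ("control", "repopulation") for st in ("saline", "lps")]
    sample_ids, rows = [], []
    for age, tr, st in groups:
        for k in range(config.n_per_group):
            sample_ids.append(f"{age}_{tr}_{st}_{k + 1}")
            rows.append({"age": age, "treatment": tr, "stimulus": st})
    design = SampleDesign(pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id")))

    def lps_lfc(age, treatment):
        if age == "adult":
            return lfc_adult
        return lfc_aged_repop if treatment == "repopulation" else lfc_aged

    lib = np.exp(rng.normal(0.0, config.libsize_sd, size=len(sample_ids)))
    mean = np.empty((n, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        age, tr, st = design.table.loc[sid, ["age", "treatment", "stimulus"]]
        lfc = lps_lfc(age, tr) if st == "lps" else 0.0
        mean[:, j] = baseline * np.power(2.0, lfc) * lib[j]
    values = _sample_counts(rng, mean, alpha)

    matrix = CountMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        scale="raw",
    )
    truth = pd.DataFrame(
        {
            "category": categories,
            "lfc_lps_adult": lfc_adult,
            "lfc_lps_aged": lfc_aged,
            "lfc_lps_aged_repop": lfc_aged_repop,
            "baseline_mean": baseline,
            "dispersion": alpha,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return matrix, design, truth


def generate_ddct_table(
    n_per_group: int,
    delta_ct_control: float,
    delta_delta_ct: float,
    noise_sd: float,
    seed: int,
    ct_reference: float = 15.0,
) -> DdctTable:
    """Two-group qPCR CT fixture with a planted ddCT shift.

    Control samples have ``dCT = delta_ct_control + noise``; treated samples
    ``dCT = delta_ct_control + delta_delta_ct + noise``. The expected
    treated fold change is ``2**(-delta_delta_ct)``.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    rng = _rng(seed, _ARM_DDCT)
    rows = []
    for group, shift in (("control", 0.0), ("treated", delta_delta_ct)):
        for k in range(n_per_group):
            dct = delta_ct_control + shift + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "sample_id": f"{group}_{k + 1}",
                    "group": group,
                    "ct_target": ct_reference + dct,
                    "ct_reference": ct_reference,
                }
            )
    return DdctTable(pd.DataFrame(rows))
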
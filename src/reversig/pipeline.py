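"""End-to-end orchestration of the DE + classification stages.

Wires the engine's primitives into the two study workflows: the reversal
analysis on the 2x2 age x treatment design and the LPS-response analysis on
the 2x2x2 design with a stimulus axis. Used by the command-line interface
and the recovery evaluation; importable directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import de
from .classify import classify_lps_response, classify_reversal, define_age_signature
from .datatypes import ContrastSpec, CountMatrix, SampleDesign

#: named contrasts of the reversal analysis (Aged Repop vs Adult Control
#: crosses both factors, hence the derived "group" factor)
REVERSAL_CONTRASTS = {
    "aged_vs_adult_control": ContrastSpec(
        factor="age", numerator="aged", denominator="adult", stratum={"treatment": "control"}
    ),
    "repop_vs_aged_control": ContrastSpec(
        factor="treatment", numerator="repopulation", denominator="control",
        stratum={"age": "aged"},
    ),
    "aged_repop_vs_adult_control": ContrastSpec(
        factor="group", numerator="aged_repopulation", denominator="adult_control"
    ),
}

LPS_CONTRASTS = {
    "adult_lps_vs_saline": ContrastSpec(
        factor="stimulus", numerator="lps", denominator="saline",
        stratum={"age": "adult", "treatment": "control"},
    ),
    "aged_lps_vs_saline": ContrastSpec(
        factor="stimulus", numerator="lps", denominator="saline",
        stratum={"age": "aged", "treatment": "control"},
    ),
    "aged_lps_vs_adult_lps": ContrastSpec(
        factor="age", numerator="aged", denominator="adult",
        stratum={"treatment": "control", "stimulus": "lps"},
    ),
    "aged_repop_lps_vs_saline": ContrastSpec(
        factor="stimulus", numerator="lps", denominator="saline",
        stratum={"age": "aged", "treatment": "repopulation"},
    ),
}


@dataclass
class PipelineResult:
    size_factors: pd.Series
    dispersions: pd.Series
    contrasts: dict
    signature: pd.DataFrame | None = None
    classification: pd.DataFrame | None = None


def run_contrasts(
    counts: CountMatrix,
    design: SampleDesign,
    specs: dict,
    base_mean_min: float = 0.0,
    covariates: list | None = None,
    size_factors: pd.Series | None = None,
) -> PipelineResult:
    """Normalize (unless the matrix is already normalized) and fit each contrast."""
    if counts.scale == "raw":
        if size_factors is None:
            size_factors = de.estimate_size_factors(counts)
        dispersions = de.estimate_dispersions(counts, design, size_factors)
        raw = counts
    else:
        # normalized input: size factors fixed at 1; inference on such data
        # is approximate since the NB likelihood assumes integer counts
        rounded = counts.data.round()
        raw = CountMatrix(rounded, scale="raw")
        size_factors = pd.Series(1.0, index=counts.sample_ids, name="size_factor")
        dispersions = de.estimate_dispersions(raw, design, size_factors)
    results = {}
    for name, spec in specs.items():
        if covariates:
            spec = ContrastSpec(spec.factor, spec.numerator, spec.denominator,
                                dict(spec.stratum), list(covariates))
        results[name] = de.fit_contrast(raw, design, spec, dispersions, size_factors,
                                        base_mean_min=base_mean_min)
    return PipelineResult(size_factors, dispersions, results)


def run_reversal_pipeline(
    counts: CountMatrix,
    design: SampleDesign,
    alpha_adj: float = 0.05,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    base_mean_min: float = 10.0,
    covariates: list | None = None,
) -> PipelineResult:
    """Age signature + reversal taxonomy on a 2x2 age x treatment design."""
    result = run_contrasts(counts, design, REVERSAL_CONTRASTS,
                           base_mean_min=base_mean_min, covariates=covariates)
    result.signature = define_age_signature(
        result.contrasts["aged_vs_adult_control"], alpha_adj=alpha_adj,
        fc_threshold=fc_threshold,
    )
    result.classification = classify_reversal(
        result.signature,
        result.contrasts["repop_vs_aged_control"],
        result.contrasts["aged_repop_vs_adult_control"],
        alpha=alpha,
    )
    return result


def run_lps_pipeline(
    counts: CountMatrix,
    design: SampleDesign,
    alpha: float = 0.05,
    fc_threshold: float | None = None,
    base_mean_min: float = 0.0,
    covariates: list | None = None,
) -> PipelineResult:
    """LPS-response taxonomy on the stimulus-extended design."""
    result = run_contrasts(counts, design, LPS_CONTRASTS,
                           base_mean_min=base_mean_min, covariates=covariates)
    result.classification = classify_lps_response(
        result.contrasts, alpha=alpha, fc_threshold=fc_threshold
    )
    return result
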
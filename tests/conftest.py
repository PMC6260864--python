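import numpy as np
import pandas as pd
import pytest

from reversig.datatypes import ContrastSpec, CountMatrix, SampleDesign


@pytest.fixture
def small_design():
    """2x2 design, 3 samples per cell."""
    rows = []
    for age in ("adult", "aged"):
        for treatment in ("control", "repopulation"):
            for k in range(3):
                rows.append({"sample_id": f"{age}_{treatment}_{k+1}",
                             "age": age, "treatment": treatment})
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleDesign(df)


@pytest.fixture
def small_counts(small_design):
    rng = np.random.default_rng(42)
    values = rng.poisson(50, size=(30, len(small_design.sample_ids)))
    return CountMatrix(
        pd.DataFrame(values,
                     index=pd.Index([f"g{i}" for i in range(30)], name="gene_id"),
                     columns=small_design.sample_ids)
    )


@pytest.fixture
def age_contrast_spec():
    return ContrastSpec(factor="age", numerator="aged", denominator="adult",
                        stratum={"treatment": "control"})


def make_contrast_frame(rows: dict) -> pd.DataFrame:
    """Build a contrast-result table from {gene: (log2fc, pvalue[, padj])}."""
    recs = {}
    for gene, vals in rows.items():
        log2fc, pvalue = vals[0], vals[1]
        padj = vals[2] if len(vals) > 2 else pvalue
        tested = pvalue is not None
        recs[gene] = {
            "base_mean": 100.0,
            "log2fc": log2fc if tested else np.nan,
            "lfc_se": 0.1,
            "stat": 0.0,
            "pvalue": pvalue if tested else np.nan,
            "padj": padj if tested else np.nan,
            "tested": tested,
        }
    df = pd.DataFrame.from_dict(recs, orient="index")
    df.index.name = "gene_id"
    return df
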
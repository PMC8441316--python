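import numpy as np
import pandas as pd
import pytest

from matreoscreen.matrisome import GeneSetCollection
from matreoscreen.scoring import DrugProfileMatrix
from matreoscreen.signature import DOWN, UP, ExpressionCohort, MatreotypeSignature


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    return GeneSetCollection(
        sets={
            "collagens": ["COL1", "COL2"],
            "glycoproteins": ["FN1"],
            "proteoglycans": ["ACAN"],
            "ECM-regulators": ["MMP1", "MMP2"],
            "secreted-factors": ["TGFB1"],
            "ECM-affiliated": ["ANX1"],
        }
    )


@pytest.fixture
def toy_signature() -> MatreotypeSignature:
    return MatreotypeSignature(
        entries={"A": UP, "B": UP, "C": DOWN, "D": DOWN},
        support={g: 3 for g in "ABCD"},
        kind="aged",
    )


@pytest.fixture
def small_profiles() -> DrugProfileMatrix:
    rng = np.random.default_rng(7)
    genes = ["A", "B", "C", "D"] + [f"G{i}" for i in range(16)]
    z = pd.DataFrame(
        rng.standard_normal((6, len(genes))),
        index=[f"d{i}" for i in range(6)],
        columns=genes,
    )
    return DrugProfileMatrix(z=z, lifespan_reported={"d0": True})


def make_cohort(
    n_genes: int = 5,
    values=None,
    tissue: str = "skin",
    donors_per_bracket: int = 3,
    brackets=(("20s", 25.0), ("70s", 75.0)),
) -> ExpressionCohort:
    """Small hand-specified cohort; ``values`` maps bracket label -> per-gene
    column vector used for every donor in that bracket (noiseless)."""
    genes = [f"g{i}" for i in range(n_genes)]
    cols, data, bracket_of = [], [], {}
    for label, _mid in brackets:
        vec = (
            np.asarray(values[label], dtype=float)
            if values is not None
            else np.full(n_genes, 10.0)
        )
        for d in range(donors_per_bracket):
            donor = f"{label}_{d}"
            cols.append(donor)
            bracket_of[donor] = label
            data.append(vec)
    matrix = pd.DataFrame(np.array(data).T, index=genes, columns=cols)
    return ExpressionCohort(
        matrix=matrix,
        tissue=tissue,
        donor_bracket=bracket_of,
        bracket_midpoints=dict(brackets),
    )
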
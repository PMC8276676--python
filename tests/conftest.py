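import numpy as np
import pandas as pd
import pytest

from il17sys.io import ExpressionMatrix
from il17sys.synth import SyntheticSpec, generate_microarray


@pytest.fixture
def tiny_matrix():
    """Two genes, two groups of two samples, hand-set values."""
    values = pd.DataFrame(
        [[3.0, 5.0, 1.0, 1.0],
         [1.0, 1.0, 1.0, 1.0]],
        index=["GENEA", "GENEB"],
        columns=["d1", "d2", "n1", "n2"],
    )
    pheno = {"d1": "disease", "d2": "disease", "n1": "normal", "n2": "normal"}
    return ExpressionMatrix(values=values, phenotype=pheno)


@pytest.fixture
def synth_cohort():
    spec = SyntheticSpec(n_genes=2000, deg_fraction=0.05, effect_size=2.0,
                         sigma=0.5, seed=1)
    return spec, *generate_microarray(spec)
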
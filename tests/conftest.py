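import numpy as np
import pandas as pd
import pytest

from transcriptage.expression import ExpressionMatrix
from transcriptage.preprocess import length_weight
from transcriptage.synthetic import fixture_small

# Expected TMM factors for make_tmm_matrix(), reference column L4 fixed at 1.
# Computed with edgeR 4.0.16 calcNormFactors(method="TMM") on the identical
# matrix (factors rescaled to the reference column).
EDGER_TMM_FACTORS = {
    "L1": 0.901450555450,
    "L2": 0.841705843859,
    "L3": 1.227763575606,
    "L4": 1.000000000000,
}
EDGER_TMM_REFERENCE = "L4"


def make_tmm_matrix() -> ExpressionMatrix:
    """200-gene, 4-library count matrix with 5% of genes 8-fold inflated in
    library L2 (a composition shift TMM must correct)."""
    rng = np.random.default_rng(20240917)
    base = rng.lognormal(mean=4.0, sigma=1.0, size=(200, 4))
    counts = rng.poisson(base).astype(float)
    counts[:10, 1] *= 8
    frame = pd.DataFrame(
        counts,
        index=pd.Index([f"g{i + 1:03d}" for i in range(200)], name="gene_id"),
        columns=["L1", "L2", "L3", "L4"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture(scope="session")
def bundle():
    return fixture_small()


@pytest.fixture(scope="session")
def fixture_genes(bundle):
    # the generating theta doubles as the analysis covariate in the fixture
    return bundle.genes.rename(columns={"theta_true": "theta"})


@pytest.fixture(scope="session")
def weighted(bundle, fixture_genes):
    return length_weight(bundle.counts, fixture_genes)


@pytest.fixture(scope="session")
def fixture_paths(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture_files")
    return bundle.write(outdir)
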
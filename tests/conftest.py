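import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_gem(tmp_path):
    """3-gene x 2-sample TSV on disk plus its expected frame."""
    path = tmp_path / "gem.tsv"
    path.write_text(
        "gene_id\tS1\tS2\n"
        "ENSG00000000001;A\t1.0\t2.0\n"
        "ENSG00000000002;B\t3.5\t0.0\n"
        "ENSG00000000003;C\t2.25\t7.0\n"
    )
    frame = pd.DataFrame(
        [[1.0, 2.0], [3.5, 0.0], [2.25, 7.0]],
        index=pd.Index(
            ["ENSG00000000001;A", "ENSG00000000002;B", "ENSG00000000003;C"],
            name="gene_id",
        ),
        columns=["S1", "S2"],
    )
    return path, frame


def correlated_cloud(rng, n, rho, loc=(0.0, 0.0), scale=1.0):
    """Bivariate normal points with the given correlation."""
    cov = np.array([[1.0, rho], [rho, 1.0]]) * scale**2
    return rng.multivariate_normal(loc, cov, size=n)


@pytest.fixture
def small_generator_config():
    from condnet.simulate import GeneratorConfig

    return GeneratorConfig(
        n_samples=150,
        n_genes=40,
        n_planted_edges=4,
        planted_conditions=("tissue_type=Primary Tumor", "cancer_type=KIRC"),
        n_global_modules=2,
        global_module_size=6,
        n_outliers=2,
        seed=7,
    )
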
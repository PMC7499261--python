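import numpy as np
import pytest

from stratld import (AnnotationMatrix, Annotation, SimConfig, SnpPanel,
                     WindowSpec, gen_annotations, gen_panel,
                     stratified_ld_scores)
from stratld.simulate import default_tau

try:
    from hypothesis import settings

    settings.register_profile("suite", deadline=None, max_examples=50,
                              derandomize=True)
    settings.load_profile("suite")
except ImportError:
    pass


def toy_panel(m=10, chrom="chr1", spacing=100, start=1000, maf=0.25):
    """Tiny handmade panel for unit tests."""
    pos = start + spacing * np.arange(m)
    return SnpPanel([f"rs{i}" for i in range(m)], [chrom] * m, pos,
                    ["A"] * m, ["G"] * m, np.full(m, maf))


@pytest.fixture(scope="session")
def sim():
    """One medium synthetic dataset shared across the suite: panel,
    genotypes, annotations (base + 4), true tau and LD scores."""
    cfg = SimConfig(m=4000, n_ref=400, n_gwas=20_000, block_len=25,
                    rho=0.6, n_chroms=4, seed=11)
    panel, geno = gen_panel(cfg)
    mat = gen_annotations(cfg, panel)
    tau = default_tau(cfg, mat)
    scores = stratified_ld_scores(geno, mat, WindowSpec("kb", 100),
                                  adjusted=False)
    return {"cfg": cfg, "panel": panel, "geno": geno, "mat": mat,
            "tau": tau, "scores": scores}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def prob_matrix():
    """Small 5-tissue probabilistic annotation matrix on a toy panel."""
    panel = toy_panel(50)
    r = np.random.default_rng(7)
    mat = AnnotationMatrix(panel)
    for t in range(5):
        mat.add(Annotation(f"tissue{t}", r.uniform(0, 1, panel.m),
                           "probabilistic"))
    return mat
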
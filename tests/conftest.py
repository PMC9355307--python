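import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import circdosage as cd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth() -> cd.TruthBundle:
    """A small zero-caller-noise synthetic study shared across tests."""
    cfg = cd.SimConfig(n_per_group=3, tissues=("blood", "muscle"), n_circ=200,
                       seed=101, fp_rate_per_caller=0.0, fn_rate_per_caller=0.0)
    return cd.simulate_study(cfg)


@pytest.fixture(scope="session")
def noisy_truth() -> cd.TruthBundle:
    """A study with caller false positives/negatives for filter tests."""
    cfg = cd.SimConfig(n_per_group=3, tissues=("blood",), n_circ=150, seed=202,
                       fp_rate_per_caller=0.1, fn_rate_per_caller=0.1)
    return cd.simulate_study(cfg)


@pytest.fixture()
def toy_gene_annotation() -> cd.Annotation:
    """Two adjacent genes on chr1 with hand-placed exons, plus a chrX PAR gene."""
    gene_a = cd.Gene("A", "chr1", "+", "autosome",
                     exons=((100, 200), (300, 400), (500, 600), (700, 800),
                            (900, 1000), (1100, 1200)))
    gene_b = cd.Gene("B", "chr1", "+", "autosome",
                     exons=((2000, 2100), (2200, 2300)))
    gene_p = cd.Gene("P", "chrX", "+", "PAR1", exons=((100_000, 100_500),))
    return cd.Annotation({"A": gene_a, "B": gene_b, "P": gene_p})
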
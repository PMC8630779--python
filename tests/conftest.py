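import numpy as np
import pandas as pd
import pytest

from cisbreak.io_model import (
    Cohort, GeneModel, IntervalTrack, SvCall, assemble_cohort,
)


def make_annotations(samples, n_types=2, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "cancer_type": [f"type{i % n_types}" for i in range(len(samples))],
        "therapy_flags": [frozenset() for _ in samples],
        "os_months": rng.uniform(1, 100, len(samples)).round(2),
        "os_event": rng.integers(0, 2, len(samples)),
    }, index=pd.Index(samples, name="sample_id"))


def make_cohort(genes, svs, samples, seed=0, tracks=None, expression=None):
    """Hand-assembled cohort with lognormal expression and flat CNA."""
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    if expression is None:
        expression = pd.DataFrame(
            rng.lognormal(3, 1, (len(genes), len(samples))).round(4),
            index=gene_ids, columns=samples,
        )
    cna = pd.DataFrame(2, index=gene_ids, columns=samples)
    return assemble_cohort(
        genes, expression, cna, svs, make_annotations(samples, seed=seed),
        tracks or {},
    )


@pytest.fixture
def random_small_cohort():
    """20 genes x 10 samples x 50 random SVs on a 2-chromosome toy genome."""
    rng = np.random.default_rng(42)
    chroms = {"chrA": 10_000_000, "chrB": 8_000_000}
    genes = []
    for i in range(20):
        chrom = "chrA" if i < 12 else "chrB"
        start = int(rng.integers(200_000, chroms[chrom] - 300_000))
        genes.append(GeneModel(f"g{i:02d}", chrom, start, start + 20_000,
                               "+" if rng.random() < 0.5 else "-"))
    samples = [f"s{i}" for i in range(10)]
    svs = []
    for k in range(50):
        c1 = "chrA" if rng.random() < 0.6 else "chrB"
        c2 = c1 if rng.random() < 0.7 else ("chrB" if c1 == "chrA" else "chrA")
        p1 = int(rng.integers(0, chroms[c1]))
        p2 = int(rng.integers(0, chroms[c2]))
        s1, s2 = rng.choice(["+", "-"], 2)
        svs.append(SvCall(str(rng.choice(samples)), c1, p1, str(s1),
                          c2, p2, str(s2), "other", f"sv{k:03d}"))
    return make_cohort(genes, svs, samples, seed=7)
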
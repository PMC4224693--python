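import numpy as np
import pytest

from surf.annotation import AnnotationBundle, GeneModel, GenomicInterval, VariantRecord
from surf.fixtures import FixtureSpec, generate_benchmark
from surf.ranking import DEFAULT_STATE_ORDER


@pytest.fixture
def hand_bundle():
    """A tiny hand-built bundle on chr1/chr2 with known overlaps."""
    gm = GeneModel(
        tss=[GenomicInterval("chr1", 5000, 5001, label="+")],
        exons=[GenomicInterval("chr1", 5000, 5200),
               GenomicInterval("chr1", 5400, 5600)],
        introns=[GenomicInterval("chr1", 5200, 5400)],
        splice_sites=[GenomicInterval("chr1", 5199, 5201),
                      GenomicInterval("chr1", 5399, 5401)],
        cpg_islands=[GenomicInterval("chr1", 4900, 5100)],
        cpg_shores=[GenomicInterval("chr1", 3900, 4900),
                    GenomicInterval("chr1", 5100, 6100)],
        gene_bodies=[GenomicInterval("chr1", 5000, 5600, label="+")],
    )
    return AnnotationBundle(
        conservation=[GenomicInterval("chr1", 100, 300, score=3.5),
                      GenomicInterval("chr1", 250, 500, score=-1.0)],
        dnase_hs=[GenomicInterval("chr1", 100, 400, score=5.0),
                  GenomicInterval("chr1", 200, 350, score=7.5)],
        footprints=[GenomicInterval("chr1", 120, 180, label="cellA"),
                    GenomicInterval("chr1", 150, 190, label="cellB"),
                    GenomicInterval("chr1", 160, 185, label="cellB")],
        chromatin_states={
            "cell1": [GenomicInterval("chr1", 0, 1000, label="Weak Enhancer")],
            "cell2": [GenomicInterval("chr1", 0, 500, label="Strong Enhancer"),
                      GenomicInterval("chr1", 500, 1000, label="Repressed")],
        },
        enhancers=[GenomicInterval("chr1", 140, 220)],
        tfbs=[GenomicInterval("chr1", 130, 260, score=9.0, label="TF1"),
              GenomicInterval("chr1", 150, 200, score=4.0, label="TF2")],
        gene_model=gm,
    )


@pytest.fixture(scope="session")
def enriched_fixture():
    """A seeded synthetic benchmark with Position+Conservation enrichment."""
    spec = FixtureSpec(seed=101, n_regions=3, n_background_per_region=120,
                       n_functional=120,
                       weights={"Position": 15, "Conservation": 10})
    bundle, region_set, lvs = generate_benchmark(spec)
    return spec, bundle, region_set, lvs


def fractional_ranks(values):
    """Independent tie-average rank oracle: sort, average tied positions."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney AUC oracle, ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
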
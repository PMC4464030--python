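import numpy as np
import pytest

from miregnet.io import InteractionMatrix
from miregnet.ontology import AnnotationStore
from miregnet.simulate import PlantedDesign, planted_matrix


@pytest.fixture
def tiny_matrix() -> InteractionMatrix:
    """3x3 matrix with every score 0.6."""
    return InteractionMatrix(
        ("m1", "m2", "m3"), ("g1", "g2", "g3"), np.full((3, 3), 0.6)
    )


@pytest.fixture
def planted_fixture():
    """The reference planted design: 4 disjoint modules of 10 miRNAs x 40 genes."""
    design = PlantedDesign.grid(seed=11)
    return planted_matrix(design)


@pytest.fixture
def manual_store() -> AnnotationStore:
    """Hand-built annotation store for exact similarity arithmetic."""
    return AnnotationStore(
        namespace="BP",
        direct={"G1": frozenset({"t1", "t2"}), "G2": frozenset({"t1"})},
        closed={
            "G1": frozenset({"t1", "t2"}),
            "G2": frozenset({"t1"}),
            "G3": frozenset({"t3"}),
        },
        ic={"t1": 1.0, "t2": 2.0, "t3": 0.5},
        n_genes=3,
    )


def super_module_matrix(seed: int = 0):
    """Four planted modules arranged as two super-modules.

    Modules within a super-module share moderate cross-scores (0.48, below
    the beta = 0.5 reliability cutoff but high enough that their union
    passes alpha = 0.5 compactness); super-modules share nothing.
    """
    rng = np.random.default_rng(seed)
    n_mirna, n_gene = 40, 160
    values = rng.uniform(0.0, 0.3, size=(n_mirna, n_gene))
    values[values < 0.05] = 0.0
    modules = []
    for k in range(4):
        ms = list(range(k * 10, (k + 1) * 10))
        gs = list(range(k * 40, (k + 1) * 40))
        values[np.ix_(ms, gs)] = rng.uniform(0.7, 1.0, size=(10, 40))
        modules.append((ms, gs))
    for a, b in ((0, 1), (2, 3)):   # within-super cross blocks
        values[np.ix_(modules[a][0], modules[b][1])] = 0.48
        values[np.ix_(modules[b][0], modules[a][1])] = 0.48
    mirnas = tuple(f"hsa-mir-{i:04d}" for i in range(n_mirna))
    genes = tuple(f"GENE{j:04d}" for j in range(n_gene))
    return InteractionMatrix(mirnas, genes, values), modules
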
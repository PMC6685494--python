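import numpy as np
import pytest

from tedyn.repeat_io import DatedTree, RepeatHit, read_tree


@pytest.fixture(scope="session")
def five_tip_tree() -> DatedTree:
    """((A,B),C) nested in a 5-tip ladder with simple ages."""
    return read_tree("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_hit(species="sp1", family="FamA", cls="SINE", start=1, length=300,
             divergence=0.01, scaffold="scaf1", strand="+") -> RepeatHit:
    return RepeatHit(species_id=species, scaffold=scaffold, start=start,
                     end=start + length - 1, strand=strand, family_name=family,
                     class_label=cls, divergence=divergence)


def random_ultrametric_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random bifurcating ultrametric tree with positive branch lengths."""
    ages = {}
    labels = [f"t{i}" for i in range(n_tips)]
    nodes = [(lab, 0.0) for lab in labels]
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.uniform(0.2, 1.5))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        (na, aa), (nb, ab) = nodes[i], nodes[j]
        merged = f"({na}:{height - aa:.10f},{nb}:{height - ab:.10f})"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((merged, height))
    return nodes[0][0] + ";"
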
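import numpy as np
import pytest

from gcpsr.datamodel import LocusAlignment
from gcpsr.io import parse_gene_tree
from gcpsr.simulate import make_fixture


def aln(locus="L1", **seqs):
    """Shorthand alignment builder: aln(a='ACGT', b='ACTT')."""
    return LocusAlignment(locus, seqs)


def tree(newick, locus="L1", rooted=False):
    return parse_gene_tree(newick, locus, rooted=rooted)


@pytest.fixture(scope="session")
def clean_two_species():
    return make_fixture("clean_two_species")


@pytest.fixture(scope="session")
def four_label_one_species():
    return make_fixture("four_label_one_species")


@pytest.fixture(scope="session")
def single_specimen():
    return make_fixture("single_specimen")


@pytest.fixture(scope="session")
def partial_fungarium():
    return make_fixture("partial_fungarium")


def random_alignment(rng, n_seq=None, n_col=None, alphabet="ACGTACGTN-RY"):
    """Random small alignment over a gap/ambiguity-rich alphabet."""
    n_seq = n_seq or int(rng.integers(2, 9))
    n_col = n_col or int(rng.integers(1, 51))
    chars = np.array(list(alphabet))
    return LocusAlignment(
        "rand",
        {
            f"s{i}": "".join(rng.choice(chars, size=n_col))
            for i in range(n_seq)
        },
    )


def random_tree(rng, n_leaves=None, with_supports=True):
    """Random topology by recursive joining, with random supports (some
    absent)."""
    n = n_leaves or int(rng.integers(4, 11))
    nodes = [f"t{i}" for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if with_supports and rng.random() < 0.8:
            sup = f"{rng.random():.2f}"
        else:
            sup = ""
        nodes.append(f"({a},{b}){sup}")
    newick = f"({','.join(nodes)});"
    return parse_gene_tree(newick, "rand")
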
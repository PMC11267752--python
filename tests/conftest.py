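import numpy as np
import pytest

from sdpre.corpus_io import DependencyTree, EntityMention, REExample, RelationSchema, Token
from sdpre.encoding import EncoderConfig, StubEncoder
from sdpre.synthetic import SynthConfig, generate_corpus


def random_tree_heads(n: int, rng: np.random.Generator) -> list[int]:
    """Random single-rooted head vector via random attachment + relabeling."""
    perm = rng.permutation(n)
    heads = [0] * n
    heads[perm[0]] = -1
    for i in range(1, n):
        heads[perm[i]] = int(perm[rng.integers(i)])
    return heads


def tree_from_heads(heads: list[int], surfaces: list[str] | None = None) -> DependencyTree:
    surfaces = surfaces or [f"w{i}" for i in range(len(heads))]
    return DependencyTree(tuple(
        Token(index=i, surface=s, head=h) for i, (s, h) in enumerate(zip(surfaces, heads))
    ))


def make_example(heads, s_anchor, o_anchor, label="REL", surfaces=None, ex_id="ex0"):
    tree = tree_from_heads(heads, surfaces)
    return REExample(
        id=ex_id, tree=tree,
        subject=EntityMention(start=s_anchor, end=s_anchor + 1, etype="CHEMICAL"),
        object=EntityMention(start=o_anchor, end=o_anchor + 1, etype="GENE"),
        label=label,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def schema():
    return RelationSchema(("A", "B", "C", "None"), none_type="None")


@pytest.fixture
def stub():
    return StubEncoder(EncoderConfig(seed=7))


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic fixture: K=4 relations + None, 500 examples."""
    return generate_corpus(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(SynthConfig(n_examples=120, labeled_budget=30,
                                       test_size=40, seed=3))
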
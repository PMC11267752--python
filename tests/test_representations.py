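"""The four instance representations and their closed-form worked cases."""

import numpy as np
import pytest

from sdpre.corpus_io import EntityMention
from sdpre.encoding import EncoderOutput
from sdpre.representations import (
    SCHEME_DIM_FACTOR,
    atlop_rep,
    build_representation,
    cls_rep,
    ent_rep,
    local_context,
    sdp_rep,
)
from sdpre.sdp import SDPResult, sdp_for_example
from conftest import make_example


def manual_output(H, A=None, h_cls=None):
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    if A is None:
        A = np.full((1, n, n), 1.0 / n)
    if h_cls is None:
        h_cls = H.mean(axis=0)
    return EncoderOutput(h_cls=np.asarray(h_cls, float), H=H, A=np.asarray(A, float))


def mention(i):
    return EntityMention(start=i, end=i + 1, etype="X")


class TestClsEnt:
    def test_cls_is_identity(self):
        enc = manual_output([[1.0, 2.0], [3.0, 4.0]], h_cls=[9.0, 9.0])
        assert np.array_equal(cls_rep(enc).vector, [9.0, 9.0])

    def test_cls_ignores_entities(self):
        enc = manual_output([[1.0, 2.0], [3.0, 4.0]])
        assert np.array_equal(cls_rep(enc).vector, cls_rep(enc).vector)

    def test_ent_concatenates_anchor_rows(self):
        enc = manual_output([[1.0, 2.0], [3.0, 4.0]])
        r = ent_rep(enc, mention(0), mention(1))
        assert np.array_equal(r.vector, [1, 2, 3, 4])

    def test_ent_swap_reverses_halves(self):
        enc = manual_output([[1.0, 2.0], [3.0, 4.0]])
        fwd = ent_rep(enc, mention(0), mention(1)).vector
        rev = ent_rep(enc, mention(1), mention(0)).vector
        assert np.array_equal(rev, np.concatenate([fwd[2:], fwd[:2]]))

    def test_multi_token_entity_uses_first_token(self):
        H = np.arange(12.0).reshape(6, 2)
        enc = manual_output(H)
        m = EntityMention(start=3, end=6, etype="X")  # anchor defaults to 3
        r = ent_rep(enc, m, mention(0))
        assert np.array_equal(r.vector[:2], H[3])


class TestLocalContext:
    def test_worked_product_example(self):
        # one head: A[s]=(.5,.25,.25), A[o]=(.2,.4,.4) -> product (.1,.1,.1)
        # normalizes to uniform -> c is the column mean of H
        H = np.array([[1.0, 0.0], [0.0, 2.0], [5.0, 1.0]])
        A = np.array([[[0.5, 0.25, 0.25], [0.2, 0.4, 0.4], [1 / 3, 1 / 3, 1 / 3]]])
        enc = manual_output(H, A)
        c = local_context(enc, mention(0), mention(1))
        assert np.allclose(c, H.mean(axis=0), atol=1e-12)

    def test_one_hot_shared_attention(self):
        H = np.array([[1.0, 1.0], [2.0, 3.0], [7.0, 7.0]])
        A = np.zeros((2, 3, 3))
        A[:, :, 1] = 1.0  # everyone attends only to token 1
        enc = manual_output(H, A)
        assert np.allclose(local_context(enc, mention(0), mention(2)), H[1])

    def test_uniform_attention_any_head_count(self, rng):
        H = rng.standard_normal((5, 3))
        for n_heads in (1, 2, 4):
            A = np.full((n_heads, 5, 5), 0.2)
            enc = manual_output(H, A)
            assert np.allclose(local_context(enc, mention(0), mention(4)),
                               H.mean(axis=0), atol=1e-9)

    def test_convex_combination_of_rows(self, stub):
        enc = stub.encode(["a", "b", "c", "d", "e"])
        c = local_context(enc, mention(0), mention(4))
        lo = enc.H.min(axis=0) - 1e-12
        hi = enc.H.max(axis=0) + 1e-12
        assert ((c >= lo) & (c <= hi)).all()

    def test_zero_mass_falls_back_to_uniform(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        A = np.array([[[1.0, 0.0], [0.0, 1.0]]])  # disjoint one-hot attentions
        enc = manual_output(H, A)
        with pytest.warns(UserWarning, match="zero-mass"):
            c = local_context(enc, mention(0), mention(1))
        assert np.allclose(c, H.mean(axis=0))


class TestSdpRep:
    def test_worked_example(self):
        H = np.array([[1.0, 0.0], [0.0, 2.0], [0.0, 4.0], [5.0, 5.0]])
        enc = manual_output(H)
        sdp = SDPResult(path=(0, 1, 2, 3), interior=(1, 2))
        r = sdp_rep(enc, sdp, mention(0), mention(3))
        assert np.allclose(r.vector, [1, 0, 0, 3, 5, 5])

    def test_empty_interior_gives_zero_middle(self):
        H = np.array([[1.0, 2.0], [3.0, 4.0]])
        enc = manual_output(H)
        r = sdp_rep(enc, SDPResult(path=(0, 1), interior=()), mention(0), mention(1))
        assert np.allclose(r.vector, [1, 2, 0, 0, 3, 4])

    def test_single_interior_token(self):
        H = np.array([[1.0, 0.0], [9.0, 9.0], [0.0, 1.0]])
        enc = manual_output(H)
        r = sdp_rep(enc, SDPResult(path=(0, 1, 2), interior=(1,)), mention(0), mention(2))
        assert np.allclose(r.vector[2:4], H[1])

    def test_middle_permutation_invariant(self, stub):
        enc = stub.encode(["a", "b", "c", "d", "e"])
        fwd = sdp_rep(enc, SDPResult((0, 1, 2, 3, 4), (1, 2, 3)), mention(0), mention(4))
        rev = sdp_rep(enc, SDPResult((0, 3, 2, 1, 4), (3, 2, 1)), mention(0), mention(4))
        assert np.allclose(fwd.vector, rev.vector)


class TestDispatch:
    def test_all_scheme_dims(self, stub):
        ex = make_example([1, -1, 1], s_anchor=0, o_anchor=2)
        enc = stub.encode(ex.tree.surfaces)
        sdp = sdp_for_example(ex)
        L = stub.config.L
        for scheme, factor in SCHEME_DIM_FACTOR.items():
            rep = build_representation(scheme, enc, ex, sdp)
            assert rep.dim == factor * L
            assert rep.scheme == scheme

    def test_cls_ignores_sdp_argument(self, stub):
        ex = make_example([1, -1, 1], s_anchor=0, o_anchor=2)
        enc = stub.encode(ex.tree.surfaces)
        with_sdp = build_representation("cls", enc, ex, sdp_for_example(ex))
        without = build_representation("cls", enc, ex, None)
        assert np.array_equal(with_sdp.vector, without.vector)

    def test_sdp_scheme_requires_path(self, stub):
        ex = make_example([1, -1, 1], s_anchor=0, o_anchor=2)
        enc = stub.encode(ex.tree.surfaces)
        with pytest.raises(ValueError, match="requires"):
            build_representation("sdp", enc, ex, None)

    def test_atlop_outer_thirds_match_ent(self, stub):
        ex = make_example([1, -1, 1], s_anchor=0, o_anchor=2)
        enc = stub.encode(ex.tree.surfaces)
        L = stub.config.L
        at = atlop_rep(enc, ex.subject, ex.object).vector
        en = ent_rep(enc, ex.subject, ex.object).vector
        assert np.array_equal(at[:L], en[:L])
        assert np.array_equal(at[2 * L:], en[L:])
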
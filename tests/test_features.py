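"""Propensity factors, composition blocks, scoring matrices, entropy and
feature-vector assembly."""

import math

import numpy as np
import pytest

from atpresi.chains import ProteinChain, fragments_of, make_fragments
from atpresi.features import (
    FragmentFeaturizer,
    PROPERTY_Q,
    composition_block,
    fit_propensity,
    fit_scoring_matrices,
    hydro_entropy,
    propensity_features,
    pwm_features,
)


def _labelled_chain(seq, labels, chain_id="t1"):
    n = len(seq)
    return ProteinChain(
        chain_id, seq, np.array([int(c) for c in labels]),
        ss=np.array(["H"] * n, dtype="U1"), rsa=np.full(n, 0.3),
        phi=np.full(n, -100.0), psi=np.full(n, 30.0),
    )


@pytest.fixture(scope="module")
def toy_fragments():
    """GGAAGA / 110000: binding centres {G,G}, non-binding {A,A,G,A}."""
    return make_fragments(_labelled_chain("GGAAGA", "110000"), L=17)


class TestPropensity:
    def test_hand_computed_toy_table(self, toy_fragments):
        table = fit_propensity(toy_fragments)
        g, a = 5, 0  # alphabetical indices of G and A
        assert table.F[g, 0] == pytest.approx(2.0)  # (2/2) / (3/6)
        assert table.F[g, 1] == pytest.approx(0.5)  # (1/4) / (3/6)
        assert table.F[a, 0] == pytest.approx(0.0)
        assert table.F[a, 1] == pytest.approx(1.5)  # (3/4) / (3/6)

    def test_identical_class_frequencies_give_unit_propensity(self):
        # same residue composition in binding and non-binding centres
        frags = make_fragments(_labelled_chain("GAGA", "1100"), L=5)
        table = fit_propensity(frags)
        assert np.allclose(table.F[[0, 5]], 1.0)  # A and G rows

    def test_unseen_residue_is_neutral(self, toy_fragments):
        table = fit_propensity(toy_fragments)
        assert np.allclose(table.F[1], 1.0)  # C never observed

    def test_single_class_rejected(self):
        frags = make_fragments(_labelled_chain("GGGG", "0000"), L=5)
        with pytest.raises(ValueError):
            fit_propensity(frags)

    def test_verbatim_form_ignores_residue_background(self, toy_fragments):
        table = fit_propensity(toy_fragments, form="verbatim")
        # every observed binding residue gets (n/2)/(2/6): G -> 3.0
        assert table.F[5, 0] == pytest.approx((2 / 2) / (2 / 6))

    def test_propensity_feature_vector(self, toy_fragments):
        table = fit_propensity(toy_fragments)
        vec = propensity_features(toy_fragments[0], table)
        assert vec.shape == (34,)
        # window of GGAAGA starts with 8 GAPs -> neutral (1, 1) pairs
        assert np.allclose(vec[:16], 1.0)
        # centre position (offset 8 -> elements 16, 17) holds G
        assert vec[16] == pytest.approx(2.0)
        assert vec[17] == pytest.approx(0.5)


class TestComposition:
    def test_counting_with_gaps(self):
        frags = make_fragments(_labelled_chain("ACD", "010"), L=17)
        block = composition_block(frags[0], "aa")
        assert block.shape == (21,)
        assert block[[0, 1, 2]] == pytest.approx(1 / 17)
        assert block[20] == pytest.approx(14 / 17)

    @pytest.mark.parametrize("prop", sorted(PROPERTY_Q))
    def test_blocks_sum_to_one(self, prop, small_fragments):
        for frag in small_fragments[:25]:
            assert composition_block(frag, prop).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_helix_window(self):
        frags = make_fragments(_labelled_chain("A" * 17, "0" * 17), L=17)
        center = frags[8]  # fully inside the chain, no GAP
        assert composition_block(center, "ss").tolist() == [1.0, 0, 0, 0]


class TestScoringMatrices:
    def test_pseudocount_hand_value(self):
        """Category unseen at a position: p = (sqrt(N)/q) / (N + sqrt(N))."""
        from atpresi.features import _pseudo_probs

        p = _pseudo_probs(np.array([0.0]), 100, 21)[0]
        assert p == pytest.approx((10 / 21) / 110)
        assert p == pytest.approx(0.004329, abs=1e-6)

    def test_matrix_matches_brute_force_recount(self):
        """m = ln(p_hat / p0) recomputed with explicit loops on a toy set."""
        chain = _labelled_chain("GAVGA", "01000")
        frags = make_fragments(chain, L=3)
        pair = fit_scoring_matrices(frags, "ss")
        pos = [f for f in frags if f.label == 1]
        n_pos, q = len(pos), 4
        # background over all 5 fragments x 3 positions
        all_codes = [0 if s == "H" else 3 for f in frags for s in f.ss]
        n_all = len(all_codes)
        p0 = [
            (all_codes.count(j) + np.sqrt(n_all) / q) / (n_all + np.sqrt(n_all))
            for j in range(q)
        ]
        for i in range(3):
            for j in range(q):
                n_ij = sum(1 for f in pos if (0 if f.ss[i] == "H" else 3) == j)
                p_ij = (n_ij + np.sqrt(n_pos) / q) / (n_pos + np.sqrt(n_pos))
                assert pair.m_pos[i, j] == pytest.approx(np.log(p_ij / p0[j]))

    def test_equal_class_sizes_with_identical_content_give_equal_matrices(self):
        frags = make_fragments(_labelled_chain("GAGA", "1010"), L=5)
        pair = fit_scoring_matrices(frags, "energy")
        # positives and negatives see different windows here, so only check
        # a property-free invariant: same class size -> same smoothing scale
        assert pair.m_pos.shape == pair.m_neg.shape == (5, 5)
        assert np.isfinite(pair.m_pos).all()

    def test_matrices_finite_and_train_only(self, small_fragments):
        pair = fit_scoring_matrices(small_fragments[:300], "aa")
        assert np.isfinite(pair.m_pos).all() and np.isfinite(pair.m_neg).all()
        assert pair.m_pos.shape == (17, 21)

    def test_count_doubling_changes_matrix_only_via_pseudocount(self, small_fragments):
        """Doubling all counts moves the log-odds only through the shrinking
        pseudocount term: tightly for the large negative class, and bounded
        for the small positive class."""
        from atpresi.features import encode_fragments

        frags = small_fragments[:400]
        codes, labels = encode_fragments(frags)
        neg = codes["energy"][labels == 0]
        counts = np.zeros((17, 5), dtype=int)
        for i in range(17):
            counts[i] = np.bincount(neg[:, i], minlength=5)
        pair1 = fit_scoring_matrices(frags, "energy")
        pair2 = fit_scoring_matrices(frags + frags, "energy")
        diff = np.abs(pair1.m_neg - pair2.m_neg)
        assert np.max(diff[counts >= 20]) < 0.05  # well-observed cells barely move
        assert np.max(diff) > 0  # ... but the pseudocount term does move
        # cells the data never supports shift by at most the pseudocount
        # decay of one doubling, ln(sqrt 2)
        assert np.max(diff) < 0.5 * np.log(2) + 0.01

    def test_pwm_feature_width(self, small_fragments):
        frags = small_fragments[:200]
        pairs = {p: fit_scoring_matrices(frags, p) for p in PROPERTY_Q}
        vec = pwm_features(frags[0], pairs)
        assert vec.shape == (204,)  # 6 properties x 2L, L = 17


class TestEntropy:
    def test_single_class_window(self):
        frags = make_fragments(_labelled_chain("A" * 17, "0" * 17), L=17)
        assert hydro_entropy(frags[8]) == pytest.approx(0.0)

    def test_ten_seven_split(self):
        frags = make_fragments(_labelled_chain("A" * 10 + "I" * 7, "0" * 17), L=17)
        expected = -(10 / 17) * math.log2(10 / 17) - (7 / 17) * math.log2(7 / 17)
        assert expected == pytest.approx(0.9774, abs=1e-4)
        assert hydro_entropy(frags[8]) == pytest.approx(expected)

    def test_bounded_by_log2_q(self, small_fragments):
        values = [hydro_entropy(f) for f in small_fragments[:50]]
        assert all(0.0 <= v <= math.log2(7) + 1e-12 for v in values)

    def test_invariant_under_class_relabeling(self, small_fragments):
        from atpresi.categories import CategoryMaps
        from atpresi.features import _N_HYDRO, _entropy_block, encode_fragments

        frag = small_fragments[0]
        codes, _ = encode_fragments([frag], CategoryMaps())
        base = _entropy_block(codes["hydro"], _N_HYDRO)[0, 0]
        permuted = (codes["hydro"] + 3) % _N_HYDRO
        assert _entropy_block(permuted, _N_HYDRO)[0, 0] == pytest.approx(base)


class TestFeaturizer:
    def test_full_layout_widths(self, small_fragments):
        fz = FragmentFeaturizer("B+F+PP+E").fit(small_fragments)
        widths = dict(fz.layout_)
        pwm_total = sum(w for name, w in fz.layout_ if name.startswith("pwm_"))
        comp_total = sum(w for name, w in fz.layout_ if name.startswith("comp_"))
        assert pwm_total == 204
        assert comp_total == 43
        assert widths["propensity"] == 34
        assert widths["entropy_hydro"] == 1
        assert fz.n_features_out_ == sum(widths.values())

    def test_feature_set_difference_is_energy_blocks(self, small_fragments):
        fz_b = FragmentFeaturizer("B").fit(small_fragments)
        fz_be = FragmentFeaturizer("B+E").fit(small_fragments)
        extra = dict(fz_be.layout_).keys() - dict(fz_b.layout_).keys()
        assert extra == {"comp_energy", "pwm_energy"}
        assert fz_be.n_features_out_ - fz_b.n_features_out_ == 5 + 34

    def test_transform_is_deterministic_and_label_free(self, small_fragments):
        fz = FragmentFeaturizer().fit(small_fragments[:300])
        test = small_fragments[300:350]
        X1 = fz.transform(test)
        X2 = fz.transform(test)
        assert np.array_equal(X1, X2)
        relabelled = [
            type(f)(f.chain_id, f.center_index, f.residues, 1 - f.label,
                    f.ss, f.rsa, f.phi, f.psi)
            for f in test
        ]
        assert np.array_equal(fz.transform(relabelled), X1)

    def test_composition_rows_sum_to_one_after_assembly(self, small_fragments):
        fz = FragmentFeaturizer("B+F+PP+E").fit(small_fragments)
        X = fz.transform(small_fragments[:20])
        offset = 0
        for name, width in fz.layout_:
            if name.startswith("comp_"):
                assert np.allclose(X[:, offset : offset + width].sum(axis=1), 1.0)
            offset += width

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(ValueError):
            FragmentFeaturizer("B+X").fit([])

    def test_unfitted_transform_rejected(self, small_fragments):
        with pytest.raises(ValueError, match="not fitted"):
            FragmentFeaturizer().transform(small_fragments[:2])

    def test_composition_permutation_invariance(self, small_fragments):
        """Composition blocks ignore window order; PWM blocks do not."""
        frag = small_fragments[40]
        reversed_frag = type(frag)(
            frag.chain_id, frag.center_index, frag.residues[::-1], frag.label,
            frag.ss[::-1].copy(), frag.rsa[::-1].copy(),
            frag.phi[::-1].copy(), frag.psi[::-1].copy(),
        )
        fz = FragmentFeaturizer("B+F+PP+E").fit(small_fragments[:300])
        a = fz.transform([frag])[0]
        b = fz.transform([reversed_frag])[0]
        offset = 0
        for name, width in fz.layout_:
            sl = slice(offset, offset + width)
            if name.startswith("comp_") or name.startswith("entropy"):
                assert np.allclose(a[sl], b[sl]), name
            offset += width
        assert not np.allclose(a, b)
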
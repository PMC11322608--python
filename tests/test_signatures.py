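import numpy as np
import pytest

from condsig.genome_io import CapAnnotations
from condsig.segmentation import Segment
from condsig.signatures import (
    CondSig,
    Signature,
    auroc,
    call_signatures,
    compute_features,
    deduplicate,
    define_negative_bins,
    filter_condsigs,
)
from condsig.topic_model import Corpus, TopicModel

from tests._oracles import auroc_brute, features_brute


def make_model(phi, theta_global=None):
    phi = np.asarray(phi, dtype=float)
    k = phi.shape[0]
    tg = np.full(k, 1 / k) if theta_global is None else np.asarray(theta_global)
    theta_doc = np.tile(tg, (3, 1))
    return TopicModel(k, phi, theta_doc, tg, 50.0 / k, 0.01, 500, 0)


def make_segment(occ, caps, bins=None):
    members = list(caps)
    q = len(members) - 1
    return Segment(
        focus_cap=members[-1],
        member_caps=members,
        beta=np.linspace(0.9, 0.1, q),
        gamma=np.zeros(q),
        bins=np.arange(occ.n_bins) if bins is None else np.asarray(bins),
        delta=np.ones(occ.n_bins if bins is None else len(bins)),
        context="non-promoter",
    )


class TestCallSignatures:
    def test_zscore_example_single_component_dropped(self, make_occ):
        # phi row (0.5, 0.3, 0.1, 0.05, 0.05): only 0.5 has z > 1.3 ->
        # 1 component < 3 -> no signature
        O = np.ones((250, 5), dtype=np.uint8)
        occ = make_occ(O, caps=list("ABCDE"))
        seg = make_segment(occ, list("ABCDE"))
        corpus = Corpus.from_documents([[0, 1] for _ in range(250)], list("ABCDE"))
        model = make_model([[0.5, 0.3, 0.1, 0.05, 0.05]])
        assert call_signatures(model, corpus, seg, occ) == []

    def test_uniform_phi_row_yields_nothing(self, make_occ):
        O = np.ones((250, 4), dtype=np.uint8)
        occ = make_occ(O, caps=list("ABCD"))
        seg = make_segment(occ, list("ABCD"))
        corpus = Corpus.from_documents([[0, 1]], list("ABCD"))
        model = make_model([[0.25, 0.25, 0.25, 0.25]])
        assert call_signatures(model, corpus, seg, occ) == []

    def test_positive_bin_threshold_is_ceiling_rule(self, make_occ):
        # 5 components out of a 15-word vocabulary; bins occupied by exactly
        # 4 of them satisfy 4 >= ceil(0.8 * 5) = 4
        n, m = 300, 15
        caps = [f"W{j:02d}" for j in range(m)]
        O = np.zeros((n, m), dtype=np.uint8)
        O[:250, :4] = 1  # 4 of 5 components
        O[250:, :5] = 1  # all 5
        occ = make_occ(O, caps=caps)
        seg = make_segment(occ, caps)
        corpus = Corpus.from_documents([[0, 1]], caps)
        # phi concentrated on first five words: z ~ 1.41 > 1.3 for them
        phi = np.full(m, 0.005)
        phi[:5] = 0.19
        sigs = call_signatures(make_model([phi]), corpus, seg, occ, min_positive=10)
        assert len(sigs) == 1
        assert sorted(sigs[0].components) == caps[:5]
        assert sigs[0].n_positive == n  # 4-of-5 bins count as positive

    def test_min_positive_filter(self, make_occ):
        caps = [f"W{j}" for j in range(10)]
        O = np.ones((100, 10), dtype=np.uint8)
        occ = make_occ(O, caps=caps)
        seg = make_segment(occ, caps)
        corpus = Corpus.from_documents([[0, 1]], caps)
        phi = np.full(10, 0.1 / 7)
        phi[:3] = 0.3  # z ~ 1.53 for the three components
        model = make_model([phi])
        assert call_signatures(model, corpus, seg, occ, min_positive=200) == []
        assert len(call_signatures(model, corpus, seg, occ, min_positive=100)) == 1


class TestNegativeBins:
    def _signature(self, occ, components, pos_rows):
        return Signature(
            id="t", focus_cap=occ.caps[-1], context="non-promoter",
            member_caps=list(occ.caps), components=components,
            component_z={c: 2.0 for c in components},
            component_prob={c: 0.2 for c in components},
            pos_rows=np.asarray(pos_rows, dtype=np.int64),
            positive_bins=occ.bin_index[np.asarray(pos_rows, dtype=np.int64)],
        )

    def test_rule_application(self, make_occ):
        # |C_pos| = 5 -> h = 4; members = 8 CAPs
        rows = [
            [1, 1, 1, 1, 1, 0, 0, 0],  # positive-like (given as pos)
            [1, 0, 0, 0, 0, 1, 1, 1],  # 4 occupied, 1 component -> negative
            [1, 1, 0, 0, 0, 1, 1, 0],  # 4 occupied, 2 components -> excluded
            [1, 0, 0, 0, 0, 1, 1, 0],  # 3 occupied -> not comparable
            [0, 0, 0, 0, 0, 1, 1, 1],  # 3 occupied -> no
        ]
        occ = make_occ(np.array(rows, dtype=np.uint8), caps=list("ABCDEFGH"))
        sig = self._signature(occ, list("ABCDE"), [0])
        neg = define_negative_bins(sig, occ, np.zeros(5, dtype=bool))
        assert list(neg) == [1]

    def test_positive_rows_never_negative(self, make_occ):
        O = np.ones((6, 5), dtype=np.uint8)
        occ = make_occ(O, caps=list("ABCDE"))
        sig = self._signature(occ, list("ABC"), [0, 1])
        neg = define_negative_bins(sig, occ, np.zeros(6, dtype=bool))
        assert not set(neg) & {0, 1}

    def test_context_matching(self, make_occ):
        O = np.zeros((4, 5), dtype=np.uint8)
        O[:, 3:] = 1
        O[:, 0] = [1, 0, 0, 0]
        occ = make_occ(O, caps=list("ABCDE"))
        sig = self._signature(occ, list("ABC"), [0])
        sig.context = "promoter"
        flags = np.array([True, True, False, False])
        neg = define_negative_bins(sig, occ, flags)
        assert set(neg) <= {1}


class TestFeatures:
    def test_worked_examples(self, make_occ, simple_annotations):
        O = np.array([[1, 1, 1, 1], [1, 1, 1, 0], [0, 0, 0, 0]], dtype=np.uint8)
        occ = make_occ(O, caps=list("ABCD"))
        f = compute_features(np.arange(3), occ, list("ABCD"), simple_annotations)
        # bin 0: occupied ABCD; LLPS = {A,B} -> 0.5; best MLO nucleolus {A,B} -> 0.5
        assert f["F_LLPS"][0] == pytest.approx(0.5)
        assert f["F_MLO"][0] == pytest.approx(0.5)
        # bin 1: occupied ABC, PPI edge A-B only -> 1/C(3,2) = 1/3
        assert f["F_PPI"][1] == pytest.approx(1 / 3)
        # bin 2: unoccupied -> excluded
        assert not f["valid"][2]
        assert np.isnan(f["F_LLPS"][2])

    def test_single_occupied_cap_has_zero_ppi(self, make_occ, simple_annotations):
        O = np.array([[1, 0, 0, 0]], dtype=np.uint8)
        occ = make_occ(O, caps=list("ABCD"))
        f = compute_features(np.array([0]), occ, list("ABCD"), simple_annotations)
        assert f["F_PPI"][0] == 0.0

    def test_matches_brute_force_on_random_bins(self, make_occ):
        rng = np.random.default_rng(21)
        caps = [f"P{j}" for j in range(8)]
        mlos = {c: set(rng.choice(["m1", "m2", "m3"], size=rng.integers(0, 3), replace=False))
                for c in caps}
        llps = {c for c in caps if rng.random() < 0.5}
        idr = {c for c in caps if rng.random() < 0.5}
        rbp = {c for c in caps if rng.random() < 0.5}
        edges = {frozenset((a, b)) for i, a in enumerate(caps) for b in caps[i + 1:]
                 if rng.random() < 0.3}
        ann = CapAnnotations(
            {c: {"is_llps": c in llps, "has_idr": c in idr, "is_rbp": c in rbp,
                 "mlos": frozenset(mlos[c]), "ps_self": 0.5, "ps_part": 0.5}
             for c in caps},
            edges,
        )
        O = (rng.random((120, 8)) < 0.4).astype(np.uint8)
        occ = make_occ(O, caps=caps)
        f = compute_features(np.arange(120), occ, caps, ann)
        for i in range(120):
            occupied = [caps[j] for j in np.nonzero(O[i])[0]]
            expect = features_brute(occupied, llps, idr, rbp, mlos, edges)
            if expect is None:
                assert not f["valid"][i]
                continue
            for name, val in expect.items():
                assert f[name][i] == pytest.approx(val, abs=1e-12), (i, name)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([2, 3], [0, 1]) == 1.0

    def test_identical_distributions_give_half(self):
        x = np.arange(10)
        assert auroc(x, x) == 0.5

    def test_tie_handling_pairwise_oracle(self):
        assert auroc([1, 0], [0, 1]) == pytest.approx((1 + 0.5 + 0.5 + 0) / 4)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            auroc([], [1.0])

    def test_matches_pairwise_count_on_random_data(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            pos = rng.integers(0, 6, size=rng.integers(1, 15)).astype(float)
            neg = rng.integers(0, 6, size=rng.integers(1, 15)).astype(float)
            assert auroc(pos, neg) == pytest.approx(auroc_brute(pos, neg), abs=1e-12)


class TestFilterCondsigs:
    def _scored(self, aurocs):
        sig = Signature(
            id="x", focus_cap="A", context="promoter", member_caps=list("ABC"),
            components=list("ABC"), component_z={}, component_prob={},
            pos_rows=np.arange(3), positive_bins=np.arange(3),
            neg_rows=np.arange(3, 6),
        )
        vals = sorted(aurocs.values(), reverse=True)
        mean3 = float(np.mean(vals[:3]))
        passing = [n for n, a in aurocs.items() if a > 0.6]
        ok = len(passing) >= 3 and mean3 > 0.65
        return CondSig(sig, aurocs, mean3, passing, ok)

    @pytest.mark.parametrize(
        "vals,expected",
        [
            ((0.70, 0.68, 0.66, 0.50, 0.50, 0.50), True),  # mean top3 = 0.68
            ((0.70, 0.62, 0.61, 0.50, 0.50, 0.50), False),  # mean top3 ~ 0.643
            ((0.90, 0.90, 0.55, 0.50, 0.50, 0.50), False),  # only 2 pass
        ],
    )
    def test_pass_rule_arithmetic(self, vals, expected):
        names = ["F_LLPS", "F_MLO", "F_IDR", "F_PPI", "F_RBP", "S_RBS"]
        cs = self._scored(dict(zip(names, vals)))
        assert cs.is_condsig is expected

    def test_signature_without_negatives_is_not_condsig(self, make_occ, simple_annotations):
        O = np.ones((5, 4), dtype=np.uint8)
        occ = make_occ(O, caps=list("ABCD"))
        sig = Signature(
            id="x", focus_cap="D", context="promoter", member_caps=list("ABCD"),
            components=list("ABC"), component_z={}, component_prob={},
            pos_rows=np.arange(5), positive_bins=np.arange(5),
        )  # neg_rows left empty
        out = filter_condsigs([sig], occ, simple_annotations)
        assert len(out) == 1 and not out[0].is_condsig

    def test_partition_of_scored_universe(self, make_occ):
        rng = np.random.default_rng(17)
        O = (rng.random((200, 6)) < 0.5).astype(np.uint8)
        occ = make_occ(O, caps=list("ABCDEF"))
        pos = np.nonzero(O[:, :4].sum(axis=1) >= 4)[0]
        sig = Signature(
            id="x", focus_cap="F", context="non-promoter", member_caps=list("ABCDEF"),
            components=list("ABCD"), component_z={}, component_prob={},
            pos_rows=pos, positive_bins=pos,
        )
        neg = define_negative_bins(sig, occ, np.zeros(200, dtype=bool))
        assert not set(pos) & set(neg)


class TestDeduplicate:
    def _condsig(self, name, components, mean3, probs=None):
        probs = probs or {c: 1.0 - i * 0.01 for i, c in enumerate(components)}
        sig = Signature(
            id=name, focus_cap=components[0], context="promoter",
            member_caps=components, components=list(components),
            component_z={}, component_prob=probs,
            pos_rows=np.arange(1), positive_bins=np.arange(1),
        )
        return CondSig(sig, {}, mean3, [], True)

    def test_identical_top5_keeps_higher_scoring(self):
        a = self._condsig("a", list("ABCDE"), 0.9)
        b = self._condsig("b", list("ABCDE"), 0.7)
        kept = deduplicate([a, b])
        assert [c.id for c in kept] == ["a"]

    def test_three_of_union_seven_dropped(self):
        a = self._condsig("a", list("ABCDE"), 0.9)
        b = self._condsig("b", list("ABCFG"), 0.7)  # overlap 3, union 7 -> 0.429
        assert [c.id for c in deduplicate([a, b])] == ["a"]

    def test_disjoint_sets_both_kept(self):
        a = self._condsig("a", list("ABCDE"), 0.9)
        b = self._condsig("b", list("FGHIJ"), 0.7)
        assert len(deduplicate([a, b])) == 2

    def test_output_contract_on_random_sets(self):
        rng = np.random.default_rng(3)
        pool = [f"c{j}" for j in range(12)]
        condsigs = []
        for i in range(60):
            comps = list(rng.choice(pool, size=6, replace=False))
            condsigs.append(self._condsig(f"s{i}", comps, float(rng.random())))
        kept = deduplicate(condsigs)
        tops = [c.top_components(5) for c in kept]
        for i in range(len(tops)):
            for j in range(i + 1, len(tops)):
                jac = len(tops[i] & tops[j]) / len(tops[i] | tops[j])
                assert jac <= 0.25
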
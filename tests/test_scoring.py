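"""Embedding backends, pair construction, similarity and AUC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from retinasample import synth
from retinasample.scoring import (GridStatsBackend, build_pairs, correctness,
                                  default_backends, mann_whitney_auc,
                                  normalized_similarity)


def brute_force_auc(match, nonmatch):
    """Independent oracle: enumerate all match x non-match pairs."""
    wins = ties = 0
    for m, n in itertools.product(match, nonmatch):
        if m > n:
            wins += 1
        elif m == n:
            ties += 1
    return (wins + 0.5 * ties) / (len(match) * len(nonmatch))


class TestReferenceBackend:
    def test_deterministic(self):
        rng = np.random.default_rng(0)
        img = rng.random((224, 224))
        be = GridStatsBackend(8)
        assert np.array_equal(be.embed(img), be.embed(img))
        assert be.embed(img).shape == (384,)

    def test_translation_sensitive(self):
        rng = np.random.default_rng(1)
        img = rng.random((224, 224))
        be = GridStatsBackend(8)
        assert np.linalg.norm(be.embed(img) - be.embed(np.roll(img, 1, axis=1))) > 0

    def test_non_finite_rejected(self):
        img = np.full((224, 224), np.nan)
        with pytest.raises(ValueError):
            GridStatsBackend(8).embed(img)

    def test_grid_must_divide_image(self):
        with pytest.raises(ValueError):
            GridStatsBackend(9)

    def test_same_identity_closer_than_different(self):
        """Across 50 identities, the two expressions of an identity embed
        closer together than images of different identities — the property
        that makes the descriptor usable for identity matching at all."""
        _, stimuli = synth.generate_identities(50, image_size=224, seed=21)
        be = GridStatsBackend(8)
        vecs = {k: be.embed(s.pixels) for k, s in stimuli.items()}
        within = [np.linalg.norm(vecs[(f"id{i:03d}", "neutral")]
                                 - vecs[(f"id{i:03d}", "happy")])
                  for i in range(50)]
        rng = np.random.default_rng(3)
        between = []
        for _ in range(200):
            i, j = rng.choice(50, size=2, replace=False)
            between.append(np.linalg.norm(vecs[(f"id{i:03d}", "neutral")]
                                          - vecs[(f"id{j:03d}", "happy")]))
        assert np.mean(within) < np.mean(between)

    def test_default_ensemble_names_unique(self):
        names = [b.name for b in default_backends()]
        assert len(set(names)) == len(names) >= 2


@pytest.fixture(scope="module")
def identities():
    ids, _ = synth.generate_identities(6, image_size=224, seed=3)
    return ids


class TestBuildPairs:
    def test_one_match_one_nonmatch_per_probe(self, identities):
        probes = [{"identity_id": "id000", "expression": "neutral",
                   "trial_id": "t0"}]
        pairs = build_pairs(probes, identities, seed=0)
        assert len(pairs) == 2
        assert sum(p["is_match"] for p in pairs) == 1

    def test_balanced_counts(self, identities):
        probes = [{"identity_id": f"id{i:03d}", "expression": "neutral",
                   "trial_id": f"t{i}"} for i in range(6) for _ in range(3)]
        pairs = build_pairs(probes, identities, seed=1)
        assert len(pairs) == 2 * len(probes)
        assert sum(p["is_match"] for p in pairs) == len(probes)

    def test_match_gallery_other_expression_same_identity(self, identities):
        pairs = build_pairs([{"identity_id": "id001", "expression": "happy",
                              "trial_id": "t"}], identities, seed=0)
        match = next(p for p in pairs if p["is_match"])
        assert match["gallery_identity"] == "id001"
        assert match["gallery_expression"] == "neutral"

    def test_nonmatch_partner_shares_demographics(self, identities):
        demo = {i.identity_id: i.demographics for i in identities}
        probes = [{"identity_id": f"id{i:03d}", "expression": "neutral",
                   "trial_id": f"t{i}"} for i in range(6)]
        for p in build_pairs(probes, identities, seed=2):
            if not p["is_match"]:
                assert p["gallery_identity"] != p["identity_id"]
                assert demo[p["gallery_identity"]] == demo[p["identity_id"]]

    def test_missing_peer_error(self, identities):
        lonely = synth.SyntheticIdentity(
            identity_id="lone", feature_patches=[],
            demographics={"gender": "X", "ethnicity": "X", "age_band": "X"},
            diagnosticity_map=identities[0].diagnosticity_map)
        with pytest.raises(ValueError):
            build_pairs([{"identity_id": "lone", "expression": "neutral",
                          "trial_id": "t"}], [*identities, lonely], seed=0)


class TestSimilarity:
    def test_endpoints(self):
        sim = normalized_similarity([0.0, 2.0, 5.0])
        assert sim[0] == 1.0 and sim[2] == 0.0

    def test_order_reversal(self):
        d = np.array([3.0, 1.0, 4.0, 1.5, 2.0])
        sim = normalized_similarity(d)
        assert np.array_equal(np.argsort(sim), np.argsort(-d, kind="stable"))

    def test_degenerate_backend_warns_and_returns_half(self):
        with pytest.warns(UserWarning):
            sim = normalized_similarity([2.0, 2.0, 2.0])
        assert np.all(sim == 0.5)

    def test_correctness_reversal(self):
        sim = np.array([0.9, 0.2])
        out = correctness(sim, np.array([True, False]))
        assert out[0] == pytest.approx(0.9) and out[1] == pytest.approx(0.8)


class TestAUC:
    def test_perfect_separation(self):
        assert mann_whitney_auc([0.9, 0.9], [0.1, 0.1, 0.1]) == 1.0

    def test_hand_computed_example(self):
        """3 match {0.8, 0.6, 0.4} vs 2 non-match {0.5, 0.3}: of the 6
        comparisons only 0.4 vs 0.5 loses, no ties -> AUC = 5/6."""
        got = mann_whitney_auc([0.8, 0.6, 0.4], [0.5, 0.3])
        assert got == pytest.approx(5.0 / 6.0)
        assert got == pytest.approx(brute_force_auc([0.8, 0.6, 0.4], [0.5, 0.3]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(2, 30))
        n = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(2, 30))
        assert mann_whitney_auc(m, n) == pytest.approx(brute_force_auc(m, n))

    def test_matches_sklearn(self):
        rng = np.random.default_rng(9)
        m, n = rng.random(40), rng.random(60) - 0.2
        expected = roc_auc_score([1] * 40 + [0] * 60, np.concatenate([m, n]))
        assert mann_whitney_auc(m, n) == pytest.approx(expected)

    def test_shuffled_labels_near_half(self):
        """Identity-uninformative scores give AUC ~ 0.5 over 100 shuffles."""
        rng = np.random.default_rng(4)
        scores = rng.random(200)
        aucs = []
        for _ in range(100):
            perm = rng.permutation(200)
            aucs.append(mann_whitney_auc(scores[perm[:100]], scores[perm[100:]]))
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        assert lo <= 0.5 <= hi

    def test_empty_class_error(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([], [0.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                    min_size=1, max_size=12),
           st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                    min_size=1, max_size=12))
    def test_rank_formula_equals_enumeration(self, m, n):
        """Property: the rank-based AUC equals brute-force enumeration for any
        score lists, including heavy ties."""
        assert mann_whitney_auc(m, n) == pytest.approx(brute_force_auc(m, n))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=20,
                    unique=True))
    def test_complement_symmetry(self, d):
        """Property: swapping the classes reflects AUC around 0.5."""
        m, n = d[: len(d) // 2] or [d[0]], d[len(d) // 2:]
        assert mann_whitney_auc(m, n) == pytest.approx(1.0 - mann_whitney_auc(n, m))
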
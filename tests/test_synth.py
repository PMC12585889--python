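"""Synthetic identities, stimuli, policies and gaze traces."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from retinasample import synth
from retinasample.events import detect_fixations


class TestIdentities:
    def test_deterministic_under_fixed_seed(self):
        a_ids, a_stim = synth.generate_identities(2, image_size=224, seed=1)
        b_ids, b_stim = synth.generate_identities(2, image_size=224, seed=1)
        assert len(a_ids) == 2 and len(a_stim) == 4
        for key in a_stim:
            assert np.array_equal(a_stim[key].pixels, b_stim[key].pixels)
        for a, b in zip(a_ids, b_ids):
            assert np.array_equal(a.diagnosticity_map, b.diagnosticity_map)
            assert a.demographics == b.demographics

    def test_different_seed_different_stimuli(self):
        _, a = synth.generate_identities(2, image_size=224, seed=1)
        _, b = synth.generate_identities(2, image_size=224, seed=2)
        assert not np.array_equal(a[("id000", "neutral")].pixels,
                                  b[("id000", "neutral")].pixels)

    def test_too_few_identities_error(self):
        with pytest.raises(ValueError):
            synth.generate_identities(1, seed=0)

    @pytest.mark.parametrize("n", [2, 5, 20])
    def test_every_identity_has_demographic_peer(self, n):
        ids, _ = synth.generate_identities(n, image_size=224, seed=7)
        demo = [tuple(sorted(i.demographics.items())) for i in ids]
        for i, d in enumerate(demo):
            assert any(j != i and dj == d for j, dj in enumerate(demo))

    def test_expression_differs_only_in_expression_regions(self, small_cohort):
        identities, stimuli, mask = small_cohort
        expr_region = np.isin(mask.labels,
                              [mask.legend["mouth"], mask.legend["brow"]])
        for ident in identities:
            diff = np.abs(stimuli[(ident.identity_id, "neutral")].pixels
                          - stimuli[(ident.identity_id, "happy")].pixels)
            assert diff[~expr_region].max() == 0.0
            assert diff[expr_region].mean() > 0.01

    def test_diagnosticity_map_invariants(self, small_cohort):
        identities, stimuli, mask = small_cohort
        shape = stimuli[("id000", "neutral")].pixels.shape
        peaks = []
        for ident in identities:
            d = ident.diagnosticity_map
            assert d.shape == shape
            assert np.isfinite(d).all() and (d >= 0).all() and d.max() <= 1.0
            assert len(ident.feature_patches) >= 2
            regions_hit = {mask.label_at(x, y)
                           for _, x, y, _ in ident.feature_patches}
            assert len(regions_hit - {"background"}) >= 2
            peaks.append(np.unravel_index(np.argmax(d), d.shape))
        # identity-specific: not all identities peak at the same location
        assert len(set(peaks)) > 1


class TestGazeTraces:
    def test_low_rate_rejected(self, small_cohort):
        identities, stimuli, _ = small_cohort
        pol = synth.default_policies(224)["random"]
        with pytest.raises(ValueError):
            synth.generate_gaze_trace(pol, stimuli[("id000", "neutral")],
                                      rate_hz=30, seed=0)

    def test_trace_invariants(self, small_cohort, geometry224):
        identities, stimuli, _ = small_cohort
        pol = synth.default_policies(224)["super"]
        tr = synth.generate_gaze_trace(pol, stimuli[("id000", "neutral")],
                                       geometry224, seed=4,
                                       diagnosticity_map=identities[0].diagnosticity_map)
        assert (np.diff(tr.t_ms) > 0).all()
        assert tr.t_ms[-1] < 5000.0 and len(tr.t_ms) == 600
        w, h = geometry224.screen_resolution
        assert (tr.x_px[tr.valid] >= 0).all() and (tr.x_px[tr.valid] <= max(w, 224)).all()

    def test_single_dwell_yields_one_fixation(self, small_cohort, geometry224):
        identities, stimuli, _ = small_cohort
        pol = synth.ObserverPolicy("random", n_fixations_mean=1.0,
                                   jitter_sd_deg=0.0)
        tr = synth.generate_gaze_trace(pol, stimuli[("id000", "neutral")],
                                       geometry224, seed=0)
        fixes = detect_fixations(tr, geometry224)
        assert len(fixes) == 1
        assert fixes[0].duration == pytest.approx(5000.0, rel=0.01)

    def test_determinism(self, small_cohort, geometry224):
        identities, stimuli, _ = small_cohort
        pol = synth.default_policies(224)["control"]
        kwargs = dict(geometry=geometry224, seed=9,
                      diagnosticity_map=identities[1].diagnosticity_map)
        a = synth.generate_gaze_trace(pol, stimuli[("id001", "neutral")], **kwargs)
        b = synth.generate_gaze_trace(pol, stimuli[("id001", "neutral")], **kwargs)
        assert np.array_equal(a.x_px, b.x_px) and np.array_equal(a.y_px, b.y_px)


def _sampled_diagnosticity(policy, stimulus, diag, geometry, n_traces, seed0):
    """Mean diagnosticity at detected fixation centroids, one value per trace."""
    out = []
    size = stimulus.pixels.shape[0]
    for s in range(n_traces):
        tr = synth.generate_gaze_trace(policy, stimulus, geometry,
                                       seed=seed0 + s, diagnosticity_map=diag)
        vals = [diag[int(round(f.y)), int(round(f.x))]
                for f in detect_fixations(tr, geometry)
                if 0 <= round(f.x) < size and 0 <= round(f.y) < size]
        if vals:
            out.append(float(np.mean(vals)))
    return np.array(out)


@pytest.fixture(scope="module")
def sampled(small_cohort, geometry224):
    identities, stimuli, _ = small_cohort
    stim = stimuli[("id000", "neutral")]
    diag = identities[0].diagnosticity_map
    pols = synth.default_policies(224)
    return {name: _sampled_diagnosticity(pols[name], stim, diag,
                                         geometry224, 80, 1000)
            for name in ("random", "control", "super")}


class TestPolicyOrdering:
    def test_mean_sampled_diagnosticity_ordered(self, sampled):
        """super > control > random, each gap significant by rank test."""
        assert sampled["super"].mean() > sampled["control"].mean() > sampled["random"].mean()
        for hi, lo in (("super", "control"), ("control", "random")):
            p = mannwhitneyu(sampled[hi], sampled[lo], alternative="greater").pvalue
            assert p < 0.01

    def test_high_targeting_beats_zero(self, small_cohort, geometry224):
        identities, stimuli, _ = small_cohort
        stim = stimuli[("id002", "neutral")]
        diag = identities[2].diagnosticity_map
        base = synth.default_policies(224)["random"]
        hot = synth.ObserverPolicy("super", spread_sigma=base.spread_sigma,
                                   targeting_weight=0.9)
        cold = _sampled_diagnosticity(base, stim, diag, geometry224, 40, 500)
        warm = _sampled_diagnosticity(hot, stim, diag, geometry224, 40, 500)
        assert warm.mean() > cold.mean()

    def test_zero_targeting_fixations_identity_agnostic(self, small_cohort,
                                                        geometry224):
        """With targeting off, fixations score no higher on the viewed
        identity's own diagnosticity map than on other identities' maps;
        with strong targeting the own map dominates."""
        identities, stimuli, _ = small_cohort
        maps = {i.identity_id: i.diagnosticity_map for i in identities}

        def map_scores(policy, seed0):
            out = {}
            for ident in identities:
                stim = stimuli[(ident.identity_id, "neutral")]
                pts = []
                for s in range(60):
                    tr = synth.generate_gaze_trace(
                        policy, stim, geometry224, seed=seed0 + s,
                        diagnosticity_map=maps[ident.identity_id])
                    pts += [(int(round(f.y)), int(round(f.x)))
                            for f in detect_fixations(tr, geometry224)
                            if 0 <= round(f.x) < 224 and 0 <= round(f.y) < 224]
                out[ident.identity_id] = {iid: float(np.mean([m[p] for p in pts]))
                                          for iid, m in maps.items()}
            return out

        random_pol = synth.default_policies(224)["random"]
        hot = synth.ObserverPolicy("super", spread_sigma=random_pol.spread_sigma,
                                   targeting_weight=0.9)
        cold_scores = map_scores(random_pol, 4000)
        hot_scores = map_scores(hot, 4000)

        # untargeted viewing: the viewed identity's own map is top-scoring no
        # more often than chance (1 in 6)
        tops = sum(max(s, key=s.get) == iid for iid, s in cold_scores.items())
        assert tops <= 2
        # targeting boosts the own-map score more than other identities' maps
        # (difference-in-differences isolates identity-specific targeting from
        # mere face-centrality of the maps)
        wins = 0
        for iid in maps:
            did_own = hot_scores[iid][iid] - cold_scores[iid][iid]
            did_other = np.mean([hot_scores[iid][j] - cold_scores[iid][j]
                                 for j in maps if j != iid])
            wins += did_own > did_other
        assert wins >= 5
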
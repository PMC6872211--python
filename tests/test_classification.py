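"""Cell-type assignment: grouping, thresholds, scoring, decision tree."""

import numpy as np
import pytest

from rgcsample import classification, synthetic, templates
from rgcsample.classification import (
    GROUP_ABOVE,
    GROUP_BELOW,
    GROUP_BETWEEN,
    GROUP_BISTRATIFIED,
    NON_CLASSIFIABLE,
    CellFeatures,
    assign_stratification_group,
    calibrate_thresholds,
    decision_tree,
    score_templates,
)
from rgcsample.core import (
    CalibrationError,
    ConfigError,
    StratificationProfile,
    UnclassifiableProfileError,
    profile_grid_centers,
)


def gaussian_profile(depth, sd=0.06, n_bins=120, weights=None):
    """Helper: normalized (mixture of) Gaussian profile(s)."""
    centers = profile_grid_centers(n_bins)
    depths = np.atleast_1d(depth)
    sds = np.broadcast_to(np.atleast_1d(sd), depths.shape)
    weights = np.ones_like(depths) if weights is None else np.asarray(weights)
    density = np.zeros(n_bins)
    for d, s, w in zip(depths, sds, weights):
        density += w * np.exp(-0.5 * ((centers - d) / s) ** 2) / s
    return StratificationProfile(density=density / density.sum(), n_bins=n_bins)


class TestStratificationGroup:
    @pytest.mark.parametrize("depth,expected", [
        (0.5, GROUP_BETWEEN),
        (1.4, GROUP_BELOW),
        (-0.3, GROUP_ABOVE),
    ])
    def test_single_peak_groups(self, depth, expected):
        assert assign_stratification_group(gaussian_profile(depth)) == expected

    def test_equal_peaks_on_both_bands_is_bistratified(self):
        prof = gaussian_profile([0.0, 1.0], sd=[0.06, 0.06], weights=[1, 1])
        assert assign_stratification_group(prof) == GROUP_BISTRATIFIED

    def test_flat_profile_unclassifiable(self):
        flat = StratificationProfile(density=np.full(120, 1 / 120))
        with pytest.raises(UnclassifiableProfileError):
            assign_stratification_group(flat)


class TestCalibrateThresholds:
    def test_perfect_correlations_give_threshold_one(self, library):
        identified = [(library[n].profile, n) for n in
                      ("1wt", "4ow", "6sw", "8w", "37c", "37d", "2an", "63")]
        thr = calibrate_thresholds(identified, library)
        assert thr.correlation == pytest.approx(1.0)

    def test_squared_lower_quartile_matches_independent_oracle(self, library):
        # mix each template with noise, then verify the threshold equals the
        # squared linearly-interpolated Q1 of independently recomputed scores
        rng = np.random.default_rng(10)
        names = ["1wt", "4ow", "6sw", "8w", "2an", "63", "6t", "37c", "37r", "8w"]
        identified = [(synthetic.profile_draw(library, n, 0.15, rng), n)
                      for n in names]
        thr = calibrate_thresholds(identified, library)
        corrs = [np.corrcoef(p.density, library[n].profile.density)[0, 1]
                 for p, n in identified]
        sims = [1.0 / (1.0 + np.linalg.norm(p.density - library[n].profile.density))
                for p, n in identified]
        assert thr.correlation == pytest.approx(np.percentile(corrs, 25) ** 2, abs=1e-12)
        assert thr.distance_similarity == pytest.approx(np.percentile(sims, 25) ** 2,
                                                        abs=1e-12)

    def test_too_few_identified_cells_raise(self, library):
        with pytest.raises(CalibrationError):
            calibrate_thresholds([(library["1wt"].profile, "1wt")] * 3, library)


class TestScoreTemplates:
    def test_query_equal_to_template_is_perfect_candidate(self, library, thresholds):
        for name in ("6sn", "1wt", "9n"):
            res = score_templates(library[name].profile, library,
                                  thresholds=thresholds)
            assert res.correlations[name] == pytest.approx(1.0)
            assert res.distances[name] == pytest.approx(0.0, abs=1e-12)
            assert name in res.candidates

    def test_smi32_marker_restricts_universe_to_alpha_templates(self, library,
                                                                thresholds):
        res = score_templates(library["8w"].profile, library, marker="SMI32",
                              thresholds=thresholds)
        assert set(res.correlations) == {"1wt", "4ow", "6sw", "8w", "W7b"}

    def test_unmarked_noise_profile_is_non_classifiable(self, library, thresholds):
        rng = np.random.default_rng(11)
        noise = rng.uniform(0.5, 1.5, 120)
        # a rough multi-bump profile orthogonal to every template
        noise[::7] += 4.0
        prof = StratificationProfile(density=noise / noise.sum())
        res = score_templates(prof, library, thresholds=thresholds,
                              group=GROUP_BETWEEN)
        result = decision_tree(res, CellFeatures(200.0, 150.0, prof), library)
        assert result.final_label == NON_CLASSIFIABLE

    def test_marked_cell_below_threshold_keeps_best_match(self, library, thresholds):
        prof = gaussian_profile(0.3, sd=0.25)  # poor match to every alpha
        res = score_templates(prof, library, marker="SMI32", thresholds=thresholds)
        assert len(res.candidates) == 1  # best match kept


class TestDecisionTree:
    def run(self, library, thresholds, discriminators, profile, diameter,
            soma=150.0, marker=None):
        res = score_templates(profile, library, marker=marker,
                              thresholds=thresholds)
        feats = CellFeatures(diameter_um=diameter, soma_area_um2=soma,
                             profile=profile)
        return decision_tree(res, feats, library, discriminators=discriminators)

    def test_size_splits_transient_on_alpha_pair(self, library, thresholds,
                                                 discriminators):
        prof = library["6sn"].profile  # same stratification as 6sw
        big = self.run(library, thresholds, discriminators, prof, diameter=320)
        small = self.run(library, thresholds, discriminators, prof, diameter=160)
        assert big.final_label == "6sw"
        assert small.final_label == "6sn"

    def test_inner_pair_returns_merged_label(self, library, thresholds,
                                             discriminators):
        res = self.run(library, thresholds, discriminators,
                       library["8n"].profile, diameter=190)
        assert res.final_label == "8n/9n"

    def test_very_large_soma_selects_sustained_on_alpha(self, library, thresholds,
                                                        discriminators):
        res = self.run(library, thresholds, discriminators,
                       library["8w"].profile, diameter=330, soma=380)
        assert res.final_label == "8w"

    def test_self_recovery_on_low_noise_draw(self, library, thresholds,
                                             discriminators):
        rng = np.random.default_rng(12)
        prof = synthetic.profile_draw(library, "5si", 0.03, rng)
        res = self.run(library, thresholds, discriminators, prof, diameter=190)
        assert res.final_label == "5si"

    def test_decision_trace_is_deterministic(self, library, thresholds,
                                             discriminators):
        rng = np.random.default_rng(13)
        prof = synthetic.profile_draw(library, "73", 0.1, rng)
        a = self.run(library, thresholds, discriminators, prof, diameter=205)
        b = self.run(library, thresholds, discriminators, prof, diameter=205)
        assert a.final_label == b.final_label
        assert a.decision_trace == b.decision_trace

    def test_every_template_self_consistent(self, library, thresholds,
                                            discriminators):
        # each library template, fed back with its own marker context, is
        # assigned its own merged label
        for t in library:
            marker = next(iter(t.markers)) if t.markers else None
            res = self.run(library, thresholds, discriminators, t.profile,
                           diameter=t.nominal_diameter_um,
                           soma=t.nominal_soma_area_um2, marker=marker)
            assert res.final_label == library.merged_label(t.name), t.name

    def test_marker_constraint_never_violated(self, library, thresholds,
                                              discriminators):
        rng = np.random.default_rng(14)
        for marker in ("SMI32", "CART", "FOXP2"):
            allowed = {library.merged_label(n) for n in library.compatible(marker)}
            for name in library.compatible(marker):
                for _ in range(10):
                    prof = synthetic.profile_draw(library, name, 0.15, rng)
                    res = self.run(library, thresholds, discriminators, prof,
                                   diameter=library[name].nominal_diameter_um,
                                   marker=marker)
                    assert res.final_label in allowed


class TestMergedLabels:
    def test_full_em_library_yields_37_labels(self, library):
        assert len(templates.merged_label_set(library)) == 37

    def test_merge_arithmetic(self, library):
        # 47 raw - 4 pair merges - 3 (ON-OFF DS 4->1) - 3 (ON DS 4->1) = 37
        n_raw = len(library.em_names())
        assert n_raw == 47
        assert n_raw - 4 - 3 - 3 == len(templates.merged_label_set(library))

    def test_empty_merge_map_returns_47(self, library):
        bare = templates.TemplateLibrary(
            templates=dict(library.templates), n_bins=library.n_bins, merge_map={})
        assert len(templates.merged_label_set(bare)) == 47

    def test_library_has_56_templates(self, library):
        assert len(library) == 56
        sources = {t.source for t in library}
        assert sources == {"EM", "HD-set", "Cdh3/W7b-set", "FOXP2-set"}


class TestOverride:
    def make_result(self, library, thresholds):
        return score_templates(library["6sn"].profile, library,
                               thresholds=thresholds)

    def test_override_replaces_label_and_sets_flag(self, library, thresholds):
        res = decision_tree(self.make_result(library, thresholds),
                            CellFeatures(160, 140, library["6sn"].profile), library)
        new = classification.apply_override(res, "8w", "expert call", library)
        assert new.final_label == "8w"
        assert new.override
        assert res.final_label == "6sn"  # original untouched
        assert any("override" in line for line in new.decision_trace)

    def test_override_to_same_label_is_noop_except_flag(self, library, thresholds):
        res = decision_tree(self.make_result(library, thresholds),
                            CellFeatures(160, 140, library["6sn"].profile), library)
        new = classification.apply_override(res, res.final_label, "confirm", library)
        assert new.final_label == res.final_label
        assert new.override

    def test_unknown_override_label_rejected(self, library, thresholds):
        res = self.make_result(library, thresholds)
        with pytest.raises(ConfigError):
            classification.apply_override(res, "not-a-type", "oops", library)

    def test_audit_trail_counts_overrides(self, library, thresholds):
        results = []
        for name in ("6sn", "1wt", "9n"):
            res = decision_tree(
                score_templates(library[name].profile, library, thresholds=thresholds),
                CellFeatures(library[name].nominal_diameter_um, 150,
                             library[name].profile), library)
            results.append(res)
        overridden = [classification.apply_override(res, "8w", "audit", library)
                      for res in results[:2]]
        session = overridden + results[2:]
        assert sum(r.override for r in session) == 2
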
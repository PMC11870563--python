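"""Split-half matching, component classification, template assembly."""

import itertools

import numpy as np
import pytest

from petica.template import (
    ComponentPair,
    Template,
    build_template,
    classify_components,
    match_components,
    split_half,
)
from petica.volumes import BrainMask, ValidationError


class TestSplitHalf:
    def test_296_subjects_split_148_148(self):
        a, b = split_half([f"s{i}" for i in range(296)], seed=0)
        assert len(a) == 148 and len(b) == 148
        assert set(a).isdisjoint(b)
        assert set(a) | set(b) == {f"s{i}" for i in range(296)}

    def test_odd_count_differs_by_one(self):
        a, b = split_half(list(range(5)), seed=1)
        assert sorted([len(a), len(b)]) == [2, 3]
        assert set(a).isdisjoint(b)

    def test_stratified_split_balances_ages(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(55, 90, 200)
        a, b = split_half(list(range(200)), seed=1, stratify_by=ages)
        diff = abs(ages[a].mean() - ages[b].mean())
        assert diff < 0.25 * ages.std()

    def test_too_few_subjects(self):
        with pytest.raises(ValidationError):
            split_half([1, 2, 3])


class TestMatching:
    def test_permuted_identity_recovers_permutation(self):
        rng = np.random.default_rng(0)
        S = rng.normal(size=(5, 300))
        perm = [3, 0, 4, 1, 2]
        pairs = match_components(S, S[perm])
        for p in pairs:
            assert perm[p.index_b] == p.index_a
            assert p.r == pytest.approx(1.0)
            assert p.sign == 1

    def test_sign_flip_detected(self):
        rng = np.random.default_rng(1)
        S = rng.normal(size=(4, 300))
        pairs = match_components(S, -S)
        for p in pairs:
            assert p.index_a == p.index_b
            assert p.r == pytest.approx(1.0)
            assert p.sign == -1

    def test_assignment_total_matches_exhaustive_search(self):
        # brute-force oracle: enumerate all 120 permutations of 5 components
        rng = np.random.default_rng(2)
        S_A = rng.normal(size=(5, 100))
        S_B = rng.normal(size=(5, 100))
        pairs = match_components(S_A, S_B)
        total = sum(p.r for p in pairs)

        R = np.abs(np.corrcoef(np.vstack([S_A, S_B]))[:5, 5:])
        best = max(
            sum(R[i, perm[i]] for i in range(5))
            for perm in itertools.permutations(range(5))
        )
        assert total == pytest.approx(best)

    def test_matching_is_symmetric(self):
        rng = np.random.default_rng(3)
        S_A = rng.normal(size=(4, 200))
        S_B = rng.normal(size=(4, 200))
        ab = {(p.index_a, p.index_b) for p in match_components(S_A, S_B)}
        ba = {(p.index_b, p.index_a) for p in match_components(S_B, S_A)}
        assert ab == ba

    def test_rectangular_inputs_report_partial_matching(self):
        rng = np.random.default_rng(4)
        S_A = rng.normal(size=(3, 200))
        S_B = rng.normal(size=(5, 200))
        pairs = match_components(S_A, S_B)
        assert len(pairs) == 3


class TestClassification:
    def _setup(self):
        rng = np.random.default_rng(0)
        V = 1000
        wm = np.zeros(V, bool)
        wm[:200] = True
        vent = np.zeros(V, bool)
        vent[200:350] = True
        return rng, V, {"white_matter": wm, "ventricle": vent}

    def test_exact_wm_map_classified_white_matter(self):
        rng, V, masks = self._setup()
        comp = np.where(masks["white_matter"], 5.0, 0.0) + rng.normal(0, 0.01, V)
        cats = classify_components(comp[None, :], masks)
        assert cats == ["white_matter"]

    def test_component_outside_confounds_is_candidate(self):
        rng, V, masks = self._setup()
        comp = np.zeros(V)
        comp[400:430] = 8.0
        cats = classify_components(comp[None, :] + rng.normal(0, 0.01, V), masks)
        assert cats == ["candidate"]

    def test_sixty_percent_ventricle_overlap_counted_directly(self):
        rng, V, masks = self._setup()
        n_top = max(1, round(0.05 * V))  # 50 voxels
        comp = np.zeros(V)
        vent_idx = np.where(masks["ventricle"])[0][:30]   # 60% of top voxels
        other_idx = np.arange(500, 520)                    # 40% elsewhere
        comp[vent_idx] = 10.0
        comp[other_idx] = 9.0
        cats = classify_components(comp[None, :], masks)
        # direct counting oracle
        z = (comp - comp.mean()) / comp.std()
        top = np.argsort(np.abs(z))[-n_top:]
        frac = masks["ventricle"][top].mean()
        assert frac == pytest.approx(0.6)
        assert cats == ["ventricle"]

    def test_manual_override_wins(self):
        rng, V, masks = self._setup()
        comp = np.where(masks["white_matter"], 5.0, 0.0)
        cats = classify_components(
            comp[None, :], masks, overrides={0: "candidate"}
        )
        assert cats == ["candidate"]

    def test_override_out_of_range(self):
        _, V, masks = self._setup()
        with pytest.raises(ValidationError):
            classify_components(np.zeros((1, V)), masks, overrides={3: "edge"})


def _pairs_with(r_values):
    return [
        ComponentPair(index_a=i, index_b=i, r=r, sign=1)
        for i, r in enumerate(r_values)
    ]


class TestBuildTemplate:
    def test_retained_map_is_mean_of_aligned_zscored_parents(self):
        rng = np.random.default_rng(0)
        S_A = rng.normal(size=(2, 400))
        S_B = -S_A + rng.normal(0, 0.05, (2, 400))  # sign-flipped noisy copy
        pairs = match_components(S_A, S_B)
        tpl = build_template(S_A, S_B, pairs, ["candidate"] * 2, ["candidate"] * 2)
        assert tpl.n_retained == 2

        def z(v):
            return (v - v.mean()) / v.std()

        for k, p in enumerate(sorted(pairs, key=lambda p: -p.r)):
            expected = z(0.5 * (z(S_A[p.index_a]) + p.sign * z(S_B[p.index_b])))
            assert np.allclose(tpl.maps[k], expected, atol=1e-12)

    def test_threshold_one_retains_nothing(self):
        rng = np.random.default_rng(1)
        S_A = rng.normal(size=(3, 200))
        S_B = rng.normal(size=(3, 200))
        pairs = match_components(S_A, S_B)
        with pytest.warns(UserWarning):
            tpl = build_template(
                S_A, S_B, pairs, ["candidate"] * 3, ["candidate"] * 3, threshold=1.0
            )
        assert tpl.n_retained == 0
        assert tpl.status == "empty"

    def test_category_disagreement_keeps_candidate_with_warning(self):
        rng = np.random.default_rng(2)
        S_A = rng.normal(size=(1, 200))
        S_B = S_A.copy()
        pairs = match_components(S_A, S_B)
        with pytest.warns(UserWarning):
            tpl = build_template(S_A, S_B, pairs, ["white_matter"], ["candidate"])
        assert tpl.n_retained == 1

    def test_invariant_to_component_input_order(self):
        rng = np.random.default_rng(3)
        S_A = rng.normal(size=(4, 300))
        S_B = S_A + rng.normal(0, 0.1, (4, 300))
        perm = [2, 0, 3, 1]
        t1 = build_template(
            S_A,
            S_B,
            match_components(S_A, S_B),
            ["candidate"] * 4,
            ["candidate"] * 4,
        )
        t2 = build_template(
            S_A[perm],
            S_B[perm],
            match_components(S_A[perm], S_B[perm]),
            ["candidate"] * 4,
            ["candidate"] * 4,
        )
        # same retained maps up to ordering by pair correlation
        assert t1.n_retained == t2.n_retained
        assert np.allclose(
            sorted(t1.pair_correlations), sorted(t2.pair_correlations)
        )
        m1 = t1.maps[np.argsort(t1.pair_correlations)]
        m2 = t2.maps[np.argsort(t2.pair_correlations)]
        assert np.allclose(m1, m2, atol=1e-12)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        grid = rng.random((6, 6, 6)) > 0.3
        mask = BrainMask(grid, np.eye(4))
        S_A = rng.normal(size=(2, mask.n_voxels))
        S_B = S_A + rng.normal(0, 0.05, S_A.shape)
        tpl = build_template(
            S_A,
            S_B,
            match_components(S_A, S_B),
            ["candidate"] * 2,
            ["candidate"] * 2,
            provenance={"model_order": 2},
        )
        tpl.save(tmp_path / "tpl", mask)
        back = Template.load(tmp_path / "tpl", mask)
        assert back.n_retained == tpl.n_retained
        assert np.allclose(back.maps, tpl.maps, atol=1e-5)
        assert back.exclusions == tpl.exclusions


class TestSplitHalfPipeline:
    """End-to-end split-half property on the default synthetic fixture."""

    def test_every_planted_network_replicates(self, splithalf_bundle):
        pairs = splithalf_bundle["pairs"]
        assert all(p.r >= 0.4 for p in pairs)

    def test_confounds_excluded_by_category_and_networks_kept(
        self, splithalf_bundle
    ):
        tpl = splithalf_bundle["template"]
        co = splithalf_bundle["cohort"]
        n_networks = len(co.truth.network_indices)
        assert tpl.n_retained == n_networks
        assert tpl.exclusions.get("white_matter", 0) == 1
        assert tpl.exclusions.get("ventricle", 0) == 1
        assert tpl.exclusions.get("edge", 0) == 1
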
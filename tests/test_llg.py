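"""Reflection enumeration, structure factors, sigmaA, and the LLG."""

import numpy as np
import pytest

from errsmear import (
    DecoySpec,
    ErrorProfile,
    ReflectionSet,
    Structure,
    cell_for,
    estimate_sigma_a,
    llg,
    llg_with_errors,
    make_decoy,
    make_reflections,
    make_target,
    simulate_observations,
    structure_factors,
)


def placed(structure, padding=10.0):
    cell, shift = cell_for(structure, padding=padding)
    return structure.with_coords(structure.coords + shift), cell


@pytest.fixture(scope="module")
def crystal():
    """Small target placed in its box with noise-free observations."""
    target = make_target(60, seed=7)
    target_c, cell = placed(target)
    refl = make_reflections(cell, d_min=3.0, d_max=20.0)
    observed = simulate_observations(target_c, refl, noise_frac=0.0, seed=0)
    return target, target_c, cell, observed


class TestMakeReflections:
    def test_matches_brute_force_enumeration(self):
        refl = make_reflections((20.0, 20.0, 20.0), d_min=10.0, d_max=20.0)
        expected = set()
        for h in range(-2, 3):
            for k in range(-2, 3):
                for l in range(-2, 3):
                    if not (h > 0 or (h == 0 and k > 0) or (h == 0 and k == 0 and l > 0)):
                        continue
                    s2 = (h * h + k * k + l * l) / 400.0
                    if 1 / 400.0 <= s2 <= 1 / 100.0:
                        expected.add((h, k, l))
        assert {tuple(m) for m in refl.miller} == expected
        assert (1, 0, 0) in expected  # d = 20 Å boundary included

    def test_origin_never_included(self):
        refl = make_reflections((30.0, 25.0, 40.0), d_min=3.0)
        assert not np.any(np.all(refl.miller == 0, axis=1))

    def test_shrinking_dmin_only_adds(self):
        coarse = make_reflections((25.0, 25.0, 25.0), d_min=5.0)
        fine = make_reflections((25.0, 25.0, 25.0), d_min=3.0)
        coarse_set = {tuple(m) for m in coarse.miller}
        fine_set = {tuple(m) for m in fine.miller}
        assert coarse_set <= fine_set

    def test_no_friedel_duplicates(self):
        refl = make_reflections((25.0, 25.0, 25.0), d_min=4.0)
        seen = {tuple(m) for m in refl.miller}
        assert not any(tuple(-np.array(m)) in seen for m in seen)

    def test_empty_range_errors(self):
        with pytest.raises(ValueError, match="no reflections|enlarge"):
            make_reflections((6.0, 6.0, 6.0), d_min=18.0, d_max=20.0)

    def test_bad_limits(self):
        with pytest.raises(ValueError):
            make_reflections((20.0, 20.0, 20.0), d_min=5.0, d_max=2.0)


class TestStructureFactors:
    def test_single_atom_at_origin_unit_amplitude(self):
        s = Structure.from_coords(np.array([[0.0, 0.0, 0.0]]))
        refl = make_reflections((20.0, 20.0, 20.0), d_min=5.0)
        f = structure_factors(s, refl)
        np.testing.assert_allclose(f, 1.0 + 0.0j, atol=1e-12)

    def test_debye_waller_closed_form(self):
        # B = 26.32 at s = 0.5 Å^-1: |F| = exp(-26.32 * 0.25 / 4)
        s = Structure.from_coords(np.array([[0.0, 0.0, 0.0]]), b_factors=[26.32])
        refl = ReflectionSet(
            miller=np.array([[10, 0, 0]]),
            inv_res_sq=np.array([0.25]),
            cell=np.array([20.0, 20.0, 20.0]),
        )
        f = structure_factors(s, refl)
        assert np.abs(f[0]) == pytest.approx(np.exp(-26.32 * 0.25 / 4.0), abs=1e-12)
        assert np.abs(f[0]) == pytest.approx(0.193, abs=1e-3)

    def test_translation_phase_relation(self, rng):
        cell = np.array([25.0, 25.0, 25.0])
        refl = make_reflections(cell, d_min=4.0)
        x1 = np.array([[8.0, 9.0, 10.0]])
        t = np.array([3.0, 1.0, 2.0])
        pair = Structure.from_coords(np.vstack([x1, x1 + t]))
        single = Structure.from_coords(x1)
        f_pair = structure_factors(pair, refl)
        f_single = structure_factors(single, refl)
        factor = 1.0 + np.exp(2j * np.pi * (refl.miller @ (t / cell)))
        np.testing.assert_allclose(f_pair, f_single * factor, atol=1e-10)

    def test_friedel_symmetry(self, crystal):
        _, target_c, cell, observed = crystal
        f = structure_factors(target_c, observed)
        negated = ReflectionSet(
            miller=-observed.miller, inv_res_sq=observed.inv_res_sq, cell=cell
        )
        f_neg = structure_factors(target_c, negated)
        np.testing.assert_allclose(np.abs(f_neg), np.abs(f), atol=1e-10)

    def test_atom_outside_cell_rejected(self):
        s = Structure.from_coords(np.array([[25.0, 5.0, 5.0]]))
        refl = make_reflections((20.0, 20.0, 20.0), d_min=5.0)
        with pytest.raises(ValueError, match="outside"):
            structure_factors(s, refl)


class TestSigmaA:
    def test_perfect_agreement_is_one(self, crystal):
        _, target_c, _, observed = crystal
        f_calc = structure_factors(target_c, observed)
        sigma, _ = estimate_sigma_a(f_calc, np.abs(f_calc), observed.inv_res_sq)
        np.testing.assert_allclose(sigma, 1.0, atol=1e-12)

    def test_unrelated_structure_low(self, crystal):
        _, target_c, cell, observed = crystal
        vals = []
        for seed in range(20):
            other = make_target(60, seed=500 + seed)
            other_c = other.with_coords(other.coords - other.coords.min(0) + 5.0)
            f_calc = structure_factors(other_c, observed)
            sigma, _ = estimate_sigma_a(f_calc, observed.f_obs, observed.inv_res_sq)
            vals.append(sigma.mean())
        assert len(observed) >= 200
        assert np.mean(vals) < 0.3

    def test_noise_gives_intermediate_values(self, crystal, rng):
        _, target_c, _, observed = crystal
        f_calc = structure_factors(target_c, observed)
        f_obs = np.abs(f_calc)
        noisy = np.clip(f_obs * (1 + 0.5 * rng.normal(size=len(f_obs))), 0, None)
        sigma, _ = estimate_sigma_a(f_calc, noisy, observed.inv_res_sq)
        assert 0.3 < sigma.mean() < 0.999

    def test_small_sets_merge_shells(self, caplog):
        import logging

        f = np.abs(np.random.default_rng(0).normal(size=12)) + 0.1
        with caplog.at_level(logging.WARNING):
            sigma, shell_of = estimate_sigma_a(f, f, np.linspace(0.01, 0.1, 12), n_shells=6)
        assert len(sigma) == 2  # 12 reflections -> two shells of >= 5
        assert "merging" in caplog.text


class TestLLG:
    def test_zero_sigma_a_gives_exactly_zero(self, crystal):
        target, target_c, _, observed = crystal
        res = llg(target_c, observed, sigma_a=np.zeros(6))
        assert res.llg == 0.0

    def test_true_model_beats_decoys(self, crystal):
        target, target_c, cell, observed = crystal
        true_llg = llg(target_c, observed).llg
        assert true_llg > 0
        for seed in range(10):
            decoy, _ = make_decoy(target, DecoySpec.random(60, seed))
            shift = target_c.coords[0] - target.coords[0]
            decoy_c = decoy.with_coords(np.clip(decoy.coords + shift, 0.01, cell - 0.01))
            assert llg(decoy_c, observed).llg < true_llg

    def test_random_models_average_near_zero(self, crystal):
        _, _, cell, observed = crystal
        vals = []
        for seed in range(20):
            rnd = make_target(60, seed=900 + seed)
            rnd_c = rnd.with_coords(rnd.coords - rnd.coords.min(0) + 5.0)
            vals.append(llg(rnd_c, observed).llg)
        assert abs(np.mean(vals)) < 0.15 * len(observed)

    def test_invariant_under_global_scale(self, crystal):
        target, target_c, _, observed = crystal
        base = llg(target_c, observed).llg
        scaled = llg(target_c, observed.with_f_obs(observed.f_obs * 7.3)).llg
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_grows_with_reflection_count(self):
        target = make_target(50, seed=13)
        target_c, cell = placed(target)
        llgs, counts = [], []
        for d_min in (4.5, 3.5, 2.8):
            refl = make_reflections(cell, d_min=d_min)
            obs = simulate_observations(target_c, refl, noise_frac=0.0, seed=0)
            llgs.append(llg(target_c, obs).llg)
            counts.append(len(refl))
        assert counts[0] < counts[1] < counts[2]
        assert llgs[0] < llgs[1] < llgs[2]

    def test_missing_observations_rejected(self, crystal):
        _, target_c, cell, _ = crystal
        bare = make_reflections(cell, d_min=3.0)
        with pytest.raises(ValueError, match="no observed"):
            llg(target_c, bare)


class TestLLGWithErrors:
    def test_zero_profile_identical_to_plain(self, crystal):
        target, target_c, _, observed = crystal
        prof = ErrorProfile.from_d(np.zeros(60))
        assert llg_with_errors(target_c, prof, observed).llg == llg(target_c, observed).llg

    def test_true_error_smearing_improves_heterogeneous_decoys(self):
        wins = 0
        n_rep = 20
        for i in range(n_rep):
            target = make_target(60, seed=300 + i)
            decoy, prof = make_decoy(target, DecoySpec.random(60, 600 + i))
            cell, shift = cell_for(target, decoy)
            t_c = target.with_coords(target.coords + shift)
            d_c = decoy.with_coords(decoy.coords + shift)
            refl = make_reflections(cell, d_min=3.0)
            obs = simulate_observations(t_c, refl, noise_frac=0.05, seed=i)
            plain = llg(d_c, obs).llg
            smeared = llg_with_errors(d_c, prof.capped(), obs).llg
            wins += smeared > plain
        assert wins >= 0.9 * n_rep

    def test_oversmearing_a_perfect_model_does_not_help(self, crystal):
        target, target_c, _, observed = crystal
        plain = llg(target_c, observed).llg
        blanket = ErrorProfile.from_d(np.full(60, 15.0))
        assert llg_with_errors(target_c, blanket, observed).llg <= plain
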
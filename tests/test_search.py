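"""Candidate enumeration, search ranking, refinement, baseline comparison."""

import itertools

import numpy as np
import pytest

from veinindex import (
    Hypercube,
    IndexFormula,
    SearchConfig,
    SearchError,
    VesselMask,
    baseline_two_wavelength,
    count_candidates,
    enumerate_candidates,
    eval_index,
    masked_rms,
    nominal_candidate_count,
    normalize_index,
    refine,
    score_formula,
    search,
)


def small_search_config(**kw):
    defaults = dict(
        coefficient_set=(-1, 0, 1),
        wavelength_stride=2,
        refine_top=3,
        keep_top=10,
        tie_break_contrast=False,
    )
    defaults.update(kw)
    return SearchConfig(**defaults)


class TestNominalCount:
    def test_full_grid_matches_published_arithmetic(self):
        cfg = SearchConfig(coefficient_set=(-2, -1, 0, 1, 2), wavelength_stride=1)
        assert nominal_candidate_count(cfg, 250, symmetry_reduced=False) == 5 ** 6 * 250 ** 3

    def test_reduced_grid_matches_published_arithmetic(self):
        cfg = SearchConfig(coefficient_set=(-2, -1, 0, 1, 2), wavelength_stride=25)
        assert nominal_candidate_count(cfg, 250, symmetry_reduced=True) == 0.5 * 5 ** 6 * 10 ** 3

    def test_degenerate_coefficient_set_rejected(self):
        with pytest.raises(SearchError):
            SearchConfig(coefficient_set=(0,))

    def test_asymmetric_coefficient_set_rejected(self):
        with pytest.raises(SearchError):
            SearchConfig(coefficient_set=(0, 1, 2))


class TestEnumerate:
    def test_count_matches_brute_force_filter(self):
        """Yielded count equals an independent brute-force filter over 3^6 * 2^3."""
        cset = (-1, 0, 1)
        cfg = SearchConfig(families=("ratio",), coefficient_set=cset, wavelength_stride=1)
        axis = np.array([500.0, 600.0])
        yielded = list(enumerate_candidates(cfg, axis))

        def neg(t):
            return tuple(-x for x in t)

        surviving = 0
        for k in itertools.product(cset, repeat=6):
            if not any(k[:3]) or not any(k[3:]):
                continue  # degenerate
            if not k < neg(k):
                continue  # sign-symmetric duplicate
            surviving += 1
        assert len(yielded) == surviving * 2 ** 3
        assert len(yielded) == count_candidates(cfg, len(axis))

    def test_formula_and_full_negation_never_both_appear(self):
        cfg = SearchConfig(families=("ratio",), coefficient_set=(-1, 0, 1), wavelength_stride=1)
        seen = set()
        for f in enumerate_candidates(cfg, np.array([500.0, 600.0])):
            key = (f.lambdas_nm, f.coeffs)
            negkey = (f.lambdas_nm, tuple(-k for k in f.coeffs))
            assert negkey not in seen
            seen.add(key)

    def test_product_family_denominator_negation_excluded(self):
        cfg = SearchConfig(
            families=("product_ratio",), coefficient_set=(-1, 0, 1), wavelength_stride=1
        )
        seen = set()
        for f in enumerate_candidates(cfg, np.array([500.0, 600.0])):
            key = (f.lambdas_nm, f.coeffs)
            negden = (f.lambdas_nm, f.coeffs[:3] + tuple(-k for k in f.coeffs[3:]))
            assert negden not in seen
            seen.add(key)

    def test_degenerate_tuples_never_emitted(self):
        cfg = SearchConfig(coefficient_set=(-1, 0, 1), wavelength_stride=1)
        for f in enumerate_candidates(cfg, np.array([500.0, 600.0])):
            assert any(f.coeffs[:3]) and any(f.coeffs[3:])


def planted_tiny_cube(rng=None):
    """8x8x6 cube where vessels follow a simple one-dip signature at band 2."""
    rng = rng or np.random.default_rng(5)
    w = np.linspace(500, 1000, 6)
    base = np.linspace(0.5, 0.8, 6)
    values = np.tile(base, (8, 8, 1))
    mask = np.zeros((8, 8), dtype=bool)
    mask[:, 3:5] = True
    vessel = base.copy()
    vessel[2] *= 0.6
    values[mask] = vessel
    values += rng.normal(0, 0.01, values.shape)
    values = np.clip(values, 0, None)
    return Hypercube(values=values, wavelengths_nm=w), VesselMask(mask)


class TestSearch:
    def test_perfect_candidate_ranked_first(self):
        """A cube built so one formula reproduces the mask exactly wins with rms 0."""
        w = np.array([500.0, 600.0, 700.0])
        values = np.full((6, 6, 3), 1.0)
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        values[mask, 1] = 2.0  # ND(500, 600) separates mask exactly
        cube = Hypercube(values=values, wavelengths_nm=w)
        cfg = small_search_config(wavelength_stride=1, keep_top=5)
        results = search(cube, VesselMask(mask), cfg)
        assert results[0].rms == pytest.approx(0.0, abs=1e-12)
        top = results[0].formula
        img = normalize_index(eval_index(cube, top))
        assert masked_rms(img, VesselMask(mask)).rms == pytest.approx(results[0].rms, abs=1e-12)

    def test_deterministic_across_runs(self):
        cube, mask = planted_tiny_cube()
        cfg = small_search_config()
        a = search(cube, mask, cfg)
        b = search(cube, mask, cfg)
        assert [(r.formula, r.rms, r.rank) for r in a] == [(r.formula, r.rms, r.rank) for r in b]

    def test_results_sorted_by_rms(self):
        cube, mask = planted_tiny_cube()
        results = search(cube, mask, small_search_config())
        rms = [r.rms for r in results]
        assert rms == sorted(rms)
        assert [r.rank for r in results] == list(range(1, len(results) + 1))

    def test_reported_rms_reproducible_through_public_ops(self):
        """Each reported score equals eval -> normalize -> masked_rms recomputed."""
        cube, mask = planted_tiny_cube()
        results = search(cube, mask, small_search_config())
        for r in results[:5]:
            score = score_formula(cube, mask, r.formula)
            assert score is not None
            assert score.rms == pytest.approx(r.rms, abs=1e-9)
            assert score.polarity == r.polarity

    def test_empty_mask_rejected(self):
        cube, _ = planted_tiny_cube()
        with pytest.raises(Exception, match="empty"):
            search(cube, VesselMask(np.zeros((8, 8), dtype=bool)), small_search_config())


class TestRefine:
    def test_monotonic_improvement(self):
        cube, mask = planted_tiny_cube()
        cfg = small_search_config()
        coarse = search(cube, mask, cfg)
        refined = refine(cube, mask, coarse, cfg)
        assert refined[0].rms <= coarse[0].rms + 1e-15

    def test_global_optimum_is_fixed_point(self):
        """Refining a stride-1 search's winner cannot change rank 1."""
        cube, mask = planted_tiny_cube()
        cfg = small_search_config(wavelength_stride=1)
        coarse = search(cube, mask, cfg)
        refined = refine(cube, mask, coarse, cfg)
        assert refined[0].rms == pytest.approx(coarse[0].rms, abs=1e-12)

    def test_refined_results_are_valid_formulas(self):
        cube, mask = planted_tiny_cube()
        cfg = small_search_config()
        for r in refine(cube, mask, search(cube, mask, cfg), cfg)[:5]:
            r.formula.validate_coefficients(cfg.coefficient_set)
            score = score_formula(cube, mask, r.formula)
            assert score is not None and score.rms == pytest.approx(r.rms, abs=1e-9)


class TestBaseline:
    def test_two_band_cube_returns_single_pair(self, rng):
        values = rng.uniform(0.2, 1.0, size=(5, 5, 2))
        cube = Hypercube(values=values, wavelengths_nm=[700.0, 800.0])
        mask = VesselMask(np.eye(5, dtype=bool))
        cfg = small_search_config(wavelength_stride=1)
        res = baseline_two_wavelength(cube, mask, cfg)
        assert set(res.formula.lambdas_nm) == {700.0, 800.0}

    def test_three_wavelength_rms_never_worse_than_two(self):
        """ND pairs are degenerate triples, so the 3-wavelength optimum nests them."""
        cube, mask = planted_tiny_cube()
        cfg = small_search_config(wavelength_stride=1, keep_top=1)
        best3 = search(cube, mask, cfg)[0]
        best2 = baseline_two_wavelength(cube, mask, cfg)
        assert best3.rms <= best2.rms + 1e-12
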
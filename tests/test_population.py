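"""The nested Monte-Carlo population energy estimator."""

import itertools

import numpy as np
import pandas as pd
import pytest

import popenergy as pe
from popenergy.demography import CLASS_ORDER, AgeSexClass
from popenergy.population import (bootstrap_class_energy, bootstrap_structure,
                                  class_counts, draw_abundance)


def composition_frame(rows):
    """rows: list of (year, {class: count}) tuples."""
    out = []
    for year, counts in rows:
        total = sum(counts.values())
        row = {"year": year, "n_total": total}
        for cls in CLASS_ORDER:
            c = counts.get(cls, 0)
            row[f"n_{cls.value}"] = c
            row[f"p_{cls.value}"] = c / total if total else np.nan
        out.append(row)
    return pd.DataFrame(out)


def uniform_counts(n_per_class):
    return {c: n_per_class for c in CLASS_ORDER}


def profiles_frame(entries):
    """entries: list of (bear_id, year, class, density, storage)."""
    return pd.DataFrame(
        [{"bear_id": b, "year": y, "class": c.value,
          "energy_density_MJ_per_kg": d, "storage_energy_MJ": s,
          "lean_mass_kg": 100.0, "body_mass_kg": 200.0,
          "storage_mass_kg": 100.0}
         for b, y, c, d, s in entries])


# ---------------------------------------------------------------- structure

def test_identical_composition_bootstrap_is_exact():
    comp = composition_frame([(y, uniform_counts(10)) for y in range(2000, 2005)])
    settings = pe.EstimatorSettings(structure_boot_iters=50,
                                    outer_replicates=1, rng_seed=1)
    out = bootstrap_structure(comp, 2002, settings)
    np.testing.assert_allclose(out, np.full(7, 1 / 7), rtol=1e-12)


def test_single_year_single_class_unit_vector():
    comp = composition_frame([(2000, {AgeSexClass.ADULT_MALE: 12})])
    settings = pe.EstimatorSettings(structure_boot_iters=100,
                                    outer_replicates=1, rng_seed=1)
    out = bootstrap_structure(comp, 2000, settings)
    expected = np.zeros(7)
    expected[CLASS_ORDER.index(AgeSexClass.ADULT_MALE)] = 1.0
    np.testing.assert_allclose(out, expected)


def test_structure_bootstrap_matches_exhaustive_enumeration():
    """3-year window with adult-male proportions {0.2, 0.5, 0.8}: all 27
    equally likely 3-resamples average to 0.5; the Monte-Carlo bootstrap
    mean must land within 3 SD of that enumeration value."""
    p_vals = [0.2, 0.5, 0.8]
    rows = []
    for year, p in zip((2000, 2001, 2002), p_vals):
        n_am = int(p * 10)
        rows.append((year, {AgeSexClass.ADULT_MALE: n_am,
                            AgeSexClass.CUB: 10 - n_am}))
    comp = composition_frame(rows)

    resample_means = [np.mean(pick) for pick in
                      itertools.product(p_vals, repeat=3)]
    assert np.mean(resample_means) == pytest.approx(0.5)
    sd_of_boot_mean = np.std(resample_means) / np.sqrt(2000)

    settings = pe.EstimatorSettings(structure_boot_iters=2000,
                                    outer_replicates=1, rng_seed=7)
    out = bootstrap_structure(comp, 2001, settings)
    am = out[CLASS_ORDER.index(AgeSexClass.ADULT_MALE)]
    # renormalization couples the classes only weakly here; allow for it
    assert abs(am - 0.5) < 3 * sd_of_boot_mean + 0.01


def test_empty_window_raises():
    comp = composition_frame([(2000, {})])
    settings = pe.EstimatorSettings(structure_boot_iters=10,
                                    outer_replicates=1, rng_seed=1)
    with pytest.raises(pe.EmptyWindow):
        bootstrap_structure(comp, 2000, settings)


# ---------------------------------------------------------------- abundance

def test_abundance_zero_se_is_mean():
    rng = np.random.default_rng(0)
    assert draw_abundance(800.0, 0.0, rng) == 800.0


def test_abundance_draws_match_normal_mean():
    rng = np.random.default_rng(1)
    draws = np.array([draw_abundance(800.0, 50.0, rng) for _ in range(100000)])
    assert abs(draws.mean() - 800.0) < 4 * 50.0 / np.sqrt(len(draws))


def test_abundance_truncated_at_zero_and_reproducible():
    rng = np.random.default_rng(2)
    draws = [draw_abundance(1.0, 5.0, rng) for _ in range(2000)]
    assert min(draws) >= 0.0
    a = [draw_abundance(800.0, 50.0, np.random.default_rng(3)) for _ in range(5)]
    b = [draw_abundance(800.0, 50.0, np.random.default_rng(3)) for _ in range(5)]
    assert a == b


# ------------------------------------------------------------- class counts

def test_class_counts_unit_vector_and_uniform():
    unit = np.zeros(7)
    unit[0] = 1.0
    np.testing.assert_allclose(class_counts(unit, 800.0),
                               [800, 0, 0, 0, 0, 0, 0])
    np.testing.assert_allclose(class_counts(np.full(7, 1 / 7), 700.0),
                               np.full(7, 100.0))


def test_class_counts_matches_hand_product():
    rng = np.random.default_rng(4)
    p = rng.dirichlet(np.ones(7))
    n = 812.5
    np.testing.assert_allclose(class_counts(p, n), p * n, rtol=1e-12)
    assert class_counts(p, n).sum() == pytest.approx(n)


def test_class_counts_rejects_bad_proportions():
    with pytest.raises(ValueError):
        class_counts(np.full(7, 0.5), 100.0)


# ------------------------------------------------------------ class energy

def test_single_bear_energy_is_exact():
    rng = np.random.default_rng(5)
    d, s = bootstrap_class_energy([14.0], [2000.0], 500, rng)
    assert (d, s) == (14.0, 2000.0)


def test_identical_bears_zero_bootstrap_variance():
    rng = np.random.default_rng(6)
    vals = [bootstrap_class_energy([10.0] * 8, [1500.0] * 8, 200, rng)
            for _ in range(20)]
    assert all(v == (10.0, 1500.0) for v in vals)


def test_two_bear_energy_matches_enumeration():
    """Bears {1000, 3000} MJ: the four equally likely 2-resamples have
    means {1000, 2000, 2000, 3000}, expectation 2000."""
    outcomes = [np.mean(p) for p in
                itertools.product([1000.0, 3000.0], repeat=2)]
    assert np.mean(outcomes) == pytest.approx(2000.0)
    sd_boot_mean = np.std(outcomes) / np.sqrt(2000)
    rng = np.random.default_rng(7)
    _, s = bootstrap_class_energy([10.0, 20.0], [1000.0, 3000.0], 2000, rng)
    assert abs(s - 2000.0) < 3 * sd_boot_mean


def test_empty_cell_raises():
    with pytest.raises(pe.NoDataForClassYear):
        bootstrap_class_energy([], [], 100, np.random.default_rng(0))


# ---------------------------------------------------------- full estimator

def degenerate_inputs(n_se=0.0, years=range(2000, 2006), storage=2000.0,
                      density=20.0, n_mean=500.0):
    """One class, identical bears, identical composition every year."""
    comp = composition_frame([(y, {AgeSexClass.ADULT_MALE: 10})
                              for y in years])
    ab = pd.DataFrame({"year": list(years), "n_mean": n_mean, "n_se": n_se})
    prof = profiles_frame([(f"B{i}{y}", y, AgeSexClass.ADULT_MALE,
                            density, storage)
                           for y in years for i in range(10)])
    return comp, ab, prof


def test_degenerate_scenario_exact_total_zero_se():
    """All stochastic stages collapse: total = 500 x 2000 MJ = 1e6 MJ,
    SE = 0, in every replicate."""
    comp, ab, prof = degenerate_inputs()
    settings = pe.EstimatorSettings(structure_boot_iters=50,
                                    energy_boot_iters=50,
                                    outer_replicates=200, rng_seed=1)
    out = pe.estimate_population_energy(comp, ab, prof, settings)
    np.testing.assert_allclose(out["se_mean"], 1_000_000.0, rtol=1e-9)
    np.testing.assert_allclose(out["se_se"], 0.0, atol=1e-6)
    np.testing.assert_allclose(out["ed_mean"], 10_000.0, rtol=1e-9)
    np.testing.assert_allclose(out["ed_se"], 0.0, atol=1e-9)


def test_single_noise_source_matches_closed_form_se():
    """With abundance the only noise source, SD of replicate totals is
    per-bear energy x n_se = 2000 x 50 = 100,000 MJ (within 5% at
    10,000 replicates)."""
    comp, ab, prof = degenerate_inputs(n_se=50.0)
    settings = pe.EstimatorSettings(structure_boot_iters=20,
                                    energy_boot_iters=20,
                                    outer_replicates=10000, rng_seed=2)
    out = pe.estimate_population_energy(comp, ab, prof, settings)
    assert out["se_se"].to_numpy() == pytest.approx(100_000.0, rel=0.05)


def test_per_class_contributions_sum_to_total_each_replicate(
        small_composition, small_bundle, small_profiles):
    settings = pe.EstimatorSettings(structure_boot_iters=30,
                                    energy_boot_iters=30,
                                    outer_replicates=50, rng_seed=3)
    out = pe.estimate_population_energy(small_composition,
                                        small_bundle.abundance,
                                        small_profiles, settings,
                                        keep_replicates=True)
    for year, rep in out.attrs["replicates"].items():
        np.testing.assert_allclose(rep["contrib"].sum(axis=1), rep["totals"],
                                   rtol=1e-12)


def test_reduced_vs_fuller_replication_agree(small_composition, small_bundle,
                                             small_profiles):
    """Self-consistency: estimates at reduced replication agree with a
    fuller run within 3 combined Monte-Carlo SEs of the mean."""
    s_small = pe.EstimatorSettings(structure_boot_iters=200,
                                   energy_boot_iters=200,
                                   outer_replicates=500, rng_seed=4)
    s_big = pe.EstimatorSettings(structure_boot_iters=500,
                                 energy_boot_iters=500,
                                 outer_replicates=2000, rng_seed=5)
    a = pe.estimate_population_energy(small_composition, small_bundle.abundance,
                                      small_profiles, s_small)
    b = pe.estimate_population_energy(small_composition, small_bundle.abundance,
                                      small_profiles, s_big)
    for col, se_col in (("ed_mean", "ed_se"), ("se_mean", "se_se")):
        mc_se = np.sqrt((a[se_col] ** 2 / s_small.outer_replicates)
                        + (b[se_col] ** 2 / s_big.outer_replicates))
        assert (np.abs(a[col] - b[col]) < 3 * mc_se + 1e-9).all()


def test_se_monotone_in_abundance_se():
    ses = []
    for n_se in (0.0, 25.0, 50.0):
        comp, ab, prof = degenerate_inputs(n_se=n_se)
        settings = pe.EstimatorSettings(structure_boot_iters=20,
                                        energy_boot_iters=20,
                                        outer_replicates=2000, rng_seed=6)
        out = pe.estimate_population_energy(comp, ab, prof, settings)
        ses.append(out["se_se"].mean())
    assert ses[0] <= ses[1] <= ses[2]


def test_estimator_invariant_to_input_order(small_composition, small_bundle,
                                            small_profiles):
    settings = pe.EstimatorSettings(structure_boot_iters=50,
                                    energy_boot_iters=50,
                                    outer_replicates=100, rng_seed=8)
    out1 = pe.estimate_population_energy(small_composition,
                                         small_bundle.abundance,
                                         small_profiles, settings)
    out2 = pe.estimate_population_energy(
        small_composition.sample(frac=1, random_state=1),
        small_bundle.abundance.sample(frac=1, random_state=2),
        small_profiles.sample(frac=1, random_state=3), settings)
    np.testing.assert_allclose(out1["se_mean"], out2["se_mean"], rtol=1e-9)
    np.testing.assert_allclose(out1["ed_mean"], out2["ed_mean"], rtol=1e-9)


def test_missing_abundance_year_reported_not_crashed():
    comp, ab, prof = degenerate_inputs()
    far = pd.concat([ab, pd.DataFrame([{"year": 2050, "n_mean": 500.0,
                                        "n_se": 0.0}])], ignore_index=True)
    settings = pe.EstimatorSettings(structure_boot_iters=10,
                                    energy_boot_iters=10,
                                    outer_replicates=10, rng_seed=1)
    out = pe.estimate_population_energy(comp, far, prof, settings)
    row_2050 = out[out["year"] == 2050]
    assert len(row_2050) == 1
    # window truncation still finds the capture years; the estimate uses
    # the nearest five years of structure data
    assert not np.isnan(row_2050["se_mean"].item())


def test_empty_class_year_falls_back_to_window_pool():
    comp = composition_frame([
        (2000, {AgeSexClass.ADULT_MALE: 5, AgeSexClass.CUB: 5}),
        (2001, {AgeSexClass.ADULT_MALE: 5, AgeSexClass.CUB: 5}),
        (2002, {AgeSexClass.ADULT_MALE: 5, AgeSexClass.CUB: 5}),
    ])
    ab = pd.DataFrame({"year": [2001], "n_mean": [100.0], "n_se": [0.0]})
    # cubs profiled only in 2000 and 2002; 2001 cell empty -> window pool
    prof = profiles_frame(
        [(f"A{i}", y, AgeSexClass.ADULT_MALE, 20.0, 2000.0)
         for y in (2000, 2001, 2002) for i in range(5)]
        + [(f"C{i}", y, AgeSexClass.CUB, 10.0, 300.0)
           for y in (2000, 2002) for i in range(5)])
    settings = pe.EstimatorSettings(structure_boot_iters=50,
                                    energy_boot_iters=50,
                                    outer_replicates=100, rng_seed=9)
    out = pe.estimate_population_energy(comp, ab, prof, settings)
    # half adult males at 2000 MJ, half cubs at 300 MJ, 100 bears
    assert out["se_mean"].item() == pytest.approx(
        50 * 2000.0 + 50 * 300.0, rel=1e-6)
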
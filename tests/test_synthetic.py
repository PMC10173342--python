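"""Synthetic study generator: prototypes, design, scores, cube, MTT reference."""

import numpy as np
import pytest
from scipy import stats as sps

from eemviva.parafac import local_maxima
from eemviva.synthetic import (
    DEFAULT_TREND_PARAMS,
    FluorophorePrototype,
    default_prototypes,
    generate_cube,
    generate_design,
    generate_scores,
    mtt_reference,
    viability_map,
)


class TestPrototypes:
    def test_component1_emission_peak_at_330(self, paper_grid):
        protos = default_prototypes(paper_grid)
        em = protos[0].emission_profile(paper_grid.em_wavelengths)
        assert paper_grid.em_wavelengths[np.argmax(em)] == 330

    @pytest.mark.parametrize("idx,ex_peak,em_peak", [
        (0, 290, 330), (1, 280, 310), (2, 300, 380), (4, 360, 450),
    ])
    def test_single_band_peak_positions(self, paper_grid, idx, ex_peak, em_peak):
        protos = default_prototypes(paper_grid)
        ex = protos[idx].excitation_profile(paper_grid.ex_wavelengths)
        em = protos[idx].emission_profile(paper_grid.em_wavelengths)
        assert paper_grid.ex_wavelengths[np.argmax(ex)] == ex_peak
        assert paper_grid.em_wavelengths[np.argmax(em)] == em_peak

    def test_component4_emission_bimodal(self, paper_grid):
        protos = default_prototypes(paper_grid)
        em = protos[3].emission_profile(paper_grid.em_wavelengths)
        maxima = local_maxima(em, paper_grid.em_wavelengths, min_rel_height=0.05)
        assert maxima == [520.0, 590.0]

    def test_profiles_unit_norm_nonnegative(self, paper_grid):
        for p in default_prototypes(paper_grid):
            em = p.emission_profile(paper_grid.em_wavelengths)
            ex = p.excitation_profile(paper_grid.ex_wavelengths)
            assert np.linalg.norm(em) == pytest.approx(1.0)
            assert np.linalg.norm(ex) == pytest.approx(1.0)
            assert (em >= 0).all() and (ex >= 0).all()

    def test_stokes_shift_enforced(self):
        with pytest.raises(ValueError, match="Stokes"):
            FluorophorePrototype("bad", ((400, 20, 1.0),), ((350, 20, 1.0),))

    def test_band_weights_positive(self):
        with pytest.raises(ValueError, match="weights"):
            FluorophorePrototype("bad", ((300, 20, -1.0),), ((400, 20, 1.0),))


class TestDesign:
    def test_default_design_144_rows(self):
        assert len(generate_design()) == 144

    def test_six_doses_per_line_including_control(self):
        d = generate_design()
        for line in ("A375", "HaCaT"):
            doses = sorted(d.loc[d.cell_line == line, "dose_uM"].unique())
            assert len(doses) == 6
            assert doses[0] == 0.0

    def test_twelve_replicates_per_group(self):
        d = generate_design()
        sub = d[(d.cell_line == "A375") & (d.dose_uM == 250.0)]
        assert len(sub) == 12


class TestViabilityMap:
    @pytest.mark.parametrize("line,dose,expect", [
        ("A375", 0, 100), ("A375", 5, 90), ("A375", 50, 80),
        ("A375", 250, 60), ("A375", 500, 10), ("A375", 1000, 10),
        ("HaCaT", 0, 100), ("HaCaT", 25, 70), ("HaCaT", 250, 50),
        ("HaCaT", 500, 10),
    ])
    def test_default_viability_values(self, line, dose, expect):
        assert viability_map(line, dose) == expect

    def test_unknown_dose_rejected(self):
        with pytest.raises(KeyError):
            viability_map("A375", 123.0)


class TestScores:
    def test_zero_noise_monotone_in_viability(self):
        design = generate_design()
        scores = generate_scores(design, noise_cv=0.0, seed=0)
        viab = np.array([viability_map(r.cell_line, r.dose_uM)
                         for r in design.itertuples()])
        rho1 = sps.spearmanr(scores[:, 0], viab).statistic
        rho2 = sps.spearmanr(scores[:, 1], viab).statistic
        assert rho1 == pytest.approx(1.0)
        assert rho2 == pytest.approx(-1.0)

    def test_same_seed_reproducible(self):
        design = generate_design()
        s1 = generate_scores(design, seed=4)
        s2 = generate_scores(design, seed=4)
        np.testing.assert_array_equal(s1, s2)

    def test_wrong_slope_sign_rejected_without_override(self):
        design = generate_design()
        bad = list(DEFAULT_TREND_PARAMS)
        bad[0] = (bad[0][0], -bad[0][1])
        with pytest.raises(ValueError, match="slope sign"):
            generate_scores(design, trend_params=tuple(bad))
        out = generate_scores(design, trend_params=tuple(bad), allow_any_slopes=True)
        assert out.shape == (144, 5)

    def test_group_means_ordered_by_viability_across_seeds(self):
        design = generate_design()
        ok = 0
        for seed in range(10):
            scores = generate_scores(design, seed=seed)
            good = True
            for line in ("A375", "HaCaT"):
                sub = design.cell_line == line
                doses = sorted(design.loc[sub, "dose_uM"].unique())
                viab = [viability_map(line, d) for d in doses]
                order = np.argsort(viab)
                for f, (_, slope) in enumerate(DEFAULT_TREND_PARAMS):
                    means = np.array([
                        scores[(sub & (design.dose_uM == d)).to_numpy(), f].mean()
                        for d in doses])
                    ranked = means[order]
                    expect = np.sort(ranked) if slope > 0 else np.sort(ranked)[::-1]
                    # ties in viability (A375 500 vs 1000 both 10%) may swap
                    viab_sorted = np.array(viab)[order]
                    untied = np.diff(viab_sorted) != 0
                    steps = np.sign(np.diff(ranked))[untied]
                    if slope > 0 and not (steps > 0).all():
                        good = False
                    if slope < 0 and not (steps < 0).all():
                        good = False
            ok += good
        assert ok >= 9

    def test_drift_term_applies_per_replicate(self):
        design = generate_design()
        s = generate_scores(design, noise_cv=0.0, drift_per_replicate=0.01, seed=0)
        base = generate_scores(design, noise_cv=0.0, seed=0)
        rep = design["replicate"].to_numpy()
        np.testing.assert_allclose(s, base * (1 + 0.01 * (rep[:, None] - 1)))


class TestCube:
    def test_default_shape(self, default_cube):
        cube, _ = default_cube
        assert cube.shape == (144, 71, 26)

    def test_zero_noise_measured_cells_exactly_trilinear(self):
        cube, truth = generate_cube({"noise_rms_fraction": 0.0}, seed=3)
        clean = np.einsum("if,jf,kf->ijk", truth.scores,
                          truth.em_loadings, truth.ex_loadings)
        m = cube.grid.measured_mask
        np.testing.assert_array_equal(cube.data[:, m], clean[:, m])
        assert np.isnan(cube.data[:, ~m]).all()

    def test_noise_level_matches_configuration(self):
        cube, truth = generate_cube(seed=4)
        clean = np.einsum("if,jf,kf->ijk", truth.scores,
                          truth.em_loadings, truth.ex_loadings)
        m = cube.grid.measured_mask
        resid = cube.data[:, m] - clean[:, m]
        signal_rms = np.sqrt((clean ** 2).mean())
        assert np.sqrt((resid ** 2).mean()) == pytest.approx(
            1e-3 * signal_rms, rel=0.02)

    def test_different_seeds_share_truth_loadings(self):
        _, t1 = generate_cube(seed=5)
        _, t2 = generate_cube(seed=6)
        np.testing.assert_array_equal(t1.em_loadings, t2.em_loadings)
        np.testing.assert_array_equal(t1.ex_loadings, t2.ex_loadings)
        assert not np.array_equal(t1.scores, t2.scores)

    def test_generator_fully_deterministic(self):
        c1, t1 = generate_cube(seed=7)
        c2, t2 = generate_cube(seed=7)
        np.testing.assert_array_equal(c1.data, c2.data)
        np.testing.assert_array_equal(t1.scores, t2.scores)


class TestMTTReference:
    def test_zero_noise_equals_viability_map(self):
        design = generate_design()
        ref = mtt_reference(design, seed=0, noise_cv=0.0)
        for row in ref.itertuples():
            assert row.viability_mean == pytest.approx(
                viability_map(row.cell_line, row.dose_uM))
            assert row.viability_sd == pytest.approx(0.0, abs=1e-12)

    def test_five_replicates_per_group(self):
        ref = mtt_reference(generate_design(), seed=1)
        assert (ref.n == 5).all()
        assert all(len(r) == 5 for r in ref.replicates)

    def test_control_mean_exactly_100_after_normalization(self):
        ref = mtt_reference(generate_design(), seed=2)
        controls = ref[ref.dose_uM == 0.0]
        np.testing.assert_allclose(controls.viability_mean, 100.0, atol=1e-12)

    def test_twelve_groups_total(self):
        ref = mtt_reference(generate_design(), seed=3)
        assert len(ref) == 12
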
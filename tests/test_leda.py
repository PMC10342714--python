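"""The deconvolution core: matrix building, solving, chromatogram modes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ledams import datasets, leda, synthgen
from ledams.leda import (CharacteristicRatioTable, DegenerateSystemError,
                         brute_force_mixture, build_ratio_table,
                         deconvolve_peak, deconvolve_scanwise, measure_ratios,
                         solve_mixture)
from ledams.msdata import ValidationError

# the 50/50 combination of the two characteristic columns, in the bundled
# table's row order (392, 384, 366, 279, 253, 221 over the 604 reference)
EQUIMOLAR_VECTOR = np.array([0.140, 0.080, 0.100, 0.055, 0.060, 0.330])


class TestBuildRatioTable:
    def test_six_equations_with_subthreshold_channel_dropped(self):
        runs = datasets.elf_pure_spectra()
        # a channel at 3% relative abundance in both isomers stays out
        for reps in runs.values():
            ri, pis = reps[0]
            base = max(pis.values())
            pis[195.0] = 0.03 * base
        table = build_ratio_table(runs, ri_mz=604.0)
        assert table.n_ions == 6
        assert table.n_isomers == 2
        assert 195.0 not in table.pi_mz
        ref = datasets.elf_ratio_table()
        for mz in ref.pi_mz:
            i_ref = list(ref.pi_mz).index(mz)
            i_new = list(table.pi_mz).index(mz)
            np.testing.assert_allclose(table.ratios[i_new], ref.ratios[i_ref],
                                       atol=1e-12)

    def test_canonical_order_descending_first_isomer(self):
        table = build_ratio_table(datasets.elf_pure_spectra(), ri_mz=604.0)
        first = table.ratios[:, 0]
        assert (np.diff(first) <= 0).all()
        assert table.pi_mz[0] == 221.0          # largest first-isomer ratio
        # the two 0.01 cells tie; ascending m/z breaks the tie
        assert list(table.pi_mz[-2:]) == [253.0, 392.0]

    def test_full_threshold_excludes_everything(self):
        with pytest.raises(ValidationError):
            build_ratio_table(datasets.elf_pure_spectra(), ri_mz=604.0,
                              inclusion_threshold_pct=101.0)

    def test_single_replicate_has_zero_sd(self):
        table = build_ratio_table(datasets.elf_pure_spectra(), ri_mz=604.0)
        assert np.all(table.sds == 0.0)

    def test_replicate_sd_computed(self, rng):
        runs = {}
        for name, reps in datasets.elf_pure_spectra().items():
            ri, pis = reps[0]
            runs[name] = [(ri, {m: a * (1 + rng.normal(0, 0.02)) for m, a in pis.items()})
                          for _ in range(5)]
        table = build_ratio_table(runs, ri_mz=604.0)
        assert np.all(table.sds[table.ratios > 0.05] > 0)

    def test_csv_round_trip(self, elf_table, tmp_path):
        path = tmp_path / "table.csv"
        elf_table.to_csv(path)
        back = CharacteristicRatioTable.from_csv(path)
        assert back.isomers == elf_table.isomers
        np.testing.assert_allclose(back.pi_mz, elf_table.pi_mz)
        np.testing.assert_allclose(back.ratios, elf_table.ratios, rtol=1e-9)


class TestMeasureRatios:
    def test_elementwise_ratio(self):
        vec = measure_ratios(1000.0, {221.0: 380.0})
        assert vec.ratios[0] == pytest.approx(0.38)

    def test_all_zero_products_give_zero_vector(self):
        vec = measure_ratios(1000.0, {221.0: 0.0, 366.0: 0.0})
        assert np.all(vec.ratios == 0.0)

    def test_zero_reference_flags_undefined(self):
        assert measure_ratios(0.0, {221.0: 10.0}) is None


class TestSolveMixture:
    def test_pure_isomer_vector_assigns_everything(self, elf_table):
        for name in elf_table.isomers:
            res = solve_mixture(elf_table, elf_table.column(name))
            assert res.fraction_of(name) == pytest.approx(1.0, abs=1e-9)
            other = [n for n in elf_table.isomers if n != name][0]
            assert res.fraction_of(other) == pytest.approx(0.0, abs=1e-9)
            assert res.residual_ss == pytest.approx(0.0, abs=1e-18)

    def test_equimolar_vector_splits_evenly(self, elf_table):
        res = solve_mixture(elf_table, EQUIMOLAR_VECTOR)
        np.testing.assert_allclose(res.fractions, [0.5, 0.5], atol=1e-9)

    @pytest.mark.parametrize("frac_a", [0.9, 0.75, 0.5, 0.25, 0.1])
    def test_linearity_recovers_any_composition(self, elf_table, frac_a):
        r = frac_a * elf_table.column("ELF94") + (1 - frac_a) * elf_table.column("ELF96")
        res = solve_mixture(elf_table, r)
        np.testing.assert_allclose(res.fractions, [frac_a, 1 - frac_a], atol=1e-9)

    @given(st.floats(0.0, 1.0))
    def test_linearity_property(self, alpha):
        table = datasets.elf_ratio_table()
        r = alpha * table.ratios[:, 0] + (1 - alpha) * table.ratios[:, 1]
        res = solve_mixture(table, r)
        np.testing.assert_allclose(res.fractions, [alpha, 1 - alpha], atol=1e-9)

    def test_solvers_agree_on_interior_optimum(self, elf_table, rng):
        r = elf_table.ratios @ [0.6, 0.4] + rng.normal(0, 0.005, 6)
        r = np.clip(r, 0, None)
        nn = solve_mixture(elf_table, r, solver="nonnegative")
        un = solve_mixture(elf_table, r, solver="unconstrained")
        assert np.all(nn.fractions >= 0)
        if np.all(un.fractions >= 0):
            np.testing.assert_allclose(nn.fractions, un.fractions, atol=1e-9)

    def test_unconstrained_may_go_negative_nonnegative_never(self, elf_table, rng):
        saw_negative = False
        for _ in range(50):
            r = np.clip(elf_table.ratios @ [1.0, 0.0] + rng.normal(0, 0.02, 6), 0, None)
            un = solve_mixture(elf_table, r, solver="unconstrained")
            nn = solve_mixture(elf_table, r, solver="nonnegative")
            assert np.all(nn.fractions >= 0)
            saw_negative |= bool(np.any(un.fractions < 0))
        assert saw_negative

    def test_identical_columns_raise_degenerate_error(self):
        col = np.array([0.1, 0.2, 0.3])
        table = CharacteristicRatioTable(isomers=("A", "B"),
                                         pi_mz=np.array([221.0, 279.0, 366.0]),
                                         ri_mz=604.0,
                                         ratios=np.column_stack([col, 2 * col]),
                                         sds=np.zeros((3, 2)))
        with pytest.raises(DegenerateSystemError, match="A~B"):
            solve_mixture(table, col)

    def test_replicate_noise_propagation(self, elf_table):
        """Per-replicate fraction scatter matches exact OLS error propagation;
        averaging the six study replicates brings it under 0.02."""
        sd = 0.01
        cov = sd ** 2 * np.linalg.inv(elf_table.ratios.T @ elf_table.ratios)
        predicted_sd = np.sqrt(cov[0, 0])
        reps = synthgen.gen_mixture_ratios(elf_table, [0.5, 0.5], noise_sd=sd,
                                           n_replicates=1200, seed=42)
        fa = np.array([solve_mixture(elf_table, v).fraction_of("ELF94") for v in reps])
        assert fa.std() == pytest.approx(predicted_sd, rel=0.12)
        six_rep_means = fa.reshape(200, 6).mean(axis=1)
        assert six_rep_means.std() <= 0.02


class TestBruteForce:
    def test_matches_least_squares_on_clean_mixture(self, elf_table):
        r = elf_table.ratios @ [0.3, 0.7]
        bf = brute_force_mixture(elf_table, r)
        ls = solve_mixture(elf_table, r)
        np.testing.assert_allclose(bf.fractions, ls.fractions, atol=0.005 + 1e-12)

    def test_zero_vector_gives_zero_fractions(self, elf_table):
        bf = brute_force_mixture(elf_table, np.zeros(6))
        np.testing.assert_allclose(bf.fractions, [0.0, 0.0])

    def test_noisy_residual_bounded_by_lsq_plus_discretisation(self, elf_table, rng):
        G = elf_table.ratios.T @ elf_table.ratios
        lam_max = np.linalg.eigvalsh(G)[-1]
        step = 0.005
        bound = lam_max * (2 * (step / 2) ** 2)  # rounding each coord by <= step/2
        for _ in range(10):
            r = np.clip(elf_table.ratios @ [0.5, 0.5] + rng.normal(0, 0.01, 6), 0, None)
            bf = brute_force_mixture(elf_table, r, grid_step=step)
            ls = solve_mixture(elf_table, r, solver="unconstrained")
            assert bf.residual_ss <= ls.residual_ss + bound + 1e-12

    def test_rejects_more_than_three_isomers(self):
        table = CharacteristicRatioTable(
            isomers=("A", "B", "C", "D"), pi_mz=np.arange(4) + 200.0, ri_mz=604.0,
            ratios=np.eye(4), sds=np.zeros((4, 4)))
        with pytest.raises(ValidationError):
            brute_force_mixture(table, np.zeros(4))


class TestPeakDeconvolution:
    def test_equimolar_run_splits_ri_area_evenly(self, elf_table, clean_chromatogram):
        chrom, truth = clean_chromatogram
        peak = deconvolve_peak(chrom, elf_table, (3.8, 5.4))
        a, b = (peak.assigned_areas[n] for n in elf_table.isomers)
        assert a == pytest.approx(peak.ri_area / 2, rel=1e-6)
        assert b == pytest.approx(peak.ri_area / 2, rel=1e-6)
        assert peak.ri_area == pytest.approx(truth["ri_peak_area"], rel=1e-3)

    def test_single_component_run_assigns_everything(self, elf_table):
        params = synthgen.ChromSimParams(table=elf_table, isomer_fractions=(0.0, 1.0),
                                         noise_cv=0.0, seed=1)
        chrom, _ = synthgen.gen_chromatogram(params)
        peak = deconvolve_peak(chrom, elf_table, (4.0, 5.2))
        assert peak.assigned_areas["ELF96"] == pytest.approx(peak.ri_area, rel=1e-9)
        assert peak.assigned_areas["ELF94"] == pytest.approx(0.0, abs=1e-6 * peak.ri_area)

    def test_bounds_outside_segment2_rejected(self, elf_table, clean_chromatogram):
        chrom, _ = clean_chromatogram
        with pytest.raises(ValidationError):
            deconvolve_peak(chrom, elf_table, (1.0, 2.0))


class TestScanwiseDeconvolution:
    def test_equimolar_profiles_overlap_and_conserve_ri(self, elf_table, clean_chromatogram):
        chrom, _ = clean_chromatogram
        prof = deconvolve_scanwise(chrom, elf_table)
        a = prof.profiles["ELF94"]
        b = prof.profiles["ELF96"]
        ok = np.isfinite(a)
        assert ok.any()
        np.testing.assert_allclose(a[ok], b[ok], rtol=1e-6)
        np.testing.assert_allclose(a[ok] + b[ok], prof.ri_interpolated[ok], rtol=1e-9)

    def test_absent_isomer_profile_is_zero(self, elf_table):
        params = synthgen.ChromSimParams(table=elf_table, isomer_fractions=(1.0, 0.0),
                                         noise_cv=0.0, seed=2)
        chrom, _ = synthgen.gen_chromatogram(params)
        prof = deconvolve_scanwise(chrom, elf_table)
        b = prof.profiles["ELF96"]
        ok = np.isfinite(b)
        assert np.allclose(b[ok], 0.0, atol=1e-6 * np.nanmax(prof.profiles["ELF94"]))

    def test_no_ri_scans_raises(self, elf_table):
        from ledams.msdata import EventChromatogram, MSMSEventScan
        scans = [MSMSEventScan(time_min=4.0, segment=2, event="Pis",
                               abundances={221.0: 1.0})]
        with pytest.raises(ValidationError):
            deconvolve_scanwise(EventChromatogram(scans=scans), elf_table)
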
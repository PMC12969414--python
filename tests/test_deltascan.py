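"""The Δ-mass scanner: Δ computation, reporter matching, filters, XIC ratios."""

import numpy as np
import pytest

from mr1scan import (
    LigandSpec,
    MsmsSpectrum,
    ScanConfig,
    SyntheticConfig,
    compute_delta,
    generate,
    match_reporters,
    mz_from_neutral,
    occupancy_ratio,
    records_to_frame,
    scan,
    stringent_filter,
)
from mr1scan.chem_core import OXYGEN_MASS

PYRIDOXAL_DELTA = 151.0633


class TestComputeDelta:
    def test_unmodified_precursor_gives_zero_delta(self, peptide, make_adduct_spectrum):
        spec = make_adduct_spectrum(delta=0.0)
        charge, delta = compute_delta(spec, peptide)
        assert charge == 3
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_pyridoxal_precursor(self, peptide, make_adduct_spectrum):
        spec = make_adduct_spectrum(delta=PYRIDOXAL_DELTA)
        _, delta = compute_delta(spec, peptide)
        assert delta == pytest.approx(PYRIDOXAL_DELTA, abs=1e-6)

    def test_delta_is_charge_invariant(self, peptide, make_adduct_spectrum):
        """The same neutral mass at z=2 and z=3 yields the same Δ."""
        d2 = compute_delta(make_adduct_spectrum(delta=PYRIDOXAL_DELTA, charge=2), peptide)[1]
        d3 = compute_delta(make_adduct_spectrum(delta=PYRIDOXAL_DELTA, charge=3), peptide)[1]
        assert d2 == pytest.approx(d3, abs=1e-4)

    def test_unknown_charge_resolved_by_reporter_count(self, peptide, make_adduct_spectrum):
        """With CHARGE absent, the reporter-maximizing candidate wins."""
        spec = make_adduct_spectrum(delta=PYRIDOXAL_DELTA, charge=3)
        blind = MsmsSpectrum(
            scan_title=spec.scan_title,
            precursor_mz=spec.precursor_mz,
            precursor_charge=None,
            retention_time=spec.retention_time,
            mz=spec.mz,
            intensity=spec.intensity,
        )
        charge, delta = compute_delta(blind, peptide)
        assert charge == 3
        assert delta == pytest.approx(PYRIDOXAL_DELTA, abs=1e-6)

    def test_unknown_charge_tie_breaks_low(self, peptide):
        """A peak-free spectrum matches nothing at any charge → lowest wins."""
        blind = MsmsSpectrum("t", 700.0, None, None, [], [])
        charge, _ = compute_delta(blind, peptide)
        assert charge == 2


class TestMatchReporters:
    def test_full_ladder_matches_twelve(self, peptide, make_adduct_spectrum):
        spec = make_adduct_spectrum(delta=PYRIDOXAL_DELTA)
        flags, n = match_reporters(spec, peptide, PYRIDOXAL_DELTA)
        assert n == 12
        assert all(flags.values())

    def test_partial_ladder_site_free_only(self, peptide, make_adduct_spectrum):
        labels = [f"y{k}" for k in range(1, 7)]
        spec = make_adduct_spectrum(delta=0.0, ion_labels=labels)
        flags, n = match_reporters(spec, peptide, 0.0)
        assert n == 6
        assert all(flags[f"y{k}"] for k in range(1, 7))
        assert not any(flags[f"y{k}"] for k in range(7, 13))

    @pytest.mark.parametrize("offset_ppm, expect", [(14.0, True), (16.0, False)])
    def test_tolerance_boundary(self, peptide, make_adduct_spectrum, offset_ppm, expect):
        """A peak displaced just inside/outside the 15 ppm tolerance."""
        spec = make_adduct_spectrum(delta=0.0, ion_labels=["y3"], mz_offset_ppm=offset_ppm)
        flags, _ = match_reporters(spec, peptide, 0.0)
        assert flags["y3"] is expect

    def test_each_ion_claims_nearest_peak(self, peptide, y_ladder):
        """Two peaks near one ion: only the nearest decides the match."""
        y3 = next(i for i in y_ladder if i.ordinal == 3)
        near = y3.mz_unmodified * (1 + 5e-6)
        far = y3.mz_unmodified * (1 + 60e-6)
        spec = MsmsSpectrum("t", 523.9426, 3, None, [near, far], [10.0, 10.0])
        flags, n = match_reporters(spec, peptide, 0.0)
        assert flags["y3"]
        assert n == 1


class TestScan:
    def test_synthetic_run_pass_counts(self, peptide):
        """10 clean pyridoxal adducts pass; 20 pure-noise decoys do not."""
        cfg = SyntheticConfig(
            ligand_panel=(LigandSpec("pyridoxal", formula="C8H9NO3", n_spectra=10),),
            n_unmodified_spectra=0,
            n_decoy_spectra=20,
            mass_error_ppm_sd=0.0,
            n_noise_peaks_per_spectrum=30,
            seed=11,
        )
        spectra, truth = generate(cfg)
        records = scan(spectra, peptide)
        passing = [r for r in records if r.passes_filters]
        assert len(records) == 30
        assert len(passing) == 10
        for r in passing:
            assert r.delta_mass_oxygen == pytest.approx(167.058, abs=1e-3)

    def test_low_delta_fails_despite_full_ladder(self, peptide, make_adduct_spectrum):
        """Δ = 20 Da with 12 matched reporters stays below the 40 Da floor."""
        records = scan([make_adduct_spectrum(delta=20.0)], peptide)
        assert records[0].n_fragments == 12
        assert not records[0].passes_filters

    @pytest.mark.parametrize("n_ions, expect", [(7, False), (8, True)])
    def test_reporter_count_threshold(self, peptide, make_adduct_spectrum, n_ions, expect):
        labels = [f"y{k}" for k in range(1, n_ions + 1)]
        records = scan([make_adduct_spectrum(delta=150.0, ion_labels=labels)], peptide)
        assert records[0].n_fragments == n_ions
        assert records[0].passes_filters is expect

    def test_record_per_spectrum_and_oxygen_invariant(self, peptide):
        cfg = SyntheticConfig(n_decoy_spectra=15, seed=3)
        spectra, _ = generate(cfg)
        records = scan(spectra, peptide)
        assert len(records) == len(spectra)
        for r in records:
            assert r.delta_mass_oxygen - r.delta_mass == pytest.approx(
                OXYGEN_MASS, abs=1e-6
            )

    def test_threshold_monotonicity(self, peptide):
        """Raising either filter threshold never increases the passing count."""
        spectra, _ = generate(SyntheticConfig(n_decoy_spectra=30, seed=5))
        base = None
        for min_shift in (0.0, 40.0, 100.0, 200.0):
            for min_frag in (0, 4, 8, 12):
                cfg = ScanConfig(min_mass_shift=min_shift, min_frag_number=min_frag)
                n_pass = sum(r.passes_filters for r in scan(spectra, peptide, cfg))
                if min_shift == 0.0 and min_frag == 0:
                    base = n_pass
                assert n_pass <= base
        # explicit pairwise check along each axis
        counts_by_frag = [
            sum(
                r.passes_filters
                for r in scan(spectra, peptide, ScanConfig(min_frag_number=k))
            )
            for k in range(0, 13)
        ]
        assert all(a >= b for a, b in zip(counts_by_frag, counts_by_frag[1:]))

    def test_decoy_pass_rate_matches_random_match_oracle(self, peptide):
        """Decoys pass at a rate consistent with random peak/tolerance geometry.

        Expected per-ion match probability for uniform noise peaks is
        roughly n_peaks × (width of the ±tol window) / (m/z span); with
        the default 15 ppm windows that probability is ~1e-4 per ion, so
        P(≥8 of 12 ions) is astronomically small — no decoy should pass.
        """
        cfg = SyntheticConfig(
            ligand_panel=(),
            n_unmodified_spectra=0,
            n_decoy_spectra=300,
            n_noise_peaks_per_spectrum=50,
            seed=17,
        )
        spectra, _ = generate(cfg)
        records = scan(spectra, peptide)
        # brute-force oracle: per-ion probability that any of n uniform
        # peaks lands within ±tol of the expected m/z
        tol_da = 15e-6 * 1000.0  # representative ion at ~1000 Th
        p_ion = 1 - (1 - 2 * tol_da / 1800.0) ** 50
        from scipy.stats import binom

        p_pass = binom.sf(7, 12, p_ion)
        assert p_pass * 300 < 0.01
        assert sum(r.passes_filters for r in records) == 0

    def test_scan_writes_csv_with_protocol_labels(self, peptide, make_adduct_spectrum, tmp_path):
        out = tmp_path / "LigandScannerAbsolute.csv"
        scan([make_adduct_spectrum(delta=PYRIDOXAL_DELTA)], peptide, out_csv=str(out))
        header = out.read_text().splitlines()[0]
        assert "#Fragments" in header
        assert "Delta_Mass_Oxygen" in header
        assert "y1" in header and "y12" in header


class TestStringentFilter:
    @pytest.mark.parametrize("n_ions, expect", [(9, False), (10, True), (12, True)])
    def test_y_ion_threshold(self, peptide, make_adduct_spectrum, n_ions, expect):
        labels = [f"y{k}" for k in range(1, n_ions + 1)]
        records = scan([make_adduct_spectrum(delta=150.0, ion_labels=labels)], peptide)
        (flagged,) = stringent_filter(records)
        assert flagged.stringent is expect

    def test_empty_record_set(self):
        assert stringent_filter([]) == []

    def test_input_not_mutated(self, peptide, make_adduct_spectrum):
        records = scan([make_adduct_spectrum(delta=150.0)], peptide)
        stringent_filter(records)
        assert records[0].stringent is None


class TestOccupancyRatio:
    def test_identical_traces_give_one(self):
        trace = [(0.0, 0.0), (1.0, 5.0), (2.0, 0.0)]
        assert occupancy_ratio(trace, trace) == pytest.approx(1.0)

    def test_rectangles(self):
        tall = [(0.0, 2.0), (1.0, 2.0)]
        short = [(0.0, 1.0), (1.0, 1.0)]
        assert occupancy_ratio(tall, short) == pytest.approx(2.0)

    def test_triangle_vs_rectangle(self):
        """Closed-form areas: triangle = ½·base·height, rectangle = base·height."""
        triangle = [(0.0, 0.0), (1.0, 4.0), (2.0, 0.0)]  # area 4
        rectangle = [(0.0, 2.0), (2.0, 2.0)]  # area 4
        assert occupancy_ratio(triangle, rectangle) == pytest.approx(1.0)

    def test_zero_unmodified_area_rejected(self):
        with pytest.raises(ValueError, match="zero area"):
            occupancy_ratio([(0, 1), (1, 1)], [(0, 0), (1, 0)])

    def test_short_or_unsorted_traces_rejected(self):
        with pytest.raises(ValueError):
            occupancy_ratio([(0, 1)], [(0, 1), (1, 1)])
        with pytest.raises(ValueError):
            occupancy_ratio([(1, 1), (0, 1)], [(0, 1), (1, 1)])
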
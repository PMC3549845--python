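import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagident.chem import PROTON, peptide_neutral_mass
from tagident.io_formats import Peak, Spectrum
from tagident.ion_match import (
    MatchResult,
    correlation_score,
    match,
    theoretical_spectrum,
)
from tagident.preprocess import preprocess

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class TestTheoreticalSpectrum:
    def test_primary_ion_intensities(self):
        theo = theoretical_spectrum("PEPTIDEK", 2)
        for p in theo.peaks:
            if p.ion_type in ("b", "y"):
                assert p.intensity == 100.0
            elif p.ion_type == "a":
                assert p.intensity == 20.0

    def test_doubly_charged_intensity(self):
        theo = theoretical_spectrum("PEPTIDEK", 2)
        assert {p.intensity for p in theo.peaks if p.ion_type in ("b2", "y2")} == {50.0}

    def test_loss_ion_intensities(self):
        theo = theoretical_spectrum("PEPTIDEK", 2)
        losses = {p.intensity for p in theo.peaks if "-" in p.ion_type}
        assert losses == {20.0}

    def test_b1_glycine_mz(self):
        theo = theoretical_spectrum("GG", 1)
        b1 = next(p for p in theo.peaks if p.ion_type == "b" and p.ordinal == 1)
        assert math.isclose(b1.mz, 57.02146 + 1.00728, abs_tol=1e-3)

    def test_peak_count_charge2(self):
        pep = "PEPTIDEK"
        theo = theoretical_spectrum(pep, 2)
        assert len(theo.peaks) == 9 * (len(pep) - 1)

    def test_peak_count_charge1(self):
        theo = theoretical_spectrum("PEPTIDEK", 1)
        assert len(theo.peaks) == 7 * 7  # no doubly charged series

    def test_nine_ion_types(self):
        theo = theoretical_spectrum("PEPTIDEK", 2)
        assert len({p.ion_type for p in theo.peaks}) == 9

    def test_single_residue_errors(self):
        with pytest.raises(ValueError):
            theoretical_spectrum("G", 2)


def spectrum_from_theoretical(theo, intensity=500.0, baseline=True):
    peaks = [Peak(p.mz, intensity) for p in theo.peaks]
    if baseline:
        mzs = {round(p.mz, 4) for p in theo.peaks}
        filler = [
            Peak(m, 10.0)
            for m in [91.37 + 7.13 * i for i in range(2 * len(peaks))]
            if round(m, 4) not in mzs and m > 50
        ]
        peaks += filler
    prec = (peptide_neutral_mass(theo.peptide) + 2 * PROTON) / 2
    return Spectrum(peaks=peaks, precursor_mz=prec, precursor_charge=2, identifier="t")


class TestMatch:
    def test_perfect_self_match(self):
        theo = theoretical_spectrum("PEPTIDEK", 2)
        proc = preprocess(spectrum_from_theoretical(theo), window_top_n=50)
        result = match(proc, theo, tolerance=0.01)
        n = len("PEPTIDEK") - 1
        assert result.Nb == n
        assert result.Ny == n
        matched_I = [i for i in result.I if i > 0]
        assert len(matched_I) == len(theo.peaks)

    def test_empty_experimental(self):
        theo = theoretical_spectrum("PEPTIDEK", 2)
        s = Spectrum(peaks=[Peak(3000.0, 5.0)], precursor_mz=500.0, precursor_charge=2)
        proc = preprocess(s, drop_level0=False)
        proc.kept[:] = False
        result = match(proc, theo, tolerance=0.5)
        assert all(i == 0.0 for i in result.I)
        assert result.Nb == result.Ny == 0

    def test_greedy_closest_assignment(self):
        # one experimental peak between two theoretical peaks: closer one wins
        theo = theoretical_spectrum("GG", 1)
        b1 = next(p for p in theo.peaks if p.ion_type == "b")
        a1 = next(p for p in theo.peaks if p.ion_type == "a")
        exp_mz = b1.mz - 0.1  # 0.1 from b1, ~28 from a1
        s = Spectrum(
            peaks=[Peak(exp_mz, 100.0), Peak(500.0, 10.0), Peak(600.0, 10.0)],
            precursor_mz=200.0,
            precursor_charge=1,
        )
        proc = preprocess(s, drop_level0=False)
        proc.kept[:] = True
        result = match(proc, theo, tolerance=0.5)
        matched_types = {theo.peaks[t].ion_type for t, _, _ in result.matched}
        assert matched_types == {"b"}


class TestCorrelationScore:
    def make_result(self, Nb, Ny, I, intensities):
        theo = theoretical_spectrum("PEPTIDEK", 2)
        peaks = theo.peaks[: len(I)]
        theo.peaks = [
            type(p)(p.mz, pi, p.ion_type, p.ordinal) for p, pi in zip(peaks, intensities)
        ]
        return MatchResult(theo=theo, I=I, Nb=Nb, Ny=Ny, matched=[])

    def test_no_match_flag(self):
        r = self.make_result(0, 0, [0.0, 0.0], [100.0, 100.0])
        sc, flagged = correlation_score(r)
        assert sc == 0.0 and flagged

    def test_literal_product_form(self):
        # Nb=2, Ny=1, dot=10 -> 2! * 1! * 10 = 20
        r = self.make_result(2, 1, [0.1], [100.0])
        sc, flagged = correlation_score(r)
        assert not flagged
        assert math.isclose(math.exp(sc), 20.0, rel_tol=1e-12)

    def test_intensity_doubling_adds_log2(self):
        r1 = self.make_result(2, 2, [0.5, 0.25], [100.0, 50.0])
        r2 = self.make_result(2, 2, [1.0, 0.5], [100.0, 50.0])
        s1, _ = correlation_score(r1)
        s2, _ = correlation_score(r2)
        assert math.isclose(s2 - s1, math.log(2), rel_tol=1e-12)

    def test_negative_intensity_errors(self):
        r = self.make_result(1, 1, [-1.0], [100.0])
        with pytest.raises(ValueError):
            correlation_score(r)

    @settings(max_examples=200, deadline=None)
    @given(
        nb=st.integers(min_value=0, max_value=10),
        ny=st.integers(min_value=0, max_value=10),
        dot=st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_log_form_equals_product_form(self, nb, ny, dot):
        log_form = (
            math.lgamma(nb + 1) + math.lgamma(ny + 1) + math.log(dot)
        )
        product_form = math.factorial(nb) * math.factorial(ny) * dot
        assert math.isclose(math.exp(log_form), product_form, rel_tol=1e-9)

    def test_monotone_in_counts(self):
        rs = [self.make_result(nb, 1, [0.5], [100.0]) for nb in range(5)]
        scores = [correlation_score(r)[0] for r in rs]
        assert scores == sorted(scores)


class TestDiscrimination:
    def test_true_peptide_beats_decoys(self, rng):
        # noise-free ladder spectra: the generating peptide's Sc exceeds a
        # shuffled same-composition decoy's in >= 99% of trials
        from tagident import synthetic

        params = synthetic.noise_free_params(seed=17)
        params.n_proteins = 150
        proteins = synthetic.generate_fasta(params)
        peptides = synthetic.sample_tryptic_peptides(proteins, 200, params.rng())
        wins = 0
        for pep in peptides:
            spec, _ = synthetic.simulate_spectrum(pep.sequence, 2, params, params.rng())
            proc = preprocess(spec)
            true_sc, _ = correlation_score(
                match(proc, theoretical_spectrum(pep.sequence, 2), 0.5)
            )
            shuffled = list(pep.sequence[:-1])
            rng.shuffle(shuffled)
            decoy = "".join(shuffled) + pep.sequence[-1]
            if decoy == pep.sequence:
                wins += 1
                continue
            decoy_sc, _ = correlation_score(
                match(proc, theoretical_spectrum(decoy, 2), 0.5)
            )
            if true_sc > decoy_sc:
                wins += 1
        assert wins / len(peptides) >= 0.99
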
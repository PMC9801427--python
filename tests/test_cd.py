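"""Mean residue ellipticity and secondary-structure deconvolution."""

import numpy as np
import pytest

from desfold.cd import (
    MOTIFS,
    CDBasisSet,
    SecondaryStructureFractions,
    deconvolve,
    fold_change,
    mean_residue_ellipticity,
    synthetic_basis,
)
from desfold.exceptions import InvalidInputError
from desfold.spectrum import Spectrum
from desfold.synthetic import gen_cd


@pytest.fixture(scope="module")
def basis():
    return synthetic_basis()


class TestMeanResidueEllipticity:
    def test_zero_in_zero_out(self):
        wl = np.arange(200.0, 250.5, 0.5)
        raw = Spectrum(wl, np.zeros_like(wl), kind="ellipticity")
        assert np.all(mean_residue_ellipticity(raw, 1e-5, 0.1, 583).values == 0)

    def test_direct_arithmetic(self):
        # 10 mdeg / (10 * 0.1 cm * 1e-5 M * 583 residues)
        wl = np.arange(200.0, 250.5, 0.5)
        raw = Spectrum(wl, np.full_like(wl, 10.0), kind="ellipticity")
        mre = mean_residue_ellipticity(raw, 1e-5, 0.1, 583)
        assert mre.values[0] == pytest.approx(10.0 / (10 * 0.1 * 1e-5 * 583), rel=1e-12)
        assert mre.values[0] == pytest.approx(1715.0, abs=0.5)

    def test_linearity_in_concentration(self):
        wl = np.arange(200.0, 250.5, 0.5)
        raw = Spectrum(wl, np.sin(wl / 10.0), kind="ellipticity")
        a = mean_residue_ellipticity(raw, 1e-5, 0.1, 583).values
        b = mean_residue_ellipticity(raw, 2e-5, 0.1, 583).values
        assert b == pytest.approx(a / 2, rel=1e-12)

    def test_per_bond_convention(self):
        wl = np.arange(200.0, 250.5, 0.5)
        raw = Spectrum(wl, np.full_like(wl, 10.0), kind="ellipticity")
        a = mean_residue_ellipticity(raw, 1e-5, 0.1, 583).values[0]
        b = mean_residue_ellipticity(raw, 1e-5, 0.1, 583, per_bond=True).values[0]
        assert b == pytest.approx(a * 583 / 582, rel=1e-12)

    def test_invalid_inputs(self):
        wl = np.arange(200.0, 250.5, 0.5)
        raw = Spectrum(wl, np.ones_like(wl), kind="ellipticity")
        with pytest.raises(InvalidInputError):
            mean_residue_ellipticity(raw, -1e-5, 0.1, 583)
        with pytest.raises(InvalidInputError):
            mean_residue_ellipticity(raw, 1e-5, 0.0, 583)


class TestDeconvolve:
    def test_pure_motif_recovered_exactly(self, basis):
        res = deconvolve(basis.motif_spectrum("alpha"), basis)
        assert res.fractions.alpha == pytest.approx(1.0, abs=1e-8)

    def test_noise_free_mixture_exact(self, basis):
        truth = SecondaryStructureFractions(0.6, 0.0, 0.0, 0.4)
        spec, _ = gen_cd(truth, basis=basis)
        res = deconvolve(spec, basis)
        assert res.fractions.as_array() == pytest.approx(truth.as_array(), abs=1e-8)

    def test_noisy_mixture_recovery_within_003(self, basis):
        """2% (of max) noise, 100 replicates: replicate-averaged fractions within 0.03."""
        truth = SecondaryStructureFractions(0.35, 0.3, 0.1, 0.25)
        clean, _ = gen_cd(truth, basis=basis)
        sd = 0.02 * np.max(np.abs(clean.values))
        errors = np.zeros((100, 4))
        for seed in range(100):
            spec, _ = gen_cd(truth, noise_sd=sd, seed=seed, basis=basis)
            errors[seed] = deconvolve(spec, basis).fractions.as_array() - truth.as_array()
        assert np.all(np.abs(errors.mean(axis=0)) < 0.03)

    def test_scale_invariance(self, basis):
        truth = SecondaryStructureFractions(0.25, 0.25, 0.2, 0.3)
        spec, _ = gen_cd(truth, basis=basis)
        scaled = Spectrum(spec.wavelengths, 13.7 * spec.values, kind="mre")
        a = deconvolve(spec, basis).fractions.as_array()
        b = deconvolve(scaled, basis).fractions.as_array()
        assert b == pytest.approx(a, rel=1e-9)

    def test_error_decreases_with_noise(self, basis):
        """Mean recovery error is monotone over the 4/2/1/0.5% noise grid."""
        truth = SecondaryStructureFractions(0.35, 0.3, 0.1, 0.25)
        clean, _ = gen_cd(truth, basis=basis)
        vmax = np.max(np.abs(clean.values))
        means = []
        for frac in (0.04, 0.02, 0.01, 0.005):
            errs = []
            for seed in range(40):
                spec, _ = gen_cd(truth, noise_sd=frac * vmax, seed=seed, basis=basis)
                errs.append(np.abs(deconvolve(spec, basis).fractions.as_array() - truth.as_array()).mean())
            means.append(np.mean(errs))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_fractions_valid_for_arbitrary_input(self, basis):
        rng = np.random.default_rng(7)
        wl = basis.wavelengths
        for _ in range(10):
            spec = Spectrum(wl, rng.normal(0, 1e4, wl.size), kind="mre")
            f = deconvolve(spec, basis).fractions.as_array()
            assert np.all(f >= 0) and f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_range_not_covered_rejected(self, basis):
        wl = np.arange(210.0, 250.5, 0.5)
        spec = Spectrum(wl, np.ones_like(wl), kind="mre")
        with pytest.raises(InvalidInputError):
            deconvolve(spec, basis, fit_range=(200.0, 250.0))

    def test_restricted_fit_range(self, basis):
        """High-absorbance solvents cut the far-UV edge; fitting 210-250 still works."""
        truth = SecondaryStructureFractions(0.5, 0.2, 0.1, 0.2)
        spec, _ = gen_cd(truth, basis=basis)
        res = deconvolve(spec, basis, fit_range=(210.0, 250.0))
        assert res.fractions.as_array() == pytest.approx(truth.as_array(), abs=1e-6)


class TestFoldChange:
    def test_identity(self):
        f = SecondaryStructureFractions(0.4, 0.3, 0.1, 0.2)
        changes = fold_change(f, f)
        assert all(c.mode == "ratio" and c.value == pytest.approx(1.0) for c in changes.values())

    def test_alpha_loss_ratio(self):
        sample = SecondaryStructureFractions(0.39, 0.21, 0.1, 0.3)
        reference = SecondaryStructureFractions(0.50, 0.10, 0.1, 0.3)
        assert fold_change(sample, reference)["alpha"].value == pytest.approx(0.78)

    def test_near_zero_reference_switches_to_absolute(self):
        sample = SecondaryStructureFractions(0.4, 0.105, 0.195, 0.3)
        reference = SecondaryStructureFractions(0.495, 0.005, 0.2, 0.3)
        c = fold_change(sample, reference)["beta"]
        assert c.mode == "absolute"
        assert c.value == pytest.approx(0.1)


def test_basis_roundtrip(tmp_path, basis):
    path = tmp_path / "basis.csv"
    basis.write(path)
    loaded = CDBasisSet.read(path)
    assert loaded.wavelengths == pytest.approx(basis.wavelengths)
    assert loaded.curves == pytest.approx(basis.curves)
    assert list(MOTIFS) == ["alpha", "beta", "turn", "unordered"]
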
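"""Synthetic PDA + MS chromatogram pairs with full ground truth.

The simulator emulates the screening campaign the pipeline is built for:
1-3 drug-like analytes at millimolar concentration in DMSO, spiked with a
4,4'-di-tert-butylbiphenyl internal standard, eluting under the 8-minute
water-acetonitrile gradient with gradient-shaped baseline drift, detector
noise, a solvent-front spike, and liquid-handling volume error (~0.5 uL on
a 100 uL preparation).

Peak areas are constructed by the exact inverse of the quantification
algebra: each analyte's elution profile is a Gaussian whose time integral is
``a = n * eps * l / Q`` with eps taken at the gradient composition of its
retention time, so with no noise the pipeline must recover the true yield
exactly (up to discretization). Ground-truth spectra are Gaussian band
mixtures — the pipeline only assumes bilinearity and band resolvability, so
shapes beyond that are irrelevant to correctness.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromdata import (
    AnalyteSpec,
    GradientProgram,
    MSTrace,
    PDAChromatogram,
    SystemConstants,
    write_ms,
    write_pda,
)
from .errors import ValidationError
from .mslocate import PROTON_MASS
from .quantify import TablePredictor, area_from_moles

__all__ = ["SimAnalyte", "SimTruth", "SimSample", "Campaign",
           "internal_standard_analyte", "simulate_sample", "simulate_campaign",
           "COMPOUND_LIBRARY"]

DEFAULT_EPS_RANGE = (2.7, 4.4)   # log10 L/(mol cm), span of drug-like analytes

#: Drug-like structures used to label simulated analytes. The structures are
#: real molecules but the attached spectra/extinction coefficients are
#: synthetic draws, not measured properties.
COMPOUND_LIBRARY = [
    ("benzamide", "NC(=O)c1ccccc1"),
    ("acetanilide", "CC(=O)Nc1ccccc1"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O"),
    ("benzocaine", "CCOC(=O)c1ccc(N)cc1"),
    ("sulfanilamide", "Nc1ccc(cc1)S(N)(=O)=O"),
    ("nicotinamide", "NC(=O)c1cccnc1"),
    ("isoniazid", "NNC(=O)c1ccncc1"),
    ("phenacetin", "CCOc1ccc(NC(C)=O)cc1"),
    ("antipyrine", "CC1=CC(=O)N(c2ccccc2)N1C"),
    ("carbamazepine", "NC(=O)N1c2ccccc2C=Cc2ccccc21"),
    ("lidocaine", "CCN(CC)CC(=O)Nc1c(C)cccc1C"),
    ("procaine", "CCN(CC)CCOC(=O)c1ccc(N)cc1"),
    ("theophylline", "Cn1c(=O)c2[nH]cnc2n(C)c1=O"),
    ("tolbutamide", "CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1"),
    ("sulfapyridine", "Nc1ccc(cc1)S(=O)(=O)Nc1ccccn1"),
    ("indomethacin-frag", "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccccc1"),
    ("quinoline-amide", "O=C(N)c1ccc2ccccc2n1"),
    ("benzotriazole", "c1ccc2[nH]nnc2c1"),
    ("phthalimide", "O=C1NC(=O)c2ccccc21"),
    ("coumarin-3-acid", "O=C(O)C1=Cc2ccccc2OC1=O"),
    ("anthranilic-acid", "Nc1ccccc1C(=O)O"),
    ("cinnamamide", "NC(=O)/C=C/c1ccccc1"),
    ("pyrazinamide", "NC(=O)c1cnccn1"),
    ("salicylamide", "NC(=O)c1ccccc1O"),
    ("mandelic-acid", "OC(C(=O)O)c1ccccc1"),
    ("benzimidazole", "c1ccc2[nH]cnc2c1"),
]

IST_SMILES = "CC(C)(C)c1ccc(-c2ccc(C(C)(C)C)cc2)cc1"  # 4,4'-di-tBu-biphenyl


@dataclass(frozen=True)
class SimAnalyte:
    """Ground-truth description of one simulated analyte.

    ``conc`` is the concentration in the injected sample (mol/L);
    ``spectrum_bands`` are (center nm, width nm, relative height) Gaussian
    bands; ``retention`` and ``peak_sigma`` are in seconds; ``mz`` is the
    observed adduct channel; ``spectral_shift`` (nm/s, default 0) drags the
    band centers during elution to reproduce the solvent-composition
    spectral-drift failure mode.
    """

    label: str
    conc: float
    log10_eps_water: float
    log10_eps_acn: float
    spectrum_bands: tuple
    retention: float
    peak_sigma: float
    mz: float
    smiles: str = ""
    ionizes: bool = True
    spectral_shift: float = 0.0
    eps_range: tuple = DEFAULT_EPS_RANGE

    def __post_init__(self):
        if self.conc < 0:
            raise ValidationError("conc must be non-negative")
        lo, hi = self.eps_range
        for v in (self.log10_eps_water, self.log10_eps_acn):
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValidationError(
                    f"log10 eps {v} outside configured range [{lo}, {hi}]")
        for c, w, h in self.spectrum_bands:
            if not (200.0 <= c <= 800.0):
                raise ValidationError(f"band center {c} nm outside 200-800 nm")
        if self.peak_sigma <= 0:
            raise ValidationError("peak_sigma must be positive")

    @property
    def lambda_red(self) -> float:
        """Reddest band center (nm)."""
        return max(c for c, _, _ in self.spectrum_bands)

    def spectrum(self, wavelengths: np.ndarray, t_offset: float = 0.0
                 ) -> np.ndarray:
        """Band-mixture spectrum normalized to 1.0 at the reddest band center.

        ``t_offset`` (s from the retention apex) applies the per-analyte
        spectral drift, if any.
        """
        shift = self.spectral_shift * t_offset
        g = np.zeros_like(wavelengths, dtype=float)
        for c, w, h in self.spectrum_bands:
            g += h * np.exp(-0.5 * ((wavelengths - (c + shift)) / w) ** 2)
        ref = 0.0
        lam_red = self.lambda_red + shift
        for c, w, h in self.spectrum_bands:
            ref += h * math.exp(-0.5 * ((lam_red - (c + shift)) / w) ** 2)
        if ref <= 0:
            raise ValidationError("spectrum vanishes at its reddest band")
        return g / ref

    def eps_red_at(self, phi_acn: float) -> float:
        """Extinction coefficient at the reddest peak for composition phi."""
        return (phi_acn * 10.0 ** self.log10_eps_acn
                + (1.0 - phi_acn) * 10.0 ** self.log10_eps_water)


def internal_standard_analyte(conc: float = 2e-3, retention: float = 360.0,
                              peak_sigma: float = 3.0) -> SimAnalyte:
    """The platform internal standard: late-eluting, single 250 nm band."""
    return SimAnalyte(
        label="IST", conc=conc, log10_eps_water=4.25, log10_eps_acn=4.25,
        spectrum_bands=((250.0, 15.0, 1.0),), retention=retention,
        peak_sigma=peak_sigma, mz=266.20, smiles=IST_SMILES, ionizes=False)


@dataclass(frozen=True)
class SimTruth:
    """Everything needed to score a simulated sample, seeded and reproducible."""

    analytes: tuple
    true_yields: dict
    true_areas: dict
    eps_red: dict
    drift: np.ndarray
    noise_sigma: float
    pipetting_error: dict
    delay: float
    ist_nominal_area: float
    seed: int


@dataclass(frozen=True)
class SimSample:
    """One campaign member: data, truth, and the target's analyte spec."""

    sample_id: str
    pda: PDAChromatogram
    ms_traces: tuple
    truth: SimTruth
    target_label: str
    target_spec: AnalyteSpec


@dataclass(frozen=True)
class Campaign:
    samples: tuple
    truth_table: pd.DataFrame
    predictor_exact: TablePredictor
    predictor: TablePredictor
    constants: SystemConstants
    gradient: GradientProgram


def _gaussian_profile(times, retention, sigma, area):
    return (area / (sigma * math.sqrt(2.0 * math.pi))
            * np.exp(-0.5 * ((times - retention) / sigma) ** 2))


def ist_nominal_area(constants: SystemConstants, gradient: GradientProgram,
                     ist: SimAnalyte | None = None) -> float:
    """Analytic (noise-free, unit injection) internal-standard peak area."""
    ist = ist or internal_standard_analyte()
    phi = gradient.fraction(ist.retention)
    eps = ist.eps_red_at(phi)
    moles = ist.conc * constants.injection_volume * 1e-6
    return area_from_moles(moles, eps, constants)


def simulate_sample(analytes, constants: SystemConstants | None = None,
                    gradient: GradientProgram | None = None,
                    noise_sigma: float = 0.002, drift_amplitude: float = 0.05,
                    delay: float = 3.0, seed: int = 0,
                    injection_factor: float = 1.0,
                    dt: float = 1.0, run_length: float = 480.0,
                    wavelengths=None, include_internal_standard: bool = True,
                    solvent_front_height: float = 0.3,
                    ms_amplitude: float = 1e6, ms_noise: float = 1e3
                    ) -> tuple[PDAChromatogram, list[MSTrace], SimTruth]:
    """Simulate one PDA + MS chromatogram pair with ground truth.

    Parameters
    ----------
    analytes : sequence of SimAnalyte
        The dissolved species (the internal standard is appended
        automatically unless ``include_internal_standard`` is False).
    noise_sigma : float
        PDA white-noise standard deviation, AU (default 2 mAU).
    drift_amplitude : float
        Baseline drift amplitude, AU; the drift follows the gradient shape
        (solvent-composition absorbance).
    delay : float
        PDA->MS transit delay in seconds; MS peaks appear at retention +
        delay.
    injection_factor : float
        Joint multiplicative perturbation of the injected amount (autosampler
        variability); scales every analyte and the internal standard alike,
        which is exactly what the internal standard corrects.
    """
    constants = constants or SystemConstants()
    gradient = gradient or GradientProgram.default_8min()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, run_length + 0.5 * dt, dt)
    wl = (np.arange(200.0, 801.0, 1.0) if wavelengths is None
          else np.asarray(wavelengths, dtype=float))

    all_analytes = list(analytes)
    if include_internal_standard and not any(a.label == "IST"
                                             for a in all_analytes):
        all_analytes.append(internal_standard_analyte())

    A = np.zeros((times.size, wl.size))
    true_areas, eps_red, true_yields = {}, {}, {}
    for an in all_analytes:
        phi = gradient.fraction(an.retention)
        eps = an.eps_red_at(phi)
        moles = an.conc * constants.injection_volume * 1e-6 * injection_factor
        area = area_from_moles(moles, eps, constants)
        profile = _gaussian_profile(times, an.retention, an.peak_sigma, area)
        if an.spectral_shift == 0.0:
            A += np.outer(profile, an.spectrum(wl))
        else:
            live = profile > 1e-9 * profile.max()
            for i in np.where(live)[0]:
                A[i] += profile[i] * an.spectrum(
                    wl, t_offset=times[i] - an.retention)
        true_areas[an.label] = area
        eps_red[an.label] = eps
        sample_conc = an.conc
        true_yields[an.label] = (sample_conc * constants.dilution_factor
                                 / constants.reactant_conc)

    # solvent front: strong short-wavelength spike right after the dead time
    if solvent_front_height > 0:
        front = _gaussian_profile(times, 15.0, 2.0,
                                  solvent_front_height * 2.0 * math.sqrt(2 * math.pi))
        front_spec = np.exp(-0.5 * ((wl - 205.0) / 12.0) ** 2)
        A += np.outer(front, front_spec)

    phi_t = np.array([gradient.fraction(t) for t in times])
    drift = drift_amplitude * (phi_t - phi_t[0]) / max(1.0 - phi_t[0], 1e-9)
    A += drift[:, None]
    # draws consumed even at zero sigma: same-seed samples share every other
    # random quantity regardless of the noise level
    A += noise_sigma * rng.standard_normal(A.shape)

    pda = PDAChromatogram(times, wl, A)

    traces = []
    for an in all_analytes:
        if not an.ionizes:
            continue
        ion_eff = ms_amplitude * float(rng.uniform(0.3, 3.0))
        inten = ion_eff * np.exp(
            -0.5 * ((times - (an.retention + delay)) / an.peak_sigma) ** 2)
        inten = inten + ms_noise * rng.standard_normal(times.size)
        traces.append(MSTrace(times, np.clip(inten, 0.0, None), mz=an.mz))

    truth = SimTruth(
        analytes=tuple(all_analytes), true_yields=true_yields,
        true_areas=true_areas, eps_red=eps_red, drift=drift,
        noise_sigma=noise_sigma,
        pipetting_error={"injection_factor": injection_factor},
        delay=delay,
        ist_nominal_area=ist_nominal_area(constants, gradient),
        seed=seed)
    return pda, traces, truth


def _draw_compound_properties(rng, eps_range):
    """Fixed per-compound synthetic optical properties for one campaign."""
    lam_red = float(rng.uniform(250.0, 420.0))
    bands = [(lam_red, float(rng.uniform(12.0, 22.0)), 1.0)]
    for _ in range(int(rng.integers(0, 3))):
        sep = float(rng.uniform(60.0, 130.0))
        center = lam_red - sep
        if center < 210.0:
            continue
        bands.append((center, float(rng.uniform(12.0, 22.0)),
                      float(rng.uniform(0.3, 1.4))))
    log_eps_w = float(rng.uniform(*eps_range))
    log_eps_a = float(np.clip(log_eps_w + rng.uniform(-0.15, 0.15), *eps_range))
    return tuple(bands), log_eps_w, log_eps_a


def simulate_campaign(n_samples: int, seed: int = 0,
                      noise_sigma: float = 0.002,
                      drift_amplitude: float = 0.05,
                      pipetting_sigma_ul: float = 0.5,
                      total_volume_ul: float = 100.0,
                      injection_error_rel: float = 0.0,
                      eps_sigma_log10: float = 0.0,
                      overlap_fraction: float = 0.3,
                      constants: SystemConstants | None = None,
                      gradient: GradientProgram | None = None,
                      delay: float = 3.0,
                      eps_range=DEFAULT_EPS_RANGE,
                      out_dir=None) -> Campaign:
    """Simulate a campaign of 1-3-analyte samples with a truth table.

    Each sample has one target analyte with a drawn true yield plus up to two
    non-target impurities; a fraction ``overlap_fraction`` of impurities are
    placed to co-elute with the target so the curve-resolution path is
    exercised. Liquid-handling error enters twice: per-analyte concentration
    error of ``pipetting_sigma_ul`` on ``total_volume_ul`` (uncorrectable)
    and a joint injection perturbation of relative scale
    ``injection_error_rel`` (corrected by the internal standard).
    ``eps_sigma_log10`` perturbs the extinction-coefficient table handed to
    the analysis, separating prediction-model error from chromatographic
    error; the exact table is always returned alongside.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    from rdkit import Chem
    from rdkit.Chem.Descriptors import ExactMolWt

    constants = constants or SystemConstants()
    gradient = gradient or GradientProgram.default_8min()
    rng = np.random.default_rng(seed)

    # per-compound properties, fixed for the campaign
    props = {}
    masses = {}
    for name, smiles in COMPOUND_LIBRARY:
        props[name] = _draw_compound_properties(rng, eps_range)
        masses[name] = float(ExactMolWt(Chem.MolFromSmiles(smiles)))
    smiles_of = dict(COMPOUND_LIBRARY)

    exact_table = TablePredictor()
    noisy_table = TablePredictor()
    for name, _ in COMPOUND_LIBRARY:
        bands, lw, la = props[name]
        lam_red = max(c for c, _, _ in bands)
        for solvent, val in (("water", lw), ("acetonitrile", la)):
            exact_table.add(smiles_of[name], solvent, val,
                            lambda_max=lam_red)
            # the standard-normal draw is consumed regardless of sigma so
            # campaigns sharing a seed differ only in error magnitude
            draw = float(rng.standard_normal())
            noisy_table.add(
                smiles_of[name], solvent, val + draw * eps_sigma_log10,
                log10_eps_std=eps_sigma_log10, lambda_max=lam_red,
                n_models=10 if eps_sigma_log10 > 0 else 1)

    base_nominal = ist_nominal_area(constants, gradient)
    constants = dataclasses.replace(constants, ist_nominal_area=base_nominal,
                                    pda_ms_delay=delay)

    samples = []
    rows = []
    conc_rel_sigma = pipetting_sigma_ul / total_volume_ul
    for i in range(n_samples):
        n_analytes = int(rng.integers(1, 4))
        names = list(rng.choice([n for n, _ in COMPOUND_LIBRARY],
                                size=n_analytes, replace=False))
        # avoid m/z collisions within a sample (unit-resolution channels)
        while True:
            mzs = [masses[n] + PROTON_MASS for n in names]
            clashes = [j for j in range(1, len(names))
                       if any(abs(mzs[j] - mzs[k]) < 1.0 for k in range(j))]
            if not clashes:
                break
            for j in clashes:
                names[j] = str(rng.choice(
                    [n for n, _ in COMPOUND_LIBRARY if n not in names]))
        target = names[0]
        true_yield = float(rng.uniform(0.15, 1.0))
        target_rt = float(rng.uniform(60.0, 330.0))
        overlapped = False
        analytes = []
        for j, name in enumerate(names):
            bands, lw, la = props[name]
            if j == 0:
                nominal_conc = (true_yield * constants.reactant_conc
                                / constants.dilution_factor)
                rt = target_rt
            else:
                nominal_conc = float(rng.uniform(1e-3, 5e-3))
                if rng.random() < overlap_fraction:
                    rt = target_rt + float(rng.uniform(3.0, 8.0)
                                           * rng.choice([-1.0, 1.0]))
                    rt = float(np.clip(rt, 50.0, 335.0))
                    overlapped = True
                else:
                    # well-separated impurity, rejection-sampled so it
                    # neither co-elutes with the target nor piles up at the
                    # run boundaries
                    for _ in range(50):
                        rt = float(rng.uniform(50.0, 335.0))
                        if abs(rt - target_rt) >= 30.0:
                            break
            conc = nominal_conc * max(
                1.0 + float(rng.standard_normal()) * conc_rel_sigma, 0.0)
            analytes.append(SimAnalyte(
                label=name, conc=conc, log10_eps_water=lw, log10_eps_acn=la,
                spectrum_bands=bands, retention=rt,
                peak_sigma=float(rng.uniform(2.0, 4.0)),
                mz=masses[name] + PROTON_MASS, smiles=smiles_of[name],
                eps_range=eps_range))
        injection_factor = float(np.clip(
            1.0 + rng.standard_normal() * injection_error_rel, 0.6, 1.4))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pda, traces, truth = simulate_sample(
            analytes, constants=constants, gradient=gradient,
            noise_sigma=noise_sigma, drift_amplitude=drift_amplitude,
            delay=delay, seed=sub_seed, injection_factor=injection_factor)
        sample_id = f"sample_{i:04d}"
        target_spec = AnalyteSpec(smiles=smiles_of[target],
                                  exact_mass=masses[target])
        samples.append(SimSample(sample_id=sample_id, pda=pda,
                                 ms_traces=tuple(traces), truth=truth,
                                 target_label=target,
                                 target_spec=target_spec))
        rows.append({"sample_id": sample_id, "target": target,
                     "smiles": smiles_of[target], "true_yield": true_yield,
                     "n_analytes": n_analytes, "overlapped": overlapped,
                     "retention": target_rt,
                     "injection_factor": injection_factor})

    truth_table = pd.DataFrame(rows)
    campaign = Campaign(samples=tuple(samples), truth_table=truth_table,
                        predictor_exact=exact_table, predictor=noisy_table,
                        constants=constants, gradient=gradient)
    if out_dir is not None:
        _write_campaign(campaign, out_dir)
    return campaign


def _write_campaign(campaign: Campaign, out_dir) -> None:
    os.makedirs(str(out_dir), exist_ok=True)
    for s in campaign.samples:
        write_pda(s.pda, os.path.join(str(out_dir), f"{s.sample_id}_pda.npz"))
        write_ms(list(s.ms_traces),
                 os.path.join(str(out_dir), f"{s.sample_id}_ms.npz"))
    campaign.truth_table.to_csv(
        os.path.join(str(out_dir), "truth.csv"), index=False)
    rows = []
    for (smiles, solvent), entry in campaign.predictor._table.items():
        rows.append({"smiles": smiles, "solvent": solvent, **entry})
    pd.DataFrame(rows).to_csv(
        os.path.join(str(out_dir), "epsilon_table.csv"), index=False)
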
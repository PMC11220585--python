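"""Shared fixtures: noiseless and noisy simulated samples with exact
extinction tables, plus a programmatic mzML writer for I/O tests."""

import base64

import numpy as np
import pytest

from chromyield.chromdata import (
    AnalyteSpec,
    GradientProgram,
    SystemConstants,
)
from chromyield.config import RunConfig
from chromyield.quantify import TablePredictor
from chromyield.simulate import SimAnalyte, ist_nominal_area, simulate_sample

BENZAMIDE = "NC(=O)c1ccccc1"


@pytest.fixture(scope="session")
def gradient():
    return GradientProgram.default_8min()


@pytest.fixture(scope="session")
def constants(gradient):
    base = SystemConstants()
    return SystemConstants(
        ist_nominal_area=ist_nominal_area(base, gradient), pda_ms_delay=3.0)


@pytest.fixture(scope="session")
def config(constants, gradient):
    return RunConfig(system=constants, gradient=gradient)


@pytest.fixture(scope="session")
def single_analyte():
    """One mid-gradient analyte at 3 mM (true yield 0.6 at 15 mM / 3x)."""
    return SimAnalyte(
        label="x", conc=3e-3, log10_eps_water=3.8, log10_eps_acn=3.9,
        spectrum_bands=((350.0, 18.0, 1.0), (270.0, 18.0, 0.8)),
        retention=200.0, peak_sigma=3.0, mz=486.00728, smiles=BENZAMIDE)


@pytest.fixture(scope="session")
def epsilon_table(single_analyte):
    pred = TablePredictor()
    pred.add(BENZAMIDE, "water", single_analyte.log10_eps_water,
             lambda_max=350.0)
    pred.add(BENZAMIDE, "acetonitrile", single_analyte.log10_eps_acn,
             lambda_max=350.0)
    return pred


@pytest.fixture(scope="session")
def target_spec():
    return AnalyteSpec(smiles=BENZAMIDE, exact_mass=485.0)


@pytest.fixture(scope="session")
def noiseless_sample(single_analyte, constants, gradient):
    return simulate_sample(
        [single_analyte], constants=constants, gradient=gradient,
        noise_sigma=0.0, drift_amplitude=0.0, delay=3.0, seed=1,
        ms_noise=0.0, solvent_front_height=0.0)


@pytest.fixture(scope="session")
def noisy_sample(single_analyte, constants, gradient):
    return simulate_sample(
        [single_analyte], constants=constants, gradient=gradient,
        noise_sigma=0.002, drift_amplitude=0.05, delay=3.0, seed=2)


def _b64(arr) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def write_minimal_mzml(path, scans, polarity="positive") -> str:
    """Write a synthetic, minimal mzML file for reader tests.

    ``scans`` is a list of (time_minutes, mz_array, intensity_array).
    """
    pol_acc = "MS:1000130" if polarity == "positive" else "MS:1000129"
    spectra = []
    for i, (t, mzs, ints) in enumerate(scans):
        spectra.append(f"""
   <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mzs)}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="{pol_acc}" name="{polarity} scan" value=""/>
    <scanList count="1"><scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{t}" unitName="minute"/>
    </scan></scanList>
    <binaryDataArrayList count="2">
     <binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/><cvParam cvRef="MS" accession="MS:1000576" name="no compression"/><cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/><binary>{_b64(mzs)}</binary></binaryDataArray>
     <binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/><cvParam cvRef="MS" accession="MS:1000576" name="no compression"/><cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/><binary>{_b64(ints)}</binary></binaryDataArray>
    </binaryDataArrayList>
   </spectrum>""")
    xml = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        ' <run id="r1">\n'
        f'  <spectrumList count="{len(scans)}">{"".join(spectra)}\n'
        "  </spectrumList>\n </run>\n</mzML>"
    )
    with open(str(path), "w") as fh:
        fh.write(xml)
    return str(path)
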
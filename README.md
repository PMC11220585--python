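# chromyield

Calibration-free reaction yield estimation from a single HPLC-PDA/MS run.

High-throughput and automated chemistry platforms routinely need the yield
of reactions for which no pure product standard exists, so no calibration
curve can be built. `chromyield` estimates yield from one chromatogram pair
instead: the expected product is located in time by its m/z in the
extracted-ion MS traces, the corresponding photo-diode-array (PDA) window is
resolved into pure components by multivariate curve resolution
(MCR-ALS, `A = CSᵀ + E` with non-negative `C` and `S`), and the resolved
product peak — integrated at the reddest maximum of its spectrum — is
converted to moles through the Beer–Lambert law,

    n = Q · a / (ε · ℓ)        yield = (n / V_inj) · d / c₀ᵣ

with flow rate `Q`, peak area `a`, path length `ℓ`, injection volume
`V_inj`, dilution factor `d` and initial reactant concentration `c₀ᵣ`. The
molar extinction coefficient ε is *predicted* (pluggable predictor; lookup
table or external trained ensemble) for pure water and pure acetonitrile and
combined at the volumetric gradient composition of the elution time. Before
any of that, the signal is smoothed, the solvent front masked, the
gradient-induced baseline drift removed per channel by asymmetrically
reweighted penalized least squares (arPLS), and all areas scaled by an
internal standard to cancel injection/dilution variability.

The package is aimed at screening-scale work (typical errors in the 10–25%
range on real systems, dominated by ε prediction and liquid handling); it
includes a full simulator of the study conditions so every stage is testable
without instrument data. See `docs/methods.md` for the model, its
assumptions and failure modes, and `docs/formats.md` for file formats.

## Worked example

Simulate one reaction sample (true yield 0.60 — i.e. a 3 mM product in the
injected sample against a 15 mM reaction diluted 3×) under realistic noise,
then estimate its yield with an exact extinction table:

```python
from chromyield import (AnalyteSpec, GradientProgram, ReactionYieldModel,
                        RunConfig, SystemConstants, TablePredictor)
from chromyield.simulate import SimAnalyte, ist_nominal_area, simulate_sample

smiles = "NC(=O)c1ccccc1"
gradient = GradientProgram.default_8min()
constants = SystemConstants(
    ist_nominal_area=ist_nominal_area(SystemConstants(), gradient),
    pda_ms_delay=3.0)
analyte = SimAnalyte(
    label="product", conc=3e-3, log10_eps_water=3.8, log10_eps_acn=3.9,
    spectrum_bands=((350.0, 18.0, 1.0), (270.0, 18.0, 0.8)),
    retention=200.0, peak_sigma=3.0, mz=486.00728, smiles=smiles)
pda, traces, truth = simulate_sample(
    [analyte], constants=constants, gradient=gradient,
    noise_sigma=0.002, drift_amplitude=0.05, delay=3.0, seed=7)

predictor = TablePredictor()
predictor.add(smiles, "water", 3.8, lambda_max=350.0)
predictor.add(smiles, "acetonitrile", 3.9, lambda_max=350.0)

model = ReactionYieldModel(
    pda, traces, AnalyteSpec(smiles=smiles, exact_mass=485.0),
    config=RunConfig(system=constants, gradient=gradient),
    epsilon_predictor=predictor)
print(model.fit().summary())
```

prints

```
Calibration-free HPLC yield estimate
============================================
yield                         0.604 (+- 0.004)
moles injected                6.038e-09 mol
sample concentration          3.019 mM
target area                   2.5808 AU*s (+- 0.0161)
quantification wavelength     350 nm
apex time                     200.0 s
epsilon (at elution)          7.124e+03 L/(mol cm) [phi_acn=0.499]
MCR components                1 (lack of fit 0.0269 AU*s)
internal-standard factor      1.0062
MS channel                    m/z 486.0073 (M+H)
signal check                  ok (suggest x1 injection)
flags                         none
config digest                 f729cefdc5aa5d9f
```

The estimate (0.604) recovers the simulated truth (0.600) to well under a
percent despite 2 mAU detector noise and 50 mAU gradient drift: the product
was found on the m/z 486.01 channel, its window resolved as a single pure
component (lack of fit 0.027 AU·s, far below the 0.2 AU·s threshold for
adding components), integrated at 350 nm, and converted with
ε ≈ 7.1 × 10³ L mol⁻¹ cm⁻¹ — the water/acetonitrile predictions averaged at
the 49.9% acetonitrile composition of the 200 s elution time. The ±0.004
uncertainty combines the MCR residual with the (here zero) ε ensemble
spread.

A command-line layer wraps the same objects:

```
chromyield simulate --n-samples 10 --out data/ --seed 1
chromyield quantify --pda data/sample_0000_pda.npz --ms data/sample_0000_ms.npz \
    --smiles "NC(=O)c1ccccc1" --config data/config.json --out report.json
chromyield campaign --dataset data/ --config data/config.json --out results.csv
```

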
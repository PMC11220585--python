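"""Data model and I/O for PDA and MS chromatograms and run constants.

A PDA (photo-diode array) chromatogram is a time x wavelength absorbance
matrix; an MS trace is an extracted-ion chromatogram for one m/z channel.
Internal time unit is seconds everywhere; minutes are accepted only at I/O
boundaries and converted once on load.

Two native dialects are supported for both data types:

* ``csv`` — plain delimited text with a two-line header (documented in
  ``docs/formats.md``), human-inspectable;
* ``npz`` — a NumPy packaged-array container plus a JSON sidecar
  (``<path>.meta.json``) carrying units and mask metadata.

MS traces can additionally be read (never written) from mzML, reduced to
extracted-ion traces at requested m/z +- tolerance.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ChannelLookupError,
    FormatError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "PDAChromatogram",
    "MSTrace",
    "AnalyteSpec",
    "SystemConstants",
    "GradientProgram",
    "load_pda",
    "write_pda",
    "load_ms",
    "write_ms",
]

_REL_DT_TOL = 1e-9


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValidationError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class PDAChromatogram:
    """Time x wavelength absorbance matrix with axes.

    Parameters
    ----------
    times : array of float
        Acquisition times in seconds, strictly increasing, uniformly spaced.
    wavelengths : array of float
        Wavelength axis in nm, strictly increasing, within [190, 900].
    absorbance : 2-D array of float
        Absorbance in AU, shape ``(len(times), len(wavelengths))``.
    t_dead : float
        Solvent-front mask: absorbance at ``t < t_dead`` is excluded from
        peak search and integration (data are kept, never deleted).
    """

    times: np.ndarray
    wavelengths: np.ndarray
    absorbance: np.ndarray
    t_dead: float = 0.0

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        wl = _as_float_array(self.wavelengths, "wavelengths")
        a = _as_float_array(self.absorbance, "absorbance")
        if a.ndim != 2 or a.shape != (times.size, wl.size):
            raise ValidationError(
                f"absorbance shape {a.shape} does not match axes "
                f"({times.size}, {wl.size})"
            )
        dt = np.diff(times)
        if times.size < 2 or np.any(dt <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _REL_DT_TOL * max(abs(dt[0]), 1.0):
            raise ValidationError(
                "time grid is not uniform; resample explicitly before "
                "constructing a PDAChromatogram"
            )
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if wl[0] < 190.0 or wl[-1] > 900.0:
            raise ValidationError("wavelength axis must lie within [190, 900] nm")
        if not (0.0 <= self.t_dead):
            raise ValidationError("t_dead must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", a)

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def live_mask(self) -> np.ndarray:
        """Boolean mask of time points outside the solvent-front dead volume."""
        return self.times >= self.t_dead

    def channel(self, wavelength: float) -> np.ndarray:
        """Absorbance trace of the channel nearest ``wavelength`` (nm)."""
        j = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return self.absorbance[:, j]

    def window_slice(self, t_start: float, t_end: float) -> slice:
        """Index slice covering ``[t_start, t_end]`` on the time axis."""
        i0 = int(np.searchsorted(self.times, t_start, side="left"))
        i1 = int(np.searchsorted(self.times, t_end, side="right"))
        return slice(i0, i1)

    def replace(self, **kw) -> "PDAChromatogram":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class MSTrace:
    """Extracted-ion chromatogram for one m/z channel."""

    times: np.ndarray
    intensity: np.ndarray
    mz: float
    polarity: str = "positive"

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        inten = _as_float_array(self.intensity, "intensity")
        if times.shape != inten.shape:
            raise ValidationError("times and intensity must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(inten < 0):
            raise ValidationError("intensities must be non-negative")
        if self.polarity not in ("positive", "negative"):
            raise ValidationError("polarity must be 'positive' or 'negative'")
        if not math.isfinite(self.mz) or self.mz <= 0:
            raise ValidationError("mz must be finite and positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensity", inten)


def _validate_smiles(smiles: str) -> None:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    if Chem.MolFromSmiles(smiles) is None:
        raise ValidationError(f"SMILES does not parse: {smiles!r}")


@dataclass(frozen=True)
class AnalyteSpec:
    """Expected product: structure, monoisotopic mass, and MS adducts."""

    smiles: str
    exact_mass: float
    adducts: tuple = ("M+H",)

    def __post_init__(self):
        _validate_smiles(self.smiles)
        if not (math.isfinite(self.exact_mass) and self.exact_mass > 0):
            raise ValidationError("exact_mass must be positive")
        object.__setattr__(self, "adducts", tuple(self.adducts))

    @classmethod
    def from_smiles(cls, smiles: str, adducts=("M+H",)) -> "AnalyteSpec":
        """Build a spec with the monoisotopic mass computed from the structure."""
        from rdkit import Chem
        from rdkit.Chem.Descriptors import ExactMolWt

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValidationError(f"SMILES does not parse: {smiles!r}")
        return cls(smiles=smiles, exact_mass=float(ExactMolWt(mol)), adducts=adducts)


@dataclass(frozen=True)
class SystemConstants:
    """Instrument and sample-preparation constants.

    Units: path_length cm, flow_rate mL/min, volumes uL, reactant_conc mol/L,
    ist_nominal_area AU*s, pda_ms_delay s (None -> estimated from the data).
    The defaults exist for tests and simulations; for real instrument data
    every field should come from the run configuration.
    """

    path_length: float = 1.0
    flow_rate: float = 1.0
    injection_volume: float = 2.0
    crude_volume: float = 50.0
    diluent_volume: float = 100.0
    reactant_conc: float = 0.015
    ist_nominal_area: float = 1.0
    pda_ms_delay: float | None = None

    def __post_init__(self):
        for name in (
            "path_length",
            "flow_rate",
            "injection_volume",
            "crude_volume",
            "diluent_volume",
            "reactant_conc",
            "ist_nominal_area",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be strictly positive, got {v}")

    @property
    def dilution_factor(self) -> float:
        """Crude -> sample dilution, (crude + diluent) / crude."""
        return (self.crude_volume + self.diluent_volume) / self.crude_volume

    @property
    def flow_rate_l_per_s(self) -> float:
        return self.flow_rate * 1e-3 / 60.0


@dataclass(frozen=True)
class GradientProgram:
    """Mobile-phase program as (time s, acetonitrile volume fraction) breakpoints."""

    breakpoints: tuple

    def __post_init__(self):
        bp = tuple((float(t), float(f)) for t, f in self.breakpoints)
        if len(bp) < 2:
            raise ValidationError("gradient needs at least two breakpoints")
        times = [t for t, _ in bp]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("breakpoint times must be non-decreasing")
        if any(not (0.0 <= f <= 1.0) for _, f in bp):
            raise ValidationError("acetonitrile fractions must lie in [0, 1]")
        object.__setattr__(self, "breakpoints", bp)

    @classmethod
    def default_8min(cls) -> "GradientProgram":
        """The standard 8-minute water-acetonitrile screening gradient.

        0.5 min at 5% MeCN, linear ramp to 100% over 6 min, 0.5 min hold,
        0.5 min return to 5%, 0.5 min re-equilibration.
        """
        return cls(
            breakpoints=(
                (0.0, 0.05),
                (30.0, 0.05),
                (390.0, 1.00),
                (420.0, 1.00),
                (450.0, 0.05),
                (480.0, 0.05),
            )
        )

    def fraction(self, t: float) -> float:
        """Piecewise-linear acetonitrile fraction at time ``t`` (s), clamped."""
        times = np.array([b[0] for b in self.breakpoints])
        fracs = np.array([b[1] for b in self.breakpoints])
        return float(np.interp(t, times, fracs))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PDA_CSV_MAGIC = "# chromyield-pda"
_MS_CSV_MAGIC = "# chromyield-ms"


def _infer_dialect(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".csv":
        return "csv"
    if ext == ".npz":
        return "npz"
    if ext == ".mzml":
        return "mzml"
    raise FormatError(f"cannot infer dialect from extension {ext!r}")


def write_pda(pda: PDAChromatogram, path, dialect: str | None = None) -> str:
    """Write a PDA chromatogram; returns the path written.

    The npz container stores the arrays; a JSON sidecar ``<path>.meta.json``
    records units and the solvent-front mask.
    """
    path = str(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        with open(path, "w") as fh:
            fh.write(f"{_PDA_CSV_MAGIC} time_unit=s wavelength_unit=nm "
                     f"t_dead={pda.t_dead!r}\n")
            fh.write("time," + ",".join(f"{w:.10g}" for w in pda.wavelengths) + "\n")
            for t, row in zip(pda.times, pda.absorbance):
                fh.write(f"{t:.10g}," + ",".join(f"{v:.12g}" for v in row) + "\n")
    elif dialect == "npz":
        np.savez(path, times=pda.times, wavelengths=pda.wavelengths,
                 absorbance=pda.absorbance)
        with open(path + ".meta.json", "w") as fh:
            json.dump({"kind": "pda", "time_unit": "s", "wavelength_unit": "nm",
                       "absorbance_unit": "AU", "t_dead": pda.t_dead}, fh)
    else:
        raise FormatError(f"unsupported PDA write dialect {dialect!r}")
    return path


def load_pda(path, dialect: str | None = None) -> PDAChromatogram:
    """Load a PDA chromatogram written by :func:`write_pda`."""
    path = str(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        return _load_pda_csv(path)
    if dialect == "npz":
        with np.load(path) as z:
            for key in ("times", "wavelengths", "absorbance"):
                if key not in z:
                    raise FormatError(f"npz container missing array {key!r}")
            times, wl, a = z["times"], z["wavelengths"], z["absorbance"]
        t_dead = 0.0
        meta_path = path + ".meta.json"
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                meta = json.load(fh)
            t_dead = float(meta.get("t_dead", 0.0))
            if meta.get("time_unit", "s") == "min":
                times = times * 60.0
        return PDAChromatogram(times, wl, a, t_dead=t_dead)
    raise FormatError(f"unsupported PDA read dialect {dialect!r}")


def _load_pda_csv(path: str) -> PDAChromatogram:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(_PDA_CSV_MAGIC):
            raise FormatError(
                f"{path}: first line must start with {_PDA_CSV_MAGIC!r}"
            )
        meta = dict(
            kv.split("=", 1) for kv in header[len(_PDA_CSV_MAGIC):].split() if "=" in kv
        )
        axis_line = fh.readline().strip()
        fields = axis_line.split(",")
        if not fields or fields[0] != "time":
            raise FormatError(f"{path}: second line must start with 'time'")
        try:
            wl = np.array([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: garbled wavelength axis: {exc}") from exc
        times, rows = [], []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            vals = line.split(",")
            if len(vals) != wl.size + 1:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(vals) - 1} wavelength "
                    f"columns, header declares {wl.size}"
                )
            times.append(float(vals[0]))
            rows.append([float(v) for v in vals[1:]])
    times = np.array(times)
    if meta.get("time_unit", "s") == "min":
        times = times * 60.0
    dt = np.diff(times)
    if times.size >= 2 and np.max(np.abs(dt - dt[0])) > _REL_DT_TOL * max(abs(dt[0]), 1.0):
        raise FormatError(
            f"{path}: non-uniform time grid; resample to a uniform grid "
            "before loading (see docs/formats.md)"
        )
    return PDAChromatogram(times, wl, np.array(rows),
                           t_dead=float(meta.get("t_dead", 0.0)))


def write_ms(traces, path, dialect: str | None = None) -> str:
    """Write extracted-ion traces (all on a shared time grid for csv)."""
    path = str(path)
    traces = list(traces)
    if not traces:
        raise ValidationError("no MS traces to write")
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        t0 = traces[0].times
        for tr in traces[1:]:
            if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
                raise ValidationError("csv dialect requires a shared time grid")
        with open(path, "w") as fh:
            fh.write(f"{_MS_CSV_MAGIC} time_unit=s "
                     f"polarity={traces[0].polarity}\n")
            fh.write("time," + ",".join(f"mz={tr.mz:.6f}" for tr in traces) + "\n")
            for i, t in enumerate(t0):
                fh.write(f"{t:.10g}," +
                         ",".join(f"{tr.intensity[i]:.10g}" for tr in traces) + "\n")
    elif dialect == "npz":
        arrays = {}
        for k, tr in enumerate(traces):
            arrays[f"times_{k}"] = tr.times
            arrays[f"intensity_{k}"] = tr.intensity
        np.savez(path, **arrays)
        with open(path + ".meta.json", "w") as fh:
            json.dump({"kind": "ms", "time_unit": "s",
                       "channels": [
                           {"mz": tr.mz, "polarity": tr.polarity}
                           for tr in traces]}, fh)
    else:
        raise FormatError(f"unsupported MS write dialect {dialect!r}")
    return path


def load_ms(path, dialect: str | None = None, mz_targets=None,
            mz_tol: float = 0.5) -> list[MSTrace]:
    """Load extracted-ion traces.

    For mzML input, ``mz_targets`` selects the channels to extract from the
    scans (each reduced to intensity summed over ``mz +- mz_tol``); without
    targets, SIM-style single-ion scans are grouped by their ion m/z.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        return _load_ms_csv(path)
    if dialect == "npz":
        meta_path = path + ".meta.json"
        if not os.path.exists(meta_path):
            raise FormatError(f"missing sidecar {meta_path}")
        with open(meta_path) as fh:
            meta = json.load(fh)
        scale = 60.0 if meta.get("time_unit", "s") == "min" else 1.0
        traces = []
        with np.load(path) as z:
            for k, ch in enumerate(meta["channels"]):
                traces.append(MSTrace(z[f"times_{k}"] * scale,
                                      z[f"intensity_{k}"],
                                      mz=float(ch["mz"]),
                                      polarity=ch.get("polarity", "positive")))
        return traces
    if dialect == "mzml":
        return _load_ms_mzml(path, mz_targets=mz_targets, mz_tol=mz_tol)
    raise FormatError(f"unsupported MS read dialect {dialect!r}")


def _load_ms_csv(path: str) -> list[MSTrace]:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(_MS_CSV_MAGIC):
            raise FormatError(f"{path}: first line must start with {_MS_CSV_MAGIC!r}")
        meta = dict(kv.split("=", 1)
                    for kv in header[len(_MS_CSV_MAGIC):].split() if "=" in kv)
        fields = fh.readline().strip().split(",")
        if not fields or fields[0] != "time":
            raise FormatError(f"{path}: second line must start with 'time'")
        try:
            mzs = [float(f.split("=", 1)[1]) for f in fields[1:]]
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: garbled channel labels: {exc}") from exc
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    times = data[:, 0]
    if meta.get("time_unit", "s") == "min":
        times = times * 60.0
    polarity = meta.get("polarity", "positive")
    return [MSTrace(times, data[:, j + 1], mz=mz, polarity=polarity)
            for j, mz in enumerate(mzs)]


def _decode_binary_array(elem, ns: str) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (float32/float64, zlib or none)."""
    import base64
    import zlib

    dtype = "<f8"
    compressed = False
    for cv in elem.findall(f"{ns}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
    binary = elem.find(f"{ns}binary")
    if binary is None or not (binary.text or "").strip():
        return np.zeros(0)
    raw = base64.b64decode(binary.text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _load_ms_mzml(path: str, mz_targets=None, mz_tol: float = 0.5) -> list[MSTrace]:
    """Minimal read-only mzML reader reducing scans to extracted-ion traces.

    Covers centroided/SIM spectra with float32/float64 arrays, zlib or no
    compression, scan start times in minutes or seconds.
    """
    from lxml import etree

    scan_times = []
    mz_arrays = []
    int_arrays = []
    polarity = "positive"
    root = etree.parse(str(path)).getroot()
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    for spec in root.iter(f"{ns}spectrum"):
        t_s = None
        for cv in spec.iter(f"{ns}cvParam"):
            acc = cv.get("accession", "")
            if acc == "MS:1000016":  # scan start time
                t_s = float(cv.get("value"))
                if "minute" in (cv.get("unitName") or "minute"):
                    t_s *= 60.0
            elif acc == "MS:1000129":
                polarity = "negative"
        if t_s is None:
            continue
        mz_arr = inten_arr = None
        for bda in spec.iter(f"{ns}binaryDataArray"):
            accs = {cv.get("accession", "")
                    for cv in bda.findall(f"{ns}cvParam")}
            if "MS:1000514" in accs:
                mz_arr = _decode_binary_array(bda, ns)
            elif "MS:1000515" in accs:
                inten_arr = _decode_binary_array(bda, ns)
        if mz_arr is None or inten_arr is None:
            continue
        scan_times.append(t_s)
        mz_arrays.append(mz_arr)
        int_arrays.append(inten_arr)
    if not scan_times:
        raise FormatError(f"{path}: no spectra with scan times found")
    order = np.argsort(scan_times)
    times = np.array(scan_times)[order]
    mz_arrays = [mz_arrays[i] for i in order]
    int_arrays = [int_arrays[i] for i in order]

    if mz_targets is None:
        # SIM-style: group by the (rounded) ion of each single-ion scan
        channels = sorted({round(float(m), 4) for arr in mz_arrays for m in arr})
        mz_targets = channels
    traces = []
    for target in mz_targets:
        intensity = np.zeros_like(times)
        hit = False
        for i, (mzs, ints) in enumerate(zip(mz_arrays, int_arrays)):
            sel = np.abs(mzs - target) <= mz_tol
            if np.any(sel):
                hit = True
                intensity[i] = float(np.sum(ints[sel]))
        if not hit:
            available = sorted({round(float(m), 4)
                                for arr in mz_arrays for m in arr})
            raise ChannelLookupError(float(target), available)
        traces.append(MSTrace(times, np.clip(intensity, 0.0, None),
                              mz=float(target), polarity=polarity))
    return traces


def select_trace(traces, mz: float, tol: float = 0.5) -> MSTrace:
    """Return the trace whose channel m/z is nearest ``mz`` within ``tol``."""
    traces = list(traces)
    if not traces:
        raise ChannelLookupError(mz, [])
    deltas = [abs(tr.mz - mz) for tr in traces]
    j = int(np.argmin(deltas))
    if deltas[j] > tol:
        raise ChannelLookupError(mz, [tr.mz for tr in traces])
    return traces[j]
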
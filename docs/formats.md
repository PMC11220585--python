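# File formats

All times are seconds and wavelengths nanometres once loaded; the CSV and
npz headers may declare `time_unit=min`, in which case the loader converts
once at the boundary. Loaders never resample: a non-uniform PDA time grid is
rejected with instructions to resample explicitly.

## PDA CSV dialect

Line 1 — magic + metadata, space-separated `key=value` pairs:

```
# chromyield-pda time_unit=s wavelength_unit=nm t_dead=0.0
```

Line 2 — axis header: the literal field `time` followed by one wavelength
per channel:

```
time,200,201,202,...,800
```

Lines 3+ — one row per time point: the time stamp then one absorbance (AU)
per declared channel. A row whose column count differs from the header is a
format error naming the line. Numbers are written with `%.12g` (values) and
`%.10g` (axes); a write/load roundtrip reproduces axes exactly and values to
better than 1e-9 AU.

## MS CSV dialect

```
# chromyield-ms time_unit=s polarity=positive
time,mz=486.007280,mz=300.100000
0,12.3,0
...
```

All channels share the time grid. Channel labels are `mz=<value>` with six
decimals.

## npz container

`numpy.savez` archives plus a JSON sidecar `<path>.meta.json`:

* PDA: arrays `times`, `wavelengths`, `absorbance`; sidecar carries units
  and the solvent-front mask `t_dead`.
* MS: arrays `times_<k>`, `intensity_<k>` per channel; sidecar lists the
  channels (`mz`, `polarity`) in order.

## mzML (read-only)

Scans are reduced to extracted-ion traces: for each requested m/z (or, with
no request, each distinct ion observed), the intensity within ±`mz_tol`
(default 0.5 Da) is summed per scan. Supported encodings: 32/64-bit float
arrays, zlib or no compression; scan start times in minutes or seconds.
Requesting an m/z absent from every scan raises a lookup error listing the
channels present.

## Run configuration (JSON)

One object with blocks `system`, `gradient`, `preprocess`, `ms`, `mcr`,
`signal`, `epsilon`; see `chromyield.config.RunConfig` for every key and
default. The gradient is written as `breakpoints_min` ([minutes, MeCN
fraction] pairs) for readability and converted to seconds on load.
`RunConfig.digest()` is the SHA-256 (first 16 hex digits) of the canonical
JSON; every run report records it.
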
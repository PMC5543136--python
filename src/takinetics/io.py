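"""Plain-text file formats: time-explicit matrices, scheme configs, reports.

The matrix layout is the de-facto standard of global-analysis software:
a header block, a first row of wavelengths, a first column of delays and
the dA body.  All files are delimited text and round-trip exactly
(``%.17g`` preserves float64); NaN cells denote masked data points and
map to zero fit weights on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datasets import TADataset
from .schemes import UNIT_TO_PS, DumpEvent, KineticScheme

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_scheme",
    "write_scheme",
    "write_spectra",
    "write_concentrations",
    "write_fit_report",
    "ParseError",
]

_DELIMS = {"tab": "\t", "comma": ","}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _fmt(x: float) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.17g}"


def write_matrix(
    dataset: TADataset,
    path,
    dialect: str = "tab",
    time_unit: str = "ps",
    title: str = "",
) -> None:
    """Write a dA(t, lambda) matrix as delimited text.

    Delays are expressed in ``time_unit`` (internally everything is in
    ps); zero-weight cells are written as NaN.
    """
    sep = _DELIMS[dialect]
    scale = UNIT_TO_PS[time_unit]
    body = np.where(dataset.weights > 0, dataset.delta_A, np.nan)
    lines = [
        "# takinetics matrix v1",
        f"# title: {title}",
        f"# time_unit: {time_unit}",
        "# wavelength_unit: nm",
        f"# delimiter: {dialect}",
        sep.join([""] + [_fmt(w) for w in dataset.wavelengths]),
    ]
    for i, t in enumerate(dataset.times):
        lines.append(sep.join([_fmt(t / scale)] + [_fmt(v) for v in body[i]]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path, dialect: str | None = None) -> TADataset:
    """Read a time-explicit matrix file into a :class:`TADataset` (ps/nm)."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[int, str]] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        if raw.startswith("#"):
            if ":" in raw:
                key, _, val = raw.lstrip("# ").partition(":")
                header[key.strip()] = val.strip()
            continue
        if raw.strip():
            rows.append((ln, raw))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    sep = _DELIMS[dialect or header.get("delimiter", "tab")]
    scale = UNIT_TO_PS.get(header.get("time_unit", "ps"))
    if scale is None:
        raise ParseError(f"{path}: unknown time unit {header.get('time_unit')!r}")

    ln0, first = rows[0]
    cells = first.split(sep)
    if cells[0].strip() not in ("", "time", "delay"):
        raise ParseError(f"{path}:{ln0}: first header cell must be empty")
    try:
        wavelengths = np.array([float(c) for c in cells[1:]])
    except ValueError as e:
        raise ParseError(f"{path}:{ln0}: bad wavelength row: {e}") from None
    times, data = [], []
    for ln, raw in rows[1:]:
        cells = raw.split(sep)
        if len(cells) != wavelengths.size + 1:
            raise ParseError(
                f"{path}:{ln}: ragged row ({len(cells)} cells, "
                f"expected {wavelengths.size + 1})"
            )
        try:
            times.append(float(cells[0]) * scale)
            data.append([float(c) for c in cells[1:]])
        except ValueError as e:
            raise ParseError(f"{path}:{ln}: bad value: {e}") from None
    times = np.array(times)
    for name, ax in (("delay", times), ("wavelength", wavelengths)):
        if ax.size > 1 and not np.all(np.diff(ax) > 0):
            raise ParseError(f"{path}: non-monotone {name} axis")
    return TADataset(
        times=times,
        wavelengths=wavelengths,
        delta_A=np.array(data),
        meta={"source": str(path), "title": header.get("title", "")},
    )


# ---------------------------------------------------------------------------
# scheme configuration


def write_scheme(scheme: KineticScheme, path, unit: str = "ps") -> None:
    """Write a kinetic scheme as a key-value text config (lossless)."""
    s = UNIT_TO_PS[unit]
    lines = ["# takinetics scheme v1"]
    if scheme.name:
        lines.append(f"name: {scheme.name}")
    lines.append(f"unit: {unit}")
    lines.append("compartments: " + " ".join(scheme.compartments))
    for key, group in (
        ("terminal", scheme.terminal),
        ("dark", scheme.dark),
        ("excited", scheme.excited),
        ("photoproduct", scheme.photoproduct),
    ):
        if group:
            lines.append(f"{key}: " + " ".join(group))
    for c, w in scheme.input_weights.items():
        if w > 0:
            lines.append(f"input: {c} {_fmt(w)}")
    for (src, dst), k in scheme.rates.items():
        lines.append(f"rate: {src} -> {dst} {_fmt(k * s)}")
    for ev in scheme.dump_events:
        for src, dst, f in ev.transfers:
            lines.append(f"dump: {_fmt(ev.time / s)} {src} -> {dst} {_fmt(f)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme(path) -> KineticScheme:
    """Parse a scheme config; rates in 1/unit, dump times in unit."""
    path = Path(path)
    unit = "ps"
    fields: dict = {
        "name": "",
        "compartments": (),
        "terminal": (),
        "dark": (),
        "excited": (),
        "photoproduct": (),
    }
    inputs: dict[str, float] = {}
    rates: dict = {}
    dumps: dict[float, list] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, rest = line.partition(":")
        key, rest = key.strip(), rest.strip()
        try:
            if key == "unit":
                if rest not in UNIT_TO_PS:
                    raise ValueError(f"unknown unit {rest!r}")
                unit = rest
            elif key == "name":
                fields["name"] = rest
            elif key in ("compartments", "terminal", "dark", "excited", "photoproduct"):
                fields[key] = tuple(rest.split())
            elif key == "input":
                c, w = rest.split()
                inputs[c] = float(w)
            elif key == "rate":
                lhs, _, val = rest.rpartition(" ")
                src, arrow, dst = lhs.split()
                if arrow != "->":
                    raise ValueError("expected 'src -> dst rate'")
                rates[(src, dst)] = float(val) / UNIT_TO_PS[unit]
            elif key == "dump":
                t, src, arrow, dst, frac = rest.split()
                if arrow != "->":
                    raise ValueError("expected 'time src -> dst fraction'")
                dumps.setdefault(float(t) * UNIT_TO_PS[unit], []).append(
                    (src, dst, float(frac))
                )
            else:
                raise ValueError(f"unknown directive {key!r}")
        except ValueError as e:
            raise ParseError(f"{path}:{ln}: {e}") from None
    events = tuple(
        DumpEvent(t, transfers) for t, transfers in sorted(dumps.items())
    )
    return KineticScheme(
        compartments=fields["compartments"],
        rates=rates,
        input_weights=inputs,
        terminal=fields["terminal"],
        dump_events=events,
        dark=fields["dark"],
        excited=fields["excited"],
        photoproduct=fields["photoproduct"],
        name=fields["name"],
    )


# ---------------------------------------------------------------------------
# result export


def write_spectra(spectra, path, dialect: str = "tab") -> None:
    sep = _DELIMS[dialect]
    lines = [
        "# takinetics spectra v1",
        f"# kind: {spectra.kind}",
        sep.join(["wavelength_nm"] + list(spectra.labels)),
    ]
    for j, wl in enumerate(spectra.wavelengths):
        lines.append(sep.join([_fmt(wl)] + [_fmt(v) for v in spectra.spectra[:, j]]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_concentrations(conc, path, dialect: str = "tab") -> None:
    sep = _DELIMS[dialect]
    lines = [
        "# takinetics concentrations v1",
        "# time_unit: ps",
        sep.join(["time_ps"] + list(conc.labels)),
    ]
    for i, t in enumerate(conc.times):
        lines.append(sep.join([_fmt(t)] + [_fmt(v) for v in conc.values[i]]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fit_report(fit, out_dir, name: str = "fit", extra_meta: dict | None = None):
    """Structured result export: text report plus a JSON log.

    The JSON log carries everything needed to reproduce the run
    (parameters, errors, SSQ, seeds, package version); spectra and
    concentration profiles go to delimited text files alongside.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{name}_report.txt").write_text(fit.summary() + "\n")
    log = {
        "version": __version__,
        "params": {k: _jsonable(v) for k, v in fit.params.items()},
        "stderr": {k: _jsonable(v) for k, v in fit.stderr.items()},
        "ssq": fit.ssq,
        "dof": fit.dof,
        "reduced_chi2": fit.reduced_chi2,
        "success": fit.success,
        "lifetimes_ps": _jsonable(fit.lifetimes),
        "yields": {
            t: {"value": v, "stderr": _jsonable(s)}
            for t, (v, s) in fit.extra.get("yields", {}).items()
        },
    }
    if extra_meta:
        log.update(extra_meta)
    (out / f"{name}_log.json").write_text(json.dumps(log, indent=2) + "\n")
    for kind, spec in fit.spectra.items():
        write_spectra(spec, out / f"{name}_{kind.lower()}.tsv")
    for i, conc in enumerate(fit.concentrations):
        write_concentrations(conc, out / f"{name}_concentrations{i}.tsv")
    return out / f"{name}_log.json"


def _jsonable(v):
    if v is None:
        return None
    if isinstance(v, np.ndarray):
        return [_jsonable(x) for x in v]
    if isinstance(v, (np.floating, float)):
        v = float(v)
        return v if np.isfinite(v) else ("inf" if v > 0 else "-inf") if not np.isnan(v) else "nan"
    return v
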
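"""TSV/YAML/JSON dialects for spectra, fraction tables, decay and enzyme data.

All numeric TSV output uses the shortest decimal representation that
round-trips each float exactly, so read(write(x)) reproduces x bit-for-bit.
Malformed files raise :class:`~sipracs.errors.FormatError` naming the
offending line or sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .kinetics import DecaySeries, EnzymePanel
from .raman import PeakShiftResult, RamanSpectrum
from .sip import FractionTable, REFRecord

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_fraction_table",
    "read_fraction_table",
    "write_decay_series",
    "read_decay_series",
    "write_enzyme_panel",
    "read_enzyme_panel",
    "write_ref_records",
    "read_ref_records",
    "write_classifications",
    "write_json",
]

_SUM_TOL = 1e-6  # tolerant of values that passed through text


def _fmt(x: float) -> str:
    # shortest decimal that round-trips the float exactly
    return repr(float(x))


def write_spectrum(s: RamanSpectrum, path: str | Path) -> None:
    """Write one spectrum as two-column TSV with '# key=value' header lines."""
    path = Path(path)
    lines = [
        f"# cell_id={s.cell_id}",
        f"# treatment={s.treatment}",
        f"# state={','.join(sorted(s.state))}",
        "wavenumber_cm-1\tintensity",
    ]
    for wn, y in zip(s.wavenumbers, s.intensities):
        lines.append(f"{_fmt(wn)}\t{_fmt(y)}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> RamanSpectrum:
    """Read the two-column spectrum dialect written by :func:`write_spectrum`."""
    path = Path(path)
    meta = {"cell_id": "", "treatment": "unknown", "state": "raw"}
    wavenumbers: list[float] = []
    intensities: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if line.startswith("wavenumber"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                wn, y = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-numeric field ({exc})") from None
            if wavenumbers and wn <= wavenumbers[-1]:
                raise FormatError(
                    f"{path.name}:{lineno}: wavenumbers must be strictly increasing"
                )
            wavenumbers.append(wn)
            intensities.append(y)
    if not wavenumbers:
        raise FormatError(f"{path.name}: no data rows")
    return RamanSpectrum(
        wavenumbers=np.array(wavenumbers),
        intensities=np.array(intensities),
        cell_id=meta["cell_id"],
        treatment=meta["treatment"],
        state=frozenset(meta["state"].split(",")),
    )


_FRACTION_COLUMNS = [
    "treatment",
    "fraction_class",
    "density_g_ml",
    "replicate",
    "asv_id",
    "rel_abundance",
]


def write_fraction_table(table: FractionTable, path: str | Path) -> None:
    """Write a fraction table in the long tidy dialect (one row per cell)."""
    rows = []
    for sid, srow in table.samples.iterrows():
        for asv_id, value in table.abundance[sid].items():
            rows.append(
                {
                    "treatment": table.treatment,
                    "fraction_class": srow["fraction_class"],
                    "density_g_ml": _fmt(srow["density_g_ml"]),
                    "replicate": srow["replicate"],
                    "asv_id": asv_id,
                    "rel_abundance": _fmt(value),
                }
            )
    pd.DataFrame(rows, columns=_FRACTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fraction_table(path: str | Path) -> FractionTable:
    """Read one treatment's long-format fraction table.

    Validates the column set, numeric fields, and that every sample's
    abundances sum to 1 (within text round-trip tolerance); a bad sample is
    named in the error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path.name}: cannot parse TSV ({exc})") from None
    missing = set(_FRACTION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    for col in ("density_g_ml", "rel_abundance"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise FormatError(
                f"{path.name}: non-numeric '{col}' at data row(s) {list(bad[:3])}"
            )
    treatments = df["treatment"].unique()
    if len(treatments) != 1:
        raise FormatError(f"{path.name}: expected one treatment, found {list(treatments)}")

    df = df.assign(
        sample_id=df["treatment"].astype(str)
        + "_"
        + df["fraction_class"].astype(str)
        + "_r"
        + df["replicate"].astype(str)
    )
    sums = df.groupby("sample_id")["rel_abundance"].sum()
    bad = sums[(sums - 1.0).abs() > _SUM_TOL]
    if len(bad):
        raise FormatError(
            f"{path.name}: sample '{bad.index[0]}' abundances sum to "
            f"{bad.iloc[0]:.6g}, expected 1"
        )
    samples = (
        df.drop_duplicates("sample_id")
        .set_index("sample_id")[["replicate", "fraction_class", "density_g_ml"]]
    )
    abundance = df.pivot_table(
        index="asv_id", columns="sample_id", values="rel_abundance", sort=False
    )[list(samples.index)]
    abundance.columns.name = None
    abundance.index.name = None
    return FractionTable(
        treatment=str(treatments[0]), samples=samples, abundance=abundance
    )


def write_decay_series(series: DecaySeries, path: str | Path) -> None:
    rows = []
    for i, t in enumerate(series.times):
        for r in range(series.concentrations.shape[1]):
            rows.append(
                {
                    "treatment": series.treatment,
                    "units": series.units,
                    "time_days": _fmt(t),
                    "replicate": r + 1,
                    "concentration": _fmt(series.concentrations[i, r]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_decay_series(path: str | Path) -> DecaySeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"treatment", "units", "time_days", "replicate", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    wide = df.pivot_table(index="time_days", columns="replicate", values="concentration")
    return DecaySeries(
        times=wide.index.to_numpy(dtype=float),
        concentrations=wide.to_numpy(dtype=float),
        treatment=str(df["treatment"].iloc[0]),
        units=str(df["units"].iloc[0]),
    )


def write_enzyme_panel(panels: list[EnzymePanel], path: str | Path) -> None:
    rows = []
    for panel in panels:
        for i, a in enumerate(panel.activities):
            label = panel.labels[i] if i < len(panel.labels) else i + 1
            rows.append(
                {
                    "enzyme": panel.enzyme,
                    "units": panel.units,
                    "sample": label,
                    "activity": _fmt(a),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_enzyme_panel(path: str | Path) -> list[EnzymePanel]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"enzyme", "units", "sample", "activity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    panels = []
    for enzyme, grp in df.groupby("enzyme", sort=False):
        panels.append(
            EnzymePanel(
                enzyme=str(enzyme),
                activities=grp["activity"].to_numpy(dtype=float),
                units=str(grp["units"].iloc[0]),
                labels=tuple(grp["sample"]),
            )
        )
    return panels


_REF_COLUMNS = [
    "asv_id",
    "a13_heavy",
    "a13_light",
    "a12_heavy",
    "a12_light",
    "ref",
    "mean_abundance",
    "active",
]


def write_ref_records(records: list[REFRecord], path: str | Path) -> None:
    rows = [
        {
            "asv_id": r.asv_id,
            "a13_heavy": _fmt(r.a13_heavy),
            "a13_light": _fmt(r.a13_light),
            "a12_heavy": _fmt(r.a12_heavy),
            "a12_light": _fmt(r.a12_light),
            "ref": _fmt(r.ref),
            "mean_abundance": _fmt(r.mean_abundance),
            "active": r.active,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_REF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ref_records(path: str | Path) -> list[REFRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        REFRecord(
            asv_id=str(r.asv_id),
            a13_heavy=float(r.a13_heavy),
            a13_light=float(r.a13_light),
            a12_heavy=float(r.a12_heavy),
            a12_light=float(r.a12_light),
            ref=float(r.ref),
            mean_abundance=float(r.mean_abundance),
            active=bool(r.active),
        )
        for r in df.itertuples()
    ]


def write_classifications(results: list[PeakShiftResult], path: str | Path) -> None:
    """Per-cell classification TSV: cell_id, observed position, shift, call."""
    rows = [
        {
            "cell_id": r.cell_id,
            "observed_position": "" if r.observed_position is None else _fmt(r.observed_position),
            "shift": "" if r.shift is None else _fmt(r.shift),
            "call": r.call,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
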
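"""Readers and writers for the pipeline's tab-separated/CSV interchange formats.

Beta matrix: tab-separated, first column ``probe_id``, header row of
sample ids.  Series-matrix dialect: same, but lines starting with ``!``
are metadata and skipped.  Sample sheet: CSV with columns sample_id,
group, family_id, relative_pool, sex, karyotype, kdm5c_copies,
kdm5d_copies.  Annotation: tab-separated per-probe metadata.  All writes
round-trip to full stored precision.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import IntensityData


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


SAMPLE_SHEET_COLUMNS = [
    "sample_id", "group", "family_id", "relative_pool", "sex",
    "karyotype", "kdm5c_copies", "kdm5d_copies",
]


def _check_unique_probes(index: pd.Index, path) -> None:
    dup = index[index.duplicated()]
    if len(dup):
        # +2: header line plus 1-based numbering
        first = int(np.flatnonzero(index.duplicated())[0]) + 2
        raise ParseError(
            f"{path}: duplicated probe_id {dup[0]!r} (line {first})"
        )


def read_beta_matrix(path) -> pd.DataFrame:
    """Tab-separated probes x samples matrix; values clipped to [0, 1]."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (line 1)")
    _check_unique_probes(df.index, path)
    vals = df.to_numpy(dtype=float)
    out_of_range = np.nan_to_num(vals, nan=0.5)
    if ((out_of_range < 0) | (out_of_range > 1)).any():
        raise ParseError(f"{path}: beta values outside [0, 1]")
    df.index.name = "probe_id"
    return df


def read_series_matrix(path) -> pd.DataFrame:
    """GEO series-matrix-style file: '!'-prefixed metadata lines skipped."""
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("!") and ln.strip()]
    if not lines:
        raise ParseError(f"{path}: no data lines after skipping metadata")
    return read_beta_matrix(_io.StringIO("".join(lines)))


def read_sample_sheet(path) -> pd.DataFrame:
    """CSV sample sheet; requires sample_id and group columns."""
    df = pd.read_csv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r} (line 1)")
    if df["sample_id"].duplicated().any():
        bad = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        line = int(df.index[df["sample_id"] == bad][1]) + 2
        raise ParseError(f"{path}: duplicated sample_id {bad!r} (line {line})")
    if "family_id" in df:
        df["family_id"] = df["family_id"].fillna("").astype(str)
    if "relative_pool" in df:
        df["relative_pool"] = df["relative_pool"].astype(bool)
    return df


def read_annotation(path) -> pd.DataFrame:
    """Tab-separated probe annotation (manifest-like)."""
    df = pd.read_csv(path, sep="\t")
    if "probe_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'probe_id' (line 1)")
    if df["probe_id"].duplicated().any():
        bad = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicated probe_id {bad!r}")
    for col in ("cpg_island", "cross_reactive", "snp_overlap"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def read_intensity_table(path) -> IntensityData:
    """Long-format intensities: probe_id, sample_id, M, U, detection_p.

    An optional per-sample ``bs_control`` column (constant within sample)
    supplies the bisulfite-conversion control intensity.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "sample_id", "M", "U", "detection_p"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)} (line 1)")
    if df.duplicated(["probe_id", "sample_id"]).any():
        i = int(df.index[df.duplicated(["probe_id", "sample_id"])][0]) + 2
        raise ParseError(f"{path}: duplicated (probe_id, sample_id) (line {i})")
    m = df.pivot(index="probe_id", columns="sample_id", values="M")
    u = df.pivot(index="probe_id", columns="sample_id", values="U")
    d = df.pivot(index="probe_id", columns="sample_id", values="detection_p")
    if "bs_control" in df.columns:
        bs = df.groupby("sample_id")["bs_control"].first()
    else:
        bs = pd.Series(np.inf, index=m.columns, name="bs_control")
    return IntensityData(m, u, d, bs.reindex(m.columns))


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.17g")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + "\n")


def format_p(p: float, digits: int = 3) -> str:
    """Scientific-notation p-value with a truncated mantissa, e.g. 9.98E-08.

    The mantissa is truncated toward zero at ``digits`` significant
    figures (9.985e-8 prints as 9.98E-08), matching the display style of
    the array-analysis reports this pipeline mirrors.
    """
    import math as _math

    if p == 0 or not np.isfinite(p):
        return f"{p:.2E}"
    exp = _math.floor(_math.log10(abs(p)))
    mant = p / 10.0**exp
    scale = 10.0 ** (digits - 1)
    mant = _math.floor(mant * scale + 1e-9) / scale
    return f"{mant:.{digits - 1}f}E{exp:+03d}"


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write a dict of named tables as <name>.tsv files under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        write_table(df, path, index=False)
        written.append(path)
    return written


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
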
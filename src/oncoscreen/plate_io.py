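"""Plate-table and plate-map I/O.

Reads long- or wide-format plate-reader exports into a tidy measurement
table (one row per well, one column per optical channel), joins plate
maps that annotate wells with construct/compound, condition and
replicate, and writes deterministic TSV/CSV result tables.

Well coordinates follow common plate-reader conventions: rows lettered
A..H (96), A..P (384), A..AF (1536) top to bottom, columns 1-based left
to right.  Canonical well IDs zero-pad the column to two digits
("A1" -> "A01"); normalization is idempotent.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, JoinError, LayoutError

#: channel columns a measurement table may carry (at least one required)
MEASUREMENT_CHANNELS = (
    "L460",
    "F535",
    "venus_fi",
    "F620",
    "F665",
    "viability_signal",
    "confluence_pct",
)

#: well roles a plate map may assign
ROLES = frozenset(
    {"ppi", "ctrl_donor_only", "ctrl_acceptor_only", "compound", "dmso", "blank", "positive"}
)

#: geometry -> (n_rows, n_cols)
GEOMETRIES = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}

_WELL_RE = re.compile(r"^([A-Za-z]{1,2})0*([1-9][0-9]*)$")


def parse_well(well: str) -> tuple[int, int]:
    """Return (row_index, column) for a well ID; row_index is 0-based (A=0, AA=26)."""
    m = _WELL_RE.match(str(well).strip())
    if m is None:
        raise LayoutError(f"unparseable well ID {well!r}")
    letters = m.group(1).upper()
    if len(letters) == 1:
        row = ord(letters) - ord("A")
    else:
        row = 26 * (ord(letters[0]) - ord("A") + 1) + (ord(letters[1]) - ord("A"))
    return row, int(m.group(2))


def normalize_well(well: str) -> str:
    """Canonical zero-padded form, e.g. "a1" -> "A01". Idempotent."""
    row, col = parse_well(well)
    if row < 26:
        letters = chr(ord("A") + row)
    else:
        letters = "A" + chr(ord("A") + row - 26)
    return f"{letters}{col:02d}"


def validate_well(well: str, geometry: int) -> str:
    """Normalize and bounds-check a well against a plate geometry."""
    if geometry not in GEOMETRIES:
        raise ConfigError(f"unknown plate geometry {geometry!r}; expected one of {sorted(GEOMETRIES)}")
    n_rows, n_cols = GEOMETRIES[geometry]
    row, col = parse_well(well)
    if row >= n_rows or col > n_cols:
        raise LayoutError(f"well {well!r} outside {geometry}-well geometry")
    return normalize_well(well)


def load_config(path) -> dict:
    """Load a YAML key-value config (dialect, geometry, channel column names)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a key-value mapping")
    return cfg


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")


def read_plate_table(
    path,
    geometry: int = 384,
    dialect: str = "long",
    columns: dict | None = None,
) -> pd.DataFrame:
    """Read a plate-reader export into a tidy well-measurement table.

    Parameters
    ----------
    path : path-like
        CSV/TSV file (separator sniffed from the extension; ``.tsv`` -> tab).
    geometry : {96, 384, 1536}
        Declared plate geometry; wells outside it raise :class:`LayoutError`.
    dialect : {"long", "wide"}
        ``long``: one row per well per channel with columns
        (plate_id, well, channel, value).  ``wide``: one row per well with
        one column per channel.
    columns : dict, optional
        Rename map from the file's column names to the expected ones,
        e.g. ``{"Plate": "plate_id", "Well": "well"}``.

    Returns
    -------
    pandas.DataFrame
        One row per (plate_id, well) with normalized well IDs and one
        column per channel present in the file.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if columns:
        df = df.rename(columns=columns)

    if dialect == "long":
        _require_columns(df, ("plate_id", "well", "channel", "value"), path)
        bad = set(df["channel"]) - set(MEASUREMENT_CHANNELS)
        if bad:
            raise FormatError(f"unknown channel(s) {sorted(bad)} in {path}")
        if df.duplicated(["plate_id", "well", "channel"]).any():
            raise FormatError(f"duplicate (plate_id, well, channel) rows in {path}")
        wide = df.pivot(index=["plate_id", "well"], columns="channel", values="value")
        wide = wide.reset_index()
        wide.columns.name = None
        # preserve order of first appearance
        order = df.drop_duplicates(["plate_id", "well"])[["plate_id", "well"]]
        wide = order.merge(wide, on=["plate_id", "well"], how="left")
    elif dialect == "wide":
        _require_columns(df, ("plate_id", "well"), path)
        present = [c for c in df.columns if c in MEASUREMENT_CHANNELS]
        if not present:
            raise FormatError(
                f"no channel column found in {path}; expected one of {MEASUREMENT_CHANNELS}"
            )
        if df.duplicated(["plate_id", "well"]).any():
            raise FormatError(f"duplicate (plate_id, well) rows in {path}")
        wide = df[["plate_id", "well", *present]].copy()
    else:
        raise ConfigError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")

    wide["well"] = [validate_well(w, geometry) for w in wide["well"]]
    channel_cols = [c for c in wide.columns if c in MEASUREMENT_CHANNELS]
    values = wide[channel_cols].to_numpy(dtype=float)
    if np.isinf(values).any():
        raise FormatError(f"non-finite intensity in {path}")
    if pd.isna(values).all(axis=1).any():
        raise FormatError(f"well with no populated channel in {path}")
    return wide


def validate_plate_map(plate_map: pd.DataFrame, geometry: int = 384) -> pd.DataFrame:
    """Normalize wells and enforce plate-map invariants (valid roles, no duplicates)."""
    _require_columns(plate_map, ("plate_id", "well", "role"), "plate map")
    pm = plate_map.copy()
    pm["well"] = [validate_well(w, geometry) for w in pm["well"]]
    if pm.duplicated(["plate_id", "well"]).any():
        dups = pm[pm.duplicated(["plate_id", "well"])][["plate_id", "well"]]
        raise FormatError(f"duplicate plate-map entries: {dups.to_records(index=False).tolist()}")
    bad_roles = set(pm["role"]) - ROLES
    if bad_roles:
        raise FormatError(f"unknown role(s) {sorted(bad_roles)} in plate map")
    if "replicate" in pm.columns:
        reps = pd.to_numeric(pm["replicate"], errors="coerce")
        if (reps.dropna() < 1).any():
            raise FormatError("replicate numbers must be positive integers")
    return pm


def join_plate_map(
    measurements: pd.DataFrame, plate_map: pd.DataFrame, geometry: int = 384
) -> pd.DataFrame:
    """Annotate each measurement row with its plate-map entry.

    Every measurement (plate_id, well) must appear in the map; unmatched
    wells raise :class:`JoinError` listing them.  An empty measurement
    table joins to an empty annotated table.
    """
    pm = validate_plate_map(plate_map, geometry)
    meas = measurements.copy()
    if len(meas) == 0:
        annotation_cols = [c for c in pm.columns if c not in ("plate_id", "well")]
        out = meas.copy()
        for c in annotation_cols:
            out[c] = pd.Series(dtype=pm[c].dtype)
        return out
    meas["well"] = [validate_well(w, geometry) for w in meas["well"]]
    joined = meas.merge(pm, on=["plate_id", "well"], how="left", validate="many_to_one")
    unmatched = joined[joined["role"].isna()]
    if len(unmatched):
        wells = list(unmatched[["plate_id", "well"]].itertuples(index=False, name=None))
        raise JoinError(f"{len(wells)} well(s) missing from plate map: {wells[:20]}", wells=wells)
    return joined


def write_results(table: pd.DataFrame, path, sep: str = "\t", allow_empty: bool = False) -> None:
    """Write a results table as delimited text with header.

    Column order is the table's own; floats are written at full ``repr``
    precision, so identical tables produce byte-identical files.
    """
    if len(table) == 0 and not allow_empty:
        raise FormatError(f"refusing to write empty table to {path} (allow_empty=False)")
    table.to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_results(path, sep: str = "\t") -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep=sep)
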
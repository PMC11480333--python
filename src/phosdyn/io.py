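"""Parsers and writers for the external table formats.

All tables are tab-separated UTF-8 text with "." as the decimal separator.
Sequences travel as FASTA (via Biopython), the study design and thresholds as
YAML, result summaries as JSON.  Site tables come in two dialects: ``generic``
(columns ``protein_id``, ``position``, ``residue``, ``loc_prob`` plus one
intensity column per sample) and ``maxquant`` (the "Phospho (STY)Sites.txt"
column names: ``Protein``, ``Position``, ``Amino acid``, ``Localization prob``
and ``Reporter intensity <sample>`` columns).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .model import (
    AnalysisThresholds,
    PhosphoSite,
    StudyDesign,
    sites_to_frame,
)

__all__ = [
    "FormatError",
    "parse_fasta",
    "write_fasta",
    "parse_site_table",
    "write_site_table",
    "parse_protein_table",
    "write_protein_table",
    "read_design",
    "write_design",
    "read_thresholds",
    "write_thresholds",
    "parse_species_windows",
    "write_species_windows",
    "parse_catalog",
    "parse_edge_table",
    "write_edge_table",
    "parse_accession_list",
    "write_json",
]

_NULL_TOKENS = {"", "na", "nan", "n/a", "null", "none"}

_MAXQUANT_COLUMNS = {
    "Protein": "protein_id",
    "Position": "position",
    "Amino acid": "residue",
    "Localization prob": "loc_prob",
}
_MAXQUANT_INTENSITY_PREFIX = "Reporter intensity "


class FormatError(ValueError):
    """A table does not conform to its declared format."""


def parse_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an accession -> uppercase sequence map.

    The accession is the header token before the first whitespace.  Empty
    files and duplicate accessions are errors.
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in records:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        records[acc] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_float_cell(value, row_label, column, errors) -> float:
    if value is None:
        return np.nan
    text = str(value).strip()
    if text.lower() in _NULL_TOKENS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        errors.append(f"row {row_label!r}, column {column!r}: unparseable value {text!r}")
        return np.nan


def parse_site_table(
    path: str | Path,
    dialect: str = "generic",
    design: StudyDesign | None = None,
) -> tuple[list[PhosphoSite], pd.DataFrame]:
    """Read a phosphosite table: one :class:`PhosphoSite` per row plus intensities.

    Returns ``(sites, intensity)`` where ``intensity`` is a DataFrame indexed
    by site_id with one column per sample (NaN for null cells).  Duplicate
    (protein, position) keys and unparseable numeric cells are rejected with
    row-level diagnostics; missing required columns raise naming the column.
    """
    if dialect not in ("generic", "maxquant"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    if dialect == "maxquant":
        missing = [c for c in _MAXQUANT_COLUMNS if c not in raw.columns]
        if missing:
            raise FormatError(f"missing required column(s) {missing} in {path}")
        intensity_cols = {
            c: c[len(_MAXQUANT_INTENSITY_PREFIX):]
            for c in raw.columns
            if c.startswith(_MAXQUANT_INTENSITY_PREFIX)
        }
        raw = raw.rename(columns={**_MAXQUANT_COLUMNS, **intensity_cols})

    required = ["protein_id", "position", "residue", "loc_prob"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")

    meta_cols = set(required) | {"site_id", "site_class", "window"}
    if design is not None:
        sample_cols = list(design.samples_all)
        absent = [s for s in sample_cols if s not in raw.columns]
        if absent:
            raise FormatError(f"missing intensity column(s) for design samples {absent}")
    else:
        sample_cols = [c for c in raw.columns if c not in meta_cols]

    errors: list[str] = []
    sites: list[PhosphoSite] = []
    intensity_rows: list[list[float]] = []
    seen: dict[tuple[str, int], str] = {}
    duplicates: list[str] = []

    for idx, row in raw.iterrows():
        label = row.get("site_id", "") or f"#{idx + 2}"  # +2: header + 1-based
        try:
            position = int(str(row["position"]).strip())
        except ValueError:
            errors.append(f"row {label!r}: unparseable position {row['position']!r}")
            continue
        loc_prob = _parse_float_cell(row["loc_prob"], label, "loc_prob", errors)
        if np.isnan(loc_prob):
            errors.append(f"row {label!r}: missing localization probability")
            continue
        protein_id = str(row["protein_id"]).strip()
        residue = str(row["residue"]).strip().upper()
        site_id = str(row.get("site_id", "")).strip() or f"{protein_id}_{residue}{position}"
        window = str(row.get("window", "")).strip() or None
        try:
            site = PhosphoSite(
                site_id=site_id,
                protein_id=protein_id,
                position=position,
                residue=residue,
                loc_prob=loc_prob,
                window=window,
            )
        except ValueError as exc:
            errors.append(f"row {label!r}: {exc}")
            continue
        key = site.key
        if key in seen:
            duplicates.append(f"{key[0]}:{key[1]} (rows {seen[key]!r} and {label!r})")
            continue
        seen[key] = label
        values = [_parse_float_cell(row[c], label, c, errors) for c in sample_cols]
        sites.append(site)
        intensity_rows.append(values)

    if duplicates:
        raise FormatError(f"duplicate (protein, position) entries: {duplicates}")
    if errors:
        raise FormatError("site table has invalid rows:\n  " + "\n  ".join(errors))

    intensity = pd.DataFrame(
        intensity_rows, index=[s.site_id for s in sites], columns=sample_cols, dtype=float
    )
    intensity.index.name = "site_id"
    return sites, intensity


def write_site_table(
    sites: Sequence[PhosphoSite],
    intensity: pd.DataFrame,
    path: str | Path,
) -> None:
    """Write the generic site-table dialect (metadata plus intensity columns)."""
    meta = sites_to_frame(sites)
    joined = meta.join(intensity.astype(float), how="left")
    joined.to_csv(path, sep="\t", index=False, na_rep="NA")


def parse_protein_table(
    path: str | Path, design: StudyDesign | None = None
) -> pd.DataFrame:
    """Read a protein intensity table (``protein_id`` + one column per sample)."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "protein_id" not in raw.columns:
        raise FormatError(f"missing required column(s) ['protein_id'] in {path}")
    if raw["protein_id"].duplicated().any():
        dups = raw.loc[raw["protein_id"].duplicated(), "protein_id"].tolist()
        raise FormatError(f"duplicate protein accessions: {dups}")
    sample_cols = [c for c in raw.columns if c != "protein_id"]
    if design is not None:
        absent = [s for s in design.samples_all if s not in sample_cols]
        if absent:
            raise FormatError(f"missing intensity column(s) for design samples {absent}")
        sample_cols = list(design.samples_all)
    errors: list[str] = []
    values = {
        c: [_parse_float_cell(v, r, c, errors) for r, v in zip(raw["protein_id"], raw[c])]
        for c in sample_cols
    }
    if errors:
        raise FormatError("protein table has invalid cells:\n  " + "\n  ".join(errors))
    out = pd.DataFrame(values, index=list(raw["protein_id"]), dtype=float)
    out.index.name = "protein_id"
    return out


def write_protein_table(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_design(path: str | Path) -> StudyDesign:
    with open(path, encoding="utf-8") as fh:
        return StudyDesign.from_dict(yaml.safe_load(fh))


def write_design(design: StudyDesign, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=False)


def read_thresholds(path: str | Path) -> AnalysisThresholds:
    with open(path, encoding="utf-8") as fh:
        return AnalysisThresholds.from_dict(yaml.safe_load(fh))


def write_thresholds(thresholds: AnalysisThresholds, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(thresholds.to_dict(), fh, sort_keys=False)


def parse_species_windows(path: str | Path) -> pd.DataFrame:
    """Read a species window table: columns ``species``, ``window_id``, ``window``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("species", "window_id", "window") if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")
    return df


def write_species_windows(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def parse_catalog(path: str | Path, name: str | None = None):
    """Read a reference site catalog keyed by (protein_id, position, residue)."""
    from .conservation import ReferenceCatalog

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("protein_id", "position", "residue") if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")
    keys = {
        (str(p), int(pos), str(r))
        for p, pos, r in zip(df["protein_id"], df["position"], df["residue"])
    }
    return ReferenceCatalog(name=name or Path(path).stem, keys=frozenset(keys))


def parse_edge_table(path: str | Path) -> pd.DataFrame:
    """Read kinase -> site edges: columns ``kinase_id``, ``site_id``, optional ``score``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("kinase_id", "site_id") if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")
    if "score" in df.columns:
        errors: list[str] = []
        df = df.assign(
            score=[_parse_float_cell(v, i, "score", errors) for i, v in enumerate(df["score"])]
        )
        if errors:
            raise FormatError("edge table has invalid scores:\n  " + "\n  ".join(errors))
    else:
        df = df.assign(score=np.nan)
    return df[["kinase_id", "site_id", "score"]]


def write_edge_table(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, na_rep="NA")


def parse_accession_list(path: str | Path) -> list[str]:
    """One accession per line; blank lines and ``#`` comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.append(token)
    return out


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
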
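"""Quantification chain: zero replacement, row-mean normalization, calibration.

The fixed order of operations is

    replace_zeros(protein_raw)
    -> rowmean_normalize(protein)
    -> rowmean_normalize(site)
    -> calibrate_sites(site_norm, protein_norm, site_to_protein)

Row-mean normalization divides each row by its own mean over non-null
entries, so every normalized row has mean exactly 1 and any global scaling of
a raw row cancels.  The zero rule applies only to the protein matrix: an
exact-zero protein cell is replaced by the global minimum non-zero value of
the matrix before normalization, so the subsequent division never hits zero.
Calibration divides each site row element-wise by the normalized row of its
parent protein, separating phosphorylation changes from protein-abundance
changes; a site whose protein was not quantified keeps its own normalized
row and is flagged ``site_only``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CalibratedMatrix",
    "replace_zeros",
    "rowmean_normalize",
    "calibrate_sites",
    "calibration_pipeline",
]


@dataclass(frozen=True)
class CalibratedMatrix:
    """Calibrated site levels plus per-site provenance.

    ``values`` is a site x sample DataFrame of positive reals;
    ``provenance`` maps each site to ``"calibrated"`` (divided by its
    protein) or ``"site_only"`` (protein not quantified, site level used
    directly).
    """

    values: pd.DataFrame
    provenance: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.provenance.index):
            raise ValueError("values and provenance must share the same site index")
        bad = set(self.provenance.unique()) - {"calibrated", "site_only"}
        if bad:
            raise ValueError(f"unknown provenance labels: {sorted(bad)}")


def replace_zeros(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace exact-zero cells with the global minimum non-zero value.

    Applies to raw protein matrices only; null cells are left untouched.
    A matrix with no positive value at all is an error.
    """
    values = matrix.to_numpy(dtype=float)
    positive = values[np.isfinite(values) & (values > 0)]
    if positive.size == 0:
        raise ValueError("cannot replace zeros: matrix has no non-zero values")
    floor = positive.min()
    out = matrix.astype(float).copy()
    out[out == 0.0] = floor
    return out


def rowmean_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its mean over non-null entries (output row means = 1)."""
    out = matrix.astype(float)
    means = out.mean(axis=1, skipna=True)
    all_null = means.isna()
    if all_null.any():
        rows = out.index[all_null].tolist()
        raise ValueError(f"row(s) with no non-null values cannot be normalized: {rows[:5]}")
    return out.div(means, axis=0)


def calibrate_sites(
    site_norm: pd.DataFrame,
    protein_norm: pd.DataFrame,
    site_to_protein: Mapping[str, str],
) -> CalibratedMatrix:
    """Divide normalized site rows by the normalized row of their protein.

    Sites whose protein is absent from ``protein_norm`` are passed through
    unchanged with provenance ``site_only``.  A zero in the normalized
    protein matrix indicates the zero rule was skipped and is an internal
    error.  Division by a null protein cell yields null for that cell.
    """
    if (protein_norm.to_numpy(dtype=float) == 0.0).any():
        raise ValueError(
            "protein matrix contains exact zeros; replace_zeros must run before normalization"
        )
    missing = [s for s in site_norm.index if s not in site_to_protein]
    if missing:
        raise ValueError(f"site(s) without a protein mapping: {missing[:5]}")

    proteins = pd.Series({s: site_to_protein[s] for s in site_norm.index})
    quantified = proteins.isin(protein_norm.index)

    values = site_norm.astype(float).copy()
    if quantified.any():
        idx = values.index[quantified]
        denom = protein_norm.loc[proteins[idx].to_numpy(), values.columns].to_numpy(dtype=float)
        values.loc[idx] = values.loc[idx].to_numpy(dtype=float) / denom
    provenance = pd.Series(
        np.where(quantified, "calibrated", "site_only"), index=values.index, name="provenance"
    )
    return CalibratedMatrix(values=values, provenance=provenance)


def calibration_pipeline(
    site_raw: pd.DataFrame,
    protein_raw: pd.DataFrame | None,
    site_to_protein: Mapping[str, str],
) -> CalibratedMatrix:
    """Run the full fixed-order chain from raw matrices to calibrated sites.

    ``protein_raw`` may be ``None`` (no proteome measured), in which case
    every site is ``site_only``.  Site-matrix zeros are treated as missing
    (the zero rule is defined for the protein matrix only).
    """
    site = site_raw.astype(float).mask(site_raw.astype(float) == 0.0)
    site_norm = rowmean_normalize(site)
    if protein_raw is None or protein_raw.empty:
        provenance = pd.Series("site_only", index=site_norm.index, name="provenance")
        return CalibratedMatrix(values=site_norm, provenance=provenance)
    protein_norm = rowmean_normalize(replace_zeros(protein_raw))
    return calibrate_sites(site_norm, protein_norm, site_to_protein)
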
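"""Cross-species conserved-phosphosite screen and novelty screening.

Each phosphosite is represented by a 13-mer sequence window (the residue
plus six flanking residues on each side, ``"_"``-padded beyond the protein
termini).  Similarity between two windows is the number of positions with
identical amino acids (pads never match anything, including another pad).
A window pair is *similar* when it matches in at least ``min_matches``
positions -- the default 9 is the smallest integer k with k/13 > 0.69 -- and
a site is *conserved* when, counting the reference species itself, at least
``min_species`` species carry a similar window.  Comparison is position-wise
on the fixed windows, all-vs-all within each species set: no alignment, no
gaps, no orthology mapping.

Novelty screening is a set lookup: a site is novel when its
(protein, position, residue) key is absent from every reference catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import rounded_percent
from .model import WINDOW_FLANK, WINDOW_LENGTH, WINDOW_PAD

__all__ = [
    "SpeciesWindowSet",
    "ReferenceCatalog",
    "extract_window",
    "count_matches",
    "similarity_threshold",
    "is_similar",
    "screen_conserved",
    "novel_sites",
]

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_ALPHABET = _AA20 | {WINDOW_PAD}


@dataclass(frozen=True)
class SpeciesWindowSet:
    """All 13-mer phosphopeptide windows observed in one species."""

    species: str
    windows: tuple[tuple[str, str], ...]  # (window_id, window)

    def __post_init__(self) -> None:
        for wid, w in self.windows:
            _validate_window(w, f"{self.species}:{wid}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, species: str | None = None) -> "SpeciesWindowSet":
        if species is not None:
            df = df[df["species"] == species]
        else:
            names = df["species"].unique()
            if len(names) != 1:
                raise ValueError(f"frame holds multiple species {list(names)}; pass one")
            species = str(names[0])
        return cls(
            species=str(species),
            windows=tuple(zip(df["window_id"].astype(str), df["window"].astype(str))),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "window_id": [wid for wid, _ in self.windows],
                "window": [w for _, w in self.windows],
            }
        )


@dataclass(frozen=True)
class ReferenceCatalog:
    """A reference phosphosite catalog keyed by (protein_id, position, residue)."""

    name: str
    keys: frozenset[tuple[str, int, str]] = field(default_factory=frozenset)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return (str(key[0]), int(key[1]), str(key[2])) in self.keys


def _validate_window(window: str, label: str = "") -> None:
    if len(window) != WINDOW_LENGTH:
        raise ValueError(f"window {label or window!r} must be length {WINDOW_LENGTH}, got {len(window)}")
    bad = set(window) - _ALPHABET
    if bad:
        raise ValueError(f"window {label or window!r} has invalid characters {sorted(bad)}")


def extract_window(sequence: str, position: int, flank: int = WINDOW_FLANK) -> str:
    """Cut the sequence window centered at a 1-based position, pad-filled at termini."""
    seq = sequence.upper()
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} out of range for sequence of length {len(seq)}")
    i = position - 1
    left = seq[max(0, i - flank) : i]
    right = seq[i + 1 : i + 1 + flank]
    return WINDOW_PAD * (flank - len(left)) + left + seq[i] + right + WINDOW_PAD * (flank - len(right))


def count_matches(w1: str, w2: str) -> int:
    """Positions where the two windows carry the same amino acid (pads never match)."""
    _validate_window(w1)
    _validate_window(w2)
    return sum(a == b and a != WINDOW_PAD for a, b in zip(w1, w2))


def similarity_threshold(min_fraction: float = 0.69, length: int = WINDOW_LENGTH) -> int:
    """Smallest integer match count whose fraction of the window exceeds ``min_fraction``."""
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must lie in [0, 1)")
    k = int(np.floor(min_fraction * length)) + 1
    while (k - 1) / length > min_fraction:  # guard against float edge cases
        k -= 1
    return k


def is_similar(w1: str, w2: str, min_matches: int = 9) -> bool:
    return count_matches(w1, w2) >= min_matches


def _window_codes(windows: Sequence[str]) -> np.ndarray:
    """Encode windows as byte arrays; pads get a per-row unique negative code."""
    arr = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(windows), WINDOW_LENGTH).astype(np.int16)


def screen_conserved(
    mouse_windows: Mapping[str, str] | pd.Series,
    species_sets: Sequence[SpeciesWindowSet],
    min_matches: int = 9,
    min_species: int = 3,
    require_center_match: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen reference-species sites for conservation across species.

    Parameters
    ----------
    mouse_windows : mapping site_id -> 13-mer window of the reference species.
    species_sets : one :class:`SpeciesWindowSet` per non-reference species.
    min_matches : minimum identical positions out of 13 for a window pair.
    min_species : minimum species (including the reference) with a similar window.
    require_center_match : additionally require the center residues to agree.

    Returns
    -------
    per_species : DataFrame with one row per (site, species) giving the best
        matching window (max match count, ties to first occurrence) and its
        match count.
    summary : DataFrame with one row per site: ``n_species_matched``
        (including the reference) and the ``conserved`` flag.
        Both outputs are sorted by site then species.
    """
    if not species_sets:
        raise ValueError("at least one non-reference species set is required")
    items = list(mouse_windows.items())
    site_ids = [str(k) for k, _ in items]
    windows = [str(w) for _, w in items]
    for sid, w in zip(site_ids, windows):
        _validate_window(w, sid)
    if not items:
        empty_cols = ["site_id", "species", "best_window_id", "best_window", "n_matches", "similar"]
        return (
            pd.DataFrame(columns=empty_cols),
            pd.DataFrame(columns=["site_id", "n_species_matched", "conserved"]),
        )

    pad = ord(WINDOW_PAD)
    mouse = _window_codes(windows)
    mouse_masked = np.where(mouse == pad, -1, mouse)  # -1 never equals a pad code

    rows = []
    for sp in species_sets:
        ids = [wid for wid, _ in sp.windows]
        wins = [w for _, w in sp.windows]
        if wins:
            other = _window_codes(wins)
            other = np.where(other == pad, -2, other)
            # matches[i, j] = identical non-pad positions of mouse i vs species window j
            matches = (mouse_masked[:, None, :] == other[None, :, :]).sum(axis=2)
            if require_center_match:
                center_ok = mouse_masked[:, None, WINDOW_FLANK] == other[None, :, WINDOW_FLANK]
                matches = np.where(center_ok, matches, -1)
            best_j = matches.argmax(axis=1)
            best_n = matches[np.arange(len(site_ids)), best_j]
        for i, sid in enumerate(site_ids):
            if wins:
                n = int(best_n[i])
                rows.append(
                    {
                        "site_id": sid,
                        "species": sp.species,
                        "best_window_id": ids[int(best_j[i])],
                        "best_window": wins[int(best_j[i])],
                        "n_matches": max(n, 0),
                        "similar": n >= min_matches,
                    }
                )
            else:
                rows.append(
                    {
                        "site_id": sid,
                        "species": sp.species,
                        "best_window_id": None,
                        "best_window": None,
                        "n_matches": 0,
                        "similar": False,
                    }
                )
    per_species = pd.DataFrame(rows).sort_values(["site_id", "species"], kind="stable")
    per_species = per_species.reset_index(drop=True)
    n_matched = per_species.groupby("site_id")["similar"].sum().astype(int) + 1  # + reference
    summary = pd.DataFrame(
        {
            "site_id": n_matched.index,
            "n_species_matched": n_matched.to_numpy(),
            "conserved": (n_matched >= min_species).to_numpy(),
        }
    ).sort_values("site_id", kind="stable").reset_index(drop=True)
    return per_species, summary


def novel_sites(
    sites: pd.DataFrame, catalogs: Iterable[ReferenceCatalog]
) -> tuple[pd.Series, dict]:
    """Flag sites absent from every reference catalog.

    Returns the per-site boolean Series (indexed by site_id) and a summary
    dict with counts and the rounded percent novel.
    """
    catalogs = list(catalogs)
    flags = []
    for row in sites.itertuples(index=False):
        key = (str(row.protein_id), int(row.position), str(row.residue))
        flags.append(not any(key in cat for cat in catalogs))
    novel = pd.Series(flags, index=sites["site_id"].to_numpy(), name="novel")
    n = int(len(novel))
    n_novel = int(novel.sum())
    summary = {
        "n_sites": n,
        "n_novel": n_novel,
        "n_known": n - n_novel,
        "pct_novel": rounded_percent(n_novel, n) if n else None,
        "catalogs": [c.name for c in catalogs],
    }
    return novel, summary
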
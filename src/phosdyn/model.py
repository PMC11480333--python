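"""Core domain model for stage-resolved phosphoproteome analysis.

The central objects are :class:`PhosphoSite` (one localized phosphorylation
event on a protein), :class:`StudyDesign` (the stage x replicate layout of the
samples), and :class:`AnalysisThresholds` (every tunable cut-off used by the
downstream stages).  Intensity tables are carried as plain pandas DataFrames
with row ids (site or protein accessions) as the index, sample ids as columns
and ``NaN`` for missing values; :func:`validate_matrix` checks the contract.

Site classes follow the standard localization-probability convention:
class I for probability > 0.75, class II for 0.5--0.75, class III below 0.5.
Only class I sites are normally carried into quantitative analysis, and when
several entries share a (protein, position) key the highest-class entry wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RESIDUES",
    "SITE_CLASSES",
    "PhosphoSite",
    "StudyDesign",
    "AnalysisThresholds",
    "classify_site",
    "dedupe_by_class",
    "sites_to_frame",
    "frame_to_sites",
    "validate_matrix",
]

RESIDUES = ("S", "T", "Y")
SITE_CLASSES = ("I", "II", "III")

#: rank used when picking the best entry among duplicates (lower = better)
_CLASS_PRIORITY = {"I": 0, "II": 1, "III": 2}

WINDOW_LENGTH = 13
WINDOW_FLANK = 6
WINDOW_PAD = "_"


def classify_site(loc_prob: float) -> str:
    """Map a localization probability to a site class.

    Class I requires probability strictly above 0.75; class III strictly
    below 0.5; everything in between (both boundaries included) is class II.

    Raises
    ------
    ValueError
        If ``loc_prob`` is outside [0, 1] or not a finite number.
    """
    p = float(loc_prob)
    if not np.isfinite(p) or p < 0.0 or p > 1.0:
        raise ValueError(f"localization probability must be in [0, 1], got {loc_prob!r}")
    if p > 0.75:
        return "I"
    if p >= 0.5:
        return "II"
    return "III"


@dataclass(frozen=True)
class PhosphoSite:
    """One localized phosphorylation event.

    Parameters
    ----------
    site_id : str
        Opaque unique key, conventionally ``"<protein>_<residue><position>"``.
    protein_id : str
        Protein accession.  Isoform suffixes (``-2``) are kept distinct
        because site positions are isoform specific.
    position : int
        1-based residue index on the protein sequence.
    residue : str
        One of S, T, Y.
    loc_prob : float
        Localization probability in [0, 1].
    site_class : str
        Derived from ``loc_prob``; if supplied it must agree with
        :func:`classify_site`.
    window : str or None
        Optional 13-mer sequence window centered on the site; positions
        beyond the protein termini are padded with ``"_"``.
    """

    site_id: str
    protein_id: str
    position: int
    residue: str
    loc_prob: float
    site_class: str = ""
    window: str | None = None

    def __post_init__(self) -> None:
        if self.residue not in RESIDUES:
            raise ValueError(f"residue must be one of {RESIDUES}, got {self.residue!r}")
        if int(self.position) < 1:
            raise ValueError(f"position is 1-based and must be >= 1, got {self.position}")
        derived = classify_site(self.loc_prob)
        if self.site_class == "":
            object.__setattr__(self, "site_class", derived)
        elif self.site_class != derived:
            raise ValueError(
                f"site_class {self.site_class!r} inconsistent with loc_prob "
                f"{self.loc_prob} (expected {derived!r})"
            )
        if self.window is not None:
            w = self.window
            if len(w) != WINDOW_LENGTH:
                raise ValueError(f"window must be length {WINDOW_LENGTH}, got {len(w)}")
            if w[WINDOW_FLANK] != self.residue:
                raise ValueError(
                    f"window center {w[WINDOW_FLANK]!r} does not match residue {self.residue!r}"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, int(self.position))


def dedupe_by_class(
    sites: Sequence[PhosphoSite],
    intensities: pd.DataFrame | None = None,
) -> PhosphoSite:
    """Pick the single best entry among duplicates of one (protein, position).

    Priority is class I > class II > class III; ties are broken by higher
    localization probability, then by larger total intensity (when an
    intensity table indexed by site_id is supplied).  The result does not
    depend on the input order.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("dedupe_by_class requires at least one site")
    keys = {s.key for s in sites}
    if len(keys) != 1:
        raise ValueError(f"all sites must share (protein, position); got {sorted(keys)}")

    def total_intensity(s: PhosphoSite) -> float:
        if intensities is None or s.site_id not in intensities.index:
            return 0.0
        return float(np.nansum(intensities.loc[s.site_id].to_numpy(dtype=float)))

    return min(
        sites,
        key=lambda s: (_CLASS_PRIORITY[s.site_class], -float(s.loc_prob), -total_intensity(s), s.site_id),
    )


_SITE_COLUMNS = ["site_id", "protein_id", "position", "residue", "loc_prob", "site_class", "window"]


def sites_to_frame(sites: Iterable[PhosphoSite]) -> pd.DataFrame:
    """Tabulate sites as a DataFrame indexed by site_id."""
    rows = [
        {
            "site_id": s.site_id,
            "protein_id": s.protein_id,
            "position": int(s.position),
            "residue": s.residue,
            "loc_prob": float(s.loc_prob),
            "site_class": s.site_class,
            "window": s.window,
        }
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=_SITE_COLUMNS)
    return df.set_index("site_id", drop=False)


def frame_to_sites(df: pd.DataFrame) -> list[PhosphoSite]:
    """Inverse of :func:`sites_to_frame` (window column optional)."""
    out = []
    for row in df.itertuples(index=False):
        window = getattr(row, "window", None)
        if window is not None and (not isinstance(window, str) or window == ""):
            window = None
        out.append(
            PhosphoSite(
                site_id=str(row.site_id),
                protein_id=str(row.protein_id),
                position=int(row.position),
                residue=str(row.residue),
                loc_prob=float(row.loc_prob),
                window=window,
            )
        )
    return out


@dataclass(frozen=True)
class StudyDesign:
    """Sample layout: ordered stages and the sample -> (stage, replicate) map."""

    stages: tuple[str, ...] = ("GV", "GVBD", "MII")
    sample_map: Mapping[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        object.__setattr__(self, "sample_map", dict(self.sample_map))
        for sample, (stage, rep) in self.sample_map.items():
            if stage not in self.stages:
                raise ValueError(f"sample {sample!r} maps to unknown stage {stage!r}")
            if int(rep) < 1:
                raise ValueError(f"replicate index is 1-based; sample {sample!r} has {rep}")
        for stage in self.stages:
            n = len(self.samples(stage))
            if n < 2:
                raise ValueError(
                    f"stage {stage!r} has {n} sample(s); at least 2 are required "
                    "for variance-based tests"
                )

    @property
    def samples_all(self) -> list[str]:
        return list(self.sample_map)

    def samples(self, stage: str) -> list[str]:
        return [s for s, (st, _) in self.sample_map.items() if st == stage]

    @classmethod
    def balanced(cls, stages: Sequence[str] = ("GV", "GVBD", "MII"), n_replicates: int = 5) -> "StudyDesign":
        """Convenience constructor for a balanced stage x replicate layout."""
        sample_map = {
            f"{stage}_{r}": (stage, r)
            for stage in stages
            for r in range(1, int(n_replicates) + 1)
        }
        return cls(stages=tuple(stages), sample_map=sample_map)

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "samples": {
                s: {"stage": stage, "replicate": int(rep)}
                for s, (stage, rep) in self.sample_map.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDesign":
        samples = d.get("samples", {})
        sample_map = {s: (v["stage"], int(v["replicate"])) for s, v in samples.items()}
        return cls(stages=tuple(d["stages"]), sample_map=sample_map)


@dataclass(frozen=True)
class AnalysisThresholds:
    """All tunable cut-offs of the pipeline.

    Attributes
    ----------
    class_min_prob : float
        Localization probability above which a site is class I (quantitative
        analysis is restricted to class I sites).
    padj_max, fc_min_phospho : float
        Significance gates for the stage comparisons on calibrated sites:
        BH-adjusted p < ``padj_max`` and fold change > ``fc_min_phospho``
        (enforced symmetrically as ``|log2 FC| > log2(fc_min_phospho)``).
    dia_p_max, dia_fc_min : float
        Gates for label-free (DIA) protein comparisons: raw p and fold change.
    flank, min_matches, min_species : int
        Conservation screen: flank width of the sequence window (13-mer for
        flank 6), minimum matching residues out of 13, and minimum number of
        species (including the reference) carrying a similar window.
    n_clusters : int
        Number of fuzzy c-means clusters for the temporal profiles.
    """

    class_min_prob: float = 0.75
    padj_max: float = 0.05
    fc_min_phospho: float = 1.5
    dia_p_max: float = 0.05
    dia_fc_min: float = 1.2
    flank: int = 6
    min_matches: int = 9
    min_species: int = 3
    n_clusters: int = 5

    def __post_init__(self) -> None:
        for name in (
            "class_min_prob", "padj_max", "fc_min_phospho", "dia_p_max",
            "dia_fc_min", "flank", "min_matches", "min_species", "n_clusters",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.fc_min_phospho <= 1 or self.dia_fc_min <= 1:
            raise ValueError("fold-change thresholds must exceed 1")
        if self.min_matches > 2 * self.flank + 1:
            raise ValueError("min_matches cannot exceed the window length 2*flank + 1")

    def to_dict(self) -> dict:
        return {
            "class_min_prob": self.class_min_prob,
            "padj_max": self.padj_max,
            "fc_min_phospho": self.fc_min_phospho,
            "dia_p_max": self.dia_p_max,
            "dia_fc_min": self.dia_fc_min,
            "flank": self.flank,
            "min_matches": self.min_matches,
            "min_species": self.min_species,
            "n_clusters": self.n_clusters,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisThresholds":
        return cls(**dict(d))

    def replace(self, **kwargs) -> "AnalysisThresholds":
        return replace(self, **kwargs)


def validate_matrix(matrix: pd.DataFrame, design: StudyDesign | None = None) -> pd.DataFrame:
    """Check an intensity matrix: numeric, nonnegative, columns match the design.

    Returns the matrix with float dtype (NaN = missing).
    """
    out = matrix.astype(float)
    if (out.to_numpy() < 0).any():
        bad = out.index[(out < 0).any(axis=1)].tolist()
        raise ValueError(f"intensity matrix contains negative values in rows {bad[:5]}")
    if out.index.has_duplicates:
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in intensity matrix: {dups[:5]}")
    if design is not None:
        missing = [s for s in design.samples_all if s not in out.columns]
        if missing:
            raise ValueError(f"matrix is missing design samples: {missing}")
        extra = [c for c in out.columns if c not in design.sample_map]
        if extra:
            raise ValueError(f"matrix has columns not in the design: {extra}")
        out = out[design.samples_all]
    return out
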
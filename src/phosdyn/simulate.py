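"""Synthetic phosphoproteome studies with known ground truth.

The generator emulates the statistical structure of a TMT-style three-stage
(GV, GVBD, MII) by five-replicate oocyte maturation design: a long-tailed
sites-per-protein distribution (zero-truncated geometric, mean ~3), residue
composition heavily skewed to serine (86.5 / 13.0 / 0.5 % S/T/Y), ~75 % of
sites regulated following one of five temporal archetypes, multiplicative
log-normal measurement noise, and a fraction of proteins drifting in
abundance so that raw site intensities confound protein-level and
phosphorylation-level change -- downstream calibration is required to
separate them.  Companion generators plant a kinase-substrate network whose
kinases draw substrates preferentially from one archetype, and cross-species
window sets at controlled Hamming distances from the reference windows.

All randomness flows from a single seed through deterministically derived
per-component streams, so the full study regenerates bit-identically and
individual components can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import extract_window
from .kinome import KinaseSubstrateNetwork
from .model import PhosphoSite, StudyDesign, sites_to_frame

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "simulate_phosphoproteome",
    "simulate_species_sets",
    "simulate_ks_network",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: stream labels hashed into the seed sequence, one per generator component
_STREAMS = {"proteome": 0, "sites": 1, "intensity": 2, "species": 3, "network": 4}

DEFAULT_ARCHETYPES: dict[str, tuple[float, float, float]] = {
    "A1": (1.0, 0.7, 0.3),   # monotone decrease
    "A2": (0.6, 1.0, 0.3),   # transient peak at meiotic resumption
    "A3": (0.3, 0.5, 1.0),   # late increase
    "A4": (0.3, 0.9, 1.0),   # early-onset increase
    "A5": (0.5, 0.6, 1.0),   # shallow-onset increase
}


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults define the emulated study conditions."""

    n_proteins: int = 500
    mean_sites_per_protein: float = 3.0
    residue_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.865, "T": 0.130, "Y": 0.005}
    )
    stages: tuple[str, ...] = ("GV", "GVBD", "MII")
    n_replicates: int = 5
    fraction_regulated: float = 0.75
    archetypes: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    sigma: float = 0.15
    drift_fraction: float = 0.1
    drift_range: tuple[float, float] = (1.5, 2.0)
    protein_detected_fraction: float = 0.9
    seq_length_range: tuple[int, int] = (150, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = dict(self.residue_freqs)
        if set(freqs) != {"S", "T", "Y"}:
            raise ValueError("residue_freqs must have exactly the keys S, T, Y")
        if not np.isclose(sum(freqs.values()), 1.0):
            raise ValueError("residue frequencies must sum to 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not 0 <= self.fraction_regulated <= 1:
            raise ValueError("fraction_regulated must lie in [0, 1]")
        templates = [tuple(v) for v in self.archetypes.values()]
        if len(set(templates)) != len(templates):
            raise ValueError("archetype templates must be distinct")
        for name, t in self.archetypes.items():
            if len(t) != len(self.stages):
                raise ValueError(f"archetype {name!r} must have one value per stage")
            if min(t) <= 0:
                raise ValueError(f"archetype {name!r} values must be positive")
        if self.mean_sites_per_protein <= 1:
            raise ValueError("mean_sites_per_protein must exceed 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth used as the oracle for downstream stages."""

    site_truth: pd.DataFrame       # site_id, protein_id, regulated, archetype, per-stage template mean
    protein_truth: pd.DataFrame    # protein_id, detected, drifting, per-stage drift factor
    kinase_truth: pd.DataFrame | None = None   # kinase_id, archetype, n_substrates
    species_truth: pd.DataFrame | None = None  # species, site_id, window, hamming_distance


@dataclass(frozen=True)
class SimulatedStudy:
    """Everything one simulated study comprises."""

    config: SimConfig
    design: StudyDesign
    sites: list[PhosphoSite]
    site_intensity: pd.DataFrame
    protein_intensity: pd.DataFrame
    sequences: dict[str, str]
    truth: SyntheticTruth

    @property
    def sites_frame(self) -> pd.DataFrame:
        return sites_to_frame(self.sites)

    @property
    def site_to_protein(self) -> dict[str, str]:
        return {s.site_id: s.protein_id for s in self.sites}


def _stream(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[component],)))


def _zt_geometric(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Zero-truncated geometric counts on {1, 2, ...} with the given mean."""
    return rng.geometric(1.0 / mean, size=size)


def simulate_phosphoproteome(config: SimConfig) -> SimulatedStudy:
    """Generate one full synthetic study (sites, matrices, sequences, truth).

    Site intensity for a sample of stage ``t`` is
    ``site_base * protein_profile(t) * template(t) * exp(N(0, sigma^2))``;
    the protein matrix carries ``protein_base * protein_profile(t)`` with its
    own independent noise.  Unregulated sites use a flat template, so their
    raw intensities still inherit any protein drift and only calibration
    classifies them correctly.  Deterministic for a fixed seed.
    """
    rng_prot = _stream(config.seed, "proteome")
    rng_sites = _stream(config.seed, "sites")
    rng_int = _stream(config.seed, "intensity")

    n_stages = len(config.stages)
    design = StudyDesign.balanced(config.stages, config.n_replicates)
    protein_ids = [f"P{i:04d}" for i in range(1, config.n_proteins + 1)]

    # --- proteins: sequence, abundance, drift profile, detection -----------
    lengths = rng_prot.integers(config.seq_length_range[0], config.seq_length_range[1] + 1,
                                size=config.n_proteins)
    sequences = {
        pid: "".join(rng_prot.choice(list(_AA20), size=int(n)))
        for pid, n in zip(protein_ids, lengths)
    }
    base_abundance = np.exp(rng_prot.normal(np.log(1e6), 1.0, size=config.n_proteins))
    drifting = rng_prot.random(config.n_proteins) < config.drift_fraction
    drift_factor = rng_prot.uniform(*config.drift_range, size=config.n_proteins)
    drift_up = rng_prot.random(config.n_proteins) < 0.5
    exponents = np.linspace(0.0, 1.0, n_stages)
    profiles = np.ones((config.n_proteins, n_stages))
    for i in np.flatnonzero(drifting):
        f = drift_factor[i] if drift_up[i] else 1.0 / drift_factor[i]
        profiles[i] = f ** exponents
    detected = rng_prot.random(config.n_proteins) < config.protein_detected_fraction

    # --- sites: placement, residue, archetype ------------------------------
    counts = _zt_geometric(rng_sites, config.mean_sites_per_protein, config.n_proteins)
    residues_alphabet = np.array(["S", "T", "Y"])
    residue_p = np.array([config.residue_freqs[r] for r in ("S", "T", "Y")])
    archetype_names = list(config.archetypes)
    templates = {k: np.asarray(v, dtype=float) for k, v in config.archetypes.items()}
    flat = np.ones(n_stages)

    sites: list[PhosphoSite] = []
    truth_rows = []
    site_templates = []
    site_protein_idx = []
    for i, pid in enumerate(protein_ids):
        seq = sequences[pid]
        k = min(int(counts[i]), len(seq))
        positions = np.sort(rng_sites.choice(len(seq), size=k, replace=False)) + 1
        chosen = rng_sites.choice(residues_alphabet, size=k, p=residue_p)
        seq_list = list(seq)
        for pos, res in zip(positions, chosen):
            seq_list[pos - 1] = res
        sequences[pid] = seq = "".join(seq_list)
        for pos, res in zip(positions, chosen):
            regulated = bool(rng_sites.random() < config.fraction_regulated)
            archetype = rng_sites.choice(archetype_names) if regulated else None
            template = templates[archetype] if regulated else flat
            loc_prob = float(rng_sites.uniform(0.76, 1.0))
            site = PhosphoSite(
                site_id=f"{pid}_{res}{pos}",
                protein_id=pid,
                position=int(pos),
                residue=str(res),
                loc_prob=loc_prob,
                window=extract_window(seq, int(pos)),
            )
            sites.append(site)
            site_templates.append(template)
            site_protein_idx.append(i)
            truth_rows.append(
                {
                    "site_id": site.site_id,
                    "protein_id": pid,
                    "regulated": regulated,
                    "archetype": archetype,
                    **{f"template_{s}": float(template[t]) for t, s in enumerate(config.stages)},
                }
            )

    # --- intensities --------------------------------------------------------
    n_sites = len(sites)
    stage_idx = np.repeat(np.arange(n_stages), config.n_replicates)
    columns = design.samples_all
    site_base = np.exp(rng_int.normal(0.0, 0.5, size=n_sites))
    site_templates_arr = np.vstack(site_templates)
    prot_idx = np.asarray(site_protein_idx)
    site_means = (
        base_abundance[prot_idx, None]
        * site_base[:, None]
        * profiles[prot_idx][:, stage_idx]
        * site_templates_arr[:, stage_idx]
    )
    site_noise = np.exp(rng_int.normal(0.0, config.sigma, size=site_means.shape)) if config.sigma else 1.0
    site_intensity = pd.DataFrame(
        site_means * site_noise, index=[s.site_id for s in sites], columns=columns
    )
    site_intensity.index.name = "site_id"

    prot_means = base_abundance[:, None] * profiles[:, stage_idx]
    prot_noise = np.exp(rng_int.normal(0.0, config.sigma, size=prot_means.shape)) if config.sigma else 1.0
    protein_intensity = pd.DataFrame(
        prot_means * prot_noise, index=protein_ids, columns=columns
    ).loc[detected]
    protein_intensity.index.name = "protein_id"

    protein_truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "detected": detected,
            "drifting": drifting,
            **{
                f"drift_{s}": profiles[:, t]
                for t, s in enumerate(config.stages)
            },
        }
    )
    truth = SyntheticTruth(
        site_truth=pd.DataFrame(truth_rows).set_index("site_id", drop=False),
        protein_truth=protein_truth.set_index("protein_id", drop=False),
    )
    return SimulatedStudy(
        config=config,
        design=design,
        sites=sites,
        site_intensity=site_intensity,
        protein_intensity=protein_intensity,
        sequences=sequences,
        truth=truth,
    )


DEFAULT_SPECIES = ("drosophila", "sea_star", "xenopus")
#: planted Hamming distances 0..6 and their draw probabilities
DEFAULT_DISTANCE_PROBS = (0.15, 0.15, 0.15, 0.15, 0.15, 0.15, 0.10)


def simulate_species_sets(
    sites: Sequence[PhosphoSite],
    species: Sequence[str] = DEFAULT_SPECIES,
    distance_probs: Sequence[float] = DEFAULT_DISTANCE_PROBS,
    max_sites: int | None = None,
    seed: int = 0,
):
    """Emit per-species window sets at planted Hamming distances from the reference.

    Only sites with pad-free windows are eligible (substitutions never touch
    the center or a terminal pad, so the emitted window's Hamming distance
    from the reference window equals the planted ``d`` exactly).  Returns
    ``(species_sets, truth)`` where truth records the distance per
    (species, site).
    """
    from .conservation import SpeciesWindowSet  # local to avoid cycle at import time

    probs = np.asarray(distance_probs, dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("distance probabilities must sum to 1")
    rng = _stream(seed, "species")
    eligible = [s for s in sites if s.window and "_" not in s.window]
    if max_sites is not None:
        eligible = eligible[: int(max_sites)]
    if not eligible:
        raise ValueError("no sites with pad-free windows to plant species windows on")

    flank = len(eligible[0].window) // 2
    mutable_positions = [i for i in range(len(eligible[0].window)) if i != flank]
    sets = []
    truth_rows = []
    for sp in species:
        windows = []
        for site in eligible:
            d = int(rng.choice(len(probs), p=probs))
            w = list(site.window)
            for i in rng.choice(mutable_positions, size=d, replace=False):
                alternatives = [a for a in _AA20 if a != w[i]]
                w[i] = alternatives[int(rng.integers(len(alternatives)))]
            emitted = "".join(w)
            wid = f"{sp}:{site.site_id}"
            windows.append((wid, emitted))
            truth_rows.append(
                {
                    "species": sp,
                    "site_id": site.site_id,
                    "window_id": wid,
                    "window": emitted,
                    "hamming_distance": d,
                }
            )
        sets.append(SpeciesWindowSet(species=sp, windows=tuple(windows)))
    return sets, pd.DataFrame(truth_rows)


def simulate_ks_network(
    truth: SyntheticTruth,
    n_kinases: int = 15,
    n_phosphatases: int = 8,
    substrates_range: tuple[int, int] = (8, 25),
    preference: float = 0.9,
    seed: int = 0,
) -> tuple[KinaseSubstrateNetwork, pd.DataFrame]:
    """Plant a kinase-substrate network on an existing simulated study.

    Enzymes are drawn from the simulated proteins; each kinase is assigned a
    preferred temporal archetype (cycling through the configured archetypes)
    and draws ``preference`` of its substrates from regulated sites of that
    archetype, the rest uniformly from other sites.  Returns the network and
    a truth table (kinase -> archetype, substrate list).
    """
    if n_kinases < 1:
        raise ValueError("at least one kinase is required")
    rng = _stream(seed, "network")
    site_truth = truth.site_truth
    protein_ids = list(truth.protein_truth["protein_id"])
    if n_kinases + n_phosphatases > len(protein_ids):
        raise ValueError("not enough proteins to annotate as enzymes")
    enzyme_ids = rng.choice(protein_ids, size=n_kinases + n_phosphatases, replace=False)
    kinase_ids = [str(x) for x in enzyme_ids[:n_kinases]]
    phosphatase_ids = [str(x) for x in enzyme_ids[n_kinases:]]

    archetypes = [a for a in site_truth["archetype"].dropna().unique()]
    archetypes.sort()
    if not archetypes:
        raise ValueError("study has no regulated sites; cannot plant archetype-linked kinases")

    lo, hi = substrates_range
    edges = []
    truth_rows = []
    for j, kinase in enumerate(kinase_ids):
        archetype = archetypes[j % len(archetypes)]
        preferred_pool = site_truth.loc[site_truth["archetype"] == archetype, "site_id"].tolist()
        other_pool = site_truth.loc[site_truth["archetype"] != archetype, "site_id"].tolist()
        size = int(rng.integers(lo, hi + 1))
        n_pref = min(int(round(size * preference)), len(preferred_pool))
        n_other = min(size - n_pref, len(other_pool))
        chosen = [str(x) for x in rng.choice(preferred_pool, size=n_pref, replace=False)]
        chosen += [str(x) for x in rng.choice(other_pool, size=n_other, replace=False)]
        for sid in chosen:
            edges.append({"kinase_id": kinase, "site_id": sid, "score": float(rng.uniform(0.5, 1.0))})
        truth_rows.append(
            {
                "kinase_id": kinase,
                "archetype": archetype,
                "n_substrates": len(chosen),
                "substrates": chosen,
            }
        )
    network = KinaseSubstrateNetwork(
        kinases=frozenset(kinase_ids),
        phosphatases=frozenset(phosphatase_ids),
        edges=pd.DataFrame(edges),
    )
    return network, pd.DataFrame(truth_rows)
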
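"""Kinase/phosphatase accounting, substrate enrichment, activity inference.

The kinase-substrate network is an input table of kinase -> site edges (e.g.
exported from a kinase-substrate predictor) plus accession lists annotating
which proteins are kinases or phosphatases.  Three analyses are built on it:

* **Enzyme accounting** -- for each annotated enzyme, whether it was
  detected (present in the proteome or phosphoproteome), phosphorylated
  (carries at least one site) and regulated (at least one regulated site);
  the three categories are nested by construction.
* **Substrate enrichment** -- per kinase, a two-sided Fisher exact test of
  substrate membership against significant upregulation in one stage
  comparison (upregulated sites vs the rest of the quantified sites), with
  BH adjustment across kinases.
* **Activity inference** -- each substrate's stage-mean profile is
  standardized to z-scores across stages and the kinase activity profile is
  the per-stage mean substrate z; the trend label (increasing / decreasing /
  transient / flat) follows the signs of consecutive differences against a
  z threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import bh_adjust, standardize_profiles

__all__ = [
    "KinaseSubstrateNetwork",
    "annotate_enzymes",
    "fisher_exact_2x2",
    "kinase_enrichment",
    "infer_activity",
]


@dataclass(frozen=True)
class KinaseSubstrateNetwork:
    """Kinase -> site edges plus enzyme-class annotation sets."""

    kinases: frozenset[str]
    phosphatases: frozenset[str] = frozenset()
    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["kinase_id", "site_id", "score"]))

    def __post_init__(self) -> None:
        edges = self.edges
        required = {"kinase_id", "site_id"}
        if not required <= set(edges.columns):
            raise ValueError(f"edge table must have columns {sorted(required)}")
        if "score" not in edges.columns:
            edges = edges.assign(score=np.nan)
        dup = edges.duplicated(subset=["kinase_id", "site_id"])
        if dup.any():
            pairs = edges.loc[dup, ["kinase_id", "site_id"]].itertuples(index=False)
            raise ValueError(f"duplicate edges: {[tuple(p) for p in pairs][:5]}")
        object.__setattr__(self, "edges", edges.reset_index(drop=True))
        overlap = self.kinases & self.phosphatases
        if overlap:
            raise ValueError(f"proteins annotated as both kinase and phosphatase: {sorted(overlap)[:5]}")

    def substrates(self, kinase_id: str) -> set[str]:
        return set(self.edges.loc[self.edges["kinase_id"] == kinase_id, "site_id"])

    def validate_sites(self, site_ids) -> None:
        known = set(site_ids)
        missing = sorted(set(self.edges["site_id"]) - known)
        if missing:
            raise ValueError(f"edges reference unknown sites: {missing[:5]}")


def annotate_enzymes(
    proteome_ids,
    sites: pd.DataFrame,
    regulated_site_ids,
    kinase_list,
    phosphatase_list,
) -> tuple[pd.DataFrame, dict]:
    """Per-enzyme status flags and nested summary counts.

    ``detected``: the enzyme appears in the proteome or carries a phosphosite;
    ``phosphorylated``: carries at least one site; ``regulated``: at least one
    of its sites is regulated.  Counts per enzyme class are returned alongside
    the per-enzyme table, with ``n_total`` the size of the annotation list.
    """
    proteome = set(map(str, proteome_ids))
    regulated = set(map(str, regulated_site_ids))
    site_proteins = sites.groupby("protein_id", sort=False)["site_id"].agg(list)

    rows = []
    for kind, enzymes in (("kinase", kinase_list), ("phosphatase", phosphatase_list)):
        for enz in map(str, enzymes):
            enz_sites = site_proteins.get(enz, [])
            phosphorylated = len(enz_sites) > 0
            rows.append(
                {
                    "enzyme_id": enz,
                    "kind": kind,
                    "detected": enz in proteome or phosphorylated,
                    "phosphorylated": phosphorylated,
                    "regulated": any(s in regulated for s in enz_sites),
                }
            )
    table = pd.DataFrame(rows, columns=["enzyme_id", "kind", "detected", "phosphorylated", "regulated"])

    counts: dict[str, dict[str, int]] = {}
    for kind, enzymes in (("kinase", kinase_list), ("phosphatase", phosphatase_list)):
        sub = table[table["kind"] == kind]
        counts[kind] = {
            "n_total": int(len(list(enzymes))),
            "n_detected": int(sub["detected"].sum()),
            "n_phosphorylated": int(sub["phosphorylated"].sum()),
            "n_regulated": int(sub["regulated"].sum()),
        }
    return table, counts


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    The p value sums, over all tables with the observed margins, the
    hypergeometric probabilities not exceeding that of the observed table
    (with the conventional (1 + 1e-7) relative guard against float ties).
    The odds ratio is the sample odds ratio ad/bc.  A zero margin makes the
    table degenerate: p = 1.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if not np.all(arr == np.floor(arr)) or (arr < 0).any():
        raise ValueError("table cells must be nonnegative integers")
    a, b, c, d = (int(x) for x in arr.ravel())
    n = a + b + c + d
    r1, c1 = a + b, a + c
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.divide(a * d, b * c) if b * c else (np.inf if a * d else np.nan)
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n or n == 0:
        return float(odds), 1.0
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return float(odds), min(p, 1.0)


def kinase_enrichment(
    calls: pd.DataFrame,
    network: KinaseSubstrateNetwork,
    site_universe,
) -> pd.DataFrame:
    """Per-kinase Fisher enrichment of significantly upregulated sites.

    For each kinase with at least one substrate in the quantified site
    universe, tests the 2x2 of substrate membership against (significant and
    up) vs the rest, then BH-adjusts across kinases.  Kinases without
    substrates in the universe are excluded (reported via the ``n_substrates``
    accounting of the caller).
    """
    comparisons = calls["comparison"].unique()
    if len(comparisons) != 1:
        raise ValueError(f"expected calls for exactly one comparison, got {list(comparisons)}")
    universe = set(map(str, site_universe))
    up = set(calls.loc[calls["significant"] & (calls["direction"] == "up"), "site_id"]) & universe
    n_up = len(up)
    n_rest = len(universe) - n_up

    rows = []
    for kinase in sorted(network.kinases):
        substrates = network.substrates(kinase) & universe
        if not substrates:
            continue
        a = len(substrates & up)
        b = len(substrates) - a
        c = n_up - a
        d = n_rest - b
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        # margins must reconcile with the global counts
        assert a + c == n_up and b + d == n_rest and a + b == len(substrates)
        rows.append(
            {
                "kinase_id": kinase,
                "n_substrates": len(substrates),
                "sub_up": a,
                "sub_rest": b,
                "nonsub_up": c,
                "nonsub_rest": d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "kinase_id", "n_substrates", "sub_up", "sub_rest",
            "nonsub_up", "nonsub_rest", "odds_ratio", "p",
        ],
    )
    result["p_adj"] = bh_adjust(result["p"].to_numpy()) if len(result) else np.nan
    result["comparison"] = str(comparisons[0]) if len(result) else None
    return result.sort_values("p", kind="stable").reset_index(drop=True)


def _trend_label(diffs: np.ndarray, threshold: float) -> str:
    moves = diffs[np.abs(diffs) > threshold]
    if moves.size == 0:
        return "flat"
    if (moves > 0).all():
        return "increasing"
    if (moves < 0).all():
        return "decreasing"
    return "transient"


def infer_activity(
    network: KinaseSubstrateNetwork,
    stage_mean_profiles: pd.DataFrame,
    min_substrates: int = 3,
    trend_threshold: float = 0.25,
    weight_by_score: bool = False,
) -> pd.DataFrame:
    """Substrate-based kinase activity profiles.

    Each quantified substrate's stage-mean profile is standardized to z
    across stages; the kinase profile is the (optionally score-weighted)
    per-stage mean of substrate z-scores, so any positive rescaling of a
    substrate row cancels.  Kinases with fewer than ``min_substrates``
    quantified substrates get a null profile.
    """
    z, _ = standardize_profiles(stage_mean_profiles)
    stages = list(stage_mean_profiles.columns)
    rows = []
    for kinase in sorted(network.kinases):
        edge_rows = network.edges[network.edges["kinase_id"] == kinase]
        usable = edge_rows[edge_rows["site_id"].isin(z.index)]
        n_sub = int(len(usable))
        if n_sub < min_substrates:
            profile = [np.nan] * len(stages)
            trend = None
        else:
            zs = z.loc[usable["site_id"]].to_numpy(dtype=float)
            if weight_by_score and usable["score"].notna().all():
                w = usable["score"].to_numpy(dtype=float)
                profile = list((zs * w[:, None]).sum(axis=0) / w.sum())
            else:
                profile = list(zs.mean(axis=0))
            trend = _trend_label(np.diff(np.asarray(profile)), trend_threshold)
        rows.append(
            {
                "kinase_id": kinase,
                **{f"z_{stage}": profile[i] for i, stage in enumerate(stages)},
                "n_substrates": n_sub,
                "trend": trend,
            }
        )
    return pd.DataFrame(rows)
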
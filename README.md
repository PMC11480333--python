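# phosdyn

Analysis pipeline for **stage-resolved quantitative phosphoproteomics time
courses**, built around the three-stage design of mammalian oocyte meiotic
maturation (GV → GVBD → MII, five replicates per stage) but usable for any
stage × replicate layout. It is aimed at proteomics bioinformaticians who
have site- and protein-level quantification tables (e.g. MaxQuant
`Phospho (STY)Sites.txt` exports) and want the full downstream chain as
tested, reusable code.

## What it computes

1. **Calibrated phosphosite levels.** Protein zeros are replaced by the
   global minimum non-zero protein value, every site and protein row is
   divided by its own mean across samples (row-mean normalization), and each
   site is divided element-wise by its parent protein:
   `cal(s, j) = site_norm(s, j) / prot_norm(p(s), j)`. Sites whose protein
   was not quantified keep their normalized level (`site_only` provenance).
   This separates phosphorylation change from protein-abundance change.
2. **Differential regulation.** Per stage comparison, a two-sided t test
   (Student pooled-variance, Welch optional) on log2 calibrated values with
   Benjamini–Hochberg adjustment; a site is *significant* when
   `p_adj < 0.05` and `|log2 FC| > log2 1.5`, and *regulated* when
   significant in ≥ 1 comparison. DIA-style protein comparisons use raw
   `p < 0.05` and `FC > 1.2`.
3. **Temporal clustering.** Fuzzy c-means (soft memberships
   `u_ij = 1 / Σ_k (d_ij/d_ik)^{2/(m−1)}`, fuzzifier `m = 2`, `c = 5`) on
   standardized log2 stage-mean profiles of the regulated sites, exposed as
   a scikit-learn-style estimator (`FuzzyCMeans`).
4. **Conservation screen.** 13-mer windows (site ± 6 residues, `_`-padded)
   compared position-wise across species; a pair is similar at ≥ 9/13
   identical residues (the smallest k with k/13 > 0.69), and a site is
   conserved when ≥ 3 species (including the reference) carry a similar
   window. Novelty screening flags sites absent from reference catalogs.
5. **Kinome accounting.** Detected / phosphorylated / regulated enzyme
   counts, per-kinase Fisher exact enrichment of upregulated substrates
   against the rest of the quantified sites (BH across kinases), and
   substrate-based activity profiles (per-stage mean of substrate z-scores
   with trend labels).

A synthetic-data generator (`phosdyn.simulate`) emulates the statistical
structure of such a study — 75 % regulated sites following five temporal
archetypes, S/T/Y composition 86.5/13.0/0.5 %, a long-tailed sites-per-protein
distribution, log-normal noise, protein drift, planted kinase–substrate
structure and cross-species windows at controlled Hamming distances — so
every stage is testable against known ground truth.

## Worked example

```python
from phosdyn import (SimConfig, simulate_phosphoproteome, calibration_pipeline,
                     differential_sites, call_regulated, temporal_profiles,
                     fuzzy_cmeans)

study = simulate_phosphoproteome(SimConfig(seed=1))
cal = calibration_pipeline(study.site_intensity, study.protein_intensity,
                           study.site_to_protein)
calls = differential_sites(cal, study.design)
regulated = call_regulated(calls)
print(len(study.sites), int(regulated.sum()))

z, _ = temporal_profiles(cal.values.loc[regulated[regulated].index], study.design)
model = fuzzy_cmeans(z, c=5, seed=1)
print(model.hard_assignment.value_counts().to_dict())
```

This prints `1541 1108` — 1541 simulated sites of which 1108 (72 %; 71.7 %
were planted as regulated) are called regulated — and the five-cluster
partition of the regulated sites
`{'C4': 258, 'C1': 237, 'C3': 223, 'C2': 223, 'C5': 167}`: the planted
archetypes recovered with adjusted Rand index 0.83 against the generator's
truth. The same pipeline runs from the shell:

```bash
phosdyn simulate --seed 1 --out study/
phosdyn normalize --sites study/sites.tsv --proteins study/proteins.tsv \
                  --design study/design.yaml --out calibrated.tsv
phosdyn diff --calibrated calibrated.tsv --design study/design.yaml --out calls.tsv
phosdyn cluster --calls calls.tsv --calibrated calibrated.tsv \
                --design study/design.yaml -c 5 --seed 1 --out clusters.tsv
```

## Layout

- `src/phosdyn/model.py` — domain types (sites, design, thresholds), site classes
- `src/phosdyn/io.py` — TSV/FASTA/YAML/JSON parsers and writers
- `src/phosdyn/normalize.py` — zero rule, row-mean normalization, calibration
- `src/phosdyn/dynamics.py` — t tests, BH, differential calls, summaries
- `src/phosdyn/cluster.py` — `FuzzyCMeans` estimator and tabular wrapper
- `src/phosdyn/conservation.py` — window extraction, similarity, screens
- `src/phosdyn/kinome.py` — enzyme accounting, Fisher enrichment, activity
- `src/phosdyn/simulate.py` — synthetic studies with planted ground truth
- `src/phosdyn/cli.py` — the `phosdyn` command
- `docs/methods.md` — models, assumptions, parameter choices, limitations
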
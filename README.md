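# riverneutral

Community-assembly analysis for riverine microbial metacommunities:
Sloan's neutral community model (NCM), rare-biosphere classification,
alpha/beta diversity, dendritic-network spatial eigenfunctions and
RDA-based variation partitioning — with a synthetic-data module that
generates neutral and niche-structured metacommunities with known ground
truth.

## Who this is for

Microbial ecologists asking whether the composition of local communities
along a river (e.g. 18S/16S OTU tables from sites sampled across seasons)
is better explained by *stochastic* processes — birth, death, immigration,
drift — or by *deterministic* environmental selection and spatial
structure. The package implements the standard toolkit for that question as
a tested, scriptable pipeline rather than a collection of one-off R
snippets.

## The model at the core

Sloan's neutral community model treats each local community as a large
assemblage whose composition drifts while receiving immigrants from a
shared metacommunity. At stationarity, the local relative abundance *x* of
a taxon with metacommunity relative abundance *p* follows a beta
distribution,

```
x ~ Beta(Nm·p, Nm·(1 − p)),
```

where *Nm* (metacommunity size *N* × immigration probability *m*) measures
how tightly local communities track the metacommunity. A taxon is detected
where *x* exceeds the detection limit *d* (one read at the sequencing
depth, *d* = 1/N), so its expected occurrence frequency across sites is

```
freq(p) = 1 − BetaCDF(d; Nm·p, Nm·(1 − p)).
```

Fitting *Nm* to the observed (p, freq) cloud by least squares gives the
immigration rate *m* = *Nm*/*N* and an R² measuring how much of the
occupancy–abundance relationship neutral dispersal alone explains. Taxa
escaping the 95% envelope around the fitted curve form the "above"
(dispersal-favoured) and "below" (dispersal-limited) partitions.

Around this core the package provides:

- **`otu`** — OTU-table I/O (TSV / JSON), seeded rarefaction, relative
  abundance, Hellinger transform, taxonomy collapsing;
- **`rarity`** — the six-category rare-biosphere classification
  (AAT/CAT/MT/ART/CRT/CRAT, thresholds 0.01% and 1%) and the pooled
  "dominant" subcommunity;
- **`alpha`** — richness, Chao1 (classic + bias-corrected), ACE, Shannon,
  Pielou, Simpson, Good's coverage, rarefaction curves;
- **`beta`** — Bray-Curtis matrices, great-circle and dendritic
  (along-river) distances, Mantel / partial Mantel, ANOSIM, PCoA,
  distance-decay regression;
- **`eigenfunctions`** — PCNM spatial eigenvectors and directional AEM
  eigenvectors with the parabolic edge weighting `w = 1 − (d/d_max)²`;
- **`varpart`** — VIF filtering, permutation-based forward selection and
  two-set variation partitioning by adjusted RDA R² (plus a
  distance-matrix analogue);
- **`simulate`** — Dirichlet-multinomial neutral metacommunities, random
  dendritic river networks and niche-structured communities on
  environmental gradients;
- **`pipeline` / `cli`** — config-driven orchestration per season and per
  rarity subcommunity (`riverneutral run --config cfg.yaml`).

## Worked example

```python
from riverneutral import (NeutralSimConfig, simulate_neutral_samples,
                          ncm_input_from_table, fit_ncm)

cfg = NeutralSimConfig(S=2000, Nm=1000.0, N=10_000, n_sites=30, seed=1)
table = simulate_neutral_samples(cfg)     # 30 sites × 2000 OTUs, 10^4 reads each
fit = fit_ncm(ncm_input_from_table(table))
print(f"Nm = {fit.Nm:.0f}, m = {fit.m:.3f}, R2 = {fit.r2:.3f}")
print(fit.partition_counts())
```

prints

```
Nm = 1274, m = 0.127, R2 = 0.936
{'above': 55, 'neutral': 1506, 'below': 47}
```

meaning: the fitted dispersal parameter is Nm ≈ 1274 (the known upward
bias of the continuous-beta fit on sequenced counts is documented in
`docs/methods.md`), the immigration rate estimate is m = Nm/N = 0.125, the
neutral model explains 94% of the variance in occurrence frequency, and
94% of the detected OTUs fall inside the 95% neutral envelope — the
signature of a purely stochastically assembled community. At the published
study depth (N = 110,394 reads), wet- and dry-season fits of
Nm = 53,309 and 49,567 correspond to m = 0.483 and 0.449.

The same analysis runs from the shell:

```bash
riverneutral simulate --kind neutral --nm 1000 --sites 30 \
    --depth 10000 --taxa 2000 --seed 1 --out table.tsv
riverneutral ncm table.tsv
```

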
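# aquassembly

Ecological inference for aquatic microbiome surveys: neutral-model
community assembly, co-occurrence network stability, and distance-decay
biogeography, with seeded synthetic generators for every analysis.

The package is aimed at microbial ecologists working with sample × taxon
relative-abundance tables (as exported by taxonomic profilers), sample
metadata (region, ecosystem, coordinates, altitude, environmental
variables), and optionally sample × unigene presence matrices from a
non-redundant gene catalog. It answers three questions about a survey
such as a plateau-wide collection of lake, river, hot-spring, wetland
and glacier samples:

1. **How are communities assembled?** The Sloan neutral community model
   (NCM) treats a local community of size *N* receiving immigrants from
   a metacommunity at rate *m*. At stationarity the local relative
   abundance *x* of a taxon with metacommunity abundance *p* follows
   Beta(*Nm·p*, *Nm*(1−*p*)), so its expected occurrence frequency over
   samples at detection limit *d* is

   F(p) = 1 − I_d(Nm·p, Nm(1−p)),

   with I the regularized incomplete beta function. `fit_ncm` estimates
   *Nm* by nonlinear least squares of observed frequencies against
   F(p); R² measures how much of the occupancy–abundance relationship
   dispersal alone explains. `bootstrap_ncm` adds 95% bands (taxon
   bootstrap or binomial style) and partitions taxa into
   above / neutral / below classes.

2. **How stable are the co-occurrence networks?** `build_network`
   thresholds Spearman correlations (|ρ| ≥ 0.8, p < 0.05 by default)
   into a molecular ecological network. Besides standard topology,
   `relative_modularity` scores RM = (Q − mean Q_null)/mean Q_null
   against size-matched random graphs and `vulnerability` computes the
   worst-case relative loss of global efficiency from a single node
   removal, tracked under random extinction of 0–90% of nodes.

3. **How does similarity decay with distance?** Bray–Curtis similarity
   and shared-gene counts are regressed (Spearman) against great-circle
   and altitudinal distance over ecosystem-matched, reference-anchored
   sample pairs; PERMANOVA, simple/partial Mantel tests and
   Benjamini–Hochberg-corrected environmental associations quantify the
   drivers, and gene accumulation curves summarize catalog saturation.

## Worked example

Simulate a neutrally assembled community and refit the model:

```python
import aquassembly as aq

counts, truth = aq.simulate_neutral(
    aq.NeutralSimConfig(nm=1000.0, n_samples=150, n_taxa=300,
                        depth=50_000, seed=7)
)
table = aq.normalize_counts(counts)
stats = aq.occurrence_stats(table, "auto")
fit = aq.fit_ncm(stats)
print(f"Nm = {fit.nm:.0f}, R^2 = {fit.r_squared:.3f}")
```

prints

```
Nm = 1184, R^2 = 0.989
```

The true dispersal parameter was *Nm* = 1000; the refit lands within a
factor of 1.2 (one-read detection and the estimated abscissa bias the
fit slightly upward — see `docs/methods.md`), and R² near 1 says the
occupancy–abundance cloud is fully explained by dispersal, as it should
be for data drawn from the model. A niche-filtered simulation
(`simulate_niche` with narrow tolerances) instead gives R² below 0.3.

The same battery runs end to end from the shell:

```bash
aquassembly simulate --kind transect --seed 11 --out-dir sim/
aquassembly run --table sim/abundance.tsv --metadata sim/metadata.tsv \
    --genes sim/genes.tsv --reference-region Tibet --seed 1 --out-dir run/
```

which writes per-stratum NCM tables, edge lists, extinction curves,
decay pair tables and a single `report.json` with provenance and every
derived seed.

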
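# persistome

Analysis pipeline for **longitudinal 16S amplicon studies with spike-in
absolute quantification**, built around the microbiome of developing
aquatic larvae (giant freshwater prawn, *Macrobrachium rosenbergii*,
sampled daily across 11 zoeal stages plus postlarva) but applicable to
any sample × ASV count table with per-sample spike-in calibration,
developmental/temporal metadata and a rooted phylogeny.

It is written for microbial ecologists who want, from one table:

1. **Absolute quantification** — per-sample standard curves from
   spike-ins added at known gradient copy numbers; reads → 16S copies →
   copies per gram wet mass.
2. **Diversity and turnover** — richness, Shannon–Wiener *H* (nats),
   Pielou's *J = H/ln S*, Faith's PD; Bray–Curtis and weighted-UniFrac
   dissimilarity; PCoA; one-way ANOSIM across stages; the time-decay
   relationship log₁₀ *S*(Δt) = *w*·log₁₀ Δt + b whose slope *w* is the
   community turnover rate, and an ANCOVA-style comparison of
   taxonomic vs phylogenetic *w*.
3. **Persistent-microbiome detection** — taxa ranked by an
   abundance–occupancy index (stage-mean occupancy + replicate
   consistency, abundance as tie-break); the core is truncated where
   the marginal gain in explained Bray–Curtis β-diversity falls to
   ≤ 2 % (first-order-difference "elbow" / last-2 %-increase rule).
4. **Sloan neutral-community-model fitting** — a taxon with
   metacommunity mean relative abundance *p* in a local community of
   size *Nt* with migration rate *m* is detected with probability

   occ(p, m) = 1 − I_d(Nt·m·p, Nt·m·(1 − p)),  d = 1/Nt

   (I = regularized incomplete beta). For count tables the package fits,
   by default, the exact count-detection form
   1 − B(a, b + Nt)/B(a, b) (beta-binomial zero class, a = Nt·m·p,
   b = Nt·m·(1 − p)); *m* is estimated by least squares on
   occupancy vs *p*, compared against the parameter-free binomial null
   1 − (1 − p)^Nt by AIC, and each ASV is partitioned into
   neutral / environmentally selected / dispersal-limited by a Wilson
   95 % band around the fitted curve.
5. **A synthetic-data generator** that emulates the full longitudinal
   design (126 samples = 21 days posthatch × 6 tanks, ~10⁵–10⁶ total
   copies/sample, 80 planted persistent ASVs carrying 95 % of the
   abundance, stage-specific transients, per-sample linear read↔copy
   spike-ins, a random rooted tree) with complete ground truth, so every
   stage of the pipeline is verifiable without any downloads.

## Worked example

Simulate a study-shaped dataset and run every stage:

```sh
persistome simulate --outdir demo --seed 42
persistome all --outdir demo/results \
    --counts demo/counts.tsv --manifest demo/manifest.tsv \
    --metadata demo/metadata.tsv --tree demo/tree.nwk --seed 42
```

which prints

```
wrote 126 samples x 2000 taxa to demo
completed stages: quantify, diversity, turnover, persistence, neutral
```

and leaves TSV/JSON results under `demo/results/`. For this seed:

- `core.json` — elbow rank **75**, abundance share **0.933**: the
  detected persistent set is <4 % of ASVs but carries 93 % of all 16S
  copies (the generator planted 80 persistent ASVs at 95 %).
- `turnover.json` — ANOSIM R = **0.282**, p = 0.001 (stages differ);
  time-decay slope w = **−0.025**, p ≈ 4e−19: community similarity
  decays with time separation.
- `slope_comparison.json` — taxonomic w = −0.0249 vs phylogenetic
  (weighted-UniFrac) w = −0.0116, interaction F = **22.7**,
  p ≈ 2e−6: on this synthetic community the two turnover rates differ.
- `neutral.json` — fitted m = **0.0573**, R² = 0.937, neutral preferred
  over the binomial null by ΔAIC ≈ **9838**; per-ASV partition: 1910
  neutral, 32 above (selected), 57 below (dispersal-limited). The low
  m reflects the strong stage structure the generator plants.
- `calibration.tsv` / `absolute.per_gram.tsv` — per-sample slopes k with
  r² = 1 (noiseless spike-ins) and absolute abundances around
  log₁₀ ≈ 7 copies/g.

The same operations are available as a library
(`import persistome as pm`): `pm.simulate_dataset`, `pm.quantify`,
`pm.alpha_diversity`, `pm.beta_matrix`, `pm.anosim`, `pm.time_decay_fit`,
`pm.compare_slopes`, `pm.classify_persistent`, `pm.fit_sloan`,
`pm.fit_binomial`, `pm.compare_models`.

## Layout

```
src/persistome/
  synth.py        synthetic longitudinal datasets with ground truth
  spikein.py      standard curves, reads -> copies, copies/gram
  diversity.py    alpha/beta diversity, Kruskal-Wallis + Dunn letters
  turnover.py     PCoA, ANOSIM, time decay, slope comparison
  persistence.py  abundance-occupancy ranking, elbow rule, core set
  neutral.py      Sloan fit, binomial null, AIC comparison, partition
  pipeline.py     orchestration with provenance headers
  cli.py          `persistome` command (simulate/quantify/.../all)
  reference.py    published persistent-set membership table
```

See `docs/methods.md` for the statistical details and design choices.
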
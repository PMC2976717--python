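# neolith

Population genetics of ancient mitochondrial HVS-I data, built around one
question: did farming reach Central Europe ~7,500 years ago by *demic
diffusion* (immigrating Near Eastern farmers) or by *cultural diffusion*
(local hunter-gatherers adopting agriculture without gene flow)?  The
package re-implements the complete analysis chain used to address this with
the Derenburg Linearbandkeramik (LBK) graveyard sample and pooled modern
comparative populations:

- **Haplotype core** — rCRS-relative HVS-I variant sets ("093C, 224C, 311C"
  notation, np 15997–16409, trimmed to np 16069–16365 for analysis),
  haplogroup binning into 19 frequency categories, population TSV and FASTA
  I/O, embedded printed-source fixtures.
- **Diversity statistics** — haplotype diversity *h*, segregating sites,
  Tajima's *D*, within-graveyard haplotype sharing, and the kin-deduplication
  rule that reduces LBK42 to LBK34.
- **Shared-haplotype analysis** — fixed-size pooled panels, exact-identity
  pivot tables, the noninformative/informative/unique classification,
  per-pool sharing percentages, two-proportion z tests, bootstrap CIs.
- **Distances and ordination** — Kimura two-parameter distances with gamma
  rate heterogeneity (shape 0.205), AMOVA-based pairwise F_ST, Nei's
  standard distance on haplogroup frequencies, classical PCA, metric MDS.
- **Distance maps** — inverse-distance-weighted gene-geography surfaces of
  Nei distances with the 0.02-step green interval legend.
- **Serial coalescent + ABC** — a backwards-in-time simulator over demes
  with growth, fusions and migration pulses, serial (ancient) sampling and
  finite-sites gamma mutation; rejection ABC over six demographic scenarios
  (H0a/H0b continuity, H1 cultural diffusion, H2 demic diffusion at
  25/50/75% migrant contribution) scored by AIC and Akaike weights on a
  five-component pairwise-F_ST summary vector.

`docs/methods.md` documents the models, defaults, and known printed-source
inconsistencies in detail.

## Worked example

```python
>>> import neolith as nl
>>> deb = nl.fixtures.derenburg_table1().with_haplotypes()
>>> deb.size
22
>>> round(nl.haplotype_diversity(deb), 4)
0.9567
>>> round(nl.tajimas_d(deb), 3)
-0.794
>>> (100 * nl.hg_frequency_vector(deb)).round(2)["N1a"]
13.64
>>> {k: len(v) for k, v in nl.within_sharing_partition(deb).items()}
{'unique': 8, 'pairs': 4, 'triples': 2, 'larger': 0}
>>> reduced, dropped = nl.deduplicate_kin(deb); dropped
8
```

The 22 sequenced Derenburg individuals carry 14 distinct haplotypes (h =
0.957): eight are unique within the graveyard, four are shared by pairs and
two by trios; removing one member of each identity group drops 8
individuals — the published kinship screen.  N1a, today a rare haplogroup,
sits at 13.6% (3/22).  The negative Tajima's D is the signature of a
recently expanded population.

Model comparison against the published observed F_ST vector:

```python
>>> import numpy as np
>>> w = nl.akaike_weights(nl.fixtures.table4_aic().to_numpy())
>>> dict(zip(nl.fixtures.MODEL_IDS, w.round(4)))
{'H0a': 0.0, 'H0b': 0.0, 'H1': 0.002, 'H2_25': 0.0555,
 'H2_50': 0.4184, 'H2_75': 0.524}
```

Over 99.7% of the model probability lands on the demic-diffusion (H2)
family, with the 75% and 50% Near-Eastern-contribution variants dominating.

A CLI mirrors the stages (`neolith diversity|share|fst|pca|mds|map|
simulate|abc|synth|run`); all tabular outputs are TSV and every stochastic
stage takes an explicit `--seed`.

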
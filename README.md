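# solor — solitary odorant-receptor gene analysis

Mouse odorant-receptor (OR) genes — roughly 1100 intact genes — sit mostly
in dense genomic clusters, which makes their regulatory sequences hard to
attribute to any single gene: enhancers and promoters within a cluster are
partially redundant and act on several neighbours. A handful of OR genes
are **solitary**: no other OR gene lies within more than 1 Mb of their
transcript on either side. Such genes carry an unambiguous, dedicated set
of regulatory sequences and are attractive simplified models for studying
*OR gene choice*, the unexplained mechanism by which each olfactory sensory
neuron expresses a single allele of a single OR gene.

`solor` is a Python library and CLI for the complete analysis around these
genes:

* **`solor.solitary`** — classify OR genes by genomic isolation from BED6 or
  GFF3 transcript annotation. Gene *g* with flanking transcript gaps
  `up, down` is solitary iff `min(up, down) > 1 Mb` (strict, edge-to-edge,
  one-sided at sequence ends); `MDAS = min(up, down)` is the width, in Mb,
  of its OR-free interval. Includes cross-species conservation tables over
  ortholog groups.
* **`solor.race`** — polish 5' RACE clones, spliced-align them to genomic
  windows (k-mer seeding + collinear chaining, GT..AG intron annotation),
  select the most upstream transcription start site per gene, and emit the
  301-bp putative minimal promoter centred on it. Also checks riboprobe
  specificity against a 75% homology cap.
* **`solor.motifs`** — build a homeodomain-site position weight matrix from
  enhancer seed sites extended to inverted-repeat (hemi-palindrome)
  boundaries, and scan promoters FIMO-style: log-odds scores in bits with
  **exact** p-values from the dynamic-programming distribution of the
  discretised word score, p(word) = P(score ≥ s | i.i.d. background).
* **`solor.alleles`** — progressive multiple alignment of promoter allele
  panels (C57BL/6J reference, wild populations, laboratory strains), 51%
  per-population consensus calling, and classification of the reference
  allele as *mutant* (every wild allele differs somewhere) and/or
  *polymorphic* (any allele differs anywhere), with per-population
  substitution totals.
* **`solor.phylo`** — Tamura–Nei (TN93) pairwise distances with pairwise
  deletion, Saitou–Nei neighbor joining with deterministic tie-breaking,
  and conservation ranking by mean pairwise distance.
* **`solor.expression`** — Abercrombie-corrected neuron counts
  (N = n·T/(T+h), every-eighth-section sampling), per-gene mean ± SD and
  CV, and the mean-vs-CV Pearson correlation with a t-based p-value.
* **`solor.simulate`** — seeded generators for every input (OR annotations
  with planted solitary genes, allele panels with planted variation, RACE
  clones from known gene models, over-dispersed cell counts), each
  returning its planted truth.

## Worked example

Generate a synthetic OR annotation at the repertoire's scale (about 1100
genes in ~50 clusters, 8 planted intact solitary genes plus 3 solitary
pseudogenes) and scan it:

```
$ solor synth annotation --seed 1 --out ann.bed
1126 genes, 11 planted solitary

$ solor solitary scan --annotation ann.bed --out calls.tsv
11 solitary genes (8 intact, 3 pseudogenes); most isolated: OrSol02
```

`calls.tsv` holds one row per gene; the solitary rows include the MDAS in
Mb and the nearest solitary partner (isolated genes often come in distant
pairs):

```
   gene_id sequence_id  mdas_mb nearest_solitary_partner
   OrSol01        chr1     14.0                  OrSol04
   OrSol04        chr1     15.3                  OrSol01
   OrSol02        chr5     42.4                        -
```

Every planted gene is recovered with its exact planted MDAS — the
classifier's calls equal the generator's truth, and the most isolated gene
(42.4 Mb) tops the summary.

Summarise the shipped per-gene cell-count table (mean ± SD of olfactory
sensory neurons expressing each solitary gene in newborn mice, n = 3
animals):

```
$ solor expression summarize --out summary.tsv
r = -0.8144, p = 0.013850 (df = 6)
```

The printed correlation says that across the eight solitary genes, the
coefficient of variation of the counts falls as the average count rises —
genes expressed in many neurons are counted with relatively tight
dispersion (CV 0.013 at mean 832), genes expressed in few neurons with
wide dispersion (CV 0.669 at mean 130).

Library use mirrors the CLI; for example the promoter pipeline is

```python
from solor import race, simulate
import numpy as np

model = simulate.generate_gene_model(np.random.default_rng(0))
clones = simulate.generate_race_clones(model, n_clones=6, seed=1)
alns = [
    race.map_clone(race.RaceClone(cid, race.polish_clone(raw, ["AAGCAGTGGTATCAACGCAGAGT"])),
                   model.window)
    for cid, raw in clones
]
tss = race.select_tss(alns, model.strand, "geneX")
promoter = race.define_promoter(tss, model.window)   # 301 bp centred on the TSS
```

See `docs/methods.md` for the models, parameter defaults and the design
decisions behind them.

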
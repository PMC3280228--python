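# aldhkit

A gene-family census toolkit, built around the grape (*Vitis vinifera*)
aldehyde dehydrogenase (ALDH) superfamily. ALDHs are NAD(P)⁺-dependent
enzymes that oxidize reactive aldehydes to carboxylic acids; plant
genomes carry a few dozen of them across up to 24 numbered families,
and cataloguing them in a new genome is a standard workflow: find
candidates, name them by sequence-identity rules, build a tree, compare
gene structures, map duplications, and screen expression data for
stress-responsive members. `aldhkit` implements that workflow as a
library with a thin command-line layer, testable end to end on packaged
catalog tables and synthetic data with planted truth.

## What it computes

- **Identification** (`aldhkit.identify`) — candidate search by
  PROSITE-syntax motif scanning plus best-identity search against a
  curated panel (OR-combined evidence).
- **Classification** (`aldhkit.classify`) — the AGNC nomenclature rule:
  pairwise global alignment (BLOSUM62, affine gaps 10/0.5) and percent
  identity *p*; a query joins a family if *p* > 40% to a named member,
  its subfamily if *p* > 60%, and founds a new family otherwise. A
  whole-proteome census names every candidate, grouping mutually novel
  queries by single linkage.
- **Phylogeny** (`aldhkit.phylo`) — progressive MSA on an NJ guide
  tree, p-distances with pairwise deletion, neighbor joining, bootstrap
  support (% of column-resampled replicate trees containing each
  bipartition of the full-data tree; default 1000 replicates), Newick I/O.
- **Gene structure** (`aldhkit.structure`) — exon–intron structures by
  spliced alignment of CDS to genomic sequence (free-length introns
  ≥ 20 bp with a GT..AG bonus), structure comparison across a family,
  splice-event classification (intron retention, alternative donor/
  acceptor, exon skip), and longest-ORF translation.
- **Duplication & synteny** (`aldhkit.synteny`) — tandem clusters
  (same-family genes with ≤ 1 intervening locus) and membership of
  genes in within- or cross-genome synteny blocks read from TSV, with
  unambiguous / ambiguous / counterpart-lost ortholog calls.
- **Expression screen** (`aldhkit.expression`) — quantile
  normalization, removal of probes absent/marginal on every array,
  moderated t with empirical-Bayes variance shrinkage (moments
  estimation of the prior), Benjamini–Hochberg FDR at 0.05, and
  gene-level responsiveness with a clustered log2-FC matrix.
- **Comparative census** (`aldhkit.compare`) — core families, lineage-
  shared families and per-organism totals over an organism × family
  count matrix.
- **Fixtures & synthetic data** (`aldhkit.fixtures`,
  `aldhkit.synthetic`) — checksummed TSV transcriptions of the grape
  ALDH catalog (25 rows, 23 loci) and the 11-organism family-count
  table, plus a seeded generator for proteomes with planted families,
  gene models, tandem arrays and two-condition expression matrices.

## Worked example

Running `python examples/catalog_counts.py` prints:

```
grape ALDH genes: 23 in 10 families (8 families with >1 member)
family sizes: {2: 3, 3: 4, 5: 3, 6: 3, 7: 2, 10: 2, 11: 2, 12: 1, 18: 2, 22: 1}
core families shared by vascular plants ['V. vinifera', 'A. thaliana', 'Z. mays', 'O. sativa']: [2, 3, 5, 6, 7, 10, 11, 12, 18, 22] (10)
of those, shared with algae: [2, 3, 5, 6, 10, 11, 12, 22] (8)
```

23 genes in 10 families is the grape census itself; the 10 core
families predate the monocot/eudicot split, and the 8 also present in
algae predate the move of plants onto land. In the same spirit,
`python examples/tandem_and_synteny.py` prints the two tandem clusters
(VvALDH5F1/5F2/5F3 and VvALDH6B3/6B5, the latter with one intervening
gene) and the 11 genes inside the six duplicated block pairs, and
`python examples/splice_variants.py` recovers a planted 20-exon
structure exactly and classifies a 113-bp intron retention and an
alternative 3′ acceptor in exon 3:

```
planted 20-exon gene: recovered 20 exons, boundaries exact: True
CDS of 1617 bp translates to 538 residues (cds/3 - 1)
v2-like: intron_retention at position 1, +113 bp
v3-like: alt_3prime_acceptor at position 3, +21 bp
```

The other examples cover the planted-family census
(`classify_families.py`), bootstrap phylogenies
(`phylogeny_bootstrap.py`) and the DE screen (`expression_screen.py`).

A thin CLI mirrors the main operations, e.g.:

```bash
aldhkit census-compare --shared-with alga
aldhkit classify --queries proteome.faa --panel panel.faa --labels labels.tsv
aldhkit de-screen --matrix m.tsv --calls c.tsv --design d.tsv --alpha 0.05
```

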
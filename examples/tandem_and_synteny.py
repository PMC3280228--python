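"""Tandem duplications and syntenic orthologs from the packaged layout.

Applies the at-most-one-intervening-gene tandem rule to the grape gene
order, maps the genes into the six within-genome duplicated block pairs
and lists grape-Arabidopsis syntenic ortholog pairs.
"""

from aldhkit import fixtures
from aldhkit.synteny import find_tandem_clusters, map_genes_to_blocks, syntenic_pairs

lay = fixtures.grape_layout()
fams = {g: fixtures.family_of_gene(g) for g in lay.genes()}

clusters = find_tandem_clusters(lay, fams, max_intervening=1)
print(f"tandem clusters ({len(clusters)}):")
for c in clusters:
    print(f"  family {c.family}: {' / '.join(c.gene_ids)} "
          f"(intervening loci: {c.intervening})")

blocks = fixtures.grape_synteny_blocks(lay)
mem = map_genes_to_blocks(sorted(fams), {"vitis": lay}, blocks)
print(f"{len(mem.genes_in_blocks())} genes sit inside the "
      f"{len(blocks)} within-genome block pairs (segmental duplicates)")

ath = fixtures.arabidopsis_layout()
all_fams = dict(fams)
all_fams.update({g: fixtures.family_of_gene(g) for g in ath.genes()})
xblocks = fixtures.grape_arabidopsis_blocks(lay, ath)
xmem = map_genes_to_blocks(sorted(all_fams),
                           {"vitis": lay, "arabidopsis": ath}, xblocks)
pairs = syntenic_pairs(xmem, all_fams, mode="cross")
print("grape-Arabidopsis syntenies:")
for status, sub in pairs.groupby("status"):
    names = [f"{r.gene_a}-{r.gene_b}" if r.gene_b else r.gene_a
             for r in sub.itertuples()]
    print(f"  {status}: {', '.join(names)}")
# Unambiguous 1:1 pairs predate the grape/Arabidopsis split; the
# counterpart-lost entry marks a synteny whose partner gene disappeared.
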
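"""Tandem duplications and synteny-block mapping.

Tandem duplicates are same-family genes lying adjacent on a chromosome
with at most ``max_intervening`` annotated loci between successive
members (default 1). Synteny blocks are consumed from file — paired
chromosomal intervals in either a rank dialect (gene-order indices) or a
coordinate dialect — and genes are mapped into them to call segmental
duplicates (within one genome) and syntenic orthologs (across genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import InputError

BACKGROUND = "."


@dataclass(frozen=True)
class LayoutEntry:
    rank: int
    locus_id: str
    gene_id: str | None  # None for background (non-family) loci


@dataclass
class GenomeLayout:
    """Per-chromosome ordered gene lists for one genome."""

    genome: str
    chromosomes: dict[str, list[LayoutEntry]]

    def __post_init__(self):
        seen: set[str] = set()
        for chrom, entries in self.chromosomes.items():
            ranks = [e.rank for e in entries]
            if ranks != list(range(1, len(entries) + 1)):
                raise InputError(f"{chrom}: ranks not consecutive from 1")
            for e in entries:
                if e.locus_id in seen:
                    raise InputError(f"duplicate locus id {e.locus_id!r}")
                seen.add(e.locus_id)

    def position_of(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, rank) of a named gene."""
        for chrom, entries in self.chromosomes.items():
            for e in entries:
                if e.gene_id == gene_id:
                    return chrom, e.rank
        raise InputError(f"gene {gene_id!r} missing from layout of {self.genome!r}")

    def genes(self) -> dict[str, tuple[str, int]]:
        out = {}
        for chrom, entries in self.chromosomes.items():
            for e in entries:
                if e.gene_id is not None:
                    out[e.gene_id] = (chrom, e.rank)
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#genome={self.genome}\n")
            fh.write("chromosome\trank\tlocus_id\tgene_id\n")
            for chrom in self.chromosomes:
                for e in self.chromosomes[chrom]:
                    gid = e.gene_id if e.gene_id is not None else BACKGROUND
                    fh.write(f"{chrom}\t{e.rank}\t{e.locus_id}\t{gid}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        genome = "genome"
        with open(path) as fh:
            first = fh.readline().strip()
            if first.startswith("#genome="):
                genome = first.split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t", dtype=str)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", dtype=str)
        chroms: dict[str, list[LayoutEntry]] = {}
        for row in df.itertuples(index=False):
            gid = None if row.gene_id in (BACKGROUND, "", None) else row.gene_id
            chroms.setdefault(row.chromosome, []).append(
                LayoutEntry(int(row.rank), row.locus_id, gid))
        for entries in chroms.values():
            entries.sort(key=lambda e: e.rank)
        return cls(genome, chroms)


@dataclass(frozen=True)
class BlockSide:
    genome: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise InputError(
                f"malformed block interval [{self.start},{self.end}] on "
                f"{self.genome}:{self.chromosome}")

    def contains(self, chromosome: str, pos: int) -> bool:
        return chromosome == self.chromosome and self.start <= pos <= self.end


@dataclass(frozen=True)
class SyntenyBlock:
    block_id: str
    a: BlockSide
    b: BlockSide
    orientation: Literal["same", "inverted"] = "same"


@dataclass
class TandemCluster:
    family: int
    gene_ids: list[str]            # ordered by rank
    intervening: list[int]         # loci between successive members
    chromosome: str


def find_tandem_clusters(
    layout: GenomeLayout,
    families: Mapping[str, int],
    max_intervening: int = 1,
) -> list[TandemCluster]:
    """Maximal runs of same-family genes separated by few loci.

    ``families`` maps gene id -> family number for every gene of
    interest; all mapped genes must appear in the layout. Intervening
    loci of any kind (background or other families) count toward the
    gap. Singleton runs are not reported.
    """
    positions = layout.genes()
    for gid in families:
        if gid not in positions:
            raise InputError(f"gene {gid!r} missing from layout")
    clusters: list[TandemCluster] = []
    by_chrom_family: dict[tuple[str, int], list[tuple[int, str]]] = {}
    for gid, fam in families.items():
        chrom, rank = positions[gid]
        by_chrom_family.setdefault((chrom, fam), []).append((rank, gid))
    for (chrom, fam), members in sorted(by_chrom_family.items()):
        members.sort()
        run: list[tuple[int, str]] = [members[0]]
        gaps: list[int] = []
        for prev, cur in zip(members, members[1:]):
            gap = cur[0] - prev[0] - 1
            if gap <= max_intervening:
                run.append(cur)
                gaps.append(gap)
            else:
                if len(run) > 1:
                    clusters.append(TandemCluster(fam, [g for _, g in run], gaps, chrom))
                run, gaps = [cur], []
        if len(run) > 1:
            clusters.append(TandemCluster(fam, [g for _, g in run], gaps, chrom))
    return clusters


@dataclass
class BlockMembership:
    table: pd.DataFrame        # columns: gene_id, block_id, side, genome
    unmapped: list[str]

    def genes_in_blocks(self) -> set[str]:
        return set(self.table["gene_id"]) if len(self.table) else set()


def map_genes_to_blocks(
    genes: Iterable[str],
    layouts: Mapping[str, GenomeLayout],
    blocks: Sequence[SyntenyBlock],
) -> BlockMembership:
    """Assign every gene to all blocks whose interval contains it.

    Positions come from the layout of the gene's genome (rank dialect);
    genes contained in no block are flagged unmapped rather than
    dropped.
    """
    positions: dict[str, tuple[str, str, int]] = {}
    for genome, layout in layouts.items():
        for gid, (chrom, rank) in layout.genes().items():
            positions[gid] = (genome, chrom, rank)
    rows = []
    unmapped = []
    for gid in genes:
        if gid not in positions:
            raise InputError(f"gene {gid!r} not present in any layout")
        genome, chrom, rank = positions[gid]
        hit = False
        for blk in blocks:
            for side_name, side in (("A", blk.a), ("B", blk.b)):
                if side.genome == genome and side.contains(chrom, rank):
                    rows.append({"gene_id": gid, "block_id": blk.block_id,
                                 "side": side_name, "genome": genome})
                    hit = True
        if not hit:
            unmapped.append(gid)
    table = pd.DataFrame(rows, columns=["gene_id", "block_id", "side", "genome"])
    return BlockMembership(table, unmapped)


def syntenic_pairs(
    membership: BlockMembership,
    families: Mapping[str, int],
    mode: Literal["within", "cross"] = "within",
) -> pd.DataFrame:
    """Same-family gene pairs on opposite sides of one block.

    For each block and family, pairs are classified ``unambiguous`` when
    the correspondence is 1:1 and ``ambiguous`` otherwise. A block side
    holding family members with no same-family gene on the opposite side
    yields ``counterpart_lost`` rows (gene_b empty), mirroring syntenic
    positions whose partner gene has been lost.
    """
    t = membership.table
    rows = []
    if len(t):
        for block_id, sub in t.groupby("block_id", sort=True):
            a_genes = sorted(sub[sub["side"] == "A"]["gene_id"].unique())
            b_genes = sorted(sub[sub["side"] == "B"]["gene_id"].unique())
            fams = sorted({families[g] for g in a_genes + b_genes if g in families})
            for fam in fams:
                fa = [g for g in a_genes if families.get(g) == fam]
                fb = [g for g in b_genes if families.get(g) == fam]
                if fa and fb:
                    status = "unambiguous" if len(fa) == 1 and len(fb) == 1 else "ambiguous"
                    for ga in fa:
                        for gb in fb:
                            rows.append({"block_id": block_id, "family": fam,
                                         "gene_a": ga, "gene_b": gb,
                                         "status": status})
                elif fa or fb:
                    for g in fa + fb:
                        rows.append({"block_id": block_id, "family": fam,
                                     "gene_a": g, "gene_b": "",
                                     "status": "counterpart_lost"})
    return pd.DataFrame(rows, columns=["block_id", "family", "gene_a", "gene_b", "status"])


# ---------------------------------------------------------------------------
# Block TSV I/O. The header line declares the dialect, e.g. "#dialect=rank".

def write_blocks_tsv(blocks: Sequence[SyntenyBlock], path: str | Path,
                     dialect: str = "rank") -> None:
    with open(path, "w") as fh:
        fh.write(f"#dialect={dialect}\n")
        fh.write("block_id\tgenome_a\tchrom_a\tstart_a\tend_a\t"
                 "genome_b\tchrom_b\tstart_b\tend_b\torientation\n")
        for blk in blocks:
            fh.write("\t".join(map(str, [
                blk.block_id,
                blk.a.genome, blk.a.chromosome, blk.a.start, blk.a.end,
                blk.b.genome, blk.b.chromosome, blk.b.start, blk.b.end,
                blk.orientation])) + "\n")


def read_blocks_tsv(path: str | Path) -> tuple[list[SyntenyBlock], str]:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#dialect="):
            raise InputError("block file must declare a dialect in its header")
        dialect = first.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t")
    blocks = []
    for row in df.itertuples(index=False):
        blocks.append(SyntenyBlock(
            str(row.block_id),
            BlockSide(row.genome_a, row.chrom_a, int(row.start_a), int(row.end_a)),
            BlockSide(row.genome_b, row.chrom_b, int(row.start_b), int(row.end_b)),
            row.orientation))
    return blocks, dialect
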
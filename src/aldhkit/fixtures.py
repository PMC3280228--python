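"""Packaged machine-readable transcriptions of the grape ALDH census.

Two tables ship with the package as TSV transcriptions guarded by
SHA-256 checksums: the 25-row grape ALDH gene catalog (23 distinct loci;
the three VvALDH2B4 splice variants share one locus) and the
organism x family member-count matrix for eleven taxa.

Chromosome assignments of the grape loci are not part of the tables, so
the derived :func:`grape_layout` orders loci by their numeric locus id
on a single proxy chromosome — a documented fixture assumption — with
background (non-ALDH) loci filling the gaps. Within-genome and
grape-Arabidopsis synteny blocks are built programmatically around the
published syntenic gene pairs.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .compare import FamilyMatrix
from .errors import FixtureError
from .synteny import BlockSide, GenomeLayout, LayoutEntry, SyntenyBlock

_CHECKSUMS = {
    "grape_aldh_genes.tsv":
        "3691cf0549414aac4328b1786a043958d2f83bbe63088292efb2db8c54b68570",
    "aldh_family_counts.tsv":
        "f2a9e331119c2d7874ca00396b9e22afb48231aab3a4d7e2003639a8cb567ecc",
}


def _data_path(name: str) -> Path:
    path = resources.files("aldhkit").joinpath("data", name)
    with resources.as_file(path) as p:
        if not p.exists():
            raise FixtureError(f"packaged fixture {name!r} is missing")
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        if digest != _CHECKSUMS.get(name, digest):
            raise FixtureError(
                f"fixture {name!r} checksum mismatch: {digest}")
        return p


@dataclass(frozen=True)
class Table1Row:
    family_label: str
    gene_id: str
    locus_id: str
    accession: str
    function: str
    cds_len: int
    orf_len: int

    @property
    def family(self) -> int:
        return int(self.family_label.split()[-1])


@dataclass
class Table1Fixture:
    rows: list[Table1Row]

    def distinct_loci(self) -> set[str]:
        return {r.locus_id for r in self.rows}

    def genes(self) -> dict[str, Table1Row]:
        """One row per locus; splice variants collapse to the _v1 row."""
        out: dict[str, Table1Row] = {}
        for r in self.rows:
            out.setdefault(r.locus_id, r)
        return {r.gene_id.split("_")[0]: r for r in out.values()}

    def family_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for row in self.genes().values():
            sizes[row.family] = sizes.get(row.family, 0) + 1
        return sizes

    def row(self, gene_id: str) -> Table1Row:
        for r in self.rows:
            if r.gene_id == gene_id:
                return r
        raise FixtureError(f"no catalog row for {gene_id!r}")


def load_table1() -> Table1Fixture:
    path = _data_path("grape_aldh_genes.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rows = [
        Table1Row(r.family, r.gene_id, r.locus_id, r.accession, r.function,
                  int(r.cds_len), int(r.orf_len))
        for r in df.itertuples(index=False)
    ]
    if len(rows) != 25:
        raise FixtureError(f"gene catalog has {len(rows)} rows, expected 25")
    return Table1Fixture(rows)


def load_table2() -> FamilyMatrix:
    return FamilyMatrix.from_tsv(_data_path("aldh_family_counts.tsv"))


def packaged_patterns_path() -> Path:
    path = resources.files("aldhkit").joinpath("data", "aldh_patterns.txt")
    with resources.as_file(path) as p:
        if not p.exists():
            raise FixtureError("packaged pattern config is missing")
        return p


_GENE_RE = re.compile(r"ALDH(\d+)")


def family_of_gene(gene_id: str) -> int:
    """Family number encoded in a systematic gene name (e.g. VvALDH3H1 -> 3)."""
    m = _GENE_RE.search(gene_id)
    if not m:
        raise FixtureError(f"cannot parse family from {gene_id!r}")
    return int(m.group(1))


def _locus_number(locus_id: str) -> int:
    # GSVIVG01036719001 -> 36719 (strip assembly prefix and version suffix)
    return int(locus_id[8:-3])


MAX_BACKGROUND_FILL = 2


def grape_layout() -> GenomeLayout:
    """Proxy gene-order layout of the 23 grape ALDH loci.

    Loci are ordered by numeric locus id on one proxy chromosome;
    between consecutive ALDH loci, (id gap - 1) background loci are
    inserted, capped at 2 — enough to exercise the at-most-one-
    intervening-gene tandem rule.
    """
    t1 = load_table1()
    loci = sorted({(_locus_number(r.locus_id), r.locus_id,
                    r.gene_id.split("_")[0]) for r in t1.rows})
    entries: list[LayoutEntry] = []
    rank = 0
    bg = 0
    prev_num = None
    for num, locus_id, gene_id in loci:
        if prev_num is not None:
            fill = min(num - prev_num - 1, MAX_BACKGROUND_FILL)
            for _ in range(fill):
                rank += 1
                bg += 1
                entries.append(LayoutEntry(rank, f"BG{bg:04d}", None))
        rank += 1
        entries.append(LayoutEntry(rank, locus_id, gene_id))
        prev_num = num
    return GenomeLayout("vitis", {"chrP": entries})


# Within-genome duplicated region pairs (six block pairs over 11 genes
# from five families). Family 2 contributes two of the three possible
# pairs among its three block-resident genes.
GRAPE_BLOCK_PAIRS = [
    ("VvALDH2B4", "VvALDH2B9"),
    ("VvALDH2B4", "VvALDH2B8"),
    ("VvALDH3H1", "VvALDH3H5"),
    ("VvALDH7B5", "VvALDH7D1"),
    ("VvALDH10A9", "VvALDH10B1"),
    ("VvALDH18B1", "VvALDH18B3"),
]


def _rank_side(layout: GenomeLayout, gene_id: str, pad: int = 0) -> BlockSide:
    chrom, rank = layout.position_of(gene_id)
    n = len(layout.chromosomes[chrom])
    return BlockSide(layout.genome, chrom, max(1, rank - pad), min(n, rank + pad))


def _span_side(layout: GenomeLayout, gene_a: str, gene_b: str) -> BlockSide:
    chrom_a, ra = layout.position_of(gene_a)
    chrom_b, rb = layout.position_of(gene_b)
    if chrom_a != chrom_b:
        raise FixtureError("span genes on different chromosomes")
    return BlockSide(layout.genome, chrom_a, min(ra, rb), max(ra, rb))


def grape_synteny_blocks(layout: GenomeLayout | None = None) -> list[SyntenyBlock]:
    """Six within-genome block pairs covering 11 ALDH genes."""
    layout = layout or grape_layout()
    blocks = []
    for i, (ga, gb) in enumerate(GRAPE_BLOCK_PAIRS, 1):
        blocks.append(SyntenyBlock(
            f"VV_B{i}", _rank_side(layout, ga, pad=1), _rank_side(layout, gb, pad=1)))
    return blocks


# Arabidopsis ALDH genes that anchor grape-Arabidopsis syntenies.
ARABIDOPSIS_GENES = [
    "AthALDH3H1", "AthALDH7B4", "AthALDH3F1", "AthALDH11A3",
    "AthALDH5F1", "AthALDH22A1", "AthALDH2B4", "AthALDH2B7",
    "AthALDH18A1", "AthALDH18A2",
]

# Unambiguous one-to-one syntenic ortholog pairs.
ORTHOLOG_PAIRS = [
    ("VvALDH3H1", "AthALDH3H1"),
    ("VvALDH7D1", "AthALDH7B4"),
    ("VvALDH3F1", "AthALDH3F1"),
    ("VvALDH11B1", "AthALDH11A3"),
    ("VvALDH5F3", "AthALDH5F1"),
    ("VvALDH22A1", "AthALDH22A1"),
]


def arabidopsis_layout() -> GenomeLayout:
    """Proxy layout of the Arabidopsis anchor genes (one chromosome).

    The tandem-like AthALDH2B4/2B7 and AthALDH18A1/18A2 duplicates sit
    adjacent so a single block side can span each duplicated pair.
    """
    entries: list[LayoutEntry] = []
    rank = 0
    bg = 0

    def add_gene(gid: str):
        nonlocal rank
        rank += 1
        entries.append(LayoutEntry(rank, f"AT{rank:04d}", gid))

    def add_bg(n: int = 2):
        nonlocal rank, bg
        for _ in range(n):
            rank += 1
            bg += 1
            entries.append(LayoutEntry(rank, f"ABG{bg:04d}", None))

    add_bg(1)
    for gid in ["AthALDH3H1", "AthALDH7B4", "AthALDH3F1", "AthALDH11A3",
                "AthALDH5F1", "AthALDH22A1"]:
        add_gene(gid)
        add_bg(2)
    add_gene("AthALDH2B4")
    add_gene("AthALDH2B7")
    add_bg(2)
    add_gene("AthALDH18A1")
    add_gene("AthALDH18A2")
    add_bg(2)
    return GenomeLayout("arabidopsis", {"athP": entries})


def grape_arabidopsis_blocks(
    vv_layout: GenomeLayout | None = None,
    ath_layout: GenomeLayout | None = None,
) -> list[SyntenyBlock]:
    """Cross-genome blocks: six 1:1 syntenies, the duplicated family-2 and
    family-18 correspondences (one grape gene vs two Arabidopsis genes),
    and the VvALDH6B3 block whose Arabidopsis counterpart has been lost."""
    vv = vv_layout or grape_layout()
    ath = ath_layout or arabidopsis_layout()
    blocks = []
    for i, (gv, ga) in enumerate(ORTHOLOG_PAIRS, 1):
        blocks.append(SyntenyBlock(
            f"X{i}", _rank_side(vv, gv), _rank_side(ath, ga)))
    blocks.append(SyntenyBlock(
        "X7", _rank_side(vv, "VvALDH2B4"),
        _span_side(ath, "AthALDH2B4", "AthALDH2B7")))
    blocks.append(SyntenyBlock(
        "X8", _rank_side(vv, "VvALDH2B9"),
        _span_side(ath, "AthALDH2B4", "AthALDH2B7"), orientation="inverted"))
    blocks.append(SyntenyBlock(
        "X9", _rank_side(vv, "VvALDH18B3"),
        _span_side(ath, "AthALDH18A1", "AthALDH18A2")))
    blocks.append(SyntenyBlock(
        "X10", _rank_side(vv, "VvALDH18B1"),
        _span_side(ath, "AthALDH18A1", "AthALDH18A2")))
    # VvALDH6B3 sits in a syntenic region with no Arabidopsis family-6
    # member: a background-only interval on the Arabidopsis side.
    blocks.append(SyntenyBlock(
        "X11", _rank_side(vv, "VvALDH6B3"),
        BlockSide(ath.genome, "athP", 1, 1)))
    return blocks
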
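"""Synthetic genomes and expression experiments with planted truth.

The generator emulates the statistical structure each downstream stage
assumes: protein families with controlled within/between-family
identity, gene models whose CDS splits into GT..AG-bounded introns,
chromosome layouts with planted tandem arrays, and two-condition
expression matrices with planted log2 fold changes and detection calls.
Every draw flows from one seeded generator, so a seed fully determines
the output, byte for byte.

Identity control uses uniform random substitutions at sampled positions
(no indels), which keeps realized identity analytically controllable:
mutating a fraction ``1-t`` of positions yields identity ~``t`` to the
seed sequence. ``within_family_identity`` and ``between_family_identity``
are therefore targets for *pairwise* identity among generated members:
members are mutated from a family founder at identity sqrt(w), making
member-member identity ~w; founders descend from a common ancestor at
sqrt(b), making cross-family identity ~w*b (comfortably below the
family threshold whenever b is).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import ParameterError
from .expression import ExpressionMatrix
from .records import AMINO_ACIDS, ProteinRecord, write_fasta, write_fasta_nt
from .structure import GeneModel, write_gff3
from .synteny import BlockSide, GenomeLayout, LayoutEntry, SyntenyBlock


@dataclass(frozen=True)
class ExpressionSpec:
    n_genes: int = 2000
    n_planted: int = 200
    log2fc: float = 2.0
    sigma: float = 1.0
    n_per_group: int = 3
    absent_fraction: float = 0.1
    probes_per_gene: int = 1

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.n_planted > self.n_genes:
            raise ParameterError("n_planted exceeds n_genes")
        if self.n_per_group < 2:
            raise ParameterError("need at least 2 arrays per group")
        if not 0 <= self.absent_fraction < 1:
            raise ParameterError("absent_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TandemArraySpec:
    family: int        # 1-based planted family index
    size: int
    intervening: int   # background loci between successive members


@dataclass(frozen=True)
class SyntheticSpec:
    n_families: int = 5
    members_per_family: int = 3
    within_family_identity: float = 0.7
    between_family_identity: float = 0.3
    seq_len: int = 400
    seed: int = 0
    tandem_arrays: tuple[TandemArraySpec, ...] = ()
    n_genes_background: int | None = None  # None: sized to fit the layout
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    exon_count_range: tuple[int, int] = (3, 9)
    intron_length_range: tuple[int, int] = (30, 90)

    def __post_init__(self):
        if not (0.4 < self.within_family_identity <= 1.0):
            raise ParameterError(
                "within_family_identity must exceed the 0.40 family threshold")
        if not (0.0 <= self.between_family_identity < 0.4):
            raise ParameterError(
                "between_family_identity must stay below the 0.40 family threshold")
        if self.seq_len < 50:
            raise ParameterError("seq_len must be at least 50")
        if self.n_families < 1 or self.members_per_family < 1:
            raise ParameterError("need at least one family and one member")
        for arr in self.tandem_arrays:
            if arr.family < 1 or arr.family > self.n_families:
                raise ParameterError(f"tandem array references family {arr.family}")
            if arr.size > self.members_per_family:
                raise ParameterError(
                    f"tandem array of size {arr.size} exceeds family size "
                    f"{self.members_per_family}")
            if arr.size < 2 or arr.intervening < 0:
                raise ParameterError("tandem array needs size >= 2, intervening >= 0")
        if self.intron_length_range[0] < 4:
            raise ParameterError("introns must fit their boundary dinucleotides")


# ---------------------------------------------------------------------------
# Sequence-level helpers

def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_to_identity(seed_seq: str, target: float, rng_seed: int) -> str:
    """Substitution-mutated copy at a target global identity.

    Positions are sampled without replacement and replaced by a uniform
    different residue; realized alignment identity lands within ~±0.05
    of the target. ``target=1`` returns the sequence itself; ``target=0``
    rewrites every position over a residue alphabet disjoint from the
    seed's (a parameter error if the seed already uses all 20 residues).
    """
    if not 0 <= target <= 1:
        raise ParameterError("target identity must be in [0, 1]")
    if len(seed_seq) < 50:
        raise ParameterError("seed sequence shorter than 50 residues")
    if target == 1.0:
        return seed_seq
    rng = np.random.default_rng(rng_seed)
    if target == 0.0:
        unused = sorted(set(AMINO_ACIDS) - set(seed_seq))
        if not unused:
            raise ParameterError(
                "identity 0 unreachable: the seed uses all 20 residues")
        return "".join(rng.choice(unused, size=len(seed_seq)))
    L = len(seed_seq)
    k = round((1.0 - target) * L)
    positions = rng.choice(L, size=k, replace=False)
    out = list(seed_seq)
    for pos in positions:
        choices = [aa for aa in AMINO_ACIDS if aa != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_STANDARD.stop_codons)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """A CDS (with stop codon) translating to the given protein."""
    codons = [_AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in protein]
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def random_cds(length_bp: int, rng: np.random.Generator) -> str:
    """ATG-initiated CDS of the requested length: no internal stop, one
    terminal stop codon."""
    if length_bp % 3 != 0 or length_bp < 6:
        raise ParameterError("CDS length must be a positive multiple of 3 (>= 6)")
    n_aa = length_bp // 3 - 2
    body = random_protein(n_aa, rng).replace("M", "L")  # keep a single unambiguous start
    return "ATG" + reverse_translate(body, rng)


_NT = list("ACGT")


def _random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_NT, size=length))


def plant_gene(
    gene_id: str,
    cds: str,
    rng: np.random.Generator,
    n_exons: int,
    intron_length_range: tuple[int, int] = (30, 90),
    chromosome: str = "chr1",
    flank_range: tuple[int, int] = (50, 150),
) -> tuple[GeneModel, str]:
    """Split a CDS into exons with canonical GT..AG introns.

    Returns the gene model (coordinates on the returned genomic
    sequence) and the genomic sequence itself.
    """
    L = len(cds)
    if n_exons < 1 or L < 3 * n_exons:
        raise ParameterError(f"cannot split {L} bp into {n_exons} exons of >= 3 bp")
    while True:
        cuts = sorted(rng.choice(np.arange(3, L - 2), size=n_exons - 1, replace=False)) \
            if n_exons > 1 else []
        if all(b - a >= 3 for a, b in zip([0] + list(cuts), list(cuts) + [L])):
            break
    pieces = []
    prev = 0
    for c in list(cuts) + [L]:
        pieces.append(cds[prev:c])
        prev = c
    lo, hi = intron_length_range
    introns = [
        "GT" + _random_nt(int(rng.integers(lo, hi + 1)) - 4, rng) + "AG"
        for _ in range(n_exons - 1)
    ]
    flank5 = _random_nt(int(rng.integers(*flank_range)), rng)
    flank3 = _random_nt(int(rng.integers(*flank_range)), rng)
    genomic = [flank5]
    exons = []
    pos = len(flank5)
    for i, piece in enumerate(pieces):
        exons.append((pos + 1, pos + len(piece)))
        genomic.append(piece)
        pos += len(piece)
        if i < len(introns):
            genomic.append(introns[i])
            pos += len(introns[i])
    genomic.append(flank3)
    model = GeneModel(gene_id, chromosome, "+", exons)
    return model, "".join(genomic)


# ---------------------------------------------------------------------------
# Whole-genome generator

@dataclass
class SyntheticGenome:
    spec: SyntheticSpec
    layout: GenomeLayout
    proteins: list[ProteinRecord]
    cds: dict[str, str]
    genomic: dict[str, str]
    gene_models: dict[str, GeneModel]
    truth_families: dict[str, int]           # gene id -> planted family index
    tandem_truth: list[list[str]]            # planted arrays (gene ids in order)

    def truth_partition(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for gid, fam in self.truth_families.items():
            out.setdefault(fam, set()).add(gid)
        return {f: frozenset(s) for f, s in out.items()}

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.faa")
        write_fasta_nt(self.cds, outdir / "cds.fna")
        write_fasta_nt(self.genomic, outdir / "genomic.fna")
        write_gff3([self.gene_models[g] for g in sorted(self.gene_models)],
                   outdir / "models.gff3")
        self.layout.to_tsv(outdir / "layout.tsv")
        truth = {
            "families": self.truth_families,
            "tandem_arrays": self.tandem_truth,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def make_genome_layout(spec: SyntheticSpec) -> SyntheticGenome:
    """Families, gene models and a chromosome layout with planted truth.

    Non-array genes are separated by at least two background loci, so
    the only tandem clusters under the at-most-one-intervening rule are
    the planted arrays.
    """
    rng = np.random.default_rng(spec.seed)
    w, b = spec.within_family_identity, spec.between_family_identity
    # Proteins start with a fixed methionine (never mutated) so every CDS
    # is ATG-initiated and translates back to its protein exactly.
    ancestor = "M" + random_protein(spec.seq_len - 1, rng)

    def mutate_body(seq: str, target: float) -> str:
        L = len(seq)
        k = min(round((1.0 - target) * L), L - 1)
        positions = rng.choice(np.arange(1, L), size=k, replace=False)
        out = list(seq)
        for pos in positions:
            choices = [aa for aa in AMINO_ACIDS if aa != out[pos]]
            out[pos] = choices[rng.integers(len(choices))]
        return "".join(out)

    founders = []
    for _ in range(spec.n_families):
        if b > 0:
            founders.append(mutate_body(ancestor, math.sqrt(b)))
        else:
            founders.append("M" + random_protein(spec.seq_len - 1, rng))

    proteins: list[ProteinRecord] = []
    truth: dict[str, int] = {}
    member_ids: dict[int, list[str]] = {}
    for f in range(1, spec.n_families + 1):
        member_ids[f] = []
        for k in range(1, spec.members_per_family + 1):
            gid = f"FAM{f}_M{k}"
            seq = mutate_body(founders[f - 1], math.sqrt(w))
            proteins.append(ProteinRecord(gid, seq))
            truth[gid] = f
            member_ids[f].append(gid)

    cds = {p.id: reverse_translate(p.seq, rng) for p in proteins}
    gene_models: dict[str, GeneModel] = {}
    genomic: dict[str, str] = {}
    lo, hi = spec.exon_count_range
    for p in proteins:
        n_exons = int(rng.integers(lo, hi + 1))
        model, gseq = plant_gene(p.id, cds[p.id], rng, n_exons,
                                 spec.intron_length_range,
                                 chromosome=f"{p.id}_region")
        gene_models[p.id] = model
        genomic[p.id] = gseq

    # Chromosome layout: planted arrays as blocks, everything else single,
    # with >= 2 background loci between units.
    used: set[str] = set()
    units: list[tuple[list[str], list[int]]] = []
    tandem_truth: list[list[str]] = []
    for arr in spec.tandem_arrays:
        genes = [g for g in member_ids[arr.family] if g not in used][:arr.size]
        if len(genes) < arr.size:
            raise ParameterError(
                f"family {arr.family} has too few unused members for its array")
        used.update(genes)
        units.append((genes, [arr.intervening] * (arr.size - 1)))
        tandem_truth.append(genes)
    for p in proteins:
        if p.id not in used:
            units.append(([p.id], []))
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    inter_unit = [int(rng.integers(2, 5)) for _ in range(max(len(units) - 1, 0))]
    required = sum(sum(gaps) for _, gaps in units) + sum(inter_unit)
    budget = spec.n_genes_background if spec.n_genes_background is not None \
        else required + 10
    if budget < required:
        raise ParameterError(
            f"n_genes_background={spec.n_genes_background} cannot fill the layout "
            f"(needs >= {required})")
    extra = budget - required

    entries: list[LayoutEntry] = []
    rank = 0
    bg = 0

    def add_background(n: int):
        nonlocal rank, bg
        for _ in range(n):
            rank += 1
            bg += 1
            entries.append(LayoutEntry(rank, f"BG{bg:05d}", None))

    def add_gene(gid: str):
        nonlocal rank
        rank += 1
        entries.append(LayoutEntry(rank, f"LOC{rank:05d}_{gid}", gid))

    for u, (genes, gaps) in enumerate(units):
        add_gene(genes[0])
        for g, gap in zip(genes[1:], gaps):
            add_background(gap)
            add_gene(g)
        if u < len(units) - 1:
            add_background(inter_unit[u])
    add_background(extra)
    layout = GenomeLayout("synthetic", {"chr1": entries})
    return SyntheticGenome(spec, layout, proteins, cds, genomic, gene_models,
                           truth, tandem_truth)


def plant_synteny_blocks(
    genome: SyntheticGenome,
    n_pairs: int,
    rng_seed: int = 0,
    pad: int = 1,
) -> tuple[list[SyntenyBlock], list[tuple[str, str]]]:
    """Blocks pairing the first two members of ``n_pairs`` families.

    Returns the blocks plus the planted (gene_a, gene_b) anchor pairs.
    """
    fams = sorted(genome.truth_partition())[:n_pairs]
    if len(fams) < n_pairs:
        raise ParameterError("not enough families to plant that many block pairs")
    layout = genome.layout
    n = len(layout.chromosomes["chr1"])
    blocks, pairs = [], []
    for i, fam in enumerate(fams, 1):
        members = sorted(genome.truth_partition()[fam])[:2]
        if len(members) < 2:
            raise ParameterError(f"family {fam} has a single member; cannot pair")
        ga, gb = members
        (_, ra), (_, rb) = layout.position_of(ga), layout.position_of(gb)
        blocks.append(SyntenyBlock(
            f"SB{i}",
            BlockSide(layout.genome, "chr1", max(1, ra - pad), min(n, ra + pad)),
            BlockSide(layout.genome, "chr1", max(1, rb - pad), min(n, rb + pad))))
        pairs.append((ga, gb))
    return blocks, pairs


# ---------------------------------------------------------------------------
# Expression generator

def make_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-condition expression matrix with planted effects.

    Non-planted probes have zero true log2 fold change; planted probes
    are shifted by ``log2fc`` in the treatment group; noise is i.i.d.
    Gaussian with scale ``sigma``. A fraction of probes (disjoint from
    the planted set, so planted truth stays recoverable) is flagged
    absent on every array; scattered marginal/absent calls elsewhere do
    not trigger the all-absent filter. Returns the matrix and the
    planted-truth table.
    """
    es = spec.expression
    rng = np.random.default_rng(spec.seed)
    n = es.n_genes
    probes = [f"PS{i + 1:05d}" for i in range(n)]
    genes = [f"G{i // es.probes_per_gene + 1:05d}" for i in range(n)]
    arrays = [f"ctrl_{i + 1}" for i in range(es.n_per_group)] + \
             [f"trt_{i + 1}" for i in range(es.n_per_group)]
    conditions = ["control"] * es.n_per_group + ["treatment"] * es.n_per_group

    n_absent = int(round(es.absent_fraction * n))
    if es.n_planted + n_absent > n:
        raise ParameterError("planted and absent probe sets cannot both fit")
    perm = rng.permutation(n)
    planted_idx = np.sort(perm[:es.n_planted])
    absent_idx = np.sort(perm[es.n_planted:es.n_planted + n_absent])

    baseline = rng.normal(8.0, 1.5, size=n)
    values = baseline[:, None] + rng.normal(0.0, es.sigma, size=(n, 2 * es.n_per_group))
    values[planted_idx, es.n_per_group:] += es.log2fc

    calls = np.full((n, 2 * es.n_per_group), "P", dtype="U1")
    noise_calls = rng.random(size=calls.shape)
    calls[noise_calls < 0.02] = "A"
    calls[(noise_calls >= 0.02) & (noise_calls < 0.04)] = "M"
    calls[:, 0][(calls[:, 0] == "A") | (calls[:, 0] == "M")] = "P"  # keep probes informative
    calls[absent_idx, :] = "A"

    vdf = pd.DataFrame(values, index=probes, columns=arrays)
    cdf = pd.DataFrame(calls, index=probes, columns=arrays)
    design = pd.Series(conditions, index=arrays, name="condition")
    probe_gene = pd.Series(genes, index=probes, name="gene_id")
    matrix = ExpressionMatrix(vdf, cdf, design, probe_gene)

    truth = pd.DataFrame({
        "probe_id": probes,
        "gene_id": genes,
        "true_lfc": [es.log2fc if i in set(planted_idx) else 0.0 for i in range(n)],
        "planted": [i in set(planted_idx) for i in range(n)],
        "absent": [i in set(absent_idx) for i in range(n)],
    }).set_index("probe_id")
    return matrix, truth
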
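"""Exon-intron structures, splice variants and ORF translation.

A :class:`GeneModel` is an ordered list of coding exons in genomic
coordinates (1-based inclusive). Structures are determined by spliced
alignment of a CDS onto its genomic sequence: introns are free-length
gaps of at least a minimum length, with a score bonus for the canonical
GT...AG boundary dinucleotides. Exons of minus-strand models are stored
in transcription order. CDS coordinates include the stop codon.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import InputError, SplicedAlignmentError
from .records import NUCLEOTIDES


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]]

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if not (0 < s <= e):
                raise InputError(f"{self.gene_id}: bad exon ({s},{e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise InputError(f"{self.gene_id}: overlapping exons")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if self.exons != expect:
            raise InputError(f"{self.gene_id}: exons not in transcription order")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    def introns(self) -> list[tuple[int, int]]:
        """Introns in transcription order, genomic coordinates (start<end)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out

    def cds_length(self) -> int:
        return sum(self.exon_lengths())


# ---------------------------------------------------------------------------
# Spliced alignment (CDS -> genome)

def structure_from_alignment(
    cds: str,
    genomic: str,
    gene_id: str = "query",
    chromosome: str = "genomic",
    strand: Literal["+", "-"] = "+",
    min_intron: int = 20,
    match: float = 1.0,
    mismatch: float = -3.0,
    intron_open: float = -6.0,
    splice_bonus: float = 2.0,
) -> GeneModel:
    """Infer exon coordinates by spliced alignment of a CDS.

    Dynamic programming over (cds position, genomic position): exon bases
    align column by column; an intron is a genomic gap of length
    >= ``min_intron`` costing ``intron_open``, refunded ``splice_bonus``
    at each canonical boundary (GT donor, AG acceptor). Genomic flanks
    are free. Raises :class:`SplicedAlignmentError` when the concatenated
    best-scoring exons do not reproduce the CDS.
    """
    cds = cds.upper()
    genomic = genomic.upper()
    for name, s in (("cds", cds), ("genomic", genomic)):
        bad = set(s) - set(NUCLEOTIDES)
        if bad:
            raise InputError(f"{name}: non-nucleotide characters {sorted(bad)}")
    n, m = len(cds), len(genomic)
    if n == 0 or m < n:
        raise SplicedAlignmentError("genomic sequence shorter than CDS")

    g = np.frombuffer(genomic.encode(), dtype="S1")
    c = np.frombuffer(cds.encode(), dtype="S1")

    # Donor bonus for an intron starting right after genomic position j
    # (1-based): first two intron bases are genomic[j], genomic[j+1] 0-based.
    donor = np.zeros(m + 1, dtype=np.float32)
    donor[1:m - 1] = np.where((g[1:m - 1] == b"G") & (g[2:m] == b"T"),
                              splice_bonus, 0.0)
    # Acceptor bonus for an exon resuming at genomic position j (1-based):
    # last two intron bases are genomic[j-3], genomic[j-2] 0-based.
    acceptor = np.zeros(m + 1, dtype=np.float32)
    jj = np.arange(3, m + 1)
    acceptor[3:] = np.where((g[jj - 3] == b"A") & (g[jj - 2] == b"G"),
                            splice_bonus, 0.0)

    NEG = np.float32(-1e9)
    D = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    choice = np.zeros((n + 1, m + 1), dtype=np.int8)      # 0=diag, 1=intron
    donor_at = np.zeros((n + 1, m + 1), dtype=np.int32)   # donor pos for intron moves

    sub = np.where(g[None, :] == c[:, None], match, mismatch).astype(np.float32)

    D[1, 1:] = sub[0, :]  # free 5' genomic flank
    for i in range(2, n + 1):
        prev = D[i - 1]
        diag = prev[:-1]  # prev[j-1] for j=1..m
        # Running max over donors j' <= j - 1 - min_intron of prev[j'] + donor[j'].
        cand = prev + donor
        runmax = np.maximum.accumulate(cand)
        # argmax of the running maximum (first index achieving it)
        improving = np.r_[True, cand[1:] > runmax[:-1]]
        idx = np.where(improving, np.arange(m + 1), 0)
        runarg = np.maximum.accumulate(idx)
        intron_scores = np.full(m + 1, NEG, dtype=np.float32)
        lo = min_intron + 1  # smallest j with a legal donor j' = j-1-min_intron >= 0
        js = np.arange(lo + 1, m + 1)
        if js.size:
            shifted = js - 1 - min_intron
            intron_scores[js] = runmax[shifted] + np.float32(intron_open) + acceptor[js]
            donor_at[i, js] = runarg[shifted]
        base = np.maximum(diag, intron_scores[1:])
        D[i, 1:] = base + sub[i - 1, :]
        choice[i, 1:] = np.where(intron_scores[1:] > diag, 1, 0)

    j_end = int(np.argmax(D[n, 1:])) + 1
    if D[n, j_end] <= NEG / 2:
        raise SplicedAlignmentError("no spliced alignment found")

    # Traceback.
    exon_ends: list[int] = []
    exon_starts: list[int] = []
    i, j = n, j_end
    cur_end = j
    while i > 1:
        if choice[i, j] == 1:
            jp = int(donor_at[i, j])
            exon_starts.append(j)
            exon_ends.append(cur_end)
            cur_end = jp
            j = jp
        else:
            j -= 1
        i -= 1
    exon_starts.append(j)
    exon_ends.append(cur_end)
    exons = sorted(zip(exon_starts, exon_ends))
    rebuilt = "".join(genomic[s - 1:e] for s, e in exons)
    if rebuilt != cds:
        raise SplicedAlignmentError(
            "CDS is not derivable from the genomic sequence under the "
            "spliced-alignment model"
        )
    tx_order = exons if strand == "+" else exons[::-1]
    return GeneModel(gene_id, chromosome, strand, [tuple(x) for x in tx_order])


# ---------------------------------------------------------------------------
# Structure comparison

@dataclass
class StructurePair:
    gene_a: str
    gene_b: str
    exon_count_equal: bool
    exon_length_flags: list[bool]
    differences: list[str]


def _diff_terminal(len_a: list[int], len_b: list[int]) -> list[str]:
    """Name lost/gained terminal exons when counts differ by one."""
    diffs = []
    if len(len_b) == len(len_a) - 1:
        if len_b == len_a[1:]:
            diffs.append("first exon lost")
        elif len_b == len_a[:-1]:
            diffs.append("last exon lost")
        else:
            diffs.append("one internal exon lost")
    elif len(len_b) == len(len_a) + 1:
        if len_b[1:] == len_a:
            diffs.append("one additional exon in 5'-end")
        elif len_b[:-1] == len_a:
            diffs.append("one additional exon in 3'-end")
        else:
            diffs.append("one additional internal exon")
    else:
        diffs.append(f"exon count differs ({len(len_a)} vs {len(len_b)})")
    return diffs


def compare_structures(models: Sequence[GeneModel]) -> list[StructurePair]:
    """Pairwise exon-count and exon-length comparison of gene models.

    Lengths are compared in transcription order, so models from opposite
    strands are comparable. Terminal gains/losses of single exons are
    named explicitly (families often keep internal structure while
    terminal exons drift).
    """
    if len(models) < 2:
        raise InputError("need at least two gene models to compare")
    report = []
    for ia in range(len(models)):
        for ib in range(ia + 1, len(models)):
            a, b = models[ia], models[ib]
            la, lb = a.exon_lengths(), b.exon_lengths()
            if len(la) == len(lb):
                flags = [x == y for x, y in zip(la, lb)]
                diffs = [] if all(flags) else [
                    f"exon {i + 1} length differs" for i, ok in enumerate(flags) if not ok
                ]
            else:
                k = min(len(la), len(lb))
                flags = [x == y for x, y in zip(la[:k], lb[:k])]
                diffs = _diff_terminal(la, lb)
            report.append(StructurePair(a.gene_id, b.gene_id,
                                        len(la) == len(lb), flags, diffs))
    return report


# ---------------------------------------------------------------------------
# Splice events

EventKind = Literal["intron_retention", "alt_3prime_acceptor",
                    "alt_5prime_donor", "exon_skip"]


@dataclass
class SpliceEvent:
    kind: EventKind
    location: int            # affected intron/exon index, transcription order
    length_delta: int        # bp gained (+) or lost (-) by the variant

    def __post_init__(self):
        if self.kind != "exon_skip" and self.length_delta == 0:
            raise InputError(f"{self.kind} with zero length delta")


def detect_splice_events(variant: GeneModel, reference: GeneModel) -> list[SpliceEvent]:
    """Minimal event list explaining the variant's coordinate differences.

    Events are reported against the reference model: retained introns,
    alternative donor/acceptor boundaries and skipped exons. Donor and
    acceptor are transcriptional (5' and 3' ends of the intron), so the
    genomic sides swap on the minus strand.
    """
    if variant.chromosome != reference.chromosome:
        raise InputError("variant and reference are on different chromosomes")
    if variant.strand != reference.strand:
        raise InputError("variant and reference are on different strands")
    strand = reference.strand
    ref_introns = reference.introns()
    var_introns = variant.introns()
    var_set = set(var_introns)
    events: list[SpliceEvent] = []
    consumed: set[int] = set()

    def donor_acceptor(intron: tuple[int, int]) -> tuple[int, int]:
        s, e = intron
        return (s, e) if strand == "+" else (e, s)

    for idx, r in enumerate(ref_introns):
        if idx in consumed or r in var_set:
            continue
        r_len = r[1] - r[0] + 1
        # Retention: a variant exon fully spans the reference intron.
        retained = any(s <= r[0] - 1 and e >= r[1] + 1 for s, e in variant.exons)
        if retained:
            events.append(SpliceEvent("intron_retention", idx + 1, r_len))
            continue
        # Exon skip: the variant has one intron spanning this intron, the
        # following reference exon and the next reference intron.
        if idx + 1 < len(ref_introns):
            nxt = ref_introns[idx + 1]
            lo = min(r[0], nxt[0])
            hi = max(r[1], nxt[1])
            if (lo, hi) in var_set:
                skipped = reference.exons[idx + 1]
                events.append(SpliceEvent(
                    "exon_skip", idx + 2, -(skipped[1] - skipped[0] + 1)))
                consumed.add(idx + 1)
                continue
        r_donor, r_acc = donor_acceptor(r)
        matched = False
        for v in var_introns:
            v_donor, v_acc = donor_acceptor(v)
            if v_donor == r_donor and v_acc != r_acc:
                v_len = v[1] - v[0] + 1
                events.append(SpliceEvent(
                    "alt_3prime_acceptor", idx + 2, r_len - v_len))
                matched = True
                break
            if v_acc == r_acc and v_donor != r_donor:
                v_len = v[1] - v[0] + 1
                events.append(SpliceEvent(
                    "alt_5prime_donor", idx + 1, r_len - v_len))
                matched = True
                break
        if not matched:
            events.append(SpliceEvent("intron_retention", idx + 1, r_len))
    return events


# ---------------------------------------------------------------------------
# ORF finding and translation

@dataclass
class OrfResult:
    found: bool
    start: int = 0   # 1-based, inclusive; interval includes the stop codon
    end: int = 0
    protein: str = ""

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


STOPS = ("TAA", "TAG", "TGA")


def find_orf_and_translate(transcript: str, min_length_aa: int = 50) -> OrfResult:
    """Longest ATG-initiated, stop-terminated ORF and its translation.

    The longest-ORF policy (rather than first ATG) reflects transcripts
    in which a frameshifting retained intron moves the usable start codon
    downstream. Returns a not-found result (no exception) when no ORF
    reaches ``min_length_aa``.
    """
    t = transcript.upper()
    bad = set(t) - set(NUCLEOTIDES)
    if bad:
        raise InputError(f"transcript has non-nucleotide characters {sorted(bad)}")
    best: tuple[int, int] | None = None  # (aa_len, -start) ties -> leftmost
    best_coords = (0, 0)
    for frame in range(3):
        stops = [i for i in range(frame, len(t) - 2, 3) if t[i:i + 3] in STOPS]
        starts = [i for i in range(frame, len(t) - 2, 3) if t[i:i + 3] == "ATG"]
        for s in starts:
            k = bisect.bisect_right(stops, s)
            if k == len(stops):
                continue
            stop = stops[k]
            aa_len = (stop - s) // 3
            key = (aa_len, -s)
            if best is None or key > best:
                best = key
                best_coords = (s + 1, stop + 3)
    if best is None or best[0] < min_length_aa:
        return OrfResult(False)
    s1, e1 = best_coords
    protein = str(Seq(t[s1 - 1:e1 - 3]).translate())
    return OrfResult(True, s1, e1, protein)


# ---------------------------------------------------------------------------
# GFF3 I/O (feature types gene/mRNA/CDS; 1-based inclusive coordinates)

def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            genomic = sorted(gm.exons)
            lo, hi = genomic[0][0], genomic[-1][1]
            gid = gm.gene_id
            fh.write(f"{gm.chromosome}\taldhkit\tgene\t{lo}\t{hi}\t.\t{gm.strand}\t.\tID={gid}\n")
            fh.write(f"{gm.chromosome}\taldhkit\tmRNA\t{lo}\t{hi}\t.\t{gm.strand}\t.\tID={gid}.t1;Parent={gid}\n")
            for s, e in genomic:
                fh.write(f"{gm.chromosome}\taldhkit\tCDS\t{s}\t{e}\t.\t{gm.strand}\t.\tParent={gid}.t1\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise InputError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes[attr["ID"]] = {"chromosome": chrom, "strand": strand, "exons": []}
            elif ftype == "mRNA":
                mrna_to_gene[attr["ID"]] = attr["Parent"]
            elif ftype == "CDS":
                gid = mrna_to_gene.get(attr["Parent"], attr["Parent"])
                genes[gid]["exons"].append((int(start), int(end)))
    out = []
    for gid, info in genes.items():
        exons = sorted(info["exons"])
        if info["strand"] == "-":
            exons = exons[::-1]
        out.append(GeneModel(gid, info["chromosome"], info["strand"], exons))
    return out
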
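"""AGNC-style family and subfamily assignment.

The nomenclature convention of the ALDH Gene Nomenclature Committee puts
two thresholds on pairwise global protein identity: a sequence more than
40% identical to a previously named member belongs to that member's
family, more than 60% identical to its subfamily, and a sequence not
exceeding 40% identity to any named member founds a new family.

This module provides the pairwise alignment engine behind the rule
(:func:`global_align`, :func:`percent_identity`), single-query
classification against a labelled panel (:func:`classify`) and a
whole-proteome census (:func:`census`) that also names mutually novel
queries by single-linkage grouping.
"""

from __future__ import annotations

import hashlib
import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError
from .records import AMINO_ACIDS, ProteinRecord

FAMILY_THRESHOLD = 0.40
SUBFAMILY_THRESHOLD = 0.60

GAP = "-"

IdentityDenominator = Literal["aligned_columns", "shorter"]


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring for global protein alignment.

    The first residue of a gap costs ``gap_open``, each further residue
    ``gap_extend`` (score units of the substitution matrix). End gaps are
    penalized (true global alignment).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def metadata(self) -> dict:
        return {
            "substitution_matrix": self.matrix,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
        }


DEFAULT_SCORING = Scoring()


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    aligner.mode = "global"
    return aligner


@dataclass
class AlignmentResult:
    """A pairwise global alignment: gapped sequences, score and identity."""

    a: str
    b: str
    score: float
    identity: float
    aligned_columns: int

    def degapped(self) -> tuple[str, str]:
        return self.a.replace(GAP, ""), self.b.replace(GAP, "")


def _validate_protein(seq: str, which: str) -> None:
    if not seq:
        raise InputError(f"{which} sequence is empty")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise InputError(f"{which} sequence has non-amino-acid characters {sorted(bad)}")


def global_align(
    a: str,
    b: str,
    scoring: Scoring = DEFAULT_SCORING,
    denominator: IdentityDenominator = "aligned_columns",
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Among co-optimal alignments the engine's first reported alignment is
    taken, which is deterministic for a given Biopython version.
    """
    _validate_protein(a, "first")
    _validate_protein(b, "second")
    aligner = _make_aligner(scoring)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    result = AlignmentResult(a=ga, b=gb, score=float(aln.score), identity=0.0,
                             aligned_columns=len(ga))
    result.identity = percent_identity(result, denominator=denominator)
    return result


def _core_columns(a: str, b: str) -> tuple[int, int]:
    """Column range [i, j) excluding terminal gap columns.

    A terminal gap column is one belonging to a leading or trailing gap
    run of either sequence.
    """
    n = len(a)
    start = 0
    for s in (a, b):
        k = 0
        while k < n and s[k] == GAP:
            k += 1
        start = max(start, k)
    end = n
    for s in (a, b):
        k = n
        while k > 0 and s[k - 1] == GAP:
            k -= 1
        end = min(end, k)
    return start, max(start, end)


def percent_identity(
    aln: AlignmentResult,
    denominator: IdentityDenominator = "aligned_columns",
) -> float:
    """Fraction of identical columns in a pairwise alignment.

    ``aligned_columns`` divides matches by the number of alignment columns
    excluding terminal gap columns (robust to length differences);
    ``shorter`` divides by the length of the shorter ungapped sequence.
    Symmetric in the two sequences.
    """
    a, b = aln.a, aln.b
    if len(a) != len(b):
        raise InputError("gapped sequences differ in length")
    ua, ub = aln.degapped()
    if not ua and not ub:
        raise InputError("both sequences are empty: identity undefined")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    if denominator == "aligned_columns":
        start, end = _core_columns(a, b)
        denom = end - start
        matches = sum(
            1 for x, y in zip(a[start:end], b[start:end]) if x == y and x != GAP
        )
    elif denominator == "shorter":
        denom = min(len(ua), len(ub))
    else:  # pragma: no cover - guarded by Literal type
        raise InputError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise InputError("zero denominator: no comparable columns")
    return matches / denom


def pairwise_identity(
    a: str,
    b: str,
    scoring: Scoring = DEFAULT_SCORING,
    denominator: IdentityDenominator = "aligned_columns",
) -> float:
    return global_align(a, b, scoring=scoring, denominator=denominator).identity


@dataclass(frozen=True)
class PanelMember:
    """A previously named sequence carrying family/subfamily labels."""

    id: str
    family: int
    subfamily: str
    member_no: int
    seq: str


@dataclass
class FamilyAssignment:
    gene_id: str
    family: int
    subfamily: str
    member_no: int
    is_new_family: bool
    is_new_subfamily: bool
    best_hit: tuple[str, float] | None

    @property
    def name(self) -> str:
        return f"ALDH{self.family}{self.subfamily}{self.member_no}"


def _digest(seq: str) -> str:
    return hashlib.sha1(seq.encode()).hexdigest()


def _subfamily_letters():
    for ch in string.ascii_uppercase:
        yield ch
    for ch1 in string.ascii_uppercase:
        for ch2 in string.ascii_uppercase:
            yield ch1 + ch2


def _next_subfamily(used: set[str]) -> str:
    for letter in _subfamily_letters():
        if letter not in used:
            return letter
    raise InputError("subfamily letters exhausted")


def classify(
    query: ProteinRecord,
    panel: Sequence[PanelMember],
    family_threshold: float = FAMILY_THRESHOLD,
    subfamily_threshold: float = SUBFAMILY_THRESHOLD,
    scoring: Scoring = DEFAULT_SCORING,
    denominator: IdentityDenominator = "aligned_columns",
) -> FamilyAssignment:
    """Assign family/subfamily to one query against a labelled panel.

    Thresholds are strict: identity must exceed ``family_threshold``
    (default 40%) to join a family and ``subfamily_threshold`` (60%) to
    join a subfamily. A query at exactly the family threshold to every
    panel member founds a new family.
    """
    if not panel:
        warnings.warn("empty panel: query founds family 1", stacklevel=2)
        return FamilyAssignment(query.id, 1, "A", 1, True, True, None)
    best: PanelMember | None = None
    best_ident = -1.0
    for member in sorted(panel, key=lambda m: m.id):
        ident = pairwise_identity(query.seq, member.seq, scoring, denominator)
        if ident > best_ident:
            best, best_ident = member, ident
    assert best is not None
    families = {m.family for m in panel}
    if best_ident > subfamily_threshold:
        member_nos = [
            m.member_no for m in panel
            if m.family == best.family and m.subfamily == best.subfamily
        ]
        return FamilyAssignment(
            query.id, best.family, best.subfamily, max(member_nos) + 1,
            False, False, (best.id, best_ident),
        )
    if best_ident > family_threshold:
        used = {m.subfamily for m in panel if m.family == best.family}
        return FamilyAssignment(
            query.id, best.family, _next_subfamily(used), 1,
            False, True, (best.id, best_ident),
        )
    return FamilyAssignment(
        query.id, max(families) + 1, "A", 1, True, True, (best.id, best_ident),
    )


def _single_linkage(ids: list[str], linked) -> list[list[str]]:
    """Connected components under a symmetric predicate, via union-find."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if linked(a, b):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


@dataclass
class CensusResult:
    assignments: dict[str, FamilyAssignment]
    family_counts: dict[int, int]
    metadata: dict = field(default_factory=dict)

    def partition(self) -> dict[int, frozenset[str]]:
        """Family number -> set of member gene ids."""
        out: dict[int, set[str]] = {}
        for a in self.assignments.values():
            out.setdefault(a.family, set()).add(a.gene_id)
        return {f: frozenset(s) for f, s in out.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": a.gene_id,
                "family": a.family,
                "subfamily": a.subfamily,
                "member_no": a.member_no,
                "name": a.name,
                "is_new_family": a.is_new_family,
                "is_new_subfamily": a.is_new_subfamily,
                "best_hit": a.best_hit[0] if a.best_hit else "",
                "best_identity": a.best_hit[1] if a.best_hit else float("nan"),
            }
            for a in self.assignments.values()
        ]
        return pd.DataFrame(rows).sort_values(["family", "subfamily", "member_no"]).reset_index(drop=True)


def census(
    queries: Sequence[ProteinRecord],
    panel: Sequence[PanelMember] = (),
    family_threshold: float = FAMILY_THRESHOLD,
    subfamily_threshold: float = SUBFAMILY_THRESHOLD,
    scoring: Scoring = DEFAULT_SCORING,
    denominator: IdentityDenominator = "aligned_columns",
) -> CensusResult:
    """Name every query and count family members.

    Queries anchored to the panel (best identity strictly above the family
    threshold) inherit the panel family; mutually novel queries are
    grouped by single linkage at the family threshold and numbered after
    the highest existing family. Within a family, subfamily membership
    uses the 60% threshold with single linkage among new-subfamily
    queries. Naming is canonicalized by sorting queries on a sequence
    digest, so family membership sets are independent of input order.
    """
    ids = [q.id for q in queries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate gene ids: {dupes}")
    if not queries:
        return CensusResult({}, {}, metadata={"n_queries": 0})

    order = sorted(queries, key=lambda q: (_digest(q.seq), q.id))
    seqs = {q.id: q.seq for q in queries}

    ident_cache: dict[tuple[str, str], float] = {}

    def ident(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in ident_cache:
            ident_cache[key] = pairwise_identity(seqs[x], seqs[y], scoring, denominator)
        return ident_cache[key]

    # Best panel hit per query.
    best_hits: dict[str, tuple[PanelMember, float] | None] = {}
    for q in order:
        best, best_ident = None, -1.0
        for member in sorted(panel, key=lambda m: m.id):
            pid = pairwise_identity(q.seq, member.seq, scoring, denominator)
            if pid > best_ident:
                best, best_ident = member, pid
        best_hits[q.id] = (best, best_ident) if best is not None else None

    anchored = [q for q in order
                if best_hits[q.id] and best_hits[q.id][1] > family_threshold]
    novel = [q for q in order if q not in anchored]

    family_of: dict[str, int] = {}
    for q in anchored:
        family_of[q.id] = best_hits[q.id][0].family

    # Single-linkage grouping of mutually novel queries at the family
    # threshold; new family numbers follow the highest existing one.
    next_family = max((m.family for m in panel), default=0)
    novel_ids = [q.id for q in novel]
    components = _single_linkage(
        novel_ids, lambda a, b: ident(a, b) > family_threshold
    )
    components.sort(key=lambda grp: min(_digest(seqs[g]) for g in grp))
    new_families = set()
    for comp in components:
        next_family += 1
        new_families.add(next_family)
        for gid in comp:
            family_of[gid] = next_family

    # Subfamily and member numbering, family by family.
    assignments: dict[str, FamilyAssignment] = {}
    for fam in sorted(set(family_of.values())):
        fam_queries = [q for q in order if family_of[q.id] == fam]
        fam_panel = [m for m in panel if m.family == fam]
        used_letters = {m.subfamily for m in fam_panel}
        member_no_ceiling: dict[str, int] = {}
        for m in fam_panel:
            member_no_ceiling[m.subfamily] = max(
                member_no_ceiling.get(m.subfamily, 0), m.member_no
            )
        # Queries whose best same-family panel identity clears the
        # subfamily threshold inherit that subfamily.
        inherited: dict[str, str] = {}
        rest = []
        for q in fam_queries:
            best, best_ident = None, -1.0
            for m in sorted(fam_panel, key=lambda m: m.id):
                pid = pairwise_identity(q.seq, m.seq, scoring, denominator)
                if pid > best_ident:
                    best, best_ident = m, pid
            if best is not None and best_ident > subfamily_threshold:
                inherited[q.id] = best.subfamily
            else:
                rest.append(q)
        subfam_of: dict[str, str] = dict(inherited)
        # Chain remaining queries onto inherited subfamilies or each other.
        groups = _single_linkage(
            [q.id for q in rest], lambda a, b: ident(a, b) > subfamily_threshold
        )
        groups.sort(key=lambda grp: min(_digest(seqs[g]) for g in grp))
        for grp in groups:
            # A group may still clear the subfamily threshold to an
            # inherited query (not a panel member): single linkage applies.
            attached = None
            for gid in grp:
                for other, letter in inherited.items():
                    if ident(gid, other) > subfamily_threshold:
                        attached = letter
                        break
                if attached:
                    break
            if attached is None:
                attached = _next_subfamily(used_letters)
                used_letters.add(attached)
            for gid in grp:
                subfam_of[gid] = attached
        for q in fam_queries:
            letter = subfam_of[q.id]
            no = member_no_ceiling.get(letter, 0) + 1
            member_no_ceiling[letter] = no
            hit = best_hits[q.id]
            assignments[q.id] = FamilyAssignment(
                q.id, fam, letter, no,
                is_new_family=fam in new_families,
                is_new_subfamily=letter not in {m.subfamily for m in fam_panel},
                best_hit=(hit[0].id, hit[1]) if hit else None,
            )

    counts: dict[int, int] = {}
    for a in assignments.values():
        counts[a.family] = counts.get(a.family, 0) + 1
    meta = {
        "n_queries": len(queries),
        "family_threshold": family_threshold,
        "subfamily_threshold": subfamily_threshold,
        "identity_denominator": denominator,
        **scoring.metadata(),
    }
    return CensusResult(assignments, counts, metadata=meta)


def read_panel_labels(fasta_records: Iterable[ProteinRecord], labels_tsv: str | Path) -> list[PanelMember]:
    """Combine a panel FASTA with a label TSV (id, family, subfamily, member_no)."""
    df = pd.read_csv(labels_tsv, sep="\t", dtype={"id": str, "subfamily": str})
    seqs = {r.id: r.seq for r in fasta_records}
    members = []
    for row in df.itertuples(index=False):
        if row.id not in seqs:
            raise InputError(f"panel label {row.id!r} has no sequence")
        members.append(PanelMember(row.id, int(row.family), row.subfamily,
                                   int(row.member_no), seqs[row.id]))
    return members
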
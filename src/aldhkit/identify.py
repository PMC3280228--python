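"""Candidate search by motif scan and identity search.

Candidate family members are flagged in a proteome through two evidence
channels, combined with OR semantics: a match to at least one
PROSITE-syntax pattern, or a best global-alignment identity to a curated
query panel at or above a floor (default 40%). Pattern content is
configuration, never hard-coded.

PROSITE grammar supported: elements joined by ``-``; ``x`` (any
residue), single letters (exact), ``[ABC]`` (one of), ``{ABC}`` (none
of), repeats ``(n)`` / ``(n,m)``, and terminal anchors ``<`` / ``>``.
A trailing ``.`` is tolerated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from .classify import DEFAULT_SCORING, IdentityDenominator, Scoring, pairwise_identity
from .errors import PatternSyntaxError
from .records import AMINO_ACIDS, ProteinRecord

ElementKind = Literal["exact", "any", "one-of", "none-of"]


@dataclass(frozen=True)
class PatternElement:
    kind: ElementKind
    residues: frozenset[str]
    min_rep: int = 1
    max_rep: int = 1

    def admits(self, ch: str) -> bool:
        if self.kind == "any":
            return True
        if self.kind == "none-of":
            return ch not in self.residues
        return ch in self.residues


@dataclass(frozen=True)
class PrositePattern:
    raw: str
    elements: tuple[PatternElement, ...]
    n_anchored: bool = False
    c_anchored: bool = False
    pattern_id: str = ""

    def to_raw(self) -> str:
        parts = []
        for el in self.elements:
            if el.kind == "any":
                core = "x"
            elif el.kind == "exact":
                core = next(iter(el.residues))
            elif el.kind == "one-of":
                core = "[" + "".join(sorted(el.residues)) + "]"
            else:
                core = "{" + "".join(sorted(el.residues)) + "}"
            if (el.min_rep, el.max_rep) != (1, 1):
                if el.min_rep == el.max_rep:
                    core += f"({el.min_rep})"
                else:
                    core += f"({el.min_rep},{el.max_rep})"
            parts.append(core)
        body = "-".join(parts)
        return ("<" if self.n_anchored else "") + body + (">" if self.c_anchored else "")


_REPEAT_RE = re.compile(r"\((\d+)(?:,(\d+))?\)$")


def parse_pattern(raw: str, pattern_id: str = "") -> PrositePattern:
    """Parse a PROSITE pattern string into a structured element list."""
    text = raw.strip()
    if text.endswith("."):
        text = text[:-1]
    if not text:
        raise PatternSyntaxError("empty pattern")
    n_anchor = text.startswith("<")
    if n_anchor:
        text = text[1:]
    c_anchor = text.endswith(">")
    if c_anchor:
        text = text[:-1]
    if not text:
        raise PatternSyntaxError("pattern has anchors but no elements")
    elements: list[PatternElement] = []
    pos = 0
    for token in text.split("-"):
        if not token:
            raise PatternSyntaxError("empty element", pos)
        rep = (1, 1)
        m = _REPEAT_RE.search(token)
        if m:
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            if lo > hi:
                raise PatternSyntaxError(f"repeat min {lo} > max {hi}", pos)
            rep = (lo, hi)
            token = token[:m.start()]
        if token == "x":
            el = PatternElement("any", frozenset(), *rep)
        elif len(token) == 1 and token in AMINO_ACIDS:
            el = PatternElement("exact", frozenset(token), *rep)
        elif token.startswith("[") and token.endswith("]"):
            body = token[1:-1]
            if not body or set(body) - set(AMINO_ACIDS):
                raise PatternSyntaxError(f"bad residue class {token!r}", pos)
            el = PatternElement("one-of", frozenset(body), *rep)
        elif token.startswith("{") and token.endswith("}"):
            body = token[1:-1]
            if not body or set(body) - set(AMINO_ACIDS):
                raise PatternSyntaxError(f"bad exclusion class {token!r}", pos)
            el = PatternElement("none-of", frozenset(body), *rep)
        else:
            raise PatternSyntaxError(f"unknown token {token!r}", pos)
        elements.append(el)
        pos += len(token) + 1
    return PrositePattern(raw.strip(), tuple(elements), n_anchor, c_anchor, pattern_id)


def scan_sequence(pattern: PrositePattern, seq: str) -> list[tuple[int, int]]:
    """All leftmost-anchored matches as 1-based inclusive intervals.

    Matches may overlap; variable-length repeats can yield several
    intervals sharing a start. Implemented as a set-propagation matcher
    (no regular-expression backend), linear in sequence length per start
    position.
    """
    n = len(seq)
    matches: list[tuple[int, int]] = []
    starts = [0] if pattern.n_anchored else range(n)
    for s in starts:
        reachable = {s}
        for el in pattern.elements:
            nxt: set[int] = set()
            for p in reachable:
                if el.min_rep == 0:
                    nxt.add(p)
                q = p
                for k in range(1, el.max_rep + 1):
                    if q >= n or not el.admits(seq[q]):
                        break
                    q += 1
                    if k >= el.min_rep:
                        nxt.add(q)
            reachable = nxt
            if not reachable:
                break
        for e in sorted(reachable):
            if e > s and (not pattern.c_anchored or e == n):
                matches.append((s + 1, e))
    return sorted(matches)


def read_patterns(path: str | Path) -> list[PrositePattern]:
    """Read a pattern config: one ``id<TAB>pattern`` per line, # comments."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, _, raw = line.partition("\t")
            if not raw:
                raise PatternSyntaxError(f"config line lacks a pattern: {line!r}")
            patterns.append(parse_pattern(raw, pattern_id=pid))
    return patterns


@dataclass
class CandidateHit:
    gene_id: str
    motif_matches: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    best_panel_hit: tuple[str, float] | None = None
    passed: bool = False
    evidence_mode: str = "OR"


def find_candidates(
    proteome: Sequence[ProteinRecord],
    panel: Sequence[ProteinRecord] = (),
    patterns: Sequence[PrositePattern] = (),
    identity_floor: float = 0.4,
    scoring: Scoring = DEFAULT_SCORING,
    denominator: IdentityDenominator = "aligned_columns",
) -> list[CandidateHit]:
    """Flag proteome members matching a pattern or the identity panel.

    A protein passes if it matches at least one pattern OR its best
    panel identity reaches ``identity_floor`` (evidence channels are
    OR-combined; the combination rule is recorded on each hit). The
    result covers every proteome entry, passed or not, with the evidence
    gathered for both channels.
    """
    hits = []
    for rec in proteome:
        hit = CandidateHit(rec.id)
        for pat in patterns:
            intervals = scan_sequence(pat, rec.seq)
            if intervals:
                hit.motif_matches[pat.pattern_id or pat.raw] = intervals
        best_id, best_ident = None, -1.0
        for member in sorted(panel, key=lambda r: r.id):
            ident = pairwise_identity(rec.seq, member.seq, scoring, denominator)
            if ident > best_ident:
                best_id, best_ident = member.id, ident
        if best_id is not None:
            hit.best_panel_hit = (best_id, best_ident)
        hit.passed = bool(hit.motif_matches) or (
            hit.best_panel_hit is not None and hit.best_panel_hit[1] >= identity_floor
        )
        hits.append(hit)
    return hits
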
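"""Genome-wide enumeration of putative L1 endonuclease nick sites.

The L1 endonuclease nicks the bottom strand of its degenerate consensus
5'-TTTT/A-3'.  A putative site is any 4-mer with at most one non-T base (and
no N) immediately followed, 3' on the same strand, by a purine.  With the
primer context written 5'->3' the five site classes are therefore snap
TTTT (perfect) or VTTT, TVTT, TTVT, TTTV (one degenerate position, numbered
from the 3' end of the primer) with a downstream R.

Both strands are scanned.  Every site carries a *nick* coordinate: the
0-based plus-strand boundary between the snap 4-mer and the downstream
purine.  For a plus-strand site the primer occupies ``[nick-10, nick)`` and
the purine sits at ``nick``; for a minus-strand site the primer occupies
``[nick, nick+10)`` on the plus strand (read reverse-complemented) and the
purine sits at ``nick - 1``.  Under reverse complementation of the whole
contig a boundary ``b`` maps to ``L - b``, which makes strand duality exact.

Sites whose nick has fewer than 10 primer-strand bases upstream are emitted
with ``status=None`` and excluded from category counts.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO

from Bio import SeqIO

from .scoring import (
    CONTEXT_LENGTH,
    SNAP_LENGTH,
    Category,
    SnapVelcroStatus,
    categorize,
)

__all__ = [
    "Pattern",
    "ENSite",
    "CategoryTable",
    "reverse_complement",
    "find_en_sites",
    "classify_snap_pattern",
    "extract_primer_context",
    "scan_fasta",
    "read_fasta",
    "write_bed",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PURINES = frozenset("AG")
_DEGENERATE = frozenset("ACG")  # V: not T, not N

#: Degenerate pattern names indexed by the position of the single non-T base
#: counted from the 3' end of the primer (1 = 3'-terminal snap base).
PATTERNS = ("perfect", "deg_pos1", "deg_pos2", "deg_pos3", "deg_pos4")


class Pattern:
    """String constants for the five endonuclease site classes."""

    PERFECT = "perfect"
    DEG_POS1 = "deg_pos1"
    DEG_POS2 = "deg_pos2"
    DEG_POS3 = "deg_pos3"
    DEG_POS4 = "deg_pos4"


@dataclass(frozen=True)
class ENSite:
    """One putative endonuclease nick site on a genome contig."""

    contig: str
    nick: int
    strand: str  # '+' or '-'
    pattern: str  # one of PATTERNS
    context10: Optional[str]  # primer-strand 5'->3', None near contig edges
    status: Optional[SnapVelcroStatus]


@dataclass
class CategoryTable:
    """Counts and frequencies over the four snap x velcro categories."""

    counts: dict[Category, int] = field(
        default_factory=lambda: {c: 0 for c in Category}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[Category, float]:
        total = self.total
        if total == 0:
            return {c: 0.0 for c in Category}
        return {c: n / total for c, n in self.counts.items()}

    def add(self, category: Category, n: int = 1) -> None:
        self.counts[category] += n

    @classmethod
    def from_sites(cls, sites: Iterable[ENSite]) -> "CategoryTable":
        table = cls()
        for site in sites:
            if site.status is not None:
                table.add(site.status.category)
        return table

    @classmethod
    def from_counts(cls, counts: dict) -> "CategoryTable":
        table = cls()
        for key, n in counts.items():
            table.add(Category(key), int(n))
        return table

    def to_dict(self) -> dict:
        return {
            "counts": {c.value: n for c, n in self.counts.items()},
            "total": self.total,
            "frequencies": {c.value: f for c, f in self.frequencies.items()},
        }

    def write_tsv(self, handle: TextIO) -> None:
        handle.write("category\tcount\tfrequency\n")
        freqs = self.frequencies
        for c in Category:
            handle.write(f"{c.value}\t{self.counts[c]}\t{freqs[c]:.6g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CategoryTable":
        table = cls()
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                table.add(Category(parts[idx["category"]]), int(parts[idx["count"]]))
        return table


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over {A, C, G, T, N}."""
    seq = sequence.upper()
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"invalid DNA characters: {sorted(invalid)}")
    return seq.translate(_COMPLEMENT)[::-1]


def classify_snap_pattern(snap: str) -> Optional[str]:
    """Pattern class of a 4-base snap window, or None if not a site.

    The window is primer-strand 5'->3'; a site has at most one non-T base,
    which must be A, C or G (N disqualifies the window).
    """
    if len(snap) != SNAP_LENGTH:
        raise ValueError(f"snap window must have length {SNAP_LENGTH}")
    non_t = [i for i, base in enumerate(snap) if base != "T"]
    if not non_t:
        return Pattern.PERFECT
    if len(non_t) > 1 or snap[non_t[0]] not in _DEGENERATE:
        return None
    # position counted from the 3' end of the primer: window index 3 -> 1
    return PATTERNS[SNAP_LENGTH - non_t[0]]


def _scan_one_strand(seq: str, contig: str, strand: str, length: int) -> Iterator[ENSite]:
    """Yield sites on one strand; `seq` is the strand's own 5'->3' sequence."""
    for j in range(SNAP_LENGTH, len(seq)):
        if seq[j] not in _PURINES:
            continue
        pattern = classify_snap_pattern(seq[j - SNAP_LENGTH : j])
        if pattern is None:
            continue
        # plus-strand boundary coordinate of the nick
        nick = j if strand == "+" else length - j
        if j >= CONTEXT_LENGTH:
            context = seq[j - CONTEXT_LENGTH : j]
            status = categorize(context) if "N" not in context else None
        else:
            context, status = None, None
        yield ENSite(
            contig=contig,
            nick=nick,
            strand=strand,
            pattern=pattern,
            context10=context,
            status=status,
        )


def find_en_sites(
    sequence: str, contig: str = "seq", masked_lowercase: bool = False
) -> list[ENSite]:
    """All putative endonuclease sites on both strands of a sequence.

    With ``masked_lowercase=True``, soft-masked (lowercase) bases are treated
    as N and never match T, V or R — this emulates a repeat-masked scan
    without running an external masker.
    """
    if masked_lowercase:
        seq = "".join("N" if b.islower() else b for b in sequence).upper()
    else:
        seq = sequence.upper()
    if not seq:
        return []
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"invalid DNA characters: {sorted(invalid)}")
    length = len(seq)
    sites = list(_scan_one_strand(seq, contig, "+", length))
    sites.extend(_scan_one_strand(reverse_complement(seq), contig, "-", length))
    sites.sort(key=lambda s: (s.nick, s.strand, s.pattern))
    return sites


def extract_primer_context(
    genome: dict[str, str], contig: str, nick: int, strand: str
) -> str:
    """The 10 primer-strand bases 5' of a nick, 5'->3'.

    ``genome`` maps contig names to plus-strand sequences; ``nick`` is the
    boundary coordinate described in the module docstring.
    """
    if contig not in genome:
        raise KeyError(f"unknown contig {contig!r}")
    seq = genome[contig].upper()
    if strand == "+":
        if nick < CONTEXT_LENGTH or nick > len(seq):
            raise ValueError(
                f"nick {nick} on {contig}:+ lacks {CONTEXT_LENGTH} upstream bases"
            )
        return seq[nick - CONTEXT_LENGTH : nick]
    if strand == "-":
        if nick < 0 or nick + CONTEXT_LENGTH > len(seq):
            raise ValueError(
                f"nick {nick} on {contig}:- lacks {CONTEXT_LENGTH} upstream bases"
            )
        return reverse_complement(seq[nick : nick + CONTEXT_LENGTH])
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into a contig -> sequence dict."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    genome: dict[str, str] = {}
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in genome:
                raise ValueError(f"duplicate contig name {record.id!r} in {path}")
            genome[record.id] = str(record.seq)
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def scan_fasta(
    path: str | Path,
    masked_lowercase: bool = False,
) -> tuple[list[ENSite], CategoryTable]:
    """Scan every contig of a FASTA file and tabulate site categories.

    Returns the full site list (sorted per contig by nick coordinate) and a
    CategoryTable over the sites with a defined status; sites too close to a
    contig edge for a 10-base context are counted and logged but excluded
    from the table.
    """
    genome = read_fasta(path)
    sites: list[ENSite] = []
    table = CategoryTable()
    n_edge = 0
    for contig, seq in genome.items():
        for site in find_en_sites(seq, contig, masked_lowercase=masked_lowercase):
            sites.append(site)
            if site.status is None:
                n_edge += 1
            else:
                table.add(site.status.category)
    if n_edge:
        logger.info("%d sites lacked a full 10-base context and were not counted", n_edge)
    return sites, table


def write_bed(sites: Iterable[ENSite], handle: TextIO) -> None:
    """Write sites as BED6: the interval covers the 3'-terminal snap base.

    Score column is velcro density x 1000 (0 for sites without status).
    """
    handle.write(
        "# nick is the 0-based plus-strand boundary between snap and purine;\n"
        "# the BED interval covers the 3'-terminal primer base\n"
    )
    for s in sites:
        start = s.nick - 1 if s.strand == "+" else s.nick
        score = round(s.status.velcro_density * 1000) if s.status else 0
        name = f"{s.pattern}:{s.status.category.value if s.status else 'NA'}"
        handle.write(f"{s.contig}\t{start}\t{start + 1}\t{name}\t{score}\t{s.strand}\n")
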
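"""Category enrichment of observed L1 insertion sites against a genome scan.

Observed insertion datasets (polymorphic or somatic L1 insertions with
nucleotide-resolution breakpoints) are first reduced to the 10 primer-strand
bases upstream of each nick, filtered to those with a recognizable
endonuclease site (snap with at most one non-T base), and categorized by
snap/velcro status.  Their category frequencies are then compared with the
frequencies of all putative sites in a reference genome scan:

* ``enrichment[c]``           = dataset frequency / reference frequency
* ``normalized_frequency[c]`` = enrichment[c] / enrichment[baseline]

with baseline category ``open_loose`` by default, so the weakest class reads
exactly 1 and the other bars express how many-fold insertions favour a
closed snap and/or a fastened velcro.  The overall distribution shift is
tested with a chi-square goodness-of-fit of observed counts against expected
counts derived from the reference frequencies (df = categories - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from scipy import stats

from .en_scan import (
    CategoryTable,
    classify_snap_pattern,
    extract_primer_context,
)
from .scoring import CONTEXT_LENGTH, SNAP_LENGTH, Category, SnapVelcroStatus, categorize

__all__ = [
    "InsertionRecord",
    "EnrichmentResult",
    "load_insertions",
    "filter_recognizable",
    "categorize_insertions",
    "enrichment_table",
    "chi_square_gof",
]

logger = logging.getLogger(__name__)


@dataclass
class InsertionRecord:
    """One observed L1 insertion site."""

    id: str
    contig: Optional[str] = None
    nick: Optional[int] = None
    strand: Optional[str] = None
    context10: Optional[str] = None
    downstream_base: Optional[str] = None
    pattern: Optional[str] = None
    status: Optional[SnapVelcroStatus] = None


@dataclass
class EnrichmentResult:
    """Per-category enrichment of a dataset against a reference scan."""

    dataset: CategoryTable
    reference: CategoryTable
    baseline: Category
    enrichment: dict[Category, float]
    normalized_frequency: dict[Category, float]
    chi2: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.value,
            "enrichment": {c.value: v for c, v in self.enrichment.items()},
            "normalized_frequency": {
                c.value: v for c, v in self.normalized_frequency.items()
            },
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "dataset": self.dataset.to_dict(),
            "reference": self.reference.to_dict(),
        }


def _parse_insertion_line(
    fields: Sequence[str], columns: dict[str, int], lineno: int
) -> InsertionRecord:
    def get(name: str) -> Optional[str]:
        i = columns.get(name)
        if i is None or i >= len(fields):
            return None
        return fields[i]

    if "junction" in columns:
        junction = get("junction")
        if junction is None or len(junction) < CONTEXT_LENGTH:
            raise ValueError(
                f"line {lineno}: junction sequence shorter than {CONTEXT_LENGTH} nt"
            )
        return InsertionRecord(
            id=get("id") or f"ins{lineno}",
            context10=junction.upper()[-CONTEXT_LENGTH:],
        )
    try:
        contig = fields[columns["contig"]]
        nick = int(fields[columns["nick"]])
        strand = fields[columns["strand"]]
    except (KeyError, IndexError, ValueError) as exc:
        raise ValueError(f"line {lineno}: malformed insertion record: {exc}") from exc
    if strand not in "+-":
        raise ValueError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
    return InsertionRecord(
        id=get("id") or f"ins{lineno}", contig=contig, nick=nick, strand=strand
    )


def load_insertions(
    path: str | Path,
    genome: Optional[dict[str, str]] = None,
    dedup: bool = False,
) -> list[InsertionRecord]:
    """Read an insertion dataset from TSV/BED and populate primer contexts.

    Two layouts are understood:

    * coordinate records — a headered TSV with columns ``contig``, ``nick``,
      ``strand`` (nick = 0-based boundary coordinate), or a headerless
      BED6 file (chrom, start, end, name, score, strand) as written by the
      scanner, where the interval covers the 3'-terminal primer base;
      requires ``genome`` to extract contexts;
    * junction records — a headered TSV with a ``junction`` column holding
      pre-extracted primer-strand sequences of >= 10 nt (last 10 used).

    Duplicate coordinates are kept unless ``dedup=True``.
    """
    path = Path(path)
    records: list[InsertionRecord] = []
    with open(path) as handle:
        lines = [
            (i + 1, line.rstrip("\n"))
            for i, line in enumerate(handle)
            if line.strip() and not line.startswith("#")
        ]
    if not lines:
        return []
    header_fields = lines[0][1].split("\t")
    lowered = [f.strip().lower() for f in header_fields]
    if "junction" in lowered or {"contig", "nick", "strand"} <= set(lowered):
        columns = {name: i for i, name in enumerate(lowered)}
        body = lines[1:]
        for lineno, line in body:
            records.append(_parse_insertion_line(line.split("\t"), columns, lineno))
    else:
        # headerless BED6: interval covers the last primer base
        for lineno, line in lines:
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: BED record needs 6 columns")
            try:
                start = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad BED coordinate: {exc}") from exc
            strand = fields[5]
            if strand not in "+-":
                raise ValueError(f"line {lineno}: bad BED strand {strand!r}")
            nick = start + 1 if strand == "+" else start
            records.append(
                InsertionRecord(
                    id=fields[3] if fields[3] != "." else f"ins{lineno}",
                    contig=fields[0],
                    nick=nick,
                    strand=strand,
                )
            )
    if genome is not None:
        for rec in records:
            if rec.context10 is None:
                if rec.contig not in genome:
                    raise ValueError(f"insertion {rec.id}: unknown contig {rec.contig!r}")
                rec.context10 = extract_primer_context(
                    genome, rec.contig, rec.nick, rec.strand
                )
                rec.downstream_base = _downstream_base(genome, rec)
    missing = [r.id for r in records if r.context10 is None]
    if missing:
        raise ValueError(
            "coordinate records need a genome to extract contexts "
            f"(first missing: {missing[0]})"
        )
    if dedup:
        seen: set[tuple] = set()
        unique = []
        for rec in records:
            key = (rec.contig, rec.nick, rec.strand, rec.context10)
            if key not in seen:
                seen.add(key)
                unique.append(rec)
        if len(unique) < len(records):
            logger.info("dedup removed %d duplicate records", len(records) - len(unique))
        records = unique
    return records


def _downstream_base(genome: dict[str, str], rec: InsertionRecord) -> Optional[str]:
    seq = genome[rec.contig].upper()
    if rec.strand == "+":
        return seq[rec.nick] if rec.nick < len(seq) else None
    pos = rec.nick - 1
    if pos < 0:
        return None
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[seq[pos]]


def filter_recognizable(
    records: Sequence[InsertionRecord],
) -> tuple[list[InsertionRecord], list[InsertionRecord]]:
    """Split records into (kept, dropped) by endonuclease-site recognizability.

    Kept records have a snap (last 4 context bases) with at most one non-T
    base, i.e. one of the five site patterns.  The downstream-purine
    condition is enforced only when the downstream base is known (records
    extracted from a genome), not for bare 10-nt junction sequences.
    Kept records get their ``pattern`` and ``status`` populated.
    """
    kept: list[InsertionRecord] = []
    dropped: list[InsertionRecord] = []
    for rec in records:
        if rec.context10 is None:
            dropped.append(rec)
            continue
        context = rec.context10.upper()
        snap = context[-SNAP_LENGTH:]
        pattern = classify_snap_pattern(snap) if "N" not in snap else None
        purine_ok = rec.downstream_base is None or rec.downstream_base in "AG"
        if pattern is None or not purine_ok or "N" in context:
            dropped.append(rec)
            continue
        rec.pattern = pattern
        rec.status = categorize(context)
        kept.append(rec)
    if dropped:
        logger.info(
            "%d of %d insertions lacked a recognizable EN site and were dropped",
            len(dropped),
            len(records),
        )
    return kept, dropped


def categorize_insertions(records: Sequence[InsertionRecord]) -> CategoryTable:
    """CategoryTable over already-filtered insertion records."""
    table = CategoryTable()
    for rec in records:
        if rec.status is None:
            raise ValueError(f"insertion {rec.id} has no status; filter first")
        table.add(rec.status.category)
    return table


def chi_square_gof(
    observed: dict[Category, int] | Sequence[int],
    expected_frequencies: dict[Category, float] | Sequence[float],
) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit of observed counts to expected frequencies.

    chi2 = sum (O_c - N f_c)^2 / (N f_c) with N = total observed count;
    df = number of categories - 1; p from the upper tail.
    """
    if isinstance(observed, dict):
        observed = [observed[c] for c in Category]
    if isinstance(expected_frequencies, dict):
        expected_frequencies = [expected_frequencies[c] for c in Category]
    obs = [float(o) for o in observed]
    freqs = [float(f) for f in expected_frequencies]
    if len(obs) != len(freqs):
        raise ValueError("observed and expected must have the same length")
    n = sum(obs)
    if n <= 0:
        raise ValueError("observed counts sum to zero")
    if any(f <= 0 for f in freqs):
        raise ValueError("expected frequencies must all be > 0")
    total_f = sum(freqs)
    if abs(total_f - 1.0) > 1e-9:
        raise ValueError(f"expected frequencies sum to {total_f}, not 1")
    expected = [n * f for f in freqs]
    if any(e < 5 for e in expected):
        warnings.warn("expected count below 5; chi-square approximation is poor")
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return float(chi2), len(obs) - 1, float(p)


def enrichment_table(
    dataset: CategoryTable,
    reference: CategoryTable,
    baseline: Category = Category.OPEN_LOOSE,
) -> EnrichmentResult:
    """Enrichment and baseline-normalized frequencies of a dataset vs a reference.

    ``baseline`` defaults to the open-snap/loose-velcro category so its
    normalized frequency is exactly 1.
    """
    if dataset.total <= 0:
        raise ValueError("dataset has no categorized sites")
    ref_freq = reference.frequencies
    if any(ref_freq[c] <= 0 for c in Category):
        raise ValueError("reference frequencies must all be > 0")
    data_freq = dataset.frequencies
    enrichment = {c: data_freq[c] / ref_freq[c] for c in Category}
    base = enrichment[baseline]
    if base <= 0:
        raise ValueError(f"baseline category {baseline.value} has zero enrichment")
    normalized = {c: enrichment[c] / base for c in Category}
    chi2, df, p = chi_square_gof(dataset.counts, ref_freq)
    return EnrichmentResult(
        dataset=dataset,
        reference=reference,
        baseline=baseline,
        enrichment=enrichment,
        normalized_frequency=normalized,
        chi2=chi2,
        df=df,
        p=p,
    )
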
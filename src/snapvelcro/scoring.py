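"""Position-weighted T-density scoring and snap/velcro classification.

L1 target-primed reverse transcription starts when the 3'-OH released by the
endonuclease nick anneals to the poly(A) tail of the L1 RNA.  The ability of a
genomic 3' end to prime reverse transcription is therefore governed by how
T-rich it is, with bases close to the 3' terminus mattering most.  This module
scores primer 3' ends accordingly:

* **T-density** — the plain fraction of Ts in the sequence.
* **Position-weighted T-count** — each T at distance *i* from the 3' end
  (3'-terminal base: *i* = 1) contributes weight 1/*i*; an all-T 20-mer scores
  the harmonic number H20 ≈ 3.60.
* **Position-weighted T-density** — the count divided by its all-T maximum
  over the same window, hence always in [0, 1].

The snap/velcro classification splits the terminal 10 bases into the *snap*
(last 4 bases; **closed** iff they are TTTT, the endonuclease consensus) and
the *velcro* (the 6 bases upstream, positions 5-10 from the 3' end;
**fastened** iff their position-weighted T-density is >= 0.5).  The cross of
the two states gives four categories, from ``closed_fastened`` (best primer)
to ``open_loose`` (worst).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "PrimerRecord",
    "Snap",
    "Velcro",
    "Category",
    "SnapVelcroStatus",
    "SNAP_LENGTH",
    "VELCRO_LENGTH",
    "CONTEXT_LENGTH",
    "VELCRO_THRESHOLD",
    "normalize_sequence",
    "t_density",
    "position_weighted_t_count",
    "position_weighted_t_density",
    "velcro_max_count",
    "snap_state",
    "velcro_density",
    "velcro_state",
    "categorize",
    "read_panel",
    "write_panel",
]

#: Number of 3'-terminal bases forming the snap (endonuclease consensus TTTT).
SNAP_LENGTH = 4
#: Number of bases upstream of the snap forming the velcro strap.
VELCRO_LENGTH = 6
#: Total primer context used for classification.
CONTEXT_LENGTH = SNAP_LENGTH + VELCRO_LENGTH
#: A velcro is fastened when its position-weighted T-density reaches this.
VELCRO_THRESHOLD = 0.5

_VALID = set("ACGTN")


class Snap(str, enum.Enum):
    """State of the 4 terminal bases: closed means a perfect TTTT match."""

    CLOSED = "closed"
    OPEN = "open"


class Velcro(str, enum.Enum):
    """State of the upstream hexamer: fastened means density >= 0.5."""

    FASTENED = "fastened"
    LOOSE = "loose"


class Category(str, enum.Enum):
    """Snap x velcro cross-classification of a primer 3' end."""

    CLOSED_FASTENED = "closed_fastened"
    CLOSED_LOOSE = "closed_loose"
    OPEN_FASTENED = "open_fastened"
    OPEN_LOOSE = "open_loose"

    @staticmethod
    def from_states(snap: Snap, velcro: Velcro) -> "Category":
        return Category(f"{snap.value}_{velcro.value}")


@dataclass
class PrimerRecord:
    """A named DNA oligonucleotide, written 5'->3'.

    Parameters
    ----------
    name : str
        Identifier of the primer.
    sequence : str
        DNA sequence over {A, C, G, T}; lowercase and U are normalized.
    activity : float, optional
        Relative extension activity, percent of the reference oligo(dT)
        primer (values above 100 are legal).
    excluded : bool
        True for primers excluded from correlation analyses (e.g. primers
        able to fold into a stable hairpin).
    """

    name: str
    sequence: str
    activity: Optional[float] = None
    excluded: bool = False

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if self.activity is not None:
            self.activity = float(self.activity)
            if math.isnan(self.activity):
                self.activity = None
            elif self.activity < 0:
                raise ValueError(
                    f"primer {self.name!r}: activity must be >= 0, "
                    f"got {self.activity}"
                )


@dataclass(frozen=True)
class SnapVelcroStatus:
    """Snap and velcro states of a primer 3' end, with the velcro density."""

    snap: Snap
    velcro: Velcro
    velcro_density: float
    category: Category = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "category", Category.from_states(self.snap, self.velcro)
        )


def normalize_sequence(sequence: str, strict: bool = False) -> str:
    """Uppercase a DNA string, map U to T, and validate the alphabet.

    ``N`` is accepted and treated as a non-T base by every scoring function
    (the conservative choice); with ``strict=True`` any base outside
    {A, C, G, T} raises instead.
    """
    if not isinstance(sequence, str):
        raise TypeError("sequence must be a string")
    seq = sequence.upper()
    if "U" in seq:
        warnings.warn("U bases mapped to T", stacklevel=2)
        seq = seq.replace("U", "T")
    invalid = set(seq) - _VALID
    if invalid:
        raise ValueError(f"invalid DNA characters: {sorted(invalid)}")
    if strict and "N" in seq:
        raise ValueError("N is not allowed in strict mode")
    return seq


def _check_window(sequence: str, n: Optional[int]) -> tuple[str, int]:
    seq = normalize_sequence(sequence)
    if not seq:
        raise ValueError("empty sequence is not a valid primer")
    if n is None:
        n = len(seq)
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if n > len(seq):
        raise ValueError(f"n={n} exceeds sequence length {len(seq)}")
    return seq, n


def t_density(sequence: str) -> float:
    """Fraction of Ts in the sequence: (#T) / length."""
    seq, n = _check_window(sequence, None)
    return seq.count("T") / n


def position_weighted_t_count(sequence: str, n: Optional[int] = None) -> float:
    """Sum of 1/i over T-holding positions i = 1..n from the 3' end.

    The 3'-terminal base sits at position 1 and carries the largest weight;
    an all-T window of length n scores the harmonic number H_n (3.60 for
    n = 20, printed at 2 decimals).
    """
    seq, n = _check_window(sequence, n)
    return sum(1.0 / i for i in range(1, n + 1) if seq[len(seq) - i] == "T")


def position_weighted_t_density(sequence: str, n: Optional[int] = None) -> float:
    """Position-weighted T-count divided by its all-T maximum H_n.

    Lies in [0, 1]; 1 iff every one of the n terminal bases is T.
    """
    seq, n = _check_window(sequence, n)
    maximum = sum(1.0 / i for i in range(1, n + 1))
    return position_weighted_t_count(seq, n) / maximum


def velcro_max_count() -> float:
    """All-T maximum of the velcro count: sum of 1/i for i = 5..10.

    Computed, never hard-coded; equals 0.84563492 at 8 decimals.
    """
    return sum(1.0 / i for i in range(SNAP_LENGTH + 1, CONTEXT_LENGTH + 1))


def snap_state(sequence: str) -> Snap:
    """Closed iff the 4 3'-terminal bases are all T."""
    seq, _ = _check_window(sequence, None)
    if len(seq) < SNAP_LENGTH:
        raise ValueError(
            f"snap state needs >= {SNAP_LENGTH} bases, got {len(seq)}"
        )
    return Snap.CLOSED if seq[-SNAP_LENGTH:] == "T" * SNAP_LENGTH else Snap.OPEN


def velcro_density(sequence: str) -> float:
    """Position-weighted T-density of the velcro hexamer (positions 5-10).

    Sum of 1/i over T-holding positions i = 5..10 from the 3' end, divided
    by the all-T maximum sum(1/i, i=5..10) ~ 0.84563492.
    """
    seq, _ = _check_window(sequence, None)
    if len(seq) < CONTEXT_LENGTH:
        raise ValueError(
            f"velcro undefined for sequences shorter than {CONTEXT_LENGTH}"
        )
    count = sum(
        1.0 / i
        for i in range(SNAP_LENGTH + 1, CONTEXT_LENGTH + 1)
        if seq[len(seq) - i] == "T"
    )
    return count / velcro_max_count()


def velcro_state(sequence: str) -> Velcro:
    """Fastened iff the velcro density is >= 0.5 (inclusive)."""
    return (
        Velcro.FASTENED
        if velcro_density(sequence) >= VELCRO_THRESHOLD
        else Velcro.LOOSE
    )


def categorize(sequence: str) -> SnapVelcroStatus:
    """Snap and velcro states of the terminal 10 bases, as one status.

    Raises for sequences shorter than 10 bases rather than truncating.
    """
    dens = velcro_density(sequence)  # validates length >= 10
    snap = snap_state(sequence)
    velcro = Velcro.FASTENED if dens >= VELCRO_THRESHOLD else Velcro.LOOSE
    return SnapVelcroStatus(snap=snap, velcro=velcro, velcro_density=dens)


# ---------------------------------------------------------------------------
# Primer panel I/O


def read_panel(path: str | Path) -> list[PrimerRecord]:
    """Read a primer panel from TSV/CSV with columns name, sequence[, activity, excluded]."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = {"name", "sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} misses columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        activity = getattr(row, "activity", None)
        if activity is not None and pd.isna(activity):
            activity = None
        excluded = bool(getattr(row, "excluded", False))
        records.append(
            PrimerRecord(
                name=str(row.name),
                sequence=str(row.sequence),
                activity=activity,
                excluded=excluded,
            )
        )
    return records


def write_panel(records: Iterable[PrimerRecord], path: str | Path) -> None:
    """Write a primer panel to TSV (or CSV if the path ends in .csv)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    records = list(records)
    df = pd.DataFrame(
        {
            "name": [r.name for r in records],
            "sequence": [r.sequence for r in records],
            "activity": [r.activity for r in records],
            "excluded": [r.excluded for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)
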
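"""Synthetic genomes, insertion sets and primer panels for end-to-end testing.

Real analyses of L1 insertion preference run against a reference genome and
catalogs of polymorphic or somatic insertions; none of those can ship with a
test suite.  These generators produce inputs with *known* ground truth:

* ``simulate_genome`` — an i.i.d. background at a human-like base
  composition, overwritten with T-homopolymer tracts at Poisson-distributed
  start points with geometric lengths.  The tracts create closed-snap /
  fastened-velcro sites that a uniform background alone would make rare.
* ``simulate_insertions`` — draws insertion sites from the genome's own
  scanned site list with probability proportional to a per-category weight
  (uniform within category).  The enrichment analysis should then recover
  the weight ratios as normalized frequencies.
* ``simulate_primer_panel`` — 20-mer primers spanning the score range, with
  activity linear in the position-weighted T-density of the terminal 10
  bases plus Gaussian noise, clipped at 0.  The regression module should
  recover the slope and place the R² plateau at the generating window.

All generators are deterministic given (seed, config); each draws from its
own child stream of a single root ``numpy`` SeedSequence so adding one
generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .en_scan import ENSite, find_en_sites
from .scoring import Category, PrimerRecord, position_weighted_t_density

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_insertions",
    "simulate_primer_panel",
    "write_insertions_tsv",
]

_BASES = np.array(list("ACGT"))
# child-stream indices of the root SeedSequence, one per generator
_STREAM = {"genome": 0, "insertions": 1, "panel": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic world.

    Defaults are calibrated once so that a 100 kb genome contains at least
    50 endonuclease sites in each snap x velcro category: a human-like base
    composition (A/T 29.5%, C/G 20.5% each), 6 T-tracts per kb with
    geometric mean length 8.  Category weights follow (open_loose,
    open_fastened, closed_loose, closed_fastened) order.
    """

    seed: int = 0
    genome_length: int = 100_000
    base_composition: tuple[float, float, float, float] = (0.295, 0.205, 0.205, 0.295)
    t_tract_rate: float = 6.0  # expected tracts per kb
    t_tract_mean_length: float = 8.0  # geometric distribution mean
    category_weights: tuple[float, float, float, float] = (1.0, 2.0, 2.0, 4.0)
    n_insertions: int = 5_000
    panel_size: int = 35
    beta0: float = 10.0
    beta1: float = 90.0
    sigma: float = 10.0

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if any(p < 0 for p in self.base_composition):
            raise ValueError("base_composition probabilities must be >= 0")
        if any(w < 0 for w in self.category_weights) or not any(self.category_weights):
            raise ValueError("category_weights must be >= 0 and not all zero")

    def rng(self, stream: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAM))
        return np.random.default_rng(children[_STREAM[stream]])

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SimulationConfig":
        """Read a flat key=value config file; later overrides win."""
        values: dict = {}
        with open(path) as handle:
            for line in handle:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key = key.strip()
                raw = raw.strip()
                if key in ("base_composition", "category_weights"):
                    values[key] = tuple(float(x) for x in raw.split(","))
                elif key in ("seed", "genome_length", "n_insertions", "panel_size"):
                    values[key] = int(raw)
                else:
                    values[key] = float(raw)
        values.update(overrides)
        return cls(**values)


#: order in which category weights are given
WEIGHT_ORDER = (
    Category.OPEN_LOOSE,
    Category.OPEN_FASTENED,
    Category.CLOSED_LOOSE,
    Category.CLOSED_FASTENED,
)


def simulate_genome(config: SimulationConfig, contig: str = "synth1") -> tuple[str, str]:
    """One synthetic contig: i.i.d. background with embedded T-tracts.

    Returns ``(contig_name, sequence)``.  Tract count is Poisson with mean
    ``t_tract_rate x length / 1000``; tract lengths are geometric with the
    configured mean; tracts overwrite the background and are clipped at the
    contig end.
    """
    rng = config.rng("genome")
    length = config.genome_length
    seq = rng.choice(_BASES, size=length, p=list(config.base_composition))
    n_tracts = rng.poisson(config.t_tract_rate * length / 1000.0)
    if n_tracts:
        starts = rng.integers(0, length, size=n_tracts)
        lengths = rng.geometric(1.0 / config.t_tract_mean_length, size=n_tracts)
        for start, tract_len in zip(starts, lengths):
            seq[start : start + tract_len] = "T"
    return contig, "".join(seq)


def simulate_insertions(
    genome: str | tuple[str, str],
    config: SimulationConfig,
    sites: Optional[Sequence[ENSite]] = None,
    replace: bool = True,
) -> list[ENSite]:
    """Draw insertion sites from a genome with category-dependent weights.

    Each site's sampling probability is proportional to the weight of its
    snap x velcro category (uniform within category).  Draws are independent
    (with replacement) by default: insertion events in different individuals
    or tumours are independent and may recur at the same genomic site, and
    only independent draws make the category frequencies converge to the
    weight-tilted genome frequencies that the enrichment analysis inverts.
    ``replace=False`` gives an exhaustive-sampling variant (requires
    ``n_insertions`` not to exceed the number of positive-weight sites); its
    category frequencies are depleted whenever a small, heavily weighted
    category runs out of sites.
    """
    if isinstance(genome, tuple):
        contig, seq = genome
    else:
        contig, seq = "synth1", genome
    if sites is None:
        sites = find_en_sites(seq, contig)
    eligible = [s for s in sites if s.status is not None]
    if not eligible:
        raise ValueError("genome contains no categorizable endonuclease sites")
    weight_of = dict(zip(WEIGHT_ORDER, config.category_weights))
    weights = np.array([weight_of[s.status.category] for s in eligible], dtype=float)
    total = weights.sum()
    if total == 0:
        raise ValueError("no site falls in a category with positive weight")
    probs = weights / total
    rng = config.rng("insertions")
    if not replace and config.n_insertions > int(np.count_nonzero(weights)):
        raise ValueError(
            "cannot draw without replacement: n_insertions exceeds the "
            "number of positive-weight sites"
        )
    idx = rng.choice(len(eligible), size=config.n_insertions, replace=replace, p=probs)
    return [eligible[i] for i in idx]


def write_insertions_tsv(insertions: Sequence[ENSite], path: str | Path) -> None:
    """Write drawn insertions as a headered TSV loadable by the enrichment module."""
    with open(path, "w") as handle:
        handle.write("id\tcontig\tnick\tstrand\n")
        for i, site in enumerate(insertions):
            handle.write(f"ins{i}\t{site.contig}\t{site.nick}\t{site.strand}\n")


def simulate_primer_panel(config: SimulationConfig) -> list[PrimerRecord]:
    """A panel of 20-mer primers with activity linear in the terminal-10 score.

    The first primer is the all-T reference (the oligo(dT) analog all
    activities are expressed against).  Per-primer T probability is drawn
    uniformly so scores span [0, 1]; activity = max(0, beta0 + beta1 *
    score + N(0, sigma)).
    """
    if config.panel_size < 3:
        raise ValueError("panel_size must be >= 3")
    rng = config.rng("panel")
    panel: list[PrimerRecord] = []
    length = 20
    for i in range(config.panel_size):
        if i == 0:
            seq = "T" * length
        else:
            p_t = rng.uniform(0.05, 1.0)
            draws = rng.random(length)
            others = rng.choice(np.array(list("ACG")), size=length)
            seq = "".join(
                "T" if d < p_t else o for d, o in zip(draws, others)
            )
        score = position_weighted_t_density(seq, 10)
        noise = rng.normal(0.0, config.sigma) if config.sigma > 0 else 0.0
        activity = max(0.0, config.beta0 + config.beta1 * score + noise)
        panel.append(PrimerRecord(name=f"SYN{i:03d}", sequence=seq, activity=activity))
    return panel
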
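# Methods

## Scoring model

The score of a primer 3′ end over its last *n* bases is the sum of 1/*i*
over the T-holding distances *i* from the 3′ terminus (terminal base:
*i* = 1), optionally normalized by the all-T maximum Hₙ = Σ 1/*i*. The 1/*i*
weight is the simplest "inversely proportional to distance" choice and is
pinned down by two closed forms the analysis is calibrated against: the
all-T 20-mer count H₂₀ (prints as 3.60) and the velcro maximum
Σᵢ₌₅..₁₀ 1/*i* = 0.84563492. Both constants are computed wherever they are
needed, never hard-coded.

Classification thresholds (all exposed as module constants, immutable
defaults): snap length 4, velcro length 6, context length 10, fastened
threshold 0.5 with the boundary inclusive (density ≥ 0.5 is fastened). Full
double precision is kept internally; comparisons with printed values round
to the printed number of decimals.

Input handling: sequences are uppercased; U is mapped to T with a warning;
N and any other base that is not T scores 0 at its position (the
conservative choice — an ambiguous base is never credited as a T); a strict
mode rejects N outright. Velcro and category computations require ≥ 10
bases and raise rather than silently truncate.

## Endonuclease-site scan

A site is a 4-mer with at most one non-T base (the non-T must be A, C or G;
a window containing N is never a site) immediately followed on the same
strand by A or G. Windows with two or more non-T bases are not sites: the
five enumerated patterns are the model. Both strands are scanned; minus
strand hits are reported with their 10-base primer context read off the
reverse complement so every context is primer-strand 5′→3′.

Coordinates: the nick is the 0-based plus-strand *boundary* between the
snap and the downstream purine. A plus-strand site's primer occupies
`[nick-10, nick)` with the purine at `nick`; a minus-strand site's primer
occupies `[nick, nick+10)` (reverse-complemented) with the purine at
`nick-1`. Reverse-complementing a contig of length L maps boundary b to
L − b, so the site list of a sequence and of its reverse complement are
exact mirror images — a property the test suite checks, together with exact
agreement against a naive sliding-window re-implementation.

Sites within 10 bases of a contig edge, and sites whose 10-base context
contains an N, are reported in the site stream but excluded from category
counts (the count of such exclusions is logged). Repeat-masking is emulated
by treating lowercase (soft-masked) bases as N under a flag; no external
masker is run.

## Enrichment analysis

Insertion records are reduced to the 10 primer-strand bases upstream of the
nick. The recognizability filter keeps records whose snap holds at most one
non-T base; the downstream-purine condition is applied only when the
downstream base is actually known (coordinate records resolved against a
genome), because a bare 10-nt junction sequence does not carry it. Records
are treated as independent observations; duplicate coordinates are kept
unless deduplication is requested, since recurrent insertions at one site
in different individuals are genuine events.

Enrichment of category c is freq_dataset(c)/freq_reference(c); normalized
frequency divides by the enrichment of the baseline category. The baseline
is `open_loose` (the weakest class, so its bar reads exactly 1 and the
other classes read as fold-preference); an alternative `open_fastened`
baseline is available behind a flag. The distribution shift is tested by a
chi-square goodness-of-fit of observed counts against expected counts
N·f_reference, df = categories − 1, no continuity correction (four cells
and large N in intended use); a warning is emitted when any expected count
falls below 5.

## Activity regression and ANOVA

Activity (percent of the all-T reference primer; pre-normalized, never
rescaled here) is regressed on the chosen score of the terminal *n* bases
by ordinary least squares with an intercept (the through-origin variant is
not offered; with an all-T reference at score 1 and activity 100 the
intercept absorbs assay background). Hairpin-flagged primers are excluded,
as hairpin formation is a length artifact of the assay construct, not a
property of the target site. The R²-vs-n curve fits every window n = 1 up
to the shortest usable primer; a window whose added position is constant
across the panel changes the score only affinely and leaves R² unchanged,
and a window where the whole score is constant is recorded with R² = 0
rather than aborting the sweep. P-values are two-sided; no multiple-testing
correction is applied across the n-grid (the curve is descriptive).

The category summary reports mean, SEM and count per snap × velcro cell and
a two-way ANOVA of activity on snap, velcro and their interaction. Type II
sums of squares are used: panels are unbalanced by construction, and Type
II tests each main effect adjusted for the other without letting the
(usually weak) interaction absorb main-effect variance. The interaction
term is fitted only when all four cells are populated; a factor observed at
a single level is dropped and reported with p = NaN; a term with
numerically zero sum of squares is reported as F = 0, p = 1 instead of NaN
(degenerate, noiseless designs).

## Synthetic data

The generators provide inputs with known ground truth in place of a
reference genome and curated insertion catalogs, which cannot ship with a
test suite.

* **Genome** — i.i.d. bases at a human-like composition (A/T 29.5%, C/G
  20.5%) overwritten with T-homopolymer tracts at Poisson-distributed
  starts (6 tracts/kb) with geometric lengths (mean 8). The tracts supply
  the long T-runs that create closed-snap and fastened-velcro sites; the
  defaults were calibrated once so a 100 kb genome holds ≥ 50 sites in
  every category (measured ≥ 340 across seeds) and were not revisited. The
  generator does not mimic chromosome structure, repeat families, GC
  isochores or mappability — a green recovery test establishes that the
  *inference machinery* is correct, not that any particular real genome
  behaves like the simulation.
* **Insertions** — sites are drawn from the genome's own scanned site list
  with probability proportional to a per-category weight (default 1, 2, 2,
  4 for open_loose, open_fastened, closed_loose, closed_fastened), uniform
  within category. Draws are independent (with replacement): insertion
  events in different genomes are independent and may recur at one site,
  and only under independent draws do the drawn frequencies converge to the
  weight-tilted genome frequencies that the enrichment analysis inverts.
  An exhaustive without-replacement variant exists but systematically
  depletes small, heavily weighted categories once draws approach the
  category's site count, and is therefore not the default forward model.
* **Primer panel** — 20-mers whose per-primer T probability is uniform on
  [0.05, 1] so scores span the unit interval, with the first primer forced
  to all-T (the reference). Activity = max(0, β₀ + β₁·score(10) + ε),
  ε ~ N(0, σ²); defaults β₀ = 10, β₁ = 90, σ = 10 with 35 primers, chosen
  to resemble a realistic panel spanning ~7–120% activity. The zero-clip
  mimics a detection floor and slightly biases the low end.

All generators derive their randomness from per-component child streams of
one root seed, so adding a generator never perturbs the draws of another,
and every output is bit-reproducible given (seed, config).

## Numerical and testing notes

Slope recovery on noisy panels is verified as a *calibration* across 30
seeds (standardized errors centred on zero, ≥ 50% within one standard
error) rather than at a single seed, since a one-standard-error band is
only a ~68%-probability event per draw. The enrichment recovery check
(normalized frequencies within 15% of the generating weights at n = 5,000)
runs on a fixed seed and finishes in well under a minute.

## Known limitations

* The scan enumerates only the five single-degeneracy patterns; doubly
  degenerate snaps, EN-independent insertion pathways and post-nick DNA
  processing are out of scope.
* The score is purely positional: no melting temperature, duplex stability
  or secondary structure is modeled, and hairpin exclusion is an input flag
  supplied by the user, not computed.
* One published worked-example primer can only be verified through a
  synthetic stand-in with the same printed score, as its sequence lives in
  a supplementary table not distributed with the package.
* No liftover between genome builds and no catalog-specific file dialects;
  insertion inputs are generic BED/TSV.
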
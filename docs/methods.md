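# Methods

## Problem and model

`svconcord` compares two callsets of structural variants (SVs, ≥ 50 bp
rearrangements) made against one reference genome by two fundamentally
different technologies:

* **assembly-based calls** from aligning a long-read (ONT) de-novo assembly
  to the reference and running MUMmer `show-diff`, which emits six record
  types — GAP, DUP, BRK, JMP, INV, SEQ;
* **optical-map calls** from aligning Bionano DLE-1 labelled genome maps to
  the in-silico labelled reference, exported as an SV-VCF with
  per-breakpoint uncertainty intervals (CIPOS/CIEND), a 0–20 quality score
  for insertions/deletions and a confidence p-value for
  inversion/translocation breakpoints.

The comparison is purely positional: after harmonization and filtering,
calls are compared on their absolute reference coordinates, and any pair of
calls from opposite technologies whose intervals share **at least 1 bp** is
linked.  The assembly side participates with its reference footprint (for
an insertion, the alignment gap it leaves on the reference); the optical
side with its *extended* interval, `[POS + CIPOS_low, END + CIEND_high]`,
which absorbs label fuzz.  Connected components of this bipartite graph are
*locations*, labelled with a two-letter svID code (first letter =
assembly side, second = optical side; U unique member, M multiple members,
N none).  UU/MU/UM/MM locations are *common*, UN/NU *specific*.

Defining locations as connected components is the one formalization under
which one-to-many multiplicities (MU), their absence in the other direction
(UM) and mixed chains (MM) are all simultaneously well-defined; mixed MM
components are reported under their own code.

## Harmonization rules

* GAP records become insertions when the query-side gap exceeds the
  reference-side gap (size = query gap) and deletions otherwise
  (size = reference gap; an exact tie counts as deletion and is logged).
  The size of assembly insertions is therefore query-based, matching a
  size filter applied to query SV size.  A GAP with both gaps ≤ 0 is a
  degenerate alignment artifact and is removed.
* SEQ/BRK/JMP records mark reference-sequence junctions, breaks and jumps —
  assembly discordance concentrated in centromeres, telomeres and rDNA
  clusters — and are removed with reason `ASSEMBLY_DISCORDANCE`.
* INV/DUP records become calls sized by their reference span.
* Optical-map records map type-for-type (insertion/deletion/inversion/
  translocation/duplication); their reported size is read from a dedicated
  INFO key (`SVSIZE` by default, falling back to `|SVLEN|`, then to the
  POS–END span).  The quality score is read from a configurable INFO key
  (`QUAL_SCORE`) with the VCF QUAL column as fallback, because the SMAP→VCF
  converter's field layout varies between Solve versions.

## Filters (defaults)

| parameter | default | meaning |
|---|---|---|
| `min_size` | 1000 bp | keep calls strictly larger; compensates long-read error and matches the optical detection floor.  Strict (`>`), so a retained-minimum of ~1003 bp is expected |
| `bionano_min_quality` | 10 | INS/DEL score floor; an *absent* score does not remove a call |
| `tra_cutoff` / `inv_cutoff` | 0.1 / 0.01 | manufacturer-recommended breakpoint-confidence cutoffs; an inversion or translocation with no confidence at all is removed (`NO_CONFIDENCE`) |
| exclusion list | none | user-supplied BED of known caller artifacts (e.g. a spurious multi-Mb insertion at an rDNA cluster), instead of hard-coded coordinates |
| embedded resolution | optical side only | when the caller reports one SV inside another, only the largest is kept; applied transitively, identical intervals keep the id-first call |

Every filter returns a report in which retained + removed = input, each
removed record carrying exactly one primary reason code (size is checked
before quality, so a small low-scored call reads `SIZE_LE_MIN`).

## Scoring

* **Conformance**: a common location is conforming when every member from
  both technologies shares one SV type; not applicable to UN/NU.
* **Overlap fraction** (UU only): intersection length over the *shorter*
  interval.  The denominator choice is deliberate: a precise assembly call
  contained in a coarse uncertainty-extended optical interval must read as
  100% for the full-overlap class to dominate, as observed.  Classes:
  FULL (= 1), GT50 (> 0.5), LE50 (≤ 0.5), integer arithmetic throughout.
* **Size comparison**: one-sided Wilcoxon rank-sum (alternative: assembly
  sizes stochastically smaller), run with and without large events
  (≥ 50 kb excluded from both samples — strict at the boundary, consistent
  with "1 kb < SV < 50 kb" panels).  Exact null distribution for combined
  n ≤ 20 without ties, else the normal approximation with continuity
  correction (`scipy.stats.mannwhitneyu`).
* **Genome bins**: fixed 100 kb bins; a 1-based position `p` falls in bin
  `p // width`, and a call increments every bin its interval touches.
  In-silico labelling scans the forward strand for the DLE-1 recognition
  site CTTAAG (its own reverse complement; the motif is a parameter but
  degenerate IUPAC codes are rejected), counting overlapping matches.
* **Annotation**: ≥ 1 bp positional intersection with gene and
  transposable-element features (GFF3 types mapped by configuration,
  defaults `{gene}` and `{transposable_element, transposable_element_gene,
  transposon_fragment}`).  TE and gene flags are independent, so a call
  over a TE nested in a gene counts in the TE∩gene cell.  Optical-map
  calls are excluded from the cross-tab by default (coarse large-scale
  observations), overridable.

## Synthetic data model

The generator plants one truth set and emits it through two noise models;
its defaults are the package's study conditions.

* **Truth**: 600 SVs over five 30 Mb chromosomes, type mix
  49/49/1.5/0.5% INS/DEL/INV/TRA, sizes log-normal with median 3.5 kb and
  log-sd 1.2 (clipped to 50 bp–400 kb); inversions/translocations drawn
  10× larger, reflecting the much larger scales at which balanced events
  are reported.  Insertions get a 1–20 bp reference footprint.  Events are
  placed uniformly with ≥ 10 kb spacing; since no pad (≤ 500 bp) or
  fragment can cross that spacing, the svID classification of the emitted
  callsets is *exactly* derivable from the emission plans, which is what
  the end-to-end tests assert.
* **Assembly-like emitter**: show-diff GAP/INV records; 5% misses;
  multiplicative size shrink uniform on [0.88, 1] (alignment trimming);
  deletions/inversions ≥ 10 kb fragment with probability 0.7 into k ∈ 2–4
  adjacent sub-records inside the parent interval (the MU mechanism);
  translocations are invisible to this emitter.  Insertions never
  fragment: they have no reference span to split, and fragmenting them
  would make the classification expectation depend on pad magnitudes.
* **Optical-like emitter**: one coarse VCF record per event; nothing below
  1 kb (detection floor); CIPOS/CIEND pads uniform 50–500 bp; reported
  size inflated uniformly on [1.0, 1.4] (label-interval coarsening); 2%
  base miss rate rising to 80% in simulated low-label-density bins (a
  per-chromosome density track with a centromere-like central dip,
  thresholded at 9 labels/100 kb); 1% INS↔DEL reported-type confusion;
  quality drawn 10–20 above 1 kb (3% absent), breakpoint confidence
  uniform 0.05–1 (5% absent).

The shrink/inflation pair was set from the reported per-technology median
sizes (optical ≈ 1.27× the assembly median): mean −6% on the assembly side
and +20% on the optical side reproduce simulated median ratios of
~1.13–1.3.  What the model does **not** emulate: sequence-level alignment
noise, breakpoint jitter *across* events, chimeric joins, coverage-driven
dropout on the assembly side, or real label positions — so passing tests
demonstrate the correctness of the comparison machinery under controlled
noise, not the calling performance of either technology on real genomes.

## Numerical and formatting choices

Internal coordinates are 1-based inclusive everywhere (MUMmer/VCF/GFF3
convention); BED import/export converts at the boundary.  Medians of
even-sized samples are midpoints of the central pair; table cells round to
one decimal (percents, Mb) or to integers (average bp), mirroring the
report layout.  Location ordinals are per-code counters in genome order —
a presentational choice.  Group tables are byte-identical under any input
permutation (members and groups are fully sorted before numbering).

## Problem sizes

The bundled acceptance run uses the generator defaults (600 planted SVs)
for the noisy study, 150 events for the zero-noise recovery check and 50
large deletions for the fragmentation check; the property suites run ~1000
randomized instances of ≤ 30 calls. These sizes give stable statistics
(hundreds of calls per side for the rank-sum test) while keeping the whole
analysis a seconds-scale desk computation.

## Known limitations

* The show-diff column map follows MUMmer 3 documentation; exotic variants
  of the format (promer output, user-edited files) are rejected rather
  than guessed.
* Overlap-fraction classes are defined only for UU locations (NA
  otherwise), and the fraction denominator (shorter interval) is a
  package decision — other tools use the union or a fixed side.
* The supplementary-data regression requires the journal's deposited
  per-call tables, which are not redistributed; without a local copy that
  check reports itself as skipped.
* GO-term enrichment is out of scope: gene lists are exported for external
  tools.
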
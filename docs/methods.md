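# Methods

This note documents the models, conventions and defaults behind `crispec`,
and what the synthetic experiments do and do not demonstrate.

## Guide model and off-target search

A guide is a 17–20-nt spacer whose genomic locus spans spacer + PAM. Design
uses an NGG PAM; off-target search uses NRG (R = A/G), reflecting SpCas9's
tolerance of NAG. Truncation removes bases at the 5′ (PAM-distal) end only;
the PAM-proximal sequence, the seed, and the cut site are unchanged.

Conventions, chosen once and used everywhere:

* Coordinates are 0-based half-open on the forward strand (BED convention);
  human-readable TSV reports use 1-based inclusive starts and say so in a
  header comment.
* Mismatch positions are numbered 1..L from the PAM-proximal base; the
  **seed region** is positions 1–12.
* The blunt cut lies 3 bp 5′ of the PAM (standard SpCas9 geometry). Its
  junction coordinate is independent of spacer length, which is what lets
  hit sets of differently truncated guides be intersected by
  (contig, cut, strand).
* A genome base of `N` (or any non-ACGT code) counts as a spacer mismatch.
  In PAM patterns, IUPAC codes have their usual meaning; `N` matches
  anything.
* The search is mismatch-only (Hamming distance); DNA/RNA bulges are not
  modelled. The two strands of one locus are counted as two sites.
* No activity scoring (CFD/MIT-style) is attached to hits.

The scanner is vectorised (numpy sliding windows over byte arrays) and is
checked in the test suite against an independent position-by-position
brute-force scan; exact set equality is required. Truncation monotonicity —
the Hamming distance of a 5′-truncated spacer at any locus is at most that
of the full spacer, hence hit counts grow weakly as spacers shorten — is a
theorem about suffixes, and the tests verify the implementation respects it.

## Microsatellite scanner

Perfect SSRs are maximal complete-unit tandem runs of primitive 1–6-nt
units meeting per-unit-length minimum repeat counts (defaults 1:10, 2:6,
3:5, 4:5, 5:5, 6:5 — the canonical MISA-style settings; configurable).
Runs are located through the self-match vector `s[i] == s[i+unit]`, which
yields leftmost-maximal runs directly. Overlaps between candidate runs of
different unit lengths are resolved longest-span-first, ties leftmost, then
shortest unit. Units are reported as they occur on the scanned strand (no
strand folding), and a composition string always re-expands literally to
the genomic substring — including interruption bases in compounds, e.g.
`(CA)6GTTC(GA)6`.

Qualifying runs separated by at most 100 bases merge into a compound
record. In addition, an **extension rule** absorbs a sub-threshold run of a
different unit lying flush against a qualifying run when it has ≥ 2
complete units — needed so that motifs like `(CA)8(GA)2`, whose `(GA)2`
tail is far below the dinucleotide threshold, are reported as one compound
locus. This is a deliberate extension of strict MISA semantics. Extension
is limited to units of 2–6 bp: a flush pair of identical single bases
occurs at a quarter of run boundaries by chance and carries no slippage
signal, so mononucleotide runs never join a compound through this rule
(they still qualify on their own at ≥ 10 repeats).

Site flagging extracts `[start − flank, end + flank)` around each candidate
site (default flank 100 bp, i.e. a ~200-bp window, clamped at contig edges
with a warning) and sets `ssr_flag` when any perfect or compound SSR
overlaps it.

## Read simulation

The generator emulates a capture-panel experiment at desk scale. Defaults
define the study conditions:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 30 000 bp | synthetic genome size |
| `gc_fraction` | 0.41 | mammalian-like GC content |
| `edit_rate` | 0.6 | on-target per-read editing probability (sorted-cell regime) |
| `indel_size_dist` | 70 % deletions of 1–6 bp, 20 % insertions of 1–2 bp | NHEJ outcome spectrum |
| `subst_error_rate` | 0.001/base | sequencing/PCR substitution noise |
| `stutter_rate` | 0.05/read | ±1 repeat-unit slippage at an SSR locus |
| `n_reads` | 300 | per-site coverage |

Planted functional off-targets are edited at 51.4 %, 31.7 % and 10.5 % in
the edited sample only — the magnitudes a strongly active guide shows at
its few genuine off-target loci. The real NHEJ indel-size spectrum is
locus-dependent and not reproduced here; the chosen mix is a generic
deletion-skewed profile and only its *location* (left edge anchored at the
cut) matters for the quantifier.

Each edited read carries exactly one indel with its left edge at the cut
position, making per-read truth labels unambiguous. Stutter adds or removes
one whole unit of the longest repeat run inside the SSR span (equiprobable
direction, anchored at the run's left edge) in control and edited samples
alike — slippage is Cas9-independent, which is precisely why SSR loci
contaminate off-target panels. Substitution errors are per-base independent.
Reads are full amplicon length at constant Q30: no pairing, adapters,
quality decay, PCR duplicates or machine error profiles. Passing tests
therefore demonstrate the *logic* of the pipeline (search completeness,
window rules, threshold behaviour, SSR attribution), not robustness to
real-world library artefacts.

All draws flow through a single seeded numpy generator in a fixed
per-read order, so identical configurations produce byte-identical FASTA/
FASTQ output.

## Alignment and indel calling

Reads are aligned to their reference amplicon (and its reverse complement;
the better score wins, ties to the forward strand) with deterministic
semi-global affine-gap alignment: match +2, mismatch −3, gap open −8, gap
extend −1, end gaps free on both sequences (Biopython `PairwiseAligner`).
A read with fewer than 60 % of its bases matching is `discarded_unaligned`.
These penalties make a single substitution (−3) always preferable to an
indel pair (≤ −16), so substitution noise cannot create indel calls.

Indels are left-aligned within repeat context before window testing, giving
slippage indels at an SSR one canonical placement. A read is an edit call
iff at least one insertion or deletion intersects the closed window
`cut ± 10 bp` (configurable; logged in the report); its recorded size is
the net signed in-window length. Out-of-window indels leave the read
wild-type but are recorded. A read carrying both in- and out-of-window
events is counted once, as edited. The efficiency denominator is aligned
reads, not raw reads. The window default means an SSR ~50 bp from a cut
site only contaminates the estimate if the window is widened to reach it —
the planted noise sites sit flush with the PAM, a handful of bases from
the cut, where real co-captured repeats do their damage.

QC before alignment: exact-prefix adapter trimming at the 3′ end with ≥ 8
bases of overlap, removal of reads containing `N`, removal of reads shorter
than 35 bases after trimming. (The last rule is the standard length filter;
discarding reads *longer* than 35 bases would empty any amplicon library.)

## Classification and reporting

Rule order is coverage → background → validation: a shallow site
(control aligned reads < 10) is never reported clean, and a
background-unstable site (control efficiency ≥ 1 %) is never promoted to a
validated off-target regardless of its edited signal, because that signal
cannot be attributed to Cas9. Unstable sites are retained and labelled —
not dropped — so the background-noise budget remains reportable, with the
SSR flag recorded as the suspected cause. The edited-sample validation
threshold defaults to the same 1 % for symmetry and is separately
configurable. Classification is a partition: every panel site receives
exactly one status. The on-target site travels through the same machinery
but is reported separately; validated off-target counts exclude it.

The T7ENI formula `100 · (1 − √(1 − f_cut))` with
`f_cut = (b+c)/(a+b+c)` inverts the expectation that a fraction *p* of
mutant alleles yields `2p(1−p) + p²·h ≈ 1 − (1−p)²` cleavable
heteroduplexes after random reannealing; it is strictly increasing in the
cut fraction and bounded in [0, 100].

## Numerical and degenerate-input choices

* Thresholds are compared with `>=` at the boundary (1.0 % control noise is
  already unstable; a site needs ≥ 10 control reads to be assessable).
* `efficiency` of an empty or unalignable read set is 0 with a warning.
* Offsetting in-window indels (net size 0) keep edit status; the first
  event's signed size is reported. The simulator never produces this case.
* Amplicon extraction clamps at contig edges and shifts `cut_pos`
  accordingly; T7ENI rejects negative or all-zero band intensities.
* Identical read sequences are memoised per site during quantification;
  this changes nothing numerically.

## Problem sizes in tests and the acceptance script

The test suite checks search-oracle equality on twenty 50-kb genomes and
SSR-oracle equality on one hundred 5-kb sequences; rate recovery uses four
editing rates × twenty seeds at 2 000 reads. The acceptance script runs the
same computations at moderately reduced sizes (ten 20-kb genomes, fifty
sequences, ten seeds per rate) — comfortable desk-scale settings chosen so
a full rerun stays fast while every estimate remains far from its decision
boundary. Genome-scale counts (the millions of candidate sites a real
genome yields) require a reference genome and are out of scope by design.

## Known limitations

* Mismatch-only search: bulged off-targets are invisible.
* No modelling of chromatin state, scoring, or probe/capture efficiency;
  capture dropout appears only as the coverage partition.
* The stutter model is ±1 unit with a flat rate; real slippage rates grow
  with repeat length and unit composition.
* Classification treats sites independently; no multiple-testing control or
  between-sample statistics are attempted.
* Single-end, error-light reads; QC is intentionally minimal.
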
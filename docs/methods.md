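# Methods

## The data and what the simulator emulates

An Rmap is the ordered list of restriction-fragment masses measured
from one surface-stretched DNA molecule. The simulator draws molecules
from one or more tumor subclones ("slices") of a shared genome:

* **Sampling.** Molecule start positions are drawn proportionally to
  subclone fraction × regional copy number (copy 2 = neutral), and
  molecules accumulate until the configured fold coverage (total
  molecule mass / reference length) is reached, so simulated coverage
  matches the nominal value by construction.
* **Length.** Gamma-distributed (shape 7, mean 420 kb) and resampled
  below 300 kb, reproducing the right-skewed 300 kb – >500 kb range of
  high-molecular-weight preparations. The realized mean is slightly
  above the nominal mean because of the truncation.
* **Error model.** Each true cut is observed with digestion efficiency
  p_d = 0.8; spurious cuts arrive as a Poisson process at 5/Mb; each
  fragment mass is multiplied by (1 + ε), ε ~ N(0, 0.06²)
  (fluorescence-based mass estimation scales with size, hence
  multiplicative); fragments below 0.8 kb desorb from the surface with
  probability 0.75, collapsing their two bounding cuts into one.
  These rates are configuration, never hard-coded, and were chosen to
  be consistent with the platform's qualitative behavior (≈3 kb
  resolution, visible partial digestion and breakage).
* **Genome.** Simulated reference sequences are i.i.d. with GC = 0.41
  (human-like). The recognition site is AT-rich, so this yields a mean
  fragment of ≈17 kb, close to the genome-wide SwaI map density.
* **Truth.** Implants (INS/DEL/INV/site gain/site loss) are recorded
  with pre- and post-implant coordinates; each molecule carries its
  origin and orientation. Site changes are single-base substitutions,
  so a gain requires a Hamming-distance-1 window.

What the simulator does **not** model: chimeric molecules (supported
but off by default), sequence-dependent digestion bias, image-level
artifacts, and correlated sizing error along a molecule. Passing tests
therefore demonstrate correctness of the algorithms under the stated
error model, not performance on any particular instrument's data.

## Alignment

The aligner is a dynamic program over fragment *blocks*: up to
`max_block` (4) consecutive query fragments match up to 4 consecutive
reference fragments. Block cost is the squared sizing z-score
`((q − r)/(σ_a·r))²` (σ_a = 0.06; the denominator scales with the
reference mass because sizing error is multiplicative) plus 9.0 per
unmatched interior cut on either side. Terminal query fragments are
unscored — molecule ends are random shear points that match partial
reference fragments.

Acceptance is deliberately not a p-value: a placement is accepted when
(1) its mean cost per query fragment (terminals included in the
denominator) is at most 6.0, and (2) it beats the best *distinct*
placement — another chromosome, or the same chromosome more than one
molecule-length away — by at least 1.0 mean-cost units. The second
test is the analogue of mapping quality: a short molecule over a long
genome can reach a decent score by chance, but chance placements come
in near-ties. Calibration on default-noise simulations gives ≈93–95%
of eligible molecules aligned, >99% at the true location and
orientation, and ≥95% of reference-free random maps rejected; the cut
penalties (9.0) were raised from smaller values because weak penalties
let random maps assemble cheap merge-heavy placements
indistinguishable from real ones.

The DP kernel is JIT-compiled with numba when available; the
pure-Python fallback is the same code path and produces identical
results.

## Iterative consensus assembly

Aligned molecules are binned by alignment midpoint into 1 Mb windows
with 500 kb overlap. Each window's consensus starts as the in-silico
reference restricted to the window **plus 400 kb margins** on each
side, so member molecules rarely overhang the map; blocks touching a
map end are excluded from all evidence (the matching boundary there is
the map edge, not a cut). Windows below `min_depth` = 5 molecules stay
unassembled.

One refinement round:

1. Realign every member with the per-block sizing cost capped at 16.
   The cap matters: a molecule spanning a 30 kb insertion would
   otherwise either be rejected outright or accepted with its mass
   error smeared over distorted merges. With the cap, the DP keeps the
   correct registration and flags the oversized block as a candidate
   indel.
2. Per consensus cut, count *spanning* molecules and *concordant*
   molecules (a block boundary on the cut). Only the interior of each
   alignment is trusted — the outermost block on each side anchors
   against an unscored terminal and misregisters easily, which
   otherwise biases cuts near molecule ends toward "missing". Cuts
   with ≥4 spanning and concordance < 0.4 are deleted (recorded with
   their support for later scoring).
3. Unmatched query cuts are projected into consensus coordinates and
   clustered with a diameter cap of `clip(2σ_a·local, 3, 8)` kb;
   clusters supported by ≥ max(4, 0.4 × spanning) molecules become new
   cuts, unless within 3 kb of a previously deleted cut (no
   oscillation) or within 1.5 kb of an existing cut (below cut
   resolution). The diameter cap prevents uniformly scattered false
   cuts from chaining into a mock consensus cut.
4. Fragment masses are re-estimated as the mean of one-to-one matched
   block masses (≥3 observations). Merged blocks contribute no mass
   evidence: pro-rating them by the current consensus ratio would
   reinforce whatever drift the consensus already has.
5. Capped ("rescue") blocks vote on indels; when enough molecules
   agree on a deviation at one fragment, its mass moves to their
   median, after which later rounds accept those molecules normally.

`iterate_assembly` runs 8 rounds; after each, still-unaligned
molecules are retried against every consensus that changed, and
membership only grows, so the per-round aligned count is
non-decreasing. Windows at a fixed point are skipped, which makes the
8 rounds cheap on unaltered regions.

**Targeted assembly** seeds from a hypothesis map (rearranged interval
with 500 kb flanks). The consensus is refined as usual — which means
refinement would happily edit *any* junction to match the data — so
the verdict is judged against the *stated* hypothesis: a bridge is a
molecule whose alignment to the original hypothesis map covers a
breakpoint ±30 kb with blocks that are at most 2:2 merges (ordinary
partial-digestion noise) and mass-consistent within 3.5σ. Support
requires ≥5 bridges at each breakpoint. A wrong junction cannot fake
the mass agreement, which reproduces the behavior that only the
correct rearrangement hypothesis "grows".

## Calling structural alterations

The window consensus is aligned back to the reference map (small
fragments merged at 0.4 kb — the same map molecules are aligned to,
because sub-0.4 kb fragments are below the detection limit). For this
classification alignment the cut penalties are raised to 50 and the
sizing cost capped at 100: the goal is a faithful decomposition, and
without the cap the DP would reinterpret any indel ≥ ~2.5 kb as a
phantom extra-cut/missing-cut pair.

Per block: unmatched reference cuts are MC candidates, unmatched
consensus cuts EC candidates, and a block with
`|q − r| ≥ max(0.13·r, 4.5 kb)` an INS/DEL candidate (indels also need
≥8 molecules of mass evidence). Two or more differences within 3
consecutive reference fragments collapse into one OTHER call — which
is also how an indel coexisting with a cut difference is labeled.
Sub-threshold size changes are never called; calls in window margins
belong to the neighboring window; duplicates from overlapping windows
deduplicate by class-specific windows, keeping the higher-support
call. Inversions are not emitted by this classifier; they are
established by targeted assembly and reported with an
inversion-supported annotation.

**Significance.** Every candidate is scored against the error model:
EC by the binomial tail of k concordant among n spanning under the
false-cut rate over the local fragment; MC by the binomial tail of k
cut observations under a *detection probability* that multiplies p_d
by desorption retention for flanks < 0.8 kb and by flank/3 kb for
flanks below the ≈3 kb resolution (a cut bounded by a tiny fragment is
rarely observable as a distinct cut, and treating it as fully
detectable manufactures false MCs); INS/DEL by a two-sided normal tail
of the mean mass deviation with per-molecule variance (σ_a·r)²; OTHER
by its strongest component. The Bonferroni denominator is the number
of loci examined — every reference cut and fragment is an implicit
test — not the number of candidates, which would make the correction
vacuous on clean genomes.

## Copy number

Midpoints of accepted alignments are counted in intervals built from a
normal dataset so each interval holds exactly m normal midpoints
(boundaries bisect flanking midpoints; the last interval keeps the
remainder). This realizes coverage normalization for restriction-site
density without modeling the site process explicitly: equal tumor
counts mean equal relative copy number. m defaults to 10 with larger
values (20–25) recommended whenever per-interval counts would fall
below ~20 — two-state separation needs the modes (ratio 2) to clear
the counting noise.

The HMM has integer states {0..4}, emission mean μ·k/2 (state 0
floored at 0.05μ), negative-binomial emissions with method-of-moments
dispersion, uniform initial distribution and stay probability
1 − 10⁻⁴, giving expected segments far longer than one interval —
arm-scale events. Decoding is standard log-space Viterbi, restarted
per chromosome (so a whole-chromosome loss pays no transition cost).
μ is the median interval count ("median as diploid"), which is correct
while aberrations cover < ~25–30% of the genome; beyond that the
median drifts into the valley between modes, a documented failure mode
flagged by a bimodality warning (heavy tails or a thin histogram
center). Per-slice analysis runs the identical chain per source label
on shared intervals and reports intervals whose decoded states differ.

## Numerical and interface choices

* Coordinates are 0-based half-open bp; masses are kb at 0.001 kb
  resolution; all on-disk formats are plain text (map TSV dialect,
  FASTA, BED4+, TSV tables, JSON reports).
* All randomness flows from a single seed through
  `numpy.random.default_rng`; identical configuration reproduces
  byte-identical outputs, and batch operations are order-independent
  (internal sorting by molecule id before every reduction).
* Tie-breaks in alignment are (lower mean cost, forward orientation,
  lower chromosome id, leftmost start).
* Small-fragment merging merges into the left neighbor (the leftmost
  fragment merges right), conserving mass exactly and idempotently.
* Degenerate inputs (empty molecule sets, chromosomes shorter than a
  window, labels without data, fewer normal midpoints than m) degrade
  to warnings or explicit unassembled/skip states, never silent wrong
  answers.

## Problem sizes

The bundled scenarios run on desk-scale genomes chosen so every
statistical property is measurable with comfortable margins: 10 Mb
genomes at 30x for variant recovery and specificity (≈650 molecules,
≈600 reference fragments), 3 Mb for the 485 kb inversion with 500 kb
flanks, and interval counts of ≈400 (two-state decoding) or ≈35
(per-slice) for copy number. Nothing in the implementation depends on
these sizes; they scale linearly in genome length and coverage.

## Known limitations

* One location per molecule: no split or chimeric alignments, hence no
  translocation discovery.
* Integer copy states only; no subclonal-mixture fractions.
* The somatic filter is purely positional/type-based; it cannot
  distinguish a private germline variant from a somatic one without an
  appropriate matched panel.
* Cut differences within ~1.5 kb of an existing cut and indels below
  `max(0.13·r, 4.5 kb)` are invisible by design — the platform's
  resolution floor.
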
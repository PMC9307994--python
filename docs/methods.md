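# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind `regland`.

## Coordinate and format conventions

All intervals are 0-based half-open (BED-native) internally; 1-based
inclusive locus strings are produced only by the display helper
(`GenomicInterval.to_ucsc`). Unknown chromosomes are a hard error
everywhere — silently dropping records would mask assembly mismatches.
Coverage is a per-chromosome step function with bedGraph semantics
(gaps are zero); a precomputed running integral makes interval sums and
sliding-window sums O(log n) lookups, so window sums are exact per-base
sums, not approximations. bedGraph writing merges adjacent equal-valued
segments and formats values at full round-trip precision, so
write∘read is a base-wise identity.

In-peak depth normalisation scales a track by `1e6 / S`, where `S` is
the signal inside the union of that sample's peak intervals (the union
avoids double-counting overlapping peak calls). The operation is
idempotent up to scale and replicate tracks are averaged value-wise.

## MAR scanning

Windows are 10 kb every 2 kb by default, starting at the region start;
a trailing window that would cross the region end is dropped rather
than truncated so all window sums stay comparable. Per-window signal is
the sum of per-base values; for a fixed window size the sum and the
mean differ by a constant factor and select identical MARs.

Tissue-specific signal is ChIP minus brain background per window,
clamped at zero by default (`clamp_negative=False` restores raw
differences): brain signal exceeding the tissue signal is not evidence
of tissue-specific activity, and non-negativity licenses the linear
two-pointer minimal-run search. With clamping disabled the search
falls back to an exhaustive prefix-sum scan, so both behaviours remain
available. Tie-breaking among equal-length qualifying runs: largest
cumulated signal, then leftmost — deterministic and density-favouring.
The scanned region is always an explicit input; the package never
infers it.

## 4C-seq processing

The processing order is fixed: smooth → normalise → average →
(subtract | boundary call). Smoothing is a centred 11-fragment running
mean; at profile edges the window shrinks symmetrically
(`min(half, i, n−1−i)` per side) so smoothed values are always centred
means — the edge behaviour is an assumption, as fragment-window edge
handling admits several conventions. Normalisation divides by the mean
smoothed score over fragments whose midpoint lies within ±5 Mb of the
viewpoint. Fragment membership in flanks and regions is decided by the
fragment midpoint, which is unambiguous for fragments straddling edges.
Viewpoint-proximal fragments are not excluded (an optional exclusion
radius exists in the simulation configuration but defaults to off).

For a boundary call between viewpoints `a` and `b` over a region of
interest, each profile is rescaled to sum to one within the region —
this makes the call invariant to any positive scaling of either raw
profile, so whether the rescaling consumes smoothed or normalised
scores is immaterial to the argmin; normalised scores are used. The
cumulative sum of `b′ − a′` is traversed in along-landscape order
(reversed for a locus stored on an inverted axis), the first minimum in
traversal order wins on exact ties, and the call is snapped to the
anchor whose midpoint is nearest the argmin fragment midpoint (ties to
the anchor earlier in traversal order). The rescaling forces the curve
to close at zero (|C_last| < 1e-9 is asserted in tests); identical
rescaled profiles leave the curve identically zero and the boundary is
reported undefined rather than arbitrarily placed. Partition regions
run between consecutive anchor midpoints; transposition to a second
species maps each anchor to its aligned partner's midpoint and
requires the anchor order to be monotone on the target assembly
(either direction, to allow inverted loci).

## pCRE and CNE annotation

Peak extension is ±660 bp per side, clipped at chromosome bounds;
merging combines overlapping and book-ended intervals. Exon overlap of
≥ 1 bp discards an interval. TSS distance is measured from the
interval's nearest edge to the TSS point (0 when contained), strand
ignored; exactly 2,000 bp classifies as enhancer (the promoter rule is
strictly "less than 2 kb"). Per-tissue activity uses the extended peak
sets, consistent with how the merged catalogue was built (raw peaks are
available via `pad=0`); the activity score of a pCRE is the maximum
overlapping peak score, whereas an enhancer-CNE's score is the mean of
the overlapping peaks of that tissue — the two conventions are
deliberately different because the CNE matrix averages by design.
Openness is the conjunction of H3K27ac activity and ATAC overlap in the
matching tissue; a tissue with no ATAC set gets no flag at all rather
than `False`.

For CNE calls the ≥ 2 kb TSS rule is evaluated on the CNE interval
itself, before any extension: peaks are extended, CNEs are not.
Minimum overlap for all intersections is 1 bp. Aligned blocks are kept
as distinct CNEs (no chaining), and one-to-many alignment
relationships stay separate pairs with distinct ids. The Fisher test
on the 2×2 specificity-by-stratum table is two-sided
(`scipy.stats.fisher_exact`); the test suite checks it against an
exact integer hypergeometric enumeration on every table with margins
≤ 20.

## Synthetic data

The generator emulates the statistical structure of the study inputs at
desk scale; one master seed derives an independent child stream per
component (coverage, 4C, peaks), so adding a generator never perturbs
earlier streams, and all placement happens on integer grids for
cross-platform determinism.

*Coverage* is simulated on a 10 bp grid over a 1.6 Mb landscape: a
shared base coverage of mean 1 unit/bp with a slow (~5 kb) ±10 %
undulation; the tissue track adds `fold × base` inside one planted
100 kb block (fold 5 by default); each track carries independent
per-bin Gaussian noise (sd 0.3 of the background rate, clipped at
zero). These defaults put the planted block at roughly 98 % of total
specific signal, the regime in which a dense acetylation block
dominates a landscape.

*4C* fragments are ~600 random restriction fragments over the
landscape. Raw scores are `exp(−|mid − viewpoint| / decay_scale)` times
`(1 + fold)` inside the viewpoint's preferred territory, times
lognormal noise (σ = 0.25). The default decay scale is 2.5 Mb —
effectively landscape-wide — because within a TAD the residual distance
decay is shallow relative to the territory structure (the steep
proximal decay is what the ±5 Mb normalisation absorbs). This matters
quantitatively: with a steep intra-TAD decay the contact mass of the
two territories is strongly asymmetric and the rescaled-profile
crossing (hence the cumulative-sum argmin) is displaced from the
territory edge by a fixed fraction of the smoothing window regardless
of noise, which would contradict the intended zero-noise behaviour of
an exact switch at the shared edge. Three default viewpoints mirror
the locus arrangement: the viewpoint nearest the landscape contacts the
nearest territory, so planted data reproduce the reverse-order
gene-to-region correspondence.

*Peaks/genes/CNEs* live on a 10 Mb two-species genome in three
non-overlapping zones (genes, CNE loci, pCRE loci) whose pitches keep
extended peaks of distinct loci from merging, so planted labels are
recoverable exactly. Each pCRE locus is pleiotropic with probability
0.3 (then active in 2–4 tissues); 10 % of loci are placed
promoter-proximal. Each CNE is active per species-A tissue with
probability 0.3; given species-A activity, the matching species-B
tissue is active with the conservation rate (default 0.3), otherwise at
a 0.1 background rate — so the recovered matched-tissue overlap is a
clean binomial in the planted rate. Peak scores are Gamma(4, 2.5).

What the generator does **not** emulate: read-level sampling noise and
mappability structure, fragment-length biases of restriction digestion,
broad acetylation domains and peak-shape variation, gene clusters and
overlapping transcripts, and alignment chaining artefacts in CNE pairs.
Passing recovery tests therefore demonstrate correctness of the
computations under the planted statistical structure, not robustness to
every artefact of real sequencing data.

## Problem sizes used in verification

Oracle and recovery checks run at the scales the package documents as
its standard verification set-up: 200 random 400-window scans for MAR
oracle equivalence, 100 seeded landscapes for MAR recovery, 100 seeded
profile sets for boundary recovery and mirror consistency, 50 random
profiles for the normalisation contract, all 35,190 2×2 tables with
margins ≤ 20 for the Fisher comparison, and 500 CNE pairs for
conservation recovery. The full suite and the acceptance script each
complete in well under a minute and a half on one CPU.

## Known limitations

- The MAR is a single interval; multi-modal landscapes with two
  comparable blocks yield the denser one, with no decomposition.
- Boundary calls assume a single dominance switch inside the region of
  interest; profiles with multiple switches return the global argmin.
- `pool_and_merge` requires all peak sets on one assembly and does not
  attempt liftover.
- The Euler sets compare id sets only; partial overlaps of a CNE with
  differently-extended peaks across species can make edge cases where
  activity is detected in one species' coordinates only — zone spacing
  removes this from the synthetic data but real data retain it.
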
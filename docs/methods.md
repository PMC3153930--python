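# Methods

## The assay being modelled

Complement *C4* sits in RCCX cassettes in the MHC class III region; each
chromosome 6 carries 1–4 cassettes, so a diploid genome has 2–8 *C4* genes,
each either *C4A* or *C4B* (~99% identical, distinguished by the exon 26
isotype motif). The most common *C4* loss-of-function point event is a 2 bp
CT insertion in exon 29 codon 1232, producing a frameshift and premature
stop. Genotyping it requires both paralog specificity and copy-number
awareness, which the restriction enzyme digest variant ratio (REDVR) design
provides: one PCR spans exon 26 to exon 29 with a FAM label on the reverse
primer; PshAI (degenerate site GACNN^NNGTC) cuts inside the *C4A*-specific
exon 26 sequence only, so on capillary electrophoresis the labelled product
sizes at 794 bp for *C4A* and 864 bp for *C4B*, and the insertion shifts
either peak by +2 bp (796/866 bp). Peak-area ratios combined with
PRT-derived integer gene copy numbers (nA, nB — consumed as trusted inputs,
never re-estimated) give the number of insertion-bearing copies per paralog.

## Reference amplicons and in-silico digest

`assay_model` builds four synthetic amplicons (paralog × insertion status)
that realise exactly the constrained geometry: total length 864 bp (866
with the insertion), a single PshAI site in the *C4A* sequences placed so
the blunt cut falls 70 bp from the unlabelled end (labelled product
794/796 bp), no site anywhere in *C4B*, and a CT duplication at position
820, between the cut and the labelled end. All other bases are random;
the two paralogs share one backbone and differ only at the 10 bp
paralog-defining block, standing in for the exon 26 motif (the assay uses
only site presence/absence, so the motif is not base-accurate). Spurious
degenerate-site matches are removed by rejection sampling: the offending
window is redrawn, protected positions (engineered site, CT duplication)
excluded, until all four sequences scan clean. Coordinates are 0-based
half-open; only the labelled strand's fragment length matters (single-dye
detection of a blunt cut), so overhangs are not modelled.

## Trace model and peak integration

`electropherogram` renders a genotype as a sum of Gaussian peaks at
794/796/864/866 bp on a 780–880 bp grid (step 0.05 bp), area proportional
to the channel's copy count. Peak width defaults to sigma = 0.3 bp so the
2 bp doublet is baseline-resolved, as the real traces show. Area noise is
multiplicative lognormal with unit mean and configurable cv (default 0.05):
fluorescence areas are positive and scale-proportional, and no published
noise figure exists, so the default was fixed once at a level where the
assay's decision margins (grid spacing ≥ 1/8) dwarf the noise.

Integration estimates the baseline as the median intensity (peaks occupy a
few percent of the grid), locates maxima with `scipy.signal.find_peaks`,
classifies each within ±0.9 bp of a reference size, and integrates ±3 sigma
windows by the trapezoid rule; doublet windows are split at the valley
between the two maxima, and an unresolved doublet (valley above 80% of the
smaller peak) or an empty trace is flagged low-quality. A ±3 sigma window
captures 99.7% of a Gaussian's mass equally across channels, so area
*fractions* are recovered essentially exactly at zero noise.

Both paralogs share one primer pair, so equal amplification efficiency is
assumed; cross-paralog ratios are therefore only a consistency signal and
the caller never overrides the PRT integers with them.

## Calling rule

For each paralog with n > 0, f = area_ins/(area_ins + area_wt) is snapped
to the nearest k/n, k ∈ 0..n, ties toward smaller k (conservative). The
detection floor is 0.02 of within-paralog area: below it a peak is
"absent". A paralog with insertion signal but no wild-type signal is
flagged `needs_spikein` — f ≈ 1 cannot distinguish k = n from an artifact —
and resolved against a second read of the sample mixed post-PCR with the
PGF reference line (2 + 2 normal copies). Mixing is modelled on normalised
quartets (post-PCR products contribute signal by volume, not copy number)
at sample share alpha, default 0.5 (equal-volume mix). Resolution fits all
candidate k through this forward model and takes the L1-closest prediction,
which stays correct for any alpha and n, rather than relying on a
closed-form ratio valid only at alpha = 0.5. Total-GCN disagreements
(nA + nB vs the PRT total) are flagged, never auto-corrected.

At zero noise the rule recovers every one of the 490 valid diploid
genotypes exactly, with the spike-in invoked precisely for the
homozygous/hemizygous states; at cv = 0.05 the nearest-grid margin
(≥ 1/(2n) ≥ 0.0625) is ~3 lognormal standard deviations even at n = 8,
giving per-sample concordance in practice indistinguishable from 100%.

## Mendelian checking

A genotype (nA, nB, iA, iB) is unphased; `decompose_genotype` enumerates
all unordered chromosome pairs (each chromosome 1–4 genes) summing to it.
A nuclear family is consistent iff some per-member decomposition lets every
child take exactly one haplotype from each parent, transmission treated as
faithful (no intra-cassette recombination — that is the hypothesis being
validated). Untyped members are wildcards, since real families include
ungenotyped relatives. The search backtracks over children's oriented
pairs, pruning on the fact that a parent can supply at most two distinct
haplotypes; the space is tiny (≤ 69 haplotypes, ≤ 69² pairs per member), so
exhaustiveness is cheap and no heuristics are needed.

## Population summaries

Carrier frequency is the percentage of individuals with ≥ 1 insertion copy
of a paralog. Chromosome frequency uses the minimal cis-placement rule —
an unphased carrier with i insertion copies contributes ceil(i/4)
chromosomes — the only rule that reproduces the published chromosome counts
(30 UK, 8 + 1 Spanish) from unphased data. Cohort proportion comparison
defaults to the pooled two-proportion z test (Fisher's exact available);
on 30/719 vs 8/449 the pooled z gives p = 0.0251, matching the published
"p = 0.02" under truncation — no standard two-sample test rounds to 0.02
here, and percentages elsewhere in the source mix truncation with rounding
(26/719 printed as 3.61%), so tests pin counts and exact floats, not
printed strings. HLA-DRB1*13 co-carriage is computed over insertion
carriers with non-missing HLA at 2-digit resolution (4-digit alleles
collapse to their first field). Marker association is the squared Pearson
correlation between dosage (or HLA allele count) and the iA integer, with
the regression p; missing dosages drop pairwise; no multiple-testing
correction is applied, matching how the per-SNP values were reported.
GCN means/SDs use the sample SD; the two-cohort mean comparison is a Welch
t from summary statistics (3.89 ± 0.76, n = 719 vs 4.13 ± 1.02, n = 449
gives p ≈ 2 × 10⁻⁵, i.e. < 0.0001).

## Synthetic cohorts

`simulate_cohort` draws two haplotypes per individual from a frequency
table over single-chromosome C4 configurations. The UK-like table puts
17.35% / 70.8% / 11.85% mass on mono/bi/tri-modular haplotypes — solved so
the per-haplotype copy mean is 1.945 and variance 0.289, i.e. total GCN
3.89 ± 0.76 — with the A/B split chosen to also hit the null-homozygote
frequencies (haplotypes lacking *C4B* at 19% so that 19%² ≈ 3.6%, lacking
*C4A* at 11.2% → 1.25%). The Spain-like table spans mono- to quadri-modular
(18/59/19/4%), giving 4.18 ± 1.02. The CT insertion rides a bimodular
A-insertion haplotype at frequency 0.0208 (UK) or 0.0089 (Spain), equal to
the reported carrier-chromosome frequencies; a 0.0011 B-insertion
haplotype models the single Spanish *C4B* event (plausibly gene
conversion). These frequencies are approximate calibrations: the real
haplotype spectrum is unpublished, and exact moment matching is not
enforced.

HLA-DRB1*13 tags attach to insertion haplotypes with probability 0.85 and
to others at the background rate (8.8% UK, 11.7% Spain, reproducing
overall allele frequencies near 10.4% / 12.3%) — imperfect LD in both
directions, as observed. Flanking markers are placed on every
A-insertion haplotype (q1 = 1) and on a background fraction q0 of the
rest, q0 solved from the haplotype-level LD identity
r² = f(1−f)(1−q0)² / (p_M(1−p_M)) against the *realized* insertion
haplotype count, with exactly round(q0·(2N−K)) background haplotypes
receiving the allele (stratified randomized rounding). This conditioning
is deliberate: with ~30 carriers per cohort, independent Bernoulli draws
leave sd(r̂²) ≈ 0.05–0.06 at targets 0.25–0.43, swamping the quantity the
generator is supposed to control; stratified assignment pins the realized
LD to the target up to pairing noise (sd ≈ 0.02 at n = 719). An r² target
is infeasible when no insertion haplotype has positive frequency, and is
rejected with an explanation.

Pedigrees draw founder haplotypes from the same table; each child inherits
one haplotype from each parent uniformly, so simulated families are
Mendelian-consistent by construction and single-copy corruptions are
detectable whenever no parental decomposition supports them.

The packaged UK/Spain fixtures are deterministic tables transcribing the
published cohort composition (carrier classes, chromosome counts, HLA
typing counts: UK 719 with 26/2/1/1 carrier classes, 28 of 30 typed, 23
DRB1*13; Spain 449 with 6/1/1 *C4A* classes plus one *C4B* carrier, 5 of 9
typed, 3 DRB1*13); non-carriers are filled as (2, 2, 0, 0) and carrier HLA
assignments beyond the *13 counts are synthetic. Fixtures are generated in
code and regenerate byte-identically.

What the generator does *not* emulate: real MHC-wide LD structure (each
marker is independent given the insertion haplotype), ancestry/admixture
structure, PRT measurement error (GCN integers are exact), digestion
inefficiency (available as an optional robustness knob in principle but
complete digestion is the default), and capillary artifacts such as
stutter, dye pull-up or size-standard miscalibration. Passing tests
therefore demonstrate the correctness of the calling logic and statistics
under the stated signal model, not robustness to every failure mode of a
real capillary run.

## Numerical choices and problem sizes

Peak classification tolerance 0.9 bp (must stay < 1 bp for the 2 bp
doublet); trace grid 0.05 bp; integration window ±3 sigma; detection floor
0.02; spike-in alpha 0.5. Random streams derive from
`numpy.random.SeedSequence` spawning, so cohort, HLA, marker and per-sample
trace streams are independently reproducible from one master seed. Test
and acceptance problem sizes — 1,000 individuals for noisy concordance,
200 replicates × 3 targets at n = 719 for r² recovery, 100 random
genotypes against the 69 × 69 brute-force decomposition grid, 30 simulated
families — were chosen as the smallest sizes at which the binomial/Monte
Carlo error of each property is comfortably below its assertion margin.

## Known limitations

PRT integers are trusted; a wrong nA/nB propagates to a wrong insertion
call (the design inherits this from the assay itself). The Mendelian
checker assumes nuclear families and faithful transmission; it reports
bare consistency, not haplotype likelihoods. The two-proportion default
reproduces the published comparison but the underlying test used there is
unstated. Printed-percentage comparisons inherit the source's mixed
truncation/rounding, so tests compare counts and exact values instead.
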
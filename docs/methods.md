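# Methods

This note documents the models and conventions behind `panelseq`: what
each stage computes, the defaults and why, what the synthetic study
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Candidate discovery

Discovery treats the calls of several independent variant callers as
noisy views of one underlying SNP set and keeps only what they agree
on.

**Caller intersection.** A site/allele is a candidate iff every required
caller reports exactly the same `(chrom, pos, ref, alt)` and every
caller's record has read depth ≥ `min_depth` (default 5) and mapping
quality ≥ `min_mq` (default 20, phred scale). Matching is exact — no
position fuzzing — because only single-base substitutions are in scope
and SNPs carry no realignment ambiguity. Depth is each caller's own
reported value (DP by default), not a recount; the per-caller mapping of
depth/MQ annotation keys is a config table because callers disagree on
field names.

**Allele-fraction supplementation.** Intersection is conservative, so
sites are also recovered directly from alignment allele counts: a site
qualifies when, in *every* required accession, depth ≥ 5 and the
non-reference read fraction is ≥ 0.95, and the majority non-reference
base is one and the same single base everywhere. Requiring a single
consistent alternate is stricter than counting all non-reference reads
jointly; ties among non-reference bases disqualify a site rather than
being broken arbitrarily. The two routes are merged per accession by
position union (consensus entry wins), so a site intersected in one
accession and count-recovered in another can still become a shared
marker.

**Self-resequencing purification.** Re-sequenced reads of the reference
line should agree with the assembly; a candidate whose self
non-reference fraction is strictly greater than 0.05 is removed as an
assembly or mapping artifact. The comparison is strict (> 5 %, so
exactly 5 % is kept) and candidates with no self coverage are retained:
absence of evidence is not discordance. The filter is idempotent and
never adds sites.

**Biallelic shared-alternate filter.** Panel markers must separate the
reference from all other accessions with one allele: a site is kept only
if every accession carries the identical single alternate. Conflicting
alternates or multi-allelic evidence exclude the site.

## Panel selection

The selection rule is a deterministic equal-bin greedy: chromosome
`[1, L]` is split into `n` equal bins and, bin by bin, the not-yet-
selected candidate nearest the bin midpoint is taken, ties broken toward
the lower coordinate. Global optimizers could shave spacing variance but
are opaque; the greedy is order-free, reproducible and easy to audit. A
minimum inter-marker distance (default 200 bp, the amplicon scale)
forbids overlapping amplicons. Selection fails loudly, naming the
chromosome, when candidates run out.

Spacing statistics are computed within chromosomes only (mean, SD, min,
max of adjacent gaps, plus a genome-wide mean of all pooled gaps);
chromosomes with fewer than two markers are flagged rather than
averaged. Densities are `count / (length / 100 kb)` rounded half-up to
one decimal, the rounding convention used throughout for printed
percentages.

## Primer design

Primers must anneal identically in all accessions, so every position
discovered as polymorphic by *any* caller in *any* accession within the
design window is masked to `N` before enumeration — except the target
marker itself, which must stay inside the product (but never under a
primer). The default window is marker ± 150 bp, the smallest window
that can host any 150–200 bp product on either side.

All N-free subsequences of length 18–32 with GC 45–65 % and Tm 60–72 °C
are enumerated as left (forward) and right (reverse-complement)
candidates; feasible pairs have a 150–200 bp product with the marker
strictly between the primers. The returned pair minimizes

```
penalty = w_len·(|len_L−25| + |len_R−25|)
        + w_tm ·(|Tm_L−65| + |Tm_R−65|)
        + w_pair·|Tm_L − Tm_R|
```

with all weights defaulting to 1.0; ties break deterministically by
leftmost start, then smallest product, then shortest left primer. This
is a transparent stand-in for a full primer-design penalty function —
hairpin/dimer thermodynamics and cross-amplicon interactions are out of
scope. Infeasible markers return a structured no-pair result naming the
binding constraint.

**Melting temperature** uses the unified nearest-neighbor
thermodynamic parameter set (ΔH/ΔS per stacked pair, helix initiation,
terminal-A/T penalties), a monovalent-salt entropy correction
`0.368·(N−1)·ln[Na⁺]`, and `CT = [primer] − [template]/2`. Defaults:
50 mM monovalent salt, 250 nM primer and template. Tests cross-check
against an independent nearest-neighbor implementation (Biopython's
`MeltingTemp`) under identical conditions; observed agreement is well
within 0.2 °C on random 25-mers against a 1.5 °C test tolerance.

## Consensus genotyping

The caller emulates pileup-consensus defaults with explicit thresholds
(the underlying tool's p-value machinery is intentionally not
replicated; every threshold is exposed in `CallerParams`):

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 8 | reads needed for any call; below → NC |
| `min_reads2` | 2 | alternate reads needed for an alternate call |
| `min_var_freq` | 0.01 | floor for counting alternate evidence |
| `min_het_freq` | 0.20 | alternate fraction at which AB starts |
| `min_freq_for_hom` | 0.75 | alternate fraction at which BB starts |
| `max_other_fraction` | 0.10 | third-allele guard; above → NC |

With `f = alt/depth`: BB at `f ≥ 0.75`, AB at `0.20 ≤ f < 0.75` (both
requiring `min_reads2`), AA at `f < 0.20`, NC otherwise. Third-allele
reads do not enter `f`; a marker with more than 10 % of them is forced
NC as a contamination guard. The het floor of 0.20 and the guard are
this package's additions, chosen so that binomially distributed allele
fractions at true AA/AB/BB (p = 0, 0.5, 1) are called correctly with
< 1 % error at depth ≥ 30.

Calls always partition the panel (#AA + #AB + #BB + #NC = panel size),
and raising `min_coverage` can only convert calls to NC, never the
reverse.

## Concordance

Theoretical genotypes follow from pedigree: reference accession AA at
every marker, each divergent inbred accession BB (markers carry the
shared alternate), F1 hybrid AB. Percentages are
`100·count/panel_size` rounded half-up to one decimal; accuracy is the
percentage in the theoretical class's column, and NC never counts as a
match.

## Saturation simulation

The unit of subsampling is the **post-mapping read allocation**:
per-marker ref/alt/other read buckets plus one off-target bucket. A
budget of `n` reads is a single multivariate-hypergeometric draw over
all sub-buckets — mathematically identical to drawing marker totals
first and allele composition within markers second, and exactly
total-conserving. Re-aligning subsampled raw reads is the emulation
boundary: alignment is upstream of this package.

The default fixture models one sequenced sample: 443 markers, 6.5
million total reads (mid-range for a multiplexed amplicon run), 45 %
on-target (the midpoint of the 39–51 % range typical of highly
multiplexed PCR), 400 of 443 markers amplifiable, and log-normal
per-marker amplification weights with σ = 1.0 (amplicon depth spread
spans roughly two orders of magnitude in practice; the true dispersion
of any given run is unknown, making the low-budget part of the curve
dispersion-sensitive — it is checked qualitatively, not to a printed
number). Amplicon reads carry a 1 % per-read miscall rate. The budget
grid is 0.01–3 million reads with 5 replicates per budget, reported as
mean ± SD.

Because the 43 non-amplifiable markers are NC by construction, accuracy
saturates at 400/443 = 90.3 %; with these defaults the mean accuracy
crosses 90 % at the 400,000-read budget and is saturated (SD 0) from
700,000 reads on.

## Synthetic study generator

`FixtureConfig` defaults describe a 1/100-scale study so an end-to-end
run completes in seconds: five chromosomes of 748/593/599/486/284 kb,
eight accessions with per-accession SNP densities of 519.2, 174.3,
127.8, 434.4, 282.2, 148.5, 268.7 and 135.9 per 100 kb (spanning
closely related to highly divergent material), and panel targets of
12/9/10/8/5 markers per chromosome. Shared SNPs — one identical
alternate in all eight accessions — are planted at 25 per 100 kb,
enough to select the target panel with low spacing variance; the rest
of each accession's budget is private SNPs. Caller error is modeled as
a 5 % per-caller false-negative rate and 20 false positives per Mb at
random non-SNP positions; per-record depth is Poisson(20) (typical
~20× re-sequencing) and mapping quality N(50, 5). Count tables carry a
1 % per-read miscall rate; 2 % of shared sites are planted as
self-resequencing artifacts (10–60 % discordant self reads) that
purification must remove.

What the generator does *not* emulate: linkage structure and recurrent
mutation (SNP positions are uniform), heterozygosity within inbred
accessions, indels and structural variants, alignment artifacts
correlated between callers (caller errors are independent, which makes
intersection look better than on real data), and read-level sequencing
error profiles. Passing tests therefore demonstrate the correctness and
calibration of the pipeline's logic under its stated model, not
performance on any particular real dataset.

All generation flows from one `numpy` Generator seeded from the config;
identical configs produce byte-identical output files.

## Numerical conventions

- Coordinates are 1-based inclusive everywhere internally (VCF
  convention); BED conversion happens only at the I/O boundary.
- Printed percentages and densities round half-up (422/443 → 95.3).
- All tie-breaks (panel bins, primer pairs, non-reference majority
  bases) are deterministic and documented at the function level; ties
  that would require an arbitrary biological choice (equal
  non-reference counts) disqualify the site instead.
- Monte-Carlo tests fix their seeds; the hypergeometric moment check
  uses a 3-standard-error band.
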
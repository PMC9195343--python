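# Methods

This note records the models, conventions and deliberate design choices
behind each stage, in the order data flows through them.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED arithmetic
throughout); VCF's 1-based positions are converted exactly once, at the
parser boundary (`VariantRecord.pos` keeps the on-disk convention and
exposes `pos0`). Soft-masked lowercase reference bases are uppercased in
all sequence logic: repeat exclusion is driven solely by explicit repeat
BED files, never by case. A missing genotype is an explicit sentinel
(`None`), never conflated with homozygous-reference `(0, 0)` — the
missingness filter depends on that distinction. Interval sets are always
normalized (sorted, merged, non-adjacent); subtraction/intersection are
exact on covered bases and are property-tested against a per-base
brute-force oracle. Emitted BEDs are headerless 3-column files.

## Duplicate removal (merged ancient reads)

Ancient-DNA fragments are short enough that overlapping read pairs are
merged before mapping, so both fragment ends are observed. Two merged
primary alignments are PCR duplicates iff they share
(reference, start, end, strand). Strand is part of the key: reads on
opposite strands are distinct molecules under standard duplicate
semantics. The retained representative is the member with the highest
base-quality sum, then highest MAPQ, then lexicographically smallest name
— a deterministic best-evidence rule (the choice of survivor is not
dictated by the method itself; any deterministic rule would do, and this
one is documented rather than consequential). Unmapped and
secondary/supplementary records must be excluded upstream; non-merged
(paired) records are rejected with an explicit error because paired-end
duplicate marking is a different problem (Picard territory).

## Depth thresholds and subsampling

The genotype-depth window is `[max(3, avg/3), 10·avg]` where `avg` is the
sample's genome-wide average depth (computable with or without
zero-coverage sites). Thresholds are kept real-valued and compared
directly — no rounding — so DP = 3 passes whenever `avg ≤ 9`; the
absolute minimum of three reads per site is non-negotiable. Depth
profiles are computed from alignment spans without base-quality masking
(no per-base rule is part of the contract). Subsampling is per-read
Bernoulli with probability target/current under a named seed — matching
streaming `samtools view -s` behavior and exactly reproducible; an exact
hypergeometric count was rejected because it cannot be computed
stream-wise. Contamination tables report, per library, the ratio of
reads mapped to each candidate contaminant mitogenome over the target
mitogenome; with several libraries both per-library rows and mean/sd
summary rows are emitted (a zero target count yields NaN, not an error).

## CpG masking

"CpG sites" are counted as positions: both bases of each CG dinucleotide
are masked, so the reference-strategy count is always even (CG
dinucleotides cannot overlap). The genotype strategy substitutes, per
selected sample, the SNV alleles that sample carries into the reference
context (reference base where no variant exists, both positions of a
pair jointly when adjacent variants exist) and masks the pair if any
carried combination reads CG — a heterozygote masks if *any* of its
alleles creates the CpG (conservative, since the point is excluding
possibly damaged sites). Indel alleles are ignored: a frameshifted
context has no well-defined dinucleotide, and indels are removed by the
cascade regardless. A missing call contributes the reference base. The
combined strategy is the union of the two masks and is therefore a
superset of each (property-tested). The sample list is configurable and
defaults to all genotyped samples.

## Filter cascade

Stage order (fixed): CpG exclusion → site quality → indel proximity →
indel removal → depth window → allelic imbalance → repeat exclusion →
merge → biallelic → missingness. Boundary semantics are literal: "at
least 30" is inclusive (QUAL 30 passes, 29.9 fails); "less than 20% or
more than 80%" is strict (a 2:8 heterozygote at exactly 20% is kept);
"more than 10% missing" is strict (exactly 10% is kept). Indel proximity
uses the indel's reference-affected span `[pos, pos+len(REF)−1]` extended
by 5 bp on each side (bcftools SnpGap semantics) — an SNV 5 bp from the
span fails, 6 bp passes. The imbalance fraction uses the AD of the two
called alleles only; reads supporting other alleles do not enter the
denominator. The quality rule is applied at site level (VCF QUAL and MQ);
a per-read base-quality filter at pileup would be the alternative
reading, but that information is no longer present in a VCF.
Multiallelic detection happens post-merge on the union of ALT alleles
listed across per-sample files, since each file can look biallelic while
the cohort is jointly triallelic. Every stage records (in, removed, out)
in a trace whose conservation is asserted, and a 12-failure-mode golden
VCF pins the cascade end to end.

## Heterozygosity (θ, ε)

Each retained site (depth ≥ 3, optionally capped at the sample's maximum
threshold) contributes a base-count quartet, aggregated by sorted value
so cost scales with distinct quartets (~dozens at typical depths), not
sites. The likelihood is a two-component mixture in the mlRho spirit: a
site is heterozygous with prior π = θ/(1+θ); given homozygous, reads are
multinomial with probabilities (1−ε, ε/3, ε/3, ε/3) around the most
frequent base; given heterozygous, the two most frequent bases are the
allele pair with per-base probabilities ((1−ε)/2 + ε/6) each and ε/3 for
the rest. The multinomial coefficient is common to both components and
is included, so degenerate cases have exact closed forms (a clean
quartet at θ = ε = 0 has log-likelihood 0; a 5/5 quartet in the θ→∞,
ε = 0 limit gives Binomial(10, ½)). Optimization is Nelder-Mead on
log-parameters within θ, ε ∈ [1e−8, 0.2] (tolerances 1e−8) — chosen for
robustness on flat likelihoods over derivative methods; the 95% CI on θ
is the profile likelihood (maximizing over ε at each θ) at a drop of
1.92 log-units, with endpoints found by Brent root-finding and clamped to
the search bounds when no crossing exists. With ε pinned at 0 the MLE
reduces analytically to θ̂ = ĥ/(1−ĥ) for the observed het-site fraction
ĥ; the optimizer reproduces this to ≤ 1e−4, which is used as an internal
consistency check. This likelihood profiles over (rather than sums over)
nucleotide identities, so numeric identity with mlRho output is not
claimed — the contract is recovery of generating parameters, verified by
simulation (20 replicates at θ = 0.002, ε = 0.005, depth 10, 2×10⁵
sites: median relative error ~3%, CI coverage ~93%, slightly under
nominal because θ̂ carries a small upward bias at this depth).
Partitioning estimates autosomes and sex chromosomes separately given a
scaffold list.

## ROH and F_ROH

plink `--homozyg` semantics: a window of `window_snps` consecutive SNPs
(default 250) is homozygous iff it has ≤ `window_max_het` (3) het and
≤ `window_max_missing` (15) missing calls; a SNP's hit rate is the
homozygous fraction of the windows containing it, eligibility requires
≥ 5%. Maximal runs of eligible SNPs, split at inter-SNP gaps > 1,000 kb,
are accepted as ROH when they have ≥ 25 SNPs, span ≥ 100 kb, average at
most 50 kb per SNP, and contain ≤ 750 hets. The six named defaults
mirror common practice for this analysis; hit-rate 0.05, gap 1,000 kb
and density 50 kb/SNP fill in plink's own defaults and are all
configurable. Chromosomes with fewer SNPs than the window use a single
window of all SNPs rather than being skipped — a deliberate divergence
from plink chosen for desk-scale testability, so numeric identity with
plink at chromosome edges is not claimed; instead the implementation is
verified segment-for-segment against an exhaustive window-enumeration
oracle on random instances. ROH coordinates span the first to last SNP
of the run (not extended into SNP-free flanks). F_ROH divides the summed
length of segments ≥ 2 Mb (recent-inbreeding scale) by the genome length
of the analyzed scaffolds, repeats not subtracted; both cutoff and
denominator are overridable.

## Mutational load

Outgroup assemblies are cut into consecutive non-overlapping 35 bp
fragments (terminal remainder discarded; names encode source and
offset); mapping them to the target reference is an external step whose
per-site outgroup bases this module consumes. The ancestral state at a
variant site is the strict majority base across covering outgroups,
requiring a configurable minimum coverage (default 1); ties, inadequate
coverage, or a majority base not among the site's alleles give "unknown"
and exclude the site — deterministic and conservative. A genotype's
derived-allele count is the number of non-ancestral alleles it carries
(heterozygote 1, homozygous-derived 2 — including a homozygous-REF
genotype where the ALT is ancestral). The relative load is
Σ RSᵢ·dᵢ / Σ dᵢ over sites with dᵢ ≥ 1 and RS inside the inclusive
[min, max] score window; the denominator counts derived alleles at the
thresholded sites only, making the load a weighted mean bounded by the
window (asserted as a property). A total derived count of zero yields an
explicit undefined sentinel (NaN), never 0, which would fake a load. The
percentile utility linearly interpolates the cumulative count of
contiguous histogram bins; positive RS means constraint, so minimum
thresholds below zero are scientifically inadvisable though not
rejected.

## Synthetic data

Generators are deterministic functions of (seed, parameters); one global
seed fans out to per-generator child streams (CRC-keyed spawn keys) so
stages can be regenerated independently. Study conditions baked into the
tests: θ/ε recovery at θ = 0.002, ε = 0.005, depth 10, 2×10⁵ sites × 20
replicates; ROH oracle instances of 1,000 SNPs (80/15/5%
hom/het/missing) × 50; a planted 3 Mb homozygous block at one SNP per
10 kb with fully heterozygous flanks; duplicate rates of 0.3 with
originals drawn with pairwise-distinct coordinate keys so the planted
duplicate count equals the deduplicator's removal count exactly. What
the generators do not emulate — damage patterns, mapping error,
reference bias, linkage disequilibrium, non-uniform coverage — bounds
what green tests mean: they demonstrate algorithmic correctness of each
stage, not robustness to every artefact of real libraries.

## Runner

`erodekit run` executes a fixed step DAG (dedup → depth → subsample;
cpg/depth → filter → roh/gerp-load) without a workflow engine: enabled
steps run in topological order, a step whose upstream product is missing
fails with a dependency error unless the upstream step is enabled (in
which case ordering handles it). Configuration validation collects all
errors in one report (unknown keys, missing eras, dangling paths,
out-of-range parameters) rather than failing one at a time.

## Problem sizes

Default test and reproduction sizes (references of 10–50 kb, 2×10⁵
pileup sites, 1,000-SNP ROH instances, 100-replicate contrasts) were
chosen so the complete suite and the reproduction script each run in
about a minute on one core while keeping every statistical check
well-powered.
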
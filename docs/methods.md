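# Methods

This note documents the models, algorithms and numerical choices behind
`nemaclock`: a pipeline that discovers candidate circadian clock protein
homologs in nematode proteomes by profile-HMM remote-homology search,
filters them by domain concordance, maps them across species by reciprocal
best hits, intersects the conserved components across query phyla, scans
clock-gene promoters for circadian cis-elements, and places the conserved
components on a distance-based phylogeny. The pipeline is exercised end to
end on synthetic proteomes and genomes with planted ground truth, so every
stage has an exact acceptance surface without any database download.

## Pairwise alignment and BLAST-style statistics

Global alignment is the Gotoh three-state affine-gap recurrence; local
alignment is the affine-gap Smith–Waterman variant with the empty alignment
(score 0) as floor. A gap of length *g* costs `gap_open + g·gap_extend`
(the BLAST convention); the bundled scoring system is BLOSUM62 with open 11,
extend 1, i.e. standalone BLASTP defaults. Traceback ties prefer
match/mismatch over a gap in the first sequence over a gap in the second,
and gap closure over extension, so alignments are deterministic. Both DP
kernels are verified against explicit enumeration of all alignment paths on
short sequences.

Cross-proteome hits are ranked by Karlin–Altschul E-values,
`E = K·m·n·e^(−λS)`, with *n* the searched database's residue count.
`(λ, K)` are estimated once per scoring system from a maximum-likelihood
Gumbel fit to local scores of i.i.d. random sequence pairs (2,000 pairs of
length 200 by default): `λ = 1/β` and `K = e^(μ/β)/(m₀n₀)` from the fitted
location/scale at the calibration lengths. Local alignment scores of random
sequences are extreme-value distributed, so this fit reproduces the "about
one hit with E ≤ 1 per random search" semantics, which is tested directly.
The best-hit cutoff is E ≤ 1e-10 (the standalone BLASTP default used for
the cross-species searches); an absent best hit is a normal empty outcome,
logged with the best sub-threshold E.

## Progressive multiple alignment

Seed ortholog sets are aligned progressively: pairwise normalized
global-alignment distances feed a neighbor-joining guide tree, and profiles
merge at internal nodes under "once a gap, always a gap", scoring a column
pair by the expected substitution score between the two column residue
distributions (gap mass contributes zero). There is no iterative
refinement; the planted-truth test bounds what this costs — at the
benchmark's divergence, at least 95% of planted domain sites end up in
shared columns, which is all the downstream profile HMMs need.

## Profile hidden Markov models

Profiles are built from an alignment with the usual match/insert/delete
architecture. Columns with gap fraction < 0.5 become match states.
Emissions and core transitions are relative frequencies smoothed by a
fixed-weight Laplace mixture with the background (total added weight 1.0
per distribution); insert states emit the background. Search mode is
local, mirroring the default mode of modern profile-search tools: a begin
state enters any match state uniformly (1/L), every match state carries a
fixed exit probability (0.1, with the remaining mass scaled over its
M/I/D transitions; the last match state exits with probability 1), and
geometric background-emitting flanks (self-loop η = 0.95) absorb the
sequence outside the matched region. The null model is i.i.d. background
with the same geometric length law, so the reported score is the log2 odds
ratio in bits. All dynamic programming runs in log space; the Forward and
Viterbi kernels are numba-compiled and verified exactly against brute-force
state-path enumeration on small models. Viterbi ties prefer M over D over
I. Model files are a documented plain-text format (header lines plus
per-state emission/transition lines, calibration scores included); they are
HMMER3-like in spirit but deliberately not byte-compatible.

### E-value calibration

Each model is calibrated against 2,000 i.i.d. background decoys of length
200. Scores are first length-normalized by `log2(target_len/200)` — the
Forward score of a null sequence grows logarithmically with target length
because each extra residue adds alignment start points, and the shift is
empirically exact across the 100–400 residue range. The P-value curve is
then the empirical survival function of the calibration scores
(log-scale interpolation between midpoint ranks) inside the observed range.
Beyond the largest decoy score the curve continues as the universal
likelihood-ratio bound: the score is a log2 odds ratio, so
`P(S ≥ s) ≤ 2^(−s)` for any null sequence (Markov inequality), and the
continuation is that bound capped at the last empirical survival value.
This hybrid is empirically calibrated at the "one hit per search at E ≤ 1"
operating point and provably conservative at the far-tail inclusion
threshold, which is what keeps decoys out at E ≤ 0.01. A free
maximum-likelihood Gumbel fit `(μ, λ)` of the decoy scores is stored with
the model as a distribution summary. The per-search E-value is the P-value
times the number of targets searched; the inclusion threshold is the
default full-sequence value 0.01. A pure Gumbel-CDF E-value was rejected
because the Forward-score tail is exponential-with-curvature rather than
Gumbel: the ML fit's tail underestimates exceedance probabilities severalfold
at the relevant quantiles (measured during development on decoy sweeps).

## Domain annotation and the acceptance rule

Each library domain gets its own calibrated profile; a hit protein is
annotated with the best Viterbi region of every domain profile whose
Forward E-value (single target, length-normalized) passes 0.01, overlaps
resolved greedily by score. A hit is *accepted* when its annotated domain
set contains the query's domain set — containment, not equality, because
published homolog tables accept best hits that carry the query's domains
plus extras while marking (in bold) those that lack query domains. Flagged
hits propagate; they are never dropped. Strict set equality is available
behind the `rule="equality"` switch.

## Orthology, conservation, intersection

Proteomes are indexed from FASTA with terminal stop symbols stripped and
duplicate ids rejected. The reciprocal-best-hit routine takes the forward
best hit of a reference protein in another species and the reverse best hit
of that protein back in the reference proteome; the pair is reciprocal when
the reverse hit resolves to the original query after isoform collapsing
(ids ending in a lowercase letter after a digit collapse to the locus stem,
e.g. F47F6.1b/F47F6.1c → F47F6.1 — the rule is a configurable regex). The
conservation table has one row per accepted query, one column per other
species; a cell is filled only by a reciprocal (and, when a domain check is
supplied, domain-concordant) hit. The cross-phylum intersection returns
reference loci that are best hits for at least one query of each phylum set
and belong to a fully conserved row; flagged-only support excludes a locus
by default, with an `include_flagged` switch, and every excluded candidate
carries an explicit reason. Applied to the bundled published hit tables
the intersection must be run with flagged hits included to reproduce the
published seven common components, because one of the seven (the
PPARGC1a/Lark locus) is printed as domain-discordant on the mammalian side;
the accepted-only rule yields six. Both numbers are computed and tested.

## Promoter cis-element scanning

The catalog is the eight circadian elements in IUPAC syntax: E-box CACGTG,
D-box TTATGYAA, RRE WAWNTRGGTCA, GRE ACANNNTGTTCT, PPRE TGACCY, CREB
TGACGTMA, HSE NGAANNGAANNTTCN, CBP TKGNGAAK. Windows are the 3000 bp
immediately 5′ of the ATG (strand-aware; truncated and flagged at contig
boundaries). Matching is exact degenerate-word comparison against
per-position symbol sets — not regular expressions; an independent regex
implementation serves as the test oracle. A subject `N` matches only a
pattern `N` (conservative counting on masked sequence). Both strands are
scanned by default; overlapping occurrences all count; for
reverse-complement-palindromic patterns (the E-box) the mirrored
minus-strand copies are deduplicated by default. Positions are reported
relative to the ATG with −1 the adjacent base; minus-strand matches are
placed at their 5′-most base on the window strand.

## Distance phylogenetics

Distances are per-pair proportions of differing sites under pairwise
deletion, corrected by the Poisson model `d = −ln(1−p)` or the
gamma-rates generalization `d = α[(1−p)^(−1/α) − 1]`. The gamma shape is
not estimated from data; it defaults to α = 1.0 and is a config knob noted
in report headers. Trees come from the Saitou–Nei neighbor-joining
agglomeration with ties broken on the lexicographically smallest taxon-pair
key and negative branch lengths clamped to zero with the deficit moved to
the sister branch (logged). Bootstrap supports resample columns with
replacement, rerun distance + NJ per replicate, and report the percentage
of replicates containing each bipartition of the full-data tree
(mapped onto that tree, not a consensus). Concatemers join per-gene
alignment rows species-wise in sorted gene order, gap-filling species
missing from a gene. NJ is property-tested to recover additive matrices
exactly; Newick output round-trips through an independent parser.

## The synthetic study design

The generator plants everything the pipeline is later asked to find.

*Sequence level.* A domain library holds random consensus sequences
(pairwise global identity < 40%, enforced by regeneration). Each family is
an ordered pair of domains joined by linkers (8–20 residues), evolved over
a species tree by i.i.d. per-site substitution: on a branch of length *b* a
site substitutes with probability `1 − e^(−b)` to a uniformly chosen
different residue. Indels are confined to linkers (length redrawn within
range per branch), so domain coordinates remain exact truth. For two
leaves on branches *b₁, b₂* the expected per-site difference is
`1 − [(1−p₁)(1−p₂) + p₁p₂/19]` with `pᵢ = 1 − e^(−bᵢ)`, tested against
simulation within three binomial standard errors. No rate variation and no
empirical substitution matrix: only the divergence level matters for
testing search sensitivity.

*Standard benchmark.* 13 nematode-like species (the first is the
reference) × 10 two-domain families × 500 i.i.d.-background decoys per
proteome (decoy lengths 100–300). Six families also evolve seed-ortholog
clades in both query phyla (five insect-like and five mammal-like taxa),
two in one phylum each, so the planted cross-phylum common set is exactly
the six shared families. Branch lengths: nematode leaves 0.18, query
leaves 0.12, stems 0.05 expected substitutions/site, keeping every planted
ortholog pair within 0.6 substitutions/site. Protein sizes (~150–200
residues) are at the small end of real clock proteins; they were chosen
once as a realistic scale at which the 1e-10 pairwise cutoff and the 0.01
inclusion threshold behave as they do on real data.

*Genome level.* Each reference clock-gene analog gets a 3000 bp upstream
window of i.i.d. uniform bases with one planted element; genes alternate
strands. A scrub pass re-randomizes any accidental catalog-motif match
outside the planted footprints, so after scrubbing every reported match
must lie inside a planted footprint — that containment, plus exact
recovery of each planted (motif, position, strand), is the acceptance
surface. Degenerate patterns can nest (a planted RRE contains a
minus-strand PPRE word), which is why the guarantee is footprint
containment rather than set equality; self-reverse-complementary concrete
words are avoided at planting time.

*Three-clade design.* For the concatemer phylogeny, seven single-domain
families evolve over three clades of four species (stems 0.45, leaves
0.08); per-family alignments are concatenated and bootstrapped (200
replicates in the tests). The three clades must each be monophyletic with
support ≥ 95.

What the generator does not emulate: real domain length/composition
statistics, rate heterogeneity, paralogy within a proteome (except in the
constructed RBH-asymmetry test), isoforms, masked/low-complexity sequence,
and real promoter base composition. Passing tests therefore demonstrate
the pipeline's internal correctness and calibration, not field performance
on WormBase-scale data.

## Published-table data

The best-hit tables of the five query phyla (with the bold
domain-discordance markup preserved as a status column) and the
conservation matrix of the seven common components across the 13 nematode
species are bundled as TSV, transcribed from the published tables. They
exercise the report renderer (E-values printed as uppercase scientific with
two decimals, e.g. `2.10E-30`; absent hits as `None`) and the intersection
logic on real data. The published per-species hit lists behind the
"thirteen mammalian / thirty-two insect conserved hits" counts live in
supplementary spreadsheets that are not part of the paper body, so those
two counts are not recomputed here; the seven-component intersection is.

## Problem sizes and determinism

Every stochastic component takes one integer seed through a single
`numpy` generator per call; two runs with the same config are
byte-identical on all non-log artifacts, and the pipeline's manifest
(config digest + output presence) lets an unchanged re-run skip every
stage. The test suite and the acceptance script use the standard benchmark
at full size (10 × 13 × 500) and scale only auxiliary checks: the
alignment brute-force oracle is exhaustive over all pairs up to length 2 on
a 4-letter alphabet and sampled (seeded) up to length 5, because literal
exhaustion to length 5 is ~10⁶ pairs of exponential-cost enumerations;
bootstrap uses 200 replicates in tests (1000 is the pipeline default);
decoy-search calibration uses 36 searches of 200-decoy proteomes.
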
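# Methods

This note documents the models and procedures implemented in `plantkinome`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data does and does not emulate.

## Kinase identification and classification

A protein is a *typical* protein kinase when at least one hit to the
Pkinase or Pkinase_Tyr domain model satisfies both an E-value ceiling
(default 10⁻¹⁰) and a minimum model coverage (default 0.5). Coverage is
measured on the **domain model** — `(hmm_to − hmm_from + 1) / model_length`
— not on the protein: "half the domain" is a statement about how much of
the kinase fold is present. Proteins failing the coverage rule are treated
as atypical (likely pseudogenes or fragments) and excluded. The number of
kinase domains per protein is the size of a greedy non-overlapping tiling
of passing hits, visited in ascending E-value; overlap is judged on protein
(envelope) coordinates so a region hit by both Pkinase and Pkinase_Tyr
counts once. One protein per gene is kept: maximal residue length, ties
broken by lexicographically smallest id for determinism.

Subfamily classification scores the kinase-domain region against a profile
set: per subfamily a log-odds position-specific score matrix (PSSM) over
the 20-letter alphabet, evaluated on every ungapped window. The best
profile is assigned only if its score reaches the profile's threshold
(default 100 bits-equivalent; a random 180-residue window scores far below
zero) **and** beats the runner-up by a margin (default 50). Anything else
is "Unknown" — the conventional bucket for kinases that match the domain
but no curated subfamily. The threshold-plus-margin rule replaces
phylogenetic validation, which is out of scope here; both values are
configurable per profile in the manifest. An adapter
(`profiles.score_with_hmms`) scores true profile HMM files through pyhmmer
when curated HMMs are available instead of PSSMs.

The built-in profile set contains ten subfamilies spanning the major plant
kinase groups (RLK-Pelle ×4, CMGC, CAMK, CK1, STE, TKL, AGC), each with an
independent random consensus generated from a fixed internal seed. Real
subfamily profiles are far more structured; the built-in set exists so
classification logic is exercised at desk scale with unambiguous truth.

## Cross-assembly merge

Greedy incremental clustering in CD-HIT's style: sequences sorted by
descending length; each joins the first cluster whose representative (the
longest member) it matches at identity ≥ 0.95 with length ratio
(shorter/longer) ≥ 0.75, else it seeds a new cluster. The identity used
for the clustering decision is **global-style** — matched residues over
the shorter sequence length (`global_identity`) — because per-column local
identity can be 1.0 for a ten-residue chance match between unrelated
proteins. `pairwise_identity` itself reports the per-column identity and
the coverage of the best local alignment (Biopython `PairwiseAligner`,
match +2 / mismatch −1 / gap −5,−1), and the product of the two is the
clustering statistic.

Retention rules: a cluster with exactly one member from each assembly
keeps the longest member (tie → lexicographically smallest id, which
prefers neither source systematically); a cluster where either source has
more than one member keeps **all** members of the larger source — a
putative duplication in one assembly should not be collapsed to the other
assembly's single copy. A tie in member counts keeps the source holding
the longest member, consistent with the single-copy rule; the choice is
ours, as no convention exists.

## Duplication detection

All-vs-all CDS similarity uses an ungapped seed-and-extend scan: exact
11-mer seeds, X-drop extension (X = 40) under the classic nucleotide
scheme +2/−3, one best HSP per diagonal per pair. Significance is the
Karlin–Altschul formula `E = K·m·n·exp(−λS)` with the published ungapped
parameters for that scheme (λ = 0.625, K = 0.41). Ungapped extension is
sufficient here because near-identical paralogs differ almost entirely by
substitutions at these identity levels; an indel-rich pair would fragment
into HSPs and fail the coverage rule, which is the conservative outcome.
The implementation is cross-checked against BLASTn on mutated copies in
the test suite.

Tandem duplication events: qualifying pairs (same chromosome, boundary gap
≤ 25 kb, identity ≥ 0.95, coverage ≥ 0.75 of the shorter CDS, E ≤ 10⁻¹⁰)
are single-linkage clustered; components of size ≥ 2 are TDEs. Distance is
measured **between nearest gene boundaries** (end of the upstream gene to
start of the downstream gene, 0 when overlapping) — well-defined for long
genes, unlike midpoints. Single linkage means a chain of ≤ 25 kb links is
one cluster even when its extremes are farther apart.

Segmental correspondences are pairs separated by > 100 kb or on different
chromosomes, tiered at identity > 0.90 / 0.75 / 0.50; tiers are nested by
construction and counted as unordered pairs. Same-chromosome pairs in the
25–100 kb dead zone fit neither definition and are reported separately as
"unclassified proximal" rather than silently dropped.

## TE association

A gene is TE-associated when some TE on the same chromosome lies within a
window (default 100 kb) of the gene, distance again between nearest
boundaries (gene intervals are GFF 1-based inclusive, TE intervals BED
0-based half-open; both are converted to half-open before comparison).
The window is anchored on gene boundaries, the inclusive reading of
"within a window from the gene". Implementation: an interval tree over
TE intervals pre-extended by the window, verified against a brute-force
all-pairs scan in the tests. Summaries report the associated fraction of
the kinome, the fraction of associated genes that are tandemly duplicated,
and the TE class composition.

## Expression

TPM per sample: `rate_i = count_i / length_i`, `TPM_i = 10⁶·rate_i/Σrate`.
Lengths are plain CDS lengths; fragment-length (effective-length)
modelling belongs to the quantifier, whose output this package consumes.
Columns sum to 10⁶ exactly up to floating point; an all-zero sample stays
all-zero and is flagged. Sample QC excludes samples whose detected
fraction (TPM > 0) falls below a configurable threshold (default 0.10 —
the criterion for "significantly low quantification" is a package choice,
as no numeric rule is standard). Replicates are combined by the arithmetic
mean; a replicate group mixing conditions or tissues is an error.
Subfamily expression is the arithmetic mean of member-transcript TPMs,
matching the node-weight convention of the networks (mean expression);
means commute with replicate averaging for equal group sizes, which the
tests verify. A presentation helper orders heatmap rows by average-linkage
clustering on Euclidean distances.

## Coexpression networks

For one condition's samples (replicate-averaged by default; "stress"
pools every `stress:*` label), subfamilies i, j are joined iff Pearson
r(i,j) ≥ 0.7. **Positive correlations only**: the edge-weight scale runs
from moderate (0.7) to strong (≥ 0.9) positive coexpression;
anti-correlation is not coexpression. Zero-variance subfamilies are
dropped from the correlation (and recorded) rather than producing
undefined r; they remain isolated nodes. Fewer than 3 samples is an error.

Hub scores are Kleinberg's HITS on the unweighted adjacency. On an
undirected graph the hub vector is the principal (Perron) eigenvector of
the adjacency matrix A. Plain power iteration on A fails to converge on
bipartite components (stars, paths), and the textbook two-step HITS
iteration on A² converges to the projection of the start vector onto a
degenerate eigenspace, not to the Perron vector — on a 3-leaf star it
returns uniform scores where the eigenvector gives (1, 0.577, 0.577, 0.577).
We therefore iterate on **A + I**, which shares A's eigenvectors while
making the Perron eigenvalue strictly dominant; iteration stops when the
L2 change drops below 10⁻¹² (cap 10,000 iterations). Scores are computed
per connected component and max-normalised within each component (so
every component with an edge has a top hub at 1.0, and the global maximum
is also 1.0); isolated nodes score 0. The tests require agreement with a
dense eigendecomposition oracle to 10⁻⁸.

Edge betweenness is Brandes' algorithm on the unweighted, undirected
graph: each unordered node pair counts once, and when several geodesics
tie, each contributes fractionally. Verified against exhaustive geodesic
enumeration on random graphs up to 30 nodes.

Network comparison requires an identical node universe and reports edge
counts, shared and per-network unique edges, isolated nodes, percent edge
loss `100·(1 − |E_stress|/|E_control|)`, and per-node hub-rank shifts.

## Protein properties and reporting

Molecular weight: sum of average (isotope-weighted) residue masses plus
one water (18.01524 Da), with the standard table recorded in the source;
the tests cross-check against an independent implementation. Isoelectric
point: bisection on the Henderson–Hasselbalch net-charge function — the
N-terminus and K/R/H contribute `+1/(1+10^(pH−pKa))`, the C-terminus and
D/E/C/Y contribute `−1/(1+10^(pKa−pH))` — which is strictly decreasing in
pH, so the root is unique; iteration stops at |charge| < 10⁻⁴ or bracket
< 10⁻⁴ pH. The default pKa table follows the EMBOSS convention; published
tables differ and shift pI by a few tenths of a unit, so the table is a
parameter. Intron count is exon count − 1 on the longest-coding
transcript.

Report percentages are `100·numerator/denominator` rounded **half-up** at
fixed per-field precision: two decimals for assembly-source composition,
one decimal elsewhere. Under these conventions every reported ratio
recomputes exactly from its printed numerator and denominator (e.g.
1,206/2,842 → 42.43%; 339/2,842 → 11.9%; 56/362 → 15.5%). Zero
denominators omit the field with a warning.

## Synthetic data: what it emulates, and what it does not

`generate_genome` builds multi-chromosome gene sets in which each kinase
protein embeds a mutated copy (5% substitution) of its subfamily consensus
between random flanks, back-translated with uniformly drawn synonymous
codons; genes carry 1–8 codon-aligned exons with 100–500 bp introns, a
fraction get a shorter second isoform (the last exon is placed after the
domain so truncation never removes it), and decoy genes (default 20–25% of
the kinase count) have no domain. Tandem arrays are planted by
copy-and-mutate of a seed CDS with **disjoint substitution positions**
across copies (⌊(1−identity)·L/2⌋ sites each, never creating stop codons),
so pairwise CDS identity equals the planted identity exactly; members are
placed at the exact requested boundary gap. Optional long-range copies on
other chromosomes plant segmental pairs. TEs are placed uniformly at a
given density with lengths 0.3–8 kb and an LTR-dominated class mix
(~88% LTR). The generator computes TE-associated genes by brute force,
independently of the interval-index implementation it is used to test.

`generate_domain_hits` gives every planted kinase isoform one passing hit
(E between 10⁻⁴⁰ and 10⁻¹⁵, model coverage 0.55–0.95) and, for a chosen
fraction of decoys, one disqualifying hit (either E above threshold or
coverage below 0.5) — so the filter's false-positive behaviour is
exercised, and with no noise the passing set equals the planted set
exactly.

`generate_expression` uses a latent-factor log-normal → Poisson model.
Per replicate group, each planted block draws a shared factor z and each
subfamily an independent ε; block subfamilies get log-signal
`a·z + σ·ε` with `a² = σ²·r/(1−r)` so the within-block correlation is
`r = a²/(a²+σ²)` (default σ = 0.1); non-block subfamilies get independent
noise of matched total variance. Gene means are exp-transformed
(200–2,000 expected counts for kinases) and counts drawn Poisson; with
σ = 0, expected counts are deterministically rounded instead, so the
zero-noise within-block correlation is exactly 1. Decoy genes act as the
background transcriptome: an order of magnitude higher expression
(2,000–20,000) with modest variability (sd 0.2), so per-sample totals are
dominated by stable background and the compositional coupling that TPM
introduces between unrelated features stays weak, as in real libraries
where kinases are a small share of the transcriptome. Replicates within a
group share the biological latents and differ only by counting noise.

Not emulated: genotype diversity across cultivars, indels and
rearrangements (all planted variation is substitutional), realistic codon
usage and GC structure, TE clustering and nesting, overdispersed
(negative-binomial) counts, batch effects, and condition-dependent block
structure (planted blocks correlate in every condition, so control and
stress networks recover the same edges and differ only by sampling noise).
Passing the planted-truth tests therefore demonstrates correctness of the
detection logic under the stated model, not performance on real genomes.

## Problem sizes and determinism

The end-to-end pipeline defaults to 6 chromosomes, 48 kinase genes (three
tandem arrays at gaps 5/8/12 kb and identities 0.98/0.975/0.97, two
long-range copies at 0.92/0.80), ~12 decoys, 2 TEs/Mbp (so the 100 kb
window associates a minority of genes rather than none or all), 30
replicate groups × 2 replicates (60 samples, 16 control groups / 14
stress), block correlation 0.9. These sizes keep every planted structure
recoverable while the whole suite runs in seconds. All randomness flows
from one `numpy.random.default_rng(seed)` per generator call; outputs are
written in sorted order, so a fixed seed reproduces every file
byte-for-byte. Genomic-anatomy stages (tandem, segmental, TE) run on the
chromosome-level assembly's gene set, the only coordinate-anchored one;
merge statistics are reported for the combined kinome.

## Known limitations

* The greedy merge depends on input order only through the deterministic
  length-then-id sort, but like the tool it mirrors it is order-greedy,
  not an optimal clustering.
* The seed-and-extend search reports one best HSP per pair; duplicated
  domains inside one CDS do not produce multiple pair records.
* Subfamily classification quality is bounded by the profile set; the
  built-in synthetic profiles are not biological.
* The pI depends on the chosen pKa table (±0.1–0.5 pH across published
  tables); molecular weights use average, not monoisotopic, masses.
* `compare_networks` assumes both networks were built over the same
  subfamily universe; comparing kinomes from different runs requires
  harmonising nodes first.
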
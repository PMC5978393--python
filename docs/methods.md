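# Methods

This note records the models, parameter choices, and numerical decisions
behind `mycoamp`, and what the synthetic-data tests do and do not
demonstrate about real sequencing runs.

## Alignment and identity

All identity decisions (clustering, read mapping, mock mapping, taxonomy
top hits) use one Needleman–Wunsch global alignment with match +1,
mismatch −1, linear gap −2, and terminal gaps penalized like internal
ones. Identity is matches divided by alignment columns, so a short
sequence aligned against a longer one pays for its overhang — the
behaviour that makes a fixed identity threshold meaningful for
variable-length amplicons. The traceback breaks ties deterministically
(diagonal, then gap-in-second, then gap-in-first) and `global_identity`
canonicalizes argument order, so identities are reproducible and
symmetric even when several optimal alignments exist. `N` is a wildcard
that matches any base at match score: reads are effectively N-free, but
the padding pre-processing mode 3′-pads reads and centroids with N, and
those columns must not count against identity, or padded reads could not
be mapped back onto their own centroids. The kernel is numba-jitted;
tests cross-check it against a plain-Python DP with the same scoring and
against Biopython's `PairwiseAligner` score.

Semi-global primer search (primer aligned end-to-end, free read flanks)
is delegated to edlib with IUPAC ambiguity codes matching their
expansions at zero cost. Edits include indels by default because
flow-based platforms produce homopolymer indels; a substitution-only
(Hamming) mode is available for strict mismatch counting. Among
equal-edit hits the leftmost is taken.

## Pre-processing

Defaults: 0 barcode mismatches, 2 primer edits, 300 bp length ceiling,
50 bp minimum insert. Barcodes are matched anchored at position 0; two
samples tying at the best distance reject the read as ambiguous rather
than guessing — a wrong guess would masquerade as tag-switching, the very
signal the pipeline later calibrates on. Three length modes share one
ceiling: `fulllength` truncates longer reads and keeps shorter reads only
when the reverse primer was found (a short read without it is an
incomplete sequence, not a short amplicon); `pad` N-pads shorter reads to
the ceiling (padding bases get Phred 2); `truncate` discards shorter
reads, kept only so the cost of the fixed-length convention can be
measured. Pair merging is an ungapped suffix–prefix scan (≥12 bp overlap,
≤5% mismatches, most-matching overlap wins, ties to the longer overlap);
disagreeing columns take the base with the higher Phred and the consensus
quality is the max of the two. Expected errors are Σ 10^(−q/10); the EE
filter (default 1.0) selects clustering input only — OTU-table counts
always come from the unfiltered demultiplexed reads, because EE grows
with read length and would otherwise bias counts against long amplicons.

## Clustering

Unique sequences are visited most-abundant first (ties lexicographic);
uniques below `min_size = 2` never found centroids, though their reads
still count through mapping. A candidate joins the *first* centroid at
identity ≥ 0.97 (inclusive); otherwise it founds a new centroid unless it
looks like a two-parent crossover of existing centroids. The chimera
test is deliberately simple: some split point leaves the left part
matching one centroid and the right part a different centroid, each at
≥99% within-centroid identity, while no single centroid explains the
whole candidate at ≥97%. Every split point is probed because the 99%
segment bar only clears at or immediately next to the true breakpoint.
This catches clean PCR crossovers — the artifact mock-based diagnostics
need to recognize — and is not a general chimera model. Read mapping
assigns each read to the best centroid at ≥97% (ties to the lowest OTU
index) and drops the rest; identical sequences are aligned once.
Rarefaction subsamples each sample column to a common depth without
replacement (multivariate hypergeometric), dropping shallower samples; it
is provided for comparability with common practice, with the caveat that
read counts do not track template abundance in the first place.

## Mock mapping, error rate, tag-switching filter

OTUs are classed against the spike-in reference by best global identity:
`mock_hit` ≥ 0.97, `mock_variant` in [0.90, 0.97), `chimera_suspect` by
the crossover test against mock references, else `non_mock`. The run
error rate is 100 × Σ(substitutions + gap columns) / Σ alignment columns
over mock hits. Tag-switching is measured in both directions:
`rate_in` = non-mock reads in the mock sample / all reads in the mock
sample; `rate_out` = mock-hit reads outside the mock sample / all
mock-hit reads. Variants and chimera suspects are excluded from both
rates (they may be artifacts rather than switched reads) but are removed
with the mock rows when filtering. The applied rate defaults to
max(in, out) — conservative; `mean`, `in`, `out` are selectable and a
user-supplied rate supports runs without a spike-in. Filtering zeroes
each cell below `ceil(rate × OTU total)`; `ceil` rather than `round` so
the filter never under-removes, and thresholds always derive from the
filter's input totals, which makes a second application a no-op.

## Taxonomy

Reference headers in the `;tax=k:…` and `k__…;p__…` dialects are
auto-detected; set ranks are truncated to a prefix (no genus without a
family). The classifier draws 32 k-mers (k = 8) with replacement from the
query's k-mer set per bootstrap, 100 bootstraps; each reference scores by
drawn-k-mer membership, ties to the smallest reference id. Rank
confidence is the fraction of bootstraps agreeing with the overall
winner, forced non-increasing down the ranks, reported to the deepest
rank at ≥0.8. These parameter values follow the conventions of k-mer
bootstrap classifiers in this field. The hybrid rule takes the alignment
top hit when identity is strictly >97% (note the asymmetry with
clustering's inclusive ≥97%, preserved intentionally); otherwise the
classifier lineage, backed off to the least common ancestor of the two
when they disagree at a rank both set. With a single classifier the
"best confidence among classifiers" clause is degenerate and reduces to
that classifier's output.

## SynMock design

Members are `SSU-tail + ITS1ᵢ + 5.8S + ITS2ᵢ + LSU-head`. The anchors
are fixed so extraction between priming sites is exact by construction:
the SSU tail carries the ITS1-F site and ends at the last base of the
ITS1 site; the 5.8S starts at the reverse-complemented ITS2 site (which
is also the ITS3 site) and ends at the last base of the fITS7 site (the
degenerate R resolved to A, still a 0-edit match for the degenerate
primer); the LSU head starts at the reverse-complemented ITS4 site.
Defaults: 12 members; ITS1 150–300 bp and ITS2 140–360 bp with lengths
spread evenly so every design contains a short (~160 bp) member —
the class of amplicon that fixed-length pipelines lose — and a long
member near the platform ceiling; GC 0.40–0.65; homopolymers capped at 5
except one planted 9 bp and one planted 7 bp run, emulating the
homopolymer content of real ITS databases; ≥10% mutual divergence over
the concatenated ITS regions. Regions are produced by constrained
rejection sampling (≤10,000 attempts per region before erroring with the
violated constraint); planted runs overwrite an interior slice with
flanks adjusted so the run cannot extend. The designer does not
reproduce any previously deposited spike-in sequences; per-member
length/GC targets are representative choices, not canonical values.

## Simulator

Per run, each template gets a multiplicative log-normal bias factor
(σ default 1.0): amplification-efficiency differences compound
geometrically over PCR cycles, so a positive heavy-tailed factor is the
natural minimal model, and at σ = 1 an equimolar 12-template community
spreads its read counts over a >3-fold range in nearly every run. Sample
compositions times bias, renormalized, parameterize a multinomial read
draw. Reads acquire substitutions (default 0.5% per base) and ±1 bp
indels adjacent to runs of ≥3 identical bases (default 0.2%); planted
error positions receive low Phred scores (8–14) and correct positions
high ones (35–40). Tag-switching is modeled as post-hoc label
reassignment of a binomial fraction of reads (default 0.1%, within the
sub-0.3% range measured on real instruments) to a uniformly random other
sample — the observable consequence of tag-switching without committing
to a mechanism; an optional dual-index mode multiplies the probability of
destinations sharing one index (off by default). `simulate_counts` is a
count-level fast path with the same bias/bleed model and no sequence
synthesis, used for table-level experiments at realistic depths
(8 × 50,000 reads) where per-read synthesis would add only runtime. The
pseudo-biological fixture (26 templates, 237–548 bp, GC 0.438–0.684, one
~96%-identical pair to stress the 97% threshold, one member with two
9 bp homopolymer runs) is synthetic: it emulates the summary properties
of a cloned-plasmid mock community, not real ITS sequences.

## What the tests show, and what they do not

Closed-loop tests demonstrate internal correctness: with zero error
rates the pipeline reproduces the simulator's count matrix exactly, and
injected tag-switching is recovered within ±50% relative error and
largely removed by filtering. The simulator omits several properties of
real runs — position-dependent quality, context-dependent error motifs,
chimera formation during PCR (chimeras are constructed explicitly in
tests instead), primer-dimer and off-target amplification, and any
relationship between template abundance and biology. Passing tests
therefore validate the algorithms against their stated models, not the
models against wet-lab reality; on real data the spike-in control itself
is the calibration instrument.

## Problem sizes

Test and acceptance experiments run at desk scale by design: 40
references for the length-mode comparison, hundreds of reads per sample
for sequence-level closed loops, count-level simulation for the
8 × 50,000 × 20-seed tag-switching experiment, and ≥500 random instances
per brute-force oracle comparison.
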
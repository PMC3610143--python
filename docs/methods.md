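# Methods

## The assay and its in-silico model

Tag-based digital gene expression counts 21-nt tags — the NlaIII anchor
`CATG` plus the next 17 nt released by MmeI — as a proxy for transcript
abundance. Because NlaIII cuts at every `CATG` but the sequencing protocol
captures the fragment nearest the 3′ poly(A) end, a transcript is expected
to contribute mostly its 3′-most productive tag. The virtual reference tag
library models digestion exactly: on each strand of each transcript, every
`CATG` with ≥ 17 nt downstream yields one tag. Sites with a truncated
downstream stretch yield nothing (MmeI cannot release a short tag; padding
would fabricate sequence). Position ranks count productive sites from the
3′ end of the strand; tags containing N are removed after ranking so the
ranks of clean tags do not shift when an ambiguous base appears upstream.

Transcript databases of different provenance are merged before digestion
under an explicit priority order (rank 1 most trusted); within a priority
level the first record wins and a warning is logged. Cross-database gene
identity is resolved through an optional identifier cross-reference table;
without one, identifiers are compared verbatim — the merge behaviour is
therefore conservative and fully auditable.

A reference tag sequence associated with exactly one gene — regardless of
how many positions inside that gene produce it — is *unambiguous*.
Ambiguity is classified on exact tag sequences at library construction;
ambiguity arising from 1-mismatch matching is resolved at mapping time,
where the full hit set of the best tier is visible.

## Filtering

The filter cascade is fixed: adaptor-containing reads, then low-quality
reads, then single-copy tags. "Low quality" is defined here as containing
N or any base below a Phred threshold (default 10); when no qualities are
supplied only the N rule applies. The threshold is deliberately minimal
and reproducible — the original vendor filters of this assay generation
were proprietary. Singleton status is evaluated on the multiset that
survives the first two filters, so "copy number 1" has a single,
well-defined meaning, and each copy-1 tag removes exactly one read. The
`FilterLedger` enforces read conservation
(`raw = adaptor + low_quality + singleton + clean`) as a class invariant,
so a bookkeeping error cannot pass silently.

Saturation analysis shuffles the read stream once with a caller-supplied
seed and scans growing prefixes — sampling without replacement, matching
the cumulative-sequencing interpretation of a rarefaction curve — rather
than repeatedly subsampling, which keeps runs deterministic per seed.

## Mapping

Clean tags are looked up in the reference with at most one mismatch
(absorbing polymorphisms between the sequenced animals and the reference
databases). The 1-mismatch tier is implemented by querying all 63
single-substitution neighbours of the 21-mer; a brute-force Hamming scan
serves as the test oracle. Precedence rules, stated because no standard
fixes them: exact hits beat 1-mismatch hits; within the best tier a single
sense gene is an unambiguous hit, a single antisense-only gene is antisense
evidence, and several distinct genes make the tag ambiguous (counted as
gene-mapped but contributing nothing to gene counts). Unmapped tags
cascade to the mitochondrial and then the nuclear genome by exact substring
match on either strand — mismatches are not extended to genomic hits to
avoid manufacturing spurious "novel transcript" positions. Gene-level
expression counts sum copy numbers of sense-unambiguous tags only.

## Differential expression

TPM = count / clean-library total × 10⁶. The clean total, not the
gene-mapped total, is the denominator; zero counts report a 0.01 TPM floor
so fold changes of presence/absence genes are defined. The floor is
applied only to zero counts.

The Audic–Claverie exact test conditions on the count x in library 1 and
evaluates the count y in library 2 under

P(y | x) = (N₂/N₁)^y (x+y)! / ( x! y! (1+N₂/N₁)^(x+y+1) ),

which is a negative binomial in y with x+1 successes and success
probability N₁/(N₁+N₂). The one-tail p is the smaller of the lower and
upper tail sums at y; the two-sided p doubles it, capped at 1. Tails are
accumulated term by term in log space (lgamma-based first term, ratio
recurrence, log-sum-exp accumulation; the infinite upper tail is summed to
numerical convergence, guaranteed by its geometric decay). Against an
exact rational-arithmetic oracle the implementation agrees to better than
1e-10 relative error across count and depth grids. One property worth
stating explicitly: because the test conditions on one library's count,
swapping the libraries changes the discrete tail boundaries; the two
directions agree exactly when x = y and within one pmf term (a factor ≤ 2
at equal depths) otherwise. The test is conservative for discrete counts —
its empirical type-I error under a simulated null sits below the nominal
level.

FDR control is Benjamini–Hochberg (step-up with enforced monotonicity, via
statsmodels). A gene is called differential only when all three hold:
p < 0.001, FDR < 0.001 and |log₂ fold change| > 2 — deliberately strict
defaults, all configurable, since published analyses of this assay family
have not always applied them consistently.

## Enrichment

Upper-tail hypergeometric p for k of n differential genes falling in a
term of K background genes out of N (scipy's survival function; exact pmf
enumeration is the test oracle). The background defaults to genes detected
in the expression data — the defensible universe for expression-dependent
enrichment — and genes without any annotation stay in N. Bonferroni
correction is applied within each category (each GO namespace, pathways),
never pooled across categories; significance at Q < 0.05.

## qPCR validation math

Technical replicates are averaged to one Ct per sample and gene
(arithmetic mean of Ct, standard 2^−ΔΔCt practice); per-sample
ΔCt = Ct_target − Ct_reference removes sample-loading effects, so a
constant shift of all of one sample's Ct values cancels exactly. The
group comparison uses a two-sided Welch t-test on per-sample ΔCt — the
safe choice at the three biological replicates per group typical of
validation panels, where equal-variance assumptions are untestable.
Amplification-efficiency correction is out of scope.

## Synthetic data

The generator emulates the study design, not any particular dataset:

- **Transcriptome** — spacer segments are drawn from {A, C, T}; because
  spacers contain no G, a `CATG` can only occur where a tag was planted,
  so each gene's sense site layout (count, order, 3′-most = rank 1) is
  known exactly and verified against the digestion code in tests.
  A configurable fraction of genes can reuse another gene's rank-1 tag to
  plant reference ambiguity.
- **Libraries** — two libraries of unequal depth, default 126,000 and
  200,000 tags over 2,000 genes. These mirror the *ratios* of a real
  two-breed experiment (depth ratio ≈ 0.63) at desk scale; magnitudes are
  three orders smaller, chosen so the full pipeline runs in seconds.
  Abundances are log-normal (σ = 1.5), reproducing the empirical pattern
  that a small minority of transcripts dominates the tag total. 200
  planted genes carry ±3 log₂ units (8-fold), split half up / half down
  and applied symmetrically (±1.5 log₂ to each library before
  renormalization); planted genes are drawn only from genes whose expected
  count exceeds 25 in both libraries, so recovery measures the test, not
  shot noise at vanishing counts. Reads are the gene's rank-1 sense tag
  with per-base substitution error (default 0.001), plus adaptor reads
  (1%) and N-containing reads (1%). The adaptor sequence is synthetic, not
  a vendor sequence.
- **Annotations / Ct tables** — random term memberships with an optional
  loaded term at a stated odds ratio; Ct tables with planted expression
  ratios and Gaussian cycle noise.

All randomness flows from a single seed through named NumPy generators;
identical config + seed reproduces every output byte for byte.

What the generator does *not* model — realistic Illumina error profiles,
PCR duplication, 3′ bias beyond the rank-1 sampling rule, incomplete
reference databases — bounds what passing tests show: they validate the
algorithms and their bookkeeping under the stated generative model, not
performance on real libraries, where mapping rates are dominated by
reference completeness.

## Numerical and scale choices

- Exact-test tails: log-space summation, ~1e-13 relative agreement with an
  exact rational oracle; two-sided by doubling, capped at 1.
- Null calibration in tests: 2,000 genes at 10⁵ tags per library; planted
  recovery: 10 seeds at the default library scale. Both complete in
  seconds; the whole suite runs in well under a minute.
- Copy-number table: the first bin is inclusive (≥ 2, restating the clean
  totals), later bins strict (> t), mirroring the conventional
  presentation.
- Degenerate inputs: empty read sets yield all-zero ledgers; an empty
  reference library is an error for mapping; a saturation step larger than
  the stream yields the single full-stream point; terms with no background
  members are skipped.
- Tie-breaks: merge ties keep the first record; equal-FDR differential
  results order by p then gene id; antisense report orders by copy total
  then gene id.
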
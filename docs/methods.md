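# Methods

## Rationale

Somatic mutation cohorts are a survivorship sample: mutations that kill the
tumor cell are not observed. Genes whose function a tumor requires should
therefore show (i) a deficit of amino-acid-changing substitutions relative to
synonymous ones (dN/dS < 1, purifying selection at the cellular level) and
(ii) a deficit of *high-functional-impact* mutations relative to what the same
gene tolerates as germline polymorphism in the population. The screen
combines these two signals with an expression requirement (an unexpressed
gene cannot be essential in that tissue) and a data-sufficiency floor.

## dN/dS estimation

**Site counting.** Expected synonymous and non-synonymous sites follow the
unweighted Nei–Gojobori (1986) scheme: each CDS position contributes one
site, split across its three possible single-nucleotide substitutions by
whether each preserves the encoded amino acid. Integer change counts are
divided by 3 only once, so the conservation identity
`n_sites + s_sites = 3 × codons` holds *exactly* in floating point. The
terminal stop codon is included (stop→stop substitutions are synonymous,
stop→sense are stop-loss); internal stops are rejected at load. A
mutation-spectrum weighting hook is deliberately absent: uncorrected NG86 is
reproducible and assumption-light, and the synthetic generator matches it
exactly (see below). Context/trinucleotide correction is a known limitation
for real UV-driven melanoma data.

**Estimator.** Per gene, ω = (n/N′) / (s/S) with n = missense SNV count,
s = synonymous SNV count. Stop gains/losses, start losses, splice variants
and indels are excluded from both counts — they have no synonymous
counterpart. For consistency, the exposure N′ is the *missense-site* count
(NG86 non-synonymous sites minus the nonsense/start-loss share and any
splice-window positions), not the full non-synonymous site count. With the
full N the estimator would be biased low by the genome-wide missense fraction
of non-synonymous changes (392/415 ≈ 0.945 under the standard code) even for
perfectly neutral data, because nonsense opportunities would sit in the
denominator while nonsense observations are excluded from the numerator.
With N′ the pooled estimator is unbiased under neutral uniform substitution —
a property the acceptance tests verify by simulation.

ω is undefined when s = 0 (no pseudocounts); undefined genes can never pass
the ω threshold. Each variant record counts once (recurrent mutations are
independent observations); per-site deduplication is available
(`estimate_dnds(..., dedupe=True)`).

**Threshold.** The negative-selection cutoff is either fixed (default 0.25)
or detected from the genome-wide histogram of defined per-gene ω values
(left-closed bins, default width 0.05 over [0, 2]): within the search window
(default ω ∈ [0.05, 0.75]) the center of the lowest-count interior bin that
is a local minimum is returned. "Local minimum" is weak — no larger than
either neighbor and strictly smaller than at least one — so a flat valley
floor qualifies; ties break toward smaller ω. If no interior minimum exists
the configured fallback (0.25) is used with an explicit warning. Detection
operates on the raw histogram, not a smoothed density, for determinism.

## High-impact fraction f

Per gene and cohort, f = #(high-impact) / #(all variants), synonymous
variants included in the denominator. High-impact means: any
insertion/deletion, stop gain/loss or splice-site variant (categorical,
score-independent), or a missense SNV with either ensemble score strictly
above the empirical 70th percentile (linear-interpolation definition) of the
scored non-synonymous SNVs. Cutoffs are derived from both cohorts pooled by
default — per-cohort cutoffs would shift the f comparison silently; the
per-cohort mode exists as a config switch. All comparisons are strict
(score = cutoff is not high-impact; f_germline = f_somatic fails depletion).
Unscored missense SNVs are conservatively not high-impact. Start-loss SNVs
are treated like missense for impact purposes.

## Expression filter

Mean expression per gene across samples; the quantile rank is
#{genes with strictly smaller mean} / (n − 1), so the lowest gene ranks 0.0
and the highest 1.0, and tied genes share a rank. Genes must rank strictly
above the quantile cutoff (default 0.20). With many genes tied near zero the
removed set can exceed 20% — intended: all-zero genes are not expressed.
Genes absent from the matrix fail the filter (unmeasured ≠ expressed). The
kept set is also the reference universe for enrichment.

## Enrichment and network

The over-representation p-value is the exact hypergeometric upper tail
P[X ≥ k], summed as integer binomial coefficients with a single final
division (no log-gamma roundoff). Set members are intersected with the
universe first; BH step-up correction is applied within each collection
source by default (globally on request). Only the upper (enrichment) tail is
tested. Note BH adjustment is order-preserving but not idempotent — that is
a property of the procedure itself, not of this implementation.

Interaction edges are undirected with scores normalized to [0, 1]
(`milli` input scale divides by 1000); duplicates keep the maximum score.
Only edges with score strictly greater than the cutoff (default 0.9) count.
A bait's preys are all its neighbors in the filtered graph, including other
baits; common-partner counts are pairwise shared-neighbor counts, and an
optional per-edge physical flag marks direct bait–bait physical links.

## Synthetic studies

The generator emulates the screen's study conditions: by default 500 genes
of 100–400 codons, 5% planted essential, Poisson(60) variants per gene per
cohort, a 374-sample log-normal expression matrix, 20 gene sets plus one
concentrated in the planted essential genes, and a scored edge list with a
high-confidence essential cluster.

**Cohorts.** Variants arise by acceptance sampling against the same codon
model the estimator uses: propose a uniform CDS position and uniform
alternative base, classify, accept synonymous proposals always and
non-synonymous proposals with probability equal to the gene's true ω (for
ω > 1 the rejection flips to the synonymous side). This matches NG86
counting by construction, so the expected observed dN/dS equals the true ω —
verified, not assumed, in the tests. Germline cohorts are neutral (ω = 1).
Indel and pre-annotated splice proposals are sprinkled at configured rates
(2% insertion, 3% deletion, 1% splice) through the same acceptance gate.

**Impact.** Damaging status is a fixed Bernoulli(0.4) property of each
candidate change, cached per site and shared between cohorts; both score
channels are drawn once per site from overlapping normals (benign μ = 0,
damaging μ = 1.5, σ = 1), so the 70th-percentile rule is an imperfect
classifier by design. Essential genes additionally retain high-impact
somatic proposals (damaging missense, nonsense, splice, indel) with
probability 0.3 — the survivorship depletion the screen is built to detect.
The ground-truth sidecar records each gene's class, true ω per cohort, an
*analytic approximation* of the expected f per cohort (using the nominal
score-mixture percentile; the realized cutoff is data-dependent), and the
expression class. The pipeline never reads the sidecar.

**What the generator does not model:** mutational signatures and
trinucleotide context, clonal structure and per-sample correlation,
copy-number events, multi-isoform transcripts, and indel left-alignment
ambiguity. Passing tests therefore demonstrate the machinery is correct and
calibrated under these idealized conditions, not that real-cohort results
are insensitive to those factors.

## Problem sizes and numerical choices

The recovery analyses use 50 genes × Poisson(200) somatic SNVs (~10,000
pooled) for pooled-ω checks and the 500-gene default study for cascade
recovery; these sizes put the binomial Monte-Carlo error comfortably inside
the asserted bounds (e.g. ±3σ ≈ ±0.21 around the 0.5 pass rate at ω = 0.25
with 50 genes). Positions are 1-based CDS coordinates on the coding strand
throughout; VCF positions follow the VCF standard, MAF positions are taken
as declared with a 0/1-based flag. The splice window is ±2 nt around a
declared exon boundary; without declared boundaries splice consequences come
only from pre-annotated input. All randomness flows through one
`numpy.random.Generator` seeded from the config, and every output table is
sorted, so identical seed + config ⇒ byte-identical outputs (manifests
record digests and basenames, never absolute paths or timestamps).

## Known limitations

Single transcript per gene; no likelihood-based (codon-model) dN/dS and no
confidence intervals on ω; no indel normalization; the fixed 0.25 fallback
threshold is a convention inherited from genome-wide tumor ω histograms and
should be re-examined per dataset (use `dnds_threshold="auto"`); enrichment
universes assume the expression-filtered gene set is the right reference,
which understates bias if gene sets are annotated on a different universe.
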
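# Methods

This note documents the models and procedures implemented in `flyseed`,
the defaults they use, and the choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Canonical sites and seed families

A miRNA's family key is its nucleotides 2–8; miRNAs identical over this
7-mer target the same sites.  The six canonical site types are the
perfect 6–8-nt Watson–Crick matches to the 8-nt seed region, written on
the target strand 5′→3′: 8mer (match to nt 2–8 plus a 3′-terminal A),
7mer-m8 (match 2–8), 7mer-A1 (match 2–7 plus A), 6mer (match 2–7),
offset-6mer (match 3–8) and 6mer-A1 (match 2–6 plus A).  The A of the
A1 types is required in the *target*, irrespective of miRNA nucleotide 1,
reflecting the dedicated adenosine pocket of Argonaute.

One locus yields one site: a candidate whose interval is contained in a
higher-priority candidate's interval (priority 8mer > 7mer-m8 > 7mer-A1 >
6mer > offset-6mer > 6mer-A1) is suppressed, so the 7mer-m8 inside every
8mer is never double-counted.  Ambiguity codes never pair, so `N`s can
never create a site.  Coordinates are 0-based half-open internally and
1-based inclusive in report output.

The `other_sites` census counts 8mer sites in the 5′ UTR and ORF plus
6mer/offset-6mer/6mer-A1 sites in the 3′ UTR — the weak sites that are
not scored directly by the context model but still predict repression.

## Representative transcripts and expression filtering

Per gene, the representative isoform has the longest ORF; ties break by
longest 3′ UTR, then longest 5′ UTR, then lexicographic transcript id so
the choice is order-independent.  Its 3′ UTR is replaced by the longest
3′ UTR among isoforms sharing the same stop codon.  Genes enter the
analyses only when mock-condition expression strictly exceeds 5.0 FPKM
("exceeds" is read as a strict inequality; the boundary value is
excluded).

## Context features

Seventeen features describe each (site, mRNA) pair: site type, the
target nucleotides opposite miRNA positions 9 and 10, local AU content
(unweighted A/U fraction of the up-to-30-nt flanks, site excluded,
truncated at UTR ends), the pairing-based 3P_score, the thermodynamic
3P_energy, structural accessibility SA, *P*<sub>CT</sub>, log₁₀ region
lengths (with +1 inside the log), region AU fractions, log₁₀ distances
of the site to the stop codon and to the nearer 3′ UTR boundary (floored
at 1 nt before the log), and the `other_sites` count.

**3P_energy** is the duplex free energy of (upstream target window +
seed match) against (miRNA seed region + a 3′ miRNA segment) minus the
seed-only duplex energy, isolating the 3′-supplementary contribution.
Defaults: miRNA segment starting at position 13, length 5 (nt 13–17),
9-nt target window; the window truncates at the UTR start.  **SA** folds
the 80-nt region centred on the seed match (truncated at UTR
boundaries) and reports log₁₀ of the *mean per-base unpaired
probability* over a 25-nt window centred on the nucleotide pairing
miRNA position 7.  The mean-of-probabilities reading was chosen over
"probability the whole segment is unpaired" (both readings circulate for
this score); the window mean matches the accessibility score's use as a
per-site average and keeps the feature finite for structured segments.

Both window parameterisations are recoverable by the grid-search
optimisers (`optimize_pairing_window`, 11 × 10 × 17 combinations over
start 9–19, length 4–13, window 4–20; `optimize_sa_window`, 41 × 25 over
centre −20…+20 and width 1–25), which score each combination by the
partial correlation between the feature and repression, controlling for
site type.

Backends are pluggable contracts: production uses ViennaRNA
(`RNA.duplexfold` for duplex energies; partition-function base-pair
probabilities for accessibility), while tests use deterministic toy
backends (−1 kcal/mol per Watson–Crick pair in the best gapless
antiparallel alignment; constant unpaired probability) whose outputs are
exactly predictable by hand.

**3P_score** retains the older pairing-based scheme as a secondary
feature: the best contiguous complementary run between miRNA nt 9+ and
the upstream target region, weighting pairs at nt 13–16 by 1.0 and
others by 0.5, minus 0.5 per nucleotide of loop asymmetry beyond 2.

Sites of poorly conserved families, and sites overlapping annotated ORF
sequence, carry *P*<sub>CT</sub> = 0.

## Conservation

**BLS.**  The branch-length score of a motif occurrence is the total
branch length of the minimal subtree connecting the reference species
and every species whose orthologous alignment columns, after gap
removal, still contain the motif (a same-type site for the same family;
no positional slack beyond those columns — the strictest reading, with
slack configurable upstream).  An occurrence present only in the
reference scores 0; one present everywhere scores the total tree length.

**Bins and bin trees.**  UTRs are split into five bins by the median
per-nucleotide BLS of their reference nucleotides (bin 1 = least
conserved background).  Branch lengths are re-estimated per bin on the
fixed species topology by maximum likelihood under a single-rate
Jukes–Cantor model (Felsenstein pruning over pattern-compressed columns,
gaps as missing data, L-BFGS-B over branch lengths).  Richer
substitution models are out of scope; simulation tests recover planted
branch lengths within 10% on 10-kb alignments and scale linearly with
the substitution rate.

**Signal:background.**  For a family and site type, the signal at a
branch-length cutoff is the number of sites whose BLS reaches it; the
background is the mean conserved fraction of 50 length-matched control
k-mers times the site count, accumulated per bin and summed.  Controls
are the k-mers nearest to the site in expected conservation — the
product of genome-aggregated per-dinucleotide conservation rates over
the k-mer's dinucleotides — excluding canonical sites of any conserved
family.  The background SD is the empirical spread across the 50
controls, and the 5% lower confidence limit is the one-sided z-bound
`signal_above − z₀.₉₅·SD`.

***P*<sub>CT</sub>.**  The probability of conserved targeting at a
site's BLS *b* is max(0, (S(b) − B(b))/S(b)) on its (family, type, bin)
curve, smoothed by isotonic regression to be non-decreasing in BLS and
evaluated as a right-continuous step function; BLS below the lowest
cutoff scores 0, as does a missing curve (with a warning).  The exact
smoother behind the published genome-scale curves is not reproduced;
isotonic regression was chosen as the minimal monotone smoother.
Aggregate *P*<sub>CT</sub> over the 7–8-nt sites of one family in one
UTR is 1 − Π(1 − pᵢ), never below the largest individual score.

**Conserved-gene counts.**  The simulation draws the number of
preferentially conserved 5′ and 3′ UTR sites from N(840, 40) and
N(12285, 214), samples that many sites without replacement from
gene-labelled pools, counts unique genes, and reports the mean and the
5th–95th percentile interval over 1000 replicates.  Draws exceeding a
pool truncate to the pool with a warning.

## 3′ UTR isoform profiles

3′-end tags cluster greedily: positions are visited in descending
read-count order (ties by ascending coordinate, fixing the "first
encountered" rule deterministically), each seed absorbing all tags
within 30 nt.  Clusters with ≥3 total and ≥2 unique reads become poly(A)
sites, represented by their most-read position; sites within 20 nt of an
annotated poly(A) site are flagged "known".  Ends within 30 nt group
into one isoform; the longest 3′ UTR is the most distal group holding
≥1% of reads.  The profile's f(p) — the fraction of transcript
molecules whose 3′ UTR extends beyond p — weights each site's context
score by f(site end), collapsing the proximal-versus-marginal
distinction of more elaborate isoform weighting into a single inclusion
fraction.  A gene is "homogeneous" when one isoform holds ≥90% of tags.
Reference-UTR construction extends annotations using intronic cleavage
sites with ≥10 reads (never past the next annotated exon) and picks the
representative transcript by the longest ORF among those with ≥60% of
the gene's maximum tag count, falling back to the longest UTR when UTR
intervals of one gene overlap.  Cross-sample normalisation scales counts
to tags-per-million before pooling (the exact published per-sample
normalisation is unspecified; TPM is the conventional choice).

## Normalisation and the context model

Shared variation across transfection experiments (batch effects,
de-repression of endogenous-miRNA targets) is estimated by partial
least-squares regression of each experiment on the others, fitted only
on genes without a cognate site, and subtracted from all genes (default
2 components).  Remaining covariate structure is removed by OLS of fold
changes on seven gene-level features (three region lengths, three
region AU contents, log expression), again fitted on no-site genes only.
Each experiment is then quartile-rescaled onto the pooled quartiles —
an affine, order-preserving map that makes global repression strength
comparable without being driven by outliers.

Features are scaled so the training 5th–95th percentile range maps to
[0, 1]; the fitted spec is persisted (JSON) and re-applied verbatim at
scoring time, making coefficients comparable in magnitude.  (The scaling
constants of the published genome-scale model were not transcribed; the
percentile map is this package's documented stand-in and is persisted so
scoring is reproducible regardless.)

Feature selection runs bidirectional stepwise regression from the
intercept-only model, scored by AIC, over bootstrap samples that each
draw 70% of the single-site mRNAs from every experiment without
replacement (direction is a package choice; the criterion is AIC).  The
robust set is the features selected in ≥90% of bootstraps.  Note that
on any *single* dataset, stepwise selection faithfully tracks chance
correlations, so null checks of the 90% rule average frequencies over
replicate datasets.

The context model is one least-squares fit per 7–8-nt site type over
the robust features; the per-type intercepts absorb the site-type
effect.  Predicted scores are capped from above at −0.03, −0.02 and
−0.01 for 8mer, 7mer-m8 and 7mer-A1 sites, giving a piecewise-linear
score that never rewards a site with a predicted *de*-repression.  Site
scores are multiplied by their isoform weights and summed per (gene,
family) into the cumulative weighted context score; percentile ranks
run from 100 (most negative in the family) downward.  A 6mer-model
variant applies the same machinery to mRNAs that lack 7–8-nt 3′ UTR
sites but carry at least one weak site, scored additively and uncapped.
Cross-validated evaluation holds out one transfection dataset at a time.

## Evaluation

Partial correlations residualise both variables on one-hot site-type
indicators before the Pearson correlation (reducing to plain Pearson for
a single type).  Site-type efficacy is compared to the no-site
distribution by the one-sided two-sample K–S test, and the "minimal
fraction of sites conferring destabilisation" is the maximal vertical
displacement of the site-containing CDF above the no-site CDF.  The
benchmark computes, at each sliding threshold t, the per-miRNA mean fold
change of its top-t predictions (skipping miRNAs with fewer than t) and
plots the mean of available means, against a 95% resampling band of
random gene draws without replacement and two baselines: all mRNAs with
any cognate canonical 7–8-nt 3′ UTR site, and those whose sites pass the
per-type conserved-BLS cutoffs 1.0 / 1.6 / 1.6.  Per-threshold
differences between algorithms use the one-sided Wilcoxon rank-sum test
(exact below 50 per group).  The explainable-variance ceiling is one
minus the ratio of predicted-target fold-change variance in non-cognate
versus cognate transfections, clamped to [0, 1].

## Synthetic worlds

The generator emulates the fly-scale regime: log-normal 3′ UTR lengths
with median 202 nt (σ = 0.55), ~60% AU content, log-normal 5′ UTRs
(median 120 nt) and ORFs (median 1200 nt, multiple of 3), six
transfected miRNAs with distinct seed families, planted site effects
following the efficacy hierarchy (−0.45 / −0.30 / −0.18 log₂ for 8mer /
7mer-m8 / 7mer-A1; ≈−0.06 for the 6-nt types), Gaussian noise
(SD 0.25), a rank-one batch component (SD 0.15) and a small
3′-UTR-length covariate bias (0.08 per log₁₀ unit).  Background
sequences are scrubbed of accidental canonical matches before planting,
so truth tables list exactly the sites a scan should find (closed-loop).
Alignments evolve outward from the reference leaf of a five-species tree
under Jukes–Cantor substitution (no indels), with planted-site intervals
copied unchanged across each edge with probability 0.95 (purifying
selection); 3′-end tags place 1–3 tandem ends per gene with Dirichlet
fractions.  One integer seed drives all sub-generators through fixed
stream indices, so outputs are byte-identical across runs.

What the generator does *not* emulate: indels and alignment error,
non-canonical sites, miRNA-specific target-site abundance or
seed-pairing-stability effects, correlated expression structure, and
sequencing artefacts in 3′-end data.  Passing recovery tests therefore
demonstrates correctness of the implementation under the stated model,
not performance on real fly data.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: classifier–
oracle equivalence on 1000 random 300-nt sequences × 6 miRNAs;
branch-length recovery on 10-kb alignments; coefficient recovery on
2000 single-site rows over 20 replicates; stepwise selection with 200
bootstraps over 3 replicate datasets; *P*<sub>CT</sub> separation over
20 simulations of 30 planted UTRs; benchmark separation on a 900-gene
world up to threshold 50.  Degenerate inputs are handled explicitly:
empty site lists yield empty curves, zero-background ratios are NaN
(undefined rather than infinite), distances floor at 1 nt before logs,
constant features are rejected at scaling time, and draws exceeding
sampling pools truncate with a warning.  Log-likelihood optimisation
bounds branch lengths to [1e−8, 10] and rescales partial likelihoods to
avoid underflow.

## Known limitations

The published genome-scale coefficients and scaling constants are not
bundled, so absolute context scores are not comparable to the published
score tables — rankings and all structural behaviour (caps, weighting,
aggregation) are.  The ORF-site census uses transcript-space
annotations; genome-space liftover is out of scope.  The benchmark
ingests external algorithms' predictions as plain ranked TSVs and makes
no attempt to regenerate them.
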
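# Methods

## The annotation problem and the family-query model

N-acyl lipids condense an amine headgroup with a fatty acid Cn:d through an
amide bond. Under positive-mode collision-induced dissociation the amide
bond cleaves and charge stays on the amine side: the spectrum is dominated
by headgroup product ions, while the complementary acylium ion is weak or
absent. Two consequences drive the design:

1. all conjugates of one headgroup share essentially the same fragment
   pattern, differing only in precursor m/z; and
2. no chain-side fragment can be required of a query, so chain identity is
   carried entirely by the precursor.

A headgroup's query is therefore a conjunction: the precursor must fall
within tolerance of one member of the theoretical [M+H]+ inclusion list for
that head's chain series, and *every* diagnostic headgroup fragment must be
present above its relative-intensity floor. Annotation is at the molecular
family level (`head-Cn:d`); regiochemistry, double-bond position and
chain hydroxylation are out of scope, as are adducts other than [M+H]+.

## Candidate space

Chains run C2–C30 with 0–4 C=C double bonds under the validity rule
n ≥ 2d + 1 (a chain of n carbons cannot hold more than ⌊(n−1)/2⌋ double
bonds given the carboxyl carbon). This yields 29 + 28 + 26 + 24 + 22 = 129
chains per headgroup and 8,256 candidates over the 64-entry registry. The
rule is a configurable predicate on the enumerator.

Free fatty acid formula: CnH(2n−2d)O2. Condensation: head + acid − H2O.
Element masses are a curated in-module IUPAC/AME table (monoisotopic = most
abundant isotope; note ⁸⁰Se, and I = 126.904472). The precursor uses the
proton mass 1.007276 Da, not the H-atom mass; at the 0.02 Da search
tolerances used throughout, the distinction is comfortably resolved.

## The headgroup registry

`data/headgroups_synthetic.tsv` carries 64 headgroups spanning the classes
the queries target: the 20 proteinogenic amino acids, non-proteinogenic
amino acids (e.g. ornithine, citrulline, GABA, homocysteine,
selenomethionine), polyamines (putrescine, cadaverine, spermidine,
spermine), biogenic amines and neurotransmitters (histamine, dopamine,
serotonin, tyramine, tryptamine, 2-phenethylamine, ...), thyroid hormones
(thyroxine, liothyronine, 3-iodothyronamine) and other diagnostically
relevant amines (glutathione, kynurenine, glucosamine, ...).

The diagnostic fragments in the shipped registry are *computed* stand-ins,
not curated experimental ions (hence the `_synthetic` label): the
protonated free headgroup [head+H]+ plus one neutral loss (water when the
head carries oxygen, else ammonia), each with a 0.02 Da tolerance and a 1%
relative-intensity floor. Users with curated fragment lists should edit the
TSV — the registry is data, not code. Isomeric headgroups that cannot be
distinguished by MS/MS (alanine/sarcosine/β-alanine; leucine/isoleucine)
are tagged with a shared `equivalence_group`, which the FDR estimator
treats as mutual true positives.

## Similarity scoring

Intensities are square-root scaled and L2-normalized per spectrum; the
score is the summed product over a one-to-one peak pairing within the
fragment tolerance (modified cosine additionally admits pairs offset by the
precursor m/z difference, so a bare headgroup reference can be compared to
its acyl conjugates). Scores below the minimum-matched-peak count are
forced to zero, mirroring library-search settings. Pairing is greedy
best-pairs-first (candidate pairs sorted by weight product, ties broken by
peak indices); an exact maximum-weight assignment
(`pairing="exact"`, via the rectangular assignment problem) exists mainly
so tests can compare against exhaustive enumeration. Raw (unscaled)
intensities are available via `scaling="raw"`.

Two named search presets reflect the two published parameter sets this
workflow standardises on: `GNPS_LIBRARY` (cosine > 0.7, ≥6 matched peaks,
0.02 Da) for library-quality checks and `FASST` (≥4 matched peaks) for
repository-style re-search.

## Clustering and consensus

De-duplication is a deterministic greedy single pass: spectra sorted by
(precursor, identifier) join the first cluster whose consensus is within
the precursor tolerance and scores at or above the threshold (default
0.95), else seed a new cluster. Clusters below the minimum size (default 2
— a spectrum must be observed at least twice) are reported separately, not
returned. The clustering score uses **raw** intensity scaling by default:
replicate acquisitions of one compound agree in their dominant peaks, and
the sqrt compression appropriate for cross-compound matching would let
low-level background peaks erode replicate similarity. The published
clustering heuristic is approximated by its outcome contract (de-duplicate;
keep ≥2 observations), not byte-reproduced; its similarity threshold for
"identical" spectra is not published, and 0.95 is our configurable default.

Consensus spectra merge peaks within the fragment tolerance to the
intensity-weighted mean m/z with summed intensity, rescaled to a base peak
of 1; the consensus precursor is the total-intensity-weighted mean of
member precursors.

## Library cascade and FDR

`build_library` composes: run all queries → cluster matches per assigned
candidate → reference-filter the kept clusters. The reference filter uses
plain cosine against a per-candidate synthetic-standard spectrum when one
is supplied, else modified cosine against the headgroup reference
(threshold 0.7). When the headgroup reference carries fewer peaks than the
minimum-matched setting, the floor is capped at the reference's peak count
— a two-ion theoretical reference could otherwise never pass. The audit
table preserves conservation at every stage (matched + unmatched = input;
kept + discarded = formed; records ≤ kept). The raw-spectrum re-filter used
for repository matches is the same operation applied to unclustered
(spectrum, candidate) pairs.

FDR is headgroup consistency: run a query over a labeled library; a match
whose label's headgroup contradicts the query's counts as false, matches to
suspect (network-propagated) entries are excluded from the denominator, and
an empty countable match set reports "no data" rather than zero.
Iterative query refinement against a high FDR is a human loop; the package
provides the report.

## Repository evidence rules

Filters act per candidate, counting distinct files: (1) exclusion of
candidates seen in human cell lines, (2) minimum three occurrences,
(3) blank/QC fraction strictly greater than 5% removes the candidate, with
the denominator being all files the candidate occurs in. Presets: `microbe`
applies 1–3, `plant` 2–3, `food` only 3 (its reference data has no
blanks/QCs). Occurrence counting per file rather than per spectrum is a
configurable choice. Chain-length classes use standard fatty-acid
nomenclature boundaries — short ≤ C6, medium C7–C12, long C13–C20,
very long ≥ C21 — and are configurable, since usage varies across
subfields.

## Group statistics

Fold changes are log2 ratios of group medians with two zero policies:
`half_min` (zeros imputed as half the feature's smallest nonzero value,
per-feature scope — the global-minimum alternative is a config choice) and
`replicate_zero` (any zero replicate zeroes the whole group; the microbial
culture rule). Mann–Whitney U p-values are exact by full enumeration of
group splits for combined n ≤ 10 (midranks for ties; two-sided by doubling
the smaller tail, capped at 1) and tie-corrected asymptotic otherwise;
Kruskal–Wallis handles >2 groups. BH adjustment delegates to statsmodels.
Both nominal and adjusted p-values are reported. Volcano classification
uses strict inequalities (p < 0.05 and |log2FC| > 2).

## Quantification

Responses are analyte/internal-standard area ratios. Calibration fits a
degree-1 polynomial by default; degree 2 is supported since curvature at
the top of a range is common, and the fitted degree is reported. The
"correlation coefficient R" of a polynomial fit is taken as √(1 − SSres/SStot)
of the fit. LOD/LOQ follow 3.3·Sb/a and 10·Sb/a with a = mean slope and
Sb = sample sd (n−1) of intercepts over ≥3 replicate low-range linear
curves. Quantification inverts the curve (analytic for degree 1; in-range
real root for degree 2), flags below-LOQ values rather than trusting them,
and converts to per-gram amounts using a 10 mg nominal sample mass and 100%
extraction yield by default (both overridable). Recovery uses the 80–120%
pass band; RSD uses the sample standard deviation.

## Synthetic data: what it does and does not emulate

A simulated lipid spectrum holds the registry's diagnostic fragments, a
precursor-related peak, and uniform background noise. The fragment
relative-intensity *profile* is a fixed per-headgroup property (drawn once
from an RNG keyed on the config seed and headgroup name, range 0.2–1.0),
because fragmentation patterns are reproducible compound characteristics;
replicates vary only by multiplicative intensity noise (lognormal,
CV 10%), m/z jitter (sd 0.003 Da, well under the 0.02 Da tolerance) and
background peaks (≤2% of base peak, kept ≥0.1 Da away from every diagnostic
fragment position). Decoys reuse plausible precursor m/z values with
fragments displaced by ≥5× the tolerance, so they can never satisfy a query
— by construction, not by chance. Spike-in heads are restricted to
"query-safe" headgroups (unique formulas, mutually separated fragments) so
ground truth is unambiguous.

Default spike-in conditions: 20 lipids × 3 replicates + 50 decoys. Feature
tables are lognormal peak areas (median 1e6, ln-sd 1.0) over 20 features ×
20 + 20 samples, with a 4× multiplicative effect on 5 designated features,
and optional zero inflation to exercise the zero policies.

Not emulated: isotope envelopes, chimeric spectra, retention time,
instrument-dependent intensity response, correlated noise across features.
Passing spike-in tests therefore demonstrates the correctness of the
pipeline's logic and thresholds under the stated noise model — not
annotation performance on real repository data, where co-eluting isomers,
in-source fragments and metadata errors dominate the error budget.

## Numerical choices and degenerate inputs

- Tolerances are absolute Da throughout (0.02 Da default); ppm mode on
  queries is available since per-query tolerances vary in practice.
- Candidate assignment tie-break: smallest |Δm/z|, then earlier entry in
  the chain-sorted precursor list (lower n, then lower d).
- Self-similarity is clamped at 1.0 against floating-point overshoot.
- Empty spectra: an error for similarity scoring; a normal no-match for
  queries; clustering seeds a singleton.
- An all-suspect match set, a both-zero-median feature, and an empty
  spectrum stream all produce explicit "no data"/empty outputs, never
  silent zeros.
- BH adjustment is deterministic and order-preserving but (like any step-up
  procedure) not a fixed point under re-application.

## Problem sizes

Test and validation runs use desk-scale inputs chosen to exercise every
code path with tight determinism: 110-spectrum spike-in datasets, 500
random small-spectrum oracle comparisons, 100-seed power simulations
(1,500 null tests for the type-I estimate), and the full 8,256-candidate
enumeration for mass cross-checks. Repository-scale quantities (hundreds of
thousands of matches) depend on access to a spectral repository and are out
of scope; the package operates on user-supplied match tables at that scale.
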
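# Methods

This note documents the models and procedures implemented in `crmcat`, the
choices made where several reasonable definitions exist, and what the
synthetic data do and do not establish about behaviour on real data.

## Coordinates and merging

All coordinates are 0-based, half-open `[start, end)` (BED convention).
"Overlap" always means a shared base, so book-ended features (end == next
start) are *not* merged anywhere — equivalent to distance-0 merging of
half-open intervals. Non-redundant sites per TF and cross-TF catalogue
regions are the connected components of the ≥ 1 bp overlap relation,
computed by a sort-and-sweep; both operations conserve members (every input
belongs to exactly one output), are idempotent and order-invariant, and are
verified in the tests against a brute-force transitive-closure oracle.

The merged summit is the arithmetic mean of member summits rounded half-up
(`floor(x + 0.5)`), clamped into the merged interval; the clamp is only a
guard, since member summits lie inside the union. The mean absolute
displacement between the merged summit and the member summits is reported as
a catalogue statistic: for n members jittered N(0, σ²) around a true summit
its expectation is σ·√(2/π)·√((n−1)/n), which the simulator tests confirm.

## Quality metrics

The strand cross-correlation at shift d is the Pearson correlation between
per-base 5' read *counts* on the forward strand over `[0, L−d)` and on the
reverse strand over `[d, L)`, computed per chromosome and combined by
chromosome-length weighting. Implementation uses coincidence counting on
sorted positions (exact; checked against a dense-vector Pearson oracle).
The fragment peak is the argmax outside a phantom-peak exclusion zone of
read_length ± 10 bp; the background value is the minimum of the profile over
the shift range (the cited definitions do not pin "background"; the profile
minimum is the convention of the standard cross-correlation QC tools).
NSC = cc(fragment)/min(cc); RSC uses background-subtracted numerator and
denominator. Thresholds are attained at equality (≥), reading the published
cutoffs as critical values to reach; the score is the number of attained
NSC/RSC thresholds (1.05, 1.10 / 0.8, 1.0) plus one FRiP point (≥ 1%), and
retention requires score ≥ 2 and ≥ 100 peaks. FRiP counts all provided 5'
positions (no deduplication — duplicate handling upstream is out of scope).

Caveat for toy genomes: the sampling noise of cc(d) scales as 1/√L. On a
gigabase genome it is negligible and min(cc) is a stable positive baseline;
on the megabase genomes used here min(cc) sits slightly *below* zero, so NSC
is uninformative (it simply contributes no score points) and the gate's
discriminative power comes from RSC and FRiP. This is a property of small
simulated genomes, not of the metric definitions.

## Synthetic data

The generator plants: gene models (non-overlapping transcripts with exon
blocks, CDS and UTRs); regulatory sites — multi-TF modules whose members are
drawn from a randomly chosen co-binding block (inclusion probability 0.8
within the block, 0.02 outside, redrawn until ≥ 2 members) plus singleton
sites; per-dataset peaks (per-site detection probability `sensitivity`,
summit jitter N(0, 15 bp), width N(300, 30 bp) floored at 50 bp, plus
uniform false peaks); stranded reads (200 bp fragments scattered N(0, 20 bp)
around summits, sequenced from a uniformly chosen end as 36 bp reads, with a
configurable uniform background fraction); and query region sets optionally
spiked with windows on sites of chosen TFs. Defaults (2 Mb + 1 Mb genome,
20 TFs in blocks of 5, 200 modules, 3 datasets/TF, sensitivity 0.85,
10 noise peaks/dataset, 30 reads/site, 20% background) describe a small but
realistically noisy compendium; peak widths match the few-hundred-bp scale
of summit-centred ChIP-seq peaks and 36 bp/200 bp are classic single-end
library parameters.

A fraction of reads (default 5%) is emitted as a duplicated strand pair at
the same locus offset by the read length. Real libraries — including input
and failed ChIP — show this read-length "phantom" peak in the
cross-correlation profile, and RSC is discriminative precisely because the
phantom value is a stable reference: without it, cc(read length) on pure
background would be an exchangeable noise draw and the ratio would be
meaningless. The generator therefore reproduces the artefact for both signal
and background reads.

Randomness is hierarchical: a single seed feeds fixed substreams for
genome, sites, datasets (one per TF × replicate), reads and queries, so
changing one component's size never perturbs the others. All outputs are
bit-reproducible given the configuration.

What the generator does *not* emulate: sequence content and motifs,
mappability and blacklist structure, duplicate-read pile-ups beyond the
phantom mechanism, chromatin-accessibility covariance between TFs, and
peak-caller-specific artefacts. Passing parameter-recovery tests therefore
demonstrates correctness of the algorithms under the stated noise model, not
robustness to every failure mode of public data.

## Genomic localization

Each region is assigned exactly one category by its midpoint base with
precedence promoter > 5'UTR > 3'UTR > exon (CDS) > intron > intergenic;
the promoter is the 3 kb window upstream of the TSS, strand-mirrored.
Exclusive midpoint assignment is used because per-category percentage
tables require categories to partition the regions; the precedence is
regulatory-first and configurable. For resource-recovery comparisons an
element counts as recovered when ≥ 1 bp is overlapped by any catalogue
region (separate promoter definitions, e.g. −2 kb/+1 kb element sets, are
the caller's choice of input). Conservation-style score tracks are consumed
as precomputed per-base values and aggregated as summit-centred means over
±1 kb, with absent bases excluded from numerator and denominator.

## Co-localization network

The overlap p-value for a query site against a reference TF is an exact
finite placement null: every position of a query-length interval lying
wholly within a single segment of the analysis domain is an equally likely
placement, and p is the fraction of placements whose gap distance to the
nearest reference interval is ≤ the observed one (distance 0 = overlap,
1 = book-ended). The implementation is closed-form over merged interval
arrays and is tested against exhaustive enumeration; for uniformly placed
queries the p-values are calibrated (P(p ≤ α) ≈ α) provided the overlap
atom F(0) — the placement probability of touching the reference — is below
α, i.e. the reference is sparse in the domain.

The analysis domain defaults to the union of all catalogue sites padded by
10 kb: a whole-genome null would make every overlap significant, while the
padded occupied space keeps the null local. The pad and an explicit domain
are exposed as options.

Per query row of the percentage matrix, partners are called moderately /
strongly specific above Q3 + 1.5·IQR / Q3 + 3·IQR (strict inequality;
quartiles by linear interpolation, numpy default type 7). This fence rule
presumes specific partners are a *minority* of the row: if more than ~25% of
a TF's partners are genuinely co-localized (e.g. three equal co-binding
blocks in a panel), Q3 itself lands among the high values and no call can
exceed the fence. The planted-partition recovery test therefore uses six
blocks of five TFs in a 30-TF panel, where each row has 4/29 specific
partners and the rule operates as intended; users analysing panels with very
large co-binding groups should expect the IQR rule to go silent and fall
back to inspecting the matrix directly. Calls collapse to an undirected
graph (strong = weight 2, moderate = 1, both directions → stronger wins)
partitioned by weighted Louvain at resolution 0.51 with a fixed seed for
reproducible tie-breaking.

## Enrichment

The region universe is the catalogue itself (CRMs + singletons), counted at
region level: N regions, K containing the TF, n hit by the query set, k hit
and containing the TF, p = hypergeometric upper tail P(X ≥ k). "Hit" is
≥ 1 bp overlap by default; a placement-null mode (hit iff overlap p ≤ α) is
available for significance-based overlap. The universe choice is the main
divergence risk against alternative formulations (peak-level counting would
weight large CRMs more). The upper tail is computed by the survival
function, switching to log-space pmf summation below 1e-280 and flooring at
the smallest positive float so p ∈ (0, 1] always holds; exactness is swept
against rational arithmetic for all parameters with N ≤ 60. Multiple testing
uses Benjamini–Hochberg across the TF panel (none/Bonferroni selectable);
ranking ties break by descending fold then TF name.

## Saturation

For each panel size, TF subsets are drawn uniformly *without* replacement
(a selection of factors, not a bootstrap), one substream per
(size, replicate) so extending the size list never reshuffles existing
draws. "CRM count" excludes singletons by default (`--include-singletons`
reports total regions). Medians and quartiles use linear interpolation;
the smoothing line is lowess with tricube weights, fraction 0.3 and 2
robustness iterations — the medians are already low-noise, so the smoother
only guides the eye.

## Problem sizes

Tests and the acceptance script run on genomes of 0.5–10 Mb, panels of
2–30 TFs, 40–300 planted modules, and 3–53 k reads per dataset — sizes
chosen so the full suite completes in minutes on one CPU while every
statistic is still well-resolved (e.g. fragment-length recovery uses ~50 k
reads, matching the scale where the cross-correlation argmax stabilises to
±5 bp).

## Known limitations

* Very large merged regions are not re-split; if upstream peaks are broad,
  the catalogue inherits that breadth (summit-aware peak splitting belongs
  to the peak-calling stage).
* The placement null conditions on the reference set; reciprocal
  significance percentages are intentionally asymmetric.
* NSC is not a useful signal on sub-gigabase simulated genomes (see above).
* The IQR specificity rule is blind when co-binding groups exceed ~a quarter
  of the panel (see above).
* Enrichment treats regions as exchangeable; no matching on region length,
  GC or chromatin context is attempted.
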
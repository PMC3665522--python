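# Methods

## Model

The central quantity is the per-column clustering statistic for mutations
aggregated onto a protein-domain model. With *n* mutations over *L* match
columns and a column carrying *c* of them, the position-based DS-Score is

    DS(c) = −log10( 1 − F(c−1; n, 1/L)^L ),

F the CDF of Binomial(n, 1/L). This is the exact tail of the *maximum* of L
independent binomial counts; it treats the joint column counts as i.i.d.
binomials, whereas uniform placement of n mutations actually makes them a
multinomial vector with weak negative dependence. The i.i.d. form is the
definition implemented; the exact multinomial-max tail exists in the test
suite only as a simulation cross-check. Because all columns with the same
count receive the same score, the m-way tie rule holds by construction.

Hotspots are called inclusively at DS ≥ 1.6 / 1.3 / 1.0, the −log10 images of
the Fisher-scale evidence levels 0.025 / 0.05 / 0.10. Feature-based scores
distribute each annotated feature's maximum position-based score to every
column of that feature; a column in several features takes the maximum, and
the arg-max column (smallest on ties) is recorded so that every feature-kind
hotspot call can name the mutation set that produced its score.
Multi-species scores pool counts additively across species and are computed
only for domains present in both species' proteomes.

## Mapping

Hits are global domain-model alignments filtered at E ≤ 0.001 (boundary
inclusive). A protein residue aligned to a match column maps directly; a
residue inside an insertion maps to the last match column before the
insertion; an insertion preceding the first match column leaves the mutation
unmapped (logged) because no "last column" exists. Mutations are counted only
on the representative protein of each gene (longest Swiss-Prot entry, else
longest RefSeq entry, else longest overall; length ties break to the
lexicographically smallest protein id). Each mutation is distributed to
*every* filtered hit covering its position — redundant domain copies
included, by design — at most once per (domain, column). Two hits of the
same accession at different offsets (repeat domains) are treated as distinct
alignments, so one mutation can legitimately occupy two columns of one
domain.

## Conservation

Column conservation is Shannon entropy of the column's 20 amino-acid
frequencies in nats (unweighted, zero frequencies contributing zero). The
global threshold is the mean plus one *population* (divide-by-N) standard
deviation over all columns of all supplied profiles, and the conservation
comparison is inclusive (H ≤ threshold). The population-SD choice is
recorded in the entropy table's metadata header so it is auditable.
Frequencies arrive precomputed; no sequence weighting or gap-fraction
handling is applied.

## De-redundification and cross-species analysis

Hotspot calls are grouped by their canonical sorted mutation-id set; each
group is one non-redundant hotspot. The representative domain of a group is
chosen by ordering accessions case-insensitively and preferring first
hierarchy roots, then domains with feature annotation, then the first
accession outright. A yeast hotspot group links to human if any member
(domain, column) — or, for feature-kind groups, any column of the same named
feature in a member domain — carries a human mutation. The accompanying
enrichment table takes yeast-mutated domain columns as rows (hotspot /
non-hotspot) and presence of a human mutation as columns; this construction
is an interpretive choice and is documented as such. Relatability classifies
each mutation by two booleans — maps inside a shared domain; gene has an
ortholog — into both / domain-only / ortholog-only / neither.

Co-occurrence events are (human mutation, yeast mutation) pairs at the same
column of an identical domain accession. To prevent redundant domain copies
inflating the counts, candidate pairs are visited in sorted order and an
event is kept only if neither (human mutation, yeast label) nor (yeast
mutation, human label) has been used before — a deterministic greedy
realization of the rule that no protein mutation is counted twice against one
other-species label. For each label pair (H, Y), the 2×2 table is
a = H∧Y overlaps, b = H∧¬Y, c = Y∧¬H, d = remaining overlaps, tested with a
right-sided Fisher exact test (hypergeometric tail, exact).

## Synthetic data

The generator emulates the joint structure of the real inputs rather than
their content: superfamilies of `redundancy_factor` identical-length domain
copies with exactly one hierarchy root and mixed source tags; human-like
proteins with 1–3 domain instances and occasional redundant isoforms,
yeast-like proteins mostly single-domain with some domain-free; global
alignments with random insertions (including occasionally before the first
match column, to exercise that edge); features covering ~25% of columns in
contiguous-plus-scattered blocks named from a small functional vocabulary;
Dirichlet per-column frequencies with ~30% near-single-residue columns and a
broad concentration spread elsewhere, so the mean + 1 SD rule yields a
non-degenerate conserved set; orthologs for 25% of genes; and 400 mutations
per species by default — roughly a quarter placed outside domain regions
(mirroring the ~75% in-domain rate typical of curated mutation sets), the
rest uniform over domain-mapped positions plus the planted clusters and
planted co-occurring label pairs. The first `n_shared` superfamilies are
deterministically the shared ones so plan entries can target shared domains
by index. All randomness derives from one seed through per-stage substreams
in fixed order, so generation is byte-reproducible and adding a stage does
not perturb earlier draws. Labels come from small closed vocabularies so
Fisher margins stay non-degenerate at desk scale.

What the generator does *not* emulate: real sequences, real HMM score
distributions, realistic disease ontologies, domain length/abundance
distributions of real databases, or correlated mutation processes. Passing
tests on synthetic data therefore demonstrate correctness of the mechanics
and calibration of the statistic under the stated null — not performance on
real curated databases, whose absolute hotspot counts depend on database
snapshots and are out of scope.

## Numerical choices

The score is evaluated in log space: with SF = P(X ≥ c),
1 − F^L = −expm1(L·log1p(−SF)), stable when F ≈ 1; scores are capped at 300
(p ≥ 1e-300). Zero-count columns and empty domains score 0, as does L = 1
(the maximum reaches any c ≤ n with certainty). Entropy requires frequencies
summing to 1 within 1e-9 (frequency tables are written at full float
precision for this reason). Fisher tails are exact hypergeometric survival
functions. All tie-breaks (representative proteins, representative domains,
feature arg-max, co-occurrence event order) are lexicographic/sorted-order
and therefore deterministic.

## Discreteness of attainable type-I rates

The DS-Score is a function of an integer count, so its attainable tail rates
are a discrete set. At the default calibration geometry (L = 100, n = 20) a
count of 3 gives DS ≈ 1.02 (per-domain max-rate ≈ 0.10) and a count of 4
gives DS ≈ 2.37 (rate ≈ 0.004): no attainable rate falls between ~0.10 and
~0.004, so a nominal 0.05-level threshold (DS ≥ 1.3) realizes a per-domain
null hotspot rate of about 0.004 under these conditions — conservative,
not anti-conservative. The null-calibration test and the acceptance script
report the measured rate.

## Problem sizes

Default scenario: 30 superfamilies × 3 copies, 60 proteins and 400 mutations
per species. Calibration uses 2,000 null domains (L = 100, n = 20);
planted-recovery sensitivity uses 200 seeded single-domain datasets with 40%
of 50 mutations planted on one of 100 columns; the redundancy check uses one
superfamily with 120 copies. The exact-oracle comparison covers all
(n ≤ 25, L ≤ 12, c ≤ n) in rational arithmetic, and the Monte-Carlo check
uses 10^6 replicates. These sizes were chosen to make every property
measurable at desk scale with stable estimates.
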
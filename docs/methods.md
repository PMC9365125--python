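# Methods

This note documents the models behind genotax, the parameters that matter,
what the simulator does and does not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer.

## Genome model and coordinates

A genome is an ordered list of replicons (uppercase DNA over {A,C,G,T,N})
plus gene features.  All internal coordinates are 0-based half-open on the
forward strand; files keep their native conventions (GFF3 is 1-based
inclusive).  Ns are tolerated: they are excluded from G+C content, treated
as mismatches by every aligner, and fragments with more than 20% N are
discarded before ANI.  Circular replicons are stored linearized at their
deposited origin; circularity is only a topology flag (the synteny module
compares deposited rotations; an origin-rotation search is deliberately
not performed).

Whether G+C content should include plasmids is not standardized; genotax
computes it over all replicons by default.

## The synthetic-data generator

`genotax.synthetic` builds an ancestral chromosome — random background at
a configurable G+C (default 50%, configurable down to the 47–52% typical
of the group the test fixtures model) — and implants labelled genes at
non-overlapping positions: a 16S rRNA gene (1,540 bp), the four MLSA
markers (*recA* 1,062, *mreB* 1,041, *rpoA* 990, *topA* 2,592 bp), any
requested catalog genes, and generic "hypothetical protein" ORFs (default
120, 150–400 codons).  ORFs are start codon + random sense codons + stop,
so every implanted gene translates cleanly and homology-mode detection has
real proteins to find.

Descendants evolve from the ancestor by, in order:

1. **Substitutions.**  Each site flips with probability *d* exactly once
   (a Bernoulli draw on the final state, not a Poisson process), so the
   expected ancestor–descendant identity is exactly 1 − *d* and ANI
   recovery tests have sharp targets.  Hits are split into transitions and
   transversions with probability κ/(κ+1) vs 1/(κ+1) (default κ = 2
   transitions per transversion), i.e. the two-rate structure the Kimura
   2-parameter estimator assumes — K2 parameter-recovery is exact by
   construction.  *d* is capped at 0.35, beyond which K2 saturates.
2. **Gene loss.**  Symbols absent from the lineage's gene complement are
   excised (ORF removed, features shifted), the mechanism behind
   clade-unique pangenome bins and chemotype round-trips.
3. **Inversions.**  Configured intervals are reverse-complemented;
   contained features are remapped and strand-flipped; an inversion
   overlapping a marker gene logs a warning.

Indels are off by default and only minimally supported; with indels on,
alignment-free identity is no longer exactly 1 − *d*, which is why the
recovery tests run without them.

Every random draw derives from the mandatory seed (lineage streams are
split by CRC32 of the lineage id), so identical seeds give byte-identical
FASTA output.  Realized substitution counts, deleted genes, inversion
coordinates and marker positions are recorded as ground truth.

The **two-clade panel** mirrors an eight-strain study design: three
lineages patterned on the bundled *Aliamphritea* gene rows and five on the
*Amphritea* rows, descending from two clade ancestors.  Defaults:
within-clade divergence 0.02, between-clade 0.10.  The between-clade value
is chosen so protein-level divergence stays inside the 50%-identity
protein-clustering regime — at nucleotide divergence ~0.25 random codon
changes push amino-acid identity below the clustering threshold and the
panel would stop exercising the Core bin.  Each lineage also carries a
Poisson-distributed count of LysR-type regulator genes (clade means 122
and 65, matching the reported group means), drawn from clade-disjoint
symbol pools so cluster-level truth stays unambiguous.

**What the simulator does not emulate:** codon usage, selection, HGT,
duplications, rearrangements other than inversions, assembly gaps and
sequencing error.  Passing recovery tests therefore demonstrates that the
estimators are correct under their own model assumptions, not that they
are robust to every artifact of real draft genomes.

## ANI (orthologous-fragment method)

Fragments of 1,020 bp (consecutive, non-overlapping, remainder dropped)
are searched against the whole partner genome on both strands.  The search
is seeded: shared 12-mers (sampled every 4 bp) vote for diagonal offset
bands (256 bp wide), and the best three bands are verified by infix
alignment (edlib HW) of the fragment against the band window.  Identity is
matches / alignment columns.  Filters follow the orthologous-fragment
convention: identity ≥ 0.35 and alignment length ≥ 0.70 of the fragment.
Best hits are tie-broken toward the lower subject coordinate, then the
smaller replicon id, for determinism.  A fragment pair is orthologous when
each fragment's best hit lands inside the other (midpoint mapped to the
partner's fragment grid); the reported value averages both directions, so
ANI(a,b) = ANI(b,a) exactly.  Zero orthologous pairs is reported as an
undefined-metric error, never as 0.

The seeded search is tested against an exhaustive best-infix search (edlib
over the full genome, no seeding) and must agree to 1e-9.

## AAI

Reciprocal best hits between proteomes (floor: 100 proteins each,
configurable).  Candidate pairs come from a shared 6-mer prefilter and are
verified by global alignment; filters are identity ≥ 0.30 with a length
ratio ≥ 0.70 (global alignment makes the shorter sequence fully covered,
so the length ratio is the coverage criterion).  AAI = 100 × mean identity
over RBH pairs, averaged over both directions.

## in silico DDH (formula-2 style)

HSPs are found by 15-mer seeds grouped by diagonal (≥ 2 seeds per
diagonal), extended ungapped with scores +1/−2 and an X-drop of 30, split
into maximal-scoring segments, filtered at 100 bp, and de-overlapped on
the query axis keeping the higher-identity HSP.  The distance is
`d2 = 1 − Σ matches / Σ HSP length`; with the simulator's substitution-only
model this equals the per-site divergence almost exactly.

The transform to a DDH percentage is configuration
(`DdhModel(intercept, slope)`: `100 / (1 + exp(intercept + slope·d2))`,
strictly decreasing).  The published regression coefficients of the
reference implementation are not public in reusable form, so the default
(−2.0183, 23.42) is calibrated to the canonical correspondences — d2 =
0.05 (ANI ≈ 95%) maps to 70%, the species boundary, and the ~0.11 regime
(ANI ≈ 89%) maps to the mid-30s.  Agreement with the reference web
service should be assumed only to ±2 percentage points; the transform's
value at d2 = 0 (88.27) is a frozen regression fixture, and self-comparison
is asserted on the distance (d2 = 0), which is transform-independent.
HSP discovery itself is an approximation to the reference tool's
(unpublished) masking and merge rules.

## 16S similarity and the K2 model

Two 16S genes are globally aligned; columns with a gap or N in either row
are excluded; P (transitions) and Q (transversions) give
`d = −½·ln((1−2P−Q)√(1−2Q))`, undefined (saturation error) when either
log argument is non-positive.  "Similarity" is 100·(1−d) by default
because distance-corrected similarity is what modern matrix tools report;
a raw-identity mode exists because published pipelines are often ambiguous
about which of the two they print — the two differ by ≤ 0.3 points in the
98–99% range that matters for the species boundary.
`trim_to_reference_window` restricts an alignment to a 1-based window of
the ungapped reference row (the conventional 54–1390 window retains
1,337 reference bases).

## MLSA

Markers are taken from annotations by exact case-insensitive symbol match
(inputs are annotated genomes; missing or multi-copy markers are hard
errors).  Per-gene MSA is center-star: the center minimizes summed
pairwise edit distance and the others are folded in by global alignment
with gap-column merging.  The concatenation is nucleotide-level with K2
distances by default (an amino-acid mode is available), and the tree is
standard neighbor-joining (negative branch lengths clamped to 0, 6-decimal
Newick).  This replaces the external MSA/phylogenetic-network tools of
classical MLSA workflows; the claim the module is designed to test is
clade membership, which is a topological statement, so acceptance is
monophyly, not branch-length equality.  NJ is verified to recover the
generating topology of random additive matrices exactly and to match an
independent NJ implementation.

## Pangenome

Greedy incremental clustering: proteins sorted by length descending (ties
by genome then feature id); each joins the oldest cluster whose
representative aligns at ≥ 50% identity with a length ratio ≥ 0.80, else
founds a new cluster.  A shared 6-mer prefilter limits candidate clusters;
at the ≥ 70%-within / ≤ 30%-between family structure used for validation
the greedy result equals exhaustive single-linkage components.  Binning is
exact set logic (Core ⇔ presence = all genomes; clade-unique ⇔ presence =
exactly one whole clade), so it is order-invariant and Core can only
shrink as genomes are added.  Absolute cluster counts from graph-based
tools (MCL on BLAST graphs) are intentionally not reproduction targets —
they depend on external-tool parameters; the tested claims are bin logic
and clade-specific placement.  The LTTR comparison counts products
containing "LysR" (case-insensitive) and applies Welch's t (scipy backend,
Welch–Satterthwaite df), with the 3-vs-5 group design of the panel.

## Synteny and inversions

Match points are exact shared 21-mers on both strands; k-mers occurring
more than 4 times in either genome are masked as repeats; k < 11 is
rejected as spurious.  Points are chained in one pass over ascending query
position into strand-consistent monotone runs (gaps ≤ 20 kb on both axes,
runs < 5 points dropped).  Each maximal run of reverse-oriented blocks
flanked by forward blocks is one inversion event whose size is its query
span.  Replicons whose id contains "plasmid" are excluded.  Detection is
reliable for inversions much longer than the chaining gap (the acceptance
bar is ≥ 90% interval overlap for ≥ 200 kb events); events touching the
sequence ends have no flanking forward block and are not called.

## Chemotaxonomy

The catalog (`data/catalog.json`) is data, not code: families own their
symbols (uniqueness enforced), and the rule engine references them
symbolically, so users can extend the catalog without touching code.
Rules are conjunctions over presence bits (module docstring of
`genotax.chemotax` lists all of them); predictions are monotone — adding
genes never removes a predicted item — and depend only on the presence
row.  Des1–Des4 are one alternative "Δ9 desaturase" group distinguished
only in evidence; when protein sequences are available, a desaturase
lacking either histidine cluster (HXXXH, HXXHH) is demoted to
"present, function-uncertain" and does not fire the aerobic rule.  C18:1ω9c
is explicitly negated rather than merely unpredicted: the desaturase route
could formally produce it, but it is absent from the recorded fatty-acid
profiles of this group, so the engine treats the desaturases as
palmitoleate-specific.  ubiF is catalogued as accessory (flagged for user
review) since the core ubiquinone pathway is consistently described with
eight ubi genes plus ispAB.  No chain-length simulation or quantitative
fatty-acid percentages are attempted.  Transporter genes (dctMPQ, tctABC,
yejABEF) are reported as presence only — they support ecological, not
chemotaxonomic, conclusions.

Homology-mode detection takes a caller-supplied symbol→reference-protein
mapping (the package bundles no real protein sequences); each reference is
globally aligned against the proteome with identity ≥ 0.40 and length
ratio ≥ 0.70.  Desaturase homologs are treated as one family with copy
count in evidence, since per-copy delineation of such homologs is not well
defined by annotation alone.

The bundled eight-strain presence matrix (`data/strain_presence.tsv`) is a
transcription of published gene-composition tables for the two genera the
package's fixtures model; where a published figure legend and table
disagreed on a gene's carriers, the table was followed.

## Delineation

Species: same ⇔ ANI ≥ 95 or dDDH ≥ 70 (OR rule; a disagreement between
the two is flagged, never silently resolved).  Genus: AAI below 65 is
distinct, within 65–66 borderline, and only values clearly above the band
(> 66 + 1.5 margin) count as same-genus evidence — reported genus
boundaries span roughly 64–67% across studies, so a value marginally above
one study's band is still treated as borderline.  Both bands are explicit
intervals with "borderline" as an output state rather than a forced binary
call.  16S ≥ 98.7% is recorded as "species cannot be excluded by 16S
alone" and never overrides genomic metrics; the precedence between a high
16S and a low ANI is deliberately not hard-coded, only traced.  The
overall verdict ("novel species", "conspecific with X", "novel genus
candidate", "conflict") is a pure function of the per-reference rule
evaluations, and the full ordered trace is retained.

The bundled `data/pt3_metrics.tsv` is the published pairwise metric table
for the strain the workflow was designed around; values published only as
a range carry representative in-range entries (noted in the file header) —
every in-range choice yields the same verdict.

## Problem sizes and tolerances in the test suite

Divergence-recovery runs use 1 Mb genomes at d ∈ {0.01, 0.05, 0.10} over
five seeds (ANI within ±1 point of 100·(1−d); all four metrics strictly
decreasing in d).  Inversion recovery uses ten 1 Mb pairs with one to
three implanted 200–230 kb inversions at d = 0.01.  Self-identity,
chemotype round-trips (200 random catalog subsets against an
independently hand-coded rule table), K2 closed-form agreement (1e-12),
NJ recovery (50 random additive matrices, ≤ 8 taxa) and the panel
analyses run at smaller sizes.  `scripts/acceptance.py` recomputes the
same quantities at moderately reduced replication (two seeds per
divergence point, four inversion pairs, 50 chemotype subsets, 30 NJ
matrices) and writes them as JSON.

## Known limitations

- The dDDH transform is a calibrated stand-in for the reference tool's
  regression; absolute dDDH values carry the stated ±2-point caveat
  (threshold logic and monotonicity are unaffected).
- Center-star MSA and greedy clustering are deterministic approximations
  chosen for testability; they are not drop-in replacements for
  progressive aligners or MCL on real, noisy data.
- The homology detector uses global alignment, so it will miss catalog
  genes fused into multi-domain proteins.
- Synteny chaining assumes collinear backbones with isolated inversions;
  heavily rearranged genome pairs produce many small blocks rather than a
  parsimonious event history, and no rearrangement distance is computed.
- 16S similarity between two sequences is computed from their pairwise
  alignment; a multiple-alignment mode exists only via the trimming
  helper.
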
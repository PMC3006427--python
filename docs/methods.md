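# Methods

This note documents the models, conventions and numerical choices behind
`mtphylo`, and what the synthetic-data validation does and does not show.

## Reference model

Coordinates are rCRS positions (`np`), 1-based, closed intervals, retained
verbatim including the historical placeholder at np 3107; that position is
never scored or classified as a variant site. The annotation table bundles
the standard NC_012920 feature coordinates: 13 protein genes, 22 tRNAs,
2 rRNAs, and the control region spanning the origin (nps 16024–16569 plus
1–576), with HVS1 taken as 16024–16383. Real peculiarities of the molecule
are honored:

* **Overlapping genes** (ATP8/ATP6, ND4L/ND4, and the single-base ATP6/CO3
  junction) are classified against *every* containing gene; the primary call
  is the most severe (nonsynonymous > synonymous), which is conservative for
  the synonymous clock. Per-gene calls are retained in the result.
* **ND6** is the one light-strand protein gene; its codons are read on the
  reverse complement before translation (vertebrate mitochondrial code,
  translation table 2, via biopython).
* **Incomplete stop codons** (ND1, ND2, ND3, ND4, CO3, CYB end in 1–2 nt
  completed by polyadenylation): substitutions in the incomplete terminal
  codon are untranslatable, classified `coding_terminal`, and excluded from
  the synonymous-capable site set.
* RNA-gene and control-region changes are never "synonymous": the synonymous
  clock counts strictly protein-coding amino-acid-preserving substitutions
  (the stricter of the possible readings; tRNA/rRNA/control mutations are
  excluded from that clock's event count).

### The synthetic reference sequence

The true rCRS bases cannot be redistributed here, so the bundled FASTA
(`synthetic_rcrs.fasta`) is a generated stand-in — flagged synthetic in the
filename, header and docstrings — with the exact length, the placeholder
'N' at 3107, and heavy-strand base composition (A 0.309, C 0.313, G 0.131,
T 0.247). It is the deterministic output of
`reference.make_synthetic_reference_sequence(seed=16569)`, and a test pins
the file to the generator. Everything coordinate-driven (filters, motifs,
codon arithmetic, strand handling) behaves exactly as on the real molecule;
only literal base identities (hence which specific alts are transitions or
synonymous at a given np) differ. Analyses of real GenBank genomes should
substitute the real rCRS FASTA via `load_reference(path)` — the annotation
and all logic apply unchanged.

## Variant scoring and naming

Canonical names follow the field's conventions: transitions `16093`,
transversions `16518T`, insertions `2232.1A` (anchor np, sub-index, base),
deletions `249del`. Naming is injective over (np, allele, class) and
`parse_variant` inverts it. Exact-length queries are diffed positionally
(vectorized); length-divergent near-reference queries are globally aligned
with edlib and indels are placed left-aligned at the lowest equivalent np.
'N' calls are skipped with a logged warning; other ambiguity codes are
errors. De-novo multiple alignment is out of scope by design — inputs are
rCRS-coordinate sequences or variant lists.

**Site-exclusion filters.** Point indels and transversions with (anchor)
np in 16180–16193 or 303–315 are removed before tree building and dating;
transitions in those windows are kept. The scope of the indel exclusion is
grammatically ambiguous in the source description; the default here scopes
*both* indels and transversions to the two windows (published C/D trees do
display indels elsewhere), with `indels_only_in_windows=False` available to
drop indels genome-wide. The filter is idempotent and never removes a
transition.

## Haplogroup nomenclature and assignment

The nomenclature is a rooted tree whose nodes carry defining variants
(increment over the parent), optional negative markers (states that must be
*absent* — needed to encode C4e, which is recognised by four transitions
plus the lack of the 2232.1A insertion), and optional back-mutation entries
(suffix `!`) that cancel an inherited marker. The bundled fixture encodes
every clade the study text defines (C5c and subclades, C4e, D4b1a2a1a/b,
D5a3/D5a3a, …) plus the minimal connecting backbone. Backbone nodes whose
motifs the text does not state are flagged `backbone` and carry either an
empty defining set or clearly-synthetic placeholder markers; the file header
says which. Two control-region context markers (16223, 16362) are attached
at D4 so the published HVS1 motifs resolve for control-region-only profiles.

Assignment returns the most derived node whose cumulative motif is fully
present (negative markers absent). Details that matter:

* HVS1-coverage profiles are matched on control-region markers only.
* Nodes with an empty considered motif (unknowable placeholders) are never
  assigned; a profile matching nothing informative returns the root with a
  `no assignment` flag.
* When several nodes carry the *same* maximal matched motif (deep
  placeholder chains, or HVS1 projections that cannot separate clades), the
  assignment falls back to the shallowest such node / the MRCA and flags
  ambiguity — the engine never over-commits.
* Matching is motif-exact by default; `max_missing=1` tolerates one missing
  marker per node (off by default, since published assignments are
  motif-exact) and then ranks candidates by matched-marker count.

## Maximum-parsimony trees

Variants are binary characters, recoded as derived wherever a haplotype
differs from the supplied clade root (so losing a root-motif variant is a
derived state). The minimum-mutation tree is a Steiner tree in the
presence/absence hypercube; identical samples collapse into one node with a
multiplicity.

* **Compatible data** (carrier sets laminar): the unique perfect phylogeny
  is built directly from the carrier-set containment hierarchy.
* **Conflicting characters, ≤ `taxon_bound` (default 8) distinct
  haplotypes:** iterative-deepening search over laminar event families.
  Each extra event either splits a character's carriers (a parallel gain)
  or widens the gain to a superset with a nested complementary reversion
  (gain + back mutation). A minimum-vertex-cover bound on the conflict
  graph (each conflicting pair needs one of its characters modified) prunes
  the search and sets the starting budget. The first minimum found in a
  fixed canonical order (characters by carrier-set size then name, subsets
  by size then members) makes tie-breaking deterministic.
* **Above the bound:** greedy heuristic — a laminar kernel of characters
  accepted largest-first, remaining characters charged one event per
  maximal kernel clade inside their carrier set. Valid but not guaranteed
  minimal; exactness is only claimed (and tested, against an independent
  exhaustive topology/Fitch oracle) below the bound. The NNI-style
  hill-climbing originally envisioned above the bound was dropped in favor
  of this kernel construction, which is deterministic and already exact on
  compatible (infinite-sites-like) data — the regime large simulated inputs
  occupy.

Event flags follow the field's display conventions: a gain occurring on
more than one edge is parallel (`<`); an event restoring the reference
state is a back mutation (`!`). Newick exports carry the mutation lists as
edge comments; a flat edge table is also written.

Multi-allelic sites (two different derived alleles at one np across the
input) are rejected: the biallelic presence/absence model cannot represent
them on one character. They did not arise in the encoded motifs.

## Rho dating

`ρ = (1/n) Σ dᵢ` over sampled individuals (with multiplicity), `σ² = (1/n²)
Σ_b ℓ_b n_b²` over branches (Saillard estimator); for star clades this
reduces to `σ² = ρ/n`, which is verified automatically on random stars.
Events are counted per occurrence — parallel events count separately, a
back mutation counts as one event. Only substitutions count toward ρ:
indels surviving the filters appear in trees but are not clock events under
either calibration (the rates are substitution rates). The complete-genome
clock counts every substitution at 3,624 years per mutation; the synonymous
clock counts synonymous substitutions at 7,884 years per mutation. Ages are
strictly linear in ρ; the published nonlinear, selection-corrected
calibration is deliberately not implemented, so printed asymmetric
confidence bounds of that calibration are not reproduced — central ages
are. The reported range is `(ρ ∓ σ)` converted linearly and floored at
zero; no multiplier is applied to σ.

`date_all_clades` labels every sampled haplotype via the nomenclature,
takes as each clade's members the samples assigned to a label or its
descendants, roots the clade at their tree MRCA, and emits one row per
clade per clock (complete-genome row first, matching the reporting
convention of the source figures).

## Synthetic data generator

The generator's defaults define the validation conditions: star or Kingman
genealogies (msprime, haploid; the coalescent parameter is the effective
size expressed directly in year units), Poisson(branch length / clock
years-per-mutation) events per branch, transition bias ts/tv = 20 (a
realistic order for human mtDNA; the source text states no value),
optional hotspot weight multipliers, infinite sites by default. A
finite-sites mode allows repeat hits — a second hit on a derived lineage
reverts it — to produce deliberate parallel/back mutations for parsimony
tests. Synonymous-clock simulations restrict candidate sites to positions
with a synonymous alternative, which makes the 7,884-year clock testable:
simulate under it, date under it, recover the TMRCA.

One numpy Generator seeded from `seed` drives everything (the msprime seed
is drawn from that stream), and branches are visited in fixed preorder, so
a config reproduces byte-identical output.

What passing recovery tests show — and what they do not: star-genealogy
recovery at n=100 and T ∈ {5, 10, 20} ky demonstrates that scoring, tree
building and ρ conversion are unbiased under the generator's idealized
mutation process (no rate heterogeneity beyond configured hotspots, no
selection, biallelic sites, complete genomes without missing data). Real
data violate several of these — notably mutation-rate heterogeneity and
purifying selection, which is exactly why the published nonlinear
calibration exists. Note also that dating a *whole-genome-clock* simulation
with the *synonymous* clock underestimates ages, because uniform site
choice yields a synonymous fraction (~0.29 with transition bias) below the
≈0.46 implied by the ratio of the two calibrated rates on real data; the
two clocks agree on real-calibration terms, not on arbitrary synthetic
mutation spectra.

## Problem sizes used in the checks

Exactness of the parsimony search is cross-checked against the exhaustive
oracle on instances with ≤6 distinct haplotypes and ≤7 segregating sites
(500 random cases), the regime where exhaustive enumeration is itself
trustworthy; round-trip identity runs on 200 simulated genomes; recovery
uses 200 replicates per TMRCA. These sizes give stable Monte-Carlo
comparisons (3-standard-error bands) while keeping the default suite quick.

## Known limitations

* The synthetic reference's base identities are not the real rCRS; motif
  positions' actual alleles differ, so transition/transversion identity at
  a specific np does not transfer to real data (coordinates and logic do).
* Backbone nomenclature nodes without stated motifs cannot be assigned;
  profiles resolve to the nearest distinguishable ancestor.
* The greedy tree path above the taxon bound is heuristic; scores are
  upper bounds there.
* No median networks/reticulations, no bootstrap, no likelihood or Bayesian
  dating, no founder analysis, no selection correction — all deliberately
  out of scope.
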
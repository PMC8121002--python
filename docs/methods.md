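# Methods

## The screening procedure

`genescreen` implements gene-centric (binning-free) screening of a
metagenome for biosynthetic potential.  The unit of evidence is the
annotated gene record: an ORF called on an assembled contig, assigned a
KEGG Orthology (KO) identifier by an annotator such as GhostKOALA, and
linked to a taxon through its contig's classifier call (Centrifuge,
Kraken2).  Three decisions are computed per catalog product:

1. **Community completeness.**  The pooled gene complement — every gene
   symbol with at least one hit anywhere in the sample, including
   records on contigs without a taxonomy call — is tested against the
   product's requirement expression (below).
2. **Single-producer calls.**  The same test is repeated on each taxon's
   own complement at a chosen rank (species by default; any rank from
   domain to species can be screened, since lineage-level completeness
   can arise either from one genome or from rollup across related
   genomes).  Records on unclassified contigs never count toward a
   taxon, which keeps Case I calls conservative.
3. **Classification.**  Case I (single microbe) if any taxon is
   complete, else Case II (mixed community) if the pooled complement is
   complete, else Case III.  The precedence makes the three cases
   mutually exclusive and exhaustive, and Case I implies community
   completeness because a taxon's complement is a subset of the pool.

## Requirement expressions

Pathways are ordered reaction steps; each step carries a boolean
expression over gene symbols with `all` (conjunction), `any`
(disjunction, for alternative routes or isofunctional enzymes), and
symbol leaves.  A pathway is complete iff every step's expression is
satisfied, so overall completeness is a monotone boolean function of the
gene complement: adding genes can never lose a product.  Steps upstream
of each pathway's entry metabolite (aspartate, acetyl-CoA, pyruvate) are
not encoded — central metabolism (glycolysis, TCA) is assumed present in
all eubacteria.

Choices embedded in the packaged catalog:

* **Acetolactate synthase** (acetoin, 2,3-butanediol):
  `all(E2.2.1.6L, any(E2.2.1.6S, ilvM))`.  Catabolic ALS enzymes can be
  single-subunit, so `PathwayCatalog.with_relaxed_als()` (CLI catalogs
  can be edited equivalently) drops the small-subunit requirement.
* **Acetoin formation**: `any(alsD, BDH, butA, budC)` — either the
  decarboxylase or the diacetyl-reductase route; 2,3-butanediol adds a
  final `any(BDH, butA, budC)` reduction step.
* **Terpenoid backbone** (all carotenoids): `any(MVA chain, MEP chain)`
  as two `all` chains; then ispA → crtE → crtB → crtI, the β-cyclase
  crtY, crtZ for zeaxanthin, plus crtW for astaxanthin; lutein instead
  requires the α-carotene branch (`all(crtY, lcyE)`) and both CYP97 ring
  hydroxylases.  These route reconstructions follow KEGG convention and
  are documented gene-by-gene in `data/catalog.yaml` so users can amend
  them.
* **KO resolution.**  KO assignments in the catalog are packaged,
  editable data, not ground truth.  Two symbol pairs coincide at KO
  resolution (phaA/atoB = K00626, butA/budC = K03366); a hit to such a
  KO credits every mapped symbol, because a KO-based annotator cannot
  distinguish them.

## Hit numbers and the rate-limiting ratio

A symbol's hit number is the number of annotated gene records mapped to
its KO.  Whether a study's "hits" are ORF-level or read-level counts is
annotation-workflow dependent; an optional per-gene weight column lets
callers emulate read-depth weighting, and all counting honors it.

For one product, the rate-limiting ratio is min/max over the per-gene
hit numbers of its expression leaves (not per-step sums, which are also
reported).  Conventions:

* Extremes are taken over genes with *positive* counts, ties broken by
  lexicographic symbol order.  Genes of an unused alternative route
  (e.g. the mevalonate chain in a MEP-only community) carry zero hits
  that say nothing about rates, so they are excluded from the extremes.
* The ratio is **undefined** — never zero, never a division error — when
  the positive-count complement does not satisfy the pathway expression:
  a required gene with zero hits is a completeness failure, not a slow
  step.
* Quotients are rounded half-away-from-zero (exact decimal arithmetic,
  default 3 places; configurable).  This reproduces printed reference
  ratios such as 0.014 = 177/12,563 and 0.175 = 2,532/14,491 exactly.
* The ratio is invariant under uniform scaling of all counts and lies in
  (0, 1], reaching 1 exactly when all per-gene counts are equal.

Relative abundance at a rank is a taxon's share of *all* gene records
(classified there or not), so listed rows plus the remainder and
unclassified rows sum to one.

## Synthetic data generator

The generator emulates the *joined annotation structure* of a real
gene-centric workflow — taxa with designed gene complements, dispersed
per-gene hit counts, contig-mediated taxonomy, unclassified contigs —
and nothing below it: no reads, no sequences, no assembly artifacts, no
annotation error.  A design specifies taxa (lineage, abundance weight,
per-product complement as "complete" or "missing these symbols"), a
count model, and an unclassified-contig fraction.  Counts are drawn per
KO — log-uniform on [50, 15000] by default, spanning the dynamic range
observed in deeply sequenced communities (~10² to ~1.5×10⁴ hits per
gene) — and each count becomes that many single-hit gene records spread
round-robin over the taxon's contigs (3 by default).  Unannotated
background records (50 per unit of abundance weight) carry each taxon's
relative abundance.  Unclassified contigs are drawn last and removed
from the taxonomy table only, so they still feed community totals.  A
taxon designed to lack a symbol never emits any record whose KO maps to
that symbol (shared-KO safety).

The manifest is written from the same draw as the tables and records the
realized, post-stripping truth: per-symbol community and per-species
counts, the expected classification of every product, and abundance
fractions.  Passing the end-to-end recovery tests therefore shows that
parsing, joining, counting, and classification are exact on clean,
well-formed inputs; it does not validate robustness to annotation error,
chimeric contigs, or classifier disagreement, which real data exhibit
and the generator deliberately omits.

### The worked-example community

`paper_like_fixture()` is a fixed, fully deterministic community of
200,000 gene records (12 named species on 5 contigs each, plus 400
unclassified contigs) built so that published worked-example hit numbers
appear as exact pooled totals: ectA = 177, lysC = 12,563, phaA = 2,532,
phaB = 2,476, phaC = 14,491, alsD = 115.  Hit totals not individually
published were fixed once, inside the same dynamic range and consistent
with the published summary ratios: the acetolactate-synthase large
subunit is set to 25,556 (the value implied by the published minimum 115
and ratio 0.0045), and crtZ (798) and crtW (795) sit against ispA
(7,231) so that both carotenoid min/max ratios round to 0.11.  The
presence/absence pattern gives six community-complete products with
lutein absent; PHB is carried completely by three species, acetoin by
four, and 2,3-butanediol by three of those four, while the ectoine and
carotenoid gene sets are split across taxa so no single member is
complete.  Species record totals are padded with unannotated background
so the most abundant species holds exactly 1.2 % of records and the
runner-up 0.9 % (ratio 1.3).

## Numerical and engineering choices

* All counting is integer; ratio arithmetic uses exact decimals before a
  single final rounding.
* Determinism: one seeded NumPy generator per design; fixed iteration
  order everywhere; reports sort rows by catalog order or by descending
  count then name, so reruns and input row permutations are
  byte-identical.
* Degenerate inputs: an empty community warns and classifies every
  product Case III; an empty annotation *file* is an input error; a
  truncated lineage leaves a contig unclassified below its last rank;
  duplicate gene or contig ids are rejected with the offending id and
  row.
* Lineages are slotted positionally into the fixed rank vocabulary
  (domain…species); tokens beyond species are dropped.
* Test problem sizes: property suites run on communities of a few
  hundred to a few thousand records with uniform counts on [1, 30]; the
  recovery suite screens 20 random designs × 5 seeds; the worked-example
  community (200k records) is generated once per session.

## Limitations

Gene presence is not production: expression, enzyme activity, pseudogene
content, and culture conditions all intervene, and hit-number ratios are
at best a rough bottleneck indicator.  The screen inherits every
upstream bias (assembly, ORF calling, KO annotation sensitivity,
classifier database coverage).  Single-producer calls at coarse ranks
may conflate genes from different genomes within the lineage.  No flux,
thermodynamic, or yield modeling is attempted, and the packaged
carotenoid/terpenoid routes are KEGG-convention reconstructions that
users should review for their system.
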
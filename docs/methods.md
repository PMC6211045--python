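# Methods

## Scope and model of the data

The package operates strictly downstream of variant calling and
annotation. Its unit of data is one called alternate allele in one
patient (`VariantRecord`) paired with external evidence
(`AnnotationBundle`): ClinVar clinical significance, allele frequencies
in three population databases (ExAC, 1000 Genomes, ESP6500), SIFT and
PolyPhen-2 categorical predictions, the variant's position within the
coding sequence, and the length of the homopolymer tract at the site.
Multi-allelic sites are split into one record per alternate allele with
allele-specific depths; when an annotator reports several transcripts,
`most_severe_consequence` keeps the most severe consequence
(truncating/splice > missense > in-frame indel > synonymous > other,
ties broken by the longest CDS). The transcript-collapsing order is a
package convention — upstream annotators differ and no canonical
transcript set is assumed.

Missing data are first-class: every annotation field has an explicit
missing marker (empty string on disk), and no reader ever substitutes a
default for an absent value.

## QC filters

A record is excluded if any of the following fires (all comparisons
strict, exactly as the thresholds are written):

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 5.0× | exclusion when total depth < 5.0 |
| `min_vaf` | 0.20 | exclusion when alt_depth / depth < 0.20 |
| `max_homopolymer` | 8 bp | exclusion when the local single-base run > 8 |
| `exclude_synonymous` | true | synonymous changes are never triaged |

Boundary semantics follow from strictness: depth 5, VAF 0.20 and run 8
are retained. VAF is recomputed from the depths at filter time rather
than trusted from a tag, so the filter is auditable; at depth 0 the VAF
is undefined and only the depth reason fires. The homopolymer length is
the longest single-base run overlapping a ±1 bp window around the
variant start (`longest_homopolymer`); a run merely flanking the
variant counts, since slippage artifacts of amplicon sequencing arise
at tract boundaries, and N never extends a run. Whether the original
procedure measured the tract *around* or *spanning* the variant is not
determinable; the window is configurable and the choice is pinned by
boundary tests. Excluded records keep **all** reasons that fired, not
just the first.

## Rarity gate and classification cascade

Rarity (`maf_threshold`, default 0.001) is evaluated as: rare ⇔ every
*present* frequency among the three databases is < 0.001. The
permissive alternative (rare in at least one database) would pass
common alleles simply absent from one panel; the strict reading matches
the gate's purpose of excluding natural variation. An allele missing
from all three databases is treated as novel (rare) with a
`no_population_data` trace note. This predicate is monotone: lowering a
frequency can never move a variant from retained to excluded.

The cascade is an ordered decision list (first match wins), evaluated
only for records that passed QC:

1. not rare → `excluded_common`;
2. null variant at the 3′ extreme end of the CDS **and** ClinVar
   conflicting → VUS;
3. null variant → pathogenic;
4. missense + ClinVar pathogenic → pathogenic;
5. missense + ClinVar likely pathogenic → likely pathogenic;
6. missense + (SIFT deleterious or PolyPhen probably damaging) → VUS;
7. ClinVar benign / likely benign → that label;
8. otherwise → VUS (`default_uncertain`).

"Null variant" means stop gain/loss, frameshift indel, or canonical
splice donor/acceptor; non-canonical splice-region changes are `other`,
the conservative reading of grouping splice with null variants. The
"3′ extreme end" has no standard definition; it is operationalised as
the terminal 5% of the coding sequence (`three_prime_fraction` = 0.95,
strict inequality, configurable). When CDS coordinates are missing,
rule 2 cannot fire and a null variant falls through to rule 3 — failing
toward the default that null variants are pathogenic. A null variant
with a benign ClinVar assertion is still labeled pathogenic by rule 3
but carries a `warning_clinvar_benign_conflict` trace entry for review.
Free-text ClinVar strings are normalised coarsely: anything containing
"conflicting" (or asserting both pathogenic and benign) →
`conflicting`; "pathogenic/likely pathogenic" → `likely_pathogenic`;
unrecognised non-empty annotations → `uncertain`.

The cascade is total and deterministic; an exhaustive enumeration of
(consequence × ClinVar × rarity × 3′ flag × SIFT × PolyPhen) is checked
against an independently coded flat decision table in the test suite.
The cascade implements only these operational rules — it is not a full
28-criterion ACMG engine, and the manual-curation step of a real
reporting workflow is out of scope.

## Founder-deletion assay

The three-primer design is modelled with exact-match primer binding:
the forward primer binds where the template contains it verbatim, the
reverse primer where the template contains its reverse complement, and
a product forms for every (forward, reverse) site pair with the forward
start 5′ of the reverse-binding end and product length ≤ `max_amplicon`
(default 2000 bp, ordinary end-point PCR practicality). Product length
is the inclusive distance from forward-primer start to reverse-binding
end. Genotypes follow the band pattern: wild-type band only →
wild-type; both bands → heterozygous; junction band only → homozygous;
none → failed assay. Mismatch tolerance, melting temperature and dimer
formation are deliberately not modelled — the assay is presence/absence
of bands. Primer sequences are **inputs**: the published assay's primer
sequences and product sizes are not public, so the package validates the
genotyping logic on synthetic loci whose structure mirrors the design
(P1 upstream, P2 inside the deleted interval, P3 downstream, brought
within amplifiable range only by the deletion).

## Phosphosite disruption

The external kinase-rewiring predictor used in the original analysis is
replaced by a transparent, local rule over a user-supplied site table
(protein, 1-based residue, S/T/Y): a substitution at an annotated site
whose alternate residue leaves {S, T, Y} is a `site_loss`;
acceptor-preserving changes (e.g. S→T) retain the phospho-acceptor
chemistry and are not flagged (noted in the trace); substitutions
within ±`window` residues (default 5, a typical kinase-motif span) of a
site are `flanking_change`. Proteins absent from the table yield `none`
with a `no_site_data` note; a reference residue contradicting the table
yields a data-inconsistency warning rather than a flag. Flags are
per-variant independent, so results are permutation-stable.

## Cohort summarization and association

Carrier (mutational) status is ≥ 1 pathogenic or likely pathogenic
variant in any panel gene; patients with only VUS are a separate
category, never carriers. Per-gene counts are distinct patients per
gene; the allele-recurrence table is keyed by the genomic identity
chrom:pos:ref:alt (protein-level keys would merge distinct alleles),
with HGVS c. notation as a display alias; an allele is recurrent at ≥ 2
distinct carriers. Carriers are partitioned once into BRCA1/2 vs
non-BRCA shares, with priority to BRCA for a patient carrying both, so
the shares sum to 100% of carriers. Percentages are computed at one
decimal with half-away-from-zero rounding (integer display is derived
from the same rule), and every printed percentage equals its
count/denominator.

Association of carrier status with a single covariate is an unadjusted
maximum-likelihood logistic regression (statsmodels), Wald p-values,
significance at p < 0.05. Continuous covariates (age, BMI) drop rows
with missing values and report `n_used`; categorical covariates keep
"missing" as its own level with the most frequent level as reference —
the closest implementable reading of "the model used all available
data". Complete separation is detected (non-convergence, exploding
coefficient, or standard error) and flagged with an infinite odds
ratio rather than raised; a constant covariate is a degenerate-fit
error.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, not
reads: annotation fields are planted directly.

- **Group sizes**: 300 cancer cases + 27 unaffected high-risk
  individuals by default.
- **Per-gene pathogenic prevalence**: defaults mirror the study's
  carrier structure (cancer group: BRCA1 15/300, BRCA2 6/300, six genes
  at 2/300, a tail of singletons; high-risk group: BRCA1 2/27, BRCA2,
  FANCF, PDE11A, POLH 1/27 each), giving an expected pooled carrier
  fraction near 16%.
- **Planted pathogenic variants** are nulls (frameshift-heavy mix
  matching the study's 22 frameshift / 13 stop / 4 splice profile) or
  ClinVar-pathogenic missense, always with all present AFs < 0.001 and
  QC-passing depths; each gene owns a fixed recurrent allele used with
  probability 0.3 so cohorts show realistic allele recurrence.
- **Founder deletion**: a configurable fraction (default 5/17) of BRCA1
  carriers carry the founder-deletion allele, represented in the
  variant table as a fixed large-deletion record with frameshift
  consequence so carrier counting is uniform, and flagged in the truth
  table for the PCR module.
- **VUS background** (rate 0.13/patient, matching ~33 VUS patients per
  300): rare missense with at least one deleterious in-silico call and
  no pathogenic ClinVar assertion. **Common polymorphisms**
  (2/patient): missense with at least one AF ≥ 0.002. **Artifacts**
  (0.05/patient per kind + 0.10 synonymous): each violates exactly one
  QC threshold.
- **Covariates**: age from a normal(41, 7.3) truncated to [23, 69]
  (resampling), BMI by category proportions, categorical fields by the
  study's marginal proportions including missingness; carriers' mean
  age is lowered by `carrier_age_shift` (default 3.0 years — the
  original analysis reports only that the age association reached
  p = 0.04, so the shift is chosen to make a borderline-detectable
  effect at n = 300 while remaining clearly recoverable at n = 2000).
- **Streams**: per-patient RNG substreams keyed by (seed, group,
  index), so enlarging a cohort never perturbs existing patients, and
  emitted files are byte-identical across runs for a fixed seed.

What the generator does **not** emulate: read-level error processes,
haplotype/LD structure, ancestry admixture, annotation noise (the
planted ClinVar/SIFT/PolyPhen fields are internally consistent with
the intended class). Passing recovery tests therefore demonstrates the
correctness of the filtering/classification logic under the stated rule
model — not robustness to annotation disagreement or caller error in
real data.

A separate deterministic fixture reproduces the *study's* carrier
structure exactly (46 of 300 cancer-group carriers, 6 of 27 high-risk
carriers, per-gene counts, the two recurrent BRCA1 alleles at 5/17
each and the recurrent BRCA2 stop gain in 2 patients, and the clinical
covariate margins), for worked-example arithmetic. The published
per-gene lists over-count the stated group totals by 2 when the
"both groups" genes (MSR1/LIG4/PDE11A) are apportioned; the fixture
gives the group totals precedence (cancer group: MSR1 2, LIG4 1,
PDE11A 1), which also reproduces the published 24/327 BRCA and 28/52
non-BRCA partitions exactly.

## Numerical and interface choices

- Coordinates are VCF-convention 1-based, left-aligned; indel ref/alt
  strings include the anchor base.
- All flat files are tab-separated with fixed headers and empty-string
  missingness; writers are deterministic (sorted report order), so
  repeated runs are byte-identical.
- The acceptance script sizes its simulations as 200 default cohorts
  for coverage, 100 loci × 5 individuals for the founder assay, one
  n = 2000 fit for effect recovery and 1000 n = 800 null replicates for
  type-I calibration.
- Thresholds and fractions are configurable via flat YAML keys and CLI
  flags (flags win); defaults reproduce the constants above.

## Known limitations

- The cascade's VUS tier is broader than a curated study VUS list: it
  reproduces stated rules only, without manual curation or external
  prior-probability lookups.
- Likely-pathogenic is only reachable via the ClinVar missense rule;
  null variants are always labeled pathogenic (the source rules draw no
  finer distinction for nulls).
- The rarity gate treats database absence as rarity; a private
  sequencing artifact passing QC is indistinguishable from a novel
  allele at this layer.
- In-silico PCR with exact-match binding overstates assay specificity;
  real primers tolerate mismatches and may mis-prime.
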
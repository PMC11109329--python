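# Methods

## Data model

A cohort is pedigrees + a variant table + a genotype-code matrix
(variant × individual) + an annotation table. Genotypes use the alphabet
hom_ref / het / hom_alt / hemi_ref / hemi_alt / missing; hemizygous codes
are reserved for male chrX (treated throughout as non-PAR; pseudoautosomal
handling is out of scope) and chrY. Variant identity is the
`(chrom, pos, ref, alt)` key on hg19 coordinates; rsids are annotation
only. A missing genotype is never treated as carrier or non-carrier: the
individual simply drops out of every denominator.

Founders carry a `side_label` taken from the reported family history
(`tumor_side` for the lineage with brain/other tumors, `married_in` for
spouses joining from outside). The labels are input annotations, never
inferred from genotype data, because family-history narratives are the only
source for them. A founder history of non-brain tumors is still labelled
`tumor_side`: what the analysis needs is "the lineage ascertained for tumor
history" versus "the spouse lineage".

## Inheritance-side inference

For a variant's affected carriers the question is which founder lineage the
allele entered the family through. Each carrier's allele is traced upward:
the possible transmitting parents are those compatible with some valid
parental allele pair (a genotyped reference parent is excluded; a
hemizygous male receives from his mother; an ungenotyped parent whose
partner is genotyped reference becomes the obligate carrier), and the trace
recurses through non-founder transmitters until founders are reached. The
family-level side is reported only when every affected carrier's entry
point is unambiguous and all agree; otherwise it is `undetermined`. De novo
mutation is never invoked to explain a carrier child of a genotyped
non-carrier parent — the obligate-carrier interpretation is used instead.
The test suite proves this trace equal to a brute-force oracle that
enumerates all genotype assignments to ungenotyped members and checks
whether every Mendelian-consistent assignment places the allele's entry on
one founder side (pedigrees ≤ 8 members).

When both founder lineages of a family carry tumor history, or an
ungenotyped married-in spouse cannot be excluded as transmitter, the method
deliberately reports `mixed`/`undetermined` rather than guessing.

## Prioritization

All criteria are binary and combined by AND; no ranking score is invented.
Defaults: AF_fin < 0.01 (strict inequality, so a variant at exactly 0.01 is
removed); sharing required across all genotyped affected members of a
supporting family; ≥ 2 supporting families with gene-level aggregation on
(a gene qualifies through the union of its qualifying variants' families);
damaging = strict majority of available predictors, falling back to ClinVar
pathogenic at ≥ 2 review stars when no predictor scores the variant class
(frameshifts); gene relevance is a curated input flag (brain-expressed
and/or glioma-relevant), not computed. The tumor-side criterion has two
config-exposed modes: `every_determinable` (default — no supporting family
may show married-in-side inheritance; undetermined families do not veto)
and `any` (at least one family must show tumor-side inheritance). The
default was chosen because unsampled parents frequently leave a family's
side undetermined, and a variant should not be discarded for missing data
alone.

The discovery stage reuses the 0.01 Finnish-frequency ceiling (the
prioritization criterion) as its default and merges caller sets by union,
maximizing sensitivity; both are configurable. Targeted-genotyping QC
defaults to call rate ≥ 0.9 and median depth ≥ 10, config-exposed and
logged — reasonable panel-QC practice where no specific rule is mandated.

## Risk loci and polygenic scores

The PRS is the standard log-additive form `Σ dosage(risk allele) · ln(OR)`
with autosomal dosage in {0,1,2} and hemizygous male X dosage in {0,1} (one
copy, no doubling — the conservative convention, config-free but documented).
Odds ratios are user-supplied per locus; nothing is estimated from the
cohort. Affected and unaffected relatives are compared on the difference of
group mean scores with a permutation null; because family members are
related, the default scheme permutes affection labels within families,
preserving each family's label counts exactly (a pooled scheme is
available). p = (1 + #extreme)/(n_perm + 1), two-sided, deterministic under
a fixed seed, with locus-exclusion lists (e.g. dropping rs55705857).

On the reference cohort the all-loci comparison is marginal (p ≈ 0.04)
because the cohort encodes only individually documented genotypes; the
additional families in which the CCDC26 SNP was seen only in unaffected
members are not individually described and therefore absent, which inflates
the affected-side mean. After excluding rs55705857 the comparison is null
(p ≈ 0.87). The acceptance suite asserts the permutation test's type-I
error (within [0.035, 0.065] at α = 0.05 over 1000 null simulations) and
the exclusion-null.

## Detection power

For a variant present in a fraction `p` of families, sequencing `n`
families detects it under the any-family rule with probability
`1 − (1−p)^n`; at p = 0.2 and n = 4 exome families this is 59.04%. The
Monte-Carlo estimator reproduces the closed form (within three Monte-Carlo
standard errors at 10⁵ simulations) and additionally supports a stricter
rule where a carrier family counts only if all sampled affected members
inherited the allele, with the per-affected carrier probability derived
from the offspring prior (0.5 for children of the carrier founder) and the
penetrance/sporadic rates. The defaults make affection uninformative about
carriage, i.e. they model detection of an arbitrary tracked allele. A
published minimum detection power of 53% for this design rests on a power
model whose details are not available; it is recorded here for context and
the package does not assert equality with it — the implemented any-family
closed form gives 59.04% under the stated p and n.

## LOH screen

At each germline-heterozygous site the tumor vs normal ref/alt read counts
form a 2×2 table tested with a two-sided Fisher exact test (exact at the
low depths typical of FFPE material), summarised by the tumor-minus-normal
alt-fraction shift, with Benjamini–Hochberg control at α = 0.05 across the
screened loci. Fisher p-values are discrete and conservative under the
null, so null screens show, if anything, fewer than 5% raw rejections.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

* **Families** — 19 by default, 2–3 generations (40% three-generation),
  sibships of 2–5, ascertained for ≥ 2 brain-tumor cases. Families that
  cannot reach the case minimum through the penetrance model within the
  retry budget (essentially all non-carrier families at a realistic
  sporadic rate) are topped up with forced cases drawn independently of all
  genotypes — a stand-in for multiplex clustering from causes outside the
  model that leaves genotype–phenotype independence intact.
* **Causal model** — two rare missense alleles of one gene (annotated
  AF_fin 10⁻⁴), each planted heterozygous in the tumor-side founder of its
  designated family and transmitted by gene drop (fair meioses, independent
  loci, X-linked rules when flagged). Carrier penetrance f₁ = 0.6 (the
  incomplete penetrance regime the design targets); sporadic rate
  f₀ = 0.005, a realistic lifetime brain-tumor probability.
* **Background** — 10⁴ variants on a log-uniform allele-frequency spectrum
  over [10⁻⁴, 0.5], 79% protein-altering, per-predictor damaging-call error
  rate 0.1 and 5% unavailable calls, half of genes flagged brain-expressed,
  genotypes by Hardy–Weinberg founders + gene drop. Loci are independent:
  no LD, recombination maps or sequence context (they play no role in the
  per-variant analysis under test).
* **Risk loci** — one common locus at frequency 0.09 with OR 3.4 by
  default. Genotype missingness 2%; optional genotype-error rate (0 by
  default) for QC testing.

What passing the synthetic suites shows: correct Mendelian bookkeeping,
side tracing, criteria logic and recovery behaviour under the assumed
generative model. What it cannot show: robustness to caller artefacts,
population stratification, annotation errors correlated with genotype, or
LD between candidate and background variants.

Recovery under these conditions is limited by phenocopies: a sporadic case
in a carrier family breaks the all-affected sharing criterion, which with
two carrier families puts expected recovery near the 95% acceptance line
(measured 95.5% over the 200 fixed-seed simulations of the acceptance
suite, with zero false candidate genes in all runs).

## Reference cohort

`build_paper_fixture()` encodes twelve documented multiplex families with
the genotypes, annotations (allele frequencies, predictor calls, CADD,
conservation, domains) and risk-locus panel needed to reproduce the
worked-example numbers exactly; its docstring lists which coordinates are
verbatim and which are synthetic placeholders, and the family-level
allocation chosen for the four not-individually-described rs55705857
carriers (two heterozygotes each in families E and L, matching the
documented totals of 8 carriers, 6 families, 7 het + 1 hom). Undocumented
genotypes default to homozygous reference for sampled members and missing
for unsampled relatives; nothing is imputed. Age bands and histology are
carried as printed strings.

## Numerical and degenerate-input choices

Frequencies absent from the annotation table count as 0 (unobserved);
variants with zero available predictors and no qualifying ClinVar record
are not damaging; consensus with zero available predictors raises at the
API level (`damaging_consensus`) but is treated as non-damaging inside
prioritization, where unscored silent variants are routine. Candidate
output is sorted by (gene, chrom, pos); all simulations and permutation
tests take explicit seeds and are reproducible bit-for-bit. Multiallelic
VCF sites are decomposed per alternate allele with other alternates
counting as reference; diploid male chrX calls are coerced to hemizygous
with a logged warning, and a heterozygous male chrX call is set to missing
on input (it is also reported as a violation by the Mendelian checker).

Problem sizes in the test and acceptance runs — 200 recovery simulations at
10⁴ background variants, 10⁵ Monte-Carlo power draws, 1000 permutation-null
simulations at 500 permutations, 100 LOH null loci — were chosen so the
statistical assertions have the resolution they claim while the whole suite
runs in a few minutes on one CPU.

## Known limitations

* Side inference needs founder labels; cohorts without family-history
  annotations yield `undetermined` everywhere and the tumor-side criterion
  then never excludes anything under the default mode.
* The power model's stricter sharing rule treats sampled affecteds as
  offspring of the carrier founder; deeper relatives need the
  `offspring_carrier_prob` parameter adjusted by hand.
* No statistical co-segregation evidence (Bayes factors, LOD scores) is
  computed — the implemented procedure is the criterion-based one, by
  design.
* The LOH screen assumes high tumor purity; allele-specific copy-number
  modelling is out of scope.
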
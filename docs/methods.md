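# Methods

This note documents the models, parameter choices and known limits of
`hemotyper`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Phenotype model

Prediction is haplotype-resolved. The panel (YAML, `data/panel.yaml`)
declares variants by genomic key (chrom, pos, ref, alt — matched after
parsimony-trimming of indel dialects; rsIDs are display labels) and named
alleles as cis-combinations with antigen effects. The rule engine then
aggregates two haplotypes per system: positive if ≥1 haplotype expresses,
weak-positive if only weak alleles express, negative otherwise; no-calls
propagate and are never converted silently.

System specifics worth calling out:

* **ABO** — the GRCh38 reference carries the c.261 frameshift, so the
  *alternate* allele marks an intact transferase; B requires both
  B-defining substitutions in cis on an intact haplotype. With all three
  sites heterozygous, phase decides between B (common trans arrangement)
  and A (all three changes in cis).
* **Rh D** — functional copies = depth-derived gene copies minus
  pseudogene-insertion alleles (the 37-bp exon-4 insertion truncates RHD;
  gene present, antigen absent). A negative functional count is a QC
  signal and yields no-call.
* **Rh E** — c.602G>C is treated as a weak E-expressing allele: omitting
  it would misclassify its carriers as E−.
* **Duffy** — expression logic is cis: GATA promoter change silences, the
  c.179_180del frameshift nulls, c.265T>C weakens, each acting only on its
  own haplotype.
* **Lewis** — a FUT3 haplotype is null with c.202T>C + c.314C>T in cis or
  c.59T>G + c.1067T>A in cis (configurable); secretor status comes from
  FUT2 c.461G>A. The common case of c.202C and c.314T on *opposite*
  haplotypes is an active FUT3. A weak-secretor allele (optional panel
  extension) produces Le(a+b+).
* **MNS** — M/N orientation is fixed by observed genotype→phenotype
  pairs: all-reference GYPA haplotypes type as N, all-alternate as M (the
  amino-acid labelling of ref/alt at these sites is ambiguous in common
  annotation). S/s come from GYPB c.143 with structural overlays: the
  GYPB deletion and the He(P2) splice change silence a haplotype, the
  Dantu hybrid expresses s weakly.
* **P1** — the default predictor is the per-haplotype majority of the
  three associated intronic SNVs (reference alleles mark the
  P1-expressing haplotype); any single-SNV predictor (e.g. rs66781836)
  can be selected and is reported separately.

Panel coordinates were compiled for GRCh38 by the package authors; the
two RH locus spans are as published, rsID positions are best-effort and
internally consistent across the panel, generator and readers (synthetic
VCFs are emitted from the same panel), which is what the analysis
exercises. Swapping in curated coordinates is a data change, not a code
change.

## Depth-ratio copy number at RH

Locus coverage uses MAPQ>20-filtered depth. The zygosity statistic is
scaled to an RHD copy-number estimate (2 × RHD/RHCE, since RHCE is
invariably diploid); the published band values (0–0.5 / 0.6–1.5 /
1.6–2.5) are only consistent with expected ratios on this scale — the raw
RHD/RHCE ratio for a hemizygote (0.5) would otherwise fall in the null
band. Values in band gaps are explicit no-calls: the bands are disjoint
by design and silent rounding would hide QC failures. The zygosity means
exclude the exon-2 conversion tract, which is copy-variable through
mismapping.

For C/c, the paralog-aware statistic divides RHD exon-2 coverage by the
number of RHD copies before forming the ratio. This is the only reading
under which the published band sets match expectations under total
mismapping — homozygous RHD with 0/1/2 conversion haplotypes gives
2.0 / 0.67 / 0 (bands ≥1.5 / 0.5–1.4 / <0.5) and hemizygous RHD gives
2.0 / 0.5 / 0 (bands >0.67 / 0.1–0.66 / <0.1). The hemizygous C−c+ bound
is exclusive, so ratios inside [0.66, 0.67] no-call. RHD-null donors use
the whole-locus ratio with bands ≥0.75 / 0.25–0.74 / <0.25, derived from
the expected depletion of 0, 1 or 2 converted haplotypes (these bands are
a package choice — the cited method does not print them — and are
configurable).

## Glycophorin HMM

Windows of 1600 bp are normalized to copy units against a
copy-number-stable flank (expected value 2.0 at diploid windows); windows
overlapping the shipped low-mappability mask are excluded. Decoding uses
a 5-state Gaussian HMM with fixed parameters: state means equal to the
copy states (0–4) on the normalized scale, a single emission σ estimated
robustly (MAD) from the window spread around diploid with a floor of
0.05, uniform start, and per-window switch probability 1e-4 split across
the other states. These defaults are package choices (the HMM details of
the prior art are not printed); the config makes them swappable and a
negative-binomial emission could be substituted without changing the
interface. With switch probability → 0 and noise-free input, Viterbi
reduces to per-window rounding — kept as a test oracle. Copy numbers
above 4 are out of the state space and surface as `complex`.

Classification: GYPB deletion het/hom when ≥80% of unmasked GYPB windows
sit at 1/0 copies; Dantu when a ≥3-copy segment covers ≥80% of the
canonical GYPB–GYPA hybrid span (template matching, not breakpoint
resolution — short-read depth cannot place hybrid breakpoints).

## Synthetic cohorts

The generator draws haplotypes independently per sample under
Hardy-Weinberg from per-haplotype class frequencies whose defaults are
the study's allele frequencies, with documented cis-linkage: B-defining
changes ride one ABO haplotype; the Duffy GATA change rides Fyb
haplotypes; the two common FUT3 inactivating changes co-occur only on the
null haplotype class; the RHCE conversion rides RHD-intact haplotypes
(the classic DCe arrangement). Depth tracks are generated directly (no
read simulation): per-window read counts are negative-binomial around the
copy-scaled mean (default 16× diploid, CV 0.15 per window), and exon-2
reads of conversion haplotypes are reassigned to RHD exon 2 at the
mismap fraction (default 1.0). Serology derives from true phenotypes:
grade 0 negative, 1 weak, uniform 2–4 positive.

The fixed study cohort (`published_fixture`) is built by deterministic
assignment rather than sampling: serology antigen-positive counts equal
the study's antigen frequencies by construction, allele counts match the
study's frequencies over 200 haplotypes wherever those are integral, and
the twelve discordances (eleven donors) are injected with the genotypes
the study prints — one ABO genotype miscall, one Lewis weak-secretor
candidate (private FUT2 missense, AC 1), one Lutheran regulatory
candidate (adjacent GATA1-site SNV pair, AC 1), six unresolved M/N and
one unresolved S/s serology overrides, one Dantu weak-s below assay
sensitivity, and one P1 regulatory candidate (STAT1-site variant, AC 2).
Where the study's antigen frequencies and allele frequencies are mutually
inconsistent (the C/c pair, the GYPA M/N triple), the fixture honors the
serology counts and the printed discordance genotypes, which the
accuracy statistics measure. The fixture uses an internal fixed seed
(18263) and window CV 0.10, making every output byte-deterministic; its
exon-2 ratio tracts span six windows so all depth-ratio classifications
sit far (≳5σ) from band edges.

Injection mechanisms: genotype-miscall (VCF only), antigen-silencing and
weak-expression (serology → 0), novel-variant (serology override plus a
planted private variant), and serology-override (unexplained grades, no
candidate) — the last covers discordances for which no candidate variant
exists.

**What the generator does not emulate:** read-level artifacts (reference
bias, GC dependence, mapping-quality structure beyond a single mismap
fraction), linkage disequilibrium beyond the declared cis rules,
genotype-calling error (other than injected miscalls), and serology
between-run variability. Passing round-trip tests therefore demonstrate
the internal consistency of rules, copy-number calling and statistics —
not robustness to real sequencing artifacts. One consequence, measured by
the test suite: under this clean depth model the whole-locus (legacy)
C/c method classifies RHD-present C carriers correctly too, so the
expectation that it scores strictly below the paralog-aware method (as it
did on real coverage) is not reproduced; the corresponding test documents
this as an open red result rather than weakening the assertion.

## Problem sizes

The test suite and acceptance script run the full pipeline on the
100-donor fixture, window-accuracy simulations on 50 planted-deletion
samples, method comparisons on seeded cohorts of 100–600 samples, and
frequency-recovery checks on 10 000 genotype-only samples — all chosen to
give stable statistics on a single CPU in seconds to a few minutes.

## Known limitations

* No CRAM input and no re-phasing: phase is consumed as produced upstream;
  unphased multi-site heterozygotes are resolved to the most common cis
  configuration with a warning.
* No detection of RHD/RHCE hybrids beyond the C conversion, no weak-D
  genotyping, no GYP hybrids beyond the Dantu template, no ABO subgroups.
* Triage classifies consequences from the panel's transcript annotation
  (curated CDS intervals, splice windows, a nonsense id list) — it does
  not predict effects from sequence, and rare intronic variants outside
  supplied regulatory intervals are not reported.
* Accuracy statistics count predicted no-calls as incorrect; a policy is
  required even though the reference analysis had none.
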
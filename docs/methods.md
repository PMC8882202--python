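# Methods

## Scope and model

`sdhbcurate` models the curation of germline *SDHB* variants as four
deterministic stages: (i) normalisation and typing of HGVS-c descriptions
on NM_003000.2; (ii) two independent classifiers — a gene-adapted ACMG rule
engine and an NGSnPPGL-style decision tree — each mapping a per-variant
evidence profile to a 5-tier class (1 = benign, 2 = likely benign, 3 = VUS,
4 = likely pathogenic, 5 = pathogenic); (iii) a two-round consensus that
arbitrates the pair of calls; (iv) cohort accounting. Genuine expert
judgment is not simulatable and is deliberately externalised: an override
ledger (TSV of cdna, final class, citation) takes absolute precedence over
the arbitration policy at both rounds, so documented panel decisions can be
replayed exactly while everything else stays rule-driven.

## Transcript model

The parser works in HGVS coding-DNA coordinates only; no genomic liftover.
The eight coding-exon intervals used for exon labelling and whole-exon
rearrangement detection are ex1 c.1–72, ex2 73–200, ex3 201–286, ex4
287–423, ex5 424–540, ex6 541–642, ex7 643–765, ex8 766–846 (stop codon
included), consistent with the canonical donor sites c.72+1, c.200+1,
c.286+1, c.423+1, c.540+1, c.642+1 and c.765+1 of the transcript.

Typing precedence, in order: a del/dup whose span covers at least one whole
exon (including `?` breakpoints in the flanking introns) is a large
rearrangement; intronic offsets of ±1–2 are splice-site changes and larger
offsets mid-intronic (substitutions) or non-coding indels — the canonical
splice dinucleotides are the conventional boundary; `c.-N` positions are
5′UTR; substitutions at c.1–3 hit the initiation codon; coding
substitutions are typed by their protein consequence (defaulting to
missense when none is supplied; an explicit `vtype` column overrides with a
logged warning); coding indels without a protein notation are frameshift vs
in-frame by net length mod 3. Descriptions are taken as submitted — the
parser strips whitespace and normalises the prefix but performs no
3′-shifting, since diagnostic submissions arrive already HGVS-normalised.
3′UTR substitutions, for which the type vocabulary has no dedicated
category, fall into the mid-intronic (non-coding substitution) bucket.

## In silico layer

Third-party predictors are consumed as pre-computed values, never executed.
The conservation ratio is k/14 over a fixed panel of 14 orthologs; alignment
gaps count as non-matching (absence of a residue is not conservation). Each
tool votes pathogenic-side, benign-side or indeterminate against its own
cutoff, and the votes aggregate to `supports_pathogenic`, `supports_benign`,
`conflicting` (at least one vote on each side) or `insufficient` (fewer than
`min_tools = 2` tools reporting, or no directional vote). Categorical
verdicts rather than numeric scores are used so both classifiers consume the
same signal, mirroring how PP3/BP4 consume predictions.

Default cutoffs are each tool's conventional published threshold —
conservation ≥ 0.9 / ≤ 0.5, PhyloP ≥ 1.6 / ≤ 0.1, Grantham ≥ 145 / ≤ 50,
Align-GVGD C35+, PolyPhen2 probably-damaging vs benign, SIFT deleterious vs
tolerated, MutationTaster disease-causing vs polymorphism; for splice
candidates a MaxEntScan relative score drop ≥ 15% (benign < 5%) or an
NNSplice site falling below 0.4 from a detected reference site. These are
package defaults, configurable per run; they are not calibrated values and
should be replaced wherever a laboratory maintains validated cutoffs.

## Gene-adapted ACMG engine

Codes excluded for *SDHB* and never emitted: PS4, BP1, PP2, PM1, PM3, PM6,
PS2 (de novo events are exceptional in this low-penetrance dominant gene)
and PP4 (the PPGL phenotype is shared by many susceptibility genes).
Tumour-based evidence maps onto a six-step adapted ladder carried by
package-local codes: BS-LOH (benign strong — variant-carrying allele lost
in tumour DNA), BP-FUNC (benign supporting — no LOH, or an assay not in
favour of SDHB loss of function), PP-LOH (pathogenic supporting — wild-type
allele lost), PM-FUNC (pathogenic moderate — assay in favour of SDH loss of
function without all SDHx genes analysed), PS-FUNC (pathogenic strong —
same with the other SDHx genes excluded), PVS-FUNC (pathogenic very strong —
SDHB-specific loss of function: SDHB IHC negative with SDHA positive and
the other SDHx genes excluded; supersedes PS-FUNC). Assays counted as
"in favour of loss of function": SDHB IHC negative, SDH activity lost,
western blot reduced, transcriptomic cluster 1A, aberrant cDNA splicing.
Mutually contradictory assays are returned with conflict markers rather
than silently resolved.

Frequency cutoffs default to BA1 ≥ 0.005, BS1 ≥ 0.0005, PM2 ≤ 1e-5 —
deliberate choices for a rare, incompletely penetrant dominant tumour
syndrome; an absent frequency is treated as absence from controls (PM2).
Prior published assertions enter through a single reputation criterion
(REP) whose strength is a step function of net pathogenic-minus-benign
assertions (≥5 strong, 2–4 moderate, 1 supporting, ≤−2 benign strong); no
published scale exists for this, so the ladder is explicit config. PVS1
applies to nonsense, frameshift, canonical-splice, whole-exon-deletion and
initiation-codon variants; it is withdrawn when RNA analysis shows normal
splicing, decremented to strong for initiation-codon variants (common
practice, configurable), and not applied to whole-exon duplications, whose
consequence on the reading frame is not established. Adapted functional
very-strong evidence and PVS1 may co-occur (independent evidence axes).

The combining algebra: pathogenic requires ≥1 very strong with (≥1 strong
or ≥1 moderate or ≥2 supporting), or ≥2 very strong, or ≥2 strong, or 1
strong with (≥3 moderate, 2 moderate + ≥2 supporting, or 1 moderate + ≥4
supporting); likely pathogenic: 1 strong + 1–2 moderate, 1 strong + ≥2
supporting, ≥3 moderate, 2 moderate + ≥2 supporting, or 1 moderate + ≥4
supporting; benign: one stand-alone or ≥2 strong benign; likely benign:
strong + supporting, or ≥2 supporting benign. Simultaneous pathogenic- and
benign-rule satisfaction, or nothing satisfied, yields VUS. Note that a
lone very-strong criterion (e.g. PVS1 on a truncating variant observed in
controls) deliberately remains VUS, while very-strong plus moderate (PVS1 +
PM2) reaches pathogenic. The test suite checks this table by exhaustive
comparison against an independently transcribed brute-force oracle over all
multisets with up to three criteria per strength.

## NGSnPPGL decision tree

The second framework ships as a versioned, JSON-serialisable tree
(`{factor, op, value, true, false}` nodes; `{class, modifiers}` leaves) so
its topology can be corrected without code changes. The default topology
follows the framework's factor order: (1) frequency gate — AF ≥ 0.005 exits
benign, ≥ 0.0005 likely benign, with no subsequent promotion (the gate
dominates); (2) truncating gate — a rare null variant is likely pathogenic;
(3) assay modifiers — a loss-of-function-direction assay promotes exactly
one class, a benign-direction assay demotes one class, saturating at 1 and
5, and a truncating call is additionally promoted to pathogenic at ≥10
independent index cases; (4) in silico + segregation gate for the
remaining variants (pathogenic verdict with segregation → likely
pathogenic, pathogenic verdict alone → VUS, benign verdict → likely
benign); (5) VUS as the fall-through leaf. One-class promotion steps keep
the tree's behaviour explainable and monotone. Every classification
returns the ordered trace of nodes, observed inputs and branches.

## Consensus policy

Round 1: an override wins outright. A concordant pair keeps its class,
except that a concordant likely-pathogenic call with ≥10 independent index
cases *and* strong or very-strong functional evidence is promoted to
pathogenic (the recurrence-promotion rule; real promoted alleles are
reported 18–52 times, so 10 is conservative). A discordant pair adopts the
class on the side of the tumour-assay direction when one exists; otherwise,
when the gap is a single class, one candidate is VUS and some directional
criterion beyond bare rarity (PM2 is too weak to arbitrate) agrees with the
non-VUS side, the non-VUS class is adopted; anything else passes to round
2. Round 2 resolves everything: override first, else the more pathogenic
candidate when any pathogenic-direction functional criterion exists, else
the less pathogenic candidate — a conservative clinical default, since
predictive testing of relatives requires an LPV/PV call. The whole
procedure is a pure function of (profiles, classes, ledger, policy):
identical inputs replay to identical decision lists.

## Synthetic cohort generator

The generator emulates the structure of the international curated SDHB
cohort at its defaults: 737 index cases over 223 distinct variants;
occurrence bins 122/75/12/9/5 (once / 2–5 / 6–10 / 11–20 / ≥20); the
variant-type spectrum 98 missense, 21 nonsense, 20 splice-site, 12
mid-intronic, 6 synonymous, 3 5′UTR, 2 initiation-codon, 38 frameshift, 14
large rearrangements, 4 in-frame, 3 non-coding and 2 splice-site indels;
truth classes 2/21/51/83/66; assay availability rates 75/223 (IHC), 26/223
(LOH), 24/223 (cluster), 15/223 (cDNA), 7/223 (western blot), 6/223
(enzymatic activity); and the clinical composition of the cohort (84.5%
single PPGL among known, 35.8% metastatic among known, 29.8% familial
among known, age ≈ N(36, 14) clipped to 6–83).

Occurrence, type and class quotas use exact (largest-remainder) quota
sampling, so the headline structural counts reproduce exactly per seed;
clinical fields are independent categorical draws and match their marginals
to binomial error only. Occurrence counts are assigned in descending order
to classes ordered PV → LPV → VUS → LBV → BV, placing the recurrent alleles
on the pathogenic classes as in real cohorts (founder alleles,
rearrangement hotspots). Benign/likely-benign/VUS classes are restricted to
non-truncating types — a clear null allele is never benign — and a
configurable fraction of pathogenic variants (default 10%) is drawn as
missense carrying tumour-based proof.

Evidence is coupled to truth: each variant always receives the minimal
evidence supporting its class at the default thresholds (benign: common
frequency; likely benign: BS1-level frequency plus benign in silico; VUS:
absence from controls only; likely pathogenic truncating: a rare-but-seen
control frequency; likely pathogenic non-truncating: moderate-tier assay,
prior reports and pathogenic in silico; pathogenic: absence from controls
plus a confirmatory assay with the other SDHx genes excluded, the modality
drawn by the availability rates). With assays drawn only at the marginal
availability rates a pathogenic variant lacking any confirmatory assay
would be resolved one class down by the conservative round-2 tie-break, so
minimal sufficiency is a property of the generator's coupling, not of the
classifiers. `evidence_noise` (default 0) flips assay directions at the
given rate. Consequently, passing the recovery test demonstrates internal
consistency of the rule engines, the tree and the consensus policy on
class-typical evidence patterns — not classifier performance on real
cohorts, where evidence is sparser, noisier and correlated with
ascertainment.

## Numerical and formatting conventions

Clinical percentages use known-value denominators ("not specified" strata
are listed as counts only) and round to one decimal, half away from zero;
variant-type percentages round to the nearest integer over the
distinct-variant total; every emitted table self-audits each percentage
against count/denominator. An occurrence of exactly 20 falls in the
open-ended "≥20" bin. TSV (UTF-8, LF) is the canonical dialect; all writers
are deterministic and embed a SHA-256-derived hash of the resolved run
configuration. The LOVD export refuses to run while any variant lacks a
final class.

## Problem sizes

The test suite and the acceptance script run the generator at its default
cohort size (737 cases / 223 variants), the combining-table enumeration at
4^7 = 16 384 multisets, and property tests at 100–300 examples each; the
full suite completes in a few seconds on one CPU.

## Known limitations

The exon model is reconstructed from the transcript's canonical splice
sites and may be off by a few bases at the 3′ end; no genomic coordinates
or 3′-shifting normalisation; the HGVS grammar excludes inversions, alleles
in trans and mosaic syntax. The NGSnPPGL tree topology and the in silico
cutoffs are package defaults standing in for laboratory-validated
configurations. The arbitration policy is one deterministic interpretation
of how panels weigh functional evidence; real expert reasoning (literature
re-review, new probands appearing mid-curation) enters only through the
override ledger. The generator does not model per-class differences in
evidence availability, allele-frequency spectra, or correlation between
clinical fields.
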
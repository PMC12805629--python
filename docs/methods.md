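# Methods

This note documents the models and procedures implemented in `thymito`,
the defaults they use, and the choices made where the underlying
conventions were genuinely open.

## Data model and coordinates

VCF input is 1-based; BED and every internal interval are 0-based
half-open; conversions happen only at the I/O boundary. Multi-allelic
records are split into one variant per ALT allele with per-sample depths
taken from FORMAT/DP and alt counts from FORMAT/AD. Tumour and normal
columns are located by sample name, never by column order. All interval
intersections are strand-agnostic (cCRE and hotspot usage is positional);
indels are consumed as left-aligned by the caller with no re-normalization.
The somatic quality score is read from QUAL by default and can be
redirected to any INFO key, since callers differ in where they expose it.

## Somatic filters

The nuclear filter applies, in order: caller PASS; quality score ≥ 18;
tumour depth ≥ 21; normal depth ≥ 21; tumour VAF > 0.25; tumour alt reads
≥ 6; normal VAF < 0.02. The mitochondrial filter applies PASS; quality
≥ 18; tumour VAF > 0.05; alt reads ≥ 5; normal VAF < 0.05, with no
coverage minima — mtDNA coverage is deep but highly variable, and the
printed criteria carry no depth term. VAF thresholds are strict
inequalities and count thresholds inclusive, read literally from the
criteria. Zero-depth samples fail their coverage criterion rather than
raising a division error; for the mitochondrial filter (which has no
coverage criterion) a zero-depth VAF is treated as failing its VAF bound.

Each rejected variant is attributed to the *first* failing criterion in
the listed order. No attribution rule is canonical; first-fail makes the
report conserve counts exactly (passes + Σ rejections = inputs), which the
tests rely on.

"Distinct reads supporting the mutation" is taken as the allelic-depth
value — the only per-variant read support available in a VCF — assuming
upstream duplicate marking. Manual review of variant-rich regions is
replaced by an off-by-default density filter (> 3 passing variants per
100 bp window rejects the cluster); read-end artefact review cannot be
reconstructed from a VCF and is out of scope. The NUMT guard retains only
read pairs whose two mates both map to the mitochondrial contig, dropping
and counting single-end and unmapped-mate records.

At the default mtDNA conditions (coverage ≈ 368×), the ≥ 5-read criterion
alone detects a true 5% heteroplasmy with probability > 0.99, which the
acceptance suite verifies by simulation against the binomial tail.

## Consequence annotation

Coding SNVs are decoded against single-isoform transcript models: the CDS
is spliced in transcript orientation, the affected codon translated under
the standard code (nuclear) or the vertebrate mitochondrial code (chrM,
where TGA is Trp and AGA/AGG are stops), and the change labelled
synonymous, nonsynonymous, stop-causing or stop-loss. Splice donor and
acceptor windows are the two intronic bases beyond each exon boundary,
assigned per strand. When several labels apply the most severe wins:
splice > stop-causing > stop-loss > nonsynonymous > synonymous — a fixed,
documented precedence in the spirit of VEP's "most severe consequence",
since no canonical order exists. Coding indels are reported under a
separate `coding_indel` label because codon-level categories are defined
for SNVs only.

Noncoding variants receive exactly one label with precedence
UTR > noncoding RNA > intron > upstream/downstream > intergenic; the
flank windows default to 2 kb (a common convention, configurable).
Intergenic is the fallback, so every variant is labelled and counts are
conserved at each stage. Annotation is an input, not a packaged build:
label fractions (e.g. the intron vs intergenic split) depend entirely on
the transcript set supplied.

Per-region mutation rates are count / (size in Mb × number of patients),
matching a per-patient per-Mb axis. The cCRE partition is a point-overlap
test against the supplied BED; the hotspot lookup reports every
(variant, region) overlap with the region's source project; cohort
recurrence reports exact positions shared by ≥ 2 patients and windowed
recurrences within a configurable 21 bp window.

The packaged mitochondrial region map uses rCRS coordinates: the D-loop
spans 16024–576 across the origin, HVR I (16024–16383) and the conserved
region (1–576) are sub-annotations that never compete with primary
regions, and positions outside every named region fall into an `other`
catch-all, so primary counts always sum to the variant count. The D-loop
takes precedence over gene annotations in assignment.

## Spectra and signature refitting

Spectra are accumulated over the conventional 96 channels (six
pyrimidine-centred substitution classes × 16 flank contexts);
purine-centred substitutions are reverse-complemented in, and an
N-containing context excludes the SNV from the 96 channels while keeping
it in the total with a logged count. Refitting solves non-negative least
squares of the observed 96-vector against L1-normalized signature rows
and reports L1-normalized exposures plus the reconstruction cosine. On
two- and three-signature synthetic mixtures of ≥ 20,000 draws the refit
recovers each weight within ±0.05, which the acceptance suite checks over
20 seeds.

The packaged reference is a **synthetic** 30-row stand-in, not measured
signature data: SBS1-like (C>T at NpCpG), SBS5-like (flat), and SBS12-like
(T>C-dominated) rows capture the structure the pipeline's cohorts emulate,
with the remaining rows sparse Dirichlet draws under a fixed internal seed.
Any real row-stochastic 30 × 96 matrix in the same layout can be loaded
instead. The seventh display category alongside the six substitution
classes is the indel count — the only unambiguous extra category in the
data model — and is flagged in the output metadata. Exposure heatmap
ordering uses hierarchical clustering (correlation distance, average
linkage); this is presentation only. Refitting is supported per case or
pooled, with per-case the default.

## Heteroplasmy and dN/dS

Heteroplasmy is the mutant-read fraction at a site. A variant is
tumour-specific when the normal level is below 0.05 and tumour-enriched
when the normal carries it at ≥ 0.05 but the tumour level is higher; the
threshold deliberately reuses the mito filter's normal-VAF bound so one
number controls both, and it is recorded in output metadata. Mutation
density is mutations / (kb × patients); the nuclear comparison uses a
documented constant of 3,099,734 kb (hg38 primary assembly) as its
default denominator.

dN/dS uses Nei–Gojobori (1986) unweighted pathway counting: each codon
position contributes the fraction of its three possible substitutions
that are nonsynonymous to N and the rest to S, so N + S equals the CDS
length exactly — an invariant the tests enforce by exhaustive
9-change-per-codon enumeration under both genetic codes. Changes creating
or destroying a stop codon count as nonsynonymous. ω = (N_d/N)/(S_d/S) is
computed from raw counts without a Jukes–Cantor correction: per-site
counts at cohort scale are far below saturation and the correction is
undefined at zero synonymous counts. S_d = 0 with N_d > 0 yields +inf,
flagged rather than raised. Group comparisons (heteroplasmy by region or
by consequence) use the two-sided Mann–Whitney U test and are skipped
with a notice unless both groups are non-empty. The five-region display
grouping {D-loop, complex I, complex III/IV, rRNA/tRNA, other} is a
presentation choice, not an analysis contract.

## Lineage trees

mtDNA is polyploid per cell, so clone fractions are read directly from
heteroplasmy VAFs with no diploid doubling. Construction: (1) order
variants by descending VAF beneath a root A0 fixed at 100% (ties broken by
position then allele for determinism); (2) optionally merge adjacent
variants whose VAF gaps are below δ (default 0.02, δ = 0 disables) into
multi-mutation clones at their mean VAF; (3) insert clones in descending
order, each under a node whose residual capacity (VAF minus the summed
VAFs of its current children) covers the clone's VAF. The residual form
enforces the constraint that no node's children may sum above its own VAF
incrementally and deterministically.

The capacity rule constrains but does not uniquely determine attachment.
The default policy attaches to the *deepest* feasible node, which provably
yields a maximal-depth tree — for descending VAFs the current chain tip
always has capacity, so the default reconstruction is always linear, the
regime these tumours appear to occupy. Because that also means the default
can never produce a branching topology, the alternative *largest-residual*
policy (which does branch) is exposed behind `parent_rule="residual"` so
the ambiguity is visible rather than hidden; both policies are reported
side by side by the CLI flag. For n ≤ 6 the acceptance suite checks the
greedy tree against exhaustive enumeration of all capacity-feasible
parent assignments: it is always a member of the feasible set and attains
the maximal depth within it.

Clone proportions p(node) = VAF(node) − Σ VAF(children) (root VAF 1.0) are
non-negative on any feasible tree and sum to exactly 1 by telescoping; a
negative proportion is raised as an infeasibility error. The first hit is
the clone of largest VAF (A1), reported with its VAF, mutations and
regions; a cohort summary adds the fraction of cases whose first-hit VAF
is ≥ 0.5. Trees are emitted as indented text and as Newick with the clone
proportion in a branch comment.

## Synthetic cohorts

The generator's defaults are the study conditions: 10 patients; per-case
coding and noncoding mutation counts negative-binomial (dispersion 2)
around means 21.1 and 1,671.3 — negative binomial rather than Poisson to
reproduce the wide per-case ranges seen in such cohorts; a
405.0/1,671.3 ≈ 0.24 cCRE fraction of noncoding mutations; trinucleotide
contexts sampled from an SBS12-dominant mixture (0.7 SBS12 / 0.2 SBS5 /
0.1 SBS1); nuclear coverages 115× (tumour) and 129× (normal) and mtDNA
coverage 368×, with per-site depths Poisson and alt reads binomial;
normals carry a 0.5% alt-read contamination rate so the normal-frequency
criteria are exercised rather than vacuous. True nuclear somatic VAFs are
Beta(14, 14) — clonal heterozygous events around 0.5 with realistic
spread. A configurable decoy complement (30% of true calls by default)
plants sub-threshold records failing each filter criterion in turn.

Mitochondrial mutations arise from per-patient linear clone chains: 90%
of patients carry mutations, counts Poisson(4.3) truncated ≥ 1, clone
VAFs descending from U(0.5, 0.95) in steps of U(0.08, 0.25) with a 0.07
floor (guaranteeing capacity feasibility and gaps wide enough to survive
the default merge tolerance), positions D-loop-enriched with weight 17/43,
and one to two mutations per clone. Manual per-patient tree specs
(chains or general trees) are validated for capacity feasibility before
any sampling. One master seed reproduces every file byte-for-byte.

The toy genome (two 1.2 Mb contigs by default) compresses the genome by
three orders of magnitude, so absolute per-Mb nuclear rates are *not*
comparable to whole-genome values — counts, ratios, spectra, heteroplasmy
levels and tree topologies are the emulated quantities. The generator
also does not model read-level artefacts (strand bias, mapping error,
OXOG), regional mutation-rate covariates, germline variation, or
copy-number structure; passing tests therefore demonstrate correctness of
the pipeline's operations under binomial read sampling, not robustness to
those real-data failure modes.

## Problem sizes and numerical choices

The test suite generates cohorts at the default scale (≈ 17,000 nuclear
variants across 10 patients, seconds to generate) and uses reduced
configurations (300 kb contigs, ~100 variants per case) where a stage is
exercised repeatedly. Simulation suites use 100 seeds for recovery rates,
20 seeds for refit recovery, and 200 draws for the exhaustive lineage
comparison at n ≤ 6. Floating-point feasibility checks use a 1e-9
tolerance; clone proportions are clamped at zero only after passing that
tolerance. Lineage topology-recovery simulations use coverage 2000 with
one mutation per clone, isolating attachment-rule correctness from merge
noise; at 368× with multi-mutation clones, read noise alone splits
co-clonal mutations often enough that clone-count recovery is not a fair
test of the construction rules.

## Known limitations

- Single-isoform transcript models; no overlapping-transcript arbitration
  beyond the severity precedence.
- Hotspot discovery is a lookup against a supplied region list plus a
  recurrence tally; no covariate-adjusted background mutation model.
- dN/dS has no correction for multiple hits at a site, appropriate only at
  low per-site counts.
- The lineage construction assumes a single tumour sample per case;
  multi-region phylogeny and bootstrap support are out of scope.
- The packaged signature reference is synthetic; quantitative exposure
  values on real data require a real reference matrix.
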
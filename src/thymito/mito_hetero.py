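"""Heteroplasmy quantification, mutation density, and dN/dS.

Heteroplasmy is the mutant-read fraction at a site. A retained mtDNA
variant is *tumour-specific* when the matched normal is below the 5%
detection threshold and *tumour-enriched* when the normal carries the
variant at >= 5% but the tumour level is higher. dN/dS uses Nei-Gojobori
unweighted pathway counting on the reference CDS, with the vertebrate
mitochondrial code for chrM genes; substitutions creating or destroying a
stop codon count as nonsynonymous, so every codon position contributes
exactly one site and N + S equals the CDS length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import mannwhitneyu

from thymito.region_annotate import (
    STANDARD_CODE,
    VERTEBRATE_MITO_CODE,
    MitoRegionMap,
    TranscriptAnnotation,
    translate_codon,
)
from thymito.variant_io import ReferenceGenome, SomaticVariant, revcomp

SHIFT_THRESHOLD = 0.05


def heteroplasmy(t_alt: int, t_depth: int) -> float:
    """Mutant-read fraction ``t_alt / t_depth``; undefined at zero depth."""
    if t_depth <= 0:
        raise ValueError("heteroplasmy undefined at zero depth")
    if not 0 <= t_alt <= t_depth:
        raise ValueError(f"alt count {t_alt} outside [0, {t_depth}]")
    return t_alt / t_depth


def classify_shift(
    h_tumour: float, h_normal: float, threshold: float = SHIFT_THRESHOLD
) -> str:
    """Shift class: ``tumour-specific`` when the normal is below threshold,
    ``tumour-enriched`` when present in normal but higher in tumour,
    ``no-shift`` otherwise (the mito filter excludes the latter upstream)."""
    if h_normal < threshold:
        return "tumour-specific"
    if h_tumour > h_normal:
        return "tumour-enriched"
    return "no-shift"


@dataclass
class MitoVariant(SomaticVariant):
    """chrM variant with heteroplasmy levels, region and consequence."""

    region: str = ""
    consequence: str = "other"  # synonymous | nonsynonymous | other

    @property
    def h_tumour(self) -> float:
        return heteroplasmy(self.t_alt, self.t_depth)

    @property
    def h_normal(self) -> float:
        if self.n_depth == 0:
            return 0.0
        return self.n_alt / self.n_depth

    @property
    def shift_class(self) -> str:
        return classify_shift(self.h_tumour, self.h_normal)

    @classmethod
    def from_variant(
        cls,
        v: SomaticVariant,
        region_map: MitoRegionMap,
        consequence: str = "other",
    ) -> "MitoVariant":
        return cls(
            chrom=v.chrom,
            pos=v.pos,
            ref=v.ref,
            alt=v.alt,
            qscore=v.qscore,
            filter_status=v.filter_status,
            t_depth=v.t_depth,
            t_alt=v.t_alt,
            n_depth=v.n_depth,
            n_alt=v.n_alt,
            region=region_map.assign(v.pos),
            consequence=consequence,
        )


def mutation_density(
    n_mutations: int, contig_kb: float, n_patients: int
) -> float:
    """Mutations per kilobase per patient."""
    if contig_kb <= 0 or n_patients <= 0:
        raise ValueError("contig_kb and n_patients must be positive")
    return n_mutations / (contig_kb * n_patients)


#: hg38 primary-assembly nuclear genome size in kb, the documented default
#: denominator for the nuclear-vs-mito density comparison
NUCLEAR_GENOME_KB = 3_099_734.0
MITO_KB = 16.569  # rCRS


# ---------------------------------------------------------------------------
# dN/dS (Nei-Gojobori unweighted pathway counting)
# ---------------------------------------------------------------------------

_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


@dataclass
class DnDsResult:
    """Observed counts, expected site counts and the omega ratio."""

    Nd: float  # observed nonsynonymous mutations
    Sd: float  # observed synonymous mutations
    N: float  # nonsynonymous sites in the reference CDS
    S: float  # synonymous sites

    @property
    def omega(self) -> float:
        """(Nd/N) / (Sd/S); +inf (flagged via ``math.isinf``) when Sd = 0
        but nonsynonymous mutations were observed."""
        pn = self.Nd / self.N if self.N > 0 else 0.0
        ps = self.Sd / self.S if self.S > 0 else 0.0
        if ps == 0.0:
            return math.inf if pn > 0 else 0.0
        return pn / ps


def expected_sites(cds_seq: str, table_id: int) -> tuple[float, float]:
    """Nei-Gojobori (N, S) site counts for one CDS.

    Each codon position contributes ``(#nonsynonymous changes)/3`` to N and
    the complement to S, so N + S equals the CDS length exactly. Changes
    into or out of a stop codon are nonsynonymous.
    """
    if len(cds_seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    n_sites = 0.0
    for i in range(0, len(cds_seq), 3):
        codon = cds_seq[i : i + 3]
        aa = translate_codon(codon, table_id)
        for j in range(3):
            for alt in _OTHER[codon[j]]:
                mutant = codon[:j] + alt + codon[j + 1 :]
                if translate_codon(mutant, table_id) != aa:
                    n_sites += 1 / 3
    return n_sites, len(cds_seq) - n_sites


def classify_cds_change(
    cds_seq: str, offset: int, alt_base: str, table_id: int
) -> str:
    """``synonymous`` or ``nonsynonymous`` for a single-base CDS change."""
    codon_i, within = divmod(offset, 3)
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    mutant = codon[:within] + alt_base + codon[within + 1 :]
    same = translate_codon(codon, table_id) == translate_codon(mutant, table_id)
    return "synonymous" if same else "nonsynonymous"


def dnds(
    mutations: Iterable[tuple[str, int, str]],
    cds_sequences: Mapping[str, str],
    table_id: int = STANDARD_CODE,
) -> DnDsResult:
    """dN/dS over a gene set.

    ``mutations`` are ``(gene, cds_offset, alt_base)`` triples in CDS
    orientation; ``cds_sequences`` maps gene name to its reference CDS.
    Site counts (N, S) are summed over all genes in ``cds_sequences``
    whether or not they carry mutations.
    """
    N = S = 0.0
    for seq in cds_sequences.values():
        n, s = expected_sites(seq, table_id)
        N += n
        S += s
    Nd = Sd = 0
    for gene, offset, alt in mutations:
        kind = classify_cds_change(cds_sequences[gene], offset, alt, table_id)
        if kind == "synonymous":
            Sd += 1
        else:
            Nd += 1
    return DnDsResult(Nd=Nd, Sd=Sd, N=N, S=S)


def dnds_from_variants(
    variants: Sequence[SomaticVariant],
    annotation: TranscriptAnnotation,
    genome: ReferenceGenome,
    mito_contigs: frozenset[str] = frozenset({"chrM", "MT"}),
) -> DnDsResult:
    """dN/dS for the coding SNVs among ``variants``.

    Variants are mapped onto each annotation's CDS; chrM transcripts use the
    vertebrate mitochondrial code. Non-CDS variants are ignored. Mixed
    nuclear/mito inputs should be split by the caller (site counts would
    otherwise pool both codes).
    """
    cds_seqs: dict[str, str] = {}
    table_ids: set[int] = set()
    mapped: list[tuple[str, int, str]] = []
    for tx in annotation.transcripts:
        if tx.coding:
            cds_seqs[tx.gene] = tx.cds_sequence(genome)
            table_ids.add(
                VERTEBRATE_MITO_CODE
                if tx.chrom in mito_contigs
                else STANDARD_CODE
            )
    if len(table_ids) > 1:
        raise ValueError("mixed genetic codes; split nuclear and chrM input")
    table_id = table_ids.pop() if table_ids else STANDARD_CODE
    for v in variants:
        if v.kind != "SNV":
            continue
        for tx in annotation.transcripts_near(v.chrom, v.pos - 1):
            if not tx.coding:
                continue
            offset = tx.cds_offset(v.pos - 1)
            if offset is None:
                continue
            alt = v.alt if tx.strand == "+" else revcomp(v.alt)
            mapped.append((tx.gene, offset, alt))
            break
    return dnds(mapped, cds_seqs, table_id)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

#: Display grouping of mitochondrial regions into five functional classes
def region_group(region: str) -> str:
    if region == "D-loop":
        return "D-loop"
    if region.startswith("MT-ND"):
        return "complex I"
    if region in {"MT-CYB", "MT-CO1", "MT-CO2", "MT-CO3"}:
        return "complex III/IV"
    if region.startswith(("MT-T", "MT-RNR")):
        return "rRNA/tRNA"
    return "other"


@dataclass
class GroupComparison:
    """Per-group heteroplasmy values and a rank-sum p-value when exactly
    two non-empty groups are compared."""

    groups: dict[str, list[float]]
    p_value: float | None
    notice: str | None = None


def heteroplasmy_by_group(
    variants: Sequence[MitoVariant],
    grouping: str = "region",
    five_region_display: bool = False,
) -> GroupComparison:
    """Heteroplasmy distributions by region or consequence.

    ``grouping='region'`` groups by the region-map label (collapsed to five
    functional classes with ``five_region_display``);
    ``grouping='consequence'`` compares nonsynonymous vs synonymous coding
    variants with a two-sided Mann-Whitney U test. The test is skipped with
    a notice unless both compared groups are non-empty.
    """
    groups: dict[str, list[float]] = {}
    for v in variants:
        if grouping == "region":
            key = region_group(v.region) if five_region_display else v.region
        elif grouping == "consequence":
            if v.consequence not in ("synonymous", "nonsynonymous"):
                continue
            key = v.consequence
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        groups.setdefault(key, []).append(v.h_tumour)
    nonempty = {k: vs for k, vs in groups.items() if vs}
    if len(nonempty) == 2:
        a, b = nonempty.values()
        stat = mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(groups, float(stat.pvalue))
    return GroupComparison(
        groups,
        None,
        notice=f"comparison skipped: {len(nonempty)} non-empty group(s)",
    )
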
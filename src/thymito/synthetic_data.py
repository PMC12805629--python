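"""Synthetic tumour/normal cohorts with complete ground truth.

The generator emulates the study conditions this pipeline targets: a
10-patient cohort of lymphocyte-rich thymomas with very few coding
mutations (mean 21.1 per case) against a large noncoding burden (mean
1,671.3 per case, 405.0 of them on candidate cis-regulatory elements), a
T>C/C>T-dominated (SBS12-like) trinucleotide spectrum, nuclear coverages
near 115x (tumour) / 129x (normal), and deep mtDNA coverage near 368x with
heteroplasmic mutations arising from a feasible clonal lineage enriched in
the D-loop. Per-case counts are negative-binomial to reproduce the wide
observed ranges, and normals carry a small alt-read contamination rate so
the normal-frequency criteria are exercised realistically. Every emitted
record maps to a ground-truth entry (or an explicitly planted decoy), and
one master seed reproduces every file byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from thymito.region_annotate import (
    MITO_LENGTH,
    HotspotTable,
    MitoRegionMap,
    Transcript,
    TranscriptAnnotation,
)
from thymito.spectrum_signature import (
    CHANNELS,
    _CHANNEL_INDEX,
    synthetic_reference_signatures,
)
from thymito.variant_io import (
    GenomicInterval,
    IntervalSet,
    ReferenceGenome,
    SomaticVariant,
    revcomp,
    write_bed,
    write_fasta,
    write_paired_vcf,
)

_BASES = np.array(list("ACGT"))
_BASE_TO_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass
class CohortConfig:
    """Study-condition parameters for cohort generation."""

    n_patients: int = 10
    # toy nuclear genome
    n_nuclear_contigs: int = 2
    nuclear_contig_length: int = 1_200_000
    genes_per_contig: int = 30
    ncrna_per_contig: int = 4
    # burdens (per case means; negative binomial with this dispersion)
    coding_mean: float = 21.1
    noncoding_mean: float = 1671.3
    dispersion: float = 2.0
    cre_fraction: float = 405.0 / 1671.3
    indel_fraction: float = 0.08
    decoy_fraction: float = 0.3
    decoys_per_case: int | None = None  # overrides decoy_fraction
    plant_hotspot_hit: bool = True
    # signature mixture driving trinucleotide contexts
    signature_mixture: dict[str, float] = field(
        default_factory=lambda: {"SBS12": 0.7, "SBS5": 0.2, "SBS1": 0.1}
    )
    # coverages
    t_coverage: float = 115.0
    n_coverage: float = 129.0
    mito_coverage: float = 368.0
    contamination: float = 0.005  # normal-sample alt-read rate
    # cCRE / hotspot files
    n_ccre: int = 400
    ccre_length: int = 300
    n_hotspots: int = 159
    # mitochondrial lineage
    mito_mutation_prob: float = 0.9  # fraction of patients with mtDNA hits
    mito_mut_mean: float = 4.3  # Poisson mean, truncated >= 1
    dloop_weight: float = 17.0 / 43.0
    mito_vaf_max: float = 0.95
    mito_vaf_min: float = 0.07
    mito_step_lo: float = 0.08
    mito_step_hi: float = 0.25
    mito_tree_specs: list[Any] | None = None  # optional per-patient specs

    def __post_init__(self) -> None:
        if self.coding_mean < 0 or self.noncoding_mean < 0:
            raise ValueError("burden means must be >= 0")
        for f in ("cre_fraction", "decoy_fraction", "mito_mutation_prob",
                  "indel_fraction", "dloop_weight"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} outside [0, 1]")


@dataclass
class ReferenceBundle:
    genome: ReferenceGenome
    annotation: TranscriptAnnotation
    region_map: MitoRegionMap
    ccre: IntervalSet
    hotspots: HotspotTable
    mito_contig: str = "chrM"


@dataclass
class Cohort:
    """A full synthetic cohort plus its ground truth."""

    reference: ReferenceBundle
    nuclear: dict[str, list[SomaticVariant]]
    mito: dict[str, list[SomaticVariant]]
    truth: dict[str, Any]

    def patients(self) -> list[str]:
        return sorted(self.nuclear)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def _make_gene(
    rng: np.random.Generator, chrom: str, start: int, coding: bool, name: str
) -> Transcript:
    n_exons = int(rng.integers(2, 5))
    exons = []
    pos = start
    for _ in range(n_exons):
        length = int(rng.integers(150, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(300, 900))
    strand = "+" if rng.random() < 0.5 else "-"
    if not coding:
        return Transcript(name, chrom, strand, exons)
    total = sum(e - s for s, e in exons)
    u5 = int(rng.integers(20, 80))
    u3 = int(rng.integers(20, 80))
    u3 += (total - u5 - u3) % 3  # make CDS length divisible by 3
    # trim u5 from the transcript 5' end, u3 from the 3' end
    left, right = (u5, u3) if strand == "+" else (u3, u5)
    cds = []
    for s, e in exons:
        lo, hi = s, e
        take_l = min(left, hi - lo)
        lo += take_l
        left -= take_l
        cds.append([lo, hi])
    for i in range(len(cds) - 1, -1, -1):
        lo, hi = cds[i]
        take_r = min(right, hi - lo)
        hi -= take_r
        right -= take_r
        cds[i][1] = hi
    cds_ivs = [(lo, hi) for lo, hi in cds if lo < hi]
    return Transcript(name, chrom, strand, exons, cds_ivs)


def generate_reference(config: CohortConfig, seed: int) -> ReferenceBundle:
    """Toy nuclear contigs with gene models, a circular 16,569 bp
    mitochondrial contig with the packaged rCRS region map, random cCRE
    intervals clear of coding sequence, and a known-hotspot table.
    Deterministic under ``seed``."""
    rng = _rng(seed, 0)
    sequences = {}
    transcripts: list[Transcript] = []
    contigs = [f"chr{i + 1}" for i in range(config.n_nuclear_contigs)]
    for ci, chrom in enumerate(contigs):
        sequences[chrom] = _random_dna(rng, config.nuclear_contig_length)
        n_genes = config.genes_per_contig + config.ncrna_per_contig
        if n_genes == 0:
            continue
        slot = config.nuclear_contig_length // max(n_genes, 1)
        if slot < 8_000:
            raise ValueError(
                "gene density too high for contig length: "
                f"{n_genes} genes on {config.nuclear_contig_length} bp"
            )
        order = rng.permutation(n_genes)
        for gi in range(n_genes):
            coding = order[gi] < config.genes_per_contig
            start = gi * slot + int(rng.integers(2100, 3000))
            prefix = "GENE" if coding else "NCRNA"
            tx = _make_gene(
                rng, chrom, start, coding, f"{prefix}_{ci}_{gi}"
            )
            if tx.end < gi * slot + slot - 2100:
                transcripts.append(tx)
    sequences["chrM"] = _random_dna(rng, MITO_LENGTH)
    genome = ReferenceGenome(sequences=sequences, circular={"chrM"})
    annotation = TranscriptAnnotation(transcripts)
    region_map = MitoRegionMap.default()

    blocked = _coding_mask(genome, annotation)
    ccre = IntervalSet()
    placed = 0
    while placed < config.n_ccre:
        chrom = contigs[int(rng.integers(0, len(contigs)))]
        start = int(rng.integers(0, config.nuclear_contig_length - config.ccre_length))
        if blocked[chrom][start : start + config.ccre_length].any():
            continue
        ccre.add(
            GenomicInterval(chrom, start, start + config.ccre_length,
                            f"cCRE_{placed:04d}")
        )
        placed += 1

    hotspots = HotspotTable()
    projects = ["pancancer", "HCC", "breast", "bladder", "DLBCL"]
    for i in range(config.n_hotspots):
        chrom = contigs[int(rng.integers(0, len(contigs)))]
        length = int(rng.integers(100, 600))
        start = int(rng.integers(0, config.nuclear_contig_length - length))
        name = "IRF8_promoter" if i == 0 else f"hotspot_{i:03d}"
        iv = GenomicInterval(chrom, start, start + length, name)
        hotspots.add(iv)
        hotspots.sources[name] = projects[i % len(projects)]
    return ReferenceBundle(genome, annotation, region_map, ccre, hotspots)


def _coding_mask(
    genome: ReferenceGenome, annotation: TranscriptAnnotation
) -> dict[str, np.ndarray]:
    """Boolean mask of CDS + splice-window positions per nuclear contig."""
    masks = {
        chrom: np.zeros(len(seq), dtype=bool)
        for chrom, seq in genome.sequences.items()
        if chrom not in genome.circular
    }
    for tx in annotation.transcripts:
        m = masks.get(tx.chrom)
        if m is None:
            continue
        for s, e in tx.cds:
            m[s:e] = True
        for s, e, _ in tx.splice_windows():
            m[max(s, 0) : e] = True
    return masks


# ---------------------------------------------------------------------------
# Context-indexed position sampling
# ---------------------------------------------------------------------------

class _ContextIndex:
    """Positions grouped by trinucleotide code within a boolean mask."""

    def __init__(self, genome: ReferenceGenome, masks: dict[str, np.ndarray]):
        self.buckets: dict[tuple[str, int], np.ndarray] = {}
        for chrom, mask in masks.items():
            seq = genome.sequences[chrom]
            codes = np.array([_BASE_TO_CODE[b] for b in seq], dtype=np.int32)
            tri = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
            valid = np.where(mask[1:-1])[0] + 1  # centre positions, 0-based
            tri_valid = tri[valid - 1]
            order = np.argsort(tri_valid, kind="stable")
            sorted_pos = valid[order]
            sorted_tri = tri_valid[order]
            bounds = np.searchsorted(sorted_tri, np.arange(65))
            for t in range(64):
                lo, hi = bounds[t], bounds[t + 1]
                if hi > lo:
                    self.buckets[(chrom, t)] = sorted_pos[lo:hi]

    @staticmethod
    def code(trinuc: str) -> int:
        return (
            _BASE_TO_CODE[trinuc[0]] * 16
            + _BASE_TO_CODE[trinuc[1]] * 4
            + _BASE_TO_CODE[trinuc[2]]
        )

    def sample(
        self, rng: np.random.Generator, channel: str, n: int, used: set
    ) -> list[tuple[str, int, str, str]]:
        """Up to ``n`` fresh (chrom, pos0, ref, alt) sites matching a
        96-channel context, drawing from both strands."""
        five, centre, _, alt, three = (
            channel[0], channel[2], channel[3], channel[4], channel[6],
        )
        fwd = five + centre + three
        rev = revcomp(fwd)
        options = []
        for trinuc, a in ((fwd, alt), (rev, revcomp(alt))):
            t = self.code(trinuc)
            for (chrom, code), positions in self.buckets.items():
                if code == t:
                    options.append((chrom, positions, trinuc[1], a))
        out = []
        if not options:
            return out
        for _ in range(n):
            chrom, positions, ref, a = options[int(rng.integers(0, len(options)))]
            for _attempt in range(20):
                pos0 = int(positions[int(rng.integers(0, len(positions)))])
                if (chrom, pos0) not in used:
                    used.add((chrom, pos0))
                    out.append((chrom, pos0, ref, a))
                    break
        return out


def _mixture_channel_probs(mixture: Mapping[str, float]) -> np.ndarray:
    ref = synthetic_reference_signatures()
    probs = np.zeros(96)
    total = sum(mixture.values())
    for name, w in mixture.items():
        probs += (w / total) * ref.loc[name].to_numpy()
    return probs / probs.sum()


# ---------------------------------------------------------------------------
# Nuclear mutation planting
# ---------------------------------------------------------------------------

def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _reads(
    rng: np.random.Generator, coverage: float, vaf: float
) -> tuple[int, int]:
    depth = max(int(rng.poisson(coverage)), 1)
    alt = int(rng.binomial(depth, vaf))
    return depth, alt


def _make_snv(
    rng, chrom, pos0, ref, alt, vaf, cfg: CohortConfig
) -> SomaticVariant:
    t_depth, t_alt = _reads(rng, cfg.t_coverage, vaf)
    n_depth, n_alt = _reads(rng, cfg.n_coverage, cfg.contamination)
    return SomaticVariant(
        chrom=chrom,
        pos=pos0 + 1,
        ref=ref,
        alt=alt,
        qscore=float(np.round(rng.uniform(19, 60), 1)),
        filter_status="PASS",
        t_depth=t_depth,
        t_alt=t_alt,
        n_depth=n_depth,
        n_alt=n_alt,
    )


_DECOY_KINDS = (
    "non_pass",
    "low_qscore",
    "low_t_coverage",
    "low_n_coverage",
    "low_vaf",
    "few_alt_reads",
    "germline_like",
)


def _make_decoy(
    rng, kind: str, chrom, pos0, ref, alt, cfg: CohortConfig
) -> SomaticVariant:
    v = _make_snv(rng, chrom, pos0, ref, alt, 0.5, cfg)
    if kind == "non_pass":
        v.filter_status = "fail"
    elif kind == "low_qscore":
        v.qscore = float(np.round(rng.uniform(0, 17.9), 1))
    elif kind == "low_t_coverage":
        v.t_depth = int(rng.integers(1, 21))
        v.t_alt = int(rng.binomial(v.t_depth, 0.5))
    elif kind == "low_n_coverage":
        v.n_depth = int(rng.integers(1, 21))
        v.n_alt = 0
    elif kind == "low_vaf":
        vaf = rng.uniform(0.03, 0.22)
        cap = int(0.25 * v.t_depth)  # keep realized VAF at or below 0.25
        v.t_alt = int(np.clip(rng.binomial(v.t_depth, vaf), 0, cap))
    elif kind == "few_alt_reads":
        v.t_depth = 21
        v.t_alt = int(rng.integers(0, 6))
    elif kind == "germline_like":
        v.n_alt = int(rng.binomial(v.n_depth, rng.uniform(0.35, 0.6)))
    return v


def plant_nuclear_mutations(
    reference: ReferenceBundle, config: CohortConfig, seed: int
) -> tuple[dict[str, list[SomaticVariant]], dict[str, Any]]:
    """Plant per-case coding/noncoding mutations with ground truth.

    Counts are negative-binomial around the configured means; positions are
    drawn from context buckets so the realized spectrum follows the
    configured signature mixture; decoys exercising every filter criterion
    are appended and flagged in the truth record.
    """
    genome, annotation = reference.genome, reference.annotation
    blocked = _coding_mask(genome, annotation)
    cds_mask = {
        chrom: np.zeros(len(genome.sequences[chrom]), dtype=bool)
        for chrom in blocked
    }
    for tx in annotation.transcripts:
        if tx.chrom in cds_mask:
            for s, e in tx.cds:
                cds_mask[tx.chrom][s:e] = True
    cre_mask = {c: np.zeros_like(m) for c, m in blocked.items()}
    for iv in reference.ccre:
        cre_mask[iv.chrom][iv.start : iv.end] = True
    noncoding = {c: ~blocked[c] for c in blocked}
    idx_coding = _ContextIndex(genome, cds_mask)
    idx_cre = _ContextIndex(
        genome, {c: noncoding[c] & cre_mask[c] for c in blocked}
    )
    idx_nonfunc = _ContextIndex(
        genome, {c: noncoding[c] & ~cre_mask[c] for c in blocked}
    )
    channel_probs = _mixture_channel_probs(config.signature_mixture)

    cohort: dict[str, list[SomaticVariant]] = {}
    truth: dict[str, Any] = {}
    for pi in range(config.n_patients):
        rng = _rng(seed, 1, pi)
        patient = f"case_{pi:02d}"
        n_coding = _negbin(rng, config.coding_mean, config.dispersion)
        n_noncoding = _negbin(rng, config.noncoding_mean, config.dispersion)
        n_cre = int(rng.binomial(n_noncoding, config.cre_fraction))
        used: set = set()
        variants: list[SomaticVariant] = []
        records: list[dict] = []

        def plant(index: _ContextIndex, n: int, category: str) -> None:
            if n <= 0:
                return
            counts = rng.multinomial(n, channel_probs)
            for ch_i in np.nonzero(counts)[0]:
                sites = index.sample(
                    rng, CHANNELS[ch_i], int(counts[ch_i]), used
                )
                for chrom, pos0, ref, alt in sites:
                    vaf = float(np.clip(rng.beta(14, 14), 0.05, 0.98))
                    if rng.random() < config.indel_fraction:
                        v = _make_indel(rng, genome, chrom, pos0, vaf, config)
                    else:
                        v = _make_snv(rng, chrom, pos0, ref, alt, vaf, config)
                    variants.append(v)
                    records.append(
                        {
                            "chrom": v.chrom,
                            "pos": v.pos,
                            "ref": v.ref,
                            "alt": v.alt,
                            "category": category,
                            "vaf_true": vaf,
                            "is_decoy": False,
                        }
                    )

        plant(idx_coding, n_coding, "coding")
        plant(idx_cre, n_cre, "cre")
        plant(idx_nonfunc, n_noncoding - n_cre, "nonfunctional")

        if config.plant_hotspot_hit and pi == 0 and len(reference.hotspots):
            iv = next(iter(reference.hotspots))
            pos0 = (iv.start + iv.end) // 2
            ref = genome.sequences[iv.chrom][pos0]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            if (iv.chrom, pos0) not in used:
                used.add((iv.chrom, pos0))
                v = _make_snv(rng, iv.chrom, pos0, ref, alt, 0.5, config)
                variants.append(v)
                records.append(
                    {
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "category": "hotspot",
                        "vaf_true": 0.5,
                        "is_decoy": False,
                    }
                )

        n_true = len(variants)
        n_decoys = (
            config.decoys_per_case
            if config.decoys_per_case is not None
            else int(round(config.decoy_fraction * n_true))
        )
        for di in range(n_decoys):
            kind = _DECOY_KINDS[di % len(_DECOY_KINDS)]
            sites = idx_nonfunc.sample(
                rng, CHANNELS[int(rng.integers(0, 96))], 1, used
            )
            if not sites:
                continue
            chrom, pos0, ref, alt = sites[0]
            v = _make_decoy(rng, kind, chrom, pos0, ref, alt, config)
            variants.append(v)
            records.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "category": "decoy",
                    "decoy_kind": kind,
                    "is_decoy": True,
                }
            )

        order = sorted(
            range(len(variants)),
            key=lambda i: (variants[i].chrom, variants[i].pos),
        )
        cohort[patient] = [variants[i] for i in order]
        truth[patient] = {
            "n_coding": n_coding,
            "n_noncoding": n_noncoding,
            "n_cre": n_cre,
            "n_decoys": n_decoys,
            "records": [records[i] for i in order],
        }
    return cohort, truth


def _make_indel(
    rng, genome: ReferenceGenome, chrom: str, pos0: int, vaf: float,
    cfg: CohortConfig,
) -> SomaticVariant:
    seq = genome.sequences[chrom]
    anchor = seq[pos0]
    if rng.random() < 0.5 or pos0 + 4 >= len(seq):
        ins = _random_dna(rng, int(rng.integers(1, 4)))
        ref, alt = anchor, anchor + ins
    else:
        size = int(rng.integers(1, 4))
        ref, alt = seq[pos0 : pos0 + 1 + size], anchor
    v = _make_snv(rng, chrom, pos0, "A", "C", vaf, cfg)
    v.ref, v.alt = ref, alt
    return v


# ---------------------------------------------------------------------------
# Mitochondrial lineage planting
# ---------------------------------------------------------------------------

@dataclass
class TrueClone:
    vaf: float
    n_mutations: int
    children: list["TrueClone"] = field(default_factory=list)

    def validate(self) -> None:
        if not 0 < self.vaf <= 1.0:
            raise ValueError(f"clone VAF {self.vaf} outside (0, 1]")
        if self.vaf < sum(c.vaf for c in self.children) - 1e-9:
            raise ValueError(
                f"infeasible tree spec: clone VAF {self.vaf} < children sum"
            )
        for c in self.children:
            if c.vaf > self.vaf + 1e-9:
                raise ValueError("child VAF exceeds parent VAF")
            c.validate()


def _random_chain(rng: np.random.Generator, cfg: CohortConfig) -> list[TrueClone]:
    """Random linear chain: mutation count ~ Poisson(mean) truncated >= 1,
    clone VAFs descending with gaps wide enough to survive merging."""
    n_mut = 0
    while n_mut < 1:
        n_mut = int(rng.poisson(cfg.mito_mut_mean))
    sizes: list[int] = []
    remaining = n_mut
    while remaining > 0:
        size = 2 if (remaining >= 2 and rng.random() < 0.25) else 1
        sizes.append(size)
        remaining -= size
    vafs: list[float] = []
    v = rng.uniform(0.5, cfg.mito_vaf_max)
    for _ in sizes:
        if v < cfg.mito_vaf_min:
            break
        vafs.append(float(v))
        v -= rng.uniform(cfg.mito_step_lo, cfg.mito_step_hi)
    # leftover mutations (chain exhausted the VAF range) join the last clone
    clones = []
    for i, vaf in enumerate(vafs):
        n = sizes[i]
        if i == len(vafs) - 1:
            n += sum(sizes[len(vafs):])
        clones.append(TrueClone(vaf=vaf, n_mutations=n))
    return clones


def _chain_to_tree(chain: list[TrueClone]) -> TrueClone | None:
    root = None
    prev = None
    for clone in chain:
        if prev is not None:
            prev.children.append(clone)
        else:
            root = clone
        prev = clone
    return root


def _spec_to_tree(spec: Any) -> TrueClone | None:
    """Parse a manual tree spec: a list of (vaf, n_mutations) is a chain;
    a dict {vaf, n_mutations, children:[...]} is a general tree."""
    if spec is None:
        return None
    if isinstance(spec, dict):
        node = TrueClone(
            vaf=float(spec["vaf"]),
            n_mutations=int(spec.get("n_mutations", 1)),
            children=[_spec_to_tree(c) for c in spec.get("children", [])],
        )
        return node
    chain = [TrueClone(vaf=float(v), n_mutations=int(n)) for v, n in spec]
    return _chain_to_tree(chain)


def _sample_mito_position(
    rng: np.random.Generator,
    region_map: MitoRegionMap,
    cfg: CohortConfig,
    used: set[int],
) -> int:
    dloop = next(r for r in region_map.primary if r.name == "D-loop")
    dloop_pos = np.concatenate(
        [np.arange(s, e) for s, e in dloop.intervals]
    )
    for _ in range(200):
        if rng.random() < cfg.dloop_weight:
            pos0 = int(dloop_pos[int(rng.integers(0, len(dloop_pos)))])
        else:
            pos0 = int(rng.integers(0, region_map.length))
            if dloop.contains(pos0):
                continue
        if pos0 not in used:
            used.add(pos0)
            return pos0
    raise RuntimeError("could not place a fresh mtDNA position")


def plant_mito_lineage(
    reference: ReferenceBundle, config: CohortConfig, seed: int
) -> tuple[dict[str, list[SomaticVariant]], dict[str, Any]]:
    """Plant clonal mtDNA mutations per patient with ground-truth trees.

    Clone VAFs follow a feasible lineage (random linear chains by default,
    or the per-patient specs in ``config.mito_tree_specs``); positions are
    D-loop-enriched; tumour alt reads are binomial at the mtDNA coverage
    and normals carry only the cross-contamination rate. Manual tree specs
    are validated for rule-3 feasibility before any sampling.
    """
    genome = reference.genome
    region_map = reference.region_map
    mito = reference.mito_contig
    seq = genome.sequences[mito]
    cohort: dict[str, list[SomaticVariant]] = {}
    truth: dict[str, Any] = {}
    specs = config.mito_tree_specs
    # validate all manual specs before sampling anything
    parsed_specs: list[TrueClone | None] = []
    if specs is not None:
        for spec in specs:
            tree = _spec_to_tree(spec)
            if tree is not None:
                if tree.vaf > 1.0:
                    raise ValueError("root clone VAF exceeds 1.0")
                tree.validate()
            parsed_specs.append(tree)
    for pi in range(config.n_patients):
        rng = _rng(seed, 2, pi)
        patient = f"case_{pi:02d}"
        if specs is not None:
            tree = parsed_specs[pi] if pi < len(parsed_specs) else None
        elif rng.random() < config.mito_mutation_prob:
            tree = _chain_to_tree(_random_chain(rng, config))
        else:
            tree = None
        variants: list[SomaticVariant] = []
        clones_truth: list[dict] = []
        used: set[int] = set()

        def emit(clone: TrueClone, parent_idx: int | None) -> None:
            my_idx = len(clones_truth)
            muts = []
            for _ in range(clone.n_mutations):
                pos0 = _sample_mito_position(rng, region_map, config, used)
                ref = seq[pos0]
                alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
                t_depth, t_alt = _reads(rng, config.mito_coverage, clone.vaf)
                n_depth, n_alt = _reads(
                    rng, config.mito_coverage, config.contamination
                )
                t_alt = max(t_alt, 1)  # a planted mutation is present
                v = SomaticVariant(
                    chrom=mito,
                    pos=pos0 + 1,
                    ref=ref,
                    alt=alt,
                    qscore=float(np.round(rng.uniform(19, 60), 1)),
                    filter_status="PASS",
                    t_depth=t_depth,
                    t_alt=t_alt,
                    n_depth=n_depth,
                    n_alt=n_alt,
                )
                variants.append(v)
                muts.append(
                    {
                        "pos": v.pos,
                        "ref": ref,
                        "alt": alt,
                        "region": region_map.assign(v.pos),
                    }
                )
            clones_truth.append(
                {
                    "vaf": clone.vaf,
                    "parent": parent_idx,
                    "mutations": muts,
                }
            )
            for child in clone.children:
                emit(child, my_idx)

        if tree is not None:
            emit(tree, None)
        variants.sort(key=lambda v: v.pos)
        cohort[patient] = variants
        truth[patient] = {
            "clones": clones_truth,
            "first_hit_vaf": clones_truth[0]["vaf"] if clones_truth else None,
            "topology": _truth_topology(clones_truth),
        }
    return cohort, truth


def _truth_topology(clones: list[dict]) -> str | None:
    if not clones:
        return None
    child_counts: dict[int | None, int] = {}
    for i, c in enumerate(clones):
        child_counts[c["parent"]] = child_counts.get(c["parent"], 0) + 1
    return "linear" if all(v <= 1 for v in child_counts.values()) else "branching"


# ---------------------------------------------------------------------------
# Cohort assembly and file output
# ---------------------------------------------------------------------------

def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate a full cohort; optionally write all files under ``out_dir``.

    Emits per patient one two-sample VCF holding nuclear + chrM records,
    plus the shared reference FASTA, transcript TSV, cCRE BED, hotspot TSV
    and a ground-truth JSON.
    """
    config = config or CohortConfig()
    reference = generate_reference(config, seed)
    nuclear, truth_nuc = plant_nuclear_mutations(reference, config, seed)
    mito, truth_mito = plant_mito_lineage(reference, config, seed)
    truth = {
        "config": asdict(config),
        "seed": seed,
        "nuclear": truth_nuc,
        "mito": truth_mito,
    }
    cohort = Cohort(reference, nuclear, mito, truth)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = cohort.reference.genome
    write_fasta(out / "reference.fa", genome)
    cohort.reference.annotation.to_tsv(out / "transcripts.tsv")
    write_bed(out / "ccre.bed", cohort.reference.ccre)
    rows = [
        (iv.chrom, iv.start, iv.end, iv.label,
         cohort.reference.hotspots.sources.get(iv.label, ""))
        for iv in cohort.reference.hotspots
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "source"]
    ).to_csv(out / "hotspots.tsv", sep="\t", index=False)
    lengths = {c: len(s) for c, s in genome.sequences.items()}
    for patient in cohort.patients():
        merged = cohort.nuclear[patient] + cohort.mito[patient]
        merged.sort(key=lambda v: (v.chrom, v.pos))
        write_paired_vcf(
            out / f"{patient}.vcf",
            merged,
            tumour_sample=f"{patient}_T",
            normal_sample=f"{patient}_N",
            contig_lengths=lengths,
        )
    (out / "ground_truth.json").write_text(
        json.dumps(cohort.truth, indent=1, sort_keys=True)
    )
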
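"""Consequence annotation, noncoding partitioning and region tallies.

Coding SNVs are decoded against transcript CDS models and classified into
six categories (synonymous, nonsynonymous, splice acceptor, splice donor,
stop-causing, stop-loss) with precedence splice > stop-causing > stop-loss >
nonsynonymous > synonymous; chrM genes use the vertebrate mitochondrial
code. Noncoding variants are assigned a single functional label with
precedence UTR > noncoding RNA > intron > upstream/downstream (2 kb) >
intergenic. Separate helpers partition noncoding variants against candidate
cis-regulatory elements, look up known hotspot regions, tally cohort
recurrence, and assign mitochondrial variants to rCRS regions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from intervaltree import IntervalTree

from thymito.variant_io import (
    GenomicInterval,
    IntervalSet,
    ReferenceGenome,
    SomaticVariant,
    revcomp,
)

STANDARD_CODE = 1
VERTEBRATE_MITO_CODE = 2

CODING_CATEGORIES = (
    "splice_acceptor",
    "splice_donor",
    "stop_causing",
    "stop_loss",
    "nonsynonymous",
    "synonymous",
)

NONCODING_LABELS = (
    "5'UTR",
    "3'UTR",
    "noncoding_RNA",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)

SPLICE_WINDOW = 2  # bp of intron beyond each exon boundary
FLANK_WINDOW = 2000  # upstream/downstream extent in bp


def translate_codon(codon: str, table_id: int) -> str:
    """Amino acid for ``codon`` under NCBI table ``table_id`` ('*' = stop)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


@dataclass
class Transcript:
    """Single-isoform gene model with 0-based half-open intervals.

    ``exons`` and ``cds`` are sorted, non-overlapping genomic intervals;
    ``coding`` is False for noncoding RNA genes (empty ``cds``).
    """

    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for ivs, label in ((self.exons, "exon"), (self.cds, "CDS")):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if e1 > s2:
                    raise ValueError(f"{self.gene}: overlapping {label}s")
        if self.cds and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        """Spliced CDS in transcript orientation."""
        seq = "".join(genome.sequences[self.chrom][s:e] for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_offset(self, pos0: int) -> int | None:
        """Transcript-orientation CDS offset of genomic position, or None."""
        cum = 0
        fwd = None
        for s, e in self.cds:
            if s <= pos0 < e:
                fwd = cum + (pos0 - s)
                break
            cum += e - s
        if fwd is None:
            return None
        return fwd if self.strand == "+" else self.cds_length - 1 - fwd

    def splice_windows(self) -> list[tuple[int, int, str]]:
        """(start, end, 'splice_donor'|'splice_acceptor') intron windows."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            left = (e1, e1 + SPLICE_WINDOW)
            right = (s2 - SPLICE_WINDOW, s2)
            if self.strand == "+":
                out.append((*left, "splice_donor"))
                out.append((*right, "splice_acceptor"))
            else:
                out.append((*left, "splice_acceptor"))
                out.append((*right, "splice_donor"))
        return out

    def utr_intervals(self) -> list[tuple[int, int, str]]:
        """Exonic intervals outside the CDS, labelled 5'UTR / 3'UTR."""
        if not self.coding:
            return []
        cds_start, cds_end = self.cds[0][0], self.cds[-1][1]
        out = []
        for s, e in self.exons:
            lo_s, lo_e = s, min(e, cds_start)
            hi_s, hi_e = max(s, cds_end), e
            if lo_s < lo_e:
                label = "5'UTR" if self.strand == "+" else "3'UTR"
                out.append((lo_s, lo_e, label))
            if hi_s < hi_e:
                label = "3'UTR" if self.strand == "+" else "5'UTR"
                out.append((hi_s, hi_e, label))
        return out


class TranscriptAnnotation:
    """Transcript collection with position lookup and footprint sizes."""

    def __init__(self, transcripts: Iterable[Transcript] = ()) -> None:
        self.transcripts: list[Transcript] = list(transcripts)
        self._trees: dict[str, IntervalTree] = {}
        for tx in self.transcripts:
            lo = tx.start - FLANK_WINDOW
            self._trees.setdefault(tx.chrom, IntervalTree()).addi(
                max(lo, 0), tx.end + FLANK_WINDOW, tx
            )

    def __len__(self) -> int:
        return len(self.transcripts)

    def transcripts_near(self, chrom: str, pos0: int) -> list[Transcript]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((h.data for h in tree.at(pos0)), key=lambda t: t.gene)

    def cds_footprint(self) -> int:
        """Total CDS bases across transcripts (no overlap collapsing)."""
        return sum(tx.cds_length for tx in self.transcripts)

    def label_footprints(self, genome: ReferenceGenome) -> dict[str, int]:
        """Approximate per-label genomic footprint in bases.

        Used for per-Mb rate denominators; assumes the toy annotation's
        transcripts do not overlap each other (true for generated cohorts).
        """
        sizes = {label: 0 for label in NONCODING_LABELS}
        sizes["coding"] = 0
        genome_total = sum(len(s) for s in genome.sequences.values())
        covered = 0
        for tx in self.transcripts:
            cds = tx.cds_length
            sizes["coding"] += cds
            for s, e, label in tx.utr_intervals():
                sizes[label] += e - s
            exonic = sum(e - s for s, e in tx.exons)
            if not tx.coding:
                sizes["noncoding_RNA"] += exonic
            sizes["intron"] += (tx.end - tx.start) - exonic
            sizes["upstream"] += FLANK_WINDOW
            sizes["downstream"] += FLANK_WINDOW
            covered += (tx.end - tx.start) + 2 * FLANK_WINDOW
        sizes["intergenic"] = max(genome_total - covered, 0)
        return sizes

    # ---- GFF-like TSV round-trip -------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for tx in self.transcripts:
            for s, e in tx.exons:
                rows.append((tx.gene, tx.chrom, tx.strand, "exon", s, e))
            for s, e in tx.cds:
                rows.append((tx.gene, tx.chrom, tx.strand, "CDS", s, e))
        pd.DataFrame(
            rows, columns=["gene", "chrom", "strand", "feature", "start", "end"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TranscriptAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        txs = []
        for (gene, chrom, strand), grp in df.groupby(
            ["gene", "chrom", "strand"], sort=True
        ):
            exons = [
                (int(r.start), int(r.end))
                for r in grp[grp.feature == "exon"].itertuples()
            ]
            cds = [
                (int(r.start), int(r.end))
                for r in grp[grp.feature == "CDS"].itertuples()
            ]
            txs.append(Transcript(str(gene), chrom, strand, exons, cds))
        return cls(txs)


# ---------------------------------------------------------------------------
# Coding / noncoding classification
# ---------------------------------------------------------------------------

def _codon_consequence(
    tx: Transcript, v: SomaticVariant, genome: ReferenceGenome, code: int
) -> str | None:
    offset = tx.cds_offset(v.pos - 1)
    if offset is None:
        return None
    cds_seq = tx.cds_sequence(genome)
    codon_i, within = divmod(offset, 3)
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    alt_base = v.alt if tx.strand == "+" else revcomp(v.alt)
    mutant = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = translate_codon(codon, code)
    aa_alt = translate_codon(mutant, code)
    if aa_ref != "*" and aa_alt == "*":
        return "stop_causing"
    if aa_ref == "*" and aa_alt != "*":
        return "stop_loss"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def classify_coding(
    variant: SomaticVariant,
    annotation: TranscriptAnnotation,
    genome: ReferenceGenome,
    mito_contigs: frozenset[str] = frozenset({"chrM", "MT"}),
) -> str | None:
    """Coding consequence of a variant, or None if it is not coding.

    Splice windows are the 2 intronic bases beyond each exon boundary.
    Codon-level categories apply to SNVs only; an indel inside a CDS is
    reported as ``coding_indel``. When several transcripts yield different
    categories the most severe one wins (splice > stop-causing > stop-loss >
    nonsynonymous > synonymous).
    """
    pos0 = variant.pos - 1
    code = (
        VERTEBRATE_MITO_CODE
        if variant.chrom in mito_contigs
        else STANDARD_CODE
    )
    labels: set[str] = set()
    for tx in annotation.transcripts_near(variant.chrom, pos0):
        if not tx.coding:
            continue
        for s, e, kind in tx.splice_windows():
            if s <= pos0 < e:
                labels.add(kind)
        if any(s <= pos0 < e for s, e in tx.cds):
            if variant.kind != "SNV":
                labels.add("coding_indel")
            else:
                cat = _codon_consequence(tx, variant, genome, code)
                if cat:
                    labels.add(cat)
    if not labels:
        return None
    for cat in CODING_CATEGORIES + ("coding_indel",):
        if cat in labels:
            return cat
    return None


def classify_noncoding(
    variant: SomaticVariant, annotation: TranscriptAnnotation
) -> str:
    """Functional label for a noncoding variant (intergenic is the fallback)."""
    pos0 = variant.pos - 1
    labels: set[str] = set()
    for tx in annotation.transcripts_near(variant.chrom, pos0):
        in_gene = tx.start <= pos0 < tx.end
        in_exon = any(s <= pos0 < e for s, e in tx.exons)
        for s, e, label in tx.utr_intervals():
            if s <= pos0 < e:
                labels.add(label)
        if in_exon and not tx.coding:
            labels.add("noncoding_RNA")
        if in_gene and not in_exon:
            labels.add("intron")
        if not in_gene:
            if tx.strand == "+":
                up = tx.start - FLANK_WINDOW <= pos0 < tx.start
            else:
                up = tx.end <= pos0 < tx.end + FLANK_WINDOW
            labels.add("upstream" if up else "downstream")
    for label in NONCODING_LABELS:
        if label in labels:
            return label
    return "intergenic"


def partition_cre(
    noncoding_variants: Sequence[SomaticVariant], ccre: IntervalSet
) -> tuple[list[SomaticVariant], list[SomaticVariant]]:
    """Split noncoding variants into (CRE-overlapping, nonfunctional).

    A variant is on a candidate cis-regulatory element iff its position
    overlaps at least one cCRE interval; counts are conserved.
    """
    cre, nonfunctional = [], []
    for v in noncoding_variants:
        if ccre.overlaps_point(v.chrom, v.pos - 1):
            cre.append(v)
        else:
            nonfunctional.append(v)
    return cre, nonfunctional


class HotspotTable(IntervalSet):
    """Known recurrently-mutated noncoding regions with their source project."""

    def __init__(self) -> None:
        super().__init__()
        self.sources: dict[str, str] = {}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HotspotTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        table = cls()
        for i, row in df.iterrows():
            try:
                iv = GenomicInterval(
                    str(row["chrom"]),
                    int(row["start"]),
                    int(row["end"]),
                    str(row["name"]),
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
            table.add(iv)
            table.sources[iv.label] = str(row.get("source", ""))
        return table


@dataclass(frozen=True)
class HotspotHit:
    variant: SomaticVariant
    region: str
    source: str


def lookup_known_hotspots(
    variants: Sequence[SomaticVariant], hotspots: HotspotTable
) -> list[HotspotHit]:
    """Report every (variant, known-hotspot region) positional overlap."""
    hits = []
    for v in variants:
        for iv in hotspots.overlapping(v.chrom, v.pos - 1):
            hits.append(
                HotspotHit(v, iv.label, hotspots.sources.get(iv.label, ""))
            )
    return hits


def cohort_recurrence_tally(
    per_patient: Mapping[str, Sequence[SomaticVariant]],
    window: int = 21,
) -> pd.DataFrame:
    """Positions/windows mutated in two or more patients.

    Exact recurrence: the same (chrom, pos) in >= 2 patients. Window
    recurrence: >= 2 patients within ``window`` bp (reported at the centre
    of the first recurrent pair). Returns a DataFrame with columns
    chrom/pos/kind/n_patients/patients.
    """
    if len(per_patient) < 2:
        raise ValueError("cohort recurrence needs >= 2 patients")
    sites: dict[tuple[str, int], set[str]] = {}
    for patient, variants in per_patient.items():
        for v in variants:
            sites.setdefault((v.chrom, v.pos), set()).add(patient)
    rows = []
    for (chrom, pos), patients in sorted(sites.items()):
        if len(patients) >= 2:
            rows.append(
                (chrom, pos, "exact", len(patients), ",".join(sorted(patients)))
            )
    # window recurrence over distinct patient sites
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for (chrom, pos), patients in sites.items():
        for p in patients:
            by_chrom.setdefault(chrom, []).append((pos, p))
    for chrom, entries in sorted(by_chrom.items()):
        entries.sort()
        i = 0
        for j in range(len(entries)):
            while entries[j][0] - entries[i][0] > window:
                i += 1
            group = entries[i : j + 1]
            patients = {p for _, p in group}
            if len(patients) >= 2 and entries[j][0] != entries[i][0]:
                rows.append(
                    (
                        chrom,
                        (entries[i][0] + entries[j][0]) // 2,
                        "window",
                        len(patients),
                        ",".join(sorted(patients)),
                    )
                )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "kind", "n_patients", "patients"]
    )
    return df.drop_duplicates(subset=["chrom", "pos", "kind"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Mitochondrial region map
# ---------------------------------------------------------------------------

MITO_LENGTH = 16569  # rCRS


@dataclass(frozen=True)
class MitoRegion:
    name: str
    region_class: str
    intervals: tuple[tuple[int, int], ...]  # 0-based half-open, wrap split
    sub_region_of: str | None = None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.intervals)


class MitoRegionMap:
    """rCRS-style region map for the circular mitochondrial contig.

    Primary regions (D-loop, genes, rRNAs, tRNAs) compete for assignment in
    file order with the D-loop first; HVR I and the conserved region are
    sub-annotations of the D-loop and never claim a variant on their own.
    Positions not covered by any region fall into an ``other`` catch-all.
    """

    def __init__(self, regions: Sequence[MitoRegion], length: int = MITO_LENGTH):
        self.length = length
        self.regions = list(regions)
        self.primary = [r for r in self.regions if r.sub_region_of is None]
        self.sub = [r for r in self.regions if r.sub_region_of is not None]

    @classmethod
    def default(cls) -> "MitoRegionMap":
        """Packaged rCRS map (D-loop 16024-576 wrapping the origin)."""
        with importlib.resources.files("thymito.data").joinpath(
            "mito_regions_rcrs.tsv"
        ).open() as fh:
            return cls.from_tsv(fh)

    @classmethod
    def from_tsv(cls, path_or_fh, length: int = MITO_LENGTH) -> "MitoRegionMap":
        df = pd.read_csv(path_or_fh, sep="\t")
        regions = []
        for row in df.itertuples(index=False):
            start1, end1 = int(row.start), int(row.end)
            if start1 <= end1:
                ivs = ((start1 - 1, end1),)
            else:  # wraps the origin
                ivs = ((start1 - 1, length), (0, end1))
            sub = getattr(row, "sub_region_of", None)
            if sub is not None and pd.isna(sub):
                sub = None
            regions.append(
                MitoRegion(str(row.name), str(row.region_class), ivs, sub)
            )
        return cls(regions, length)

    def assign(self, pos: int) -> str:
        """Primary region name for 1-based ``pos`` (wraps; D-loop wins)."""
        if not 1 <= pos:
            raise ValueError(f"position {pos} < 1")
        pos0 = (pos - 1) % self.length
        if pos > self.length:
            raise ValueError(
                f"position {pos} beyond contig length {self.length}"
            )
        for region in self.primary:
            if region.contains(pos0):
                return region.name
        return "other"

    def sub_regions(self, pos: int) -> list[str]:
        pos0 = (pos - 1) % self.length
        return [r.name for r in self.sub if r.contains(pos0)]

    def region_length(self, name: str) -> int:
        for r in self.regions:
            if r.name == name:
                return r.length
        if name == "other":
            covered = set()
            for r in self.primary:
                for s, e in r.intervals:
                    covered.update(range(s, e))
            return self.length - len(covered)
        raise KeyError(name)


@dataclass
class RegionTally:
    """Per-region mutation counts, sizes, and per-Mb per-patient rates."""

    counts: dict[str, int]
    sizes_bp: dict[str, int]
    n_patients: int
    sub_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def rate_per_mb(self, region: str) -> float:
        size = self.sizes_bp[region]
        if size == 0:
            return 0.0
        return self.counts.get(region, 0) / (size / 1e6) / self.n_patients

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, self.counts.get(name, 0), self.sizes_bp[name],
             self.rate_per_mb(name))
            for name in self.counts
        ]
        return pd.DataFrame(
            rows, columns=["region", "count", "size_bp", "rate_per_mb_per_patient"]
        )


def mito_region_tally(
    variants: Sequence[SomaticVariant],
    region_map: MitoRegionMap,
    n_patients: int = 1,
) -> RegionTally:
    """Assign each chrM variant to exactly one region and tally.

    The D-loop takes precedence over gene annotations; HVR I (and the
    conserved region) are reported as sub-tallies of the D-loop so that
    primary counts still sum to the number of variants.
    """
    counts: dict[str, int] = {}
    sub_counts: dict[str, int] = {}
    for v in variants:
        name = region_map.assign(v.pos)
        counts[name] = counts.get(name, 0) + 1
        for sub in region_map.sub_regions(v.pos):
            sub_counts[sub] = sub_counts.get(sub, 0) + 1
    sizes = {name: region_map.region_length(name) for name in counts}
    return RegionTally(counts, sizes, n_patients, sub_counts)
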
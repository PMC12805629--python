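"""Core variant/interval data model and readers/writers for standard formats.

Coordinate conventions: VCF positions are 1-based; BED and every internal
interval are 0-based half-open. Conversions happen only at I/O boundaries.
All interval queries are strand-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from cyvcf2 import VCF
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def variant_kind(ref: str, alt: str) -> str:
    """Classify a ref/alt pair as ``SNV``, ``insertion`` or ``deletion``."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass
class SomaticVariant:
    """One tumour/normal paired variant call.

    ``qscore`` is the caller's somatic quality score; ``filter_status`` is
    the raw VCF FILTER string; depths and alt-read counts are per sample.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qscore: float
    filter_status: str
    t_depth: int
    t_alt: int
    n_depth: int
    n_alt: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0 <= self.t_alt <= self.t_depth):
            raise ValueError(f"t_alt {self.t_alt} outside [0, {self.t_depth}]")
        if not (0 <= self.n_alt <= self.n_depth):
            raise ValueError(f"n_alt {self.n_alt} outside [0, {self.n_depth}]")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")

    @property
    def kind(self) -> str:
        return variant_kind(self.ref, self.alt)

    @property
    def t_vaf(self) -> float:
        """Tumour frequency: alt reads over total reads; 0 at zero depth."""
        return self.t_alt / self.t_depth if self.t_depth else 0.0

    @property
    def n_vaf(self) -> float:
        """Normal frequency; 0 at zero depth."""
        return self.n_alt / self.n_depth if self.n_depth else 0.0


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with a free-text label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Strand-agnostic interval collection with fast point/range overlap.

    Backed by one :class:`intervaltree.IntervalTree` per chromosome.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, iv
        )
        self._intervals.append(iv)

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def overlapping(self, chrom: str, pos0: int) -> list[GenomicInterval]:
        """Intervals containing 0-based position ``pos0``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.at(pos0)),
            key=lambda iv: (iv.start, iv.end, iv.label),
        )

    def overlaps_point(self, chrom: str, pos0: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.at(pos0))

    def total_length(self) -> int:
        """Summed interval length in bases (overlaps counted twice)."""
        return sum(len(iv) for iv in self._intervals)


@dataclass
class ReferenceGenome:
    """Named upper-case DNA sequences; circular contigs wrap coordinates.

    The mitochondrial contig is registered in ``circular`` so that context
    extraction and region maps wrap through the origin.
    """

    sequences: dict[str, str]
    circular: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - _DNA
            if bad:
                raise ValueError(f"{name}: non-DNA characters {sorted(bad)}")

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Base at 1-based ``pos``; wraps on circular contigs."""
        seq = self.sequences[chrom]
        if chrom in self.circular:
            return seq[(pos - 1) % len(seq)]
        if 1 <= pos <= len(seq):
            return seq[pos - 1]
        return "N"


def trinucleotide_context(
    genome: ReferenceGenome, chrom: str, pos: int
) -> str:
    """3-mer centred on 1-based ``pos``.

    Circular contigs wrap modulo their length; linear contig edges are
    N-padded. Unknown chromosomes raise ``KeyError``.
    """
    if chrom not in genome.sequences:
        raise KeyError(f"unknown chromosome {chrom!r}")
    n = genome.length(chrom)
    if chrom not in genome.circular and not (1 <= pos <= n):
        raise ValueError(f"position {pos} outside {chrom} (length {n})")
    return "".join(genome.base(chrom, p) for p in (pos - 1, pos, pos + 1))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_paired_vcf(
    path: str | Path,
    tumour_sample: str,
    normal_sample: str,
    qscore_field: str = "QUAL",
) -> list[SomaticVariant]:
    """Read a tumour/normal paired VCF into :class:`SomaticVariant` records.

    One variant is emitted per ALT allele (multi-allelic records are split).
    Depths come from per-sample FORMAT/DP (falling back to the AD sum) and
    alt counts from FORMAT/AD. The somatic quality score is taken from QUAL
    by default, or from the INFO key named by ``qscore_field``. Records
    lacking allelic depths are skipped with a logged warning.

    Samples are located by name, never by column order.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (tumour_sample, normal_sample):
        if name not in samples:
            raise KeyError(
                f"sample {name!r} not in VCF (has {samples})"
            )
    t_idx = samples.index(tumour_sample)
    n_idx = samples.index(normal_sample)

    out: list[SomaticVariant] = []
    skipped = 0
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            skipped += 1
            continue
        dp = rec.format("DP")
        if rec.QUAL is not None and qscore_field == "QUAL":
            qscore = float(rec.QUAL)
        elif qscore_field != "QUAL" and rec.INFO.get(qscore_field) is not None:
            qscore = float(rec.INFO.get(qscore_field))
        else:
            qscore = 0.0
        filt = rec.FILTER if rec.FILTER is not None else "PASS"
        for ai, alt in enumerate(rec.ALT):
            t_alt = int(ad[t_idx][ai + 1])
            n_alt = int(ad[n_idx][ai + 1])
            if dp is not None:
                t_depth = int(dp[t_idx][0])
                n_depth = int(dp[n_idx][0])
            else:
                t_depth = int(sum(max(x, 0) for x in ad[t_idx]))
                n_depth = int(sum(max(x, 0) for x in ad[n_idx]))
            out.append(
                SomaticVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    qscore=qscore,
                    filter_status=filt,
                    t_depth=t_depth,
                    t_alt=t_alt,
                    n_depth=n_depth,
                    n_alt=n_alt,
                )
            )
    if skipped:
        logger.warning("skipped %d records lacking AD fields", skipped)
    return out


def write_paired_vcf(
    path: str | Path,
    variants: Iterable[SomaticVariant],
    tumour_sample: str = "TUMOUR",
    normal_sample: str = "NORMAL",
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write variants as an uncompressed two-sample VCF 4.2 file.

    Per-variant depths/alt counts are encoded as FORMAT DP and a biallelic
    AD (ref = depth - alt); the somatic quality score goes to QUAL and the
    raw filter string to FILTER. Records are written in the given order.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=thymito",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FILTER=<ID=fail,Description="Failed caller filters">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths (ref,alt)">',
    ]
    for contig, length in (contig_lengths or {}).items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{tumour_sample}\t{normal_sample}"
    )
    for v in variants:
        t_ref = v.t_depth - v.t_alt
        n_ref = v.n_depth - v.n_alt
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qscore:g}\t"
            f"{v.filter_status}\t.\tGT:DP:AD\t"
            f"0/1:{v.t_depth}:{t_ref},{v.t_alt}\t"
            f"0/0:{v.n_depth}:{n_ref},{v.n_alt}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED / FASTA / TSV
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3/BED4 file (0-based half-open, label from column 4)."""
    out = IntervalSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            label = fields[3] if len(fields) > 3 else ""
            out.add(GenomicInterval(chrom, start, end, label))
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_fasta(
    path: str | Path, circular: Iterable[str] = ()
) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome` (upper-cased)."""
    from Bio import SeqIO

    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }
    return ReferenceGenome(sequences=seqs, circular=set(circular))


def write_fasta(path: str | Path, genome: ReferenceGenome, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.sequences:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_interval_tsv(
    path: str | Path,
    chrom_col: str = "chrom",
    start_col: str = "start",
    end_col: str = "end",
    label_col: str = "name",
    one_based: bool = False,
) -> IntervalSet:
    """Read a headered TSV of regions (hotspot lists, region maps).

    ``one_based=True`` converts 1-based inclusive coordinates to the internal
    0-based half-open convention. Malformed rows are fatal with row numbers.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={chrom_col: str})
    out = IntervalSet()
    for i, row in df.iterrows():
        try:
            start = int(row[start_col]) - (1 if one_based else 0)
            end = int(row[end_col])
            out.add(
                GenomicInterval(
                    str(row[chrom_col]), start, end, str(row[label_col])
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return out
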
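"""Somatic filtering for nuclear and mitochondrial variants.

The nuclear filter applies seven criteria in a fixed order: caller PASS,
somatic quality score >= 18, tumour coverage >= 21x, normal coverage >= 21x,
tumour frequency > 0.25, >= 6 alt-supporting tumour reads, and normal
frequency < 0.02. The mitochondrial filter applies five: PASS, quality
>= 18, tumour frequency > 0.05, >= 5 alt reads, normal frequency < 0.05 —
no coverage minima, reflecting the much deeper and more variable mtDNA
coverage. VAF thresholds are strict inequalities; count thresholds are
inclusive. Rejections are attributed to the first failing criterion, so the
per-criterion tallies plus passes sum exactly to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from thymito.variant_io import SomaticVariant

NUCLEAR_CRITERIA = (
    "filter_pass",
    "qscore",
    "tumour_coverage",
    "normal_coverage",
    "tumour_vaf",
    "tumour_alt_reads",
    "normal_vaf",
)

MITO_CRITERIA = (
    "filter_pass",
    "qscore",
    "tumour_vaf",
    "tumour_alt_reads",
    "normal_vaf",
)


@dataclass
class FilterConfig:
    """Thresholds for the nuclear and mitochondrial somatic filters."""

    # nuclear
    nuclear_qscore_min: float = 18.0
    nuclear_t_cov_min: int = 21
    nuclear_n_cov_min: int = 21
    nuclear_t_vaf_min: float = 0.25  # exclusive
    nuclear_t_alt_min: int = 6
    nuclear_n_vaf_max: float = 0.02  # exclusive
    # mitochondrial
    mito_qscore_min: float = 18.0
    mito_t_vaf_min: float = 0.05  # exclusive
    mito_t_alt_min: int = 5
    mito_n_vaf_max: float = 0.05  # exclusive

    def __post_init__(self) -> None:
        for name in (
            "nuclear_t_vaf_min",
            "nuclear_n_vaf_max",
            "mito_t_vaf_min",
            "mito_n_vaf_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "nuclear_qscore_min",
            "nuclear_t_cov_min",
            "nuclear_n_cov_min",
            "nuclear_t_alt_min",
            "mito_qscore_min",
            "mito_t_alt_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FilterReport:
    """Per-criterion first-fail rejection tallies.

    Invariant: ``n_pass + sum(rejections.values()) == n_input``.
    """

    criteria: tuple[str, ...]
    n_input: int = 0
    n_pass: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.criteria:
            self.rejections.setdefault(c, 0)

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [("input", self.n_input), ("pass", self.n_pass)]
        rows += [(f"reject_{c}", self.rejections[c]) for c in self.criteria]
        return rows


def _first_failed_nuclear(v: SomaticVariant, cfg: FilterConfig) -> str | None:
    if v.filter_status != "PASS":
        return "filter_pass"
    if v.qscore < cfg.nuclear_qscore_min:
        return "qscore"
    if v.t_depth < cfg.nuclear_t_cov_min:
        return "tumour_coverage"
    if v.n_depth < cfg.nuclear_n_cov_min:
        return "normal_coverage"
    if not v.t_vaf > cfg.nuclear_t_vaf_min:
        return "tumour_vaf"
    if v.t_alt < cfg.nuclear_t_alt_min:
        return "tumour_alt_reads"
    if not v.n_vaf < cfg.nuclear_n_vaf_max:
        return "normal_vaf"
    return None


def _first_failed_mito(v: SomaticVariant, cfg: FilterConfig) -> str | None:
    if v.filter_status != "PASS":
        return "filter_pass"
    if v.qscore < cfg.mito_qscore_min:
        return "qscore"
    if not v.t_vaf > cfg.mito_t_vaf_min:
        return "tumour_vaf"
    if v.t_alt < cfg.mito_t_alt_min:
        return "tumour_alt_reads"
    if not v.n_vaf < cfg.mito_n_vaf_max:
        return "normal_vaf"
    return None


def _run_filter(variants, cfg, criteria, check):
    report = FilterReport(criteria=criteria)
    passing = []
    for v in variants:
        report.n_input += 1
        failed = check(v, cfg)
        if failed is None:
            passing.append(v)
            report.n_pass += 1
        else:
            report.rejections[failed] += 1
    return passing, report


def filter_nuclear(
    variants: Iterable[SomaticVariant], cfg: FilterConfig | None = None
) -> tuple[list[SomaticVariant], FilterReport]:
    """Apply the seven nuclear somatic criteria.

    A zero-depth sample can never satisfy its coverage criterion, so such
    variants are rejected there and no VAF division is attempted.
    """
    cfg = cfg or FilterConfig()
    return _run_filter(variants, cfg, NUCLEAR_CRITERIA, _first_failed_nuclear)


def filter_mito(
    variants: Iterable[SomaticVariant], cfg: FilterConfig | None = None
) -> tuple[list[SomaticVariant], FilterReport]:
    """Apply the five mitochondrial criteria (no coverage minima)."""
    cfg = cfg or FilterConfig()
    return _run_filter(variants, cfg, MITO_CRITERIA, _first_failed_mito)


class ReadPair(NamedTuple):
    """Minimal mapping descriptor for one read pair."""

    contig1: str | None  # None = unmapped
    contig2: str | None
    paired: bool = True


def numt_readpair_filter(
    pairs: Iterable[ReadPair], mito_contig: str = "chrM"
) -> tuple[list[ReadPair], dict[str, int]]:
    """Keep only pairs with both mates mapped to the mitochondrial contig.

    Guards mtDNA calls against reads straddling nuclear-embedded
    mitochondrial segments (NUMTs): a mate anchored on a nuclear chromosome
    disqualifies the pair. Single-end records are dropped and counted.
    Returns ``(retained, counts)`` where counts tallies the drop reasons.
    """
    retained: list[ReadPair] = []
    counts = {"retained": 0, "single_end": 0, "unmapped_mate": 0, "off_target": 0}
    for p in pairs:
        if not p.paired:
            counts["single_end"] += 1
        elif p.contig1 is None or p.contig2 is None:
            counts["unmapped_mate"] += 1
        elif p.contig1 == mito_contig and p.contig2 == mito_contig:
            retained.append(p)
            counts["retained"] += 1
        else:
            counts["off_target"] += 1
    return retained, counts


def compute_tmb(
    coding_variants: Sequence[SomaticVariant] | int, coding_region_size: float
) -> float:
    """Tumour mutational burden: coding substitutions + indels per megabase.

    ``coding_variants`` may be the variant list itself or a pre-computed
    count; synonymous changes are included by definition and noncoding
    variants must already have been excluded by the caller.
    ``coding_region_size`` is in bases.
    """
    if coding_region_size <= 0:
        raise ValueError("coding_region_size must be positive")
    n = (
        coding_variants
        if isinstance(coding_variants, int)
        else len(coding_variants)
    )
    return n / (coding_region_size / 1e6)


def density_filter(
    variants: Sequence[SomaticVariant],
    max_per_window: int = 3,
    window: int = 100,
) -> tuple[list[SomaticVariant], list[SomaticVariant]]:
    """Reject clusters of > ``max_per_window`` variants within ``window`` bp.

    Automatable proxy for manual review of variant-rich regions; off by
    default in the pipeline. Read-end artefact review is not recoverable
    from a VCF and has no proxy here. Returns ``(kept, rejected)``.
    """
    by_chrom: dict[str, list[SomaticVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    rejected_ids = set()
    for chrom, vs in by_chrom.items():
        vs = sorted(vs, key=lambda v: v.pos)
        i = 0
        for j in range(len(vs)):
            while vs[j].pos - vs[i].pos >= window:
                i += 1
            if j - i + 1 > max_per_window:
                for k in range(i, j + 1):
                    rejected_ids.add(id(vs[k]))
    kept = [v for v in variants if id(v) not in rejected_ids]
    rej = [v for v in variants if id(v) in rejected_ids]
    return kept, rej
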
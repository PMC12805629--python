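"""Trinucleotide mutation spectra and signature refitting.

SNVs are counted over the 96 pyrimidine-centred trinucleotide channels
(purine-centred substitutions are reverse-complemented in), collapsed to
the six substitution classes C>A, C>G, C>T, T>A, T>C, T>G — with an
optional seventh indel category for mitochondrial displays — and refit
against a 30-signature reference by non-negative least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from thymito.variant_io import (
    ReferenceGenome,
    SomaticVariant,
    revcomp,
    trinucleotide_context,
)

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: conventional 96-channel order: substitution class, then 5' then 3' flank
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX = {ch: i for i, ch in enumerate(CHANNELS)}


def channel_of(ref: str, alt: str, context: str) -> str | None:
    """Canonical pyrimidine-centred channel for an SNV, or None if the
    context contains N. ``context`` is the reference 3-mer around the site
    (its centre must equal ``ref``)."""
    if context[1] != ref:
        raise ValueError(f"context {context} centre != ref {ref}")
    if "N" in context or "N" in alt:
        return None
    if ref in "AG":  # purine-centred: collapse to the reverse-complement
        context = revcomp(context)
        ref = context[1]
        alt = revcomp(alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutationSpectrum:
    """Counts over the 96 channels plus bookkeeping for excluded SNVs."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(96, dtype=float)
    )
    n_excluded: int = 0  # SNVs with N-containing context

    @property
    def total_snvs(self) -> int:
        return int(self.counts.sum()) + self.n_excluded

    def add(self, ref: str, alt: str, context: str) -> None:
        ch = channel_of(ref, alt, context)
        if ch is None:
            self.n_excluded += 1
        else:
            self.counts[_CHANNEL_INDEX[ch]] += 1

    def collapse6(self) -> np.ndarray:
        """Six-class vector in the order C>A, C>G, C>T, T>A, T>C, T>G."""
        return self.counts.reshape(6, 16).sum(axis=1)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name="count")


def build_spectrum(
    snvs: Sequence[SomaticVariant], genome: ReferenceGenome
) -> MutationSpectrum:
    """Spectrum of the SNVs in ``snvs`` (non-SNVs are ignored)."""
    spec = MutationSpectrum()
    for v in snvs:
        if v.kind != "SNV":
            continue
        ctx = trinucleotide_context(genome, v.chrom, v.pos)
        spec.add(v.ref, v.alt, ctx)
    return spec


def collapse_classes(
    spectrum: MutationSpectrum,
    include_indel_category: bool = False,
    indel_count: int = 0,
) -> pd.Series:
    """6-class vector, or 7 categories with an appended indel count.

    The seventh category used in mitochondrial displays is the indel tally;
    the choice is recorded in the series name.
    """
    values = list(spectrum.collapse6())
    index = list(SUBSTITUTION_CLASSES)
    name = "six_class"
    if include_indel_category:
        values.append(float(indel_count))
        index.append("indel")
        name = "seven_class_with_indel"
    return pd.Series(values, index=index, name=name)


@dataclass
class SignatureExposure:
    """Normalized non-negative signature weights and reconstruction quality."""

    weights: pd.Series  # L1-normalized, >= 0
    cosine: float  # cosine(reconstruction, observed spectrum)
    residual: float  # NNLS residual norm

    def top(self, n: int = 5) -> pd.Series:
        return self.weights.sort_values(ascending=False).head(n)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def refit_signatures(
    spectrum: MutationSpectrum | np.ndarray, reference: pd.DataFrame
) -> SignatureExposure:
    """Refit a 96-channel spectrum against a signature reference.

    ``reference`` has one row per signature and the 96 channels as columns
    (rows are L1-normalized before solving). Solves
    ``min ||y - A x||_2  s.t.  x >= 0`` with ``A`` the channel-by-signature
    matrix, then L1-normalizes the exposures.
    """
    y = (
        spectrum.counts
        if isinstance(spectrum, MutationSpectrum)
        else np.asarray(spectrum, dtype=float)
    )
    if y.sum() <= 0:
        raise ValueError("cannot refit an all-zero spectrum")
    ref = reference.reindex(columns=list(CHANNELS))
    if ref.isna().any().any():
        raise ValueError("reference matrix is missing channels")
    rows = ref.to_numpy(dtype=float)
    rows = rows / rows.sum(axis=1, keepdims=True)
    x, residual = nnls(rows.T, y)
    total = x.sum()
    weights = x / total if total > 0 else x
    recon = rows.T @ x
    return SignatureExposure(
        weights=pd.Series(weights, index=ref.index, name="exposure"),
        cosine=_cosine(recon, y),
        residual=float(residual),
    )


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Load a signature TSV (rows = signatures, columns = 96 channels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.reindex(columns=list(CHANNELS))


def synthetic_reference_signatures(n_signatures: int = 30) -> pd.DataFrame:
    """Synthetic 30-signature row-stochastic reference matrix.

    This is a synthetic stand-in, not measured signature data: SBS1 mimics
    the clock-like C>T-at-CpG process, SBS5 is a flat background, SBS12 is
    the T>C-transition-dominated pattern this pipeline's cohorts emulate,
    and the remaining rows are sparse Dirichlet draws under a fixed
    internal seed so the matrix is reproducible. Any real row-stochastic
    matrix with the same layout can be substituted via
    :func:`read_signature_matrix`.
    """
    rng = np.random.default_rng(20240612)
    mat = np.zeros((n_signatures, 96))
    names = [f"SBS{i + 1}" for i in range(n_signatures)]

    def idx(sub, five, three):
        return _CHANNEL_INDEX[f"{five}[{sub}]{three}"]

    # SBS1-like: C>T at NpCpG
    for five in _BASES:
        mat[0, idx("C>T", five, "G")] = 1.0
    # SBS5-like: flat with mild transition tilt
    mat[4, :] = 0.5
    for sub in ("C>T", "T>C"):
        for five in _BASES:
            for three in _BASES:
                mat[4, idx(sub, five, three)] = 1.0
    # SBS12-like: dominated by T>C with a minor C>T component
    for five in _BASES:
        for three in _BASES:
            mat[11, idx("T>C", five, three)] = 4.0
            mat[11, idx("C>T", five, three)] = 0.5
    for i in range(n_signatures):
        if i in (0, 4, 11):
            continue
        mat[i, :] = rng.dirichlet(np.full(96, 0.15))
    mat /= mat.sum(axis=1, keepdims=True)
    return pd.DataFrame(mat, index=names, columns=list(CHANNELS))


def exposure_heatmap_order(exposures: pd.DataFrame) -> list[str]:
    """Case ordering for the exposure display via hierarchical clustering
    (correlation distance, average linkage). Presentation helper only."""
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import pdist

    if len(exposures) < 3:
        return list(exposures.index)
    dist = pdist(exposures.to_numpy(), metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)
    return [exposures.index[i] for i in leaves_list(average(dist))]
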
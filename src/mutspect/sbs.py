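"""Single-base-substitution classification and 96-channel spectra.

Substitutions are reported in the pyrimidine-strand convention: if the
reference base is a purine, the substitution and its trinucleotide
context are reverse-complemented before classification, so every event
is a C>N or T>N change in a 5'/3' context. The 96 channels follow the
COSMIC order: substitution types C>A, C>G, C>T, T>A, T>C, T>G; within
each type the 16 contexts ordered by 5' then 3' base, each A,C,G,T
(channel 1 = A[C>A]A ... channel 96 = T[T>G]T).

Also provides rainfall series (per-chromosome inter-mutation distances)
and a chromosome-end proximity summary, used to quantify the clustering
of mutations in subtelomeric single-stranded DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (
    GenomeSequence,
    pyrimidine_motif,
    reverse_complement,
    trinucleotide_context,
)
from .variants import VariantRecord, VariantSet

SUBSTITUTION_TYPES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Channel labels in canonical COSMIC order, e.g. "A[C>A]A".
CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in "ACGT"
    for three in "ACGT"
)

_CHANNEL_INDEX = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}


def channel_label(index: int) -> str:
    """Label of a 0-based channel index."""
    return CHANNEL_LABELS[index]


def channel_motif(index: int) -> str:
    """Pyrimidine-centered trinucleotide motif of a 0-based channel."""
    lab = CHANNEL_LABELS[index]
    return lab[0] + lab[2] + lab[6]


def channel_index(label: str) -> int:
    """0-based index of a channel label like 'A[C>A]A'."""
    try:
        return _CHANNEL_INDEX[label]
    except KeyError:
        raise ValueError(f"unknown SBS channel label {label!r}") from None


class ClassificationError(ValueError):
    """Raised when a variant cannot be reconciled with the genome."""


@dataclass
class SbsSpectrum:
    """Counts (or weights) over the 96 SBS channels in canonical order."""

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("SBS spectrum must have exactly 96 channels")
        if np.any(self.counts < 0):
            raise ValueError("negative SBS channel count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return self.counts / self.total

    def to_tsv(self, path: str | Path) -> None:
        freqs = self.counts / self.total if self.total > 0 else np.zeros(96)
        with open(path, "w") as fh:
            fh.write("channel\tcount\tfrequency\n")
            for i, lab in enumerate(CHANNEL_LABELS):
                fh.write(f"{lab}\t{self.counts[i]:.10g}\t{freqs[i]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "SbsSpectrum":
        """Read a channel/count table; rows may be in any order."""
        counts = np.full(96, np.nan)
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if not fields[0] or fields[0].lower() in ("channel", "type"):
                    continue
                counts[channel_index(fields[0])] = float(fields[1])
        if np.isnan(counts).any():
            raise ValueError(f"channels missing from {path}")
        return cls(counts=counts, label=label or str(path))


@dataclass
class RainfallSeries:
    """Per-chromosome (position, distance-to-previous) series.

    The first mutation on each chromosome has distance None.
    """

    per_chromosome: dict[str, list[tuple[int, int | None]]] = field(
        default_factory=dict
    )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tdistance\n")
            for chrom, series in self.per_chromosome.items():
                for pos, dist in series:
                    fh.write(
                        f"{chrom}\t{pos}\t{'' if dist is None else dist}\n"
                    )


def classify_substitution(
    v: VariantRecord, genome: GenomeSequence
) -> tuple[int, int] | None:
    """Assign a substitution to its (type, channel) in the 96-channel scheme.

    Returns 0-based (type_index in 0..5, channel_index in 0..95), or None
    when the trinucleotide context is unavailable (chromosome end or N in
    the window). A mismatch between ``v.ref`` and the genome base at
    ``v.pos`` raises — silent skips would hide wrong-genome pairings.
    """
    if not v.is_substitution:
        raise ClassificationError(
            f"{v.chrom}:{v.pos} {v.ref}>{v.alt} is not a single-base substitution"
        )
    ref_base = genome.base(v.chrom, v.pos)
    if ref_base != v.ref:
        raise ClassificationError(
            f"reference mismatch at {v.chrom}:{v.pos}: VCF ref {v.ref!r}, "
            f"genome {ref_base!r}"
        )
    ctx = trinucleotide_context(genome, v.chrom, v.pos)
    if ctx is None:
        return None
    ref, alt = v.ref, v.alt
    if ref in "AG":
        ctx = reverse_complement(ctx)
        ref = reverse_complement(ref)
        alt = reverse_complement(alt)
    label = f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
    chan = _CHANNEL_INDEX[label]
    return chan // 16, chan


def build_spectrum(
    vs: VariantSet,
    genome: GenomeSequence,
    label: str = "",
    per_occurrence: bool = False,
) -> SbsSpectrum:
    """Count unique substitutions into a 96-channel spectrum.

    Each unique variant contributes 1 to its channel regardless of how
    many samples carry it; set ``per_occurrence`` to weight each variant
    by its carrier count instead (sensitivity analysis only).
    Unclassifiable variants (no context) are excluded and tallied in
    ``vs.diagnostics['unclassifiable_sbs']``.
    """
    counts = np.zeros(96)
    unclassifiable = 0
    for r in vs.records:
        result = classify_substitution(r, genome)
        if result is None:
            unclassifiable += 1
            continue
        _, chan = result
        counts[chan] += len(r.samples) if per_occurrence else 1
    vs.diagnostics["unclassifiable_sbs"] = unclassifiable
    return SbsSpectrum(counts=counts, label=label)


def type_fractions(s: SbsSpectrum) -> dict[str, float]:
    """Collapse 96 channels to the 6 substitution-type fractions."""
    if s.total == 0:
        raise ValueError("type fractions undefined for an empty spectrum")
    by_type = s.counts.reshape(6, 16).sum(axis=1) / s.total
    return dict(zip(SUBSTITUTION_TYPES, by_type.tolist()))


def rainfall(vs: VariantSet, genome: GenomeSequence) -> RainfallSeries:
    """Inter-mutation distances per chromosome (substitutions and indels).

    Variants are sorted by position within each chromosome; the distance
    of each mutation is its position minus the previous mutation's
    position on the same chromosome. Chromosomes are never concatenated.
    """
    series: dict[str, list[tuple[int, int | None]]] = {}
    by_chrom: dict[str, list[int]] = {}
    for r in vs.records:
        if r.chrom not in genome.chromosomes:
            raise ClassificationError(f"unknown chromosome {r.chrom!r}")
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    for chrom in genome.chromosomes:
        if chrom not in by_chrom:
            continue
        positions = sorted(set(by_chrom[chrom]))
        out: list[tuple[int, int | None]] = []
        prev: int | None = None
        for pos in positions:
            out.append((pos, None if prev is None else pos - prev))
            prev = pos
        series[chrom] = out
    return RainfallSeries(per_chromosome=series)


def end_proximity_summary(
    vs: VariantSet, genome: GenomeSequence, window: int
) -> tuple[float, dict[str, float]]:
    """Fraction of variants within ``window`` bases of either chromosome end.

    Returns (overall fraction, per-chromosome fractions). A variant at
    position p on a chromosome of length L is end-proximal when p <=
    window or p > L - window. Empty input is an error (undefined
    fraction).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not vs.records:
        raise ValueError("end proximity undefined for an empty variant set")
    near_total = 0
    per_chrom_near: dict[str, int] = {}
    per_chrom_n: dict[str, int] = {}
    for r in vs.records:
        length = genome.lengths[r.chrom]
        near = r.pos <= window or r.pos > length - window
        per_chrom_n[r.chrom] = per_chrom_n.get(r.chrom, 0) + 1
        per_chrom_near[r.chrom] = per_chrom_near.get(r.chrom, 0) + int(near)
        near_total += int(near)
    per_chrom = {
        c: per_chrom_near[c] / per_chrom_n[c] for c in per_chrom_n
    }
    return near_total / len(vs.records), per_chrom
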
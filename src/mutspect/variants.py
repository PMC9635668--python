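"""Per-sample variant handling: VCF input, quality/depth filtering, and
merging samples into a set of unique variants.

The pipeline mirrors how haploid mutation-accumulation data are handled:
each sample's calls are filtered independently (QUAL >= 30 and INFO/DP >=
10 by default), then samples are merged so that a variant called in
several isolates becomes one unique variant carrying the set of its
samples. Unique counting is the anti-selection-bias convention: a
recurrent hotspot (e.g. selected reporter-gene inactivation) contributes a
single observation to every downstream spectrum.

Variant identity is the 4-tuple (chrom, pos, ref, alt). Genotype columns
are ignored: calls are haploid, and a record's presence in a sample's VCF
defines carriage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from cyvcf2 import VCF

from .genome_io import GenomeSequence

DEFAULT_MIN_QUAL = 30.0
DEFAULT_MIN_DEPTH = 10

_VALID_ALLELE = set("ACGT")


class VariantError(ValueError):
    """Raised for malformed variant input."""


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in VCF convention (1-based, anchor-base indels)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    depth: int = 0
    samples: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"non-positive position {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - _VALID_ALLELE:
                raise VariantError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} is not "
                    "a non-empty string over ACGT"
                )
        if self.ref == self.alt:
            raise VariantError(
                f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        """True for simple anchor-base insertions/deletions.

        Exactly one of ref/alt has length 1 and is a prefix of the other.
        """
        if len(self.ref) == 1 and len(self.alt) > 1:
            return self.alt.startswith(self.ref)
        if len(self.alt) == 1 and len(self.ref) > 1:
            return self.ref.startswith(self.alt)
        return False


@dataclass
class VariantSet:
    """Unique variants merged across samples, sorted and deduplicated."""

    records: list[VariantRecord]
    n_samples: int
    n_total_calls: int
    diagnostics: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise VariantError("duplicate (chrom, pos, ref, alt) in VariantSet")
        if self.n_total_calls < len(self.records):
            raise VariantError(
                "total call count below unique record count"
            )

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tn_samples\tsamples\n")
            for r in self.records:
                fh.write(
                    f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t"
                    f"{len(r.samples)}\t{','.join(sorted(r.samples))}\n"
                )

    def to_vcf(self, path: str | Path, genome: GenomeSequence | None = None) -> None:
        """Write the merged set as a sites VCF with carrier annotation."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write(
                '##INFO=<ID=NS,Number=1,Type=Integer,'
                'Description="Number of carrying samples">\n'
            )
            fh.write(
                '##INFO=<ID=CARRIERS,Number=.,Type=String,'
                'Description="Carrying sample identifiers">\n'
            )
            if genome is not None:
                for name, length in genome.lengths.items():
                    fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in self.records:
                info = (
                    f"DP={r.depth};NS={len(r.samples)};"
                    f"CARRIERS={','.join(sorted(r.samples))}"
                )
                fh.write(
                    f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t"
                    f"{r.qual:g}\tPASS\t{info}\n"
                )


def read_vcf(path: str | Path, sample_id: str) -> list[VariantRecord]:
    """Read one sample's VCF (plain or bgzipped) into VariantRecords.

    Multi-allelic records are split into one record per alt allele, each
    sharing the line's QUAL and INFO/DP. Missing QUAL or DP become the
    sentinels 0.0 / 0, which the default filter removes. Symbolic or
    non-ACGT alt alleles (<DEL>, *, spanning deletions) are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[VariantRecord] = []
    samples = frozenset([sample_id])
    for v in VCF(str(path)):
        qual = float(v.QUAL) if v.QUAL is not None else 0.0
        dp = v.INFO.get("DP")
        depth = int(dp) if dp is not None else 0
        ref = str(v.REF).upper()
        if set(ref) - _VALID_ALLELE:
            continue
        for alt in v.ALT:
            alt = str(alt).upper()
            if not alt or set(alt) - _VALID_ALLELE or alt == ref:
                continue
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=ref,
                    alt=alt,
                    qual=qual,
                    depth=depth,
                    samples=samples,
                )
            )
    return records


def filter_variants(
    records: Iterable[VariantRecord],
    min_qual: float = DEFAULT_MIN_QUAL,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[VariantRecord]:
    """Keep records with qual >= min_qual AND depth >= min_depth.

    Order is preserved. Raising either threshold can only shrink the
    result (monotonicity).
    """
    if min_qual < 0 or min_depth < 0:
        raise VariantError("filter thresholds must be non-negative")
    return [
        r for r in records if r.qual >= min_qual and r.depth >= min_depth
    ]


def merge_unique(
    per_sample: Mapping[str, Iterable[VariantRecord]],
    chrom_order: Iterable[str] | None = None,
) -> VariantSet:
    """Merge per-sample calls into unique variants with carrier sets.

    Records are grouped by (chrom, pos, ref, alt); the samples field is
    the union of carriers, and qual/depth of a merged record is the
    per-sample maximum (reporting only — filtering happens per sample
    before merging). ``n_total_calls`` preserves the pre-deduplication
    call count.
    """
    merged: dict[tuple, VariantRecord] = {}
    n_total = 0
    all_samples: set[str] = set()
    for sample_id, records in per_sample.items():
        all_samples.add(sample_id)
        for r in records:
            n_total += 1
            carriers = r.samples if r.samples else frozenset([sample_id])
            prev = merged.get(r.key)
            if prev is None:
                merged[r.key] = replace(r, samples=carriers)
            else:
                merged[r.key] = replace(
                    prev,
                    qual=max(prev.qual, r.qual),
                    depth=max(prev.depth, r.depth),
                    samples=prev.samples | carriers,
                )
    if chrom_order is not None:
        order = {c: i for i, c in enumerate(chrom_order)}
        sort_key = lambda k: (order.get(k[0], len(order)), k[0], k[1], k[2], k[3])
    else:
        sort_key = lambda k: k
    records = [merged[k] for k in sorted(merged, key=sort_key)]
    return VariantSet(
        records=records, n_samples=len(all_samples), n_total_calls=n_total
    )


def partition_by_class(vs: VariantSet) -> tuple[VariantSet, VariantSet]:
    """Split a merged set into substitutions and simple indels.

    Records that are neither (MNVs, complex substitutions) are excluded
    and tallied under ``diagnostics['complex_count']`` on both outputs.
    """
    subs, indels, complex_count = [], [], 0
    for r in vs.records:
        if r.is_substitution:
            subs.append(r)
        elif r.is_indel:
            indels.append(r)
        else:
            complex_count += 1
    diag = {"complex_count": complex_count}
    return (
        VariantSet(subs, vs.n_samples, vs.n_total_calls, dict(diag)),
        VariantSet(indels, vs.n_samples, vs.n_total_calls, dict(diag)),
    )
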
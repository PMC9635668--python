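"""Indel normalization and 83-channel classification.

Small insertions/deletions are left-aligned against the reference, then
classified by the COSMIC ID83 scheme: 1 bp events by pyrimidine base
(T/C, strand-collapsed) and homopolymer run length; longer events by
length bin (2, 3, 4, 5+) and the number of tandem copies of the indel
unit adjacent in the reference; deletions with exactly one copy are
additionally tested for microhomology — sequence identity between the
deleted segment and its immediate flank, the hallmark of end-joining
repair — and classified into MH channels when homology exists.

The 83 channels collapse to the 16-category view used for plotting:
1 bp del C/T, 1 bp ins C/T, del 2/3/4/5+, ins 2/3/4/5+, MH-del 2/3/4/5+.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import GenomeSequence
from .sbs import ClassificationError
from .variants import VariantRecord, VariantSet

#: 16-category labels in plotting order.
CATEGORY_16: tuple[str, ...] = (
    "1bp_del_C",
    "1bp_del_T",
    "1bp_ins_C",
    "1bp_ins_T",
    "del_2",
    "del_3",
    "del_4",
    "del_5+",
    "ins_2",
    "ins_3",
    "ins_4",
    "ins_5+",
    "mh_del_2",
    "mh_del_3",
    "mh_del_4",
    "mh_del_5+",
)


def _build_id83_channels() -> tuple[tuple[str, ...], dict[str, int]]:
    """ID83 channel labels and their 16-category mapping, in COSMIC order."""
    labels: list[str] = []
    cat_of: dict[str, int] = {}
    # 1 bp deletions at C, T: homopolymer length 1..5, 6+
    for bi, base in enumerate("CT"):
        for run in ["1", "2", "3", "4", "5", "6+"]:
            lab = f"1:Del:{base}:{run}"
            labels.append(lab)
            cat_of[lab] = bi  # 1bp_del_C / 1bp_del_T
    # 1 bp insertions at C, T: adjacent homopolymer length 0..4, 5+
    for bi, base in enumerate("CT"):
        for run in ["0", "1", "2", "3", "4", "5+"]:
            lab = f"1:Ins:{base}:{run}"
            labels.append(lab)
            cat_of[lab] = 2 + bi
    # >=2 bp deletions in (possible) repeat context: repeat units 1..5, 6+
    for li, length in enumerate(["2", "3", "4", "5+"]):
        for units in ["1", "2", "3", "4", "5", "6+"]:
            lab = f"{length}:Del:R:{units}"
            labels.append(lab)
            cat_of[lab] = 4 + li
    # >=2 bp insertions: repeat units 0..4, 5+
    for li, length in enumerate(["2", "3", "4", "5+"]):
        for units in ["0", "1", "2", "3", "4", "5+"]:
            lab = f"{length}:Ins:R:{units}"
            labels.append(lab)
            cat_of[lab] = 8 + li
    # microhomology deletions: MH length 1..(length-1), capped 5+
    for li, (length, mh_bins) in enumerate(
        [("2", ["1"]), ("3", ["1", "2"]), ("4", ["1", "2", "3"]),
         ("5+", ["1", "2", "3", "4", "5+"])]
    ):
        for mh in mh_bins:
            lab = f"{length}:Del:M:{mh}"
            labels.append(lab)
            cat_of[lab] = 12 + li
    assert len(labels) == 83
    return tuple(labels), cat_of


ID83_LABELS, _CATEGORY_OF_LABEL = _build_id83_channels()
_ID83_INDEX = {lab: i for i, lab in enumerate(ID83_LABELS)}
#: For each of the 83 channels, the index of its 16-category bucket.
CHANNEL_TO_CATEGORY: tuple[int, ...] = tuple(
    _CATEGORY_OF_LABEL[lab] for lab in ID83_LABELS
)


@dataclass(frozen=True)
class IndelCall:
    """A normalized (left-aligned) indel.

    ``pos`` is the 1-based position of the anchor base, i.e. the
    reference base immediately 5' of the event; the deleted bases occupy
    pos+1 .. pos+len(sequence), and an insertion sits between pos and
    pos+1.
    """

    chrom: str
    pos: int
    kind: str  # "deletion" | "insertion"
    sequence: str
    left_aligned: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError(f"bad indel sequence {self.sequence!r}")


@dataclass
class IndelSpectrum:
    """Counts over the 83 ID83 channels in canonical order."""

    counts: np.ndarray
    label: str = ""
    diagnostics: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (83,):
            raise ValueError("indel spectrum must have exactly 83 channels")
        if np.any(self.counts < 0):
            raise ValueError("negative indel channel count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def collapse_16(self) -> dict[str, float]:
        """Collapse to the 16-category view; totals are preserved."""
        out = np.zeros(16)
        for chan, cat in enumerate(CHANNEL_TO_CATEGORY):
            out[cat] += self.counts[chan]
        return dict(zip(CATEGORY_16, out.tolist()))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("channel\tcount\n")
            for lab, c in zip(ID83_LABELS, self.counts):
                fh.write(f"{lab}\t{c:.10g}\n")

    def collapse_16_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for cat, c in self.collapse_16().items():
                fh.write(f"{cat}\t{c:.10g}\n")


def normalize_indel(v: VariantRecord, genome: GenomeSequence) -> IndelCall:
    """Strip the VCF anchor base and left-align the event.

    Left alignment shifts the event 5' while the reference permits: for
    an event with unit sequence s at anchor p, the shift is valid while
    the reference base at the 3' end of the event equals the base
    entering from the 5' side (the standard rotate-and-shift rule over
    repeated sequence).
    """
    if not v.is_indel:
        raise ClassificationError(
            f"{v.chrom}:{v.pos} {v.ref}>{v.alt} is not a simple indel"
        )
    genome_ref = genome.slice(v.chrom, v.pos, v.pos + len(v.ref) - 1)
    if genome_ref != v.ref:
        raise ClassificationError(
            f"reference mismatch at {v.chrom}:{v.pos}: VCF ref {v.ref!r}, "
            f"genome {genome_ref!r}"
        )
    if len(v.ref) > len(v.alt):
        kind, seq = "deletion", v.ref[1:]
    else:
        kind, seq = "insertion", v.alt[1:]
    pos, seq = _left_align(genome, v.chrom, v.pos, seq)
    return IndelCall(
        chrom=v.chrom, pos=pos, kind=kind, sequence=seq, left_aligned=True
    )


def _left_align(
    genome: GenomeSequence, chrom: str, pos: int, seq: str
) -> tuple[int, str]:
    """Shift an indel 5' over repeated sequence to its minimal anchor.

    The event (deletion of ``seq`` at anchor ``pos``, or insertion of
    ``seq`` after ``pos``) can shift one base left whenever the last base
    of ``seq`` equals the reference base at the anchor; the unit rotates
    as it shifts.
    """
    chrom_seq = genome.chromosomes[chrom]
    while pos >= 1 and seq[-1] == chrom_seq[pos - 1]:
        seq = chrom_seq[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def repeat_units(call: IndelCall, genome: GenomeSequence) -> int:
    """Number of repeat units of the indel's sequence at the site.

    For 1 bp events: the homopolymer run length of the base in the
    reference at the event site (for deletions the run containing the
    deleted base; for insertions the run adjacent 3' of the anchor —
    zero when the neighboring base differs).

    For >=2 bp events: the number of tandem copies of ``sequence``
    immediately 3' of the anchor in the reference. For deletions the
    deleted copy itself counts, so a deletion always has >= 1 unit; an
    insertion with no adjacent reference copy has 0.
    """
    chrom_seq = genome.chromosomes[call.chrom]
    seq, k = call.sequence, len(call.sequence)
    if k == 1:
        # run of seq bases starting at pos+1 (reference coordinates)
        i = call.pos  # 0-based index of the base after the anchor
        run = 0
        while i + run < len(chrom_seq) and chrom_seq[i + run] == seq:
            run += 1
        return run
    copies = 0
    i = call.pos  # 0-based index where the first copy would start
    while chrom_seq[i : i + k] == seq:
        copies += 1
        i += k
    return copies


def microhomology_length(call: IndelCall, genome: GenomeSequence) -> int:
    """Breakpoint microhomology of a non-repeat deletion.

    The longer of (a) the longest prefix of the deleted sequence matching
    the reference immediately 3' of the deletion and (b) the longest
    suffix matching immediately 5' of it, capped at length-1. Only
    defined for deletions of length >= 2 with exactly one repeat unit.
    """
    if call.kind != "deletion":
        raise ValueError("microhomology is defined for deletions only")
    seq, k = call.sequence, len(call.sequence)
    if k < 2:
        raise ValueError("microhomology requires deletion length >= 2")
    if repeat_units(call, genome) != 1:
        raise ValueError(
            "microhomology is undefined in a tandem-repeat context"
        )
    chrom_seq = genome.chromosomes[call.chrom]
    right = chrom_seq[call.pos + k :]  # 3' flank after the deleted bases
    left = chrom_seq[: call.pos]  # 5' flank up to and incl. the anchor
    prefix = 0
    while prefix < k - 1 and prefix < len(right) and seq[prefix] == right[prefix]:
        prefix += 1
    suffix = 0
    while (
        suffix < k - 1
        and suffix < len(left)
        and seq[k - 1 - suffix] == left[len(left) - 1 - suffix]
    ):
        suffix += 1
    return max(prefix, suffix)


def _bin_label(value: int, top: int) -> str:
    """Bin an integer as '<value>' below ``top``, else '<top>+'."""
    return f"{top}+" if value >= top else str(value)


def classify_indel(call: IndelCall, genome: GenomeSequence) -> int:
    """0-based ID83 channel of a normalized indel.

    Priority: (1) 1 bp events by pyrimidine base and homopolymer run;
    (2) >=2 bp events binned by length and adjacent repeat-unit count;
    (3) deletions with exactly one unit and microhomology >= 1 go to MH
    channels; (4) everything else stays in its repeat bin (1 for
    deletions, 0 for insertions).
    """
    seq, k = call.sequence, len(call.sequence)
    units = repeat_units(call, genome)
    if k == 1:
        base = seq if seq in "CT" else {"A": "T", "G": "C"}[seq]
        if call.kind == "deletion":
            run = _bin_label(max(units, 1), 6)
            lab = f"1:Del:{base}:{run}"
        else:
            run = _bin_label(units, 5)
            lab = f"1:Ins:{base}:{run}"
        return _ID83_INDEX[lab]
    length = _bin_label(k, 5)
    if call.kind == "insertion":
        lab = f"{length}:Ins:R:{_bin_label(units, 5)}"
        return _ID83_INDEX[lab]
    if units >= 2:
        lab = f"{length}:Del:R:{_bin_label(units, 6)}"
        return _ID83_INDEX[lab]
    mh = microhomology_length(call, genome)
    if mh >= 1:
        if k >= 5:
            lab = f"5+:Del:M:{_bin_label(min(mh, 5), 5)}"
        else:
            lab = f"{k}:Del:M:{min(mh, k - 1)}"
        return _ID83_INDEX[lab]
    return _ID83_INDEX[f"{length}:Del:R:1"]


def build_indel_spectrum(
    vs: VariantSet, genome: GenomeSequence, label: str = ""
) -> IndelSpectrum:
    """Count unique indels into an ID83 spectrum.

    Unique indels each count once regardless of carrier count. Records
    that are not simple indels are excluded and tallied.
    """
    counts = np.zeros(83)
    unclassifiable = 0
    for r in vs.records:
        if not r.is_indel:
            unclassifiable += 1
            continue
        call = normalize_indel(r, genome)
        counts[classify_indel(call, genome)] += 1
    diag = {
        "total_calls": vs.n_total_calls,
        "unique": len(vs.records),
        "unclassifiable": unclassifiable,
    }
    return IndelSpectrum(counts=counts, label=label, diagnostics=diag)
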
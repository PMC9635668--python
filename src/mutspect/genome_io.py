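"""Reference-genome handling: FASTA input, trinucleotide contexts, and
genome-wide trinucleotide abundances.

Genomes are held fully in memory as uppercase strings over {A,C,G,T,N};
the yeast-scale genomes this package targets (~12 Mb) make random-access
indexing unnecessary. All coordinates are 1-based inclusive, matching the
VCF convention used throughout the package.

Trinucleotide abundances follow the mutational-signature convention:
counts for motifs centered on A or G are folded into their reverse
complements, leaving 32 pyrimidine-centered motifs (5' base x {C,T} x
3' base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The 32 pyrimidine-centered trinucleotide motifs in lexicographic order
#: (5' base, center in {C,T}, 3' base; each flank ordered A,C,G,T).
PYRIMIDINE_MOTIFS: tuple[str, ...] = tuple(
    five + center + three
    for center in "CT"
    for five in "ACGT"
    for three in "ACGT"
)

_MOTIF_INDEX = {m: i for i, m in enumerate(PYRIMIDINE_MOTIFS)}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def pyrimidine_motif(trinuc: str) -> str:
    """Collapse a trinucleotide onto its pyrimidine-centered representative.

    Motifs centered on A or G are reverse-complemented; motifs centered on
    C or T are returned unchanged.
    """
    if trinuc[1] in "CT":
        return trinuc
    return reverse_complement(trinuc)


class GenomeError(ValueError):
    """Raised for malformed or inconsistent genome input."""


@dataclass
class GenomeSequence:
    """Named chromosome sequences with insertion order preserved.

    ``chromosomes`` maps chromosome name to an uppercase nucleotide string
    over {A,C,G,T,N}.
    """

    chromosomes: dict[str, str]
    lengths: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not name:
                raise GenomeError("empty chromosome name")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise GenomeError(
                    f"chromosome {name!r} contains non-IUPAC characters: "
                    f"{sorted(bad)}"
                )
        self.lengths = {n: len(s) for n, s in self.chromosomes.items()}

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self._seq(chrom, pos)
        return seq[pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Reference bases in the closed interval [start, end], 1-based."""
        seq = self.chromosomes[chrom]
        if start < 1 or end > len(seq):
            raise GenomeError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"(length {len(seq)})"
            )
        return seq[start - 1 : end]

    def _seq(self, chrom: str, pos: int) -> str:
        try:
            seq = self.chromosomes[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None
        if not 1 <= pos <= len(seq):
            raise GenomeError(
                f"position {pos} outside {chrom} (length {len(seq)})"
            )
        return seq


@dataclass
class TrinucFrequencies:
    """Proportions of the 32 pyrimidine-centered trinucleotide motifs.

    ``proportions`` has exactly the keys of :data:`PYRIMIDINE_MOTIFS`;
    values are non-negative and sum to 1 when ``total_count`` > 0.
    """

    proportions: dict[str, float]
    total_count: int

    def __post_init__(self) -> None:
        if set(self.proportions) != set(PYRIMIDINE_MOTIFS):
            raise GenomeError(
                "trinucleotide table must cover exactly the 32 "
                "pyrimidine-centered motifs"
            )
        if any(p < 0 for p in self.proportions.values()):
            raise GenomeError("negative trinucleotide proportion")
        if self.total_count > 0:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise GenomeError(
                    f"proportions sum to {total!r}, expected 1"
                )

    def as_array(self) -> np.ndarray:
        """Proportions as a length-32 vector in canonical motif order."""
        return np.array(
            [self.proportions[m] for m in PYRIMIDINE_MOTIFS], dtype=float
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write a two-column (motif, proportion) table."""
        with open(path, "w") as fh:
            fh.write("motif\tproportion\n")
            for m in PYRIMIDINE_MOTIFS:
                fh.write(f"{m}\t{self.proportions[m]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TrinucFrequencies":
        """Read a (motif, proportion) table written by :meth:`to_tsv`.

        Accepts any row order; a header line is detected and skipped.
        Proportions are renormalized to sum to 1 so that raw counts are
        also accepted.
        """
        props: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if not fields or not fields[0]:
                    continue
                if fields[0].lower() in ("motif", "trinucleotide", "context"):
                    continue
                motif, value = fields[0], float(fields[1])
                if motif not in _MOTIF_INDEX:
                    raise GenomeError(
                        f"unknown motif {motif!r} in {path}"
                    )
                props[motif] = value
        missing = set(PYRIMIDINE_MOTIFS) - set(props)
        if missing:
            raise GenomeError(f"motifs missing from {path}: {sorted(missing)}")
        total = sum(props.values())
        if total <= 0:
            raise GenomeError(f"non-positive proportion total in {path}")
        return cls(
            proportions={m: v / total for m, v in props.items()},
            total_count=0,
        )


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-record) FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased and U is mapped to T; any other character
    outside {A,C,G,T,N} is rejected. Record order is preserved and
    duplicate record names are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise GenomeError(f"duplicate chromosome name {record.id!r}")
        seq = str(record.seq).upper().replace("U", "T")
        chromosomes[record.id] = seq
    if not chromosomes:
        raise GenomeError(f"no FASTA records in {path}")
    return GenomeSequence(chromosomes)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    """Write a genome as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def trinucleotide_context(
    genome: GenomeSequence, chrom: str, pos: int
) -> str | None:
    """Reference-strand 3-mer centered on ``pos`` (1-based).

    Returns None when no context exists: at a chromosome end (missing
    flank) or when any base in the window is N. Unknown chromosomes and
    out-of-range positions raise :class:`GenomeError`.
    """
    seq = genome._seq(chrom, pos)
    if pos == 1 or pos == len(seq):
        return None
    ctx = seq[pos - 2 : pos + 1]
    if "N" in ctx:
        return None
    return ctx


def count_trinucleotides(
    genome: GenomeSequence, exclude: Iterable[str] = ()
) -> TrinucFrequencies:
    """Tabulate pyrimidine-collapsed trinucleotide proportions genome-wide.

    Every width-3 window with both flanks present is counted; windows
    containing N are skipped; windows centered on A or G count toward
    their reverse-complement motif. ``exclude`` names chromosomes to
    leave out (e.g. a mitochondrial contig or reporter cassette).

    Raises if no countable window exists.
    """
    exclude = set(exclude)
    unknown = exclude - set(genome.chromosomes)
    if unknown:
        raise GenomeError(f"exclusion list names unknown chromosomes: {sorted(unknown)}")
    counts = np.zeros(32, dtype=np.int64)
    # vectorized sliding-window count: encode bases, build 3-mer codes
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    # motif code for (5', center, 3') with pyrimidine collapsing, precomputed
    motif_of_code = np.empty(64, dtype=np.int64)
    for c5 in range(4):
        for cc in range(4):
            for c3 in range(4):
                tri = "ACGT"[c5] + "ACGT"[cc] + "ACGT"[c3]
                motif_of_code[c5 * 16 + cc * 4 + c3] = _MOTIF_INDEX[
                    pyrimidine_motif(tri)
                ]
    for name, seq in genome.chromosomes.items():
        if name in exclude or len(seq) < 3:
            continue
        arr = code[np.frombuffer(seq.encode(), dtype=np.uint8)]
        valid = arr >= 0
        win_ok = valid[:-2] & valid[1:-1] & valid[2:]
        codes = arr[:-2] * 16 + arr[1:-1] * 4 + arr[2:]
        codes = codes[win_ok]
        counts += np.bincount(motif_of_code[codes], minlength=32)
    total = int(counts.sum())
    if total == 0:
        raise GenomeError("genome has no countable trinucleotide window")
    props = counts / total
    return TrinucFrequencies(
        proportions={m: float(props[i]) for i, m in enumerate(PYRIMIDINE_MOTIFS)},
        total_count=total,
    )
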
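"""Synthetic mutagenized-genome generator.

Emulates the data structure of an ssDNA mutagenesis experiment: a small
multi-chromosome haploid genome; point mutations drawn from a specified
96-channel signature; indels drawn from a specified 16-category
distribution; enrichment of events near chromosome ends (where
subtelomeric ssDNA forms under the reporter system's restrictive
conditions); recurrence of some variants across samples; and per-variant
QUAL/DP annotations with a configurable fraction failing the standard
quality/depth filter.

Substitution sites are drawn channel-first: a channel is drawn from the
signature, then a genomic site whose pyrimidine-collapsed trinucleotide
matches the channel's motif is drawn (position-weighted, without
replacement within a channel). This guarantees the realized unique-
variant spectrum is an exact multinomial draw from the signature,
independent of the genome's motif composition — a site-first scheme
would convolve the two and blunt parameter-recovery tests.

Truth tables record every event's channel/category so tests never
re-derive ground truth from the classifiers under test; the generator's
own placement checks for indel categories are written inline here and do
not call the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    COMPLEMENT,
    GenomeSequence,
    PYRIMIDINE_MOTIFS,
    write_fasta,
)
from .indels import CATEGORY_16
from .sbs import CHANNEL_LABELS, channel_motif
from .variants import VariantRecord

_MOTIF_INDEX = {m: i for i, m in enumerate(PYRIMIDINE_MOTIFS)}


def flat_signature() -> np.ndarray:
    """Uniform mass over all 96 channels."""
    return np.full(96, 1.0 / 96)


def aldehyde_like_signature() -> np.ndarray:
    """A broad signature with elevated C>A mass, strongest at tCn motifs.

    Shaped after small-aldehyde mutagenesis of ssDNA: a flat background
    over all channels (translesion-synthesis-like), a threefold boost of
    the 16 C>A channels, and a further threefold boost of the T[C>A]N
    channels where guanine adducts preferentially mutate.
    """
    w = np.ones(96)
    for c, lab in enumerate(CHANNEL_LABELS):
        if lab[2:5] == "C>A":
            w[c] *= 3.0
            if lab[0] == "T":
                w[c] *= 3.0
    return w / w.sum()


def control_like_indel_distribution() -> np.ndarray:
    """16-category indel mix dominated by 1 bp homopolymer slippage."""
    d = {
        "1bp_del_C": 0.15, "1bp_del_T": 0.25, "1bp_ins_C": 0.10,
        "1bp_ins_T": 0.20, "del_2": 0.05, "del_3": 0.03, "del_4": 0.02,
        "del_5+": 0.02, "ins_2": 0.04, "ins_3": 0.03, "ins_4": 0.02,
        "ins_5+": 0.01, "mh_del_2": 0.03, "mh_del_3": 0.02,
        "mh_del_4": 0.02, "mh_del_5+": 0.01,
    }
    return np.array([d[c] for c in CATEGORY_16])


def acetaldehyde_like_indel_distribution() -> np.ndarray:
    """16-category mix with elevated 5+ bp deletion mass (no MH)."""
    d = {
        "1bp_del_C": 0.12, "1bp_del_T": 0.18, "1bp_ins_C": 0.08,
        "1bp_ins_T": 0.12, "del_2": 0.04, "del_3": 0.03, "del_4": 0.03,
        "del_5+": 0.22, "ins_2": 0.03, "ins_3": 0.02, "ins_4": 0.02,
        "ins_5+": 0.01, "mh_del_2": 0.03, "mh_del_3": 0.02,
        "mh_del_4": 0.02, "mh_del_5+": 0.03,
    }
    return np.array([d[c] for c in CATEGORY_16])


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    Defaults describe a scaled-down haploid yeast-like setting: 16
    chromosomes of 50 kb at 38% GC, tenfold mutation enrichment within
    5 kb of chromosome ends, 10 sequenced isolates with a few hundred
    substitutions and a few dozen indels each, 5% cross-sample
    recurrence, and 5% of raw calls failing each of the QUAL>=30 and
    DP>=10 cutoffs.
    """

    seed: int = 0
    n_chromosomes: int = 16
    chromosome_length: int = 50_000
    gc_content: float = 0.38
    subtelomere_window: int = 5_000
    subtelomere_enrichment: float = 10.0
    n_samples: int = 10
    substitutions_per_sample: int = 300
    signature: np.ndarray = field(default_factory=aldehyde_like_signature)
    indels_per_sample: int = 30
    indel_distribution: np.ndarray = field(
        default_factory=control_like_indel_distribution
    )
    recurrence_rate: float = 0.05
    low_qual_fraction: float = 0.05
    low_depth_fraction: float = 0.05

    def __post_init__(self) -> None:
        self.signature = np.asarray(self.signature, dtype=float)
        self.indel_distribution = np.asarray(self.indel_distribution, dtype=float)
        if self.signature.shape != (96,) or np.any(self.signature < 0):
            raise ValueError("signature must be a non-negative 96-vector")
        if abs(self.signature.sum() - 1) > 1e-9:
            raise ValueError("signature must sum to 1")
        if self.indel_distribution.shape != (16,) or np.any(
            self.indel_distribution < 0
        ):
            raise ValueError("indel distribution must be a non-negative 16-vector")
        if abs(self.indel_distribution.sum() - 1) > 1e-9:
            raise ValueError("indel distribution must sum to 1")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be strictly between 0 and 1")
        if self.subtelomere_enrichment < 1:
            raise ValueError("subtelomere_enrichment must be >= 1")
        if not 0 <= self.recurrence_rate <= 1:
            raise ValueError("recurrence_rate must be a probability")
        for name in ("n_chromosomes", "chromosome_length", "n_samples",
                     "substitutions_per_sample", "indels_per_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def expected_filtered_fraction(self) -> float:
        """Expected fraction of raw calls removed by the default filter."""
        return 1.0 - (1.0 - self.low_qual_fraction) * (
            1.0 - self.low_depth_fraction
        )


@dataclass
class SimResult:
    """Per-sample calls plus the generating truth table."""

    per_sample: dict[str, list[VariantRecord]]
    truth: pd.DataFrame  # sample, chrom, pos, ref, alt, channel, category


def generate_genome(cfg: SimConfig) -> GenomeSequence:
    """I.i.d. random genome at the configured GC fraction, seed-reproducible."""
    rng = np.random.default_rng([cfg.seed, 0])
    p = np.array(
        [(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
         cfg.gc_content / 2, (1 - cfg.gc_content) / 2]
    )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms: dict[str, str] = {}
    for i in range(cfg.n_chromosomes):
        draw = rng.choice(bases, size=cfg.chromosome_length, p=p)
        chroms[f"chr{i + 1}"] = draw.tobytes().decode()
    return GenomeSequence(chroms)


def _motif_site_index(
    genome: GenomeSequence,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per pyrimidine-motif index of genomic sites.

    Returns motif index -> (chrom ids, 1-based positions) over all
    interior positions whose pyrimidine-collapsed context is that motif.
    """
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    motif_of_code = np.empty(64, dtype=np.int64)
    for c5 in range(4):
        for cc in range(4):
            for c3 in range(4):
                tri = "ACGT"[c5] + "ACGT"[cc] + "ACGT"[c3]
                if tri[1] in "CT":
                    pyr = tri
                else:
                    pyr = "".join(COMPLEMENT[b] for b in reversed(tri))
                motif_of_code[c5 * 16 + cc * 4 + c3] = _MOTIF_INDEX[pyr]
    chrom_ids: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    motifs: list[np.ndarray] = []
    for ci, (name, seq) in enumerate(genome.chromosomes.items()):
        if len(seq) < 3:
            continue
        arr = code[np.frombuffer(seq.encode(), dtype=np.uint8)]
        valid = (arr[:-2] >= 0) & (arr[1:-1] >= 0) & (arr[2:] >= 0)
        codes = arr[:-2] * 16 + arr[1:-1] * 4 + arr[2:]
        pos = np.arange(2, len(seq), dtype=np.int64)  # 1-based center
        pos = pos[valid]
        codes = codes[valid]
        chrom_ids.append(np.full(len(pos), ci, dtype=np.int64))
        positions.append(pos)
        motifs.append(motif_of_code[codes])
    if not positions:
        raise ValueError("genome too short to host any mutation")
    chrom_id = np.concatenate(chrom_ids)
    pos_all = np.concatenate(positions)
    motif_all = np.concatenate(motifs)
    index: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for m in range(32):
        sel = motif_all == m
        index[m] = (chrom_id[sel], pos_all[sel])
    return index


def _position_weights(
    positions: np.ndarray, length: int, window: int, enrichment: float
) -> np.ndarray:
    near = (positions <= window) | (positions > length - window)
    return np.where(near, enrichment, 1.0)


def _sample_weighted_position(
    rng: np.random.Generator, length: int, window: int, enrichment: float
) -> int:
    """One 1-based position under the end-enrichment weight model."""
    w = min(window, length // 2)
    end_mass = 2 * w * enrichment
    mid_mass = max(length - 2 * w, 0)
    if rng.random() < end_mass / (end_mass + mid_mass):
        p = int(rng.integers(1, 2 * w + 1))
        return p if p <= w else length - (p - w) + 1
    return int(rng.integers(w + 1, length - w + 1))


def _draw_qual_depth(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[float, int]:
    if rng.random() < cfg.low_qual_fraction:
        qual = float(rng.uniform(0, 29.9))
    else:
        qual = float(rng.uniform(30, 90))
    if rng.random() < cfg.low_depth_fraction:
        depth = int(rng.integers(0, 10))
    else:
        depth = int(rng.integers(10, 61))
    return round(qual, 1), depth


class SimulationError(RuntimeError):
    """Raised when the configuration cannot be realized on the genome."""


_MAX_REJECTION_FACTOR = 500


def spike_mutations(genome: GenomeSequence, cfg: SimConfig) -> SimResult:
    """Draw substitutions and indels onto a genome, per-sample.

    Returns per-sample VariantRecords (the genome itself is never
    edited, so every REF matches the reference) and a truth table with
    one row per (event, carrying sample).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    chrom_names = list(genome.chromosomes)
    sample_ids = [f"s{i + 1:02d}" for i in range(cfg.n_samples)]
    per_sample: dict[str, list[VariantRecord]] = {s: [] for s in sample_ids}
    truth_rows: list[dict] = []
    used_keys: set[tuple] = set()

    def emit(chrom: str, pos: int, ref: str, alt: str,
             channel: str, category: str) -> None:
        primary = int(rng.integers(0, cfg.n_samples))
        carriers = [sample_ids[primary]]
        if cfg.n_samples > 1 and rng.random() < cfg.recurrence_rate:
            other = int(rng.integers(0, cfg.n_samples - 1))
            if other >= primary:
                other += 1
            carriers.append(sample_ids[other])
        for sid in carriers:
            qual, depth = _draw_qual_depth(rng, cfg)
            per_sample[sid].append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    qual=qual, depth=depth, samples=frozenset([sid]),
                )
            )
            truth_rows.append(
                dict(sample=sid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                     channel=channel, category=category)
            )

    # --- substitutions: channel-first, weighted, without replacement ---
    n_subs = cfg.n_samples * cfg.substitutions_per_sample
    if n_subs > 0:
        site_index = _motif_site_index(genome)
        channel_counts = rng.multinomial(n_subs, cfg.signature)
        for chan in range(96):
            k = int(channel_counts[chan])
            if k == 0:
                continue
            motif = channel_motif(chan)
            chrom_ids, positions = site_index[_MOTIF_INDEX[motif]]
            if len(positions) < k:
                raise SimulationError(
                    f"channel {CHANNEL_LABELS[chan]} needs {k} sites but the "
                    f"genome offers only {len(positions)} {motif} positions"
                )
            lengths = np.array(
                [genome.lengths[chrom_names[c]] for c in chrom_ids]
            )
            w = np.where(
                (positions <= cfg.subtelomere_window)
                | (positions > lengths - cfg.subtelomere_window),
                cfg.subtelomere_enrichment,
                1.0,
            )
            pick = rng.choice(
                len(positions), size=k, replace=False, p=w / w.sum()
            )
            lab = CHANNEL_LABELS[chan]
            pyr_ref, pyr_alt = lab[2], lab[4]
            for idx in np.sort(pick):
                chrom = chrom_names[chrom_ids[idx]]
                pos = int(positions[idx])
                ref = genome.base(chrom, pos)
                alt = pyr_alt if ref == pyr_ref else COMPLEMENT[pyr_alt]
                emit(chrom, pos, ref, alt, channel=lab, category="")
                used_keys.add((chrom, pos, ref, alt))

    # --- indels: 16-category multinomial with rejection placement ---
    n_indels = cfg.n_samples * cfg.indels_per_sample
    if n_indels > 0:
        category_counts = rng.multinomial(n_indels, cfg.indel_distribution)
        for cat_i, cat in enumerate(CATEGORY_16):
            for _ in range(int(category_counts[cat_i])):
                chrom, pos, ref, alt = _place_indel(
                    rng, genome, chrom_names, cat, cfg, used_keys
                )
                emit(chrom, pos, ref, alt, channel="", category=cat)
                used_keys.add((chrom, pos, ref, alt))

    for sid in sample_ids:
        order = {c: i for i, c in enumerate(chrom_names)}
        per_sample[sid].sort(key=lambda r: (order[r.chrom], r.pos, r.ref, r.alt))
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "channel", "category"],
    )
    return SimResult(per_sample=per_sample, truth=truth)


def _place_indel(
    rng: np.random.Generator,
    genome: GenomeSequence,
    chrom_names: list[str],
    category: str,
    cfg: SimConfig,
    used_keys: set,
) -> tuple[str, int, str, str]:
    """Rejection-sample a reference site realizing one 16-category event.

    All placement checks are direct string comparisons against the
    reference (left-alignedness, absence/presence of flank homology,
    absence of tandem copies) — independent of the classifier they are
    later tested against.
    """
    for _ in range(_MAX_REJECTION_FACTOR):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        seq = genome.chromosomes[chrom]
        L = len(seq)
        pos = _sample_weighted_position(
            rng, L, cfg.subtelomere_window, cfg.subtelomere_enrichment
        )
        result = _try_place(rng, seq, pos, category)
        if result is None:
            continue
        anchor_pos, ref, alt = result
        if (chrom, anchor_pos, ref, alt) in used_keys:
            continue
        return chrom, anchor_pos, ref, alt
    raise SimulationError(
        f"could not place an indel of category {category!r} after "
        f"{_MAX_REJECTION_FACTOR} attempts"
    )


def _try_place(
    rng: np.random.Generator, seq: str, pos: int, category: str
) -> tuple[int, str, str] | None:
    """Try to realize ``category`` near 1-based ``pos``; None to resample."""
    L = len(seq)
    if category.startswith("1bp_del_"):
        want = category[-1]  # C or T, strand-collapsed
        if pos < 2 or pos > L:
            return None
        base = seq[pos - 1]
        if base not in (want, COMPLEMENT[want]):
            return None
        anchor = pos - 1
        return anchor, seq[anchor - 1 : pos], seq[anchor - 1]
    if category.startswith("1bp_ins_"):
        want = category[-1]
        if pos < 1 or pos > L - 1:
            return None
        ins = want if rng.random() < 0.5 else COMPLEMENT[want]
        anchor_base = seq[pos - 1]
        return pos, anchor_base, anchor_base + ins
    kind, length_lab = (
        ("del", category[4:]) if category.startswith("del_")
        else ("ins", category[4:]) if category.startswith("ins_")
        else ("mh", category[7:])
    )
    k = int(rng.integers(5, 9)) if length_lab == "5+" else int(length_lab)
    if kind == "ins":
        if pos < 1 or pos > L - 1:
            return None
        ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=k))
        anchor_base = seq[pos - 1]
        if ins[-1] == anchor_base:  # keep the emitted record left-aligned
            return None
        return pos, anchor_base, anchor_base + ins
    # deletion: deleted segment is seq[pos-1 : pos-1+k] (0-based), anchor pos-1
    s0 = pos - 1  # 0-based start of deleted segment
    if pos < 2 or s0 + 2 * k > L:
        return None
    deleted = seq[s0 : s0 + k]
    anchor_base = seq[s0 - 1]
    if deleted[-1] == anchor_base:  # would left-shift
        return None
    if seq[s0 + k : s0 + 2 * k] == deleted:  # tandem copy -> repeat context
        return None
    prefix_mh = seq[s0 + k] == deleted[0]
    if kind == "del" and prefix_mh:
        return None
    if kind == "mh" and not prefix_mh:
        return None
    anchor = pos - 1
    return anchor, seq[anchor - 1 : s0 + k], anchor_base


def write_sample_vcfs(
    genome: GenomeSequence,
    per_sample: dict[str, list[VariantRecord]],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one VCF 4.2 per sample (QUAL column, INFO/DP, haploid GT)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, records in per_sample.items():
        path = out_dir / f"{sid}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##source=mutspect-simulate\n')
            for name, length in genome.lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write(
                '##INFO=<ID=DP,Number=1,Type=Integer,'
                'Description="Read depth">\n'
            )
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,'
                'Description="Genotype">\n'
            )
            fh.write(
                f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sid}\n"
            )
            for r in records:
                fh.write(
                    f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t"
                    f"{r.qual:.1f}\t.\tDP={r.depth}\tGT\t1\n"
                )
        paths[sid] = path
    return paths


def simulate_dataset(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Generate genome + per-sample VCFs + truth table under ``out_dir``.

    Returns a manifest dict with file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(cfg)
    fasta = out_dir / "genome.fa"
    write_fasta(genome, fasta)
    result = spike_mutations(genome, cfg)
    vcf_paths = write_sample_vcfs(genome, result.per_sample, out_dir / "vcf")
    truth_path = out_dir / "truth.tsv"
    result.truth.to_csv(truth_path, sep="\t", index=False)
    return {
        "genome": fasta,
        "vcfs": vcf_paths,
        "truth": truth_path,
        "samples": list(result.per_sample),
    }
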
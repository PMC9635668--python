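"""Independent brute-force reference implementations.

Straight-line, loop-based code kept deliberately separate from the
package internals so that oracle-equivalence tests compare two
independent derivations of each quantity.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def brute_trinuc_counts(chroms: dict[str, str]) -> dict[str, int]:
    """Window-by-window pyrimidine-collapsed trinucleotide counts."""
    counts: dict[str, int] = {}
    for seq in chroms.values():
        for i in range(1, len(seq) - 1):
            w = seq[i - 1 : i + 2]
            if "N" in w:
                continue
            if w[1] not in "CT":
                w = revcomp(w)
            counts[w] = counts.get(w, 0) + 1
    return counts


def brute_sbs_label(ctx: str, ref: str, alt: str) -> str:
    """SBS channel label via explicit enumeration of both strands."""
    assert ctx[1] == ref
    forward = f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
    rc_ctx = revcomp(ctx)
    reverse = f"{rc_ctx[0]}[{_COMP[ref]}>{_COMP[alt]}]{rc_ctx[2]}"
    return forward if ref in "CT" else reverse


def brute_left_align_deletion(chrom_seq: str, start0: int, k: int) -> tuple[int, str]:
    """Minimal-position representation of deleting chrom_seq[start0:start0+k].

    Returns (0-based start of the left-most equivalent deleted segment,
    the deleted sequence there), found by exhaustive comparison of the
    resulting strings.
    """
    target = chrom_seq[:start0] + chrom_seq[start0 + k :]
    for s in range(start0 + 1):
        if chrom_seq[:s] + chrom_seq[s + k :] == target:
            return s, chrom_seq[s : s + k]
    raise AssertionError("unreachable")


def brute_left_align_insertion(
    chrom_seq: str, anchor0: int, ins: str
) -> tuple[int, str]:
    """Minimal-anchor representation of inserting ``ins`` after anchor0.

    anchor0 is the 0-based index of the base the insertion follows (-1
    for an insertion before the first base). Returns the left-most
    equivalent (anchor0', inserted sequence).
    """
    k = len(ins)
    target = chrom_seq[: anchor0 + 1] + ins + chrom_seq[anchor0 + 1 :]
    for a in range(-1, anchor0 + 1):
        cand = target[a + 1 : a + 1 + k]
        if chrom_seq[: a + 1] + cand + chrom_seq[a + 1 :] == target:
            return a, cand
    raise AssertionError("unreachable")


def brute_repeat_units(
    chrom_seq: str, anchor0: int, kind: str, seq: str
) -> int:
    """Tandem-copy scan. anchor0 = 0-based anchor base index."""
    k = len(seq)
    i = anchor0 + 1
    if k == 1:
        run = 0
        while i + run < len(chrom_seq) and chrom_seq[i + run] == seq:
            run += 1
        return run
    copies = 0
    while chrom_seq[i : i + k] == seq:
        copies += 1
        i += k
    return copies


def brute_microhomology(chrom_seq: str, anchor0: int, seq: str) -> int:
    """Two-sided breakpoint-homology scan for a deletion, capped at k-1."""
    k = len(seq)
    del_start = anchor0 + 1
    right = chrom_seq[del_start + k :]
    left = chrom_seq[:del_start]
    prefix = 0
    for i in range(min(k - 1, len(right))):
        if seq[i] == right[i]:
            prefix += 1
        else:
            break
    suffix = 0
    for i in range(min(k - 1, len(left))):
        if seq[k - 1 - i] == left[len(left) - 1 - i]:
            suffix += 1
        else:
            break
    return max(prefix, suffix)


def brute_indel_channel(chrom_seq: str, anchor0: int, kind: str, seq: str) -> str:
    """ID83 label by a straight-line rewrite of the 4-step priority rule.

    Expects an already left-aligned event.
    """
    k = len(seq)
    units = brute_repeat_units(chrom_seq, anchor0, kind, seq)

    def bin_(v: int, top: int) -> str:
        return f"{top}+" if v >= top else str(v)

    if k == 1:
        base = seq if seq in "CT" else _COMP[seq]
        if kind == "deletion":
            return f"1:Del:{base}:{bin_(max(units, 1), 6)}"
        return f"1:Ins:{base}:{bin_(units, 5)}"
    length = bin_(k, 5)
    if kind == "insertion":
        return f"{length}:Ins:R:{bin_(units, 5)}"
    if units >= 2:
        return f"{length}:Del:R:{bin_(units, 6)}"
    mh = brute_microhomology(chrom_seq, anchor0, seq)
    if mh >= 1:
        if k >= 5:
            return f"5+:Del:M:{bin_(min(mh, 5), 5)}"
        return f"{k}:Del:M:{min(mh, k - 1)}"
    return f"{length}:Del:R:1"


def brute_filter(records, min_qual, min_depth):
    return [r for r in records if r.qual >= min_qual and r.depth >= min_depth]


def brute_merge_keys(per_sample) -> dict[tuple, set]:
    """Dictionary grouping of calls by (chrom, pos, ref, alt)."""
    groups: dict[tuple, set] = {}
    for sample_id, records in per_sample.items():
        for r in records:
            groups.setdefault((r.chrom, r.pos, r.ref, r.alt), set()).add(sample_id)
    return groups


def brute_cosine(a, b) -> float:
    dot = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    return dot / (na * nb)
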
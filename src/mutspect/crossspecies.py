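"""Cross-species trinucleotide-frequency correction of SBS spectra.

A mutational pattern measured in one genome reflects that genome's motif
abundances. To predict how the same mutational process would appear in
another species, each of the 96 channel frequencies is multiplied by the
ratio of the target genome's proportion of the channel's trinucleotide
motif to the source genome's proportion: a motif half as abundant in the
target scales its channels by 0.5. The corrected vector is renormalized
to sum to 1; downstream cosine comparisons are scale-invariant, so the
renormalization changes no similarity value.
"""

from __future__ import annotations

import warnings

import numpy as np

from .genome_io import PYRIMIDINE_MOTIFS, TrinucFrequencies
from .sbs import SbsSpectrum, channel_motif

_MOTIF_INDEX = {m: i for i, m in enumerate(PYRIMIDINE_MOTIFS)}
#: For each of the 96 channels, the index of its motif in the 32-motif order.
CHANNEL_MOTIF_INDEX: tuple[int, ...] = tuple(
    _MOTIF_INDEX[channel_motif(c)] for c in range(96)
)


def channel_multipliers(
    source: TrinucFrequencies, target: TrinucFrequencies
) -> np.ndarray:
    """Per-channel ratio p_target(motif) / p_source(motif), length 96.

    Channels whose motif has zero source proportion get NaN (undefined);
    :func:`correct_spectrum` rejects those only when the spectrum puts
    mass there.
    """
    p_src = source.as_array()[list(CHANNEL_MOTIF_INDEX)]
    p_tgt = target.as_array()[list(CHANNEL_MOTIF_INDEX)]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(p_src > 0, p_tgt / p_src, np.nan)


def correct_spectrum(
    s: SbsSpectrum,
    source: TrinucFrequencies,
    target: TrinucFrequencies,
) -> tuple[SbsSpectrum, np.ndarray]:
    """Re-weight a spectrum from source-genome to target-genome motif
    abundances.

    Returns the corrected spectrum (as frequencies summing to 1) and the
    per-channel multipliers applied before renormalization. A motif with
    zero source proportion but nonzero spectrum mass is an error (the
    ratio is undefined); a motif with zero *target* proportion zeroes its
    channels with a warning (it cannot mutate in the target genome).
    """
    f = s.as_frequencies()
    mult = channel_multipliers(source, target)
    undefined = np.isnan(mult) & (f > 0)
    if undefined.any():
        bad = [channel_motif(c) for c in np.flatnonzero(undefined)]
        raise ValueError(
            "source proportion is zero for motifs with spectrum mass: "
            f"{sorted(set(bad))}"
        )
    mult_safe = np.nan_to_num(mult, nan=0.0)
    zeroed = (mult_safe == 0) & (f > 0)
    if zeroed.any():
        warnings.warn(
            "channels with zero target motif proportion were removed "
            "before renormalization",
            stacklevel=2,
        )
    corrected = f * mult_safe
    total = corrected.sum()
    if total <= 0:
        raise ValueError("correction removed all spectrum mass")
    return (
        SbsSpectrum(counts=corrected / total, label=f"{s.label} (corrected)"),
        mult,
    )
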
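"""Canonical SBS96 channel ordering and trinucleotide-context utilities.

The 96 single-base-substitution channels follow the COSMIC file convention:
six pyrimidine-centred substitution blocks (C>A, C>G, C>T, T>A, T>C, T>G),
each expanded over the 16 flanking-base pairs in lexicographic order
(5' flank A,C,G,T x 3' flank A,C,G,T), labelled like ``A[C>A]A``.
Variants reported with a purine reference are reverse-complemented onto the
pyrimidine-centred channel.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_channel(label: str) -> tuple[str, str, str, str]:
    """Split ``A[C>T]G`` into (five, ref, alt, three)."""
    if len(label) != 7:
        raise ValueError(f"malformed SBS96 label: {label!r}")
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    if f"{five}[{ref}>{alt}]{three}" != label:
        raise ValueError(f"malformed SBS96 label: {label!r}")
    return five, ref, alt, three


def channel_of(ref: str, alt: str, context: str) -> int:
    """Map a single-nucleotide variant onto its SBS96 channel index.

    ``context`` is the reference-strand trinucleotide centred on the variant
    position; its middle base must equal ``ref``. Purine-reference variants
    are collapsed onto the pyrimidine strand.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(context) != 3:
        raise ValueError(f"context must be a 3-mer, got {context!r}")
    context = context.upper()
    if context[1] != ref.upper():
        raise ValueError(f"context {context} middle base != ref {ref}")
    if ref.upper() not in PYRIMIDINES:
        context = revcomp(context)
        ref = revcomp(ref)
        alt = revcomp(alt)
    label = f"{context[0]}[{ref.upper()}>{alt.upper()}]{context[2]}"
    try:
        return CHANNEL_INDEX[label]
    except KeyError as exc:
        raise ValueError(f"invalid channel {label!r} (non-ACGT base?)") from exc


def pyrimidine_context(label_index: int) -> str:
    """Pyrimidine-strand trinucleotide of a channel, e.g. ``A[C>T]G`` -> ``ACG``."""
    five, ref, _alt, three = parse_channel(CHANNELS[label_index])
    return five + ref + three


# The 32 distinct pyrimidine-centred trinucleotides, in channel order.
PYR_TRINUCS: tuple[str, ...] = tuple(
    dict.fromkeys(pyrimidine_context(i) for i in range(96))
)
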
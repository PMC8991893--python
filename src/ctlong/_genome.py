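"""Shared genome constants: autosome sizes, substitution classes, 96-channel labels."""

from __future__ import annotations

# hg38 autosome lengths rounded down to whole Mb (used for simulation grids
# and 1 Mb binning; sex chromosomes are excluded throughout, matching the
# autosome-only normalization convention).
AUTOSOME_MB: dict[str, int] = {
    "chr1": 248, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 181,
    "chr6": 170, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 133,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 101,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 58, "chr20": 64,
    "chr21": 46, "chr22": 50,
}

AUTOSOMES: tuple[str, ...] = tuple(AUTOSOME_MB)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six pyrimidine-referenced substitution classes, in conventional order.
SUB_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def pyrimidine_class(ref: str, alt: str) -> str:
    """Map an SNV to its pyrimidine-referenced substitution class.

    Purine reference alleles are complemented (A>C becomes T>G).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in COMPLEMENT or alt not in COMPLEMENT or ref == alt:
        raise ValueError(f"not a valid SNV: {ref}>{alt}")
    if ref in ("A", "G"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def channel_labels() -> list[str]:
    """The 96 trinucleotide-context channel labels in COSMIC order.

    Ordered by substitution class, then 5' flank, then 3' flank:
    A[C>A]A, A[C>A]C, ... T[T>G]T.
    """
    labels = []
    for sub in SUB_CLASSES:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


CHANNELS: tuple[str, ...] = tuple(channel_labels())
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}


def channel_of(ref: str, alt: str, context: str) -> str:
    """Channel label for an SNV given its 3-base reference context.

    ``context`` is the trinucleotide centred on the variant position in
    reference orientation; purine-reference sites are reverse-complemented
    including their flanks.
    """
    context = context.upper()
    if len(context) != 3 or any(b not in COMPLEMENT for b in context):
        raise ValueError(f"ambiguous or malformed context: {context!r}")
    ref, alt = ref.upper(), alt.upper()
    if context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if ref in ("A", "G"):
        context = revcomp(context)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"
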
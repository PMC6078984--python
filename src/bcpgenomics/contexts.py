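"""Trinucleotide substitution contexts in the pyrimidine-strand convention.

Single-base substitutions are folded onto the pyrimidine strand: a G>A change
at 5'-TGC-3' is recorded on the opposite strand as C>T at 5'-GCA-3', channel
``G[C>T]A``.  The canonical order groups the 96 channels by the six
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) and, within each class,
by 5' then 3' flanking base in alphabetical order.
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six pyrimidine-strand substitution classes, canonical order
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGT only)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _build_labels() -> tuple[str, ...]:
    labels = []
    for sub in SUBSTITUTION_CLASSES:
        ref, alt = sub.split(">")
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{ref}>{alt}]{three}")
    return tuple(labels)


#: the 96 canonical channel labels, e.g. "A[C>A]A" ... "T[T>G]T"
CONTEXT_LABELS: tuple[str, ...] = _build_labels()
CONTEXT_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def channel(trinucleotide: str, ref: str, alt: str) -> str:
    """Map a substitution and its trinucleotide context to a canonical channel.

    Parameters
    ----------
    trinucleotide : str
        The 3-mer centred on the mutated base, on the reference strand.
    ref, alt : str
        Reference and alternate alleles on the reference strand.

    Purine reference alleles are reverse-complemented onto the pyrimidine
    strand before lookup.
    """
    trinucleotide = trinucleotide.upper()
    ref, alt = ref.upper(), alt.upper()
    if len(trinucleotide) != 3 or any(b not in BASES for b in trinucleotide):
        raise ValueError(f"invalid trinucleotide context {trinucleotide!r}")
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if trinucleotide[1] != ref:
        raise ValueError(
            f"context {trinucleotide!r} does not have ref base {ref!r} at its centre"
        )
    if ref not in PYRIMIDINES:
        trinucleotide = revcomp(trinucleotide)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    label = f"{trinucleotide[0]}[{ref}>{alt}]{trinucleotide[2]}"
    if label not in CONTEXT_INDEX:  # pragma: no cover - defensive
        raise ValueError(f"unmappable channel {label!r}")
    return label


def parse_channel(label: str) -> tuple[str, str, str]:
    """Split a canonical label into (trinucleotide, ref, alt)."""
    if label not in CONTEXT_INDEX:
        raise ValueError(f"unknown channel label {label!r}")
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def canonicalize_label(label: str) -> str:
    """Normalise foreign spellings like "ACA>ATA" or "A[C>T]A " to canonical form."""
    lab = label.strip().upper()
    if lab in CONTEXT_INDEX:
        return lab
    # "ACA>ATA" style: two 3-mers differing at the centre
    if ">" in lab and "[" not in lab:
        left, right = lab.split(">")
        left, right = left.strip(), right.strip()
        if len(left) == 3 and len(right) == 3 and left[0] == right[0] and left[2] == right[2]:
            return channel(left, left[1], right[1])
    raise ValueError(f"unrecognised context label {label!r}")
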
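"""Canonical 96-channel trinucleotide mutation classification.

Single nucleotide substitutions are folded onto the pyrimidine-centred
representation (COSMIC convention): a mutation reported with a purine
reference base (A or G) is re-expressed as the substitution of the
complementary pyrimidine on the opposite strand, with the flanking context
reverse-complemented. This gives six substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G), each observed in 16 trinucleotide contexts
ordered by the 5' then the 3' flanking base, alphabetically A < C < G < T.

The A:T>T:A class (pyrimidine-centred T>A) additionally has an
adenine-centric display order, in which the context is read 5'->3' around
the mutated adenine; this is the order in which motifs such as CAG>CTG and
TAG>TTG are usually quoted, and the order used for cosine comparison of
A:T>T:A context patterns.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

#: The six pyrimidine-centred substitution classes, in canonical order.
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 16 flanking contexts, 5' base outer loop, 3' base inner loop.
CONTEXTS = tuple(f5 + f3 for f5 in BASES for f3 in BASES)

N_CHANNELS = 96

#: Channel indices of the A:T>T:A (pyrimidine-centred T>A) class.
TA_SLICE = slice(48, 64)


def complement(base: str) -> str:
    """Complement of a single base (case preserved)."""
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence."""
    return seq.translate(_COMP)[::-1]


def channel_index(ref: str, alt: str, context5: str, context3: str) -> int:
    """Map a substitution with flanking bases to its channel in [0, 96).

    Purine-centred inputs are folded to the pyrimidine-centred strand:
    ref G>T at context T_T is the same event as C>A at A_A on the other
    strand, and both map to the same channel.

    Raises
    ------
    ValueError
        If any base is not one of A, C, G, T or ``ref == alt``.
    """
    for b in (ref, alt, context5, context3):
        if b not in BASES:
            raise ValueError(f"invalid base {b!r}; expected one of A,C,G,T")
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}")
    if ref in PURINES:
        ref, alt = complement(ref), complement(alt)
        context5, context3 = complement(context3), complement(context5)
    cls = SUB_CLASSES.index(f"{ref}>{alt}")
    return 16 * cls + 4 * BASES.index(context5) + BASES.index(context3)


def channel_label(i: int) -> str:
    """COSMIC-style label, e.g. ``A[C>A]A`` for channel 0."""
    cls, ctx = divmod(i, 16)
    sub = SUB_CLASSES[cls]
    return f"{CONTEXTS[ctx][0]}[{sub}]{CONTEXTS[ctx][1]}"


CHANNEL_LABELS = tuple(channel_label(i) for i in range(N_CHANNELS))


def channel_context(i: int) -> str:
    """Pyrimidine-centred reference trinucleotide of a channel, e.g. ``ACA``."""
    cls, ctx = divmod(i, 16)
    centre = SUB_CLASSES[cls][0]
    return CONTEXTS[ctx][0] + centre + CONTEXTS[ctx][1]


#: The 32 pyrimidine-centred trinucleotides: 16 NCN then 16 NTN,
#: contexts ordered as in :data:`CONTEXTS`.
PYR_TRINUCS = tuple(c[0] + centre + c[1] for centre in "CT" for c in CONTEXTS)


def fold_trinuc(trinuc: str) -> str:
    """Fold a trinucleotide onto its pyrimidine-centred representative."""
    if len(trinuc) != 3 or any(b not in BASES for b in trinuc):
        raise ValueError(f"invalid trinucleotide {trinuc!r}")
    return trinuc if trinuc[1] in PYRIMIDINES else revcomp(trinuc)


# Adenine-centric view of the T>A class. Adenine-centric context (a5, a3)
# around the mutated A corresponds, on the opposite strand, to the
# pyrimidine-centred context (comp(a3), comp(a5)) around the mutated T:
# CAG>CTG is T>A at CTG.
ADENINE_CONTEXTS = tuple(f5 + "A" + f3 for f5 in BASES for f3 in BASES)

ADENINE_LABELS = tuple(f"{c[0]}[A>T]{c[2]}" for c in ADENINE_CONTEXTS)


def ta_channel_for_adenine_context(a5: str, a3: str) -> int:
    """Channel index of the T>A event whose adenine-centric context is a5·A·a3."""
    return channel_index("A", "T", a5, a3)


#: ``ADENINE_TO_CHANNEL[j]`` is the 96-channel index holding the counts for
#: the j-th adenine-centric context (ordered 5' then 3', A<C<G<T).
ADENINE_TO_CHANNEL = tuple(
    ta_channel_for_adenine_context(c[0], c[2]) for c in ADENINE_CONTEXTS
)
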
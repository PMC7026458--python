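"""Small sequence helpers shared across modules.

Sequences are handled internally in DNA alphabet (ACGT); U is unified to T
on input and the original alphabet is restored only at output time.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Watson-Crick plus G:T (G:U in RNA) wobble, on the DNA alphabet.
PAIRABLE = frozenset(
    {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}
)
WOBBLE = frozenset({("G", "T"), ("T", "G")})


def to_dna(seq: str) -> str:
    """Uppercase and unify U -> T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Substitution distance between equal-length strings.

    With ``limit`` set, returns ``limit + 1`` as soon as it is exceeded.
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE
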
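"""In-silico PCR: locate primer binding sites and extract amplicons.

Verifies a primer assay against a reference sequence the way an
electronic-PCR tool does: the forward primer is matched on a strand, the
reverse primer as its reverse complement downstream, and every such pairing
under a length cap is reported as an amplicon. Matching is IUPAC-aware on
both primer and reference (an ambiguity code matches when the base sets
intersect) and allows a configurable number of mismatches. Both strands are
searched; minus-strand hits are mapped back to forward-strand coordinates.

The bundled herring assay targets a 69 bp fragment of the mitochondrial 16S
rRNA gene (17 nt forward footprint + 30 nt insert + 22 nt reverse footprint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .errors import DataError

__all__ = [
    "HERRING_FORWARD",
    "HERRING_REVERSE",
    "PrimerAssay",
    "Amplicon",
    "in_silico_pcr",
    "synthetic_herring_reference",
]

# Herring (Clupea) mt16S assay primer pair, written 5'->3'
HERRING_FORWARD = "CGCCCACCAATCACGAA"
HERRING_REVERSE = "ACGTTTGTGCCAGTATCACGTT"

# 4-bit base encoding: IUPAC codes are unions of A=1, C=2, G=4, T=8
_IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}


@dataclass(frozen=True)
class PrimerAssay:
    """A primer pair (5'->3') plus the allowed per-primer mismatch budget."""

    forward: str = HERRING_FORWARD
    reverse: str = HERRING_REVERSE
    max_mismatches: int = 0

    def __post_init__(self):
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{name} primer must be nonempty")
            bad = set(seq.upper()) - set(_IUPAC_MASK)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC characters {sorted(bad)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class Amplicon:
    """One predicted product; coordinates are 0-based, end-exclusive, on the
    forward strand of the supplied reference, inclusive of both primer
    footprints."""

    start: int
    end: int
    length: int
    sequence: str
    strand: str  # "+" if the forward primer sits on the given strand


def _encode(seq: str, label: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_IUPAC_MASK[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise DataError(f"{label} contains non-IUPAC character {exc.args[0]!r}") from None


def _match_positions(ref_mask: np.ndarray, primer_mask: np.ndarray, max_mm: int) -> np.ndarray:
    """Start indices where the primer matches with <= max_mm mismatches."""
    n, m = ref_mask.size, primer_mask.size
    if n < m:
        return np.empty(0, dtype=int)
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        mism += (ref_mask[j:j + n - m + 1] & primer_mask[j]) == 0
    return np.flatnonzero(mism <= max_mm)


def _scan_strand(ref: str, assay: PrimerAssay, length_cap: int):
    """Amplicons with the forward primer on ``ref`` as given."""
    ref_mask = _encode(ref, "reference")
    fwd = _encode(assay.forward, "forward primer")
    rev_rc = _encode(str(Seq(assay.reverse).reverse_complement()), "reverse primer")

    fwd_starts = _match_positions(ref_mask, fwd, assay.max_mismatches)
    rev_starts = _match_positions(ref_mask, rev_rc, assay.max_mismatches)

    out = []
    for f in fwd_starts:
        for r in rev_starts:
            if r < f + fwd.size:  # reverse footprint must lie downstream
                continue
            end = r + rev_rc.size
            if end - f <= length_cap:
                out.append((int(f), int(end)))
    return sorted(set(out))


def in_silico_pcr(assay: PrimerAssay, reference: str, *, length_cap: int = 2000) -> list:
    """Predict all PCR products of ``assay`` on ``reference``.

    Both strands are searched; every forward/reverse site pairing that yields
    a product no longer than ``length_cap`` nucleotides is returned, sorted
    by position on the forward strand.
    """
    if not reference:
        raise DataError("reference sequence is empty")
    reference = str(reference).upper().replace("\n", "")
    _encode(reference, "reference")  # alphabet check up front
    n = len(reference)

    hits: dict[tuple[int, int], str] = {}
    for start, end in _scan_strand(reference, assay, length_cap):
        hits.setdefault((start, end), "+")
    rc = str(Seq(reference).reverse_complement())
    for start, end in _scan_strand(rc, assay, length_cap):
        key = (n - end, n - start)
        hits.setdefault(key, "-")

    return [
        Amplicon(start=s, end=e, length=e - s, sequence=reference[s:e], strand=strand)
        for (s, e), strand in sorted(hits.items())
    ]


def synthetic_herring_reference(seed: int = 20210303, flank: int = 400) -> str:
    """A synthetic stand-in for the herring mitochondrial 16S region.

    The true mitogenome is not bundled; this sequence is *synthetic*: random
    flanks around the exact forward-primer site, a fixed 30 nt insert, and
    the reverse-complemented reverse-primer site, so the herring assay yields
    its single 69 bp amplicon. Useful for exercising the matcher offline; it
    carries no herring sequence beyond the primer footprints.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def random_flank(k: int) -> str:
        return "".join(rng.choice(bases, size=k))

    insert = "TATCCCTAGGGTAACTTGGTCCGTGAAGAA"  # fixed 30 nt spacer
    core = HERRING_FORWARD + insert + str(Seq(HERRING_REVERSE).reverse_complement())
    assay = PrimerAssay()
    for _ in range(64):
        ref = random_flank(flank) + core + random_flank(flank)
        if len(in_silico_pcr(assay, ref)) == 1:
            return ref
    raise RuntimeError("could not build a clean synthetic reference")
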
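"""Reference-genome container and nuclease placement geometry.

A :class:`GenomeRef` is the shared coordinate authority for every other
module: the simulator writes protospacers into it, site discovery scans it
for PAM-adjacent matches, and all interval arithmetic is 0-based half-open
against its chromosome lengths.

Nuclease geometry is the package's single definition of where a CRISPR
nuclease cuts relative to a protospacer placement:

* Cas9 (PAM NGG, 3' of the protospacer) makes a blunt cut 3 bp 5' of the
  PAM, i.e. between protospacer positions 17 and 18 of a 20-mer. The cut
  is modelled as a single genomic coordinate.
* Cas12a (PAM TTTV, 5' of the protospacer) is represented by a single
  coordinate 18 bp into the protospacer from its PAM-proximal end; the
  staggered overhang is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from ._util import IUPAC, iupac_match, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeRef:
    """Ordered named chromosome sequences (uppercase A/C/G/T only)."""

    chroms: tuple[tuple[str, str], ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chroms]
        if len(set(names)) != len(names) or any(not n for n in names):
            raise ValueError("chromosome names must be unique and non-empty")
        for name, seq in self.chroms:
            n_acgt = sum(seq.count(b) for b in "ACGT")
            if not seq or n_acgt != len(seq):
                raise ValueError(f"chromosome {name!r}: sequence must be non-empty A/C/G/T")
        object.__setattr__(self, "_index", {name: seq for name, seq in self.chroms})

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.chroms)

    def seq(self, chrom: str) -> str:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open subsequence, clipped to the chromosome."""
        s = self.seq(chrom)
        return s[max(0, start):max(0, end)]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.chroms)


def make_genome(n_chroms: int, lengths: list[int], seed: int) -> GenomeRef:
    """Generate an i.i.d.-uniform A/C/G/T toy genome, deterministic per seed."""
    if n_chroms != len(lengths):
        raise ValueError(f"n_chroms={n_chroms} but {len(lengths)} lengths given")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    chroms = []
    for i, length in enumerate(lengths):
        arr = _BASES[rng.integers(0, 4, size=length, dtype=np.uint8)]
        chroms.append((f"chr{i + 1}", arr.tobytes().decode("ascii")))
    return GenomeRef(tuple(chroms))


def write_fasta(genome: GenomeRef, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> GenomeRef:
    from Bio import SeqIO

    chroms = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")
    )
    return GenomeRef(chroms)


# --- nuclease geometry -------------------------------------------------------

#: default PAM pattern per nuclease; NAG for Cas9 may be enabled explicitly
#: by passing pam_rule="NRG" (covers NGG+NAG) where relaxed matching is wanted.
DEFAULT_PAM = {"cas9": "NGG", "cas12a": "TTTV"}

#: PAM side relative to the protospacer, in protospacer orientation.
PAM_SIDE = {"cas9": "3prime", "cas12a": "5prime"}

#: distance of the modelled cut coordinate from the PAM-proximal protospacer end.
_CUT_FROM_PAM_PROXIMAL = {"cas9": 3, "cas12a": 18}


def validate_nuclease(nuclease: str, protospacer: str) -> None:
    if nuclease not in DEFAULT_PAM:
        raise ValueError(f"unknown nuclease {nuclease!r}; expected cas9 or cas12a")
    if set(protospacer) - set("ACGT"):
        raise ValueError("protospacer must be A/C/G/T")
    n = len(protospacer)
    if nuclease == "cas9" and n != 20:
        raise ValueError(f"cas9 protospacer must be 20 nt, got {n}")
    if nuclease == "cas12a" and not 20 <= n <= 23:
        raise ValueError(f"cas12a protospacer must be 20-23 nt, got {n}")


def placement_coords(
    p_start: int, proto_len: int, strand: str, nuclease: str, pam_len: int
) -> tuple[int, int, int, tuple[int, int]]:
    """Reference coordinates for a protospacer placed at ``p_start``.

    ``p_start`` is the leftmost reference coordinate of the protospacer
    (whatever its strand). Returns ``(pam_start, pam_end, cut_pos, span)``
    where ``span`` is the half-open reference interval covering both the
    protospacer and its PAM.
    """
    d = _CUT_FROM_PAM_PROXIMAL[nuclease]
    side = PAM_SIDE[nuclease]
    p_end = p_start + proto_len
    # On the + strand the protospacer 5'->3' runs left to right; a 3' PAM is
    # to the right. Everything mirrors on the - strand.
    pam_right = (side == "3prime") == (strand == "+")
    if pam_right:
        pam_start, pam_end = p_end, p_end + pam_len
        span = (p_start, pam_end)
    else:
        pam_start, pam_end = p_start - pam_len, p_start
        span = (pam_start, p_end)
    if side == "3prime":  # cut measured from the 3' (PAM-proximal) end
        cut = (p_end - d) if strand == "+" else (p_start + d)
    else:  # cas12a: cut measured from the 5' (PAM-proximal) end
        cut = (p_start + d) if strand == "+" else (p_end - d)
    return pam_start, pam_end, cut, span


def pam_matches(genome: GenomeRef, chrom: str, pam_start: int, pam_end: int,
                strand: str, pam_rule: str) -> bool:
    """Does the reference carry a PAM at these coordinates (protospacer strand)?"""
    if pam_start < 0 or pam_end > len(genome.seq(chrom)):
        return False
    s = genome.fetch(chrom, pam_start, pam_end)
    if strand == "-":
        s = revcomp(s)
    return iupac_match(pam_rule, s)


def realize_pam(pam_rule: str, rng: np.random.Generator) -> str:
    """Draw a concrete PAM sequence satisfying an IUPAC pattern."""
    return "".join(
        b if b in "ACGT" else IUPAC[b][rng.integers(0, len(IUPAC[b]))]
        for b in pam_rule
    )
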
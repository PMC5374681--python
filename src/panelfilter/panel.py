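"""Amplicon panel primitives.

An amplicon panel is an ordered set of PCR targets; each amplicon carries
its own reference sequence and a 1-based genomic start so that variant
coordinates can be reported in VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DNA_ALPHABET = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(DNA_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ConfigurationError(ValueError):
    """Raised when a panel or run configuration is invalid."""


@dataclass(frozen=True)
class Amplicon:
    """A single amplicon target.

    Parameters
    ----------
    id : str
        Unique amplicon name (used as read provenance).
    chrom : str
        Contig name for VCF output.
    start : int
        1-based inclusive position of the first base of ``sequence``.
    sequence : str
        Uppercase reference sequence, alphabet {A, C, G, T}, length >= 30.
    """

    id: str
    chrom: str
    start: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ConfigurationError(f"amplicon {self.id}: start must be >= 1")
        if len(self.sequence) < 30:
            raise ConfigurationError(
                f"amplicon {self.id}: sequence shorter than 30 bp"
            )
        if set(self.sequence) - set(DNA_ALPHABET):
            raise ConfigurationError(
                f"amplicon {self.id}: sequence contains non-ACGT characters"
            )

    @property
    def end(self) -> int:
        """1-based inclusive position of the last base."""
        return self.start + len(self.sequence) - 1

    def ref_base(self, pos: int) -> str:
        """Reference base at 1-based genomic position ``pos``."""
        return self.sequence[pos - self.start]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_TO_CODE.items():
    _CODE_LUT[ord(_b)] = _c


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(DNA_ALPHABET[c] for c in codes)


def homopolymer_runs(seq: str) -> np.ndarray:
    """Per-position length of the homopolymer run containing each base."""
    n = len(seq)
    out = np.empty(n, dtype=np.int32)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run in ``seq``."""
    if not seq:
        raise ValueError("empty sequence")
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def random_panel(
    n_amplicons: int,
    length: int,
    seed: int | np.random.Generator,
    chrom_prefix: str = "chr",
    gap: int = 1000,
) -> list[Amplicon]:
    """Generate a synthetic panel of ``n_amplicons`` random amplicons.

    Amplicons are placed on distinct pseudo-contigs (one gene per contig,
    emulating a multi-gene design) with i.i.d. uniform base composition,
    which yields the natural background of short homopolymer runs.
    """
    if n_amplicons < 1:
        raise ConfigurationError("panel must contain at least one amplicon")
    rng = np.random.default_rng(seed)
    panel = []
    for k in range(n_amplicons):
        seq = decode(rng.integers(0, 4, size=length).astype(np.uint8))
        panel.append(
            Amplicon(
                id=f"amp{k + 1:02d}",
                chrom=f"{chrom_prefix}{k + 1}",
                start=1 + gap,
                sequence=seq,
            )
        )
    return panel
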
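"""Per-call filter statistics.

Beyond the standard caller annotations this module adds the three
statistics targeted at allele-balance and strand-bias artifacts:

``ADT``
    allele-depth imbalance |AD1 - AD2| / (AD1 + AD2): near 0 for a
    balanced heterozygote, 1 when only one allele is observed.
``ADTL``
    log10(AD1 + AD2) * ADT, coupling the imbalance to the amount of
    evidence at the locus.
``FS``
    two-sided Fisher exact p-value of the 2x2 ref/alt x forward/reverse
    read-count table (strand bias).  Stored as a raw p-value, so the
    VCF INFO key is ``FS_P`` to avoid clashing with GATK's phred-scaled
    FS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .caller import RawCall

#: Canonical order of the ten filter features used in trees and rules.
FEATURE_NAMES = (
    "BQRS", "RPRS", "CRS", "MQRS", "DP", "MQ", "GQ", "FS", "ADT", "ADTL",
)


class UndefinedStatisticError(ValueError):
    """A statistic was requested on an input where it is undefined."""


def compute_adt(ad1: int, ad2: int) -> float:
    """Allele-depth imbalance |AD1 - AD2| / (AD1 + AD2), in [0, 1]."""
    total = ad1 + ad2
    if total < 1:
        raise UndefinedStatisticError("ADT undefined with AD1 + AD2 = 0")
    return abs(ad1 - ad2) / total


def compute_adtl(ad1: int, ad2: int) -> float:
    """log10(AD1 + AD2) * ADT; grows with both imbalance and evidence."""
    total = ad1 + ad2
    if total < 1:
        raise UndefinedStatisticError("ADTL undefined with AD1 + AD2 = 0")
    return math.log10(total) * compute_adt(ad1, ad2)


def compute_fs(strand_table) -> float:
    """Two-sided Fisher exact p-value of a 2x2 contingency table.

    Exact integer hypergeometric enumeration: with fixed margins, sum
    the probabilities of all tables whose probability does not exceed
    the observed table's.  Comparisons are done on integer numerators
    over the common denominator C(n, r1), so no floating-point tolerance
    is needed.  Degenerate tables (a zero row or column margin) carry no
    association and return 1.0.
    """
    (a, b), (c, d) = strand_table
    if min(a, b, c, d) < 0:
        raise UndefinedStatisticError("negative count in strand table")
    n = a + b + c + d
    if n < 1:
        raise UndefinedStatisticError("all-zero strand table")
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    # P(x) ∝ C(r1, x) * C(n - r1, c1 - x); denominator C(n, c1) is common
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    weights = {
        x: math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)
    }
    observed = weights[a]
    numerator = sum(w for w in weights.values() if w <= observed)
    return numerator / math.comb(n, c1)


@dataclass(frozen=True)
class AnnotationVector:
    """The complete per-call filter vector (ten features + raw depths)."""

    BQRS: float
    RPRS: float
    CRS: float
    MQRS: float
    DP: int
    MQ: float
    GQ: int
    FS: float
    ADT: float
    ADTL: float
    AD1: int
    AD2: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ADT <= 1.0:
            raise ValueError("ADT out of [0, 1]")
        if not 0.0 < self.FS <= 1.0:
            raise ValueError("FS out of (0, 1]")
        if self.DP < self.AD1 + self.AD2:
            raise ValueError("DP < AD1 + AD2")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def annotate_call(raw: RawCall) -> AnnotationVector:
    """Assemble the full annotation vector for one non-reference call."""
    return AnnotationVector(
        BQRS=raw.BQRS,
        RPRS=raw.RPRS,
        CRS=raw.CRS,
        MQRS=raw.MQRS,
        DP=raw.DP,
        MQ=raw.MQ,
        GQ=raw.GQ,
        FS=compute_fs(raw.strand_table),
        ADT=compute_adt(raw.AD1, raw.AD2),
        ADTL=compute_adtl(raw.AD1, raw.AD2),
        AD1=raw.AD1,
        AD2=raw.AD2,
    )
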
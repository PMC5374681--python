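"""Truth labeling of called variants and assignment to analysis strata.

A call is a true variant (TV) when its exact (sample, chrom, pos, ref,
alt) key — after left-aligned normalization — was planted with at least
one alternate allele; anything else is a false variant (FV).  Calls are
stratified by variant type and by the CALLED zygosity (not the truth),
within each coverage arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .annotations import FEATURE_NAMES, AnnotationVector, annotate_call
from .caller import RawCall
from .panel import Amplicon
from .simulate import TruthCatalog, normalize_variant

TV = "TV"
FV = "FV"

ARMS = ("LC", "HC")
VTYPES = ("SNV", "INDEL")
ZYGOSITIES = ("hom", "het")

#: The eight analysis cells: type x called zygosity x coverage arm.
ALL_STRATA = tuple(
    (vtype, zyg, arm) for arm in ARMS for vtype in VTYPES for zyg in ZYGOSITIES
)


@dataclass(frozen=True)
class LabeledCall:
    sample_id: str
    replicate_id: int
    coverage_arm: str  # "LC" | "HC"
    raw: RawCall
    annotations: AnnotationVector
    label: str  # "TV" | "FV"

    @property
    def vtype(self) -> str:
        return "INDEL" if self.raw.is_indel else "SNV"

    @property
    def zygosity(self) -> str:
        return "hom" if self.raw.called_genotype == "hom_alt" else "het"

    @property
    def stratum(self) -> tuple[str, str, str]:
        return (self.vtype, self.zygosity, self.coverage_arm)


def truth_key_set(truth: TruthCatalog) -> set[tuple[str, str, int, str, str]]:
    """(sample, chrom, pos, ref, alt) keys planted with >= 1 alt allele."""
    return {
        (sample, *vkey)
        for (sample, vkey), gt in truth.genotypes.items()
        if gt in ("het", "hom_alt")
    }


def label_calls(
    calls: Iterable[tuple[str, RawCall]],
    truth: TruthCatalog,
    coverage_arm: str,
    replicate_id: int = 0,
    panel: list[Amplicon] | None = None,
) -> list[LabeledCall]:
    """Label each (sample_id, call) pair as TV or FV against the truth.

    When ``panel`` is given, call alleles are re-normalized against the
    amplicon reference before matching, so the comparison is
    representation-independent.
    """
    known = set(truth.sample_ids)
    truth_keys = truth_key_set(truth)
    amp_by_chrom = {a.chrom: a for a in panel} if panel else {}
    out: list[LabeledCall] = []
    for sample_id, raw in calls:
        if known and sample_id not in known:
            raise ValueError(f"unknown sample {sample_id!r}")
        pos, ref, alt = raw.pos, raw.ref, raw.alt
        amp = amp_by_chrom.get(raw.chrom)
        if amp is not None:
            pos, ref, alt = normalize_variant(
                pos, ref, alt, amp.sequence, amp.start
            )
        label = TV if (sample_id, raw.chrom, pos, ref, alt) in truth_keys else FV
        out.append(
            LabeledCall(
                sample_id=sample_id,
                replicate_id=replicate_id,
                coverage_arm=coverage_arm,
                raw=raw,
                annotations=annotate_call(raw),
                label=label,
            )
        )
    return out


def stratify(
    labeled: Iterable[LabeledCall],
) -> dict[tuple[str, str, str], list[LabeledCall]]:
    """Partition labeled calls into the eight strata (all keys present)."""
    out: dict[tuple[str, str, str], list[LabeledCall]] = {
        s: [] for s in ALL_STRATA
    }
    for call in labeled:
        out[call.stratum].append(call)
    return out


def calls_to_frame(labeled: Iterable[LabeledCall]) -> pd.DataFrame:
    """Flatten labeled calls into the analysis table (one row per call,
    ten feature columns plus identity, label and stratum columns)."""
    rows = []
    for lc in labeled:
        row = {
            "sample": lc.sample_id,
            "replicate": lc.replicate_id,
            "arm": lc.coverage_arm,
            "chrom": lc.raw.chrom,
            "pos": lc.raw.pos,
            "ref": lc.raw.ref,
            "alt": lc.raw.alt,
            "genotype": lc.raw.called_genotype,
            "vtype": lc.vtype,
            "zygosity": lc.zygosity,
            "label": lc.label,
            "AD1": lc.annotations.AD1,
            "AD2": lc.annotations.AD2,
        }
        row.update(lc.annotations.as_dict())
        rows.append(row)
    columns = [
        "sample", "replicate", "arm", "chrom", "pos", "ref", "alt",
        "genotype", "vtype", "zygosity", "label", "AD1", "AD2",
        *FEATURE_NAMES,
    ]
    return pd.DataFrame(rows, columns=columns)
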
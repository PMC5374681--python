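"""Flanking-sequence analysis of false-positive calls.

Recurrent false-positive indels cluster in low-complexity reference
context; this module extracts the 11-nucleotide reference window around
each variant locus (the locus is the 6th base), counts recurrent
windows among FV call instances and scores their homopolymer content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .panel import Amplicon, max_homopolymer_run

logger = logging.getLogger(__name__)

WINDOW = 5  # bases on each side; total window length 11


class BoundaryError(ValueError):
    """The requested window does not fit inside the contig."""


@dataclass(frozen=True)
class FlankWindow:
    chrom: str
    pos: int  # 1-based variant locus, the 6th base of ``sequence``
    sequence: str  # length 11
    occurrence_count: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * WINDOW + 1:
            raise ValueError("flanking window must be 11 nt")

    @property
    def max_run(self) -> int:
        return max_homopolymer_run(self.sequence)

    @property
    def display(self) -> str:
        """Lowercase context with the variant locus uppercase-marked."""
        s = self.sequence.lower()
        return s[:WINDOW] + s[WINDOW].upper() + s[WINDOW + 1 :]


def _find_amplicon(panel: list[Amplicon], chrom: str, pos: int) -> Amplicon:
    for amp in panel:
        if amp.chrom == chrom and amp.start <= pos <= amp.end:
            return amp
    raise BoundaryError(f"no amplicon covers {chrom}:{pos}")


def flanking_window(
    reference: list[Amplicon] | Amplicon, chrom: str, pos: int
) -> FlankWindow:
    """The 11-nt reference window centred (6th base) on ``pos``.

    Raises :class:`BoundaryError` when the window leaves the contig; no
    padding is applied.
    """
    amp = (
        reference
        if isinstance(reference, Amplicon)
        else _find_amplicon(reference, chrom, pos)
    )
    if pos - WINDOW < amp.start or pos + WINDOW > amp.end:
        raise BoundaryError(
            f"window around {chrom}:{pos} leaves amplicon bounds"
        )
    lo = pos - WINDOW - amp.start
    return FlankWindow(
        chrom=chrom, pos=pos, sequence=amp.sequence[lo : lo + 2 * WINDOW + 1]
    )


def fv_flank_table(
    calls: pd.DataFrame,
    reference: list[Amplicon],
    vtype: str | None = None,
    zygosity: str | None = None,
    arm: str | None = None,
    label: str = "FV",
) -> pd.DataFrame:
    """Recurrent flanking windows among false-positive call instances.

    Occurrences count call instances (sample x replicate) at each
    (chrom, pos) locus; rows are sorted by descending occurrence, ties
    by coordinate.  Loci whose window leaves the amplicon are skipped
    with a warning.
    """
    sub = calls[calls["label"] == label]
    if vtype is not None:
        sub = sub[sub["vtype"] == vtype]
    if zygosity is not None:
        sub = sub[sub["zygosity"] == zygosity]
    if arm is not None:
        sub = sub[sub["arm"] == arm]
    rows = []
    if len(sub):
        counts = sub.groupby(["chrom", "pos"]).size()
        for (chrom, pos), n in counts.items():
            try:
                w = flanking_window(reference, chrom, int(pos))
            except BoundaryError:
                logger.warning(
                    "skipping locus %s:%d: flanking window out of bounds",
                    chrom, pos,
                )
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "flank": w.sequence,
                    "display": w.display,
                    "occurrences": int(n),
                    "max_run": w.max_run,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "flank", "display", "occurrences", "max_run"],
    )
    if len(out):
        out = out.sort_values(
            ["occurrences", "chrom", "pos"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return out
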
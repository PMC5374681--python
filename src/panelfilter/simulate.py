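"""Synthetic amplicon-panel data: variant catalog, diploid genotypes,
haplotype sequences and simulated reads.

The generator emulates a targeted gene-panel study design: a catalog of
SNVs and short indels with population allele frequencies, a cohort of
diploid samples genotyped by Hardy-Weinberg sampling at those
frequencies, per-sample haplotype sequences, and reads drawn from both
haplotypes and strands under a simple per-base error model.  The error
model multiplies the indel-error rate inside reference homopolymer runs,
the mechanism by which low-complexity sequence produces recurrent false
positive indel calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import (
    Amplicon,
    ConfigurationError,
    decode,
    encode,
    homopolymer_runs,
    reverse_complement,
)

logger = logging.getLogger(__name__)

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"

# Margins keeping catalog variants clear of amplicon edges: 5 bp on the
# left for the flanking window, 8 bp on the right (window + longest
# deletion footprint).
_LEFT_MARGIN = 5
_RIGHT_MARGIN = 8
_MAX_INDEL_LEN = 3

#: The paper-style empirical allele-frequency grid for a cohort of 26
#: diploid individuals: allele counts 1..26 out of 52 chromosomes.
DEFAULT_AF_GRID = tuple(k / 52.0 for k in range(1, 27))


class CapacityError(ValueError):
    """Requested more variants than the panel can host."""


@dataclass(frozen=True)
class CatalogVariant:
    """A catalog entry: a left-anchored, normalized variant with an
    allele frequency."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    type: str  # "SNV" | "INDEL"
    af: float

    def __post_init__(self) -> None:
        if not 0.0 < self.af <= 1.0:
            raise ConfigurationError(f"af must be in (0, 1], got {self.af}")
        if self.type == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ConfigurationError(f"invalid SNV {self.ref}>{self.alt}")
        elif self.type == "INDEL":
            if len(self.ref) == len(self.alt) or self.ref[0] != self.alt[0]:
                raise ConfigurationError(
                    f"indel must be left-anchored, got {self.ref}>{self.alt}"
                )
        else:
            raise ConfigurationError(f"unknown variant type {self.type!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TruthCatalog:
    """Catalog variants plus, once assigned, per-sample genotypes."""

    variants: list[CatalogVariant]
    genotypes: dict[tuple[str, tuple[str, int, str, str]], str] = field(
        default_factory=dict
    )
    sample_ids: list[str] = field(default_factory=list)

    def genotype(self, sample_id: str, variant: CatalogVariant) -> str:
        return self.genotypes.get((sample_id, variant.key), HOM_REF)

    def truth_rows(self) -> list[dict]:
        """Long-format truth table rows (sample, chrom, pos, ref, alt, genotype)."""
        rows = []
        for sample in self.sample_ids:
            for v in self.variants:
                gt = self.genotype(sample, v)
                if gt != HOM_REF:
                    rows.append(
                        {
                            "sample": sample,
                            "chrom": v.chrom,
                            "pos": v.pos,
                            "ref": v.ref,
                            "alt": v.alt,
                            "genotype": gt,
                        }
                    )
        return rows


def normalize_variant(
    pos: int, ref: str, alt: str, sequence: str, start: int
) -> tuple[int, str, str]:
    """Normalize a variant to its minimal left-aligned representation.

    ``sequence``/``start`` give the reference context (1-based ``start``).
    Shared suffix bases are trimmed first, then shared prefix bases
    (keeping one anchor base for indels), then indels are shifted left
    while the flanking context allows it.
    """
    pos, ref, alt = int(pos), str(ref), str(alt)
    # right-trim shared trailing bases; when an allele empties, extend
    # both to the left with the previous reference base (this walks an
    # indel leftwards through a homopolymer run to its canonical anchor)
    while ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        if min(len(ref), len(alt)) == 1:
            if pos <= start:
                break
            prev = sequence[pos - 1 - start]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        else:
            ref, alt = ref[:-1], alt[:-1]
    # trim shared leading bases, keeping one anchor base for indels
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _resolve_af_sampler(af_sampler):
    """Accept None (default grid), a sequence of allowed values, or a
    callable(rng, n) -> array."""
    if af_sampler is None:
        af_sampler = DEFAULT_AF_GRID
    if callable(af_sampler):
        return af_sampler
    values = np.asarray(list(af_sampler), dtype=float)
    if values.size == 0 or np.any(values <= 0) or np.any(values > 1):
        raise ConfigurationError("af grid values must lie in (0, 1]")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(values, size=n, replace=True)

    return sample


def build_catalog(
    panel: list[Amplicon],
    n_snv: int,
    n_indel: int,
    af_sampler=None,
    seed: int | np.random.Generator = 0,
) -> TruthCatalog:
    """Draw a variant catalog of ``n_snv`` SNVs and ``n_indel`` indels at
    distinct positions inside the panel's amplicons.

    Positions keep a small margin from amplicon edges so that flanking
    windows and indel footprints stay in bounds.  Indels are emitted in
    normalized left-aligned form.
    """
    if not panel:
        raise ConfigurationError("panel is empty")
    rng = np.random.default_rng(seed)
    sampler = _resolve_af_sampler(af_sampler)

    eligible: list[tuple[Amplicon, int]] = []
    for amp in panel:
        lo = amp.start + _LEFT_MARGIN
        hi = amp.end - _RIGHT_MARGIN
        eligible.extend((amp, pos) for pos in range(lo, hi + 1))
    n_total = n_snv + n_indel
    if n_total > len(eligible):
        raise CapacityError(
            f"requested {n_total} variants but only {len(eligible)} eligible positions"
        )

    order = rng.permutation(len(eligible))
    afs = sampler(rng, n_total)
    variants: list[CatalogVariant] = []
    used_pos: set[tuple[str, int]] = set()
    n_made_snv = n_made_indel = 0
    for idx in order:
        if n_made_snv == n_snv and n_made_indel == n_indel:
            break
        amp, pos = eligible[idx]
        make_snv = n_made_snv < n_snv
        if make_snv:
            ref = amp.ref_base(pos)
            alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
            npos, nref, nalt, vtype = pos, ref, alt, "SNV"
        else:
            k = int(rng.integers(1, _MAX_INDEL_LEN + 1))
            if rng.random() < 0.5:  # deletion of k bases after pos
                ref = amp.sequence[pos - amp.start : pos - amp.start + k + 1]
                alt = ref[0]
            else:  # insertion of k random bases after pos
                ref = amp.ref_base(pos)
                alt = ref + decode(rng.integers(0, 4, size=k).astype(np.uint8))
            npos, nref, nalt = normalize_variant(
                pos, ref, alt, amp.sequence, amp.start
            )
            vtype = "INDEL"
        if (amp.chrom, npos) in used_pos or npos < amp.start + _LEFT_MARGIN:
            continue
        used_pos.add((amp.chrom, npos))
        variants.append(
            CatalogVariant(
                chrom=amp.chrom,
                pos=npos,
                ref=nref,
                alt=nalt,
                type=vtype,
                af=float(afs[len(variants)]),
            )
        )
        if make_snv:
            n_made_snv += 1
        else:
            n_made_indel += 1
    if n_made_snv < n_snv or n_made_indel < n_indel:
        raise CapacityError(
            "could not place all requested variants without position collisions"
        )
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return TruthCatalog(variants=variants)


def assign_genotypes(
    catalog: TruthCatalog,
    sample_ids: list[str],
    seed: int | np.random.Generator = 0,
) -> TruthCatalog:
    """Assign diploid genotypes by drawing two alleles independently with
    P(alt) = af for every (sample, variant) pair (Hardy-Weinberg)."""
    if not catalog.variants:
        raise ConfigurationError("catalog has no variants")
    if not sample_ids:
        raise ConfigurationError("no samples given")
    rng = np.random.default_rng(seed)
    afs = np.array([v.af for v in catalog.variants])
    # allele draws: (samples, variants, 2)
    draws = rng.random((len(sample_ids), len(afs), 2)) < afs[None, :, None]
    counts = draws.sum(axis=2)
    genotypes: dict[tuple[str, tuple[str, int, str, str]], str] = {}
    for i, sample in enumerate(sample_ids):
        for j, v in enumerate(catalog.variants):
            c = counts[i, j]
            if c == 1:
                genotypes[(sample, v.key)] = HET
            elif c == 2:
                genotypes[(sample, v.key)] = HOM_ALT
    return TruthCatalog(
        variants=list(catalog.variants),
        genotypes=genotypes,
        sample_ids=list(sample_ids),
    )


@dataclass
class DiploidAmplicon:
    """Two haplotype sequences of one amplicon for one sample, with
    haplotype-to-reference coordinate maps."""

    amplicon: Amplicon
    hap_seqs: tuple[str, str]
    #: per haplotype, array of length len(hap_seq): 1-based reference
    #: position of each haplotype base, or -1 for inserted bases
    hap_maps: tuple[np.ndarray, np.ndarray]
    #: per haplotype, list of (variant, hap_anchor_index) actually applied
    applied: tuple[list, list]

    @property
    def ref_to_hap(self) -> tuple[dict[int, int], dict[int, int]]:
        out = []
        for hmap in self.hap_maps:
            out.append(
                {int(p): i for i, p in enumerate(hmap) if p >= 0}
            )
        return tuple(out)


def _apply_variants_to_amplicon(
    amp: Amplicon, variants: list[CatalogVariant]
) -> tuple[str, np.ndarray, list]:
    """Apply ``variants`` (sorted by pos) to one amplicon copy.

    Returns the mutated sequence, the hap->ref coordinate map and the
    list of (variant, hap_anchor_index) applied.  Overlapping indel
    footprints resolve leftmost-first: a variant whose reference span
    intersects an already-consumed span is skipped with a warning.
    """
    seq_parts: list[str] = []
    map_parts: list[np.ndarray] = []
    applied: list = []
    cursor = amp.start  # next unconsumed reference position
    for v in sorted(variants, key=lambda x: x.pos):
        if v.pos < cursor:
            logger.warning(
                "skipping variant %s:%d %s>%s overlapping an earlier indel",
                v.chrom, v.pos, v.ref, v.alt,
            )
            continue
        # untouched reference chunk before the variant
        chunk = amp.sequence[cursor - amp.start : v.pos - amp.start]
        seq_parts.append(chunk)
        map_parts.append(np.arange(cursor, v.pos))
        anchor_idx = sum(len(s) for s in seq_parts)
        # the variant itself
        seq_parts.append(v.alt)
        alt_map = np.full(len(v.alt), -1, dtype=np.int64)
        n_shared = min(len(v.ref), len(v.alt))
        alt_map[:n_shared] = np.arange(v.pos, v.pos + n_shared)
        map_parts.append(alt_map)
        applied.append((v, anchor_idx))
        cursor = v.pos + len(v.ref)
    seq_parts.append(amp.sequence[cursor - amp.start :])
    map_parts.append(np.arange(cursor, amp.end + 1))
    hap_seq = "".join(seq_parts)
    hap_map = (
        np.concatenate(map_parts) if map_parts else np.empty(0, dtype=np.int64)
    )
    return hap_seq, hap_map, applied


def make_diploid_sequences(
    panel: list[Amplicon],
    catalog: TruthCatalog,
    sample_id: str,
    seed: int | np.random.Generator = 0,
) -> dict[str, DiploidAmplicon]:
    """Build the sample's two haplotype sequences per amplicon.

    Heterozygous variants land on one randomly chosen haplotype
    (seeded); homozygous-alt variants on both.  Reverse-complement
    copies are derivable with :func:`panel.reverse_complement`.
    """
    rng = np.random.default_rng(seed)
    by_amp: dict[str, list[list[CatalogVariant]]] = {
        amp.id: [[], []] for amp in panel
    }
    amp_by_chrom: dict[str, Amplicon] = {}
    for amp in panel:
        amp_by_chrom[amp.chrom] = amp
    for v in catalog.variants:
        gt = catalog.genotype(sample_id, v)
        if gt == HOM_REF:
            continue
        amp = amp_by_chrom.get(v.chrom)
        if amp is None or not (amp.start <= v.pos <= amp.end):
            continue
        if gt == HOM_ALT:
            by_amp[amp.id][0].append(v)
            by_amp[amp.id][1].append(v)
        else:  # het: one random haplotype
            by_amp[amp.id][int(rng.integers(0, 2))].append(v)
    out: dict[str, DiploidAmplicon] = {}
    for amp in panel:
        seqs, maps, applied = [], [], []
        for h in (0, 1):
            s, m, a = _apply_variants_to_amplicon(amp, by_amp[amp.id][h])
            seqs.append(s)
            maps.append(m)
            applied.append(a)
        out[amp.id] = DiploidAmplicon(
            amplicon=amp,
            hap_seqs=(seqs[0], seqs[1]),
            hap_maps=(maps[0], maps[1]),
            applied=(applied[0], applied[1]),
        )
    return out


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error model.

    ``indel_rate`` is multiplied by ``homopolymer_multiplier`` when the
    template base lies inside a homopolymer run of length >=
    ``homopolymer_min_run`` — the minimal mechanism producing recurrent
    homopolymer indel errors.
    """

    sub_rate: float = 0.01
    indel_rate: float = 0.001
    homopolymer_multiplier: float = 50.0
    homopolymer_min_run: int = 4
    qual_mean: float = 33.0
    qual_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1), got {r}")
        eff = self.indel_rate * self.homopolymer_multiplier
        if eff >= 1.0:
            raise ConfigurationError(
                f"indel_rate * homopolymer_multiplier = {eff} must stay < 1"
            )


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read with full truth provenance.

    ``bases``/``quals`` are in sequencing orientation (reverse-strand
    reads are reverse-complemented); error records are kept in haplotype
    coordinates so downstream pileup needs no realignment.
    """

    amplicon_id: str
    strand: str  # "forward" | "reverse"
    haplotype: int  # 1 | 2
    offset: int  # 0-based start within the haplotype sequence
    bases: str
    quals: tuple[int, ...]
    sub_errors: tuple[tuple[int, str], ...] = ()  # (hap_pos, observed base)
    indel_errors: tuple[tuple[int, str], ...] = ()  # (hap_pos, "ins"|"del")

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")


@dataclass
class AmpliconReadBatch:
    """Vectorized read set for one amplicon of one sample.

    Columns are parallel arrays over reads; quals is a (n_reads,
    read_len) matrix in template (forward haplotype) orientation.
    Error events are sparse row/position lists.
    """

    diploid: DiploidAmplicon
    hap: np.ndarray  # int8, 0/1
    strand: np.ndarray  # int8, 0=forward 1=reverse
    offset: np.ndarray  # int32, start in hap coords
    read_len: np.ndarray  # int32, template span length per read
    quals: np.ndarray  # int16 (n, max_len), template orientation
    sub_read: np.ndarray  # int32 indices into reads
    sub_pos: np.ndarray  # int64 hap positions (0-based)
    sub_base: np.ndarray  # uint8 observed base codes
    ind_read: np.ndarray  # int32 indices into reads
    ind_pos: np.ndarray  # int64 hap positions (0-based)
    ind_kind: np.ndarray  # uint8, 0=del 1=ins (duplication of the base)

    @property
    def n_reads(self) -> int:
        return len(self.hap)

    def to_reads(self) -> list[SimulatedRead]:
        """Materialize per-read objects (FASTQ writing, small-scale tests)."""
        subs_by_read: dict[int, list[tuple[int, str]]] = {}
        for r, p, b in zip(self.sub_read, self.sub_pos, self.sub_base):
            subs_by_read.setdefault(int(r), []).append((int(p), "ACGT"[int(b)]))
        inds_by_read: dict[int, list[tuple[int, str]]] = {}
        for r, p, k in zip(self.ind_read, self.ind_pos, self.ind_kind):
            inds_by_read.setdefault(int(r), []).append(
                (int(p), "del" if int(k) == 0 else "ins")
            )
        reads = []
        for i in range(self.n_reads):
            h = int(self.hap[i])
            hap_seq = self.diploid.hap_seqs[h]
            o = int(self.offset[i])
            L = int(self.read_len[i])
            template = list(hap_seq[o : o + L])
            tquals = [int(q) for q in self.quals[i, :L]]
            for p, b in sorted(subs_by_read.get(i, [])):
                template[p - o] = b
            # apply indel errors right-to-left so indices stay valid
            for p, kind in sorted(inds_by_read.get(i, []), reverse=True):
                j = p - o
                if kind == "del":
                    del template[j]
                    del tquals[j]
                else:
                    template.insert(j + 1, template[j])
                    tquals.insert(j + 1, tquals[j])
            bases = "".join(template)
            quals = tuple(tquals)
            if int(self.strand[i]) == 1:
                bases = reverse_complement(bases)
                quals = quals[::-1]
            reads.append(
                SimulatedRead(
                    amplicon_id=self.diploid.amplicon.id,
                    strand="reverse" if int(self.strand[i]) == 1 else "forward",
                    haplotype=h + 1,
                    offset=o,
                    bases=bases,
                    quals=quals,
                    sub_errors=tuple(sorted(subs_by_read.get(i, []))),
                    indel_errors=tuple(sorted(inds_by_read.get(i, []))),
                )
            )
        return reads


def _indel_rate_profile(hap_seq: str, model: ErrorModel) -> np.ndarray:
    """Per-template-base indel error probability."""
    runs = homopolymer_runs(hap_seq)
    rate = np.full(len(hap_seq), model.indel_rate, dtype=float)
    rate[runs >= model.homopolymer_min_run] *= model.homopolymer_multiplier
    return rate


def simulate_reads(
    diploid: dict[str, DiploidAmplicon],
    depth: float,
    read_length: int,
    error_model: ErrorModel | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[str, AmpliconReadBatch]:
    """Simulate reads for every amplicon of one sample.

    Reads are assigned independently to haplotype and strand with equal
    probability; start offsets are uniform over valid positions (with
    the default full-amplicon read length every read spans the whole
    amplicon).  Returns one :class:`AmpliconReadBatch` per amplicon.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be positive")
    if read_length < 1:
        raise ConfigurationError("read_length must be >= 1")
    model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    out: dict[str, AmpliconReadBatch] = {}
    for amp_id, dip in diploid.items():
        L_ref = len(dip.amplicon.sequence)
        if read_length > L_ref:
            logger.warning(
                "read_length %d exceeds amplicon %s length %d; truncating",
                read_length, amp_id, L_ref,
            )
        hap_lens = [len(s) for s in dip.hap_seqs]
        rl_nominal = min(read_length, L_ref)
        n_reads = max(1, int(round(depth * L_ref / rl_nominal)))
        hap = rng.integers(0, 2, size=n_reads).astype(np.int8)
        strand = rng.integers(0, 2, size=n_reads).astype(np.int8)
        rl = np.minimum(rl_nominal, np.array(hap_lens)[hap]).astype(np.int32)
        max_start = np.array(hap_lens)[hap] - rl
        offset = (rng.random(n_reads) * (max_start + 1)).astype(np.int32)
        max_rl = int(rl.max())
        quals = np.clip(
            np.rint(rng.normal(model.qual_mean, model.qual_sd, (n_reads, max_rl))),
            2, 40,
        ).astype(np.int16)

        # sparse error events over the (read, template position) grid
        sub_r, sub_p, sub_b = [], [], []
        ind_r, ind_p, ind_k = [], [], []
        for h in (0, 1):
            rows = np.flatnonzero(hap == h)
            if rows.size == 0:
                continue
            hap_seq = dip.hap_seqs[h]
            hap_codes = encode(hap_seq)
            width = int(rl[rows].max())
            # hap position of each (read, within-read index)
            pos_grid = offset[rows][:, None] + np.arange(width)[None, :]
            valid = np.arange(width)[None, :] < rl[rows][:, None]
            if model.sub_rate > 0:
                m = (rng.random((rows.size, width)) < model.sub_rate) & valid
                rr, cc = np.nonzero(m)
                hp = pos_grid[rr, cc]
                orig = hap_codes[hp]
                newb = (orig + rng.integers(1, 4, size=rr.size)) % 4
                sub_r.append(rows[rr])
                sub_p.append(hp)
                sub_b.append(newb.astype(np.uint8))
            if model.indel_rate > 0:
                profile = _indel_rate_profile(hap_seq, model)
                m = (rng.random((rows.size, width)) < profile[pos_grid]) & valid
                rr, cc = np.nonzero(m)
                hp = pos_grid[rr, cc]
                ind_r.append(rows[rr])
                ind_p.append(hp)
                ind_k.append(rng.integers(0, 2, size=rr.size).astype(np.uint8))

        def _cat(parts, dtype):
            return (
                np.concatenate(parts).astype(dtype)
                if parts
                else np.empty(0, dtype=dtype)
            )

        out[amp_id] = AmpliconReadBatch(
            diploid=dip,
            hap=hap,
            strand=strand,
            offset=offset,
            read_len=rl,
            quals=quals,
            sub_read=_cat(sub_r, np.int32),
            sub_pos=_cat(sub_p, np.int64),
            sub_base=_cat(sub_b, np.uint8),
            ind_read=_cat(ind_r, np.int32),
            ind_pos=_cat(ind_p, np.int64),
            ind_kind=_cat(ind_k, np.uint8),
        )
    return out
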
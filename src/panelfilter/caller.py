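"""Minimal pileup-based diploid variant caller over simulated reads.

Alignment is trivial because every read records its amplicon, haplotype
and offset, so observations land on reference columns through the
haplotype coordinate maps.  Genotypes come from a symmetric binomial
likelihood model; per-call annotations mirror the GATK-style rank-sum
statistics plus depth, mapping and genotype quality.

Two equivalent paths are provided: an explicit per-read pileup
(:func:`pileup` + :func:`genotype_site`), convenient for small inputs
and used as its own cross-check, and a vectorized batch path
(:func:`call_batches`) used by the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .simulate import (
    AmpliconReadBatch,
    DiploidAmplicon,
    SimulatedRead,
    normalize_variant,
)

#: The simulator emits a single constant mapping quality and no clipped
#: bases, so MQ is 60 everywhere and the MQ/clipping rank sums are ~0.
MQ_CONST = 60.0

HET = "het"
HOM_ALT = "hom_alt"
HOM_REF = "hom_ref"


def rank_sum_annotation(values_ref, values_alt) -> float:
    """Tie-corrected Mann-Whitney z-score comparing a per-read quantity
    between ref- and alt-supporting reads.

    Orientation follows the GATK convention: alt values ranking lower
    than ref values give a negative z.  Returns 0.0 when either group is
    empty or the statistic is degenerate (all values tied).
    """
    ref = np.asarray(values_ref, dtype=float)
    alt = np.asarray(values_alt, dtype=float)
    n1, n2 = len(ref), len(alt)
    if n1 == 0 or n2 == 0:
        return 0.0
    pooled = np.concatenate([ref, alt])
    ranks = rankdata(pooled)  # midranks
    r_alt = ranks[n1:].sum()
    u_alt = r_alt - n2 * (n2 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts.astype(float) ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return float((u_alt - mu) / math.sqrt(var))


@dataclass
class PileupObservation:
    """One read's contribution to a reference column."""

    read_index: int
    base: str | None  # None when the read deleted this base
    qual: int
    strand: str  # "forward" | "reverse"
    mq: float
    clip: int
    read_pos: int  # distance from the nearer read end
    indel_token: tuple[int, str, str] | None = None  # (pos, ref, alt)


@dataclass
class PileupColumn:
    chrom: str
    pos: int  # 1-based
    ref_base: str
    obs: list[PileupObservation]

    @property
    def depth(self) -> int:
        return sum(1 for o in self.obs if o.base is not None)


@dataclass(frozen=True)
class RawCall:
    """A non-reference genotype call with its annotation inputs."""

    chrom: str
    pos: int
    ref: str
    alt: str
    called_genotype: str  # "het" | "hom_alt"
    AD1: int  # ref-supporting reads
    AD2: int  # alt-supporting reads
    strand_table: tuple[tuple[int, int], tuple[int, int]]  # (ref, alt) x (fwd, rev)
    DP: int
    GQ: int
    MQ: float
    BQRS: float
    RPRS: float
    CRS: float
    MQRS: float

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def __post_init__(self) -> None:
        if self.AD1 + self.AD2 > self.DP:
            raise ValueError("AD1 + AD2 cannot exceed DP")
        if not 0 <= self.GQ <= 99:
            raise ValueError("GQ out of [0, 99]")


@dataclass(frozen=True)
class CallerParams:
    epsilon: float = 0.01  # symmetric per-read error in the genotype model
    min_depth: int = 8  # emit calls only at DP >= min_depth


def genotype_likelihoods(ad1: int, ad2: int, epsilon: float) -> tuple[float, float, float]:
    """log10 likelihoods (hom_ref, het, hom_alt) of the allele-depth pair
    under the symmetric binomial read-error model."""
    def term(n: int, p: float) -> float:
        if n == 0:
            return 0.0
        if p <= 0.0:
            return -math.inf
        return n * math.log10(p)

    l_ref = term(ad1, 1 - epsilon) + term(ad2, epsilon)
    l_het = term(ad1 + ad2, 0.5)
    l_alt = term(ad2, 1 - epsilon) + term(ad1, epsilon)
    return (l_ref, l_het, l_alt)


def _best_genotype(ad1: int, ad2: int, epsilon: float) -> tuple[str, int]:
    lls = genotype_likelihoods(ad1, ad2, epsilon)
    order = sorted(range(3), key=lambda i: lls[i], reverse=True)
    best, second = order[0], order[1]
    diff = lls[best] - lls[second]
    gq = 99 if math.isinf(diff) else min(99, int(round(10.0 * diff)))
    return ((HOM_REF, HET, HOM_ALT)[best], gq)


def _canonical_indel_token(
    dip: DiploidAmplicon, hap: int, hap_pos: int, kind: str
) -> tuple[int, str, str] | None:
    """Canonical reference-space (pos, ref, alt) of an indel sequencing
    error at haplotype position ``hap_pos`` (left-aligned, so all errors
    within one homopolymer run pool to a single variant key)."""
    amp = dip.amplicon
    hmap = dip.hap_maps[hap]
    if kind == "del":
        p = int(hmap[hap_pos])
        if p < amp.start + 1 or p > amp.end:  # need an anchor base before p
            return None
        ref = amp.ref_base(p - 1) + amp.ref_base(p)
        alt = amp.ref_base(p - 1)
        pos = p - 1
    else:  # duplication insertion of the template base after hap_pos
        j = hap_pos
        while j >= 0 and hmap[j] < 0:
            j -= 1
        if j < 0:
            return None
        p = int(hmap[j])
        if p < amp.start or p >= amp.end:
            return None
        b = dip.hap_seqs[hap][hap_pos]
        ref = amp.ref_base(p)
        alt = ref + b
        pos = p
    return normalize_variant(pos, ref, alt, amp.sequence, amp.start)


def _template_layout(read: SimulatedRead) -> tuple[dict[int, int], int]:
    """Map haplotype position -> index in the (edited, sequencing-ready)
    read for every template base the read actually reports."""
    o, n_bases = read.offset, len(read.bases)
    # reconstruct template length before indel-error edits
    n_del = sum(1 for _, k in read.indel_errors if k == "del")
    n_ins = sum(1 for _, k in read.indel_errors if k == "ins")
    tmpl_len = n_bases + n_del - n_ins
    slots: list[int | None] = list(range(o, o + tmpl_len))
    for p, kind in sorted(read.indel_errors, reverse=True):
        j = p - o
        if kind == "del":
            del slots[j]
        else:
            slots.insert(j + 1, None)  # inserted base reports no column
    layout: dict[int, int] = {}
    for k, hp in enumerate(slots):
        if hp is not None:
            layout[hp] = k
    return layout, len(slots)


def pileup(
    reads: list[SimulatedRead], diploid: dict[str, DiploidAmplicon]
) -> list[PileupColumn]:
    """Assemble reference-column observations from provenance-carrying
    reads of one sample.  Columns are emitted in coordinate order."""
    columns: dict[tuple[str, int], PileupColumn] = {}
    chrom_order: dict[str, int] = {}
    for idx, read in enumerate(reads):
        if read.amplicon_id not in diploid:
            raise ValueError(f"read references unknown amplicon {read.amplicon_id!r}")
        dip = diploid[read.amplicon_id]
        amp = dip.amplicon
        chrom_order.setdefault(amp.chrom, len(chrom_order))
        h = read.haplotype - 1
        hmap = dip.hap_maps[h]
        hap_seq = dip.hap_seqs[h]
        layout, edited_len = _template_layout(read)
        seq_quals = read.quals[::-1] if read.strand == "reverse" else read.quals
        subs = dict(read.sub_errors)
        tokens: dict[int, tuple[int, str, str]] = {}
        # planted variants this read spans
        span_lo = read.offset
        span_hi = read.offset + (len(read.bases)
                                 + sum(1 for _, k in read.indel_errors if k == "del")
                                 - sum(1 for _, k in read.indel_errors if k == "ins")) - 1
        for v, anchor in dip.applied[h]:
            end = min(anchor + len(v.alt), len(hap_seq) - 1)
            if span_lo <= anchor and span_hi >= end:
                tokens.setdefault(v.pos, (v.pos, v.ref, v.alt))
        # one token per column per read: planted first, then error events
        # in sorted order (deterministic when several pool to one anchor)
        for p, kind in sorted(read.indel_errors):
            tok = _canonical_indel_token(dip, h, p, kind)
            if tok is not None:
                tokens.setdefault(tok[0], tok)
        deleted = {p for p, k in read.indel_errors if k == "del"}
        for hp in range(span_lo, span_hi + 1):
            ref_pos = int(hmap[hp])
            if ref_pos < 0:
                continue
            key = (amp.chrom, ref_pos)
            col = columns.get(key)
            if col is None:
                col = columns[key] = PileupColumn(
                    chrom=amp.chrom, pos=ref_pos,
                    ref_base=amp.ref_base(ref_pos), obs=[],
                )
            if hp in deleted:
                continue  # no base observation from this read here
            k = layout.get(hp)
            if k is None:
                continue
            base = subs.get(hp, hap_seq[hp])
            col.obs.append(
                PileupObservation(
                    read_index=idx,
                    base=base,
                    qual=int(seq_quals[k]),
                    strand=read.strand,
                    mq=MQ_CONST,
                    clip=0,
                    read_pos=min(k, edited_len - 1 - k),
                    indel_token=tokens.get(ref_pos),
                )
            )
    return [
        columns[k]
        for k in sorted(columns, key=lambda k: (chrom_order[k[0]], k[1]))
    ]


def _assemble_call(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    dp: int,
    ref_obs: list[tuple[int, str, float, int, int]],
    alt_obs: list[tuple[int, str, float, int, int]],
    epsilon: float,
) -> RawCall | None:
    """Score one candidate allele; obs tuples are (qual, strand_code,
    mq, clip, read_pos) with strand_code 0=forward, 1=reverse."""
    ad1, ad2 = len(ref_obs), len(alt_obs)
    gt, gq = _best_genotype(ad1, ad2, epsilon)
    if gt == HOM_REF:
        return None
    strand_table = (
        (sum(1 for o in ref_obs if o[1] == 0), sum(1 for o in ref_obs if o[1] == 1)),
        (sum(1 for o in alt_obs if o[1] == 0), sum(1 for o in alt_obs if o[1] == 1)),
    )
    return RawCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        called_genotype=gt, AD1=ad1, AD2=ad2,
        strand_table=strand_table, DP=dp, GQ=gq,
        MQ=MQ_CONST,
        BQRS=rank_sum_annotation([o[0] for o in ref_obs], [o[0] for o in alt_obs]),
        RPRS=rank_sum_annotation([o[4] for o in ref_obs], [o[4] for o in alt_obs]),
        CRS=rank_sum_annotation([o[3] for o in ref_obs], [o[3] for o in alt_obs]),
        MQRS=rank_sum_annotation([o[2] for o in ref_obs], [o[2] for o in alt_obs]),
    )


def genotype_site(
    column: PileupColumn, ref_base: str | None = None, error_rate: float = 0.01
) -> RawCall | None:
    """Call the most frequent candidate allele at one column, or no-call.

    Candidate alleles are the distinct non-reference bases plus any
    indel token supported by >= 2 reads; the most frequent candidate is
    scored under the binomial genotype model and only non-hom_ref calls
    are emitted.  Ties break toward base candidates, then toward the
    lexicographically smaller allele.
    """
    ref_base = ref_base or column.ref_base
    base_counts: dict[str, int] = {}
    token_counts: dict[tuple[int, str, str], int] = {}
    for o in column.obs:
        if o.base is not None and o.base != ref_base:
            base_counts[o.base] = base_counts.get(o.base, 0) + 1
        if o.indel_token is not None and o.indel_token[0] == column.pos:
            token_counts[o.indel_token] = token_counts.get(o.indel_token, 0) + 1
    candidates: list[tuple[int, int, str, object]] = []
    for b, c in base_counts.items():
        candidates.append((-c, 0, b, ("B", b)))
    for t, c in token_counts.items():
        if c >= 2:
            candidates.append((-c, 1, t[1] + ">" + t[2], ("T", t)))
    if not candidates:
        return None
    candidates.sort(key=lambda x: (x[0], x[1], x[2]))
    _, kind_code, _, cand = candidates[0]
    dp = column.depth
    if cand[0] == "B":
        b = cand[1]
        ref_obs = [
            (o.qual, 0 if o.strand == "forward" else 1, o.mq, o.clip, o.read_pos)
            for o in column.obs if o.base == ref_base
        ]
        alt_obs = [
            (o.qual, 0 if o.strand == "forward" else 1, o.mq, o.clip, o.read_pos)
            for o in column.obs if o.base == b
        ]
        return _assemble_call(
            column.chrom, column.pos, ref_base, b, dp, ref_obs, alt_obs, error_rate
        )
    tok = cand[1]
    ref_obs = [
        (o.qual, 0 if o.strand == "forward" else 1, o.mq, o.clip, o.read_pos)
        for o in column.obs
        if o.indel_token is None and o.base == ref_base
    ]
    alt_obs = [
        (o.qual, 0 if o.strand == "forward" else 1, o.mq, o.clip, o.read_pos)
        for o in column.obs
        if o.indel_token == tok and o.base is not None
    ]
    return _assemble_call(
        column.chrom, tok[0], tok[1], tok[2], dp, ref_obs, alt_obs, error_rate
    )


def call_pileup(
    columns: list[PileupColumn], params: CallerParams | None = None
) -> list[RawCall]:
    """Object-path caller: genotype every column, gate on minimum depth."""
    params = params or CallerParams()
    calls = []
    for col in columns:
        if col.depth < params.min_depth:
            continue
        call = genotype_site(col, error_rate=params.epsilon)
        if call is not None:
            calls.append(call)
    return calls


def call_sample(
    reads: list[SimulatedRead],
    diploid: dict[str, DiploidAmplicon],
    params: CallerParams | None = None,
) -> list[RawCall]:
    """Pileup + genotype one sample's reads (object path)."""
    return call_pileup(pileup(reads, diploid), params)


def call_batches(
    batches: dict[str, AmpliconReadBatch], params: CallerParams | None = None
) -> list[RawCall]:
    """Vectorized caller over :class:`AmpliconReadBatch` inputs.

    Produces the same calls as the object path (pileup + genotype_site):
    only columns that can possibly yield a call — planted variant sites
    and columns with >= 2 concordant error observations — are evaluated,
    which is exhaustive because a single supporting read can never beat
    hom_ref at the minimum calling depth.
    """
    params = params or CallerParams()
    out: list[RawCall] = []
    for amp_id in sorted(batches):
        out.extend(_call_one_batch(batches[amp_id], params))
    out.sort(key=lambda c: (c.chrom, c.pos))
    return out


def _call_one_batch(batch: AmpliconReadBatch, params: CallerParams) -> list[RawCall]:
    dip = batch.diploid
    amp = dip.amplicon
    r2h = dip.ref_to_hap
    hap_arr = batch.hap
    off = batch.offset.astype(np.int64)
    rl = batch.read_len.astype(np.int64)

    # per-(hap, hap_pos) substitution / deletion structure
    sub_at: dict[tuple[int, int], dict[int, str]] = {}
    for r, p, b in zip(batch.sub_read, batch.sub_pos, batch.sub_base):
        h = int(hap_arr[r])
        sub_at.setdefault((h, int(p)), {})[int(r)] = "ACGT"[int(b)]
    del_at: dict[tuple[int, int], set[int]] = {}
    read_events: dict[int, list[tuple[int, str]]] = {}
    for r, p, k in zip(batch.ind_read, batch.ind_pos, batch.ind_kind):
        h = int(hap_arr[r])
        kind = "del" if int(k) == 0 else "ins"
        if kind == "del":
            del_at.setdefault((h, int(p)), set()).add(int(r))
        read_events.setdefault(int(r), []).append((int(p), kind))

    # per-read, per-column token assignment mirroring the object path:
    # planted variants claim their anchor first, then error tokens in
    # sorted event order
    read_tokens: dict[int, dict[int, tuple[int, str, str]]] = {}
    planted_at: dict[int, list] = {}
    for h in (0, 1):
        hap_len = len(dip.hap_seqs[h])
        for v, anchor in dip.applied[h]:
            planted_at.setdefault(v.pos, []).append((h, v, anchor))
            end = min(anchor + len(v.alt), hap_len - 1)
            cov = np.flatnonzero((hap_arr == h) & (off <= anchor) & (off + rl > end))
            for r in cov:
                read_tokens.setdefault(int(r), {}).setdefault(
                    v.pos, (v.pos, v.ref, v.alt)
                )
    for r, events in read_events.items():
        h = int(hap_arr[r])
        for p, kind in sorted(events):
            tok = _canonical_indel_token(dip, h, p, kind)
            if tok is not None:
                read_tokens.setdefault(r, {}).setdefault(tok[0], tok)

    # candidate columns: planted sites, concordant substitution errors,
    # and token anchors with >= 2 assigned reads
    cand_cols: set[int] = set(planted_at)
    sub_col_counts: dict[tuple[int, str], int] = {}
    for (h, p), d in sub_at.items():
        ref_pos = int(dip.hap_maps[h][p])
        if ref_pos < 0:
            continue
        for b in d.values():
            sub_col_counts[(ref_pos, b)] = sub_col_counts.get((ref_pos, b), 0) + 1
    for (ref_pos, b), c in sub_col_counts.items():
        if c >= 2 and b != amp.ref_base(ref_pos):
            cand_cols.add(ref_pos)
    tok_counts: dict[int, int] = {}
    for toks in read_tokens.values():
        for pos in toks:
            tok_counts[pos] = tok_counts.get(pos, 0) + 1
    for pos, c in tok_counts.items():
        if c >= 2:
            cand_cols.add(pos)

    calls: list[RawCall] = []
    for pos in sorted(cand_cols):
        call = _evaluate_column(
            batch, pos, r2h, sub_at, del_at, read_tokens, read_events, params
        )
        if call is not None:
            calls.append(call)
    return calls


def _evaluate_column(
    batch: AmpliconReadBatch,
    pos: int,
    r2h,
    sub_at,
    del_at,
    read_tokens,
    read_events,
    params: CallerParams,
) -> RawCall | None:
    dip = batch.diploid
    amp = dip.amplicon
    ref_base = amp.ref_base(pos)
    hap_arr = batch.hap
    off = batch.offset.astype(np.int64)
    rl = batch.read_len.astype(np.int64)

    read_ids: list[np.ndarray] = []
    bases: list[np.ndarray] = []
    quals: list[np.ndarray] = []
    strands: list[np.ndarray] = []
    rpos: list[np.ndarray] = []
    for h in (0, 1):
        j = r2h[h].get(pos)
        if j is None:
            continue
        cov = np.flatnonzero((hap_arr == h) & (off <= j) & (off + rl > j))
        if cov.size == 0:
            continue
        b = np.full(cov.size, dip.hap_seqs[h][j], dtype=object)
        for r, nb in sub_at.get((h, j), {}).items():
            hit = np.flatnonzero(cov == r)
            if hit.size:
                b[hit[0]] = nb
        keep = np.ones(cov.size, dtype=bool)
        for r in del_at.get((h, j), set()):
            hit = np.flatnonzero(cov == r)
            if hit.size:
                keep[hit[0]] = False
        cov, b = cov[keep], b[keep]
        k = j - off[cov]
        # read position in the edited read: indel errors upstream of the
        # column shift the index and change the read length
        kk = k.astype(np.int64).copy()
        elen = rl[cov].astype(np.int64).copy()
        for i, r in enumerate(cov):
            for p, kind in read_events.get(int(r), ()):  # sparse
                if kind == "ins":
                    elen[i] += 1
                    if p < j:
                        kk[i] += 1
                else:
                    elen[i] -= 1
                    if p < j:
                        kk[i] -= 1
        read_ids.append(cov)
        bases.append(b)
        quals.append(batch.quals[cov, k])
        strands.append(batch.strand[cov])
        rpos.append(np.minimum(kk, elen - 1 - kk))
    if not read_ids:
        return None
    read_ids = np.concatenate(read_ids)
    bases = np.concatenate(bases)
    quals = np.concatenate(quals)
    strands = np.concatenate(strands)
    rpos = np.concatenate(rpos)
    dp = int(read_ids.size)
    if dp < params.min_depth:
        return None

    token_support: dict[tuple[int, str, str], set[int]] = {}
    has_token = np.zeros(dp, dtype=bool)
    for i, r in enumerate(read_ids):
        tok = read_tokens.get(int(r), {}).get(pos)
        if tok is not None:
            token_support.setdefault(tok, set()).add(int(r))
            has_token[i] = True

    base_counts: dict[str, int] = {}
    for b in bases:
        if b != ref_base:
            base_counts[b] = base_counts.get(b, 0) + 1
    candidates: list[tuple[int, int, str, object]] = []
    for b, c in base_counts.items():
        candidates.append((-c, 0, b, ("B", b)))
    for t, s in token_support.items():
        if len(s) >= 2:
            candidates.append((-len(s), 1, t[1] + ">" + t[2], ("T", t)))
    if not candidates:
        return None
    candidates.sort(key=lambda x: (x[0], x[1], x[2]))
    _, _, _, cand = candidates[0]

    def pack(mask: np.ndarray) -> list[tuple[int, str, float, int, int]]:
        return [
            (int(quals[i]), int(strands[i]), MQ_CONST, 0, int(rpos[i]))
            for i in np.flatnonzero(mask)
        ]

    if cand[0] == "B":
        b = cand[1]
        ref_mask = bases == ref_base
        alt_mask = bases == b
        return _assemble_call(
            amp.chrom, pos, ref_base, b, dp,
            pack(ref_mask), pack(alt_mask), params.epsilon,
        )
    tok = cand[1]
    supp = token_support[tok]
    alt_mask = np.array([int(r) in supp for r in read_ids])
    ref_mask = (~has_token) & (bases == ref_base)
    return _assemble_call(
        amp.chrom, tok[0], tok[1], tok[2], dp,
        pack(ref_mask), pack(alt_mask), params.epsilon,
    )
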
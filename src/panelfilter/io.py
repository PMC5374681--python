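"""File formats and run configuration.

VCF writing/parsing is implemented directly over the VCFv4.2 text
format (the subset this tool emits), so custom INFO floats round-trip
bit-exactly through ``repr``/``float``; FASTA/FASTQ go through
Biopython.  The strand table is stored per sample as the GATK-style SB
field (ref-fwd, ref-rev, alt-fwd, alt-rev), which makes the ADT/ADTL/
FS_P annotations recomputable from a VCF alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations import AnnotationVector, annotate_call
from .caller import CallerParams, RawCall
from .panel import Amplicon, ConfigurationError, reverse_complement
from .rules import NodeSelectionParams
from .simulate import DiploidAmplicon, ErrorModel, SimulatedRead, TruthCatalog
from .tree import TreeParams

#: internal feature name -> VCF INFO key
INFO_KEYS = {
    "DP": "DP",
    "MQ": "MQ",
    "BQRS": "BaseQRankSum",
    "RPRS": "ReadPosRankSum",
    "MQRS": "MQRankSum",
    "CRS": "ClippingRankSum",
    "ADT": "ADT",
    "ADTL": "ADTL",
    "FS": "FS_P",
}
_INFO_BACK = {v: k for k, v in INFO_KEYS.items()}


class ParseError(ValueError):
    """Malformed record in an input file."""


# --- FASTA / FASTQ ---------------------------------------------------------

def write_haplotype_fasta(path, sample_id: str, diploid: dict[str, DiploidAmplicon]) -> None:
    """Four records per amplicon: 2 haplotypes x forward/reverse."""
    records = []
    for amp_id in sorted(diploid):
        dip = diploid[amp_id]
        for h in (0, 1):
            seq = dip.hap_seqs[h]
            for orient, s in (("fwd", seq), ("rev", reverse_complement(seq))):
                records.append(
                    SeqRecord(
                        Seq(s),
                        id=f"{sample_id}|{amp_id}|hap{h + 1}|{orient}",
                        description="",
                    )
                )
    SeqIO.write(records, str(path), "fasta")


def write_fastq(path, reads: list[SimulatedRead]) -> None:
    records = []
    for i, r in enumerate(reads):
        rec = SeqRecord(
            Seq(r.bases),
            id=f"read{i}|{r.amplicon_id}|hap{r.haplotype}|{r.strand}|{r.offset}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[SeqRecord]:
    try:
        return list(SeqIO.parse(str(path), "fastq"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_panel_fasta(path, panel: list[Amplicon]) -> None:
    """Amplicon reference FASTA; id encodes ``name|chrom|start``."""
    records = [
        SeqRecord(Seq(a.sequence), id=f"{a.id}|{a.chrom}|{a.start}", description="")
        for a in panel
    ]
    SeqIO.write(records, str(path), "fasta")


def read_panel_fasta(path) -> list[Amplicon]:
    panel = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ParseError(f"panel record id {rec.id!r} is not name|chrom|start")
        panel.append(
            Amplicon(
                id=parts[0],
                chrom=parts[1],
                start=int(parts[2]),
                sequence=str(rec.seq).upper(),
            )
        )
    return panel


# --- truth tables ----------------------------------------------------------

def write_truth_tsv(path, truth: TruthCatalog) -> None:
    pd.DataFrame(
        truth.truth_rows(),
        columns=["sample", "chrom", "pos", "ref", "alt", "genotype"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "pos", "ref", "alt", "genotype"}
    if not required.issubset(df.columns):
        raise ParseError(f"truth table lacks columns {required - set(df.columns)}")
    return df


# --- VCF -------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the site">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality">',
    '##INFO=<ID=BaseQRankSum,Number=1,Type=Float,Description="Rank-sum z of base qualities, alt vs ref reads">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Rank-sum z of position from read end, alt vs ref reads">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Rank-sum z of mapping qualities, alt vs ref reads">',
    '##INFO=<ID=ClippingRankSum,Number=1,Type=Float,Description="Rank-sum z of clipped-base counts, alt vs ref reads">',
    '##INFO=<ID=ADT,Number=1,Type=Float,Description="Allele-depth imbalance |AD1-AD2|/(AD1+AD2)">',
    '##INFO=<ID=ADTL,Number=1,Type=Float,Description="log10(AD1+AD2) * ADT">',
    '##INFO=<ID=FS_P,Number=1,Type=Float,Description="Two-sided Fisher exact p of the strand table (raw p, not phred)">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Unfiltered ref,alt supporting read counts">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=SB,Number=4,Type=Integer,Description="Strand table: ref-fwd,ref-rev,alt-fwd,alt-rev">',
]


def _fmt(value: float) -> str:
    return repr(float(value))


def write_vcf(
    path,
    sample_id: str,
    calls: list[tuple[RawCall, AnnotationVector]],
    panel: list[Amplicon] | None = None,
    filters: list[str] | None = None,
) -> None:
    """Write one sample's annotated calls as VCFv4.2.

    ``filters`` optionally gives the per-call FILTER column entries
    (default '.'); custom INFO floats are emitted with full precision.
    """
    lines = ["##fileformat=VCFv4.2", f"##source=panelfilter"]
    if panel:
        for amp in panel:
            lines.append(f"##contig=<ID={amp.chrom},length={amp.end}>")
    lines.extend(_VCF_HEADER_LINES)
    if filters:
        for name in sorted({f for f in filters if f not in (".", "PASS")}):
            lines.append(f'##FILTER=<ID={name},Description="Hard-filter rule set">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for i, (raw, ann) in enumerate(calls):
        info = ";".join(
            [
                f"DP={ann.DP}",
                f"MQ={_fmt(ann.MQ)}",
                f"BaseQRankSum={_fmt(ann.BQRS)}",
                f"ReadPosRankSum={_fmt(ann.RPRS)}",
                f"MQRankSum={_fmt(ann.MQRS)}",
                f"ClippingRankSum={_fmt(ann.CRS)}",
                f"ADT={_fmt(ann.ADT)}",
                f"ADTL={_fmt(ann.ADTL)}",
                f"FS_P={_fmt(ann.FS)}",
            ]
        )
        gt = "0/1" if raw.called_genotype == "het" else "1/1"
        (rf, rr), (af, ar) = raw.strand_table
        sample_field = (
            f"{gt}:{raw.AD1},{raw.AD2}:{raw.DP}:{raw.GQ}:{rf},{rr},{af},{ar}"
        )
        filt = filters[i] if filters else "."
        lines.append(
            f"{raw.chrom}\t{raw.pos}\t.\t{raw.ref}\t{raw.alt}\t.\t{filt}\t"
            f"{info}\tGT:AD:DP:GQ:SB\t{sample_field}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Parse a (single-sample) VCF into a flat table.

    Recognized INFO keys land in feature columns (internal names);
    FORMAT GT/AD/DP/GQ/SB are unpacked.  Unknown keys are ignored.
    """
    rows = []
    sample_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                parts = line.split("\t")
                if len(parts) < 10:
                    raise ParseError(f"line {lineno}: no sample column")
                sample_id = parts[9]
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ParseError(f"line {lineno}: expected >= 10 columns")
            chrom, pos, _, ref, alt, _, filt, info_s, fmt, sample_s = parts[:10]
            try:
                pos = int(pos)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad POS {pos!r}") from exc
            row = {
                "sample": sample_id,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "filter": filt,
            }
            for item in info_s.split(";"):
                if "=" not in item:
                    continue
                k, v = item.split("=", 1)
                if k in _INFO_BACK:
                    row[_INFO_BACK[k]] = float(v) if k != "DP" else int(v)
            fmt_keys = fmt.split(":")
            fmt_vals = sample_s.split(":")
            if len(fmt_keys) != len(fmt_vals):
                raise ParseError(f"line {lineno}: FORMAT/sample field mismatch")
            sample_map = dict(zip(fmt_keys, fmt_vals))
            if "GT" in sample_map:
                gt = sample_map["GT"].replace("|", "/")
                row["genotype"] = "hom_alt" if gt == "1/1" else "het"
            if "AD" in sample_map:
                ad = sample_map["AD"].split(",")
                row["AD1"], row["AD2"] = int(ad[0]), int(ad[1])
            if "GQ" in sample_map:
                row["GQ"] = int(sample_map["GQ"])
            if "DP" in sample_map:
                row["DP"] = int(sample_map["DP"])
            if "SB" in sample_map:
                sb = [int(x) for x in sample_map["SB"].split(",")]
                if len(sb) != 4:
                    raise ParseError(f"line {lineno}: SB needs 4 counts")
                row["SB"] = tuple(sb)
            rows.append(row)
    return pd.DataFrame(rows)


def calls_from_vcf(path) -> list[tuple[str, RawCall]]:
    """Reconstruct (sample_id, RawCall) pairs from a VCF written by
    :func:`write_vcf` (requires the SB field)."""
    df = read_vcf(path)
    out = []
    for _, row in df.iterrows():
        rf, rr, af, ar = row["SB"]
        out.append(
            (
                row["sample"],
                RawCall(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    called_genotype=row["genotype"],
                    AD1=int(row["AD1"]),
                    AD2=int(row["AD2"]),
                    strand_table=((rf, rr), (af, ar)),
                    DP=int(row["DP"]),
                    GQ=int(row["GQ"]),
                    MQ=float(row["MQ"]),
                    BQRS=float(row["BQRS"]),
                    RPRS=float(row["RPRS"]),
                    CRS=float(row["CRS"]),
                    MQRS=float(row["MQRS"]),
                ),
            )
        )
    return out


def annotated_calls(calls: list[RawCall]) -> list[tuple[RawCall, AnnotationVector]]:
    return [(c, annotate_call(c)) for c in calls]


# --- run configuration -----------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full simulation/tuning run.

    Coverage arms map arm labels to mean sequencing depth; the default
    pairs a low-coverage (20x) and a high-coverage (100x) arm.
    """

    seed: int
    n_samples: int = 26
    n_replicates: int = 10
    n_amplicons: int = 10
    amplicon_length: int = 300
    read_length: int | None = None  # None: full-amplicon reads
    n_snv: int = 48
    n_indel: int = 12
    arms: dict = field(default_factory=lambda: {"LC": 20.0, "HC": 100.0})
    error_model: ErrorModel = field(default_factory=ErrorModel)
    caller: CallerParams = field(default_factory=CallerParams)
    tree: TreeParams = field(default_factory=TreeParams)
    selection: NodeSelectionParams = field(default_factory=NodeSelectionParams)
    write_vcfs: bool = False
    write_fastq: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory for simulation runs")
        if self.n_samples < 1 or self.n_replicates < 1:
            raise ConfigurationError("need >= 1 sample and >= 1 replicate")
        if not self.arms:
            raise ConfigurationError("at least one coverage arm required")
        for name, depth in self.arms.items():
            if depth <= 0:
                raise ConfigurationError(f"arm {name}: depth must be positive")
        if set(self.arms) - {"LC", "HC"}:
            raise ConfigurationError("arm labels must be LC and/or HC")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("error_model", ErrorModel),
            ("caller", CallerParams),
            ("tree", TreeParams),
            ("selection", NodeSelectionParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
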
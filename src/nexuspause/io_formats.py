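"""Readers and writers for every format the pipeline touches.

Strict dialects: FASTA (upper-cased ACGTN), a TSV dialect for aligned
5'-end read records, UCSC bedGraph for strand-separated stop-base
profiles, a half-life TSV, and a YAML pipeline configuration.  All file
coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("nexuspause")

_VALID_BASES = set("ACGTN")
_READ_COLUMNS = ["reference", "five_prime_pos", "strand", "barcode", "unique"]


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read reduced to its exonuclease stop base.

    ``five_prime_pos`` is the 0-based position of the read's 5' end on
    the reference; ``barcode`` is the ChIP-nexus random+fixed barcode
    string used for PCR-duplicate removal; ``unique`` marks unique
    alignment.
    """

    reference: str
    five_prime_pos: int
    strand: str
    barcode: str
    unique: bool = True

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0:
            raise ValueError(f"five_prime_pos must be >= 0, got {self.five_prime_pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.barcode:
            raise ValueError("barcode must be non-empty")


@dataclass(frozen=True)
class HalfLifeRecord:
    """Paused Pol II half-life of one promoter, in minutes.

    ``censored`` means the value is a lower bound (the promoter retained
    too much signal for the decay inversion to be informative).
    """

    promoter_id: str
    halflife_min: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.halflife_min > 0:
            raise ValueError(
                f"halflife_min must be > 0, got {self.halflife_min} "
                f"for {self.promoter_id}"
            )


@dataclass
class MotifConfig:
    consensus: str
    window_bio: tuple[int, int]  # biological positions of allowed match span


@dataclass
class PipelineConfig:
    """Tunable parameters shared across the pipeline.

    Defaults encode the canonical core-promoter-element consensi and
    windows (TATA box STATAWAWR fully inside -40..-20; initiator TCAKTY
    anchored at -2..+4; three downstream pausing-element consensi inside
    +15..+40), one allowed mismatch, the 301-bp total-signal window and
    the 30/60-minute half-life class thresholds.
    """

    motifs: dict[str, list[MotifConfig]] = field(default_factory=lambda: {
        "TATA": [MotifConfig("STATAWAWR", (-40, -20))],
        "INR": [MotifConfig("TCAKTY", (-2, 4))],
        "PAUSE": [
            MotifConfig("CSARCSSA", (15, 40)),
            MotifConfig("KCGGTTSK", (15, 40)),
            MotifConfig("KCGRWCG", (15, 40)),
        ],
    })
    max_mismatches: int = 1
    window_width: int = 301
    tata_class_max_min: float = 30.0
    stable_class_min_min: float = 60.0
    treat_min: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_width <= 0 or self.window_width % 2 == 0:
            raise ValueError("window_width must be odd and positive")
        if self.tata_class_max_min <= 0 or self.stable_class_min_min <= 0:
            raise ValueError("class thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        motifs_raw = raw.pop("motifs", None)
        cfg = cls(**raw)
        if motifs_raw is not None:
            cfg.motifs = {
                kind: [MotifConfig(m["consensus"], tuple(m["window_bio"])) for m in specs]
                for kind, specs in motifs_raw.items()
            }
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["motifs"] = {
            kind: [{"consensus": m.consensus, "window_bio": list(m.window_bio)}
                   for m in specs]
            for kind, specs in self.motifs.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> upper-case sequence mapping."""
    path = Path(path)
    out: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
                )
            out[rec.id] = seq
    except ValueError as exc:
        if "invalid characters" in str(exc):
            raise
        raise ValueError(f"{path}: malformed FASTA: {exc}") from exc
    if not out:
        logger.warning("FASTA file %s contains no records", path)
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    if not sequences:
        raise ValueError("refusing to write an empty FASTA map")
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Read tables

def read_reads(path: str | Path) -> list[ReadRecord]:
    """Read the aligned 5'-end TSV dialect into ReadRecords.

    Expects header columns reference, five_prime_pos, strand, barcode,
    unique.  Errors name the offending row (1-based, excluding header).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: list[ReadRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pos = int(row.five_prime_pos)
            unique = str(row.unique).strip().lower() in ("true", "1", "t", "yes")
            records.append(
                ReadRecord(
                    reference=str(row.reference),
                    five_prime_pos=pos,
                    strand=str(row.strand),
                    barcode=str(row.barcode),
                    unique=unique,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad read record at row {i}: {exc}") from exc
    return records


def write_reads(reads: Iterable[ReadRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.reference, r.five_prime_pos, r.strand, r.barcode, r.unique)
            for r in reads
        ],
        columns=_READ_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(profile, path_plus: str | Path, path_minus: str | Path) -> None:
    """Write a stop-base profile as two single-strand bedGraph files.

    Plus-strand counts are written as positive values, minus-strand
    counts as negative values (the above/below-axis plotting
    convention).  Zero runs are omitted; intervals are 0-based
    half-open per the bedGraph standard.
    """
    for path, counts, sign, strand in (
        (path_plus, profile.plus_counts, 1.0, "+"),
        (path_minus, profile.minus_counts, -1.0, "-"),
    ):
        with open(path, "w") as fh:
            fh.write(
                f'track type=bedGraph name="{profile.reference}_{strand}"\n'
            )
            for pos, value in enumerate(counts):
                if value != 0:
                    v = sign * value
                    v_str = f"{v:g}"
                    fh.write(f"{profile.reference}\t{pos}\t{pos + 1}\t{v_str}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph back into (reference, start, end, value) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            ref, start, end, value = line.split("\t")
            rows.append((ref, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["reference", "start", "end", "value"])


# ---------------------------------------------------------------------------
# Half-life tables

def read_halflife_table(path: str | Path) -> list[HalfLifeRecord]:
    df = pd.read_csv(path, sep="\t")
    if "promoter_id" not in df.columns or "halflife_min" not in df.columns:
        raise ValueError(f"{path}: need columns promoter_id, halflife_min")
    dupes = df["promoter_id"][df["promoter_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate promoter_id {sorted(set(dupes))}")
    has_censored = "censored" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        censored = bool(row.censored) if has_censored else False
        try:
            records.append(
                HalfLifeRecord(str(row.promoter_id), float(row.halflife_min), censored)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return records


def write_halflife_table(records: Iterable[HalfLifeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.promoter_id, r.halflife_min, r.censored) for r in records],
        columns=["promoter_id", "halflife_min", "censored"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Optional BAM adapter (isolated; the TSV dialect is the primary route)

def reads_from_bam(path: str | Path, barcode_tag: str = "RX",
                   min_mapq: int = 30) -> list[ReadRecord]:
    """Extract 5'-end ReadRecords from a BAM/SAM file.

    5' end = alignment start for +, alignment end - 1 for -; barcode
    from ``barcode_tag``; uniqueness = mapping quality >= ``min_mapq``.
    """
    import pysam  # deferred: only this adapter needs it

    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam:
            if aln.is_unmapped:
                continue
            if aln.is_reverse:
                strand, pos = "-", aln.reference_end - 1
            else:
                strand, pos = "+", aln.reference_start
            barcode = (
                aln.get_tag(barcode_tag) if aln.has_tag(barcode_tag)
                else aln.query_name
            )
            records.append(
                ReadRecord(
                    reference=aln.reference_name,
                    five_prime_pos=pos,
                    strand=strand,
                    barcode=str(barcode),
                    unique=aln.mapping_quality >= min_mapq,
                )
            )
    return records
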
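"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; BED is native,
SAM is converted at the boundary (1-based POS to 0-based).  The
simulator truth table (TSV) is the canonical alignment source; a minimal
SAM dialect (FLAG for strand, POS, match/soft-clip CIGARs) is supported
for real data.  All writers are deterministic given identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragsites import AlignedReadPair
from .simdata import GenomeSequence, TruthFragment

log = logging.getLogger("tagqc")

TRUTH_COLUMNS = ["read_id", "genome", "start", "end",
                 "molecule_id", "is_duplicate", "barcode"]


def read_fasta(path) -> list[GenomeSequence]:
    """Read FASTA records, upper-casing sequences.

    Non-ACGT characters are preserved in the returned string but flagged
    with a warning (simulated genomes are always clean).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate identifiers in {path}")
    out = []
    for r in records:
        raw = str(r.seq)
        seq = raw.upper()
        if raw != seq:
            log.info("%s: lowercase bases upper-cased in %s", path, r.id)
        if set(seq) - set("ACGT"):
            log.warning("%s: non-ACGT characters in %s", path, r.id)
            out.append(_AmbiguousGenome(r.id, seq))
        else:
            out.append(GenomeSequence(r.id, seq))
    return out


@dataclass(frozen=True)
class _AmbiguousGenome:
    """Stand-in for FASTA records containing ambiguity codes."""

    name: str
    seq: str

    def __len__(self):
        return len(self.seq)


def write_fasta(genomes, path) -> None:
    """Write genomes as FASTA with 60-column wrapping."""
    records = [SeqRecord(Seq(g.seq), id=g.name, description="")
               for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def write_fastq(reads, path, quality_char: str = "I") -> None:
    """Write (name, seq) records as Phred+33 FASTQ with constant quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"barcode": str}, keep_default_na=False)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns {sorted(missing)}")
    df["is_duplicate"] = df["is_duplicate"].astype(str).str.lower().isin(
        ["true", "1"])
    return df


def pairs_from_truth(truth: pd.DataFrame,
                     read_len: int | None = None) -> list[AlignedReadPair]:
    """Convert truth-table rows to aligned pairs (perfect mapping)."""
    return [AlignedReadPair(genome=row.genome, start1=int(row.start),
                            end2=int(row.end), strand1="+",
                            is_duplicate=bool(row.is_duplicate),
                            read_len=read_len)
            for row in truth.itertuples(index=False)]


def pairs_from_fragments(fragments: list[TruthFragment],
                         read_len: int | None = None) -> list[AlignedReadPair]:
    return [AlignedReadPair(genome=f.genome, start1=f.start, end2=f.end,
                            strand1="+", read_len=read_len)
            for f in fragments]


def write_min_sam(truth: pd.DataFrame, genome, read_len: int, path) -> None:
    """Write truth pairs as a minimal coordinate-correct SAM file.

    Reads shorter than the fragment are written full-length; reads from
    shorter fragments carry soft-clipped adaptor tails so that reference
    start/end round-trip exactly.
    """
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": genome.name, "LN": len(genome)}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in enumerate(truth.itertuples(index=False)):
            start, end = int(row.start), int(row.end)
            flen = end - start
            aligned = min(read_len, flen)
            clip = read_len - aligned
            for is_read2 in (False, True):
                a = pysam.AlignedSegment(out.header)
                a.query_name = row.read_id
                a.reference_id = 0
                a.mapping_quality = 60
                flag = 0x1 | 0x2
                if is_read2:
                    flag |= 0x80 | 0x10
                    a.reference_start = start if clip else end - read_len
                    a.cigarstring = (f"{clip}S{aligned}M" if clip
                                     else f"{read_len}M")
                else:
                    flag |= 0x40 | 0x20
                    a.reference_start = start
                    a.cigarstring = (f"{aligned}M{clip}S" if clip
                                     else f"{read_len}M")
                if bool(row.is_duplicate):
                    flag |= 0x400
                a.flag = flag
                a.query_sequence = "N" * read_len
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * read_len)
                out.write(a)


@dataclass
class SamReadResult:
    pairs: list[AlignedReadPair]
    n_unpaired: int = 0
    n_skipped: int = 0


def read_min_sam(path) -> SamReadResult:
    """Read a minimal SAM into aligned pairs.

    Records are paired by name; secondary, supplementary and unmapped
    records are skipped with counts.  Only match/soft-clip CIGARs are
    expected; pysam's reference coordinates already exclude soft clips.
    """
    by_name: dict[str, dict[int, pysam.AlignedSegment]] = {}
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if (rec.is_secondary or rec.is_supplementary or rec.is_unmapped
                    or rec.reference_id < 0):
                skipped += 1
                continue
            slot = 2 if rec.is_read2 else 1
            by_name.setdefault(rec.query_name, {})[slot] = rec
        refnames = list(fh.references)
    pairs = []
    unpaired = 0
    for name, mates in by_name.items():
        if len(mates) != 2:
            unpaired += 1
            continue
        r1, r2 = mates[1], mates[2]
        pairs.append(AlignedReadPair(
            genome=refnames[r1.reference_id],
            start1=r1.reference_start,
            end2=r2.reference_end,
            strand1="-" if r1.is_reverse else "+",
            mapq=r1.mapping_quality,
            is_duplicate=r1.is_duplicate,
            read_len=r1.query_length or None))
    pairs.sort(key=lambda p: (p.genome, p.start1, p.end2))
    return SamReadResult(pairs, unpaired, skipped)


def read_bed(path) -> list[tuple[int, int]]:
    """Read 0-based half-open intervals from a BED file (first contig's
    coordinates; chrom column ignored for single-reference use)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [(int(s), int(e)) for s, e in zip(df["start"], df["end"])]


def write_bedgraph(track, path, values=None, chrom: str | None = None) -> None:
    """Write a coverage track (or normalized values) as BedGraph."""
    vals = track.depth if values is None else values
    name = chrom or track.genome or "chr"
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[start]:
                fh.write(f"{name}\t{start}\t{i}\t{vals[start]:g}\n")
                start = i
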
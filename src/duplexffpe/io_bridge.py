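"""Standard-format I/O and normalization into internal record types.

All internal coordinates are 0-based half-open; conversion to/from the
1-based conventions of SAM and VCF happens only at format boundaries.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: CIGAR operations that consume query bases / reference bases.
CONSUMES_QUERY = frozenset("MIS=X")
CONSUMES_REF = frozenset("MDN=X")

_CIGAR_OPS = "MIDNSHP=XB"


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned mate, reference-oriented.

    ``seq`` is stored in reference orientation (as in SAM), ``cigar`` is a
    tuple of ``(op_char, length)`` runs, and ``qual`` is either a flat Phred
    value applying to every base or a per-base tuple.
    """

    start: int
    is_reverse: bool
    seq: str
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    qual: int | tuple[int, ...] = 30

    @property
    def reference_end(self) -> int:
        return self.start + sum(n for op, n in self.cigar if op in CONSUMES_REF)

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in CONSUMES_QUERY)

    @property
    def aligned_length(self) -> int:
        """Reference bases covered by match-type operations."""
        return sum(n for op, n in self.cigar if op in "M=X")

    def has_soft_clip(self) -> bool:
        return any(op == "S" for op, _ in self.cigar)

    def qual_at(self, i: int) -> int:
        if isinstance(self.qual, int):
            return self.qual
        return self.qual[i]


@dataclass
class AlignedPairRecord:
    """A sequenced read pair keyed by the coordinates of its source molecule.

    ``trim`` is the number of terminal aligned query positions of each mate
    masked from downstream evidence (set by the read filter's end trimming;
    it never alters the template coordinates, which are the molecule
    identifier).
    """

    qname: str
    ref_name: str
    r1: ReadAlignment
    r2: Optional[ReadAlignment]
    proper: bool = True
    trim: int = 0

    @property
    def start(self) -> int:
        if self.r2 is None:
            return self.r1.start
        return min(self.r1.start, self.r2.start)

    @property
    def end(self) -> int:
        if self.r2 is None:
            return self.r1.reference_end
        return max(self.r1.reference_end, self.r2.reference_end)

    @property
    def orientation(self) -> Optional[str]:
        """'top' if read 1 maps forward, 'bottom' if reverse.

        Defined only for proper pairs; improper records return ``None``.
        """
        if not self.proper or self.r2 is None:
            return None
        return "bottom" if self.r1.is_reverse else "top"

    @property
    def template_key(self) -> tuple[str, int, int]:
        return (self.ref_name, self.start, self.end)

    @property
    def mapq(self) -> int:
        if self.r2 is None:
            return self.r1.mapq
        return min(self.r1.mapq, self.r2.mapq)

    def mates(self) -> tuple[ReadAlignment, ...]:
        return (self.r1,) if self.r2 is None else (self.r1, self.r2)


# ---------------------------------------------------------------------------
# alignment files
# ---------------------------------------------------------------------------


def _cigar_from_pysam(cigartuples) -> tuple[tuple[str, int], ...]:
    return tuple((_CIGAR_OPS[op], n) for op, n in cigartuples)


def _cigar_to_pysam(cigar: Sequence[tuple[str, int]]) -> list[tuple[int, int]]:
    return [(_CIGAR_OPS.index(op), n) for op, n in cigar]


def _read_from_segment(seg: pysam.AlignedSegment) -> ReadAlignment:
    quals = seg.query_qualities
    if quals is None:
        qual: int | tuple[int, ...] = 30
    else:
        qset = set(quals)
        qual = qset.pop() if len(qset) == 1 else tuple(quals)
    return ReadAlignment(
        start=seg.reference_start,
        is_reverse=seg.is_reverse,
        seq=seg.query_sequence or "",
        cigar=_cigar_from_pysam(seg.cigartuples or ()),
        mapq=seg.mapping_quality,
        qual=qual,
    )


def load_alignments(
    path: str | os.PathLike,
    region: Optional[tuple[str, int, int]] = None,
) -> list[AlignedPairRecord]:
    """Load a coordinate-sorted SAM/BAM file as mate-joined pair records.

    Mates are joined by query name. Reads whose mate is unmapped or absent
    are emitted as single-ended records flagged not-proper. The result is
    ordered by ``(reference, start)``.

    ``region`` is a 0-based half-open ``(ref_name, start, end)`` triple. For
    BAM input a region query requires an index; a missing index raises with
    a remediation hint. SAM input is scanned linearly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    segments: list[pysam.AlignedSegment] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        if region is not None and mode == "rb":
            if not af.has_index():
                raise FileNotFoundError(
                    f"{path}: region queries on BAM need an index; "
                    f"run 'samtools index {path}'"
                )
            it: Iterable[pysam.AlignedSegment] = af.fetch(
                region[0], region[1], region[2]
            )
        else:
            it = af.fetch(until_eof=True)
        for seg in it:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            if region is not None and mode == "r":
                ref, lo, hi = region
                if seg.reference_name != ref:
                    continue
                if seg.reference_end <= lo or seg.reference_start >= hi:
                    continue
            segments.append(seg)

    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    for seg in segments:
        by_name.setdefault(seg.query_name, []).append(seg)

    records: list[AlignedPairRecord] = []
    for qname, segs in by_name.items():
        if len(segs) == 2:
            a, b = segs
            if not a.is_read1:
                a, b = b, a
            proper = bool(a.is_proper_pair and b.is_proper_pair)
            records.append(
                AlignedPairRecord(
                    qname=qname,
                    ref_name=a.reference_name,
                    r1=_read_from_segment(a),
                    r2=_read_from_segment(b),
                    proper=proper,
                )
            )
        else:
            for seg in segs:
                records.append(
                    AlignedPairRecord(
                        qname=qname,
                        ref_name=seg.reference_name,
                        r1=_read_from_segment(seg),
                        r2=None,
                        proper=False,
                    )
                )
    records.sort(key=lambda r: (r.ref_name, r.start, r.end, r.qname))
    return records


def write_alignments(
    records: Iterable[AlignedPairRecord],
    path: str | os.PathLike,
    reference_lengths: Mapping[str, int],
) -> None:
    """Write pair records as a coordinate-sorted SAM (or BAM by extension)."""
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in reference_lengths.items()
        ],
    }
    recs = sorted(records, key=lambda r: (r.ref_name, r.start, r.end, r.qname))
    mode = "wb" if path.suffix == ".bam" else "w"
    segs: list[pysam.AlignedSegment] = []
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        tid = {name: i for i, name in enumerate(reference_lengths)}
        for rec in recs:
            mates = rec.mates()
            for idx, mate in enumerate(mates):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = rec.qname
                seg.reference_id = tid[rec.ref_name]
                seg.reference_start = mate.start
                seg.mapping_quality = mate.mapq
                seg.cigar = _cigar_to_pysam(mate.cigar)
                seg.query_sequence = mate.seq
                if isinstance(mate.qual, int):
                    seg.query_qualities = pysam.qualitystring_to_array(
                        chr(mate.qual + 33) * len(mate.seq)
                    )
                else:
                    seg.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in mate.qual)
                    )
                flag = 0x1
                if rec.proper:
                    flag |= 0x2
                if mate.is_reverse:
                    flag |= 0x10
                flag |= 0x40 if idx == 0 else 0x80
                other = mates[1 - idx] if len(mates) == 2 else None
                if other is not None:
                    if other.is_reverse:
                        flag |= 0x20
                    seg.next_reference_id = tid[rec.ref_name]
                    seg.next_reference_start = other.start
                    tlen = rec.end - rec.start
                    seg.template_length = tlen if mate.start <= other.start else -tlen
                else:
                    flag |= 0x8
                    seg.next_reference_id = -1
                    seg.next_reference_start = -1
                seg.flag = flag
                segs.append(seg)
        segs.sort(key=lambda s: (s.reference_id, s.reference_start, s.query_name))
        for seg in segs:
            out.write(seg)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_fasta(path: str | os.PathLike) -> dict[str, str]:
    with pysam.FastaFile(str(path)) as fa:
        return {name: fa.fetch(name) for name in fa.references}


# ---------------------------------------------------------------------------
# population allele-frequency table
# ---------------------------------------------------------------------------


@dataclass
class PopulationAFTable:
    """Site-and-allele keyed population allele frequencies.

    Lookup of an absent site returns ``None`` ("unknown"), which is distinct
    from a stored frequency of 0.
    """

    entries: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    n_rejected: int = 0

    def lookup(self, ref_name: str, pos: int, ref: str, alt: str) -> Optional[float]:
        return self.entries.get((ref_name, pos, ref, alt))

    def add(self, ref_name: str, pos: int, ref: str, alt: str, af: float) -> bool:
        if not (0.0 <= af <= 1.0):
            self.n_rejected += 1
            return False
        self.entries[(ref_name, pos, ref, alt)] = af
        return True

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_dataframe(cls, snps: pd.DataFrame, ref_name: str) -> "PopulationAFTable":
        """Build a table from a SNP frame with 0-based ``pos``/``ref``/``alt``/``af``."""
        table = cls()
        for row in snps.itertuples(index=False):
            table.add(ref_name, int(row.pos), row.ref, row.alt, float(row.af))
        return table


def load_af_table(path: str | os.PathLike, fmt: Optional[str] = None) -> PopulationAFTable:
    """Load an allele-frequency table from VCF or 5-column TSV.

    TSV columns: chrom, pos (1-based), ref, alt, af. Multiallelic VCF rows
    are split per alternate allele; rows with AF outside [0, 1] are rejected
    and counted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv"
    table = PopulationAFTable()
    if fmt == "vcf":
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                afs = rec.info.get("AF")
                if afs is None:
                    continue
                if not isinstance(afs, (tuple, list)):
                    afs = (afs,)
                for alt, af in zip(rec.alts or (), afs):
                    if not table.add(rec.chrom, rec.pos - 1, rec.ref, alt, float(af)):
                        logger.warning(
                            "AF out of range at %s:%d %s>%s", rec.chrom, rec.pos, rec.ref, alt
                        )
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for row in df.itertuples(index=False):
            if not table.add(str(row.chrom), int(row.pos) - 1, row.ref, row.alt, float(row.af)):
                logger.warning("AF out of range at %s:%d", row.chrom, row.pos)
    else:
        raise ValueError(f"unknown AF table format: {fmt!r}")
    if table.n_rejected:
        logger.warning("rejected %d AF rows outside [0, 1]", table.n_rejected)
    return table


def write_af_vcf(snps: pd.DataFrame, path: str | os.PathLike, ref_name: str) -> None:
    """Write a minimal AF-annotated VCF (CHROM POS REF ALT; AF in INFO).

    ``snps`` must carry 0-based ``pos`` plus ``ref``, ``alt``, ``af``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">\n'
        )
        fh.write(f"##contig=<ID={ref_name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in snps.sort_values("pos").itertuples(index=False):
            fh.write(
                f"{ref_name}\t{int(row.pos) + 1}\t.\t{row.ref}\t{row.alt}\t.\t.\tAF={row.af:.6g}\n"
            )
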
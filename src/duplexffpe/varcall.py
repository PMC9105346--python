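"""Duplex-supported variant calling and common-polymorphism removal.

The caller cannot distinguish somatic mutations from rare germline variants
(no matched germline genome is used), so its output is labelled simply
"mutations"; the population-frequency filter only removes common sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .consensus import DuplexConsensus
from .io_bridge import PopulationAFTable

VariantClass = str  # 'SNV' | 'insertion' | 'deletion'


@dataclass(frozen=True)
class VariantCall:
    ref_name: str
    pos: int  # 0-based position of the first REF base (VCF-style anchored for indels)
    ref: str
    alt: str
    vclass: VariantClass
    template_key: tuple[str, int, int]
    af: Optional[float] = None

    @property
    def site(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class SnpFilterConfig:
    """A call is removed iff its table AF is strictly above ``af_threshold``."""

    af_threshold: float = 0.01

    def validate(self) -> None:
        if not (0.0 <= self.af_threshold <= 1.0):
            raise ValueError("af_threshold must be in [0, 1]")


def normalize_variant(pos: int, ref: str, alt: str, refseq: str) -> tuple[int, str, str]:
    """Left-align and trim an allele pair against the reference sequence.

    Standard parsimony/left-shuffling: right-trim shared trailing bases
    (extending leftward through repeats), then left-trim shared leading
    bases. SNVs pass through unchanged.
    """
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    ref_l, alt_l = list(ref), list(alt)
    while ref_l and alt_l and ref_l[-1] == alt_l[-1] and (len(ref_l) > 1 or len(alt_l) > 1):
        last = ref_l.pop()
        alt_l.pop()
        if not ref_l or not alt_l:
            if pos == 0:
                # cannot extend past the reference start; undo and stop
                ref_l.append(last)
                alt_l.append(last)
                break
            pos -= 1
            base = refseq[pos]
            ref_l.insert(0, base)
            alt_l.insert(0, base)
    while len(ref_l) > 1 and len(alt_l) > 1 and ref_l[0] == alt_l[0]:
        ref_l.pop(0)
        alt_l.pop(0)
        pos += 1
    return pos, "".join(ref_l), "".join(alt_l)


def call_variants(
    duplexes: Iterable[DuplexConsensus],
    refseq: str,
    ref_name: str,
) -> list[VariantCall]:
    """Emit one call per duplex-supported difference from the reference.

    SNVs are emitted per position; deletions and insertions once per event,
    left-aligned. A deletion run is only emitted when it is flanked on both
    sides by duplex-called non-deleted positions, so its full extent is
    certain. Per-call template provenance is retained.
    """
    calls: list[VariantCall] = []
    n = len(refseq)
    for dup in duplexes:
        items = sorted(dup.calls.items())
        del_run: list[int] = []

        def flush_deletion(run: list[int]) -> None:
            if not run:
                return
            s, e = run[0], run[-1] + 1
            left, right = s - 1, e
            if dup.calls.get(left, "-")[0] == "-" or dup.calls.get(right, "-")[0] == "-":
                return  # truncated or unbounded run: extent uncertain
            p, r, a = normalize_variant(left, refseq[left:e], refseq[left], refseq)
            calls.append(
                VariantCall(ref_name, p, r, a, "deletion", dup.key)
            )

        for pos, token in items:
            if pos < 0 or pos >= n:
                raise ValueError(f"duplex position {pos} outside reference (corrupt input)")
            if token == "-":
                if del_run and pos != del_run[-1] + 1:
                    flush_deletion(del_run)
                    del_run = []
                del_run.append(pos)
                continue
            if del_run:
                flush_deletion(del_run)
                del_run = []
            base, _, ins = token.partition("+")
            if base != refseq[pos]:
                calls.append(
                    VariantCall(ref_name, pos, refseq[pos], base, "SNV", dup.key)
                )
            if ins:
                p, r, a = normalize_variant(pos, refseq[pos], refseq[pos] + ins, refseq)
                calls.append(VariantCall(ref_name, p, r, a, "insertion", dup.key))
        # a run still open at the end of the called span has no right flank
    calls.sort(key=lambda c: (c.ref_name, c.pos, c.ref, c.alt, c.template_key))
    return calls


def filter_common_snps(
    calls: Sequence[VariantCall],
    af_table: PopulationAFTable,
    config: SnpFilterConfig | None = None,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls into (retained, removed-as-common).

    Removal requires a table AF strictly greater than the threshold;
    AF equal to the threshold, below it, or unknown retains the call.
    Matching is allele-exact. Each call is annotated with its looked-up AF.
    """
    config = config or SnpFilterConfig()
    config.validate()
    retained: list[VariantCall] = []
    removed: list[VariantCall] = []
    for call in calls:
        af = af_table.lookup(call.ref_name, call.pos, call.ref, call.alt)
        annotated = VariantCall(
            call.ref_name, call.pos, call.ref, call.alt, call.vclass,
            call.template_key, af,
        )
        if af is not None and af > config.af_threshold:
            removed.append(annotated)
        else:
            retained.append(annotated)
    return retained, removed


def write_vcf(
    calls: Sequence[VariantCall],
    path,
    ref_name: str,
    reference_length: int,
) -> None:
    """Write calls as a minimal VCF with AF and template provenance in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">\n')
        fh.write('##INFO=<ID=TK,Number=1,Type=String,Description="Supporting template key">\n')
        fh.write('##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">\n')
        fh.write(f"##contig=<ID={ref_name},length={reference_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.pos, c.ref, c.alt, c.template_key)):
            af = "." if c.af is None else f"{c.af:.6g}"
            tk = f"{c.template_key[0]}_{c.template_key[1]}_{c.template_key[2]}"
            fh.write(
                f"{c.ref_name}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\t.\t"
                f"AF={af};TK={tk};VC={c.vclass}\n"
            )
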
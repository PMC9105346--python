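"""Read-pair exclusion and end trimming applied before consensus building.

Rules are evaluated in a fixed order — proper pair, mapping confidence,
soft clips, excessive mismatches — and each dropped pair is attributed to
the first rule it fails. End trimming masks terminal bases from evidence
without touching template coordinates, because the outer coordinates are
the molecule identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io_bridge import AlignedPairRecord, ReadAlignment

logger = logging.getLogger(__name__)

RULE_ORDER = ("improper", "ambiguous", "soft_clip", "excessive_mismatch")


@dataclass
class FilterConfig:
    min_mapping_confidence: int = 30
    forbid_soft_clips: bool = True
    require_proper_pair: bool = True
    end_trim: int = 5
    max_mismatch_count: int = 7
    max_mismatch_fraction: float = 0.10

    def validate(self, read_length: int | None = None) -> None:
        if self.end_trim < 0:
            raise ValueError("end_trim must be >= 0")
        if read_length is not None and self.end_trim >= read_length / 2:
            raise ValueError("end_trim must be < half the read length")
        if self.max_mismatch_count < 0 or self.max_mismatch_fraction < 0:
            raise ValueError("mismatch thresholds must be >= 0")
        if self.min_mapping_confidence < 0:
            raise ValueError("min_mapping_confidence must be >= 0")


@dataclass
class FilterReport:
    input_pairs: int = 0
    dropped: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in RULE_ORDER}
    )
    malformed: int = 0
    passed: int = 0

    @property
    def pass_fraction(self) -> float:
        if self.input_pairs == 0:
            return float("nan")
        return self.passed / self.input_pairs

    def to_rows(self) -> list[tuple[str, float]]:
        rows: list[tuple[str, float]] = [("input_pairs", self.input_pairs)]
        rows += [(f"dropped_{rule}", n) for rule, n in self.dropped.items()]
        rows += [
            ("malformed", self.malformed),
            ("passed", self.passed),
            ("pass_fraction", self.pass_fraction),
        ]
        return rows


def _count_mismatches(read: ReadAlignment, refseq: str) -> tuple[int, int]:
    """(mismatches, aligned length) over match-type CIGAR runs."""
    mm = 0
    aligned = 0
    qpos = 0
    rpos = read.start
    seq = read.seq
    for op, n in read.cigar:
        if op in "M=X":
            aligned += n
            if seq[qpos : qpos + n] != refseq[rpos : rpos + n]:
                for i in range(n):
                    if seq[qpos + i] != refseq[rpos + i]:
                        mm += 1
            qpos += n
            rpos += n
        elif op in "IS":
            qpos += n
        elif op in "DN":
            rpos += n
    return mm, aligned


def _failing_rule(
    pair: AlignedPairRecord, config: FilterConfig, refseq: str
) -> str | None:
    if config.require_proper_pair and (not pair.proper or pair.r2 is None):
        return "improper"
    if pair.mapq < config.min_mapping_confidence:
        return "ambiguous"
    if config.forbid_soft_clips and any(m.has_soft_clip() for m in pair.mates()):
        return "soft_clip"
    for mate in pair.mates():
        mm, aligned = _count_mismatches(mate, refseq)
        limit = max(config.max_mismatch_count, config.max_mismatch_fraction * aligned)
        if mm > limit:
            return "excessive_mismatch"
    return None


def filter_pairs(
    pairs: Iterable[AlignedPairRecord],
    config: FilterConfig | None = None,
    refseq: str = "",
) -> tuple[list[AlignedPairRecord], FilterReport]:
    """Apply the exclusion rules; surviving pairs are returned unchanged.

    A pair is dropped if either mate violates any enabled rule; the drop is
    attributed to the first failing rule in ``RULE_ORDER``. Malformed
    records (empty alignments) are counted and skipped with a warning.
    """
    config = config or FilterConfig()
    config.validate()
    report = FilterReport()
    passing: list[AlignedPairRecord] = []
    for pair in pairs:
        report.input_pairs += 1
        if not pair.r1.cigar or not pair.r1.seq:
            report.malformed += 1
            logger.warning("skipping malformed record %s", pair.qname)
            continue
        rule = _failing_rule(pair, config, refseq)
        if rule is None:
            passing.append(pair)
            report.passed += 1
        else:
            report.dropped[rule] += 1
    return passing, report


def trim_ends(pair: AlignedPairRecord, end_trim: int) -> AlignedPairRecord:
    """Mask the terminal ``end_trim`` aligned positions of each read.

    Masked bases are excluded from consensus support; template coordinates
    (the molecule identity) are not altered. ``end_trim`` of 0 is the
    identity.
    """
    if end_trim < 0:
        raise ValueError("end_trim must be >= 0")
    if end_trim == pair.trim:
        return pair
    return replace(pair, trim=end_trim)


def trim_all(
    pairs: Sequence[AlignedPairRecord], end_trim: int
) -> list[AlignedPairRecord]:
    return [trim_ends(p, end_trim) for p in pairs]
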
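"""Coordinate-keyed strand families, strand consensus and duplex merging.

Because the library is bottlenecked to a small number of molecules before
amplification, the mapped template coordinates uniquely identify each
original molecule; exact ``(reference, start, end)`` matching replaces
molecular barcodes. Each molecule yields up to two strand families (one per
orientation), whose per-position consensus calls are merged into a duplex
consensus containing only positions supported by both strands.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .io_bridge import AlignedPairRecord, ReadAlignment

TemplateKey = tuple[str, int, int]

#: evidence tokens: 'A'/'C'/'G'/'T'/'N' base call, '-' deletion of the
#: reference position, or '<base>+<seq>' for a base followed by an insertion.
Token = str


@dataclass
class ConsensusConfig:
    min_copies: int = 5
    min_agreement: float = 0.8
    min_base_quality: int = 20

    def validate(self) -> None:
        if self.min_copies < 1:
            raise ValueError("min_copies must be >= 1")
        if not (0.5 < self.min_agreement <= 1.0):
            raise ValueError("min_agreement must be in (0.5, 1]")


@dataclass
class StrandConsensus:
    key: TemplateKey
    orientation: str
    calls: dict[int, Token]
    depth: dict[int, int]
    #: agreement fraction at called positions; positions absent from this
    #: map were unanimous (agreement 1.0) — see :meth:`agreement_at`.
    agreement: dict[int, float]
    n_members: int

    @property
    def called_length(self) -> int:
        return len(self.calls)

    def agreement_at(self, pos: int) -> float:
        return self.agreement.get(pos, 1.0)


@dataclass
class ConsensusRejection:
    key: TemplateKey
    orientation: str
    reason: str
    n_members: int


@dataclass
class DuplexConsensus:
    key: TemplateKey
    calls: dict[int, Token]

    @property
    def duplex_length(self) -> int:
        return len(self.calls)


@dataclass
class TemplateResult:
    """Everything derived from one unique template."""

    key: TemplateKey
    top: Union[StrandConsensus, ConsensusRejection, None]
    bottom: Union[StrandConsensus, ConsensusRejection, None]
    duplex: Optional[DuplexConsensus]

    @property
    def strand_consensuses(self) -> list[StrandConsensus]:
        return [s for s in (self.top, self.bottom) if isinstance(s, StrandConsensus)]


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def group_templates(
    pairs: Iterable[AlignedPairRecord],
) -> dict[TemplateKey, dict[str, list[AlignedPairRecord]]]:
    """Group pairs into strand families by exact template coordinates.

    Each template key maps to up to two families keyed 'top'/'bottom'.
    Improper pairs (undefined orientation) are ignored; they should have
    been removed by the read filter.
    """
    grouped: dict[TemplateKey, dict[str, list[AlignedPairRecord]]] = {}
    for pair in pairs:
        orient = pair.orientation
        if orient is None:
            continue
        grouped.setdefault(pair.template_key, {}).setdefault(orient, []).append(pair)
    return grouped


# ---------------------------------------------------------------------------
# per-pair evidence
# ---------------------------------------------------------------------------


def _read_evidence(
    read: ReadAlignment, trim: int, min_base_quality: int
) -> dict[int, Token]:
    """Per-reference-position evidence tokens from one mate.

    The first and last ``trim`` aligned query positions are masked. Deletion
    positions contribute '-' unless adjacent to a masked query position;
    insertions are anchored to the token of the preceding reference-aligned
    base.
    """
    out: dict[int, Token] = {}
    qlen = read.query_length
    lo_q, hi_q = trim, qlen - trim
    if hi_q <= lo_q:
        return out
    flat_q = isinstance(read.qual, int)
    if flat_q and read.qual < min_base_quality:
        return out

    # fast path: single match run, no indels or clips
    if len(read.cigar) == 1 and read.cigar[0][0] == "M":
        start = read.start
        seq = read.seq
        if flat_q:
            return dict(zip(range(start + lo_q, start + hi_q), seq[lo_q:hi_q]))
        qual = read.qual
        for i in range(lo_q, hi_q):
            if qual[i] >= min_base_quality:
                out[start + i] = seq[i]
        return out

    qpos = 0
    rpos = read.start
    anchor: Optional[int] = None  # ref pos of last emitted aligned base
    for op, n in read.cigar:
        if op in "M=X":
            for i in range(n):
                q = qpos + i
                r = rpos + i
                if lo_q <= q < hi_q and (
                    flat_q or read.qual[q] >= min_base_quality
                ):
                    out[r] = read.seq[q]
                    anchor = r
                else:
                    anchor = None
            qpos += n
            rpos += n
        elif op == "I":
            if (
                anchor is not None
                and lo_q <= qpos
                and qpos + n <= hi_q
                and anchor in out
            ):
                out[anchor] = out[anchor].partition("+")[0] + "+" + read.seq[qpos : qpos + n]
            else:
                anchor = None
            qpos += n
        elif op in "DN":
            if anchor is not None and op == "D":
                for i in range(n):
                    out[rpos + i] = "-"
            rpos += n
            anchor = None
        elif op == "S":
            qpos += n
            anchor = None
        # H/P consume nothing relevant
    return out


def pair_evidence(
    pair: AlignedPairRecord, min_base_quality: int = 20
) -> dict[int, Token]:
    """Evidence of one pair: union of its mates, conflicts dropped.

    Where both mates cover a position with different tokens the pair
    contributes nothing there (simple counting; no quality fusion).
    """
    ev1 = _read_evidence(pair.r1, pair.trim, min_base_quality)
    if pair.r2 is None:
        return ev1
    ev2 = _read_evidence(pair.r2, pair.trim, min_base_quality)
    if not ev1:
        return ev2
    if not ev2 or ev1 == ev2:
        return ev1
    out = dict(ev1)
    for pos, tok in ev2.items():
        prev = out.get(pos)
        if prev is None:
            out[pos] = tok
        elif prev != tok:
            # keep the richer token when one mate saw the insertion and the
            # other only the base; anything else is a conflict
            if prev.partition("+")[0] == tok.partition("+")[0] and (
                "+" in prev or "+" in tok
            ):
                out[pos] = prev if "+" in prev else tok
            else:
                del out[pos]
    return out


# ---------------------------------------------------------------------------
# consensus building
# ---------------------------------------------------------------------------


def build_strand_consensus(
    family: Sequence[AlignedPairRecord],
    config: ConsensusConfig | None = None,
    orientation: Optional[str] = None,
) -> Union[StrandConsensus, ConsensusRejection]:
    """Consensus of one strand family, or a rejection value.

    Families with fewer than ``min_copies`` member pairs are rejected. At
    each position a token is called iff at least ``min_copies`` member pairs
    contribute evidence there and the modal token reaches ``min_agreement``
    of the contributing pairs; otherwise the position is undetermined.
    """
    if not family:
        raise ValueError("family must be nonempty")
    config = config or ConsensusConfig()
    config.validate()
    key = family[0].template_key
    orient = orientation or family[0].orientation or "?"
    for pair in family:
        if pair.template_key != key:
            raise ValueError("family members must share a template key")
    if len(family) < config.min_copies:
        return ConsensusRejection(key, orient, "below_min_copies", len(family))

    min_copies = config.min_copies
    min_agree = config.min_agreement
    evidences = [pair_evidence(p, config.min_base_quality) for p in family]

    # Members of a family are near-identical (same molecule, same windows),
    # so tally per position only where some member deviates from the first;
    # everywhere else the call is unanimous at full depth.
    base = evidences[0]
    base_items = set(base.items())
    contested: set[int] = set()
    for ev in evidences[1:]:
        if ev == base:
            continue
        for pos, _ in base_items.symmetric_difference(ev.items()):
            contested.add(pos)

    n = len(family)
    calls: dict[int, Token] = {}
    depth: dict[int, int] = {}
    agreement: dict[int, float] = {}
    if n >= min_copies:
        calls = {pos: tok for pos, tok in base.items() if pos not in contested}
        depth = dict.fromkeys(calls, n)
    for pos in contested:
        tally: Counter = Counter()
        for ev in evidences:
            tok = ev.get(pos)
            if tok is not None:
                tally[tok] += 1
        d = sum(tally.values())
        if d < min_copies:
            continue
        tok, cnt = tally.most_common(1)[0]
        frac = cnt / d
        if frac >= min_agree:
            calls[pos] = tok
            depth[pos] = d
            if frac < 1.0:
                agreement[pos] = frac
    return StrandConsensus(key, orient, calls, depth, agreement, len(family))


def merge_duplex(top: StrandConsensus, bottom: StrandConsensus) -> DuplexConsensus:
    """Duplex consensus: positions called identically by both strands.

    Tokens are stored reference-oriented on both strands, so concordance is
    token equality. Discordant or half-called positions are undetermined.
    """
    if top.key != bottom.key:
        raise ValueError(f"mismatched template keys: {top.key} vs {bottom.key}")
    small, large = (top.calls, bottom.calls) if len(top.calls) <= len(bottom.calls) else (bottom.calls, top.calls)
    calls = {pos: tok for pos, tok in small.items() if large.get(pos) == tok}
    return DuplexConsensus(top.key, calls)


def build_duplexes(
    grouped: Mapping[TemplateKey, Mapping[str, Sequence[AlignedPairRecord]]],
    config: ConsensusConfig | None = None,
) -> list[TemplateResult]:
    """Run strand consensus and duplex merging over all grouped templates."""
    config = config or ConsensusConfig()
    results: list[TemplateResult] = []
    for key in sorted(grouped):
        fams = grouped[key]
        top = (
            build_strand_consensus(fams["top"], config, "top")
            if "top" in fams
            else None
        )
        bottom = (
            build_strand_consensus(fams["bottom"], config, "bottom")
            if "bottom" in fams
            else None
        )
        duplex = None
        if isinstance(top, StrandConsensus) and isinstance(bottom, StrandConsensus):
            merged = merge_duplex(top, bottom)
            if merged.duplex_length > 0:
                duplex = merged
        results.append(TemplateResult(key, top, bottom, duplex))
    return results


def duplex_fraction(results: Sequence[TemplateResult]) -> float:
    """Fraction of unique templates yielding a non-empty duplex consensus.

    Returns NaN (a flagged undefined value, not an exception) when there are
    no templates.
    """
    if not results:
        return float("nan")
    return sum(1 for r in results if r.duplex is not None) / len(results)
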
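"""Generative simulator of bottlenecked duplex libraries from damaged DNA.

The model follows the library chemistry that the analysis has to survive:
a small diploid reference with germline SNPs, true double-strand mutations
planted per molecule, single-strand base lesions (dominated by cytosine
deamination), lognormal fragment lengths, geometric 5'-overhangs at both
ends, per-strand dropout (nicks/gaps), end repair either by a polymerase
(which fills overhangs and thereby copies lesions onto the opposite strand,
fixing them as false double-strand mutations near fragment ends) or by a
single-strand nuclease (which removes the overhangs, shortening the
template), a molecule bottleneck, PCR duplication per strand, and per-copy
PCR and sequencing errors. Reads are emitted pre-aligned — coordinates are
known by construction — together with a complete ground-truth ledger.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_bridge import (
    AlignedPairRecord,
    ReadAlignment,
    write_af_vcf,
    write_alignments,
    write_fasta,
)
from .varcall import normalize_variant

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}

POLYMERASE = "polymerase"
NUCLEASE = "nuclease"


@dataclass
class SimulationParams:
    reference_length: int = 1_000_000
    reference_name: str = "chrS"
    snp_density_per_mb: float = 600.0
    snp_common_fraction: float = 0.5
    snp_common_af_range: tuple[float, float] = (0.05, 0.5)
    snp_rare_af_range: tuple[float, float] = (0.002, 0.01)
    somatic_rate_snv: float = 20.0
    somatic_rate_indel: float = 0.0
    max_indel_length: int = 3
    lesion_rate: float = 0.0
    lesion_deamination_fraction: float = 0.9
    fragment_length_median: float = 146.0
    fragment_length_sigma: float = 0.18
    overhang_mean: float = 6.0
    strand_dropout_prob: float = 0.2
    end_repair_mode: str = POLYMERASE
    n_templates: int = 20000
    pcr_copies_mean: float = 6.0
    pcr_error_rate: float = 1e-5
    seq_error_rate: float = 1e-3
    read_length: int = 150
    base_quality: int = 30
    decoy_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        rates = (
            self.snp_density_per_mb, self.somatic_rate_snv, self.somatic_rate_indel,
            self.lesion_rate, self.pcr_error_rate, self.seq_error_rate,
            self.decoy_fraction,
        )
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be >= 0")
        if self.fragment_length_median <= 2 * self.overhang_mean:
            raise ValueError("fragment_length_median must exceed 2 x overhang_mean")
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        if self.pcr_copies_mean < 1:
            raise ValueError("pcr_copies_mean must be >= 1")
        if not (0.0 <= self.strand_dropout_prob <= 1.0):
            raise ValueError("strand_dropout_prob must be in [0, 1]")
        if self.end_repair_mode not in (POLYMERASE, NUCLEASE):
            raise ValueError(
                f"end_repair_mode must be '{POLYMERASE}' or '{NUCLEASE}'"
            )
        if not (0.0 <= self.lesion_deamination_fraction <= 1.0):
            raise ValueError("lesion_deamination_fraction must be in [0, 1]")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("snp_common_af_range", "snp_rare_af_range"):
            if key in d and not isinstance(d[key], tuple):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground-truth ledger emitted alongside the reads."""

    germline: pd.DataFrame
    fragments: pd.DataFrame
    somatic: pd.DataFrame
    lesions: pd.DataFrame
    decoys: pd.DataFrame
    lesions_skipped: int = 0

    def duplex_formable_fraction(self) -> float:
        """Fraction of molecules with both strands amplifiable (pre-PCR)."""
        f = self.fragments
        if len(f) == 0:
            return float("nan")
        return float((~f.drop_top & ~f.drop_bottom).mean())

    def write(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        self.germline.to_csv(out / "truth_germline.tsv", sep="\t", index=False)
        self.fragments.to_csv(out / "truth_fragments.tsv", sep="\t", index=False)
        self.somatic.to_csv(out / "truth_somatic.tsv", sep="\t", index=False)
        self.lesions.to_csv(out / "truth_lesions.tsv", sep="\t", index=False)
        self.decoys.to_csv(out / "truth_decoys.tsv", sep="\t", index=False)


@dataclass
class SimLibrary:
    params: SimulationParams
    ref_name: str
    pairs: list[AlignedPairRecord]
    truth: SimTruth


def simulate_reference(
    params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> tuple[str, pd.DataFrame]:
    """Uniform-random reference plus a germline SNP table with population AFs.

    The AF mixture contains both common (> 1%) and rare (<= 1%) sites so the
    population filter has work to do in both directions.
    """
    params.validate()
    if params.reference_length < 10_000:
        raise ValueError("reference_length must be >= 10 kb")
    rng = rng or np.random.default_rng([params.seed, 0])
    L = params.reference_length
    codes = rng.integers(0, 4, size=L)
    seq = codes.astype(np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    reference = lut[seq].tobytes().decode("ascii")

    n_snps = int(rng.poisson(params.snp_density_per_mb * L / 1e6))
    if n_snps > L // 10:
        raise ValueError(
            "reference_length too small to place the requested SNP density "
            f"({n_snps} sites on {L} bases)"
        )
    if n_snps == 0:
        snps = pd.DataFrame(columns=["pos", "ref", "alt", "af"]).astype(
            {"pos": int, "af": float}
        )
        return reference, snps
    positions = np.sort(rng.choice(L, size=n_snps, replace=False))
    is_common = rng.random(n_snps) < params.snp_common_fraction
    lo_c, hi_c = params.snp_common_af_range
    lo_r, hi_r = params.snp_rare_af_range
    afs = np.where(
        is_common,
        rng.uniform(lo_c, hi_c, n_snps),
        rng.uniform(lo_r, hi_r, n_snps),
    )
    refs = [reference[p] for p in positions]
    alt_idx = rng.integers(0, 3, n_snps)
    alts = [_OTHER[r][i] for r, i in zip(refs, alt_idx)]
    snps = pd.DataFrame(
        {"pos": positions.astype(int), "ref": refs, "alt": alts, "af": afs}
    )
    return reference, snps


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------


def _build_walk(
    refseq: str,
    t_start: int,
    t_end: int,
    sub: dict[int, str],
    dels: set[int],
    ins: dict[int, str],
) -> tuple[str, Optional[list[int]]]:
    """Molecule strand sequence over the template span plus query->ref map.

    Returns ``(qseq, qref)`` where ``qref[i]`` is the reference position of
    query base ``i`` or -1 for inserted bases. ``qref`` is ``None`` when the
    molecule is a pure match (the common case), signalling the fast path.
    """
    if not sub and not dels and not ins:
        return refseq[t_start:t_end], None
    if not dels and not ins:
        s = list(refseq[t_start:t_end])
        for p, b in sub.items():
            s[p - t_start] = b
        return "".join(s), None
    qbases: list[str] = []
    qref: list[int] = []
    for p in range(t_start, t_end):
        if p in dels:
            continue
        qbases.append(sub.get(p) or refseq[p])
        qref.append(p)
        extra = ins.get(p)
        if extra:
            qbases.extend(extra)
            qref.extend([-1] * len(extra))
    return "".join(qbases), qref


def _slice_cigar(
    qref: list[int], lo: int, hi: int
) -> tuple[int, tuple[tuple[str, int], ...]]:
    """Reference start and CIGAR of the read covering query span [lo, hi).

    Leading/trailing insertions become soft clips; internal reference gaps
    become deletions.
    """
    ops: list[tuple[str, int]] = []
    ref_start = -1
    prev_ref = -1
    for i in range(lo, hi):
        r = qref[i]
        if r < 0:
            op = "I"
        else:
            if prev_ref >= 0 and r > prev_ref + 1:
                ops.append(("D", r - prev_ref - 1))
            if ref_start < 0:
                ref_start = r
            prev_ref = r
            op = "M"
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    if ops and ops[0][0] == "I":
        ops[0] = ("S", ops[0][1])
    if ops and ops[-1][0] == "I":
        ops[-1] = ("S", ops[-1][1])
    return ref_start, tuple(ops)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    s = list(seq)
    for i in rng.integers(0, len(s), size=k):
        b = s[i]
        s[i] = _OTHER.get(b, "ACG")[rng.integers(0, 3)]
    return "".join(s)


def simulate_library(
    reference: str,
    snps: pd.DataFrame,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> SimLibrary:
    """Emit coordinate-sorted aligned read pairs plus the truth ledger."""
    params.validate()
    rng = rng or np.random.default_rng([params.seed, 1])
    L = len(reference)
    n = params.n_templates
    rl = params.read_length

    # --- individual genotype: two haplotype indicators per SNP (HWE) ------
    n_snps = len(snps)
    if n_snps:
        afs = snps["af"].to_numpy()
        hap_carry = [rng.random(n_snps) < afs, rng.random(n_snps) < afs]
    else:
        hap_carry = [np.zeros(0, bool), np.zeros(0, bool)]
    germline = snps.copy()
    germline["hap0"] = hap_carry[0]
    germline["hap1"] = hap_carry[1]
    snp_pos = snps["pos"].to_numpy() if n_snps else np.zeros(0, int)
    snp_alt = snps["alt"].to_numpy() if n_snps else np.zeros(0, object)
    carried_idx = [np.flatnonzero(hap_carry[h]) for h in (0, 1)]
    carried_pos = [snp_pos[idx] for idx in carried_idx]
    carried_alt = [snp_alt[idx] for idx in carried_idx]

    # --- molecule-level draws (mode-independent, shared random stream) ----
    mu = math.log(params.fragment_length_median)
    lens = np.rint(rng.lognormal(mu, params.fragment_length_sigma, n)).astype(int)
    lens = np.clip(lens, 40, max(40, L - 1))
    starts = rng.integers(0, L - lens + 1)
    haps = rng.integers(0, 2, n)
    if params.overhang_mean > 0:
        p_geo = 1.0 / (params.overhang_mean + 1.0)
        o_left = rng.geometric(p_geo, n) - 1
        o_right = rng.geometric(p_geo, n) - 1
    else:
        o_left = np.zeros(n, int)
        o_right = np.zeros(n, int)
    o_left = np.minimum(o_left, lens // 3)
    o_right = np.minimum(o_right, lens // 3)
    drop_top = rng.random(n) < params.strand_dropout_prob
    drop_bottom = rng.random(n) < params.strand_dropout_prob
    copies_top = 1 + rng.poisson(params.pcr_copies_mean - 1.0, n)
    copies_bottom = 1 + rng.poisson(params.pcr_copies_mean - 1.0, n)
    mb = lens / 1e6
    n_snv = rng.poisson(params.somatic_rate_snv * mb)
    n_indel = rng.poisson(params.somatic_rate_indel * mb)
    n_les_top = rng.poisson(params.lesion_rate * mb)
    n_les_bottom = rng.poisson(params.lesion_rate * mb)

    nuclease = params.end_repair_mode == NUCLEASE

    frag_rows: list[tuple] = []
    som_rows: list[tuple] = []
    les_rows: list[tuple] = []
    decoy_rows: list[tuple] = []
    pairs: list[AlignedPairRecord] = []
    lesions_skipped = 0
    deam_target = {"top": "C", "bottom": "G"}
    deam_alt = {"top": "T", "bottom": "A"}

    for m in range(n):
        start = int(starts[m])
        flen = int(lens[m])
        end = start + flen
        hap = int(haps[m])
        ol = int(o_left[m])
        orr = int(o_right[m])

        shared_sub: dict[int, str] = {}
        dels: set[int] = set()
        ins: dict[int, str] = {}
        strand_sub = {"top": {}, "bottom": {}}

        # germline genotype on this molecule's haplotype
        lo = np.searchsorted(carried_pos[hap], start)
        hi = np.searchsorted(carried_pos[hap], end)
        for p, a in zip(carried_pos[hap][lo:hi], carried_alt[hap][lo:hi]):
            shared_sub[int(p)] = a

        # somatic double-strand events (private to this molecule)
        normalized_seen: set[tuple[int, str, str]] = set()
        for _ in range(int(n_snv[m])):
            p = int(rng.integers(start, end))
            if p in shared_sub or p in dels or p in ins:
                continue
            ref_b = reference[p]
            alt_b = _OTHER[ref_b][rng.integers(0, 3)]
            shared_sub[p] = alt_b
            som_rows.append((m, p, ref_b, alt_b, "SNV", p))
        # indels stay clear of the overhang spans so their extent is never
        # truncated by nuclease blunting
        i_lo = start + ol + 2
        i_hi = end - orr - 2
        for _ in range(int(n_indel[m])):
            k = int(rng.integers(1, params.max_indel_length + 1))
            is_del = rng.random() < 0.5
            if is_del:
                if i_hi - k <= i_lo:
                    continue
                p = int(rng.integers(i_lo, i_hi - k))
                span = range(p - 1, p + k + 1)
                if any(q in dels or q in ins or q in shared_sub for q in span):
                    continue
                npos, nref, nalt = normalize_variant(
                    p - 1, reference[p - 1 : p + k], reference[p - 1], reference
                )
                if (npos, nref, nalt) in normalized_seen:
                    continue
                normalized_seen.add((npos, nref, nalt))
                dels.update(range(p, p + k))
                som_rows.append((m, npos, nref, nalt, "deletion", p))
            else:
                if i_hi <= i_lo:
                    continue
                p = int(rng.integers(i_lo, i_hi))
                if p in dels or p in ins or p + 1 in dels:
                    continue
                seq_ins = "".join(_BASES[rng.integers(0, 4)] for _ in range(k))
                npos, nref, nalt = normalize_variant(
                    p, reference[p], reference[p] + seq_ins, reference
                )
                if (npos, nref, nalt) in normalized_seen:
                    continue
                normalized_seen.add((npos, nref, nalt))
                ins[p] = seq_ins
                som_rows.append((m, npos, nref, nalt, "insertion", p))

        # single-strand lesions, placed on the physical extent of each strand
        extents = {"top": (start, end - orr), "bottom": (start + ol, end)}
        for strand, count in (("top", int(n_les_top[m])), ("bottom", int(n_les_bottom[m]))):
            e_lo, e_hi = extents[strand]
            smap = strand_sub[strand]
            for _ in range(count):
                if rng.random() < params.lesion_deamination_fraction:
                    target = deam_target[strand]
                    cands = [
                        p
                        for p in range(e_lo, e_hi)
                        if p not in dels
                        and p not in smap
                        and (shared_sub.get(p) or reference[p]) == target
                    ]
                    if not cands:
                        lesions_skipped += 1
                        continue
                    p = cands[int(rng.integers(0, len(cands)))]
                    orig = target
                    alt_b = deam_alt[strand]
                else:
                    p = int(rng.integers(e_lo, e_hi))
                    if p in dels or p in smap:
                        lesions_skipped += 1
                        continue
                    orig = shared_sub.get(p) or reference[p]
                    alt_b = _OTHER[orig][rng.integers(0, 3)]
                smap[p] = alt_b
                les_rows.append((m, strand, p, orig, alt_b, False, False))

        # end-repair mode transform
        n_copied = 0
        if nuclease:
            t_start, t_end = start + ol, end - orr
            shared_sub = {p: b for p, b in shared_sub.items() if t_start <= p < t_end}
            for strand in ("top", "bottom"):
                kept = {}
                for p, b in strand_sub[strand].items():
                    if t_start <= p < t_end:
                        kept[p] = b
                    else:
                        for i in range(len(les_rows) - 1, -1, -1):
                            row = les_rows[i]
                            if row[0] == m and row[1] == strand and row[2] == p:
                                les_rows[i] = row[:6] + (True,)
                                break
                strand_sub[strand] = kept
        else:
            t_start, t_end = start, end
            # fill-in copies whatever the protruding strand carries
            for p in range(start, start + ol):
                b = strand_sub["top"].get(p)
                if b is not None:
                    strand_sub["bottom"][p] = b
                    n_copied += 1
                    for i in range(len(les_rows) - 1, -1, -1):
                        row = les_rows[i]
                        if row[0] == m and row[1] == "top" and row[2] == p:
                            les_rows[i] = row[:5] + (True, row[6])
                            break
            for p in range(end - orr, end):
                b = strand_sub["bottom"].get(p)
                if b is not None:
                    strand_sub["top"][p] = b
                    n_copied += 1
                    for i in range(len(les_rows) - 1, -1, -1):
                        row = les_rows[i]
                        if row[0] == m and row[1] == "bottom" and row[2] == p:
                            les_rows[i] = row[:5] + (True, row[6])
                            break

        dt, db = bool(drop_top[m]), bool(drop_bottom[m])
        ct = 0 if dt else int(copies_top[m])
        cb = 0 if db else int(copies_bottom[m])
        frag_rows.append(
            (m, start, end, hap, ol, orr, t_start, t_end, dt, db, ct, cb, n_copied)
        )
        if (dt and db) or t_end - t_start < 20:
            continue

        # --- emission ----------------------------------------------------
        for strand, n_copies in (("top", ct), ("bottom", cb)):
            if n_copies == 0:
                continue
            smap = dict(shared_sub)
            smap.update(strand_sub[strand])
            sdels = {p for p in dels if t_start <= p < t_end}
            sins = {p: s for p, s in ins.items() if t_start <= p < t_end}
            qseq, qref = _build_walk(reference, t_start, t_end, smap, sdels, sins)
            M = len(qseq)
            w1 = (0, min(rl, M))
            w2 = (max(0, M - rl), M)
            for c in range(n_copies):
                cseq = _apply_errors(qseq, params.pcr_error_rate, rng)
                reads = []
                for (lo_q, hi_q) in (w1, w2):
                    sub_seq = _apply_errors(
                        cseq[lo_q:hi_q], params.seq_error_rate, rng
                    )
                    if qref is None:
                        ref_start = t_start + lo_q
                        cigar: tuple[tuple[str, int], ...] = (("M", hi_q - lo_q),)
                    else:
                        ref_start, cigar = _slice_cigar(qref, lo_q, hi_q)
                    reads.append((ref_start, sub_seq, cigar))
                (s1, q1, c1), (s2, q2, c2) = reads
                if strand == "top":
                    r1 = ReadAlignment(s1, False, q1, c1, 60, params.base_quality)
                    r2 = ReadAlignment(s2, True, q2, c2, 60, params.base_quality)
                else:
                    r1 = ReadAlignment(s2, True, q2, c2, 60, params.base_quality)
                    r2 = ReadAlignment(s1, False, q1, c1, 60, params.base_quality)
                qname = f"m{m}_{strand}_{c}"
                pair = AlignedPairRecord(
                    qname, params.reference_name, r1, r2, proper=True
                )
                if params.decoy_fraction > 0 and rng.random() < params.decoy_fraction:
                    pair = _make_decoy(pair, rng)
                    decoy_rows.append((qname, pair.decoy_defect))  # type: ignore[attr-defined]
                pairs.append(pair)

    pairs.sort(key=lambda p: (p.start, p.end, p.qname))
    truth = SimTruth(
        germline=germline,
        fragments=pd.DataFrame(
            frag_rows,
            columns=[
                "molecule", "start", "end", "hap", "o_left", "o_right",
                "t_start", "t_end", "drop_top", "drop_bottom",
                "copies_top", "copies_bottom", "n_copied_events",
            ],
        ),
        somatic=pd.DataFrame(
            som_rows, columns=["molecule", "pos", "ref", "alt", "vclass", "raw_pos"]
        ),
        lesions=pd.DataFrame(
            les_rows,
            columns=["molecule", "strand", "pos", "orig", "alt", "copied", "removed"],
        ),
        decoys=pd.DataFrame(decoy_rows, columns=["qname", "defect"]),
        lesions_skipped=lesions_skipped,
    )
    return SimLibrary(params, params.reference_name, pairs, truth)


_DECOY_DEFECTS = ("soft_clip", "ambiguous", "improper", "excessive_mismatch")


def _make_decoy(pair: AlignedPairRecord, rng: np.random.Generator) -> AlignedPairRecord:
    """Corrupt a pair so that exactly one filter rule must catch it."""
    from dataclasses import replace

    defect = _DECOY_DEFECTS[int(rng.integers(0, len(_DECOY_DEFECTS)))]
    r1 = pair.r1
    if defect == "soft_clip":
        op, n0 = r1.cigar[0]
        if op == "M" and n0 > 20:
            clip = 10
            new_cigar = (("S", clip), ("M", n0 - clip)) + r1.cigar[1:]
            r1 = replace(r1, start=r1.start + clip, cigar=new_cigar)
        pair = replace(pair, r1=r1)
    elif defect == "ambiguous":
        pair = replace(pair, r1=replace(r1, mapq=5))
    elif defect == "improper":
        pair = replace(pair, proper=False)
    else:  # excessive_mismatch
        seq = list(r1.seq)
        k = max(10, int(0.15 * len(seq)) + 8)
        for i in rng.choice(len(seq), size=min(k, len(seq)), replace=False):
            seq[i] = _OTHER[seq[i]][rng.integers(0, 3)] if seq[i] in _OTHER else "A"
        pair = replace(pair, r1=replace(r1, seq="".join(seq)))
    pair.decoy_defect = defect  # type: ignore[attr-defined]
    return pair


def write_library(
    library: SimLibrary,
    reference: str,
    snps: pd.DataFrame,
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write FASTA, sorted SAM, AF VCF and truth TSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = library.ref_name
    paths = {
        "reference": out / "reference.fa",
        "alignments": out / "reads.sam",
        "af_table": out / "population_af.vcf",
    }
    write_fasta({name: reference}, paths["reference"])
    write_alignments(library.pairs, paths["alignments"], {name: len(reference)})
    write_af_vcf(snps, paths["af_table"], name)
    library.truth.write(out)
    return paths
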
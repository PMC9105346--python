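"""Consensus tests, including an independent exhaustive per-position oracle
used to cross-check the production implementation on hand-built families."""

import math

import pytest

from duplexffpe import (
    ConsensusConfig,
    build_duplexes,
    build_strand_consensus,
    duplex_fraction,
    group_templates,
    merge_duplex,
)
from duplexffpe.consensus import (
    ConsensusRejection,
    StrandConsensus,
    pair_evidence,
)

from conftest import make_pair

REF = "ACGTA" * 40  # 200 bases


# ---------------------------------------------------------------------------
# independent oracle: plain nested-loop tally over pair evidence
# ---------------------------------------------------------------------------


def oracle_strand_consensus(family, config):
    """Exhaustive per-position tally, written independently of the
    production code path (no shortcuts, no shared tallying logic)."""
    if len(family) < config.min_copies:
        return ("rejected", "below_min_copies")
    per_pair = [pair_evidence(p, config.min_base_quality) for p in family]
    positions = sorted({pos for ev in per_pair for pos in ev})
    calls = {}
    for pos in positions:
        votes = [ev[pos] for ev in per_pair if pos in ev]
        if len(votes) < config.min_copies:
            continue
        best = max(set(votes), key=votes.count)
        if votes.count(best) / len(votes) >= config.min_agreement:
            calls[pos] = best
    return ("called", calls)


def oracle_duplex(top_calls, bottom_calls):
    return {
        pos: tok
        for pos, tok in top_calls.items()
        if bottom_calls.get(pos) == tok
    }


def mutate(seq, offset, base):
    s = list(seq)
    s[offset] = base
    return "".join(s)


def family_of(n, start=10, length=60, seq=None, orientation="top", **kw):
    seq = seq or REF[start : start + length]
    return [
        make_pair(start, seq, qname=f"f{i}", reverse_r1=(orientation == "bottom"), **kw)
        for i in range(n)
    ]


class TestOracleEquivalence:
    def test_twenty_hand_built_families(self):
        config = ConsensusConfig()
        families = []
        base = REF[10:70]
        families.append(family_of(4))                      # rejected: 4 copies
        families.append(family_of(5))                      # exact min
        families.append(family_of(6))
        # one discordant member at one site (5/6 = 0.83 >= 0.8)
        fam = family_of(5) + [make_pair(10, mutate(base, 20, "A" if base[20] != "A" else "C"), qname="err")]
        families.append(fam)
        # 2/6 disagree -> 0.67 < 0.8: undetermined site
        alt = mutate(base, 20, "A" if base[20] != "A" else "C")
        families.append(family_of(4) + [make_pair(10, alt, qname=f"e{i}") for i in range(2)])
        # three-way split at a site
        for b in "ACG":
            families.append(family_of(3) + [
                make_pair(10, mutate(base, 30, b2), qname=f"x{b2}")
                for b2 in "ACT" if b2 != b
            ])
        # families with deletions / insertions in some members
        del_cigar = (("M", 20), ("D", 2), ("M", 38))
        del_seq = base[:20] + base[22:]
        families.append([
            make_pair(10, del_seq, cigar1=del_cigar, cigar2=del_cigar, qname=f"d{i}", end=70)
            for i in range(5)
        ])
        ins_cigar = (("M", 20), ("I", 2), ("M", 38))
        ins_seq = base[:20] + "TT" + base[20:58]
        families.append([
            make_pair(10, ins_seq, cigar1=ins_cigar, cigar2=ins_cigar, qname=f"i{i}", end=68)
            for i in range(6)
        ])
        # mixed cigar family: majority plain, minority deleted
        families.append(family_of(5) + [
            make_pair(10, del_seq, cigar1=del_cigar, cigar2=del_cigar, qname="dmin", end=70)
        ])
        # different sizes and trims
        families.append([p for p in family_of(7)])
        families.append([make_pair(10, base, qname=f"t{i}") for i in range(5)])
        for extra in range(1, 4):
            families.append(family_of(4 + extra, start=15 + extra, length=40 + extra))
        families.append(family_of(9, length=30))
        families.append(family_of(5, length=25))
        assert len(families) <= 20

        for fam in families:
            got = build_strand_consensus(fam, config)
            want = oracle_strand_consensus(fam, config)
            if want[0] == "rejected":
                assert isinstance(got, ConsensusRejection)
                assert got.reason == want[1]
            else:
                assert isinstance(got, StrandConsensus)
                assert got.calls == want[1], f"family of {len(fam)} mismatch"

    def test_oracle_duplex_merge_agreement(self):
        config = ConsensusConfig()
        base = REF[10:70]
        lesion = mutate(base, 25, "A" if base[25] != "A" else "C")
        top = build_strand_consensus(family_of(6), config)
        bottom = build_strand_consensus(
            [make_pair(10, lesion, qname=f"b{i}", reverse_r1=True) for i in range(6)],
            config,
        )
        got = merge_duplex(top, bottom)
        assert got.calls == oracle_duplex(top.calls, bottom.calls)
        assert 35 not in got.calls  # pos 10+25: strands discordant -> undetermined


class TestStrandConsensus:
    def test_four_copies_rejected(self):
        got = build_strand_consensus(family_of(4), ConsensusConfig())
        assert isinstance(got, ConsensusRejection)
        assert got.reason == "below_min_copies"

    def test_five_identical_copies(self):
        got = build_strand_consensus(family_of(5), ConsensusConfig())
        assert isinstance(got, StrandConsensus)
        assert got.calls == {10 + i: REF[10 + i] for i in range(60)}
        assert all(d == 5 for d in got.depth.values())

    def test_agreement_5_of_6(self):
        base = REF[10:70]
        fam = family_of(5) + [
            make_pair(10, mutate(base, 20, "A" if base[20] != "A" else "C"), qname="e")
        ]
        got = build_strand_consensus(fam, ConsensusConfig())
        assert got.calls[30] == base[20]
        assert got.agreement_at(30) == pytest.approx(5 / 6)
        assert got.agreement_at(31) == 1.0

    def test_mixed_keys_rejected(self):
        fam = family_of(3) + family_of(3, start=11)
        with pytest.raises(ValueError, match="template key"):
            build_strand_consensus(fam, ConsensusConfig())

    def test_empty_family(self):
        with pytest.raises(ValueError, match="nonempty"):
            build_strand_consensus([], ConsensusConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ConsensusConfig(min_agreement=0.4).validate()
        with pytest.raises(ValueError):
            ConsensusConfig(min_copies=0).validate()


class TestMerge:
    def test_fully_concordant(self):
        config = ConsensusConfig()
        top = build_strand_consensus(family_of(5), config)
        bottom = build_strand_consensus(family_of(5, orientation="bottom"), config)
        dup = merge_duplex(top, bottom)
        assert dup.duplex_length == 60
        assert dup.calls == top.calls

    def test_half_called_undetermined(self):
        config = ConsensusConfig()
        top = build_strand_consensus(family_of(6), config)
        # bottom has an internal 2/6 disagreement at offset 20 -> uncalled there
        base = REF[10:70]
        alt = mutate(base, 20, "A" if base[20] != "A" else "C")
        bottom = build_strand_consensus(
            family_of(4, orientation="bottom")
            + [make_pair(10, alt, qname=f"z{i}", reverse_r1=True) for i in range(2)],
            config,
        )
        dup = merge_duplex(top, bottom)
        assert 30 not in dup.calls
        assert dup.duplex_length == 59

    def test_key_mismatch_errors(self):
        config = ConsensusConfig()
        a = build_strand_consensus(family_of(5), config)
        b = build_strand_consensus(family_of(5, start=11), config)
        with pytest.raises(ValueError, match="keys"):
            merge_duplex(a, b)


class TestGrouping:
    def test_opposite_orientations_one_template(self):
        pairs = [make_pair(10, REF[10:70], qname="a"),
                 make_pair(10, REF[10:70], qname="b", reverse_r1=True)]
        grouped = group_templates(pairs)
        assert len(grouped) == 1
        (_, fams), = grouped.items()
        assert set(fams) == {"top", "bottom"}
        assert len(fams["top"]) == len(fams["bottom"]) == 1

    def test_one_base_offset_distinct_templates(self):
        pairs = [make_pair(10, REF[10:70]), make_pair(11, REF[11:71])]
        assert len(group_templates(pairs)) == 2

    def test_simulator_unique_templates_near_truth(self, clean_library):
        params, _, _, library = clean_library
        grouped = group_templates(library.pairs)
        n_frag = len(library.truth.fragments)
        # exact-coordinate identity may merge rare coordinate collisions
        assert n_frag * 0.98 <= len(grouped) <= n_frag


class TestDuplexFraction:
    def test_ideal_case_near_one(self, clean_library):
        # with no dropout, every strand family that clears min_copies forms
        # a duplex; at min_copies=1 the fraction is exactly 1
        _, _, _, library = clean_library
        grouped = group_templates(library.pairs)
        results = build_duplexes(grouped, ConsensusConfig(min_copies=1))
        assert duplex_fraction(results) == 1.0
        # at the default min_copies=5 the only loss is Poisson family size:
        # P(1 + Poisson(mean-1) >= 5)^2
        from scipy.stats import poisson

        p5 = poisson.sf(3, 7.0)
        results5 = build_duplexes(grouped, ConsensusConfig())
        assert duplex_fraction(results5) == pytest.approx(p5**2, abs=0.05)

    def test_no_family_reaching_five_copies(self):
        pairs = [make_pair(10, REF[10:70], qname=f"q{i}") for i in range(3)]
        results = build_duplexes(group_templates(pairs), ConsensusConfig())
        assert duplex_fraction(results) == 0.0

    def test_zero_templates_flagged_not_error(self):
        assert math.isnan(duplex_fraction([]))


class TestProperties:
    def test_min_copies_monotonicity(self, clean_library):
        _, _, _, library = clean_library
        grouped = group_templates(library.pairs)
        counts = []
        for mc in (1, 3, 5, 8, 12):
            results = build_duplexes(grouped, ConsensusConfig(min_copies=mc))
            counts.append(sum(1 for r in results if r.duplex is not None))
        assert counts == sorted(counts, reverse=True)

    def test_duplex_never_contradicts_strands(self, clean_library):
        _, _, _, library = clean_library
        results = build_duplexes(group_templates(library.pairs), ConsensusConfig())
        for res in results:
            if res.duplex is None:
                continue
            for pos, tok in res.duplex.calls.items():
                assert res.top.calls[pos] == tok
                assert res.bottom.calls[pos] == tok

    def test_lesions_reach_strand_but_never_duplex(self):
        """Single-strand events appear in strand consensuses at a positive
        rate but are absent from duplex output."""
        from duplexffpe import SimulationParams, simulate_library, simulate_reference

        params = SimulationParams(
            reference_length=50_000, n_templates=400, seed=23,
            lesion_rate=3000, somatic_rate_snv=0, snp_density_per_mb=0,
            end_repair_mode="nuclease", strand_dropout_prob=0.0,
            pcr_copies_mean=8, pcr_error_rate=0, seq_error_rate=0,
        )
        ref, snps = simulate_reference(params)
        lib = simulate_library(ref, snps, params)
        results = build_duplexes(group_templates(lib.pairs), ConsensusConfig())
        strand_mismatches = 0
        for res in results:
            for sc in res.strand_consensuses:
                for pos, tok in sc.calls.items():
                    if tok != ref[pos]:
                        strand_mismatches += 1
            if res.duplex is not None:
                for pos, tok in res.duplex.calls.items():
                    assert tok == ref[pos]
        assert strand_mismatches > 50
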
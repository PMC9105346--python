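import math

import numpy as np
import pandas as pd
import pytest

from duplexffpe import SimulationParams, simulate_library, simulate_reference
from duplexffpe.consensus import pair_evidence


def small_params(**kw) -> SimulationParams:
    base = dict(reference_length=30_000, n_templates=200, seed=5)
    base.update(kw)
    return SimulationParams(**base)


class TestParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            small_params(lesion_rate=-1).validate()

    def test_overhang_vs_fragment_invariant(self):
        with pytest.raises(ValueError, match="overhang"):
            small_params(fragment_length_median=10, overhang_mean=6).validate()

    @pytest.mark.parametrize("field,value", [
        ("n_templates", 0),
        ("pcr_copies_mean", 0.5),
        ("end_repair_mode", "klenow"),
        ("strand_dropout_prob", 1.5),
    ])
    def test_invalid_fields(self, field, value):
        with pytest.raises(ValueError):
            small_params(**{field: value}).validate()

    def test_from_dict_rejects_unknown(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationParams.from_dict({"nope": 1})


class TestReference:
    def test_snp_count_and_af_range(self):
        p = SimulationParams(reference_length=1_000_000, snp_density_per_mb=1000, seed=1)
        ref, snps = simulate_reference(p)
        assert len(ref) == 1_000_000
        assert 850 <= len(snps) <= 1150  # Poisson around 1000
        assert ((snps.af > 0) & (snps.af <= 1)).all()
        assert (snps.af > 0.01).any() and (snps.af <= 0.01).any()
        for row in snps.head(50).itertuples(index=False):
            assert ref[row.pos] == row.ref and row.alt != row.ref

    def test_determinism(self):
        p = small_params(seed=7)
        ref1, snps1 = simulate_reference(p)
        ref2, snps2 = simulate_reference(p)
        assert ref1 == ref2
        pd.testing.assert_frame_equal(snps1, snps2)

    def test_zero_density(self):
        ref, snps = simulate_reference(small_params(snp_density_per_mb=0))
        assert len(snps) == 0

    def test_too_short_reference(self):
        with pytest.raises(ValueError, match="10 kb"):
            simulate_reference(small_params(reference_length=500))

    def test_density_overflow_names_constraint(self):
        with pytest.raises(ValueError, match="SNP density"):
            simulate_reference(
                SimulationParams(reference_length=10_000, snp_density_per_mb=500_000, seed=0)
            )


def _haplotype_base(reference, truth, mol_row, pos):
    """Expected molecule base at a reference position (no noise case)."""
    g = truth.germline
    carried = g[(g.pos == pos) & g[f"hap{int(mol_row.hap)}"]]
    if len(carried):
        return carried.alt.iloc[0]
    return reference[pos]


class TestLibrary:
    def test_noise_free_reads_match_haplotype(self, clean_library):
        params, reference, snps, library = clean_library
        frags = library.truth.fragments.set_index("molecule")
        checked = 0
        for pair in library.pairs[:300]:
            mol = int(pair.qname.split("_")[0][1:])
            row = frags.loc[mol]
            ev = pair_evidence(pair, 0)
            som = library.truth.somatic
            touched = set()
            for s in som[som.molecule == mol].itertuples(index=False):
                touched.update(range(int(s.raw_pos) - 4, int(s.raw_pos) + 8))
            for pos, tok in ev.items():
                if pos in touched or "+" in tok or tok == "-":
                    continue
                assert tok == _haplotype_base(reference, library.truth, row, pos)
                checked += 1
        assert checked > 1000

    def test_determinism_byte_identical(self, tmp_path):
        from duplexffpe import write_library

        p = small_params(lesion_rate=500, somatic_rate_indel=30, decoy_fraction=0.05)
        outs = []
        for sub in ("a", "b"):
            ref, snps = simulate_reference(p)
            lib = simulate_library(ref, snps, p)
            d = tmp_path / sub
            write_library(lib, ref, snps, d)
            outs.append(d)
        for name in ("reads.sam", "reference.fa", "population_af.vcf",
                     "truth_somatic.tsv", "truth_lesions.tsv", "truth_fragments.tsv"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_no_reads_from_dropped_strands(self):
        p = small_params(strand_dropout_prob=0.5, n_templates=300)
        ref, snps = simulate_reference(p)
        lib = simulate_library(ref, snps, p)
        frags = lib.truth.fragments.set_index("molecule")
        seen = {("top", int(q.split("_")[0][1:])) if "_top_" in q else ("bottom", int(q.split("_")[0][1:]))
                for q in (pair.qname for pair in lib.pairs)}
        for strand, mol in seen:
            assert not frags.loc[mol, f"drop_{strand}"]

    def test_dropout_closed_form(self):
        p = small_params(
            reference_length=200_000, n_templates=5000,
            strand_dropout_prob=0.55, pcr_copies_mean=1,
        )
        ref, snps = simulate_reference(p)
        lib = simulate_library(ref, snps, p)
        frac = lib.truth.duplex_formable_fraction()
        expect = 0.45**2
        sd = math.sqrt(expect * (1 - expect) / p.n_templates)
        assert abs(frac - expect) < 3 * sd

    def test_dropout_monotonicity(self):
        fracs = []
        for q in (0.0, 0.3, 0.6, 0.9):
            p = small_params(n_templates=2000, strand_dropout_prob=q, pcr_copies_mean=1)
            ref, snps = simulate_reference(p)
            lib = simulate_library(ref, snps, p)
            fracs.append(lib.truth.duplex_formable_fraction())
        assert fracs == sorted(fracs, reverse=True)

    def test_mode_shares_molecule_sampling(self):
        libs = {}
        for mode in ("polymerase", "nuclease"):
            p = small_params(lesion_rate=1000, overhang_mean=8, end_repair_mode=mode,
                             pcr_error_rate=0, seq_error_rate=0)
            ref, snps = simulate_reference(p)
            libs[mode] = simulate_library(ref, snps, p)
        fp = libs["polymerase"].truth.fragments
        fn = libs["nuclease"].truth.fragments
        pd.testing.assert_frame_equal(
            fp[["molecule", "start", "end", "hap", "o_left", "o_right"]],
            fn[["molecule", "start", "end", "hap", "o_left", "o_right"]],
        )
        # nuclease templates are the polymerase ones shrunk by the overhangs
        assert (fn.t_start == fn.start + fn.o_left).all()
        assert (fn.t_end == fn.end - fn.o_right).all()
        assert (fp.t_start == fp.start).all() and (fp.t_end == fp.end).all()

    def test_copied_lesions_lie_in_overhang_spans(self):
        p = small_params(lesion_rate=3000, overhang_mean=10, end_repair_mode="polymerase")
        ref, snps = simulate_reference(p)
        lib = simulate_library(ref, snps, p)
        les = lib.truth.lesions
        copied = les[les.copied]
        assert len(copied) > 0
        frags = lib.truth.fragments.set_index("molecule")
        for row in copied.itertuples(index=False):
            f = frags.loc[int(row.molecule)]
            in_left = f.start <= row.pos < f.start + f.o_left
            in_right = f.end - f.o_right <= row.pos < f.end
            assert in_left or in_right
            assert (row.strand == "top") == in_left

    def test_nuclease_mode_never_copies(self):
        p = small_params(lesion_rate=3000, overhang_mean=10, end_repair_mode="nuclease")
        ref, snps = simulate_reference(p)
        lib = simulate_library(ref, snps, p)
        assert not lib.truth.lesions.copied.any()
        assert (lib.truth.fragments.n_copied_events == 0).all()

    def test_read_through_truncation_no_exception(self):
        p = small_params(fragment_length_median=80, read_length=150)
        ref, snps = simulate_reference(p)
        lib = simulate_library(ref, snps, p)
        assert lib.pairs
        for pair in lib.pairs[:50]:
            for mate in pair.mates():
                assert mate.query_length <= 150

    def test_decoys_recorded(self):
        p = small_params(decoy_fraction=0.2)
        ref, snps = simulate_reference(p)
        lib = simulate_library(ref, snps, p)
        assert len(lib.truth.decoys) > 0
        assert set(lib.truth.decoys.defect) <= {
            "soft_clip", "ambiguous", "improper", "excessive_mismatch"
        }
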
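"""Helpers comparing pipeline output against a simulation truth ledger.

These are used by the test-suite oracles and by anyone validating a run of
the simulator end to end; they replay the ledger, never the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .consensus import DuplexConsensus, TemplateKey, TemplateResult
from .simdata import SimTruth
from .varcall import VariantCall

Site = tuple[int, str, str]


def template_key_molecules(truth: SimTruth, ref_name: str) -> dict[TemplateKey, list[int]]:
    """Map each template key to the molecule ids that produced it."""
    out: dict[TemplateKey, list[int]] = {}
    for row in truth.fragments.itertuples(index=False):
        key = (ref_name, int(row.t_start), int(row.t_end))
        out.setdefault(key, []).append(int(row.molecule))
    return out


def molecule_variants(truth: SimTruth) -> dict[int, list[tuple]]:
    """Planted somatic events per molecule as (site, vclass, raw_pos, raw_len)."""
    out: dict[int, list[tuple]] = {}
    for row in truth.somatic.itertuples(index=False):
        raw_len = len(row.ref) - 1 if row.vclass == "deletion" else 1
        out.setdefault(int(row.molecule), []).append(
            ((int(row.pos), row.ref, row.alt), row.vclass, int(row.raw_pos), raw_len)
        )
    return out


def germline_variants_for_hap(truth: SimTruth, hap: int) -> list[tuple[Site, float]]:
    col = f"hap{hap}"
    g = truth.germline
    carried = g[g[col]]
    return [
        ((int(row.pos), row.ref, row.alt), float(row.af))
        for row in carried.itertuples(index=False)
    ]


def _covered(duplex: DuplexConsensus, vclass: str, raw_pos: int, raw_len: int) -> bool:
    """Is the planted event fully observable in this duplex's called span?"""
    calls = duplex.calls
    if vclass == "SNV":
        return raw_pos in calls
    if vclass == "insertion":
        tok = calls.get(raw_pos)
        return tok is not None and "+" in tok
    # deletion: every deleted position plus both flanks must be called
    span = range(raw_pos, raw_pos + raw_len)
    if not all(calls.get(p) == "-" for p in span):
        return False
    left = calls.get(raw_pos - 1)
    right = calls.get(raw_pos + raw_len)
    return left is not None and left != "-" and right is not None and right != "-"


@dataclass
class ConservationOutcome:
    false_positives: list[VariantCall]
    missed: list[tuple[TemplateKey, Site]]
    matched: int
    ambiguous_keys: int  # template keys shared by >1 molecule (collisions)

    @property
    def exact(self) -> bool:
        return not self.false_positives and not self.missed


def check_conservation(
    results: Sequence[TemplateResult],
    retained: Sequence[VariantCall],
    truth: SimTruth,
    ref_name: str,
    af_threshold: float = 0.01,
) -> ConservationOutcome:
    """Compare retained calls against the planted truth, per template.

    Expected content of each duplex: the somatic events of its source
    molecule plus the rare (AF <= threshold) germline variants carried by
    that molecule's haplotype, restricted to what the duplex-called span can
    observe. Template keys hit by more than one molecule are counted as
    ambiguous and skipped (coordinate-collision error mode, quantified
    separately).
    """
    key_mols = template_key_molecules(truth, ref_name)
    mol_vars = molecule_variants(truth)
    frag = truth.fragments.set_index("molecule")
    germ_by_hap = {h: germline_variants_for_hap(truth, h) for h in (0, 1)}

    calls_by_key: dict[TemplateKey, set[Site]] = {}
    for c in retained:
        calls_by_key.setdefault(c.template_key, set()).add(c.site)

    false_positives: list[VariantCall] = []
    missed: list[tuple[TemplateKey, Site]] = []
    matched = 0
    ambiguous = 0
    expected_by_key: dict[TemplateKey, set[Site]] = {}

    for res in results:
        if res.duplex is None:
            continue
        mols = key_mols.get(res.key, [])
        if len(mols) != 1:
            ambiguous += 1
            continue
        mol = mols[0]
        expected: set[Site] = set()
        for site, vclass, raw_pos, raw_len in mol_vars.get(mol, []):
            if _covered(res.duplex, vclass, raw_pos, raw_len):
                expected.add(site)
        hap = int(frag.loc[mol, "hap"])
        for site, af in germ_by_hap[hap]:
            if af <= af_threshold and site[0] in res.duplex.calls:
                expected.add(site)
        expected_by_key[res.key] = expected

    for key, expected in expected_by_key.items():
        observed = calls_by_key.get(key, set())
        for site in expected - observed:
            missed.append((key, site))
        matched += len(expected & observed)
    ambiguous_keys = {k for k, mols in key_mols.items() if len(mols) > 1}
    for c in retained:
        if c.template_key in ambiguous_keys:
            continue
        if c.site not in expected_by_key.get(c.template_key, set()):
            false_positives.append(c)

    return ConservationOutcome(false_positives, missed, matched, ambiguous)


def split_retained_by_truth(
    retained: Sequence[VariantCall],
    truth: SimTruth,
    ref_name: str,
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall]]:
    """Split retained calls into (somatic-matched, germline-matched, other).

    Matching is by normalized site against the truth ledger; germline
    matching ignores AF (it serves to excise rare-germline contamination
    from somatic-rate estimates).
    """
    somatic_sites = {
        (int(r.pos), r.ref, r.alt) for r in truth.somatic.itertuples(index=False)
    }
    germline_sites = {
        (int(r.pos), r.ref, r.alt) for r in truth.germline.itertuples(index=False)
    }
    somatic, germline, other = [], [], []
    for c in retained:
        if c.site in somatic_sites:
            somatic.append(c)
        elif c.site in germline_sites:
            germline.append(c)
        else:
            other.append(c)
    return somatic, germline, other
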
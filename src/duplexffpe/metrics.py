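"""Summary statistics: mutation load with exact binomial CIs, mutation
spectrum, template/duplex statistics and the fragment-end positional
profile of mutations."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import DuplexConsensus, StrandConsensus, TemplateResult
from .varcall import VariantCall

MB = 1_000_000

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class ProfileConfig:
    window: int = 50

    def validate(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


def mutation_rate_ci(
    k: int, n: int, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Mutation rate per Mb with an exact (Clopper-Pearson) binomial CI.

    ``k`` mutations over ``n`` duplex bases. Returns ``(rate, lo, hi)`` in
    events per Mb. ``n`` of zero returns NaNs (a flagged undefined value).
    """
    if n < 0 or k < 0 or k > max(n, 0):
        raise ValueError("need 0 <= k <= n")
    if n == 0:
        return (float("nan"),) * 3
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (k / n * MB, lo * MB, hi * MB)


def _call_distance(call: VariantCall, window: int) -> Optional[int]:
    """1-based distance of a call from the nearer end of its template."""
    _, t_start, t_end = call.template_key
    d = 1 + min(call.pos - t_start, t_end - 1 - call.pos)
    return d if 1 <= d <= window else None


def end_distance_profile(
    calls: Sequence[VariantCall],
    duplexes: Iterable[DuplexConsensus],
    config: ProfileConfig | None = None,
) -> pd.DataFrame:
    """Per-distance mutation counts and coverage-normalized rates.

    Distance is 1-based from the nearer template end (min of the two ends).
    Counts are normalized by the number of duplex-called bases observed at
    each distance, so short templates do not bias the tail. Distances with
    zero coverage get a NaN rate.
    """
    config = config or ProfileConfig()
    config.validate()
    w = config.window
    events = np.zeros(w, dtype=int)
    coverage = np.zeros(w, dtype=int)
    for dup in duplexes:
        _, t_start, t_end = dup.key
        for pos in dup.calls:
            d = 1 + min(pos - t_start, t_end - 1 - pos)
            if 1 <= d <= w:
                coverage[d - 1] += 1
    for call in calls:
        d = _call_distance(call, w)
        if d is not None:
            events[d - 1] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(coverage > 0, events / np.maximum(coverage, 1), np.nan)
    return pd.DataFrame(
        {
            "distance": np.arange(1, w + 1),
            "events": events,
            "covered_bases": coverage,
            "rate": rate,
        }
    )


def enrichment_ratio(
    profile: pd.DataFrame,
    head: tuple[int, int] = (1, 10),
    tail: tuple[int, int] = (41, 50),
) -> float:
    """Mean per-position rate over ``head`` divided by mean over ``tail``.

    Only covered positions enter each mean; NaN when either range has no
    coverage, infinity when the tail rate is zero but the head is not.
    """
    def _mean(rng: tuple[int, int]) -> float:
        sel = profile[
            (profile.distance >= rng[0])
            & (profile.distance <= rng[1])
            & (profile.covered_bases > 0)
        ]
        if len(sel) == 0:
            return float("nan")
        return float(sel.rate.mean())

    h, t = _mean(head), _mean(tail)
    if math.isnan(h) or math.isnan(t):
        return float("nan")
    if t == 0.0:
        return float("inf") if h > 0 else float("nan")
    return h / t


def profile_uniformity_pvalue(profile: pd.DataFrame, bin_size: int = 10) -> float:
    """Chi-square p-value against coverage-proportional (uniform) rates.

    Distances are aggregated into bins of ``bin_size`` to keep expected
    counts reasonable; expected events per bin are proportional to the
    duplex coverage observed in that bin.
    """
    cov = profile.covered_bases.to_numpy(dtype=float)
    ev = profile.events.to_numpy(dtype=float)
    w = len(cov)
    nb = max(1, w // bin_size)
    cov_b = np.add.reduceat(cov, np.arange(0, nb * bin_size, bin_size))
    ev_b = np.add.reduceat(ev, np.arange(0, nb * bin_size, bin_size))
    keep = cov_b > 0
    cov_b, ev_b = cov_b[keep], ev_b[keep]
    total = ev_b.sum()
    if total == 0 or len(cov_b) < 2:
        return 1.0
    expected = total * cov_b / cov_b.sum()
    stat = float(((ev_b - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, df=len(cov_b) - 1))


def spectrum(calls: Sequence[VariantCall]) -> dict:
    """Class fractions (SNV/insertion/deletion) and pyrimidine-context
    substitution-type fractions. Empty input yields an empty report."""
    if not calls:
        return {"n": 0, "class_fractions": {}, "substitution_fractions": {}}
    classes = {"SNV": 0, "insertion": 0, "deletion": 0}
    subs = {t: 0 for t in SUBSTITUTION_TYPES}
    for c in calls:
        classes[c.vclass] += 1
        if c.vclass == "SNV":
            ref, alt = c.ref, c.alt
            if ref in "AG":
                ref = ref.translate(_COMPLEMENT)
                alt = alt.translate(_COMPLEMENT)
            subs[f"{ref}>{alt}"] += 1
    n = len(calls)
    n_snv = classes["SNV"]
    return {
        "n": n,
        "class_fractions": {k: v / n for k, v in classes.items()},
        "substitution_fractions": {
            k: (v / n_snv if n_snv else 0.0) for k, v in subs.items()
        },
    }


# ---------------------------------------------------------------------------
# single-strand (corrected) events and the sample report
# ---------------------------------------------------------------------------


def single_strand_events(
    results: Sequence[TemplateResult], refseq: str
) -> tuple[int, int]:
    """(corrected single-strand events, total called strand-consensus bases).

    An event is a strand-consensus position differing from the reference
    whose difference is NOT reproduced in the duplex consensus — exactly the
    class of errors duplex sequencing corrects.
    """
    n_events = 0
    strand_bases = 0
    for res in results:
        dup_calls = res.duplex.calls if res.duplex is not None else {}
        for sc in res.strand_consensuses:
            strand_bases += sc.called_length
            for pos, tok in sc.calls.items():
                base = tok.partition("+")[0]
                is_diff = (
                    base == "-" or base != refseq[pos] or "+" in tok
                )
                if is_diff and dup_calls.get(pos) != tok:
                    n_events += 1
    return n_events, strand_bases


@dataclass
class SampleReport:
    """All per-sample summary numbers, with numerators and denominators
    stored so every rate is recomputable."""

    total_read_pairs: int = 0
    pass_fraction: float = float("nan")
    unique_templates: int = 0
    duplex_templates: int = 0
    duplex_fraction: float = float("nan")
    median_template_length: float = float("nan")
    duplex_bases: int = 0
    strand_consensus_bases: int = 0
    single_strand_events: int = 0
    single_strand_rate_per_mb: float = float("nan")
    retained_mutations: int = 0
    mutation_rate_per_mb: float = float("nan")
    mutation_rate_ci95: tuple[float, float] = (float("nan"), float("nan"))
    removed_common_snps: int = 0
    common_snp_rate_per_mb: float = float("nan")
    snv_fraction: float = float("nan")
    insertion_fraction: float = float("nan")
    deletion_fraction: float = float("nan")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["mutation_rate_ci95"] = list(self.mutation_rate_ci95)
        return d

    def to_rows(self) -> list[tuple[str, object]]:
        rows = []
        for key, value in self.to_dict().items():
            if isinstance(value, list):
                rows.append((key + "_lo", value[0]))
                rows.append((key + "_hi", value[1]))
            else:
                rows.append((key, value))
        return rows


def build_report(
    *,
    total_read_pairs: int,
    pass_fraction: float,
    results: Sequence[TemplateResult],
    retained: Sequence[VariantCall],
    removed: Sequence[VariantCall],
    refseq: str,
) -> SampleReport:
    from .consensus import duplex_fraction as _df

    report = SampleReport()
    report.total_read_pairs = total_read_pairs
    report.pass_fraction = pass_fraction
    report.unique_templates = len(results)
    report.duplex_templates = sum(1 for r in results if r.duplex is not None)
    report.duplex_fraction = _df(list(results))
    if results:
        lengths = [r.key[2] - r.key[1] for r in results]
        report.median_template_length = float(np.median(lengths))
    report.duplex_bases = sum(
        r.duplex.duplex_length for r in results if r.duplex is not None
    )
    ev, bases = single_strand_events(results, refseq)
    report.single_strand_events = ev
    report.strand_consensus_bases = bases
    if bases:
        report.single_strand_rate_per_mb = ev / bases * MB
    report.retained_mutations = len(retained)
    report.removed_common_snps = len(removed)
    if report.duplex_bases:
        rate, lo, hi = mutation_rate_ci(len(retained), report.duplex_bases)
        report.mutation_rate_per_mb = rate
        report.mutation_rate_ci95 = (lo, hi)
        report.common_snp_rate_per_mb = len(removed) / report.duplex_bases * MB
    spec = spectrum(retained)
    if spec["n"]:
        report.snv_fraction = spec["class_fractions"]["SNV"]
        report.insertion_fraction = spec["class_fractions"]["insertion"]
        report.deletion_fraction = spec["class_fractions"]["deletion"]
    return report
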
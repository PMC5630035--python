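"""Evaluation statistics for regional constraint tracks.

Three tests quantify how strongly patient-ascertained pathogenic variants
concentrate in missense-depleted regions:

* a one-sided exact binomial test for preferential enrichment of case
  variants within the gene's most intolerant MTR quartile;
* a two-sided Mann-Whitney U test comparing case and control MTR
  distributions (no intolerance threshold required);
* a two-sided Fisher exact test on 2x2 presence/absence tables (e.g. how
  often qualified vs unqualified pathogenic variants appear in population
  reference cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from mtrkit.mtr import MtrTrack


@dataclass
class EnrichmentResult:
    n_total: int
    n_in_quartile: int
    p0: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError(f"p0 must lie in (0,1), got {self.p0}")
        if self.n_in_quartile > self.n_total:
            raise ValueError("n_in_quartile exceeds n_total")


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    median_case: float
    median_control: float
    n_case: int
    n_control: int
    exact: bool


def possible_snv_quartile_fraction(track: MtrTrack, quantile: float = 0.25) -> float:
    """Fraction of codons (hence of possible missense SNVs under uniform
    per-codon possible counts) whose MTR falls at or below the gene's
    ``quantile`` threshold.  Serves as a better-calibrated null proportion for
    the quartile test when threshold ties make the nominal quartile inexact."""
    thr = (track.percentile_thresholds or {}).get(quantile)
    if thr is None:
        raise ValueError(f"track has no {quantile:.0%} threshold")
    values = track.mtr_values()
    return float(np.mean(values <= thr))


def quartile_enrichment_test(
    case_codons: Sequence[int],
    track: MtrTrack,
    p0: float | None = 0.25,
    quantile: float = 0.25,
) -> EnrichmentResult:
    """One-sided binomial test: do case variants preferentially occur in the
    most intolerant quartile of the gene's MTR distribution?

    ``case_codons`` lists the codon of each case variant (one entry per
    distinct variant; codons may repeat).  A variant is "in the quartile"
    when its codon's MTR is <= the gene's 25th-percentile threshold (ties
    included).  Case variants at null-MTR codons are excluded.  ``p0=None``
    uses the empirical fraction of codons at or below the threshold instead
    of the nominal 0.25.
    """
    if len(case_codons) == 0:
        raise ValueError("empty case list")
    thr = (track.percentile_thresholds or {}).get(quantile)
    if thr is None:
        raise ValueError(f"track has no {quantile:.0%} threshold")
    if p0 is None:
        p0 = possible_snv_quartile_fraction(track, quantile)
    k = 0
    n = 0
    for codon in case_codons:
        mtr = track.mtr_at(codon)
        if mtr is None:
            continue
        n += 1
        if mtr <= thr:
            k += 1
    if n == 0:
        raise ValueError("no case variant falls on a codon with an MTR estimate")
    p = float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
    return EnrichmentResult(n_total=n, n_in_quartile=k, p0=float(p0), p_value=p)


def mtr_rank_test(
    case_mtr: Sequence[float], control_mtr: Sequence[float], exact_max_n: int = 25
) -> RankTestResult:
    """Two-sided Mann-Whitney U comparison of case vs control MTR values.

    Exact null distribution when the combined sample size is <= ``exact_max_n``
    and there are no ties; otherwise the normal approximation with tie
    correction.  U is reported for the case group.
    """
    case = np.asarray([v for v in case_mtr if v is not None], dtype=float)
    control = np.asarray([v for v in control_mtr if v is not None], dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([case, control])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (case.size + control.size <= exact_max_n) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(case, control, alternative="two-sided", method=method)
    return RankTestResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_case=float(np.median(case)),
        median_control=float(np.median(control)),
        n_case=int(case.size),
        n_control=int(control.size),
        exact=use_exact,
    )


def presence_fisher_test(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric tables with probability <= that of the observed table.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("table has an empty margin")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)
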
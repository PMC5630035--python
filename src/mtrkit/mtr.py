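"""The Missense Tolerance Ratio (MTR) sliding-window track.

For each codon i of a transcript with L codons, a window spanning codons
max(1, i-15) .. min(L, i+15) — 31 codons in the interior, truncated at the
termini — collects two tallies:

* observed: distinct quality-passing missense and synonymous variant sites
  reported in a standing-variation cohort within the window;
* possible: all missense and synonymous SNVs obtainable by single-base
  mutagenesis of the window, each treated as equally likely.

The MTR is the observed missense proportion divided by the possible missense
proportion::

    MTR = [mis_obs / (mis_obs + syn_obs)] / [mis_pos / (mis_pos + syn_pos)]

MTR < 1 indicates preferential depletion of missense variation (purifying
selection); the ratio is stable at low counts where log(dN/dS) blows up.
Each window also gets a two-sided exact binomial test for deviation from
MTR = 1, adjusted across all windows in a run by the Benjamini-Hochberg
procedure, and gene-level 5th/25th/50th percentile thresholds of the
per-codon MTR values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mtrkit.transcripts import TranscriptModel, enumerate_possible_snvs
from mtrkit.variants import CoverageTrack, VariantSite, codon_coverage

DEFAULT_WINDOW_RADIUS = 15
DEFAULT_PERCENTILES = (0.05, 0.25, 0.50)


@dataclass
class WindowEstimate:
    """Per-codon window tallies and the derived MTR estimate."""

    codon_index: int
    window_lo: int
    window_hi: int
    obs_missense: int
    obs_synonymous: int
    pos_missense: int
    pos_synonymous: int
    mtr: float | None
    p_value: float | None = None
    fdr_q: float | None = None
    coverage: float | None = None
    coverage_flagged: bool = False


@dataclass
class MtrTrack:
    transcript_id: str
    estimates: list[WindowEstimate]
    percentile_thresholds: dict[float, float] | None = None

    @property
    def length(self) -> int:
        return len(self.estimates)

    def mtr_at(self, codon_index: int) -> float | None:
        return self.estimates[codon_index - 1].mtr

    def mtr_values(self) -> np.ndarray:
        """Non-null per-codon MTR values, in codon order."""
        return np.array([e.mtr for e in self.estimates if e.mtr is not None])


def mtr_ratio(
    obs_missense: int, obs_synonymous: int, pos_missense: int, pos_synonymous: int
) -> float | None:
    """Observed missense proportion over possible missense proportion.

    Null when the window has no observed variants (0/0 is undefined)."""
    n_obs = obs_missense + obs_synonymous
    if n_obs == 0:
        return None
    p0 = pos_missense / (pos_missense + pos_synonymous)
    return (obs_missense / n_obs) / p0


def _per_codon_possible_counts(model: TranscriptModel) -> tuple[np.ndarray, np.ndarray]:
    L = model.protein_length
    mis = np.zeros(L, dtype=np.int64)
    syn = np.zeros(L, dtype=np.int64)
    for snv in enumerate_possible_snvs(model):
        if snv.consequence == "missense":
            mis[snv.codon_index - 1] += 1
        elif snv.consequence == "synonymous":
            syn[snv.codon_index - 1] += 1
    return mis, syn


def _per_codon_observed_counts(
    model: TranscriptModel, observed: Iterable[VariantSite]
) -> tuple[np.ndarray, np.ndarray]:
    L = model.protein_length
    mis = np.zeros(L, dtype=np.int64)
    syn = np.zeros(L, dtype=np.int64)
    seen: set[tuple[int, str]] = set()
    for site in observed:
        if not site.qc_pass or site.consequence not in ("missense", "synonymous"):
            continue
        key = (site.genomic_pos, site.alt)
        if key in seen:  # distinct sites, not allele counts
            continue
        seen.add(key)
        if not 1 <= site.codon_index <= L:
            raise ValueError(
                f"observed site at codon {site.codon_index} outside transcript "
                f"{model.transcript_id} (L={L})"
            )
        if site.consequence == "missense":
            mis[site.codon_index - 1] += 1
        else:
            syn[site.codon_index - 1] += 1
    return mis, syn


def _window_sums(per_codon: np.ndarray, radius: int) -> np.ndarray:
    """Sliding-window sums with windows truncated at the transcript ends."""
    L = per_codon.shape[0]
    csum = np.concatenate([[0], np.cumsum(per_codon)])
    idx = np.arange(L)
    lo = np.maximum(idx - radius, 0)
    hi = np.minimum(idx + radius, L - 1)
    return csum[hi + 1] - csum[lo]


def compute_mtr_track(
    model: TranscriptModel,
    observed: Sequence[VariantSite],
    window_radius: int = DEFAULT_WINDOW_RADIUS,
    coverage: CoverageTrack | None = None,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    compute_tests: bool = True,
) -> MtrTrack:
    """Compute the full per-codon MTR track for one transcript.

    Observed sites are deduplicated by (genomic position, alt allele) and
    restricted to quality-passing missense/synonymous SNVs.  Windows with no
    observed variants have a null MTR and are excluded from tests and
    percentile thresholds.  FDR adjustment across transcripts is applied
    separately (see :func:`adjust_track_fdr`); when ``compute_tests`` is set
    the per-window binomial p-values are filled in here.
    """
    L = model.protein_length
    if L < 1:
        raise ValueError(f"{model.transcript_id}: empty transcript")
    pos_mis_c, pos_syn_c = _per_codon_possible_counts(model)
    obs_mis_c, obs_syn_c = _per_codon_observed_counts(model, observed)

    pos_mis = _window_sums(pos_mis_c, window_radius)
    pos_syn = _window_sums(pos_syn_c, window_radius)
    obs_mis = _window_sums(obs_mis_c, window_radius)
    obs_syn = _window_sums(obs_syn_c, window_radius)

    estimates: list[WindowEstimate] = []
    for i in range(L):
        n_obs = int(obs_mis[i] + obs_syn[i])
        n_pos = int(pos_mis[i] + pos_syn[i])
        if n_pos == 0:
            raise ValueError(f"{model.transcript_id}: window at codon {i + 1} has no possible SNVs")
        mtr = mtr_ratio(int(obs_mis[i]), int(obs_syn[i]), int(pos_mis[i]), int(pos_syn[i]))
        est = WindowEstimate(
            codon_index=i + 1,
            window_lo=max(1, i + 1 - window_radius),
            window_hi=min(L, i + 1 + window_radius),
            obs_missense=int(obs_mis[i]),
            obs_synonymous=int(obs_syn[i]),
            pos_missense=int(pos_mis[i]),
            pos_synonymous=int(pos_syn[i]),
            mtr=mtr,
        )
        if compute_tests:
            est.p_value = window_deviation_test(est)
        if coverage is not None:
            est.coverage, est.coverage_flagged = codon_coverage(coverage, model, i + 1)
        estimates.append(est)

    track = MtrTrack(transcript_id=model.transcript_id, estimates=estimates)
    track.percentile_thresholds = gene_percentile_thresholds(track, percentiles)
    return track


def window_deviation_test(w: WindowEstimate) -> float | None:
    """Two-sided exact binomial test for deviation from MTR = 1.

    k = observed missense, n = observed missense + synonymous, null success
    probability p0 = possible missense proportion.  Null when the window has
    no observed variants.  Uses the minimum-likelihood-sum convention for
    two-sidedness.
    """
    n = w.obs_missense + w.obs_synonymous
    if n == 0:
        return None
    p0 = w.pos_missense / (w.pos_missense + w.pos_synonymous)
    return float(stats.binomtest(w.obs_missense, n, p0, alternative="two-sided").pvalue)


def adjust_fdr_bh(p_values: Sequence[float | None]) -> list[float | None]:
    """Benjamini-Hochberg step-up q-values; None entries pass through."""
    idx = [i for i, p in enumerate(p_values) if p is not None]
    out: list[float | None] = [None] * len(p_values)
    if not idx:
        return out
    ps = np.array([p_values[i] for i in idx], dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0,1]")
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    for i, qi in zip(idx, q):
        out[i] = float(qi)
    return out


def adjust_track_fdr(tracks: Sequence[MtrTrack]) -> None:
    """Apply BH adjustment study-wide across all windows of all tracks."""
    ests = [e for t in tracks for e in t.estimates]
    qs = adjust_fdr_bh([e.p_value for e in ests])
    for e, q in zip(ests, qs):
        e.fdr_q = q


def gene_percentile_thresholds(
    track: MtrTrack, percentiles: Sequence[float] = DEFAULT_PERCENTILES
) -> dict[float, float]:
    """Empirical percentiles of the gene's non-null per-codon MTR values.

    Linear interpolation over codon-level values; null windows excluded.
    """
    values = track.mtr_values()
    if values.size == 0:
        raise ValueError(f"{track.transcript_id}: all windows have null MTR")
    return {
        float(p): float(np.percentile(values, 100.0 * p, method="linear"))
        for p in percentiles
    }


def compute_log_dnds(w: WindowEstimate) -> float | None:
    """log[(obs_mis/pos_mis) / (obs_syn/pos_syn)] — the classical analogue.

    Null (undefined) when either observed count is zero; the MTR itself stays
    finite in those windows, which is its point.
    """
    if w.obs_missense == 0 or w.obs_synonymous == 0:
        return None
    return math.log(
        (w.obs_missense / w.pos_missense) / (w.obs_synonymous / w.pos_synonymous)
    )


# ---- export ----------------------------------------------------------------


def track_table(track: MtrTrack) -> pd.DataFrame:
    rows = []
    for e in track.estimates:
        rows.append(
            {
                "transcript_id": track.transcript_id,
                "codon_index": e.codon_index,
                "protein_pos": e.codon_index,
                "obs_mis": e.obs_missense,
                "obs_syn": e.obs_synonymous,
                "pos_mis": e.pos_missense,
                "pos_syn": e.pos_synonymous,
                "mtr": e.mtr,
                "p_value": e.p_value,
                "fdr_q": e.fdr_q,
                "coverage": e.coverage,
            }
        )
    return pd.DataFrame(rows)


def track_summary(track: MtrTrack) -> dict:
    return {
        "transcript_id": track.transcript_id,
        "n_codons": track.length,
        "n_windows_with_estimate": int(track.mtr_values().size),
        "percentile_thresholds": {
            f"{int(round(100 * p))}": v for p, v in (track.percentile_thresholds or {}).items()
        },
    }


def plot_track(track: MtrTrack, ax=None, fdr_alpha: float = 0.05):
    """MTR line with FDR-significant segments, threshold lines, coverage trace."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    x = np.array([e.codon_index for e in track.estimates])
    y = np.array([e.mtr if e.mtr is not None else np.nan for e in track.estimates])
    ax.plot(x, y, color="black", lw=1.0, label="MTR")
    sig = np.array(
        [e.fdr_q is not None and e.fdr_q < fdr_alpha for e in track.estimates], dtype=bool
    )
    if sig.any():
        ysig = np.where(sig, y, np.nan)
        ax.plot(x, ysig, color="red", lw=1.6, label=f"FDR < {fdr_alpha:g}")
    ax.axhline(1.0, color="tab:blue", ls="--", lw=0.8, label="MTR = 1")
    styles = {0.50: ("black", "median"), 0.25: ("darkgreen", "25th pct"), 0.05: ("orange", "5th pct")}
    for p, thr in (track.percentile_thresholds or {}).items():
        color, label = styles.get(round(p, 2), ("gray", f"{100 * p:.0f}th pct"))
        ax.axhline(thr, color=color, ls="--", lw=0.8, label=label)
    cov = np.array(
        [e.coverage if e.coverage is not None else np.nan for e in track.estimates]
    )
    if np.isfinite(cov).any():
        ax.plot(x, cov, color="gray", ls="--", lw=0.8, label="frac ≥10×")
    ax.set_xlabel("protein position (codon)")
    ax.set_ylabel("MTR")
    ax.set_title(track.transcript_id)
    ax.legend(fontsize=7, ncol=3, loc="upper right")
    return ax
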
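"""Gene-specific probability-of-pathogenicity (GPP) modelling.

The pipeline distinguishes pathogenic from presumed-benign missense variants
using precomputed bioinformatic feature rank scores (each in [0,1]) plus,
optionally, the variant's regional MTR estimate.  The stages run in a fixed
order:

1. median imputation of missing scores within each gene;
2. near-zero-variance feature pruning (dominant-value ratio > 4 and
   distinct-value fraction < 5%);
3. iterative pairwise-correlation pruning (|Pearson r| > 0.75, dropping the
   member of the worst pair with the larger mean absolute correlation);
4. shadow-feature permutation importance: every feature is paired with a
   column-shuffled "shadow" copy, a random forest is fitted repeatedly, and
   features are kept only when their out-of-bag mean-decrease-accuracy
   Z-scores consistently beat the best shadow;
5. forward-backward stepwise logistic regression guided by the Akaike
   relative likelihood exp(dAIC/2), producing a per-gene logistic model whose
   inverse-logit predictions are the GPP scores.

The random forest is built tree-by-tree from sklearn decision trees so that
per-tree out-of-bag accuracy decreases (the classical mean-decrease-accuracy
importance) are available through public APIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

MTR_COLUMN = "MTR"


@dataclass
class FeatureMatrix:
    """Variant-by-feature rank-score matrix with optional labels and MTR.

    ``scores`` holds the feature columns (values in [0,1], NaN = missing);
    ``labels`` is 1 for case / 0 for control rows when used for training;
    ``genes`` partitions rows by gene for per-gene imputation; ``mtr`` carries
    the raw codon MTR per variant (exempt from the [0,1] range).
    """

    scores: pd.DataFrame
    labels: pd.Series | None = None
    genes: pd.Series | None = None
    mtr: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.labels is not None and not set(self.labels.unique()) <= {0, 1}:
            raise ValueError("labels must be 0 (control) or 1 (case)")
        vals = self.scores.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("feature rank scores must lie in [0,1]")

    @property
    def n_variants(self) -> int:
        return len(self.scores)

    def has_missing(self) -> bool:
        return bool(self.scores.isna().any().any())


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """TSV input: variant_id, gene, label, optional mtr, then feature columns."""
    df = pd.read_csv(path, sep="\t")
    if "variant_id" in df.columns:
        df = df.set_index("variant_id")
    labels = df.pop("label").astype(int) if "label" in df.columns else None
    genes = df.pop("gene").astype(str) if "gene" in df.columns else None
    mtr = df.pop("mtr") if "mtr" in df.columns else None
    return FeatureMatrix(scores=df.astype(float), labels=labels, genes=genes, mtr=mtr)


# ---- stage 1: imputation ---------------------------------------------------


def impute_missing_scores(m: FeatureMatrix) -> FeatureMatrix:
    """Fill missing scores with the per-gene per-feature median.

    With no gene partition the median is taken over all rows.  A feature
    entirely missing within a gene is an error — there is nothing to anchor
    the imputation.
    """
    scores = m.scores.copy()
    if m.genes is None:
        groups = [(None, scores.index)]
    else:
        groups = [(g, idx) for g, idx in scores.groupby(m.genes).groups.items()]
    for gene, idx in groups:
        block = scores.loc[idx]
        med = block.median()
        dead = med.index[med.isna() & block.isna().any()]
        if len(dead):
            raise ValueError(
                f"feature(s) {list(dead)} entirely missing within gene {gene!r}"
            )
        scores.loc[idx] = block.fillna(med)
    return FeatureMatrix(scores=scores, labels=m.labels, genes=m.genes, mtr=m.mtr)


# ---- stage 2: near-zero variance -------------------------------------------


def prune_near_zero_variance(
    m: FeatureMatrix | pd.DataFrame, freq_ratio_cut: float = 4.0, unique_cut: float = 0.05
) -> list[str]:
    """Features surviving the near-zero-variance screen.

    A feature is dropped when BOTH the ratio of the most common to the
    second-most common value exceeds ``freq_ratio_cut`` (80/20 -> 4) AND the
    fraction of distinct values is below ``unique_cut``.
    """
    scores = m.scores if isinstance(m, FeatureMatrix) else m
    retained: list[str] = []
    n = len(scores)
    for col in scores.columns:
        vals = scores[col].dropna()
        counts = vals.value_counts()
        if len(counts) <= 1:
            continue  # constant: dropped
        freq_ratio = counts.iloc[0] / counts.iloc[1]
        unique_frac = len(counts) / n
        if freq_ratio > freq_ratio_cut and unique_frac < unique_cut:
            continue
        retained.append(col)
    return retained


# ---- stage 3: pairwise correlation ----------------------------------------


def prune_pairwise_correlated(
    m: FeatureMatrix | pd.DataFrame, threshold: float = 0.75
) -> list[str]:
    """Iteratively remove one member of each |r| > threshold pair.

    While any remaining pair exceeds the threshold, the pair with the largest
    |r| is found and the member with the larger mean absolute correlation
    against all currently remaining features is removed; means are recomputed
    each step (the "exact" elimination order).
    """
    scores = m.scores if isinstance(m, FeatureMatrix) else m
    remaining = list(scores.columns)
    if len(remaining) < 2:
        return remaining
    corr = scores.corr().abs()
    while len(remaining) > 1:
        sub = corr.loc[remaining, remaining].copy()
        np.fill_diagonal(sub.values, 0.0)
        max_r = sub.values.max()
        if max_r <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        a, b = remaining[i], remaining[j]
        mean_a = sub.loc[a].sum() / (len(remaining) - 1)
        mean_b = sub.loc[b].sum() / (len(remaining) - 1)
        remaining.remove(a if mean_a >= mean_b else b)
    return remaining


# ---- stage 4: shadow-feature importance ------------------------------------


@dataclass
class FeatureImportanceReport:
    """Per-feature importance Z-scores across runs plus the shadow null."""

    features: list[str]
    z_scores: np.ndarray  # (runs, n_features)
    shadow_max: np.ndarray  # (runs,)
    hits: dict[str, int]
    categories: dict[str, Literal["uninformative", "inconclusive", "informative", "highly_informative"]]

    def informative(self) -> list[str]:
        return [
            f
            for f in self.features
            if self.categories[f] in ("informative", "highly_informative")
        ]

    def ranked_features(self) -> list[str]:
        """Informative features ordered by decreasing median Z-score."""
        med = {f: float(np.median(self.z_scores[:, i])) for i, f in enumerate(self.features)}
        return sorted(self.informative(), key=lambda f: -med[f])


def _oob_mda_z(
    X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int, rng: np.random.Generator
) -> np.ndarray:
    """Out-of-bag mean-decrease-accuracy Z-scores for each column of X.

    One bootstrap-sampled decision tree at a time; per tree, the drop in
    out-of-bag accuracy when a column is permuted.  Z = mean / SD of the
    per-tree decreases.
    """
    n, p = X.shape
    decreases = np.zeros((n_trees, p))
    max_features = min(mtry, p)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        base_acc = float(np.mean(tree.predict(X[oob]) == y[oob]))
        for j in range(p):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            decreases[t, j] = base_acc - float(np.mean(tree.predict(Xp) == y[oob]))
    mean = decreases.mean(axis=0)
    sd = decreases.std(axis=0, ddof=1)
    sd = np.where(sd < 1e-12, 1e-12, sd)
    return mean / sd


def assess_feature_importance(
    m: FeatureMatrix,
    seed: int = 15,
    runs: int = 1000,
    trees: int = 500,
    vars_per_split: int = 4,
    alpha: float = 0.05,
) -> FeatureImportanceReport:
    """Shadow-feature permutation importance (the Boruta scheme).

    Each run pairs every feature with a freshly permuted shadow copy, fits a
    random forest, and records each feature's out-of-bag
    mean-decrease-accuracy Z-score together with the best shadow's Z-score.
    A feature scores a "hit" when its Z exceeds the shadow maximum; across
    runs the hit count is tested against Binomial(runs, 1/2) with a
    Bonferroni-corrected level ``alpha``:

    * informative — significantly more hits than chance;
    * uninformative — significantly fewer;
    * inconclusive — neither;
    * highly_informative — informative AND the feature's minimum non-outlier
      Z (1.5 x IQR whisker convention) exceeds the overall maximum shadow Z.
    """
    if m.labels is None:
        raise ValueError("feature matrix has no labels")
    y = m.labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    features = list(m.scores.columns)
    if not features:
        raise ValueError("no features to assess")
    X0 = m.scores.to_numpy(dtype=float)
    if np.isnan(X0).any():
        raise ValueError("impute missing scores before importance assessment")
    rng = np.random.default_rng(seed)
    p = len(features)
    z_scores = np.zeros((runs, p))
    shadow_max = np.zeros(runs)
    for r in range(runs):
        shadows = np.column_stack([X0[rng.permutation(len(y)), j] for j in range(p)])
        X = np.hstack([X0, shadows])
        z = _oob_mda_z(X, y, trees, vars_per_split, rng)
        z_scores[r] = z[:p]
        shadow_max[r] = z[p:].max()

    hits = {f: int(np.sum(z_scores[:, i] > shadow_max)) for i, f in enumerate(features)}
    level = alpha / p  # Bonferroni over features
    categories: dict[str, str] = {}
    overall_shadow_max = float(shadow_max.max())
    for i, f in enumerate(features):
        p_more = stats.binomtest(hits[f], runs, 0.5, alternative="greater").pvalue
        p_less = stats.binomtest(hits[f], runs, 0.5, alternative="less").pvalue
        if p_more < level:
            zs = z_scores[:, i]
            q1, q3 = np.percentile(zs, [25, 75])
            whisker_lo = q1 - 1.5 * (q3 - q1)
            non_outlier_min = zs[zs >= whisker_lo].min()
            categories[f] = (
                "highly_informative" if non_outlier_min > overall_shadow_max else "informative"
            )
        elif p_less < level:
            categories[f] = "uninformative"
        else:
            categories[f] = "inconclusive"
    return FeatureImportanceReport(
        features=features,
        z_scores=z_scores,
        shadow_max=shadow_max,
        hits=hits,
        categories=categories,  # type: ignore[arg-type]
    )


# ---- stage 5: stepwise logistic model --------------------------------------


@dataclass
class GeneModel:
    """A fitted per-gene logistic model: GPP = expit(b0 + sum_i b_i x_i)."""

    gene_symbol: str
    intercept: float
    coefficients: dict[str, float]
    selection_trace: list[dict] = field(default_factory=list)
    training_auc: float | None = None
    used_ridge_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "gene_symbol": self.gene_symbol,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "selection_trace": self.selection_trace,
            "training_auc": self.training_auc,
            "used_ridge_fallback": self.used_ridge_fallback,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            gene_symbol=d["gene_symbol"],
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            selection_trace=d.get("selection_trace", []),
            training_auc=d.get("training_auc"),
            used_ridge_fallback=d.get("used_ridge_fallback", False),
        )


@dataclass
class _Fit:
    params: np.ndarray  # intercept first
    llf: float
    aic: float
    ridge: bool
    conf_int: np.ndarray | None = None  # (k+1, 2) Wald intervals


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge_alpha: float = 1e-2) -> _Fit:
    """Maximum-likelihood logistic fit with a ridge fallback.

    statsmodels Logit first; if it fails to converge or the coefficients run
    away (perfect separation), refit with a weak L2 penalty and report the
    unpenalized log-likelihood at the penalized estimates.
    """
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    k = Xc.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(np.abs(res.params) < 50):
                return _Fit(
                    params=np.asarray(res.params),
                    llf=float(res.llf),
                    aic=float(res.aic),
                    ridge=False,
                    conf_int=np.asarray(res.conf_int()),
                )
        except Exception:
            pass
    # weakly penalized fallback
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1.0 / ridge_alpha, max_iter=2000)
    lr.fit(X, y)
    params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    eta = params[0] + X @ params[1:]
    llf = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return _Fit(params=params, llf=llf, aic=2 * k - 2 * llf, ridge=True)


def _relative_likelihood(aic_new: float, aic_old: float) -> float:
    return float(np.exp((aic_new - aic_old) / 2.0))


def select_gene_model(
    m: FeatureMatrix,
    ranked_features: Sequence[str],
    include_mtr: bool = True,
    gene_symbol: str = "",
    stop_p: float = 0.05,
) -> GeneModel:
    """Forward-backward stepwise logistic selection over ranked candidates.

    The incumbent starts as intercept-only, or intercept + MTR when
    ``include_mtr`` (mirroring the screen that admits the MTR only for genes
    where it is itself predictive).  Candidates are offered in rank order;
    a step (forward addition or backward removal) is accepted only when the
    incumbent's Akaike relative likelihood against the candidate model,
    exp((AIC_new - AIC_old)/2), is <= ``stop_p`` — i.e. the new model must
    make the old one implausible.  Forward selection halts at the first
    rejected candidate; after each accepted addition every included feature
    is re-tested for removal by the same criterion.
    """
    if m.labels is None:
        raise ValueError("feature matrix has no labels")
    y = m.labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    design = m.scores.copy()
    if include_mtr:
        if m.mtr is None:
            raise ValueError("include_mtr requested but the matrix has no MTR column")
        design[MTR_COLUMN] = m.mtr.to_numpy(dtype=float)

    included: list[str] = [MTR_COLUMN] if include_mtr else []
    trace: list[dict] = []

    def fit(cols: list[str]) -> _Fit:
        X = design[cols].to_numpy(dtype=float) if cols else np.empty((len(y), 0))
        return _fit_logistic(X, y)

    current = fit(included)
    trace.append({"action": "start", "features": list(included), "aic": current.aic})

    for cand in ranked_features:
        if cand in included:
            continue
        if cand not in design.columns:
            raise KeyError(f"candidate feature {cand!r} not in the matrix")
        trial = fit(included + [cand])
        rl = _relative_likelihood(trial.aic, current.aic)
        accepted = rl <= stop_p
        trace.append(
            {
                "action": "forward",
                "feature": cand,
                "aic": trial.aic,
                "relative_likelihood": rl,
                "accepted": accepted,
            }
        )
        if not accepted:
            break
        included.append(cand)
        current = trial
        # backward pass: re-test every included feature for removal
        changed = True
        while changed and len(included) > 1:
            changed = False
            for feat in list(included):
                if feat == cand:
                    continue
                reduced_cols = [f for f in included if f != feat]
                reduced = fit(reduced_cols)
                rl_b = _relative_likelihood(reduced.aic, current.aic)
                if rl_b <= stop_p:
                    included = reduced_cols
                    current = reduced
                    trace.append(
                        {
                            "action": "backward",
                            "feature": feat,
                            "aic": reduced.aic,
                            "relative_likelihood": rl_b,
                            "accepted": True,
                        }
                    )
                    changed = True
                    break

    coeffs = {f: float(b) for f, b in zip(included, current.params[1:])}
    model = GeneModel(
        gene_symbol=gene_symbol,
        intercept=float(current.params[0]),
        coefficients=coeffs,
        selection_trace=trace,
        used_ridge_fallback=current.ridge,
    )
    model.training_auc = evaluate_auc(score_gpp_frame(model, design), y)
    return model


def fit_logistic_model(
    m: FeatureMatrix, features: Sequence[str], gene_symbol: str = ""
) -> tuple[GeneModel, np.ndarray | None]:
    """Fit a fixed-feature logistic model (no selection); returns the model
    and the Wald 95% confidence intervals (rows: intercept then features)."""
    if m.labels is None:
        raise ValueError("feature matrix has no labels")
    y = m.labels.to_numpy(dtype=int)
    X = m.scores[list(features)].to_numpy(dtype=float)
    f = _fit_logistic(X, y)
    model = GeneModel(
        gene_symbol=gene_symbol,
        intercept=float(f.params[0]),
        coefficients={c: float(b) for c, b in zip(features, f.params[1:])},
        used_ridge_fallback=f.ridge,
    )
    model.training_auc = evaluate_auc(score_gpp_frame(model, m.scores), y)
    return model, f.conf_int


# ---- scoring and evaluation -------------------------------------------------


def score_gpp(model: GeneModel, features_of_variant: dict[str, float]) -> float:
    """GPP score for one variant: inverse-logit of the linear predictor."""
    eta = model.intercept
    for feat, beta in model.coefficients.items():
        if feat not in features_of_variant or features_of_variant[feat] is None:
            raise KeyError(f"variant is missing model feature {feat!r}")
        eta += beta * float(features_of_variant[feat])
    return float(expit(eta))


def score_gpp_frame(model: GeneModel, frame: pd.DataFrame) -> np.ndarray:
    """Vectorized GPP scores for a variant-by-feature frame."""
    missing = [f for f in model.coefficients if f not in frame.columns]
    if missing:
        raise KeyError(f"frame is missing model feature(s) {missing}")
    eta = np.full(len(frame), model.intercept)
    for feat, beta in model.coefficients.items():
        eta = eta + beta * frame[feat].to_numpy(dtype=float)
    return expit(eta)


def evaluate_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: P(random case outscores random control), ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = np.sum(ranks[labels == 1]) - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
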
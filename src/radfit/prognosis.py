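"""Prognostic evaluation of FTH signatures.

Feature matrices are z-score normalised across patients (population SD
convention, ddof = 0).  Prognostic discrimination is measured with a
threefold (event-stratified) cross-validated Cox proportional hazards
model: the model is fitted on the training folds and Harrell's
C-statistic is computed on the held-out fold, then averaged (unweighted)
over folds.  Nested feature sets (baseline clinical factors, + kinetic
markers, + FTH signature) are compared with a likelihood-ratio test on
full-data fits.  Per-patient risk scores use the coefficients of the
fold in which the patient was a test case; Kaplan-Meier analysis
dichotomises at the median risk score and tests separation with the
two-sample log-rank test.

Phenotype discovery runs Ward hierarchical clustering on the z-scored
signatures; the stable cluster count is selected by consensus clustering
(0.8 subsampling, consensus-CDF area criterion) and cluster significance
is assessed with a simplified SigClust: a Monte-Carlo null of a single
Gaussian fitted to the data, comparing the observed 2-means cluster
index (within-cluster over total sum of squares) against the null
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .io import SIGNATURE_COLUMNS, ValidationError

__all__ = [
    "FEATURE_SETS",
    "CVResult",
    "PhenotypeResult",
    "zscore",
    "cv_cox",
    "risk_scores",
    "km_dichotomize",
    "discover_phenotypes",
    "covariate_associations",
]

BASELINE_FEATURES = ["er", "pr", "tumor_size", "pcr", "aln"]
KINETIC_FEATURES = ["suv", "k1", "ki"]
FTH_FEATURES = ["bcss_tss", "phi12", "phi23", "phi13"]

FEATURE_SETS = {
    "baseline": BASELINE_FEATURES,
    "baseline+kinetic": BASELINE_FEATURES + KINETIC_FEATURES,
    "baseline+fth": BASELINE_FEATURES + FTH_FEATURES,
}


def zscore(features: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score normalisation (population SD, ddof = 0).

    Zero-variance columns are dropped with a warning.
    """
    if len(features) < 2:
        raise ValidationError("z-scoring needs at least 2 rows")
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(float)
        sd = x.std(ddof=0)
        if sd == 0:
            warnings.warn(f"dropping zero-variance column {col!r}")
            continue
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=features.index)


# --------------------------------------------------------------------------
# cross-validated Cox models
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    feature_names: list
    fold_assignment: np.ndarray      # fold index per patient
    coefficients: np.ndarray         # (folds, n_features)
    fold_c: np.ndarray               # test C per fold
    mean_c: float
    full_log_likelihood: float
    full_coefficients: pd.Series
    converged: np.ndarray = field(default=None)


def _stratified_folds(event: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Event-stratified random fold assignment."""
    rng = np.random.default_rng(seed)
    assign = np.empty(event.size, dtype=int)
    for val in (0, 1):
        idx = np.where(event == val)[0]
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def _fit_cox(df: pd.DataFrame, penalizer: float = 0.0):
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col="rfs_time", event_col="event")
    return cph


def cv_cox(records: pd.DataFrame, feature_set: str = "baseline+fth",
           folds: int = 3, seed: int = 0,
           standardize: bool = True) -> CVResult:
    """Cross-validated Cox PH model over a named feature set.

    Features are z-scored across the cohort (signatures are expected to
    be z-scored per the protocol; standardising everything keeps the
    coefficients comparable).  Returns per-fold test-set C-statistics and
    coefficients plus the full-data fit for likelihood-ratio comparison.
    """
    feats = FEATURE_SETS[feature_set] if isinstance(feature_set, str) else list(feature_set)
    df = records.reset_index(drop=True)
    X = df[feats].astype(float)
    if standardize:
        X = zscore(X)
        feats = list(X.columns)
    data = pd.concat([X, df[["rfs_time", "event"]].astype(float)], axis=1)
    event = df["event"].to_numpy(int)
    assign = _stratified_folds(event, folds, seed)
    for f in range(folds):
        if event[assign == f].sum() < 2:
            raise ValidationError(f"fold {f} has fewer than 2 events")

    coefs = np.zeros((folds, len(feats)))
    cs = np.zeros(folds)
    conv = np.ones(folds, dtype=bool)
    for f in range(folds):
        train = data[assign != f]
        test = data[assign == f]
        try:
            cph = _fit_cox(train)
        except Exception:
            warnings.warn(f"fold {f}: Cox fit failed, retrying with ridge")
            cph = _fit_cox(train, penalizer=0.1)
            conv[f] = False
        coefs[f] = cph.params_[feats].to_numpy()
        risk = test[feats].to_numpy() @ coefs[f]
        cs[f] = concordance_index(test["rfs_time"], -risk, test["event"])

    try:
        full = _fit_cox(data)
    except Exception:
        full = _fit_cox(data, penalizer=0.1)
    return CVResult(
        feature_names=feats, fold_assignment=assign, coefficients=coefs,
        fold_c=cs, mean_c=float(cs.mean()),
        full_log_likelihood=float(full.log_likelihood_),
        full_coefficients=full.params_, converged=conv,
    )


def likelihood_ratio_test(nested: CVResult, full: CVResult) -> dict:
    """LR test of two nested full-data Cox fits."""
    stat = 2.0 * (full.full_log_likelihood - nested.full_log_likelihood)
    dof = len(full.feature_names) - len(nested.feature_names)
    if dof <= 0:
        raise ValidationError("models are not nested")
    return {"statistic": stat, "dof": dof,
            "p": float(stats.chi2.sf(max(stat, 0.0), dof))}


def risk_scores(records: pd.DataFrame, cv: CVResult,
                standardize: bool = True) -> np.ndarray:
    """Per-patient risk score using their test-fold coefficients."""
    df = records.reset_index(drop=True)
    X = df[cv.feature_names].astype(float)
    if standardize:
        X = zscore(X)[cv.feature_names]
    X = X.to_numpy()
    if cv.fold_assignment.size != len(df):
        raise ValidationError("fold assignment does not cover the cohort")
    out = np.empty(len(df))
    for f in range(cv.coefficients.shape[0]):
        sel = cv.fold_assignment == f
        out[sel] = X[sel] @ cv.coefficients[f]
    return out


def km_dichotomize(scores: np.ndarray, times: np.ndarray, events: np.ndarray,
                   threshold: float | None = None) -> dict:
    """Median-split Kaplan-Meier analysis with a two-sample log-rank test.

    Returns group labels (1 = high risk), the log-rank statistic and p,
    and fitted KM estimators per group.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if threshold is None:
        threshold = float(np.median(scores))
    high = scores > threshold
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValidationError("dichotomisation leaves a group with < 2 patients")
    res = logrank_test(times[high], times[~high],
                       event_observed_A=events[high],
                       event_observed_B=events[~high])
    kms = {}
    for name, sel in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(times[sel], events[sel], label=name)
        kms[name] = km
    return {"group": high.astype(int), "statistic": float(res.test_statistic),
            "p": float(res.p_value), "threshold": threshold, "km": kms}


# --------------------------------------------------------------------------
# phenotype discovery
# --------------------------------------------------------------------------

@dataclass
class PhenotypeResult:
    linkage: np.ndarray
    c: int
    phenotype: np.ndarray            # 1..c per patient (ranked by FTH index)
    consensus: dict                  # c -> consensus matrix
    cdf_area: dict                   # c -> consensus-CDF area
    sigclust_p: float
    cluster_index: float
    stable: bool


def _cluster_index_2means(X: np.ndarray, seed: int = 0) -> float:
    """2-means within-cluster over total sum of squares (lower = more
    cluster structure)."""
    km = KMeans(n_clusters=2, random_state=seed, n_init=10).fit(X)
    tss = float(np.sum((X - X.mean(axis=0)) ** 2))
    return km.inertia_ / tss if tss > 0 else 1.0


def sigclust(X: np.ndarray, n_sim: int = 500, seed: int = 0) -> dict:
    """Simplified SigClust: Monte-Carlo Gaussian null for 2-cluster
    structure.

    The null is a single multivariate Gaussian with the sample mean and
    covariance; p is the fraction of null 2-means cluster-index values
    at or below the observed one.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    obs = _cluster_index_2means(X, seed=seed)
    mean = X.mean(axis=0)
    cov = np.cov(X.T, ddof=1)
    cov = np.atleast_2d(cov) + 1e-10 * np.eye(X.shape[1])
    null = np.empty(n_sim)
    for s in range(n_sim):
        sim = rng.multivariate_normal(mean, cov, size=X.shape[0],
                                      method="cholesky")
        null[s] = _cluster_index_2means(sim, seed=seed)
    p = float((1 + np.sum(null <= obs)) / (1 + n_sim))
    return {"p": p, "cluster_index": obs, "null": null}


def consensus_matrix(X: np.ndarray, c: int, n_resample: int = 500,
                     subsample: float = 0.8, seed: int = 0) -> np.ndarray:
    """Co-clustering frequency under Ward clustering of subsamples."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    together = np.zeros((n, n))
    both = np.zeros((n, n))
    size = max(int(np.ceil(subsample * n)), c + 1)
    for _ in range(n_resample):
        idx = rng.choice(n, size=size, replace=False)
        lab = fcluster(linkage(X[idx], method="ward"), c, criterion="maxclust")
        same = lab[:, None] == lab[None, :]
        both[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same
    M = np.divide(together, both, out=np.zeros_like(together), where=both > 0)
    np.fill_diagonal(M, 1.0)
    return M


def _cdf_area(M: np.ndarray) -> float:
    v = M[np.triu_indices_from(M, k=1)]
    grid = np.linspace(0, 1, 101)
    cdf = np.searchsorted(np.sort(v), grid, side="right") / v.size
    return float(np.trapezoid(cdf, grid))


def discover_phenotypes(signatures: pd.DataFrame | np.ndarray,
                        fth_index: np.ndarray | None = None,
                        c_max: int = 6, n_resample: int = 500,
                        subsample: float = 0.8, seed: int = 0,
                        n_sim: int = 500) -> PhenotypeResult:
    """Unsupervised FTH phenotype discovery.

    Ward clustering of z-scored signatures; the stable cluster count c
    maximises the relative consensus-CDF area gain (c = 2 scores its
    absolute area); simplified-SigClust significance is evaluated for
    the 2-cluster structure.  Phenotypes are ranked by mean FTH index
    (phenotype 1 = lowest heterogeneity).
    """
    X = np.asarray(signatures, dtype=float)
    if X.shape[0] < 10:
        raise ValidationError("phenotype discovery needs >= 10 patients")
    if fth_index is None:
        fth_index = X.mean(axis=1)

    Z = linkage(X, method="ward")
    consensus = {}
    areas = {}
    for c in range(2, c_max + 1):
        consensus[c] = consensus_matrix(X, c, n_resample=n_resample,
                                        subsample=subsample, seed=seed + c)
        areas[c] = _cdf_area(consensus[c])
    deltas = {2: areas[2]}
    for c in range(3, c_max + 1):
        deltas[c] = (areas[c] - areas[c - 1]) / max(areas[c - 1], 1e-12)
    c_best = max(deltas, key=lambda c: deltas[c])

    sc = sigclust(X, n_sim=n_sim, seed=seed)
    stable = c_best > 1 and sc["p"] < 0.05
    lab = fcluster(Z, c_best, criterion="maxclust")
    order = np.argsort([fth_index[lab == c].mean() for c in range(1, c_best + 1)])
    lut = np.empty(c_best + 1, dtype=int)
    for rank, c in enumerate(order, start=1):
        lut[c + 1] = rank
    phenotype = lut[lab]
    return PhenotypeResult(linkage=Z, c=int(c_best), phenotype=phenotype,
                           consensus=consensus, cdf_area=areas,
                           sigclust_p=sc["p"],
                           cluster_index=sc["cluster_index"], stable=stable)


# --------------------------------------------------------------------------
# covariate associations
# --------------------------------------------------------------------------

CATEGORICAL_MARKERS = ["er", "pr", "her2", "pcr", "aln"]
CONTINUOUS_MARKERS = ["ki", "k1", "suv", "tumor_size"]


def covariate_associations(phenotypes: np.ndarray, records: pd.DataFrame,
                           categorical=None, continuous=None) -> pd.DataFrame:
    """Association of each marker with the phenotype assignment.

    Chi-square tests on phenotype x category contingency tables (exact
    Fisher test when an expected cell count drops below 1 on 2x2
    tables); one-way ANOVA for continuous markers, with per-phenotype
    IQR and variance reported.
    """
    phenotypes = np.asarray(phenotypes)
    groups = np.unique(phenotypes)
    if groups.size < 2:
        raise ValidationError("need at least 2 phenotypes")
    categorical = CATEGORICAL_MARKERS if categorical is None else categorical
    continuous = CONTINUOUS_MARKERS if continuous is None else continuous
    rows = []
    for col in categorical:
        if col not in records:
            continue
        table = pd.crosstab(phenotypes, records[col]).to_numpy()
        note = ""
        if table.shape[1] < 2 or table.shape[0] < 2:
            rows.append({"marker": col, "type": "categorical",
                         "statistic": np.nan, "dof": 0, "p": np.nan,
                         "note": "degenerate table"})
            continue
        chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
        if expected.min() < 1 and table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
            chi2, dof, note = np.nan, 0, "exact test (low expected counts)"
        rows.append({"marker": col, "type": "categorical", "statistic": chi2,
                     "dof": dof, "p": p, "note": note})
    for col in continuous:
        if col not in records:
            continue
        samples = [records[col].to_numpy(float)[phenotypes == g] for g in groups]
        stat, p = stats.f_oneway(*samples)
        row = {"marker": col, "type": "continuous", "statistic": stat,
               "dof": groups.size - 1, "p": p, "note": ""}
        for g, s in zip(groups, samples):
            row[f"iqr_ph{g}"] = float(np.subtract(*np.percentile(s, [75, 25])))
            row[f"var_ph{g}"] = float(np.var(s, ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)
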
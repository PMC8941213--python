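"""Empirical-Bayes moderated two-cohort testing with Storey q-values, plus
the sample-structure summaries (PCA scores, Euclidean distances).

The moderated t-statistic shrinks per-group sample variances toward a
pooled prior estimated by method of moments on log s^2 (closed forms via
digamma/trigamma inversion), then refers the rescaled statistic to a
Student-t distribution with augmented degrees of freedom. Significance is
the conjunction the study design uses: p <= 0.005 AND q < 0.1; the
|log2FC| > 1 flag is carried separately for volcano display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .quant import NORMALIZED, QuantMatrix


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Returns (d0, s0^2); d0 = inf means all log-variance spread is explained
    by sampling noise and every group shrinks fully to s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 groups with positive variance")
    z = np.log(s2[ok])
    e = z - digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, df[ok] / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no dispersion beyond sampling noise: infinite prior df, common
        # variance taken as the geometric mean of the observed s^2 (exact
        # when all s^2 coincide)
        d0 = np.inf
        s0_2 = float(np.exp(z.mean()))
    return d0, s0_2


def squeeze_variance(s2: np.ndarray, df: np.ndarray, d0: float,
                     s0_2: float) -> np.ndarray:
    """Posterior variance: (d0*s0^2 + df*s^2) / (d0 + df)."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_2)
    return (d0 * s0_2 + df * s2) / (d0 + df)


def moderated_ttest(matrix: QuantMatrix) -> pd.DataFrame:
    """Moderated t-test of UC vs healthy per protein group.

    Groups need >= 2 non-missing values per cohort to be tested; groups
    passing the missingness filter but untestable are reported with
    ``presence_only=True`` and missing statistics (they do not enter the
    prior fit or the multiple-testing universe).
    """
    if matrix.scale != NORMALIZED:
        raise ValueError("moderated_ttest expects a normalized-log matrix")
    h = matrix.values[matrix.cohort_columns("healthy")].to_numpy(dtype=float)
    u = matrix.values[matrix.cohort_columns("UC")].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(h), axis=1)
    n2 = np.sum(~np.isnan(u), axis=1)
    testable = (n1 >= 2) & (n2 >= 2)
    if testable.sum() < 2:
        raise ValueError("fewer than 2 testable groups; prior not estimable")

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Degrees of freedom")
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        m1 = np.nanmean(h, axis=1)
        m2 = np.nanmean(u, axis=1)
        v1 = np.nanvar(h, axis=1, ddof=1)
        v2 = np.nanvar(u, axis=1, ddof=1)
    df = n1 + n2 - 2.0
    s2 = np.where(df > 0,
                  ((n1 - 1) * np.nan_to_num(v1) + (n2 - 1) * np.nan_to_num(v2))
                  / np.where(df > 0, df, 1.0),
                  np.nan)

    d0, s0_2 = fit_variance_prior(s2[testable], df[testable])
    s2_post = squeeze_variance(s2, df, d0, s0_2)
    se = np.sqrt(s2_post * (1.0 / np.where(n1 > 0, n1, np.nan)
                            + 1.0 / np.where(n2 > 0, n2, np.nan)))
    t = (m2 - m1) / se
    df_total = (d0 + df) if np.isfinite(d0) else np.inf
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame({
        "group_id": matrix.values.index,
        "log2_fold_change": m2 - m1,
        "moderated_t": t,
        "p_value": p,
        "n_healthy": n1.astype(int),
        "n_uc": n2.astype(int),
        "presence_only": ~testable,
    })
    out.loc[~testable, ["log2_fold_change", "moderated_t", "p_value"]] = np.nan
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    return out.reset_index(drop=True)


def qvalues(p_values, pi0: float | None = None, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda (default 0.5).

    pi0 = min(1, #{p > lam} / ((1 - lam) m)); q_(i) = min_{j >= i}
    pi0 * m * p_(j) / j on sorted p. With pi0 = 1 this is exactly the
    Benjamini-Hochberg step-up adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, np.sum(p > lam) / ((1.0 - lam) * m))
        pi0 = max(pi0, 1.0 / m)  # guard against zero when all p are small
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_significant(
    results: pd.DataFrame, p_max: float = 0.005, q_max: float = 0.1
) -> tuple[pd.DataFrame, tuple[int, int, int]]:
    """Attach q-values and significance calls; report cohort-wise counts.

    Significant iff p <= p_max AND q < q_max. Direction follows the sign of
    the UC - healthy log2 fold change. Returns the annotated table and
    (n_healthy_enriched, n_uc_enriched, total). ``large_fc`` (|log2FC| > 1)
    is a display attribute for volcano coloring, not a gate.
    """
    out = results.copy()
    tested = out["p_value"].notna()
    out["q_value"] = np.nan
    if tested.sum() > 0:
        out.loc[tested, "q_value"] = qvalues(out.loc[tested, "p_value"].to_numpy())
    out["significant"] = tested & (out["p_value"] <= p_max) & (out["q_value"] < q_max)
    out["direction"] = np.where(
        out["significant"] & (out["log2_fold_change"] > 0), "UC",
        np.where(out["significant"], "healthy", ""))
    out["large_fc"] = out["log2_fold_change"].abs() > 1.0
    n_uc = int((out["direction"] == "UC").sum())
    n_healthy = int((out["direction"] == "healthy").sum())
    return out, (n_healthy, n_uc, n_healthy + n_uc)


def expected_false_positives(n_significant: int, q_threshold: float) -> int:
    """Expected false discoveries among calls at a q cutoff: round(n * q)."""
    if n_significant < 0:
        raise ValueError("n_significant must be >= 0")
    if not 0.0 < q_threshold < 1.0:
        raise ValueError("q_threshold must lie in (0, 1)")
    return int(np.floor(n_significant * q_threshold + 0.5))


def _imputed_sample_matrix(matrix: QuantMatrix) -> np.ndarray:
    """samples x groups array with per-group mean imputation (summaries only)."""
    vals = matrix.values.to_numpy(dtype=float)
    row_mean = np.nanmean(vals, axis=1)
    filled = np.where(np.isnan(vals), row_mean[:, None], vals)
    filled = filled[~np.isnan(filled).any(axis=1)]  # all-missing groups drop out
    return filled.T


def pca_scores(matrix: QuantMatrix, n_components: int = 2
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the first principal components, by centered SVD.

    Missing values are mean-imputed per group for this summary only. Signs
    are fixed so each component's largest-magnitude loading is positive.
    Returns (scores DataFrame indexed by sample, fraction of variance
    explained per component).
    """
    X = _imputed_sample_matrix(matrix)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U[:, :k] * S[:k]
    total = np.sum(S ** 2)
    var_explained = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    df = pd.DataFrame(scores, index=matrix.values.columns,
                      columns=[f"PC{i + 1}" for i in range(k)])
    return df, var_explained


def sample_distance_matrix(matrix: QuantMatrix) -> pd.DataFrame:
    """Symmetric sample x sample Euclidean distances (mean-imputed)."""
    from scipy.spatial.distance import pdist, squareform

    X = _imputed_sample_matrix(matrix)
    d = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(d, index=matrix.values.columns,
                        columns=matrix.values.columns)
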
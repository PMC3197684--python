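"""Shell-morphometry discrimination between the two genotype populations.

Three lengths are measured per shell: the specimen major axis in edge view
(overall size), and the major axes of the terminal chamber and of the
aperture. The size-normalized apertural length is the aperture/terminal
chamber ratio; in log space it is plotted against log size and the two
populations (north / south of the front, standing for Type I / Type II) are
compared with a two-group linear discriminant analysis (Wilks' lambda, its
exact F transform for p = 2 variables) and, on the one-dimensional log-ratio
descriptor, with Mann-Whitney U and two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("north", "south")


class BiometricsError(ValueError):
    pass


@dataclass
class MorphoSpecimen:
    specimen_id: str
    major_axis: float
    chamber_axis: float
    aperture_axis: float
    group: str  # "north" | "south"

    def __post_init__(self) -> None:
        for name in ("major_axis", "chamber_axis", "aperture_axis"):
            if getattr(self, name) <= 0:
                raise BiometricsError(f"{name} must be positive")
        if self.group not in GROUPS:
            raise BiometricsError(f"group must be one of {GROUPS}")


def specimens_to_frame(specimens) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "specimen_id": s.specimen_id,
                "major_axis": s.major_axis,
                "chamber_axis": s.chamber_axis,
                "aperture_axis": s.aperture_axis,
                "group": s.group,
            }
            for s in specimens
        ]
    )


def frame_to_specimens(df: pd.DataFrame) -> list[MorphoSpecimen]:
    return [
        MorphoSpecimen(
            specimen_id=str(r["specimen_id"]),
            major_axis=float(r["major_axis"]),
            chamber_axis=float(r["chamber_axis"]),
            aperture_axis=float(r["aperture_axis"]),
            group=str(r["group"]),
        )
        for _, r in df.iterrows()
    ]


def descriptors(major_axis, chamber_axis, aperture_axis):
    """Log descriptors of one or many specimens.

    Returns (log_size, log_ratio_apc, log_ratio_combined) where
    log_size = ln(major axis), log_ratio_apc = ln(aperture / chamber) and
    log_ratio_combined = log_ratio_apc - log_size (the ratio of the
    size-normalized apertural length to specimen size, in log space).
    """
    major = np.asarray(major_axis, dtype=float)
    chamber = np.asarray(chamber_axis, dtype=float)
    aperture = np.asarray(aperture_axis, dtype=float)
    if np.any(major <= 0) or np.any(chamber <= 0) or np.any(aperture <= 0):
        raise BiometricsError("all lengths must be positive")
    log_size = np.log(major)
    log_ratio_apc = np.log(aperture / chamber)
    return log_size, log_ratio_apc, log_ratio_apc - log_size


@dataclass
class DiscriminationResult:
    wilks_lambda: float
    F: float
    df: tuple[int, int]
    p_value: float
    weights: np.ndarray          # discriminant axis in feature space
    threshold: float             # cut on the discriminant score
    classification_rate: float   # resubstitution, percent
    cv_classification_rate: float  # leave-one-out, percent
    confusion: pd.DataFrame


def _wilks(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    means = []
    for g in np.unique(y):
        sub = X[y == g]
        c = sub - sub.mean(axis=0)
        W += c.T @ c
        means.append(sub.mean(axis=0))
    det_w, det_t = np.linalg.det(W), np.linalg.det(T)
    lam = float(det_w / det_t) if det_t != 0 else float("nan")
    return lam, W, np.array(means)


def two_group_lda(features, groups) -> DiscriminationResult:
    """Fisher two-group linear discriminant analysis.

    ``features`` is an (N, p) array (canonically p = 2: log size and
    log aperture/chamber ratio); ``groups`` the per-specimen labels (two
    levels). Wilks' lambda = det(W)/det(T); its exact F transform for two
    groups is F = ((1 - lambda)/lambda) * ((N - p - 1)/p) on (p, N - p - 1)
    degrees of freedom. Classification assigns each specimen by its
    discriminant score against the midpoint of the two group mean scores;
    both the resubstitution rate and a leave-one-out cross-validated rate
    are reported.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(groups)
    if X.ndim != 2:
        raise BiometricsError("features must be a 2-D array")
    levels = np.unique(y)
    if len(levels) != 2:
        raise BiometricsError(f"exactly two groups required, got {list(levels)}")
    for g in levels:
        if (y == g).sum() < 3:
            raise BiometricsError(f"group {g!r} needs at least 3 specimens")
    N, p = X.shape
    lam, W, means = _wilks(X, y)
    if not np.isfinite(lam) or lam <= 0:
        raise BiometricsError(
            "singular scatter matrix: jitter the data or drop a variable"
        )
    df = (p, N - p - 1)
    F = (1 - lam) / lam * df[1] / df[0]
    p_value = float(stats.f.sf(F, *df))

    def _axis_threshold(Xf, yf):
        _, Wf, mf = _wilks(Xf, yf)
        Sw = Wf / (len(yf) - 2)  # pooled within-group covariance
        w = np.linalg.solve(Sw, mf[0] - mf[1])
        thr = 0.5 * (mf[0] + mf[1]) @ w
        return w, thr

    w, thr = _axis_threshold(X, y)
    scores = X @ w
    pred = np.where(scores > thr, levels[0], levels[1])
    correct = pred == y
    confusion = pd.crosstab(
        pd.Series(y, name="actual"), pd.Series(pred, name="predicted")
    )

    cv_correct = 0
    for i in range(N):
        keep = np.ones(N, dtype=bool)
        keep[i] = False
        try:
            wi, ti = _axis_threshold(X[keep], y[keep])
        except np.linalg.LinAlgError:
            continue
        pi = levels[0] if X[i] @ wi > ti else levels[1]
        cv_correct += pi == y[i]

    return DiscriminationResult(
        wilks_lambda=lam,
        F=float(F),
        df=df,
        p_value=p_value,
        weights=w,
        threshold=float(thr),
        classification_rate=100.0 * correct.mean(),
        cv_classification_rate=100.0 * cv_correct / N,
        confusion=confusion,
    )


@dataclass
class NonparametricTestResult:
    test: str  # "mann_whitney" | "kolmogorov_smirnov"
    statistic: float
    p_value: float


def rank_tests(values, groups) -> tuple[NonparametricTestResult, NonparametricTestResult]:
    """Mann-Whitney U and two-sample Kolmogorov-Smirnov tests.

    U is reported direction-free as min(U, n1*n2 - U). The U p-value uses
    exact enumeration when both samples hold at most 20 values and there
    are no ties, a normal approximation otherwise; the Kolmogorov-Smirnov
    p-value uses the asymptotic Kolmogorov distribution.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(groups)
    levels = np.unique(y)
    if len(levels) != 2:
        raise BiometricsError("exactly two groups required")
    x1, x2 = v[y == levels[0]], v[y == levels[1]]
    if x1.size == 0 or x2.size == 0:
        raise BiometricsError("empty group")
    has_ties = np.unique(v).size < v.size
    method = "exact" if (max(x1.size, x2.size) <= 20 and not has_ties) else "asymptotic"
    mw = stats.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
    u = min(float(mw.statistic), x1.size * x2.size - float(mw.statistic))
    ks = stats.ks_2samp(x1, x2, method="asymp")
    return (
        NonparametricTestResult("mann_whitney", u, float(mw.pvalue)),
        NonparametricTestResult("kolmogorov_smirnov", float(ks.statistic), float(ks.pvalue)),
    )


def kernel_density(values, bandwidth: float | None = None,
                   grid_points: int = 512, pad_bandwidths: float = 8.0) -> pd.DataFrame:
    """Gaussian kernel density on an explicit grid.

    With no bandwidth given, Silverman's rule of thumb
    0.9 * min(sd, IQR/1.34) * n^(-1/5) is used (falling back to 1e-3 times
    the absolute scale for degenerate samples). The grid pads the data
    range by ``pad_bandwidths`` bandwidths so the returned curve integrates
    to 1 within 1e-6.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise BiometricsError("need at least 2 values")
    if bandwidth is None:
        sd = x.std(ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        scale = min(sd, iqr / 1.34) if iqr > 0 else sd
        if scale == 0:
            scale = max(abs(x).max(), 1.0) * 1e-3
        bandwidth = 0.9 * scale * x.size ** (-0.2)
    if bandwidth <= 0:
        raise BiometricsError("bandwidth must be positive")
    grid = np.linspace(x.min() - pad_bandwidths * bandwidth,
                       x.max() + pad_bandwidths * bandwidth, grid_points)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = stats.norm.pdf(z).mean(axis=1) / bandwidth
    return pd.DataFrame({"x": grid, "density": dens})
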
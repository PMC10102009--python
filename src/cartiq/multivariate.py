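"""Control normalization, collinearity screening, LDA classification and
metabolic relative-change mapping against a reference perturbation table.

Classification follows the canonical linear-discriminant recipe: class means
with a pooled within-class covariance and (by default) equal priors.  OCA is
the resubstitution accuracy of the fitted discriminants; CVCA refits the
model on every leave-one-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .image_io import METRIC_COLUMNS

COLLINEARITY_THRESHOLD = 0.7
#: Fraction of reference-class samples the displayed ellipsoid should cover.
DEFAULT_COVERAGE = 0.75
METABOLIC_COLUMNS = ["redox_ratio", "nadh_llif", "beta"]


# ---------------------------------------------------------------------------
# Control normalization


def normalize_to_control(
    table: pd.DataFrame,
    control_selector: dict,
    metrics: Sequence[str] = tuple(METRIC_COLUMNS),
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Divide each metric by the mean of matching control rows.

    ``control_selector`` is a column -> value mapping identifying control
    rows (e.g. ``{"group": "sham"}``).  With ``by=("time_point",)`` the
    control mean is computed within each time point separately.  A missing
    or zero control mean is an error naming the stratum.
    """
    out = table.copy()
    for m in metrics:
        out[m] = out[m].astype(float)
    ctrl = np.ones(len(table), dtype=bool)
    for col, val in control_selector.items():
        ctrl &= (table[col] == val).to_numpy()
    if not ctrl.any():
        raise ValueError(f"no control rows match {control_selector}")

    strata = (
        table[list(by)].apply(tuple, axis=1)
        if by
        else pd.Series([()] * len(table), index=table.index)
    )
    for stratum in strata.unique():
        in_stratum = (strata == stratum).to_numpy()
        ctrl_rows = in_stratum & ctrl
        if not ctrl_rows.any():
            raise ValueError(f"no control rows in stratum {dict(zip(by, stratum))}")
        for m in metrics:
            mean = table.loc[ctrl_rows, m].mean()
            if not np.isfinite(mean) or mean == 0:
                raise ValueError(
                    f"control mean for {m!r} in stratum {dict(zip(by, stratum))} is {mean}"
                )
            out.loc[in_stratum, m] = table.loc[in_stratum, m] / mean
    return out


# ---------------------------------------------------------------------------
# Collinearity screen


def collinearity_screen(
    table: pd.DataFrame,
    metrics: Sequence[str] = tuple(METRIC_COLUMNS),
    threshold: float = COLLINEARITY_THRESHOLD,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Pairwise Pearson r matrix with |r| >= threshold pairs flagged.

    Constant columns yield undefined correlations; their pairs are flagged
    as offending so they are never silently retained.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    X = table[list(metrics)].to_numpy(dtype=float)
    n = len(metrics)
    r = np.eye(n)
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = X[:, i], X[:, j]
            if xi.std() == 0 or xj.std() == 0:
                r[i, j] = r[j, i] = np.nan
                flagged.append((metrics[i], metrics[j]))
                continue
            rij = stats.pearsonr(xi, xj).statistic
            r[i, j] = r[j, i] = rij
            if abs(rij) >= threshold:
                flagged.append((metrics[i], metrics[j]))
    return pd.DataFrame(r, index=list(metrics), columns=list(metrics)), flagged


# ---------------------------------------------------------------------------
# Linear discriminant analysis


@dataclass
class LdaModel:
    classes: np.ndarray
    means: np.ndarray  # (n_classes, n_features)
    pooled_cov: np.ndarray
    priors: np.ndarray
    ridged: bool = False

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores delta_k(x), one column per class."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        inv = np.linalg.inv(self.pooled_cov)
        w = self.means @ inv  # (K, p)
        b = -0.5 * np.einsum("kp,kp->k", w, self.means) + np.log(self.priors)
        return X @ w.T + b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision_values(X), axis=1)]


@dataclass
class LdaReport:
    oca: float  # percent
    cvca: float  # percent
    per_class: dict
    model: LdaModel
    flags: list[str] = field(default_factory=list)


def fit_lda(
    X: np.ndarray,
    y: Sequence,
    priors: Optional[np.ndarray] = None,
    ridge: float = 1e-6,
) -> LdaModel:
    """Fit class means and pooled within-class covariance.

    Priors are equal by default.  A singular pooled covariance gets a ridge
    of ``ridge * trace`` on the diagonal and the model is flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    p = X.shape[1]
    if np.any(counts < p + 2):
        raise ValueError(
            f"every class needs >= {p + 2} rows for {p} features; counts: "
            f"{dict(zip(classes.tolist(), counts.tolist()))}"
        )
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    scatter = np.zeros((p, p))
    for c, mu in zip(classes, means):
        d = X[y == c] - mu
        scatter += d.T @ d
    pooled = scatter / (len(X) - len(classes))

    ridged = False
    if np.linalg.cond(pooled) > 1e12 or np.linalg.eigvalsh(pooled)[0] <= 0:
        pooled = pooled + ridge * np.trace(pooled) * np.eye(p)
        ridged = True
    if priors is None:
        priors = np.full(len(classes), 1.0 / len(classes))
    return LdaModel(classes=classes, means=means, pooled_cov=pooled, priors=np.asarray(priors), ridged=ridged)


def lda_classify(
    X: np.ndarray, y: Sequence, priors: Optional[np.ndarray] = None
) -> LdaReport:
    """Overall (resubstitution) and leave-one-out cross-validated accuracy.

    OCA applies the discriminants fitted on the entire data set back to it;
    CVCA refits the model with each observation held out in turn.  Both are
    reported in percent, with per-class accuracies alongside.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    model = fit_lda(X, y, priors=priors)
    pred = model.predict(X)
    oca = float((pred == y).mean() * 100.0)

    loo_correct = np.zeros(len(X), dtype=bool)
    idx = np.arange(len(X))
    for i in idx:
        keep = idx != i
        m = fit_lda(X[keep], y[keep], priors=priors)
        loo_correct[i] = m.predict(X[i : i + 1])[0] == y[i]
    cvca = float(loo_correct.mean() * 100.0)

    per_class = {
        str(c): {
            "oca": float((pred[y == c] == c).mean() * 100.0),
            "cvca": float(loo_correct[y == c].mean() * 100.0),
            "n": int((y == c).sum()),
        }
        for c in model.classes
    }
    flags = ["pooled covariance ridged"] if model.ridged else []
    return LdaReport(oca=oca, cvca=cvca, per_class=per_class, model=model, flags=flags)


# ---------------------------------------------------------------------------
# Metabolic relative-change mapping


@dataclass
class PerturbationReference:
    """Labeled reference samples in the 3-metric relative-change space,
    with per-class centroids, covariances and a coverage quantile for the
    displayed ellipsoids (75% by default)."""

    samples: pd.DataFrame  # columns: class + METABOLIC_COLUMNS deltas
    coverage: float = DEFAULT_COVERAGE
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        need = ["class"] + [f"d_{c}" for c in METABOLIC_COLUMNS]
        missing = [c for c in need if c not in self.samples.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        if not 0 < self.coverage < 1:
            raise ValueError("coverage quantile must lie in (0, 1)")
        self._stats = {}
        for cls, grp in self.samples.groupby("class"):
            vals = grp[[f"d_{c}" for c in METABOLIC_COLUMNS]].to_numpy(dtype=float)
            if len(vals) < 4:
                self.flags.append(f"reference class {cls!r} has < 4 samples; skipped")
                continue
            self._stats[cls] = (vals.mean(axis=0), np.cov(vals.T))

    @classmethod
    def from_csv(cls, path, coverage: float = DEFAULT_COVERAGE) -> "PerturbationReference":
        return cls(samples=pd.read_csv(path), coverage=coverage)

    def class_stats(self) -> dict:
        return dict(self._stats)

    def ellipsoid_radius_sq(self) -> float:
        """Squared Mahalanobis radius of the coverage ellipsoid (chi^2, 3 dof)."""
        return float(stats.chi2.ppf(self.coverage, df=len(METABOLIC_COLUMNS)))

    def nearest_class(self, delta: np.ndarray) -> tuple[str, float]:
        """Nearest reference class by Mahalanobis distance (class covariance)."""
        if not self._stats:
            raise ValueError("reference holds no usable classes")
        best, best_d = None, np.inf
        for cls, (mu, cov) in self._stats.items():
            d2 = float((delta - mu) @ np.linalg.inv(cov) @ (delta - mu))
            if d2 < best_d:
                best, best_d = cls, d2
        return best, float(np.sqrt(best_d))


def metabolic_delta(
    table: pd.DataFrame,
    control_selector: dict,
    reference: Optional[PerturbationReference] = None,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-row fractional changes of the three metabolic metrics vs control.

    Returns the input rows with ``d_<metric> = (x - control_mean) /
    control_mean`` columns appended; control rows themselves are included
    (their deltas average to zero).  With a reference table, each row also
    gets its nearest perturbation class and Mahalanobis distance.
    """
    ctrl = np.ones(len(table), dtype=bool)
    for col, val in control_selector.items():
        ctrl &= (table[col] == val).to_numpy()
    if not ctrl.any():
        raise ValueError(f"no control rows match {control_selector}")

    out = table.copy()
    strata = (
        table[list(by)].apply(tuple, axis=1)
        if by
        else pd.Series([()] * len(table), index=table.index)
    )
    for m in METABOLIC_COLUMNS:
        out[f"d_{m}"] = np.nan
    for stratum in strata.unique():
        in_stratum = (strata == stratum).to_numpy()
        ctrl_rows = in_stratum & ctrl
        if not ctrl_rows.any():
            raise ValueError(f"no control rows in stratum {dict(zip(by, stratum))}")
        for m in METABOLIC_COLUMNS:
            mean = table.loc[ctrl_rows, m].mean()
            if not np.isfinite(mean) or mean == 0:
                raise ValueError(f"control mean for {m!r} is {mean}")
            out.loc[in_stratum, f"d_{m}"] = (table.loc[in_stratum, m] - mean) / mean

    if reference is not None:
        deltas = out[[f"d_{c}" for c in METABOLIC_COLUMNS]].to_numpy(dtype=float)
        nearest, dist = [], []
        for row in deltas:
            cls, d = reference.nearest_class(row)
            nearest.append(cls)
            dist.append(d)
        out["nearest_class"] = nearest
        out["mahalanobis"] = dist
    return out


def export_visne_csv(table: pd.DataFrame, path, metrics: Sequence[str] = tuple(METRIC_COLUMNS)) -> None:
    """Tidy CSV of normalized metrics for external embedding tools."""
    keep = [c for c in table.columns if c not in metrics] + list(metrics)
    table[keep].to_csv(path, index=False)
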
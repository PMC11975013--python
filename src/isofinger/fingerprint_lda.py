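"""delta13C-EAA fingerprinting by linear discriminant analysis.

Essential amino acids carry multivariate carbon-isotope patterns
("fingerprints") diagnostic of their biosynthetic origin.  A linear
discriminant model fitted on reference (endmember) classes — bacteria,
fungi, plants — defines axes that maximally separate those origins;
consumer tissues projected onto the axes can then be read against the
reference classes.

The discriminant axes are computed from first principles as the
generalized eigenvectors of the between-class covariance against the
pooled within-class covariance, scaled so each axis has unit pooled
within-class variance (the convention used by classical canonical
discriminant analysis, so score-space within-class geometry is spherical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import chi2

from .isotope_io import EAA_CODES, SchemaError, ValidationError

SCALING_CONVENTION = "unit-pooled-within-variance"

TRAINING_COLUMNS = ("sample_id", "class_label", "analyte", "delta13C")


@dataclass(frozen=True)
class EndmemberTrainingSet:
    """Labelled delta13C-EAA profiles for the classifier endmember classes.

    Attributes
    ----------
    X : ndarray, shape (n_profiles, n_analytes)
        Per-profile mean delta13C values (permil vs VPDB).
    labels : ndarray of str
        Class label per profile (e.g. ``bacteria``, ``fungi``, ``plants``).
    analytes : tuple of str
        Shared analyte order of the columns of ``X``.
    sample_ids : tuple of str
        Profile identifiers aligned with the rows of ``X``.
    """

    X: np.ndarray
    labels: np.ndarray
    analytes: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        labels = np.asarray(self.labels)
        if X.ndim != 2 or X.shape[0] != labels.shape[0]:
            raise ValidationError("X and labels are misaligned")
        if X.shape[1] != len(self.analytes):
            raise ValidationError("X columns and analyte order are misaligned")
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) < 2:
            raise ValidationError("training set needs at least 2 classes")
        if (counts < 2).any():
            small = classes[counts < 2].tolist()
            raise ValidationError(f"every class needs >= 2 profiles; too few in {small}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", labels)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(np.unique(self.labels))

    def with_calibration(self, offsets: Mapping[str, float]) -> "EndmemberTrainingSet":
        """Apply a per-analyte additive calibration offset (permil).

        Interlaboratory calibration of training data is exposed only as
        this additive shift; analytes absent from ``offsets`` are left
        unchanged.
        """
        shift = np.array([float(offsets.get(a, 0.0)) for a in self.analytes])
        return EndmemberTrainingSet(self.X + shift, self.labels, self.analytes,
                                    self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, lab, row in zip(self.sample_ids, self.labels, self.X):
            for a, v in zip(self.analytes, row):
                rows.append((sid, lab, a, v))
        return pd.DataFrame(rows, columns=list(TRAINING_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   analytes: Sequence[str] | None = None) -> "EndmemberTrainingSet":
        missing = [c for c in TRAINING_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        wide = df.pivot_table(index=["sample_id", "class_label"], columns="analyte",
                              values="delta13C", aggfunc="first")
        if analytes is None:
            analytes = [a for a in EAA_CODES if a in wide.columns] or sorted(wide.columns)
        missing_a = [a for a in analytes if a not in wide.columns]
        if missing_a:
            raise ValidationError(f"analyte(s) absent from training data: {missing_a}")
        wide = wide.loc[:, list(analytes)]
        if wide.isna().any().any():
            raise ValidationError("training profiles do not share a common analyte set")
        meta = wide.index.to_frame(index=False)
        return cls(wide.to_numpy(float), meta["class_label"].to_numpy(),
                   tuple(analytes), tuple(meta["sample_id"]))


def read_training(path: str | Path, delimiter: str | None = None) -> EndmemberTrainingSet:
    """Read an endmember training table (long format, CSV/TSV)."""
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    return EndmemberTrainingSet.from_frame(df)


@dataclass
class LDAModel:
    """Fitted linear discriminant axes and class statistics."""

    analytes: tuple[str, ...]
    classes: tuple[str, ...]
    grand_centroid: np.ndarray          # (p,)
    class_centroids: np.ndarray         # (g, p)
    pooled_cov: np.ndarray              # (p, p), within-class covariance
    coef: np.ndarray                    # (p, k) discriminant coefficients
    eigenvalues: np.ndarray             # (k,), non-increasing, >= 0
    scaling: str = SCALING_CONVENTION
    ridge: float = 0.0

    @property
    def n_axes(self) -> int:
        return self.coef.shape[1]

    def class_scores(self) -> np.ndarray:
        """Projected class centroids, shape (g, k)."""
        return (self.class_centroids - self.grand_centroid) @ self.coef

    def to_dict(self) -> dict:
        return {
            "analytes": list(self.analytes),
            "classes": list(self.classes),
            "grand_centroid": self.grand_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "coef": self.coef.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "scaling": self.scaling,
            "ridge": self.ridge,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            analytes=tuple(d["analytes"]),
            classes=tuple(d["classes"]),
            grand_centroid=np.asarray(d["grand_centroid"], float),
            class_centroids=np.asarray(d["class_centroids"], float),
            pooled_cov=np.asarray(d["pooled_cov"], float),
            coef=np.asarray(d["coef"], float),
            eigenvalues=np.asarray(d["eigenvalues"], float),
            scaling=d.get("scaling", SCALING_CONVENTION),
            ridge=float(d.get("ridge", 0.0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LDAModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_lda(training: EndmemberTrainingSet, ridge: float = 0.0) -> LDAModel:
    """Fit canonical linear discriminant axes on an endmember training set.

    Solves the symmetric-definite generalized eigenproblem ``B v = lambda
    W v`` where ``B`` is the between-class covariance (weighted by class
    size, divided by g - 1) and ``W`` the pooled within-class covariance
    plus ``ridge * I``.  Axes are sorted by decreasing eigenvalue, limited
    to ``min(g - 1, p)``, scaled to unit pooled within-class variance, and
    sign-fixed so each axis's largest-magnitude coefficient is positive.

    Parameters
    ----------
    training : EndmemberTrainingSet
    ridge : float
        Non-negative diagonal regularization added to the within-class
        covariance.  Default 0 (no silent regularization); a singular
        within-class covariance raises an error advising a positive ridge.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    X, labels = training.X, training.labels
    classes = training.classes
    g, (n, p) = len(classes), X.shape

    grand = X.mean(axis=0)
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    counts = np.array([(labels == c).sum() for c in classes])

    Sw = np.zeros((p, p))
    for c, mu in zip(classes, centroids):
        d = X[labels == c] - mu
        Sw += d.T @ d
    W = Sw / (n - g) + ridge * np.eye(p)
    diffs = centroids - grand
    B = (counts[:, None] * diffs).T @ diffs / (g - 1)

    try:
        np.linalg.cholesky(W)
        evals, evecs = scipy.linalg.eigh(B, W)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular; refit with a small "
            "positive ridge (e.g. ridge=1e-6)"
        ) from exc

    order = np.argsort(evals)[::-1]
    k = min(g - 1, p)
    evals = np.clip(evals[order][:k], 0.0, None)
    coef = evecs[:, order][:, :k]
    # scipy.linalg.eigh(B, W) normalizes v' W v = I, i.e. unit pooled
    # within-class variance per axis, which is the declared convention.
    for j in range(k):
        if coef[np.argmax(np.abs(coef[:, j])), j] < 0:
            coef[:, j] = -coef[:, j]

    return LDAModel(analytes=training.analytes, classes=classes,
                    grand_centroid=grand, class_centroids=centroids,
                    pooled_cov=W, coef=coef, eigenvalues=evals, ridge=float(ridge))


def _as_matrix(model: LDAModel, samples) -> tuple[np.ndarray, list[str] | None]:
    """Coerce profiles (tidy DataFrame or ndarray) to the model's analyte order."""
    if isinstance(samples, pd.DataFrame):
        from .isotope_io import profiles_to_matrix

        try:
            meta, X = profiles_to_matrix(samples, analytes=model.analytes)
        except ValidationError as exc:
            raise ValidationError(f"projection input: {exc}") from exc
        return X, meta["sample_id"].tolist()
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[1] != len(model.analytes):
        raise ValidationError(
            f"expected {len(model.analytes)} analyte columns "
            f"({', '.join(model.analytes)}), got {X.shape[1]}"
        )
    return X, None


def project(model: LDAModel, samples) -> pd.DataFrame:
    """Project samples onto the discriminant axes.

    ``samples`` is either a tidy profile table (see
    :func:`isofinger.isotope_io.aggregate_replicates`) or an array whose
    columns follow ``model.analytes``.  Scores are
    ``(x - grand_centroid) @ coef``.  Returns a DataFrame with columns
    ``LD1..LDk`` and, when available, ``sample_id``.
    """
    X, ids = _as_matrix(model, samples)
    scores = (X - model.grand_centroid) @ model.coef
    cols = [f"LD{i + 1}" for i in range(model.n_axes)]
    out = pd.DataFrame(scores, columns=cols)
    if ids is not None:
        out.insert(0, "sample_id", ids)
    return out


def score_matrix(scores: pd.DataFrame) -> np.ndarray:
    """Extract the (n, k) LD-coordinate matrix from a scores frame."""
    cols = [c for c in scores.columns if c.startswith("LD")]
    return scores.loc[:, cols].to_numpy(float)


def classify(model: LDAModel, sample, priors: Mapping[str, float] | None = None
             ) -> dict[str, float]:
    """Gaussian equal-covariance posteriors for one sample.

    Densities are evaluated in score space, where the pooled within-class
    covariance is the identity by the scaling convention; the posterior for
    class c is proportional to ``prior_c * exp(-||z - z_c||^2 / 2)``.
    Priors default to uniform over the training classes (class sizes
    reflect data availability, not prevalence).
    """
    if priors is None:
        priors = {c: 1.0 / len(model.classes) for c in model.classes}
    pr = np.array([float(priors.get(c, 0.0)) for c in model.classes])
    if (pr < 0).any() or not np.isclose(pr.sum(), 1.0, atol=1e-9):
        raise ValueError("priors must be non-negative and sum to 1 over the model classes")
    z = score_matrix(project(model, np.atleast_2d(sample)))[0]
    zc = model.class_scores()
    log_post = np.log(np.where(pr > 0, pr, np.nan)) - 0.5 * ((z - zc) ** 2).sum(axis=1)
    log_post = np.where(np.isnan(log_post), -np.inf, log_post)
    log_post -= log_post.max()
    p = np.exp(log_post)
    p /= p.sum()
    return dict(zip(model.classes, p))


@dataclass(frozen=True)
class Ellipse:
    """Confidence ellipse in 2-D score space."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]      # major, minor
    angle: float                        # radians, major axis vs LD1
    level: float

    def contains(self, point: Sequence[float]) -> bool:
        d = np.asarray(point, float) - np.asarray(self.center)
        c, s = np.cos(self.angle), np.sin(self.angle)
        u = np.array([c * d[0] + s * d[1], -s * d[0] + c * d[1]])
        a, b = self.semi_axes
        return (u[0] / a) ** 2 + (u[1] / b) ** 2 <= 1.0


def confidence_ellipse(scores: np.ndarray | pd.DataFrame, level: float = 0.95) -> Ellipse:
    """Gaussian confidence ellipse for one group of 2-D scores.

    The ellipse is centred on the group mean with the sample covariance
    scaled by the chi-square quantile at ``level`` (2 degrees of freedom),
    so squared semi-axis lengths are ``eigenvalue * chi2.ppf(level, 2)``.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    Z = score_matrix(scores) if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    if Z.ndim != 2 or Z.shape[1] != 2:
        raise ValidationError("confidence_ellipse requires a 2-axis score space")
    if Z.shape[0] < 3:
        raise ValidationError("need >= 3 samples for a confidence ellipse")
    mean = Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 0:
        raise ValidationError("degenerate score covariance; ellipse undefined")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = chi2.ppf(level, df=2)
    semi = np.sqrt(evals * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=(float(mean[0]), float(mean[1])),
                   semi_axes=(float(semi[0]), float(semi[1])),
                   angle=angle, level=level)
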
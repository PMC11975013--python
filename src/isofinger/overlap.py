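"""Bhattacharyya overlap between groups in discriminant-score space.

The Bhattacharyya coefficient BC = integral of sqrt(p(x) q(x)) dx measures
the similarity of two probability distributions: 1 for identical
distributions, 0 for disjoint support.  For two multivariate Gaussians it
has the closed form BC = exp(-D_B) with

    D_B = 1/8 (mu_A - mu_B)' S^-1 (mu_A - mu_B)
          + 1/2 ln( det S / sqrt(det S_A det S_B) ),    S = (S_A + S_B) / 2.

Group distributions are estimated from discriminant scores assuming
Gaussianity (a modelling choice forced by the small per-group sample sizes
typical of this design), optionally with shrinkage of the covariance
toward its diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd


class DegenerateCovarianceError(ValueError):
    """Covariance is not positive definite; advise shrinkage."""


@dataclass(frozen=True)
class GroupDistribution:
    """Gaussian summary of one group (e.g. treatment x organ) in score space."""

    group_id: Hashable
    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, float)
        cov = np.asarray(self.cov, float)
        if cov.shape != (mean.size, mean.size) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric and match the mean dimension")
        if self.n < 2:
            raise ValueError("group distributions need n >= 2")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


@dataclass
class OverlapResult:
    """Pairwise Bhattacharyya distances/coefficients and their median."""

    pairs: pd.DataFrame          # group_a, group_b, n_a, n_b, d_b, bc
    median_bc: float
    scheme: str


def _check_pd(cov: np.ndarray, label: str) -> None:
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DegenerateCovarianceError(
            f"covariance for {label} is not positive definite; apply shrinkage "
            "(empirical_group(..., shrinkage > 0)) or pool groups"
        ) from exc


def gaussian_bhattacharyya(mean_a, cov_a, mean_b, cov_b) -> tuple[float, float]:
    """Closed-form Bhattacharyya distance and coefficient of two Gaussians.

    Returns ``(D_B, BC)`` with ``BC = exp(-D_B)``.  Raises
    :class:`DegenerateCovarianceError` for non-positive-definite inputs.
    """
    mean_a, mean_b = np.atleast_1d(np.asarray(mean_a, float)), np.atleast_1d(np.asarray(mean_b, float))
    cov_a, cov_b = np.atleast_2d(np.asarray(cov_a, float)), np.atleast_2d(np.asarray(cov_b, float))
    _check_pd(cov_a, "A")
    _check_pd(cov_b, "B")
    pooled = 0.5 * (cov_a + cov_b)
    _check_pd(pooled, "(A+B)/2")
    diff = mean_a - mean_b
    maha = float(diff @ np.linalg.solve(pooled, diff))
    _, ld_pooled = np.linalg.slogdet(pooled)
    _, ld_a = np.linalg.slogdet(cov_a)
    _, ld_b = np.linalg.slogdet(cov_b)
    d_b = maha / 8.0 + 0.5 * (ld_pooled - 0.5 * (ld_a + ld_b))
    d_b = max(d_b, 0.0)
    return d_b, float(np.exp(-d_b))


def empirical_group(scores: np.ndarray | pd.DataFrame, group_id: Hashable = "group",
                    shrinkage: float = 0.0) -> GroupDistribution:
    """Estimate a group's Gaussian score-space distribution.

    The covariance uses the (n - 1) denominator and is then shrunk toward
    its own diagonal: ``(1 - shrinkage) * S + shrinkage * diag(S)``.  With
    ``shrinkage = 1`` the covariance is exactly diagonal; with 0 it is the
    plain sample covariance.
    """
    if not (0.0 <= shrinkage <= 1.0):
        raise ValueError("shrinkage must be in [0, 1]")
    if isinstance(scores, pd.DataFrame):
        from .fingerprint_lda import score_matrix

        Z = score_matrix(scores)
    else:
        Z = np.asarray(scores, float)
        if Z.ndim == 1:
            Z = Z[:, None]
    n = Z.shape[0]
    if n < 2:
        raise ValueError("need n >= 2 scores to estimate a distribution")
    mean = Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False).reshape(Z.shape[1], Z.shape[1])
    cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    return GroupDistribution(group_id=group_id, mean=mean, cov=cov, n=n)


def empirical_groups_pooled(blocks: "dict[Hashable, np.ndarray]") -> list[GroupDistribution]:
    """Estimate group means with a single pooled within-group covariance.

    Under the equal-covariance assumption already made by the discriminant
    model, the within-group covariance is estimated once from the residuals
    of every group (summed cross-products divided by n_total - n_groups)
    and shared across groups.  With few samples per group this is far more
    stable than per-group covariances and leaves the Bhattacharyya distance
    driven by mean separation alone.
    """
    if len(blocks) < 1:
        raise ValueError("need at least one group")
    resid, meta = [], []
    for gid, Z in blocks.items():
        Z = np.asarray(Z, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] < 2:
            raise ValueError(f"group {gid!r} needs n >= 2 scores")
        mu = Z.mean(axis=0)
        resid.append(Z - mu)
        meta.append((gid, mu, Z.shape[0]))
    R = np.vstack(resid)
    df = R.shape[0] - len(blocks)
    if df < 1:
        raise ValueError("no residual degrees of freedom for a pooled covariance")
    pooled = R.T @ R / df
    return [GroupDistribution(gid, mu, pooled, n) for gid, mu, n in meta]


def pairwise_overlap(groups: Sequence[GroupDistribution],
                     scheme: str = "matched_organ") -> OverlapResult:
    """Pairwise Bhattacharyya overlap under a declared pairing scheme.

    ``matched_organ`` expects group ids of the form ``(treatment, organ)``
    and pairs each GF organ with the same CVZ organ; ``all_pairs``
    enumerates every unordered pair.  The headline summary is the median
    BC over the scheme's pairs.
    """
    if scheme == "matched_organ":
        by_id = {g.group_id: g for g in groups}
        organs = sorted({gid[1] for gid in by_id if isinstance(gid, tuple)})
        pairs = [ (by_id[("GF", o)], by_id[("CVZ", o)])
                  for o in organs if ("GF", o) in by_id and ("CVZ", o) in by_id ]
    elif scheme == "all_pairs":
        pairs = [(groups[i], groups[j])
                 for i in range(len(groups)) for j in range(i + 1, len(groups))]
    else:
        raise ValueError(f"unknown pairing scheme {scheme!r}")
    if not pairs:
        raise ValueError(f"pairing scheme {scheme!r} yields no pairs")

    rows = []
    for a, b in pairs:
        d_b, bc = gaussian_bhattacharyya(a.mean, a.cov, b.mean, b.cov)
        rows.append((str(a.group_id), str(b.group_id), a.n, b.n, d_b, bc))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "d_b", "bc"])
    return OverlapResult(pairs=table, median_bc=float(table["bc"].median()), scheme=scheme)
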
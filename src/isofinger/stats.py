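"""Group-comparison statistics for diet-normalized delta13C-EAA data.

Implements the inference toolkit used on offset and score tables:

* two-way ANOVA with interaction (Type I on balanced designs, where all
  classical types coincide; Type II sums of squares on unbalanced data);
* one-way MANOVA via Pillai's trace with the standard F approximation;
* Tukey-Kramer mean separation rendered as a compact letter display;
* a box-constrained least-squares estimator of the gut-microbial EAA
  contribution fraction f from per-amino-acid offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .isotope_io import ValidationError


def format_p(p: float) -> str:
    """Render a p-value, reporting values below 1e-4 as '< 0.0001'."""
    if np.isnan(p):
        return "NA"
    return "< 0.0001" if p < 1e-4 else f"{p:.4g}"


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTerm:
    term: str
    df: int
    ss: float
    ms: float
    f: float            # nan when the residual MS is 0 (degenerate data)
    p: float
    degenerate: bool = False


@dataclass
class AnovaResult:
    terms: list[AnovaTerm]
    residual: AnovaTerm
    ss_type: str

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [(t.term, t.df, t.ss, t.ms, t.f, t.p) for t in self.terms]
        rows.append((self.residual.term, self.residual.df, self.residual.ss,
                     self.residual.ms, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["term", "df", "ss", "ms", "F", "p"])


def _dummy(levels: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy block (n, k-1) for a factor."""
    cats = np.unique(values)
    return (values[:, None] == cats[None, 1:]).astype(float)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def one_way_anova(values: Sequence[float], labels: Sequence) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA."""
    y = np.asarray(values, float)
    lab = np.asarray(labels)
    cats = np.unique(lab)
    if len(cats) < 2:
        raise ValidationError("one-way ANOVA needs >= 2 levels")
    n = y.size
    grand = y.mean()
    ss_between = sum(((y[lab == c].mean() - grand) ** 2) * (lab == c).sum() for c in cats)
    ss_within = sum(((y[lab == c] - y[lab == c].mean()) ** 2).sum() for c in cats)
    df_b, df_w = len(cats) - 1, n - len(cats)
    ms_b = ss_between / df_b
    if df_w <= 0:
        raise ValidationError("no residual degrees of freedom")
    ms_w = ss_within / df_w
    degenerate = ms_w == 0.0
    f = np.nan if degenerate else ms_b / ms_w
    p = np.nan if degenerate else float(sps.f.sf(f, df_b, df_w))
    term = AnovaTerm("group", df_b, float(ss_between), ms_b, f, p, degenerate)
    resid = AnovaTerm("residual", df_w, float(ss_within), ms_w, np.nan, np.nan)
    return AnovaResult([term], resid, ss_type="I")


def two_way_anova(data: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction.

    On balanced designs the sums of squares are the classical (Type I =
    Type II = Type III) decomposition; unbalanced designs use Type II
    (each main effect adjusted for the other, interaction adjusted for
    both), computed by model comparison on least-squares fits.

    Raises an error when any factor cell is empty, since the interaction
    is then inestimable.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValidationError(f"column {col!r} not found")
    y = data[value].to_numpy(float)
    a = data[factor_a].astype(str).to_numpy()
    b = data[factor_b].astype(str).to_numpy()
    a_levels, b_levels = np.unique(a), np.unique(b)
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValidationError("each factor needs >= 2 levels")
    cell_counts = pd.crosstab(a, b)
    if (cell_counts == 0).any().any():
        raise ValidationError("empty factor cell: interaction model is inestimable")
    n = y.size
    df_a, df_b_ = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b_
    df_res = n - len(a_levels) * len(b_levels)
    if df_res < 0:
        raise ValidationError("more cells than observations")

    ones = np.ones((n, 1))
    Xa, Xb = _dummy(a_levels, a), _dummy(b_levels, b)
    inter = (Xa[:, :, None] * Xb[:, None, :]).reshape(n, -1)
    rss_a = _rss(np.hstack([ones, Xa]), y)
    rss_b = _rss(np.hstack([ones, Xb]), y)
    rss_ab_main = _rss(np.hstack([ones, Xa, Xb]), y)
    rss_full = _rss(np.hstack([ones, Xa, Xb, inter]), y)

    ss_a = max(rss_b - rss_ab_main, 0.0)
    ss_b = max(rss_a - rss_ab_main, 0.0)
    ss_ab = max(rss_ab_main - rss_full, 0.0)
    ss_res = rss_full

    balanced = cell_counts.to_numpy().std() == 0
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    # zero residual variance up to numerical noise -> F undefined, flagged
    scale = max(1.0, float(np.mean(y ** 2)))
    degenerate = not (ms_res > 1e-12 * scale)

    def term(name: str, ss: float, df: int) -> AnovaTerm:
        ms = ss / df
        if degenerate:
            return AnovaTerm(name, df, ss, ms, np.nan, np.nan, True)
        f = ms / ms_res
        return AnovaTerm(name, df, ss, ms, f, float(sps.f.sf(f, df, df_res)))

    terms = [term(factor_a, ss_a, df_a), term(factor_b, ss_b, df_b_),
             term(f"{factor_a}:{factor_b}", ss_ab, df_ab)]
    resid = AnovaTerm("residual", df_res, ss_res, ms_res, np.nan, np.nan, degenerate)
    return AnovaResult(terms, resid, ss_type="I" if balanced else "II")


# ---------------------------------------------------------------------------
# MANOVA (Pillai's trace)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PillaiResult:
    """One-way MANOVA summarized by Pillai's trace V = tr(H (H + E)^-1)."""

    pillai: float
    df_hypothesis: int
    df_error: int
    f: float
    df_num: float
    df_den: float
    p: float

    def formatted_p(self) -> str:
        return format_p(self.p)


def pillai_manova(X: np.ndarray, labels: Sequence) -> PillaiResult:
    """One-way MANOVA on a (n, p) response matrix with group labels.

    Pillai's trace is computed from the between-group (H) and within-group
    (E) cross-product matrices; the p-value uses the standard F
    approximation, which is exact when min(p, g - 1) = 1.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    lab = np.asarray(labels)
    cats = np.unique(lab)
    g, (n, p) = len(cats), X.shape
    if g < 2:
        raise ValidationError("MANOVA needs >= 2 groups")
    if n <= p + g - 1:
        raise ValidationError(
            f"total n ({n}) must exceed responses + groups - 1 ({p + g - 1})")
    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for c in cats:
        Xc = X[lab == c]
        d = (Xc.mean(axis=0) - grand)[:, None]
        H += Xc.shape[0] * (d @ d.T)
        r = Xc - Xc.mean(axis=0)
        E += r.T @ r
    T = H + E
    if np.linalg.matrix_rank(T) < p:
        raise ValidationError("singular total cross-product matrix (H + E)")
    V = float(np.trace(np.linalg.solve(T, H)))
    V = min(max(V, 0.0), float(min(p, g - 1)))

    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2.0
    nn = (n - g - p - 1) / 2.0
    df_num = s * (2 * m + s + 1)
    df_den = s * (2 * nn + s + 1)
    if df_den <= 0:
        raise ValidationError("insufficient error degrees of freedom for the F approximation")
    if V >= s:
        f_stat, pval = np.inf, 0.0
    else:
        f_stat = (df_den / df_num) * (V / (s - V))
        pval = float(sps.f.sf(f_stat, df_num, df_den))
    return PillaiResult(pillai=V, df_hypothesis=g - 1, df_error=n - g,
                        f=float(f_stat), df_num=df_num, df_den=df_den, p=pval)


# ---------------------------------------------------------------------------
# Tukey-Kramer compact letter display
# ---------------------------------------------------------------------------

@dataclass
class LetterDisplay:
    """Group means in descending order with compact significance letters.

    Two groups share at least one letter iff their Tukey-Kramer comparison
    is non-significant at the declared alpha.
    """

    table: pd.DataFrame          # columns: level, mean, n, letters
    alpha: float
    significant_pairs: frozenset = field(default_factory=frozenset)

    def letters(self) -> dict[str, str]:
        return dict(zip(self.table["level"], self.table["letters"]))


def tukey_letter_display(means: Mapping[str, float], ms_resid: float, df_resid: int,
                         n_per_group: Mapping[str, int] | int,
                         alpha: float = 0.05) -> LetterDisplay:
    """Tukey-Kramer all-pairwise comparisons with letter assignment.

    A pair (i, j) differs significantly when
    ``|m_i - m_j| > q_{alpha, k, df} * sqrt(MS_res / 2 * (1/n_i + 1/n_j))``
    with ``q`` the studentized range quantile.  Letters are assigned by the
    insert-and-absorb algorithm on descending means (ties broken by level
    name for determinism).
    """
    if ms_resid <= 0:
        raise ValidationError("residual mean square must be positive")
    if df_resid < 1:
        raise ValidationError("residual df must be >= 1")
    levels = sorted(means, key=lambda k: (-means[k], str(k)))
    k = len(levels)
    if k < 2:
        raise ValidationError("need >= 2 groups")
    if isinstance(n_per_group, int):
        n_per_group = {lv: n_per_group for lv in levels}
    q_crit = sps.studentized_range.ppf(1 - alpha, k, df_resid)

    sig = set()
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            se = np.sqrt(ms_resid / 2.0 * (1.0 / n_per_group[a] + 1.0 / n_per_group[b]))
            if abs(means[a] - means[b]) > q_crit * se:
                sig.add(frozenset((a, b)))

    # insert-and-absorb: start with one letter covering all, split on each
    # significant pair, drop sets absorbed by supersets
    letter_sets: list[set] = [set(levels)]
    for pair in sig:
        a, b = tuple(pair)
        new_sets: list[set] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        letter_sets = [s for s in new_sets if s]
        letter_sets = [s for i, s in enumerate(letter_sets)
                       if not any(s < t or (s == t and i > j)
                                  for j, t in enumerate(letter_sets) if i != j)]

    # order letters by the highest-mean member they contain
    letter_sets.sort(key=lambda s: min(levels.index(lv) for lv in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned = {lv: "" for lv in levels}
    for idx, s in enumerate(letter_sets):
        for lv in levels:
            if lv in s:
                assigned[lv] += alphabet[idx % 26]

    table = pd.DataFrame({
        "level": levels,
        "mean": [means[lv] for lv in levels],
        "n": [n_per_group[lv] for lv in levels],
        "letters": [assigned[lv] for lv in levels],
    })
    return LetterDisplay(table=table, alpha=alpha, significant_pairs=frozenset(sig))


# ---------------------------------------------------------------------------
# Microbial contribution fraction
# ---------------------------------------------------------------------------

@dataclass
class ContributionEstimate:
    """Box-constrained least-squares estimate of the microbial fraction f.

    Model: offset_a = f * microbe_offset_a + noise, fitted across amino
    acids (optionally stacked over organs); the interval is a bootstrap
    over amino acids.
    """

    f: float
    residuals: np.ndarray
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int
    per_analyte: dict[str, float] = field(default_factory=dict)


def estimate_contribution(offsets: Sequence[float], microbe_offset: Sequence[float],
                          analytes: Sequence[str] | None = None,
                          bounds: tuple[float, float] = (0.0, 1.0),
                          n_bootstrap: int = 1000, seed: int = 0) -> ContributionEstimate:
    """Estimate the gut-microbial EAA contribution fraction f.

    Parameters
    ----------
    offsets : array-like
        Per-amino-acid consumer offsets (permil), already referenced to the
        diet and, where applicable, corrected for incomplete turnover
        (see :func:`turnover_corrected_offsets`) and for the germ-free
        control.
    microbe_offset : array-like
        Per-amino-acid (delta_microbe - delta_diet) source contrasts
        (permil), aligned with ``offsets``.
    """
    d = np.asarray(offsets, float)
    m = np.asarray(microbe_offset, float)
    if d.shape != m.shape or d.ndim != 1:
        raise ValidationError("offsets and microbe_offset must be 1-D and aligned")
    if d.size < 2 or np.count_nonzero(m) < 2:
        raise ValidationError(
            "need >= 2 amino acids with nonzero microbe offset; f is unidentifiable")
    lo, hi = bounds

    def _fit(dd: np.ndarray, mm: np.ndarray) -> float:
        denom = float(mm @ mm)
        if denom == 0.0:
            return np.nan
        return float(np.clip((dd @ mm) / denom, lo, hi))

    f_hat = _fit(d, m)
    residuals = d - f_hat * m

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(int(n_bootstrap)):
        idx = rng.integers(0, d.size, size=d.size)
        fb = _fit(d[idx], m[idx])
        if not np.isnan(fb):
            boots.append(fb)
    if boots:
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    else:
        ci_low = ci_high = f_hat

    per_analyte = {}
    if analytes is not None:
        for a, dd, mm in zip(analytes, d, m):
            per_analyte[a] = float(np.clip(dd / mm, lo, hi)) if mm != 0 else np.nan

    return ContributionEstimate(f=f_hat, residuals=residuals,
                                ci_low=float(ci_low), ci_high=float(ci_high),
                                n_bootstrap=int(n_bootstrap), seed=int(seed),
                                per_analyte=per_analyte)


def turnover_corrected_offsets(offsets: pd.DataFrame, turnover: Mapping[str, float],
                               diet_shift: Mapping[str, float]) -> pd.DataFrame:
    """Correct diet offsets for incomplete isotopic turnover.

    Under the single-pool incorporation model the raw offset of an organ
    with replacement fraction p contains a memory term from the pre-switch
    diet: ``offset = p * signal + (1 - p) * diet_shift`` where
    ``diet_shift = delta_old_diet - delta_new_diet`` per analyte.  The
    corrected offset ``(offset - (1 - p) * diet_shift) / p`` isolates the
    fully-turned-over signal.  Organs with p = 0 carry no new-diet signal
    and are dropped.
    """
    out = offsets.copy()
    p = out["organ"].map(lambda o: float(turnover.get(o, np.nan)))
    if p.isna().any():
        bad = sorted(out.loc[p.isna(), "organ"].unique())
        raise ValidationError(f"no turnover fraction for organ(s): {bad}")
    shift = out["analyte"].map(lambda a: float(diet_shift.get(a, 0.0)))
    keep = p > 0
    out = out.loc[keep].copy()
    out["offset"] = (offsets.loc[keep, "offset"] - (1.0 - p[keep]) * shift[keep]) / p[keep]
    return out
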
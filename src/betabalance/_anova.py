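"""Additive two-way ANOVA and Tukey HSD for balanced designs.

The whole statistical core of the package runs on balanced two-way tables
(factor A = condition of interest, factor B = participant) with an additive
model (no interaction term), so the sums of squares have closed forms in the
cell/level means.  The implementation is vectorised over a trailing axis so
the same code drives both the scalar time-bin ANOVAs and the per-coefficient
wavelet ANOVAs (160 coefficients at once).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["AnovaResult", "additive_two_way_anova", "tukey_hsd"]


@dataclass
class AnovaResult:
    """Result of an additive two-way ANOVA, optionally with Tukey post hocs.

    ``factor_F`` / ``factor_p`` map factor name -> statistic.  ``posthoc`` is
    a list of pairwise contrast records (filled by :func:`tukey_hsd`).
    """

    factor_F: dict
    factor_p: dict
    ss: dict
    df: dict
    mse: float
    posthoc: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, F in self.factor_F.items():
            if np.any(np.asarray(F) < -1e-12):
                raise ValueError(f"negative F statistic for factor {name!r}")


def _check_balanced(a_codes: np.ndarray, b_codes: np.ndarray) -> tuple[int, int, int]:
    a_levels = np.unique(a_codes)
    b_levels = np.unique(b_codes)
    counts = np.zeros((a_levels.size, b_levels.size), dtype=int)
    ai = np.searchsorted(a_levels, a_codes)
    bi = np.searchsorted(b_levels, b_codes)
    np.add.at(counts, (ai, bi), 1)
    if counts.min() < 1 or counts.max() != counts.min():
        raise ValueError("design is unbalanced: unequal cell counts")
    return a_levels.size, b_levels.size, int(counts[0, 0])


def additive_two_way_anova(
    values: np.ndarray,
    factor_a,
    factor_b,
    names: tuple[str, str] = ("A", "B"),
) -> AnovaResult:
    """Additive (no-interaction) two-way ANOVA on a balanced design.

    Parameters
    ----------
    values : array, shape (n,) or (n, m)
        Observations; a trailing axis runs the same ANOVA on m variables at
        once (``factor_F`` entries are then arrays of length m).
    factor_a, factor_b : array-like, length n
        Level labels for the two factors.  Every (a, b) cell must contain the
        same number of observations (>= 1).
    """
    values = np.asarray(values, dtype=float)
    a_codes = np.asarray(factor_a)
    b_codes = np.asarray(factor_b)
    if values.shape[0] != a_codes.shape[0] or a_codes.shape[0] != b_codes.shape[0]:
        raise ValueError("values and factor labels must have equal length")
    n_a, n_b, n_rep = _check_balanced(a_codes, b_codes)
    n = values.shape[0]
    if n_a < 2 or n_b < 2:
        # Reduce gracefully: a single-level factor contributes zero SS and df.
        pass

    grand = values.mean(axis=0)
    a_levels = np.unique(a_codes)
    b_levels = np.unique(b_codes)
    mean_a = np.stack([values[a_codes == lv].mean(axis=0) for lv in a_levels])
    mean_b = np.stack([values[b_codes == lv].mean(axis=0) for lv in b_levels])

    ss_total = ((values - grand) ** 2).sum(axis=0)
    ss_a = (n / n_a) * ((mean_a - grand) ** 2).sum(axis=0)
    ss_b = (n / n_b) * ((mean_b - grand) ** 2).sum(axis=0)
    ss_resid = ss_total - ss_a - ss_b

    df_a = n_a - 1
    df_b = n_b - 1
    df_resid = n - 1 - df_a - df_b
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the additive model")

    mse = ss_resid / df_resid
    # Guard: rounding can leave a tiny negative residual SS on exact fits.
    mse = np.maximum(mse, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        F_a = np.where(mse > 0, (ss_a / max(df_a, 1)) / np.where(mse > 0, mse, 1.0), np.inf)
        F_b = np.where(mse > 0, (ss_b / max(df_b, 1)) / np.where(mse > 0, mse, 1.0), np.inf)
    # Zero effect with zero residual is F = 0, not inf.
    F_a = np.where((ss_a <= 1e-300) & (mse <= 0), 0.0, F_a)
    F_b = np.where((ss_b <= 1e-300) & (mse <= 0), 0.0, F_b)
    p_a = stats.f.sf(F_a, max(df_a, 1), df_resid)
    p_b = stats.f.sf(F_b, max(df_b, 1), df_resid)
    if df_a == 0:
        F_a, p_a = np.zeros_like(F_a), np.ones_like(p_a)
    if df_b == 0:
        F_b, p_b = np.zeros_like(F_b), np.ones_like(p_b)

    squeeze = values.ndim == 1
    out = lambda x: float(x) if squeeze else x  # noqa: E731

    return AnovaResult(
        factor_F={names[0]: out(F_a), names[1]: out(F_b)},
        factor_p={names[0]: out(p_a), names[1]: out(p_b)},
        ss={
            names[0]: out(ss_a),
            names[1]: out(ss_b),
            "residual": out(ss_resid),
            "total": out(ss_total),
        },
        df={names[0]: df_a, names[1]: df_b, "residual": df_resid},
        mse=out(mse),
    )


def tukey_hsd(
    level_means: dict,
    n_per_level: int,
    mse: float,
    df_resid: int,
    alpha: float = 0.05,
    pairs: list[tuple] | None = None,
) -> list[dict]:
    """Tukey honest-significant-difference contrasts on level means.

    Uses the studentized range with k = number of levels and the residual
    degrees of freedom of the additive model.  ``pairs`` restricts the
    comparisons (e.g. each level against a reference); by default all pairs
    are compared.  Returns one record per pair with the signed mean
    difference, the q statistic, the adjusted p-value and a significance flag
    at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    levels = list(level_means)
    k = len(levels)
    if k < 2:
        raise ValueError("Tukey HSD needs at least two levels")
    if pairs is None:
        pairs = [(levels[i], levels[j]) for i in range(k) for j in range(i + 1, k)]
    se = np.sqrt(mse / n_per_level)
    records = []
    for lo, hi in pairs:
        diff = level_means[hi] - level_means[lo]
        if se > 0:
            q = abs(diff) / se
            p_adj = stats.studentized_range.sf(q, k, df_resid)
        else:
            q = np.inf if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        records.append(
            {
                "pair": (lo, hi),
                "diff": float(diff),
                "q": float(q),
                "p_adj": float(p_adj),
                "significant": bool(p_adj < alpha),
            }
        )
    return records
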
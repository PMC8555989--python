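"""Rank and multiple-comparison statistics used by the analysis stages.

Two procedures are implemented here rather than delegated, because their
exact behaviour (enumeration cutoffs, tie handling, step-down formula) is
part of the analysis contract:

* :func:`mann_whitney_u` — two-sample Mann–Whitney U with an exact null
  distribution for small tie-free samples and a tie/continuity-corrected
  normal approximation otherwise.
* :func:`holm_sidak` — step-down Šidák adjustment of a family of p-values,
  optionally computing the raw p-values from per-group samples with Welch
  t-tests.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError

EXACT_LIMIT = 20  # largest n_x + n_y for which the exact null is enumerated


def _exact_u_counts(nx: int, ny: int) -> np.ndarray:
    """Count rank assignments by U statistic.

    Returns an array ``c`` of length ``nx * ny + 1`` where ``c[u]`` is the
    number of ways to choose which ``nx`` of the ``nx + ny`` ranks belong to
    x such that the Mann–Whitney U of x equals ``u``.  Uses the recurrence
    N(u; i, j) = N(u - j; i - 1, j) + N(u; i, j - 1), conditioning on whether
    the largest rank is an x (it then beats all j y's) or a y.
    """
    prev = [np.array([1.0]) for _ in range(ny + 1)]  # i = 0: U = 0 only
    for i in range(1, nx + 1):
        cur: list[np.ndarray] = [np.array([1.0])]  # j = 0
        for j in range(1, ny + 1):
            a = np.zeros(i * j + 1)
            pa = prev[j]       # (i-1, j)
            pb = cur[j - 1]    # (i, j-1)
            a[j : j + pa.size] += pa
            a[: pb.size] += pb
            cur.append(a)
        prev = cur
    return prev[ny]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sample Mann–Whitney U test.

    U is computed from midranks.  When ``len(x) + len(y) <= 20`` and there
    are no ties, the p-value comes from the exact permutation null
    distribution of U; otherwise from the normal approximation with tie
    correction and a 0.5 continuity correction.

    Returns
    -------
    (U, p) : tuple of floats
        U is the statistic of the first sample ``x``.
    """
    if alternative != "two-sided":
        raise ValidationError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if n <= EXACT_LIMIT and not has_ties:
        counts = _exact_u_counts(nx, ny)
        total = counts.sum()
        u_int = int(round(u_x))
        u_low = min(u_int, nx * ny - u_int)
        p = 2.0 * counts[: u_low + 1].sum() / total
        return u_x, float(min(p, 1.0))

    mu = nx * ny / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        # complete tie: no evidence against the null
        return u_x, 1.0
    # continuity correction toward the mean
    z = (u_x - mu - 0.5 * np.sign(u_x - mu)) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return u_x, float(min(p, 1.0))


def mann_whitney_u_asymptotic(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Normal-approximation branch regardless of sample size (for calibration)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    _, tie_counts = np.unique(pooled, return_counts=True)
    mu = nx * ny / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u_x, 1.0
    z = (u_x - mu - 0.5 * np.sign(u_x - mu)) / np.sqrt(sigma2)
    return u_x, float(min(2.0 * sps.norm.sf(abs(z)), 1.0))


def holm_sidak_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Step-down Šidák adjustment.

    Sort ascending; adjusted_i = max_{j<=i} [1 - (1 - p_j)^(m - j + 1)]
    (1-based j), clipped to 1; returned in the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


def _welch_p(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Welch two-sample t-test p-value with a variance floor for degenerate groups."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    flagged = False
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 1.0, True
        # identical within groups but different means: inject a tiny variance
        # floor so the statistic is finite; flag the comparison
        scale = max(abs(np.mean(a)), abs(np.mean(b)), 1.0)
        eps = (1e-12 * scale) ** 2
        va = vb = eps
        flagged = True
        se = np.sqrt(va / a.size + vb / b.size)
        t = (np.mean(a) - np.mean(b)) / se
        df = a.size + b.size - 2
        return float(2.0 * sps.t.sf(abs(t), df)), flagged
    _, p = sps.ttest_ind(a, b, equal_var=False)
    return float(p), flagged


def holm_sidak(
    groups: Mapping[str, Sequence[float]] | None = None,
    pvalues: Iterable[float] | None = None,
):
    """Holm–Šidák multiple-comparison correction.

    Either pass ``pvalues`` (raw p-values, adjusted and returned in order) or
    ``groups`` (label -> sample): all pairwise Welch two-sample t-tests are
    computed and adjusted, returned as a list of dicts with keys
    ``group_a, group_b, p_raw, p_adjusted, flagged``.
    """
    if (groups is None) == (pvalues is None):
        raise ValidationError("pass exactly one of groups= or pvalues=")
    if pvalues is not None:
        return holm_sidak_adjust(list(pvalues))
    labels = list(groups)
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValidationError(f"group {k!r} needs at least two values")
    pairs = list(combinations(labels, 2))
    raw, flags = [], []
    for a, b in pairs:
        p, fl = _welch_p(arrays[a], arrays[b])
        raw.append(p)
        flags.append(fl)
    adj = holm_sidak_adjust(raw)
    return [
        {"group_a": a, "group_b": b, "p_raw": raw[i], "p_adjusted": float(adj[i]),
         "flagged": flags[i]}
        for i, (a, b) in enumerate(pairs)
    ]
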
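"""Pearson and Spearman concordance between potency vectors.

Small-n rank concordance is the core of in vitro / in vivo comparison
(IVIVC) here: typically 4-8 particles.  Spearman's rho is computed as
1 - 6*sum(d^2)/(n*(n^2-1)) for untied ranks, which equals the Pearson
product-moment coefficient on midranks in general (midranks are used for
ties).  p-values default to the t-approximation

    t = r * sqrt((n - 2) / (1 - r^2)),   df = n - 2

halved for a one-tailed test in the positive direction; an exact
permutation p (proportion of the n! rank permutations at least as
concordant) is available for n <= 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .exceptions import ConfigurationError, InsufficientDataError, ValidationError
from .integrate import rank_particles

PEARSON = "pearson"
SPEARMAN_T = "spearman_t_approx"
SPEARMAN_EXACT = "spearman_exact"

ONE = "one"
TWO = "two"

EXACT_MAX_N = 8


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    n: int
    tail: str
    p: float
    method: str


def _check_xy(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if len(x) < min_n:
        raise InsufficientDataError(
            message=f"need at least {min_n} observations, got {len(x)}"
        )
    return x, y


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValidationError("correlation undefined: zero variance input")
    return float(np.sum(xc * yc) / (sx * sy))


def _t_approx_p(r: float, n: int, tail: str) -> float:
    """p-value from the t transform of a correlation coefficient.

    At |r| = 1 the statistic diverges and the p-value is 0 to machine
    precision (reported as such; display layers may print '<0.001').
    """
    if tail not in (ONE, TWO):
        raise ConfigurationError(f"tail must be 'one' or 'two', got {tail!r}")
    if abs(r) >= 1.0:
        return 0.0
    tt = r * np.sqrt((n - 2) / (1.0 - r * r))
    if tail == TWO:
        return float(2.0 * t_dist.sf(abs(tt), n - 2))
    # one-tailed, positive direction hypothesized
    return float(t_dist.sf(tt, n - 2))


def pearson_correlation(x, y, tail: str = TWO) -> CorrelationResult:
    """Product-moment correlation with a t-based p-value.

    The one-tailed p tests for positive association (consistent
    directionality of the two variables).
    """
    x, y = _check_xy(x, y)
    r = _pearson_r(x, y)
    return CorrelationResult(r, len(x), tail, _t_approx_p(r, len(x), tail), PEARSON)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    # Pearson on midranks; identical to 1 - 6*sum(d^2)/(n(n^2-1)) when untied.
    rho = _pearson_r(rx, ry)
    # ranks are rational with widely separated attainable values at small n;
    # snap float noise so perfectly concordant ranks give exactly +/-1
    if abs(abs(rho) - 1.0) < 1e-12:
        rho = 1.0 if rho > 0 else -1.0
    return rho


def spearman_correlation(
    x, y, tail: str = ONE, method: str = "t_approx"
) -> CorrelationResult:
    """Rank-order correlation; inputs may be raw values or ranks.

    method="t_approx" (default) uses the same t transform as the Pearson
    test.  method="exact_permutation" (n <= 8) enumerates all n! rank
    permutations; its one-tailed p is the proportion with coefficient >=
    the observed one, two-tailed with |coefficient| >= |observed|.
    """
    x, y = _check_xy(x, y)
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = len(x)
    if method == "t_approx":
        return CorrelationResult(rho, n, tail, _t_approx_p(rho, n, tail), SPEARMAN_T)
    if method == "exact_permutation":
        if n > EXACT_MAX_N:
            raise ValidationError(
                f"exact permutation test is limited to n <= {EXACT_MAX_N} "
                f"(got n = {n}); use method='t_approx' for larger samples"
            )
        if tail not in (ONE, TWO):
            raise ConfigurationError(f"tail must be 'one' or 'two', got {tail!r}")
        eps = 1e-12
        count = 0
        for perm in permutations(ry):
            r = _spearman_rho(rx, np.asarray(perm))
            if tail == ONE:
                count += r >= rho - eps
            else:
                count += abs(r) >= abs(rho) - eps
        return CorrelationResult(
            rho, n, tail, count / factorial(n), SPEARMAN_EXACT
        )
    raise ConfigurationError(f"unknown Spearman p method {method!r}")


DEFAULT_PAIRS = (
    ("toxicity", "beta_r_cells", "beta_t"),
    ("inflammation", "beta_iv_cells", "beta_i"),
    ("integrated", "ibeta", "ibeta_invivo"),
)


def concordance_table(
    invitro: pd.DataFrame,
    invivo: pd.DataFrame,
    exclusions: Sequence[str] = (),
    pairs: Sequence[tuple[str, str, str]] = DEFAULT_PAIRS,
    pearson_tail: str = ONE,
    spearman_tail: str = ONE,
    spearman_method: str = "t_approx",
) -> pd.DataFrame:
    """Cross-model concordance for each index pair, with and without each
    listed exclusion.

    ``invitro``/``invivo`` are per-particle index tables indexed by particle
    (as produced by the integration module).  For every pair the table
    reports Pearson on the index values and Spearman on potency ranks
    (rank 1 = most potent), over all shared particles and after dropping
    each excluded particle in turn.
    """
    shared = invitro.index.intersection(invivo.index)
    if len(shared) < 3:
        raise InsufficientDataError(
            message=f"need >= 3 shared particles, got {len(shared)}"
        )
    subsets: list[tuple[str, pd.Index]] = [("all", shared)]
    for excl in exclusions:
        subsets.append((f"no {excl}", shared.difference([excl])))

    rows = []
    for label, col_vitro, col_vivo in pairs:
        for subset_label, idx in subsets:
            x = invitro.loc[idx, col_vitro].astype(float)
            y = invivo.loc[idx, col_vivo].astype(float)
            keep = x.notna() & y.notna()
            x, y = x[keep], y[keep]
            if len(x) < 3:
                continue
            pe = pearson_correlation(x.to_numpy(), y.to_numpy(), pearson_tail)
            rank_x = rank_particles(x)
            rank_y = rank_particles(y)
            sp = spearman_correlation(
                rank_x.to_numpy(), rank_y.to_numpy(), spearman_tail, spearman_method
            )
            for res in (pe, sp):
                rows.append(
                    {
                        "pair": label,
                        "subset": subset_label,
                        "method": res.method,
                        "coefficient": res.coefficient,
                        "n": res.n,
                        "tail": res.tail,
                        "p": res.p,
                    }
                )
    return pd.DataFrame(rows)


def rank_concordance(
    ranks_invitro: Mapping[str, float],
    ranks_invivo: Mapping[str, float],
    exclude: Iterable[str] = (),
    tail: str = ONE,
    method: str = "t_approx",
) -> CorrelationResult:
    """Spearman concordance of two particle rank vectors.

    Ranks are re-ranked after exclusions (rank 1 = most potent), so dropping
    a particle from printed 1..n ranks reproduces the bracketed reduced
    ranks convention.
    """
    shared = [p for p in ranks_invitro if p in ranks_invivo and p not in set(exclude)]
    x = rank_particles({p: -ranks_invitro[p] for p in shared})
    y = rank_particles({p: -ranks_invivo[p] for p in shared})
    return spearman_correlation(x.to_numpy(), y.to_numpy(), tail, method)
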
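"""Circular statistics for burst-phase data.

Descriptives (circular mean and mean resultant length R) and the inferential
tests used for phase comparisons: the Rayleigh test of uniformity, the
Watson-Williams multi-sample test of equal circular means, and the
Harrison-Kanji two-way ANOVA for circular data.  The formulations follow the
standard circular-statistics literature (Fisher; Zar; Berens' CircStat
toolbox), including the concentration (kappa) corrections and the
Harrison-Kanji low-concentration chi-square variant.

Angles are degrees in [0, 360) at the interface and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import wrap_deg

__all__ = [
    "CircularSample",
    "circ_mean_r",
    "rayleigh_test",
    "watson_williams",
    "harrison_kanji",
    "kappa_from_r",
]


@dataclass
class CircularSample:
    """Angles in degrees, wrapped to [0, 360), with optional weights."""

    angles_deg: np.ndarray
    weights: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        a = np.asarray(self.angles_deg, dtype=float).ravel()
        if a.size < 1:
            raise ValueError("empty circular sample")
        self.angles_deg = wrap_deg(a)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
            if self.weights.shape != self.angles_deg.shape:
                raise ValueError("weights must match angles")

    @property
    def n(self) -> int:
        return self.angles_deg.size


def _as_sample(sample) -> CircularSample:
    if isinstance(sample, CircularSample):
        return sample
    return CircularSample(np.asarray(sample, dtype=float))


def _resultant(rad: np.ndarray, w: np.ndarray | None = None) -> tuple[float, float]:
    """(mean angle rad, mean resultant length R) of unit vectors."""
    if w is None:
        w = np.ones_like(rad)
    z = np.sum(w * np.exp(1j * rad))
    R = np.abs(z) / np.sum(w)
    return float(np.angle(z)), float(R)


def circ_mean_r(sample) -> tuple[float, float]:
    """Circular mean (degrees in [0, 360)) and vector length R in [0, 1].

    The mean is undefined (NaN) when R = 0 (perfect cancellation).
    """
    s = _as_sample(sample)
    rad = np.deg2rad(s.angles_deg)
    mu, R = _resultant(rad, s.weights)
    if R < 1e-12:
        return float("nan"), 0.0
    return float(wrap_deg(np.rad2deg(mu))), min(R, 1.0)


def rayleigh_test(sample) -> float:
    """Rayleigh test of circular uniformity; small p = concentrated sample.

    Uses the standard approximation with the finite-n correction:
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` with ``Rn = n R``.
    """
    s = _as_sample(sample)
    if s.n < 3:
        raise ValueError("Rayleigh test needs n >= 3")
    _, R = _resultant(np.deg2rad(s.angles_deg), s.weights)
    n = s.n
    Rn = n * R
    z = Rn**2 / n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - Rn**2)) - (1 + 2 * n))
    return float(min(max(p, np.finfo(float).tiny), 1.0)) if np.isfinite(z) else 1.0


def kappa_from_r(R: float, n: int | None = None) -> float:
    """Maximum-likelihood-style estimate of the concentration parameter kappa.

    Piecewise approximation (Fisher 1993), with the small-sample correction
    when ``n`` (< 15) is given.
    """
    R = float(R)
    if R < 0.53:
        kappa = 2 * R + R**3 + 5 * R**5 / 6
    elif R < 0.85:
        kappa = -0.4 + 1.39 * R + 0.43 / (1 - R)
    else:
        kappa = 1.0 / (R**3 - 4 * R**2 + 3 * R)
    if n is not None and 1 < n < 15:
        if kappa < 2:
            kappa = max(kappa - 2.0 / (n * kappa), 0.0)
        else:
            kappa = (n - 1) ** 3 * kappa / (n**3 + n)
    return float(kappa)


@dataclass
class WatsonWilliamsResult:
    F: float
    p: float
    df: tuple[int, int]
    warning: str | None = None


def watson_williams(groups: list) -> WatsonWilliamsResult:
    """Watson-Williams one-way test of equal circular means across groups.

    ``F = beta * (N - k) (sum_i R_i - R) / ((k - 1) (N - sum_i R_i))`` with
    group resultant lengths ``R_i = n_i r_i``, total resultant ``R = N r``,
    and correction ``beta = 1 + 3 / (8 kappa)``.  The test assumes
    von-Mises-like samples with adequate, similar concentration; when the
    within-group mean resultant length falls below 0.45 the result carries a
    warning instead of failing, since the test is routinely applied to small
    phase samples.
    """
    samples = [_as_sample(g) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for s in samples:
        if s.n < 3:
            raise ValueError("each group needs n >= 3")
    k = len(samples)
    N = sum(s.n for s in samples)
    Ri = [s.n * _resultant(np.deg2rad(s.angles_deg))[1] for s in samples]
    all_rad = np.concatenate([np.deg2rad(s.angles_deg) for s in samples])
    R = N * _resultant(all_rad)[1]
    rw = sum(Ri) / N           # within-group mean resultant length
    warning = None
    if rw < 0.45:
        warning = (f"mean resultant length {rw:.3f} < 0.45: concentration too "
                   "low for the Watson-Williams approximation to be reliable")
    kappa = kappa_from_r(rw)
    beta = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    num = (N - k) * (sum(Ri) - R)
    den = (k - 1) * (N - sum(Ri))
    F = beta * num / den if den > 0 else np.inf
    df = (k - 1, N - k)
    p = float(stats.f.sf(F, *df)) if np.isfinite(F) else 0.0
    return WatsonWilliamsResult(F=float(F), p=p, df=df, warning=warning)


def harrison_kanji(sample, factor_a, factor_b) -> pd.DataFrame:
    """Harrison-Kanji two-way ANOVA for circular data.

    Decomposes the resultant-length sums of squares over two crossed factors
    and their interaction.  With an estimated concentration ``kappa > 2``
    the high-concentration F variant (with the ``1/(1 - 1/(5k) - 1/(10k^2))``
    correction) is used; otherwise the low-concentration chi-square variant.
    Returns a table with one row per effect (A, B, interaction): df, test
    statistic and p-value.
    """
    s = _as_sample(sample)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if fa.size != s.n or fb.size != s.n:
        raise ValueError("factor labels must match the sample length")
    la, lb = np.unique(fa), np.unique(fb)
    pL, qL = la.size, lb.size
    if pL < 2 or qL < 2:
        raise ValueError("each factor needs at least 2 levels")
    rad = np.deg2rad(s.angles_deg)
    n = s.n

    gn = np.zeros((pL, qL))
    gr = np.zeros((pL, qL))
    for i, A in enumerate(la):
        for j, B in enumerate(lb):
            sel = (fa == A) & (fb == B)
            if sel.sum() < 2:
                raise ValueError(f"cell ({A!r}, {B!r}) has fewer than 2 observations")
            gn[i, j] = sel.sum()
            gr[i, j] = sel.sum() * _resultant(rad[sel])[1]

    tr = n * _resultant(rad)[1]
    kk = kappa_from_r(tr / n)

    # row/column resultants are vector resultants over all angles at that
    # level, not sums of per-cell resultant magnitudes
    row_r = np.array([ (fa == A).sum() * _resultant(rad[fa == A])[1]
                       for A in la])
    col_r = np.array([ (fb == B).sum() * _resultant(rad[fb == B])[1]
                       for B in lb])
    row_n, col_n = gn.sum(axis=1), gn.sum(axis=0)
    eff_1 = np.sum(row_r**2 / row_n) - tr**2 / n
    eff_2 = np.sum(col_r**2 / col_n) - tr**2 / n
    eff_cells = np.sum(gr**2 / gn)
    eff_i = eff_cells - np.sum(col_r**2 / col_n) - np.sum(row_r**2 / row_n) \
        + tr**2 / n
    eff_r = n - eff_cells
    df_1, df_2 = pL - 1, qL - 1
    df_i = (pL - 1) * (qL - 1)
    df_r = n - pL * qL

    rows = []
    if kk > 2:   # high-concentration F variant
        beta = 1.0 / (1 - 1 / (5 * kk) - 1 / (10 * kk**2))
        ms_r = eff_r / df_r
        for name, eff, df in (("A", eff_1, df_1), ("B", eff_2, df_2),
                              ("interaction", eff_i, df_i)):
            F = beta * (eff / df) / ms_r
            rows.append({"effect": name, "df": (df, df_r),
                         "statistic": float(F), "kind": "F",
                         "p": float(stats.f.sf(F, df, df_r))})
    else:        # low-concentration chi-square variant
        from scipy.special import i0 as _i0, i1 as _i1
        ratio = _i1(kk) / _i0(kk)
        f = 2.0 / (1 - ratio**2)
        for name, eff, df in (("A", eff_1, df_1), ("B", eff_2, df_2),
                              ("interaction", eff_i, df_i)):
            chi = f * eff
            rows.append({"effect": name, "df": (df,),
                         "statistic": float(chi), "kind": "chi2",
                         "p": float(stats.chi2.sf(chi, df))})
    return pd.DataFrame(rows)
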
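"""Group aggregation and pointwise bootstrap comparison of time series.

Normalized (percent-change) series are averaged trial -> experiment ->
group; experiments are the independent replicates, so the bootstrap
resamples experiments with replacement.  Per time bin the observed statistic
is a Welch (unequal-variance) t between the two groups' experiment values;
the null is built by recentering each group on the pooled mean and
resampling within group; the two-sided p-value uses the +1 correction
``p = (1 + #{|t*| >= |t_obs|}) / (iterations + 1)`` so finite iterations
never produce p = 0.  Inference is pointwise (per bin) with no multiplicity
correction, mirroring the banded significance display; an optional
family-wise (max-|t*|) variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RhythmSeries, child_rng

__all__ = [
    "SeriesGroup",
    "BootstrapResult",
    "aggregate_series",
    "bootstrap_timeseries_test",
    "significance_bands",
    "BAND_EDGES",
]

#: significance bands, strict upper edges, as displayed (black/green/yellow/
#: orange/red in the original color coding)
BAND_EDGES = [(1e-4, "<0.0001"), (1e-3, "<0.001"), (1e-2, "<0.01"),
              (5e-2, "<0.05")]
NS_BAND = "ns"


@dataclass
class SeriesGroup:
    """One averaged, normalized series per experiment, on a common grid."""

    values: np.ndarray          # (n_experiments, n_bins)
    times: np.ndarray
    label: str = ""
    kind: str = "percent-change"

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.times):
            raise ValueError("values and time grid do not match")

    @property
    def n_experiments(self) -> int:
        return self.values.shape[0]

    def grand_mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)


@dataclass
class BootstrapResult:
    """Per-timepoint two-group p-values with banded classification."""

    p: np.ndarray
    times: np.ndarray
    t_obs: np.ndarray
    iterations: int
    seed: int
    bands: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "t": self.t_obs, "p": self.p,
                             "band": self.bands})


def aggregate_series(
    trials_per_experiment: list[list[RhythmSeries]],
    label: str = "",
) -> SeriesGroup:
    """Average trials within each experiment and stack experiments.

    Means are pairwise-complete over missing bins.  All series must share
    the time grid.
    """
    if not trials_per_experiment:
        raise ValueError("need at least one experiment")
    grid = trials_per_experiment[0][0].times
    rows = []
    for trials in trials_per_experiment:
        if not trials:
            raise ValueError("each experiment needs at least one trial")
        for s in trials:
            if s.times.shape != grid.shape or not np.allclose(s.times, grid):
                raise ValueError("all series must share the time grid")
        rows.append(np.nanmean(np.vstack([s.values for s in trials]), axis=0))
    return SeriesGroup(values=np.vstack(rows), times=grid.copy(), label=label,
                       kind=trials_per_experiment[0][0].kind)


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch t per column for 2-D (members x bins) arrays (no NaNs)."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(denom == 0, 0.0, t)


def _resampled_stats(x: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and var(mean) of with-replacement resamples given multinomial counts."""
    n = x.shape[0]
    s1 = counts @ x
    s2 = counts @ (x * x)
    mean = s1 / n
    var = (s2 - n * mean**2) / (n - 1)
    return mean, var / n


def bootstrap_timeseries_test(
    a: SeriesGroup,
    b: SeriesGroup,
    iterations: int = 10_000,
    seed: int = 0,
    family_wise: bool = False,
) -> BootstrapResult:
    """Pointwise bootstrap t-test between two groups of experiment series.

    Deterministic given ``seed``.  Bins where either group has fewer than
    two non-missing values get a missing p-value.  With ``family_wise=True``
    the null is the per-iteration max |t*| across bins (off by default; the
    study display is pointwise).
    """
    if a.values.shape[1] != b.values.shape[1] or not np.allclose(a.times, b.times):
        raise ValueError("groups must share the time grid")
    if a.n_experiments < 2 or b.n_experiments < 2:
        raise ValueError("both groups need at least 2 experiments")
    na, nb = a.n_experiments, b.n_experiments
    nbins = a.values.shape[1]
    rng = child_rng(seed, "bootstrap")
    counts_a = rng.multinomial(na, np.full(na, 1.0 / na), size=iterations)
    counts_b = rng.multinomial(nb, np.full(nb, 1.0 / nb), size=iterations)

    p = np.full(nbins, np.nan)
    t_obs_full = np.full(nbins, np.nan)
    complete = ~(np.isnan(a.values).any(axis=0) | np.isnan(b.values).any(axis=0))

    def _pvals(av, bv, ca, cb):
        t_obs = _welch_t(av, bv)
        pooled = np.concatenate([av, bv]).mean(axis=0)
        a0 = av - av.mean(axis=0) + pooled
        b0 = bv - bv.mean(axis=0) + pooled
        ma, va_ = _resampled_stats(a0, ca)
        mb, vb_ = _resampled_stats(b0, cb)
        denom = np.sqrt(va_ + vb_)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = np.abs(ma - mb) / denom
        t_star = np.where(denom == 0, 0.0, t_star)
        if family_wise:
            t_star = t_star.max(axis=1, keepdims=True)
        exceed = (t_star >= np.abs(t_obs)[None, :]).sum(axis=0)
        return t_obs, (1.0 + exceed) / (iterations + 1.0)

    if complete.any():
        t_obs_full[complete], p[complete] = _pvals(
            a.values[:, complete], b.values[:, complete], counts_a, counts_b)

    # incomplete bins: recompute with the available members only
    for j in np.flatnonzero(~complete):
        av = a.values[~np.isnan(a.values[:, j]), j:j + 1]
        bv = b.values[~np.isnan(b.values[:, j]), j:j + 1]
        if av.shape[0] < 2 or bv.shape[0] < 2:
            continue
        rj = child_rng(seed, "bootstrap-bin", j)
        ca = rj.multinomial(av.shape[0], np.full(av.shape[0], 1 / av.shape[0]),
                            size=iterations)
        cb = rj.multinomial(bv.shape[0], np.full(bv.shape[0], 1 / bv.shape[0]),
                            size=iterations)
        t_obs_full[j:j + 1], p[j:j + 1] = _pvals(av, bv, ca, cb)

    result = BootstrapResult(p=p, times=a.times.copy(), t_obs=t_obs_full,
                             iterations=iterations, seed=int(seed))
    result.bands = significance_bands(result)
    return result


def significance_bands(result: BootstrapResult | np.ndarray) -> list[str]:
    """Map p-values onto the five display bands (strict inequalities).

    ``[0, 0.0001) -> "<0.0001"``, ``[0.0001, 0.001) -> "<0.001"``,
    ``[0.001, 0.01) -> "<0.01"``, ``[0.01, 0.05) -> "<0.05"``, else ``ns``
    (p = 0.05 itself is not significant); missing p gives ``""``.
    """
    p = result.p if isinstance(result, BootstrapResult) else np.asarray(result)
    out = []
    for v in np.atleast_1d(p):
        if not np.isfinite(v):
            out.append("")
            continue
        for edge, name in BAND_EDGES:
            if v < edge:
                out.append(name)
                break
        else:
            out.append(NS_BAND)
    return out
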
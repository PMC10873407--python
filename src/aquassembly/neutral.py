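"""Sloan neutral community model (NCM).

The model treats a local community of size ``N`` receiving immigrants
from a metacommunity at rate ``m``.  At stationarity the local relative
abundance of a taxon whose metacommunity mean abundance is ``p`` follows
a ``Beta(Nm*p, Nm*(1-p))`` law, so the probability of detecting the
taxon above a detection limit ``d`` — its expected occurrence frequency
across samples — is the Beta survival function

    F(p; Nm, d) = 1 - I_d(Nm*p, Nm*(1-p)),

with ``I`` the regularized incomplete beta function.  ``Nm`` is the
single fitted parameter; R-squared of observed occurrence frequencies
against ``F`` measures how much of the occupancy–abundance relationship
stochastic dispersal alone explains.  Confidence bands come from a
nonparametric bootstrap over taxa, and each taxon is partitioned as
occurring *above*, *below* or within (*neutral*) the 95% band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from aquassembly.io import AbundanceTable

_LOG_NM_BOUNDS = (0.0, np.log(1e9))
_NM_STARTS = (10.0, 1e2, 1e3, 1e4)


class NCMFitError(RuntimeError):
    """Optimizer failure or degenerate occurrence data."""


@dataclass
class OccurrenceStats:
    """Per-taxon mean abundance and occurrence frequency.

    ``p`` is the mean relative abundance over all samples (zeros
    included); ``f`` is the fraction of samples in which the taxon is
    detected, i.e. has abundance at or above the detection limit ``d``.
    Taxa never detected are dropped.
    """

    taxon_ids: list[str]
    p: np.ndarray
    f: np.ndarray
    detection_limit: float
    n_samples: int


@dataclass
class NCMFit:
    """Fitted NCM: dispersal parameter, fit quality, bands, partition."""

    nm: float
    r_squared: float
    detection_limit: float
    p: np.ndarray
    f: np.ndarray
    predicted: np.ndarray
    taxon_ids: list[str]
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    partition: dict[str, str] = field(default_factory=dict)
    nm_replicates: np.ndarray | None = None
    n_bootstrap: int = 0
    seed: int | None = None
    m: float | None = None

    def partition_counts(self) -> dict[str, int]:
        counts = {"above": 0, "neutral": 0, "below": 0}
        for label in self.partition.values():
            counts[label] += 1
        return counts


def occurrence_stats(
    table: AbundanceTable,
    detection_limit: float | str = "auto",
) -> OccurrenceStats:
    """Summarize a table into the (p, f) pairs the NCM is fitted to.

    The automatic detection limit is one read in a sample of median
    depth when depths are known, otherwise the smallest positive
    abundance in the table — the de facto "one read" detectability rule.
    Detection is inclusive (abundance >= d) so that a single read at the
    automatic limit counts as presence.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if detection_limit == "auto":
        if table.depths is not None:
            d = 1.0 / float(np.median(table.depths))
        else:
            positive = table.abundance[table.abundance > 0]
            if positive.size == 0:
                raise ValueError("table has no positive abundances")
            d = float(positive.min())
    else:
        d = float(detection_limit)
    if d <= 0:
        raise ValueError("detection limit must be positive")
    p = table.abundance.mean(axis=0)
    f = (table.abundance >= d).mean(axis=0)
    keep = f > 0
    return OccurrenceStats(
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        p=p[keep],
        f=f[keep],
        detection_limit=d,
        n_samples=table.n_samples,
    )


def ncm_frequency(p, nm: float, d: float):
    """Predicted occurrence frequency ``F(p; Nm, d)``.

    Vectorized over ``p``; monotone nondecreasing in ``p`` for fixed
    ``(Nm, d)``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if not 0 < d < 1:
        raise ValueError("detection limit must lie in (0, 1)")
    if nm <= 0:
        raise ValueError("Nm must be positive")
    return 1.0 - special.betainc(nm * p, nm * (1.0 - p), d)


def _sse(log_nm: float, p: np.ndarray, f: np.ndarray, d: float) -> float:
    resid = f - ncm_frequency(p, np.exp(log_nm), d)
    return float(resid @ resid)


def _fit_nm(p: np.ndarray, f: np.ndarray, d: float) -> float:
    """Least-squares Nm via multi-start bounded search over log(Nm)."""
    best = None
    for start in _NM_STARTS:
        res = optimize.minimize_scalar(
            _sse,
            bounds=_LOG_NM_BOUNDS,
            args=(p, f, d),
            method="bounded",
            options={"xatol": 1e-10},
        )
        # minimize_scalar(bounded) ignores starts; refine around each
        # start with a local bracket to escape flat tails.
        local = optimize.minimize(
            _sse,
            x0=np.log(start),
            args=(p, f, d),
            bounds=[_LOG_NM_BOUNDS],
            method="L-BFGS-B",
        )
        for cand in (res, local):
            x = float(np.atleast_1d(cand.x)[0])
            val = float(cand.fun)
            if best is None or val < best[1] - 1e-15:
                best = (x, val)
    if best is None or not np.isfinite(best[1]):
        raise NCMFitError("Nm optimization failed to converge")
    return float(np.exp(best[0]))


def fit_ncm(
    stats: OccurrenceStats,
    community_size: float | None = None,
) -> NCMFit:
    """Fit ``Nm`` by nonlinear least squares of f against F(p; Nm, d).

    R-squared is computed on untransformed frequencies about the mean
    of ``f`` and may be negative; if ``f`` is exactly constant it is 0
    by convention.  ``m`` is reported only when the caller supplies the
    local community size ``N``.
    """
    p, f, d = stats.p, stats.f, stats.detection_limit
    if len(np.unique(p)) < 2:
        raise NCMFitError("need at least 2 distinct mean abundances")
    nm = _fit_nm(p, f, d)
    predicted = ncm_frequency(p, nm, d)
    ss_res = float(np.sum((f - predicted) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return NCMFit(
        nm=nm,
        r_squared=r2,
        detection_limit=d,
        p=p.copy(),
        f=f.copy(),
        predicted=predicted,
        taxon_ids=list(stats.taxon_ids),
        m=None if community_size is None else nm / community_size,
    )


def bootstrap_ncm(
    stats: OccurrenceStats,
    n_bootstrap: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    band: str = "bootstrap",
    max_failure_fraction: float = 0.2,
) -> NCMFit:
    """Fit with pointwise 95% bands in one of two styles.

    ``band="bootstrap"`` (default): taxa — the exchangeable unit of the
    occupancy–abundance regression — are resampled with replacement
    ``n_bootstrap`` times, each replicate refits ``Nm``, and the bands
    are the pointwise percentile envelope of the replicate curves.
    This band expresses uncertainty in the fitted curve itself and is
    narrow when many taxa constrain the fit; with ``n_bootstrap=0`` it
    collapses onto the fitted curve.

    ``band="binomial"``: Wilson score interval for an occurrence
    proportion observed over ``n_samples`` trials at the predicted
    frequency.  This band expresses the sampling scatter an individual
    taxon's frequency should show around the curve, and is the
    appropriate reference for partitioning taxa into above / neutral /
    below classes.  Replicate ``Nm`` values are still collected when
    ``n_bootstrap > 0``.
    """
    if band not in ("bootstrap", "binomial"):
        raise ValueError(f"unknown band style {band!r}")
    fit = fit_ncm(stats)
    rng = np.random.default_rng(seed)
    n_taxa = len(stats.p)
    curves = []
    nms = []
    failures = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n_taxa, size=n_taxa)
        p_b, f_b = stats.p[idx], stats.f[idx]
        try:
            if len(np.unique(p_b)) < 2:
                raise NCMFitError("degenerate resample")
            nm_b = _fit_nm(p_b, f_b, stats.detection_limit)
        except NCMFitError:
            failures += 1
            continue
        nms.append(nm_b)
        curves.append(ncm_frequency(stats.p, nm_b, stats.detection_limit))
    if n_bootstrap > 0 and failures > max_failure_fraction * n_bootstrap:
        raise NCMFitError(
            f"{failures}/{n_bootstrap} bootstrap replicates failed to fit"
        )
    fit.nm_replicates = np.asarray(nms)
    if band == "binomial":
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(
            np.round(fit.predicted * stats.n_samples),
            stats.n_samples, alpha=1.0 - level, method="wilson",
        )
        fit.ci_lower = np.minimum(np.asarray(lo), fit.predicted)
        fit.ci_upper = np.maximum(np.asarray(hi), fit.predicted)
    elif curves:
        curves = np.asarray(curves)
        alpha = (1.0 - level) / 2.0
        fit.ci_lower = np.quantile(curves, alpha, axis=0)
        fit.ci_upper = np.quantile(curves, 1.0 - alpha, axis=0)
    else:
        fit.ci_lower = fit.predicted.copy()
        fit.ci_upper = fit.predicted.copy()
    fit.n_bootstrap = n_bootstrap
    fit.seed = seed
    fit.partition = partition_taxa(fit, stats)
    return fit


def partition_taxa(fit: NCMFit, stats: OccurrenceStats) -> dict[str, str]:
    """Classify each taxon against the confidence bands at its own p.

    *above* if its occurrence frequency exceeds the upper band, *below*
    if under the lower band, *neutral* otherwise.
    """
    if fit.ci_lower is None or fit.ci_upper is None:
        raise ValueError("fit has no confidence bands; run bootstrap_ncm")
    out: dict[str, str] = {}
    for taxon, f_i, lo, hi in zip(stats.taxon_ids, stats.f, fit.ci_lower,
                                  fit.ci_upper):
        if f_i > hi:
            out[taxon] = "above"
        elif f_i < lo:
            out[taxon] = "below"
        else:
            out[taxon] = "neutral"
    return out
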
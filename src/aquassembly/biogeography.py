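"""Distance matrices, ordination, permutation tests and distance decay.

Compositional distance is Bray–Curtis on relative abundances;
geographic distance is the great-circle (haversine) distance in km;
altitudinal distance is the absolute difference in metres.  On top of
these the module provides classical PCoA, PERMANOVA, simple and partial
Mantel tests (permutation p-values use the ``(1 + more-extreme)/(1 + n)``
convention so p is never zero), Spearman distance-decay statistics for
compositional similarity and shared gene counts, per-variable
environmental association with Benjamini–Hochberg FDR, and gene
accumulation curves over an ORF-to-unigene catalog.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from aquassembly.io import AbundanceTable, GenePresenceMatrix, OrfCatalog

logger = logging.getLogger("aquassembly")

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal, plus labels."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be exactly zero")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu, ju = np.triu_indices(self.n, k=1)
        return self.values[iu, ju]

    def select(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(s) for s in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.metric_name
        )


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    sample_ids: list[str]


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None = None


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    kind: str = "simple"
    conditioned_on: str | None = None
    method: str = "pearson"


@dataclass
class DecayResult:
    spearman_r: float
    p_value: float
    n_pairs: int
    pair_table: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# distance matrices


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between all sample pairs."""
    d = squareform(pdist(table.abundance, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.sample_ids), d, "bray-curtis")


def similarity_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Compositional similarity 1 - Bray–Curtis (diagonal forced to 0).

    The diagonal is irrelevant for pair statistics, which only read the
    off-diagonal entries; keeping it at zero lets the similarity reuse
    the DistanceMatrix container.
    """
    bc = bray_curtis(table)
    sim = 1.0 - bc.values
    np.fill_diagonal(sim, 0.0)
    return DistanceMatrix(list(table.sample_ids), sim, "similarity")


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two points in kilometres."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(
        dlam / 2.0
    ) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geographic_distance(metadata: pd.DataFrame) -> DistanceMatrix:
    """Haversine distance matrix (km) from metadata coordinates.

    Samples with missing coordinates are excluded with a log entry.
    """
    ok = metadata["latitude"].notna() & metadata["longitude"].notna()
    if (~ok).any():
        logger.info("geographic_distance: dropped %d samples without "
                    "coordinates: %s", (~ok).sum(),
                    list(metadata.index[~ok])[:10])
    sub = metadata.loc[ok]
    lat = np.radians(sub["latitude"].to_numpy(dtype=float))
    lon = np.radians(sub["longitude"].to_numpy(dtype=float))
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat[:, None]) * np.cos(
        lat[None, :]
    ) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(sub.index), d, "haversine-km")


def altitude_difference(metadata: pd.DataFrame) -> DistanceMatrix:
    """Pairwise absolute altitude difference in metres."""
    ok = metadata["altitude_m"].notna()
    if (~ok).any():
        logger.info("altitude_difference: dropped %d samples without "
                    "altitude", (~ok).sum())
    sub = metadata.loc[ok]
    alt = sub["altitude_m"].to_numpy(dtype=float)
    d = np.abs(alt[:, None] - alt[None, :])
    return DistanceMatrix(list(sub.index), d, "altitude-m")


# ---------------------------------------------------------------------------
# ordination and permutation tests


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical principal coordinates analysis.

    Eigendecomposition of the Gower-centered matrix -1/2 J D^2 J.
    Negative eigenvalues are retained in the report (not corrected);
    coordinates are returned only for positive eigenvalues and the
    proportion explained is taken over the positive part.
    """
    if d.n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    n = d.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d.values**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-10 * abs(eigval[0]))
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    total_pos = eigval[pos].sum()
    prop = np.zeros_like(eigval)
    if total_pos > 0:
        prop[pos] = eigval[pos] / total_pos
    return OrdinationResult(coords, eigval, prop, list(d.labels))


def _permanova_f(d2: np.ndarray, groups: np.ndarray, n_groups: int):
    """Pseudo-F and R^2 from a squared distance matrix and labels."""
    n = d2.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    ss_total = d2[iu, ju].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore"):  # ss_within may be exactly zero
        f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_among / ss_total


def permanova(
    d: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA with free permutation of group labels.

    Sums of squares follow Anderson's formulation on squared
    distances: ``SS_total = sum_{i<j} d_ij^2 / N``, ``SS_within``
    summed per group with its own size, pseudo-F on ``(a-1, N-a)``
    degrees of freedom, ``R^2 = SS_among / SS_total``.
    """
    groups = pd.Series(list(groups), index=d.labels)
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(uniques[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"singleton group(s): {small}")
    d2 = d.values**2
    f_obs, r2 = _permanova_f(d2, codes, len(uniques))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_perm, _ = _permanova_f(d2, perm, len(uniques))
        if f_perm >= f_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p),
                           n_permutations, seed)


def _pair_correlation(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation {method!r}")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _mantel_permutations(n: int, n_permutations: int, rng):
    """Permutations of sample indices; exact enumeration for tiny n.

    When every distinct permutation can be enumerated within the
    requested budget the full n! lattice is used (identity included in
    the numerator and denominator), which makes small-n p-values exact.
    """
    from itertools import permutations as iperm

    if math.factorial(n) <= n_permutations + 1:
        perms = [np.asarray(p) for p in iperm(range(n))]
        return perms, True
    return [rng.permutation(n) for _ in range(n_permutations)], False


def mantel(
    d_a: DistanceMatrix,
    d_b: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    method: str = "pearson",
) -> MantelResult:
    """Simple Mantel test between two distance matrices.

    The statistic correlates the unrolled upper triangles; the null
    distribution simultaneously permutes rows and columns of the first
    matrix.  Two-sided p with the add-one convention; for very small n
    the full permutation lattice is enumerated exactly.
    """
    if list(d_a.labels) != list(d_b.labels):
        raise ValueError("distance matrices must share labels in order")
    n = d_a.n
    if n < 3:
        raise ValueError("Mantel needs at least 3 samples")
    iu, ju = np.triu_indices(n, k=1)
    x, y = d_a.values[iu, ju], d_b.values[iu, ju]
    r_obs = _pair_correlation(x, y, method)
    if np.isnan(r_obs):
        raise ValueError("a matrix has zero variance among pairs")
    rng = np.random.default_rng(seed)
    perms, exact = _mantel_permutations(n, n_permutations, rng)
    hits = 0
    total = 0
    for perm in perms:
        if exact and np.array_equal(perm, np.arange(n)):
            continue  # identity counted via the +1 convention
        xp = d_a.values[np.ix_(perm, perm)][iu, ju]
        r_perm = _pair_correlation(xp, y, method)
        total += 1
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1.0 + hits) / (1.0 + total)
    return MantelResult(float(r_obs), float(p), total, "simple", None, method)


def _residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of y on x with intercept (least squares)."""
    denom = np.sum((x - x.mean()) ** 2)
    if denom == 0:
        return y - y.mean()
    beta = np.sum((x - x.mean()) * (y - y.mean())) / denom
    return y - (y.mean() + beta * (x - x.mean()))


def partial_mantel(
    d_a: DistanceMatrix,
    d_b: DistanceMatrix,
    d_c: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel: correlation of A and B controlling for C.

    Residual method — both unrolled matrices are regressed on the
    unrolled control matrix and the residuals correlated.  Permutation
    acts on the rows/columns of A.  A constant control matrix triggers
    a warning and falls back to the simple test.
    """
    for other in (d_b, d_c):
        if list(d_a.labels) != list(other.labels):
            raise ValueError("distance matrices must share labels in order")
    n = d_a.n
    if n < 4:
        raise ValueError("partial Mantel needs at least 4 samples")
    iu, ju = np.triu_indices(n, k=1)
    z = d_c.values[iu, ju]
    if z.std() == 0:
        warnings.warn("control matrix is constant; using simple Mantel")
        res = mantel(d_a, d_b, n_permutations, seed)
        return MantelResult(res.statistic, res.p_value, res.n_permutations,
                            "partial", d_c.metric_name or "control",
                            res.method)
    y = _residuals(d_b.values[iu, ju], z)
    x_obs = _residuals(d_a.values[iu, ju], z)
    r_obs = _pair_correlation(x_obs, y, "pearson")
    rng = np.random.default_rng(seed)
    perms, exact = _mantel_permutations(n, n_permutations, rng)
    hits = 0
    total = 0
    for perm in perms:
        if exact and np.array_equal(perm, np.arange(n)):
            continue
        xp = _residuals(d_a.values[np.ix_(perm, perm)][iu, ju], z)
        r_perm = _pair_correlation(xp, y, "pearson")
        total += 1
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1.0 + hits) / (1.0 + total)
    return MantelResult(float(r_obs), float(p), total, "partial",
                        d_c.metric_name or "control", "pearson")


# ---------------------------------------------------------------------------
# distance decay and genes


def select_pairs(
    labels,
    ecosystems,
    reference,
) -> list[tuple[int, int]]:
    """Unordered pairs sharing an ecosystem with one end in the reference.

    This is the single pair-selection path used for both compositional
    similarity and shared-gene decay: a pair is retained iff both
    samples carry the same ecosystem label and at least one of them
    belongs to the reference subset.
    """
    eco = pd.Series(list(ecosystems), index=labels)
    ref = set(reference)
    pairs = []
    lab = list(labels)
    for i in range(len(lab)):
        for j in range(i + 1, len(lab)):
            if eco.iloc[i] != eco.iloc[j]:
                continue
            if lab[i] not in ref and lab[j] not in ref:
                continue
            pairs.append((i, j))
    return pairs


def distance_decay(
    response: DistanceMatrix,
    distance: DistanceMatrix,
    ecosystems,
    reference,
    min_pairs: int = 3,
) -> DecayResult:
    """Spearman decay of a pair response against a pair distance.

    ``response`` holds per-pair values (compositional similarity or
    shared gene counts) aligned to ``distance``.  Pairs are filtered by
    :func:`select_pairs`; the statistic is the Spearman rank correlation
    of response against distance with its two-sided p-value.
    """
    if list(response.labels) != list(distance.labels):
        raise ValueError("response and distance must share labels in order")
    pairs = select_pairs(distance.labels, ecosystems, reference)
    if len(pairs) < min_pairs:
        raise ValueError(f"only {len(pairs)} pairs retained (< {min_pairs})")
    ii = np.array([i for i, _ in pairs])
    jj = np.array([j for _, j in pairs])
    x = distance.values[ii, jj]
    y = response.values[ii, jj]
    if np.ptp(y) == 0:
        raise ValueError("constant response over retained pairs")
    r, p = stats.spearmanr(x, y)
    lab = list(distance.labels)
    table = pd.DataFrame(
        {
            "sample_a": [lab[i] for i in ii],
            "sample_b": [lab[j] for j in jj],
            "distance": x,
            "response": y,
        }
    )
    return DecayResult(float(r), float(p), len(pairs), table)


def shared_gene_counts(
    genes: GenePresenceMatrix, pairs=None
) -> DistanceMatrix | np.ndarray:
    """Count of unigenes present in both samples of each pair.

    With ``pairs=None`` returns the full pairwise matrix (diagonal set
    to zero so it can serve as a decay response); otherwise returns the
    counts for the listed (sample_a, sample_b) label pairs.
    """
    m = genes.presence.astype(np.int64)
    shared = m @ m.T
    if pairs is None:
        shared = shared.astype(float)
        np.fill_diagonal(shared, 0.0)
        return DistanceMatrix(list(genes.sample_ids), shared, "shared-genes")
    index = {s: k for k, s in enumerate(genes.sample_ids)}
    out = []
    for a, b in pairs:
        if a not in index or b not in index:
            raise ValueError(f"unknown sample in pair ({a!r}, {b!r})")
        out.append(int(shared[index[a], index[b]]))
    return np.asarray(out)


def gene_accumulation(
    catalog: OrfCatalog,
    fractions=None,
    n_repeats: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Accumulation curve: distinct unigenes in random ORF subsamples.

    For each sampling fraction (default 5% steps up to 100%) the ORF set
    is subsampled without replacement ``n_repeats`` times and distinct
    unigenes counted.  The final point at fraction 1 is the exact
    catalog size with zero spread.
    """
    if not catalog.orf_ids:
        raise ValueError("empty catalog")
    if fractions is None:
        fractions = [round(0.05 * k, 2) for k in range(1, 21)]
    unigene_codes = pd.factorize(
        np.asarray([catalog.unigene_of[o] for o in catalog.orf_ids])
    )[0]
    n_orfs = len(unigene_codes)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        k = int(round(frac * n_orfs))
        if k >= n_orfs:
            exact = len(np.unique(unigene_codes))
            rows.append({"fraction": float(frac), "mean_unigenes": float(exact),
                         "sd": 0.0, "n_repeats": n_repeats})
            continue
        counts = [
            len(np.unique(unigene_codes[rng.choice(n_orfs, size=k,
                                                   replace=False)]))
            for _ in range(n_repeats)
        ]
        rows.append({
            "fraction": float(frac),
            "mean_unigenes": float(np.mean(counts)),
            "sd": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
            "n_repeats": n_repeats,
        })
    return pd.DataFrame(rows)


def env_association(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    variables,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha_p: float = 0.05,
    alpha_q: float = 0.1,
) -> pd.DataFrame:
    """Mantel association of each environmental variable with composition.

    Per variable: samples missing that variable are dropped, the
    variable is z-scored, and a simple Mantel test relates its Euclidean
    distance to the Bray–Curtis matrix over the same samples.  q-values
    are Benjamini–Hochberg across the tested variables, and a variable
    is flagged significant iff p < 0.05 and q < 0.1.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for var in variables:
        if var not in metadata.columns:
            logger.info("env_association: %s absent from metadata; skipped",
                        var)
            continue
        vals = pd.to_numeric(metadata[var], errors="coerce")
        keep = [s for s in table.sample_ids
                if s in vals.index and np.isfinite(vals.get(s, np.nan))]
        if len(keep) < 3:
            logger.info("env_association: %s has <3 observed samples; "
                        "skipped", var)
            continue
        v = vals.loc[keep].to_numpy(dtype=float)
        if v.std() == 0:
            logger.info("env_association: %s is constant; skipped", var)
            continue
        z = (v - v.mean()) / v.std()
        d_env = DistanceMatrix(keep, np.abs(z[:, None] - z[None, :]), var)
        d_bc = bray_curtis(table.select_samples(keep))
        res = mantel(d_bc, d_env, n_permutations,
                     seed=int(rng.integers(0, 2**31 - 1)))
        rows.append({"variable": var, "r": res.statistic, "p": res.p_value,
                     "n_samples": len(keep)})
    out = pd.DataFrame(rows, columns=["variable", "r", "p", "n_samples"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = (out["p"] < alpha_p) & (out["q"] < alpha_q)
    else:
        out["q"] = []
        out["significant"] = []
    return out


def geo_env_partial_mantel(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    variables,
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """R_Geo|Env and R_Env|Geo partial Mantel tests.

    Geographic variation is encoded as Euclidean distance on
    (great-circle km, altitude km) scaled to unit variance;
    environmental variation as Euclidean distance on the z-scored
    variables (samples with any missing variable are dropped for this
    analysis).
    """
    cols = ["latitude", "longitude", "altitude_m", *variables]
    meta = metadata.loc[[s for s in table.sample_ids
                         if s in metadata.index], cols].dropna()
    keep = list(meta.index)
    if len(keep) < 4:
        raise ValueError("too few samples with complete geography and "
                         "environment")
    sub = table.select_samples(keep)
    d_bc = bray_curtis(sub)
    geo_km = geographic_distance(metadata.loc[keep]).values
    alt_km = altitude_difference(metadata.loc[keep]).values / 1000.0

    def _unit(m):
        iu, ju = np.triu_indices(len(keep), k=1)
        s = m[iu, ju].std()
        return m / s if s > 0 else m

    d_geo = DistanceMatrix(
        keep, np.sqrt(_unit(geo_km) ** 2 + _unit(alt_km) ** 2), "geography"
    )
    z = (meta[list(variables)] - meta[list(variables)].mean()) / meta[
        list(variables)
    ].std(ddof=0)
    d_env = DistanceMatrix(
        keep,
        squareform(pdist(z.to_numpy(), metric="euclidean")),
        "environment",
    )
    rng = np.random.default_rng(seed)
    geo_given_env = partial_mantel(d_bc, d_geo, d_env, n_permutations,
                                   seed=int(rng.integers(0, 2**31 - 1)))
    env_given_geo = partial_mantel(d_bc, d_env, d_geo, n_permutations,
                                   seed=int(rng.integers(0, 2**31 - 1)))
    return {"geo_given_env": geo_given_env, "env_given_geo": env_given_geo,
            "n_samples": len(keep)}
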
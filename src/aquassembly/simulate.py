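"""Seeded generators of ground-truth communities for every analysis.

Four generators emulate the statistical structure the analyses assume:

* :func:`simulate_neutral` — neutrally assembled communities.  Each
  sample's composition is drawn from the Sloan stationary distribution,
  ``Dirichlet(Nm * p)`` around a metacommunity ``p``, and read counts
  from a multinomial at the configured depth.  This samples the fitted
  model's stationary law directly rather than running birth–death
  dynamics, so occupancy matches the NCM prediction exactly in
  expectation and parameter-recovery tests are sharp.
* :func:`simulate_niche` — deterministic Gaussian niche responses to an
  environmental gradient plus lognormal noise: the non-neutral
  alternative the model is tested against.
* :func:`simulate_modular` — module-structured co-abundances from
  shared latent factors, with planted module labels.
* :func:`simulate_transect` — a spatial transect whose composition
  drifts as a random walk with distance and whose gene pool decays
  exponentially from a reference pool, yielding known distance-decay
  structure in both taxonomy and gene content.

Every generator is a pure function of its config (including the seed):
reruns are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aquassembly.io import AbundanceTable, CountTable, GenePresenceMatrix

EARTH_RADIUS_KM = 6371.0


def log_series_abundances(n_taxa: int, x: float = 0.98) -> np.ndarray:
    """Ranked log-series metacommunity abundances normalized to one.

    ``p_k ∝ x^k / k`` for ranks k = 1..n_taxa — the classic skewed
    rank-abundance shape of survey data.
    """
    k = np.arange(1, n_taxa + 1, dtype=float)
    p = x**k / k
    return p / p.sum()


@dataclass
class NeutralSimConfig:
    n_taxa: int = 300
    n_samples: int = 150
    depth: int = 50_000
    nm: float = 1000.0
    metacommunity: np.ndarray | None = None  # defaults to log-series
    log_series_x: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nm <= 0:
            raise ValueError("Nm must be positive")
        if self.depth < 100:
            raise ValueError("depth must be at least 100 reads")
        if self.metacommunity is not None:
            p = np.asarray(self.metacommunity, dtype=float)
            if abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("metacommunity must sum to 1")
            self.metacommunity = p
            self.n_taxa = len(p)


@dataclass
class NicheSimConfig:
    n_taxa: int = 300
    n_samples: int = 150
    depth: int = 50_000
    gradient: np.ndarray | None = None  # defaults to linspace(0, 1)
    tolerance: float = 0.05
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class ModularNetSimConfig:
    n_modules: int = 4
    taxa_per_module: int = 10
    n_samples: int = 80
    correlation: float = 0.95  # within-module latent correlation target
    n_background: int = 20  # independent taxa buffering the composition
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.correlation <= 1:
            raise ValueError("correlation target must lie in (0, 1]")


@dataclass
class TransectSimConfig:
    n_samples: int = 40
    total_km: float = 2500.0
    n_taxa: int = 200
    depth: int = 50_000
    drift: float = 0.005  # log-abundance step variance per km
    gene_pool: int = 2000  # genes per sample, constant along the transect
    gene_decay: float = 0.0015  # per-km loss rate of reference genes
    origin: tuple = (31.0, 88.0)  # (lat, lon) of the reference end
    bearing_deg: float = 90.0
    max_altitude_m: float = 4800.0
    min_altitude_m: float = 100.0
    ecosystem: str = "river"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift < 0 or self.gene_decay < 0:
            raise ValueError("rates must be non-negative")


def simulate_neutral(config: NeutralSimConfig):
    """Dirichlet-multinomial neutral communities.

    Returns ``(CountTable, truth)`` where truth records the true Nm,
    metacommunity and seed.
    """
    rng = np.random.default_rng(config.seed)
    p = (
        config.metacommunity
        if config.metacommunity is not None
        else log_series_abundances(config.n_taxa, config.log_series_x)
    )
    comps = rng.dirichlet(config.nm * p, size=config.n_samples)
    counts = rng.multinomial(config.depth, comps)
    table = CountTable(
        [f"S{i:04d}" for i in range(config.n_samples)],
        [f"t{j:04d}" for j in range(len(p))],
        counts,
    )
    truth = {"model": "neutral", "nm": config.nm, "depth": config.depth,
             "metacommunity": p.tolist(), "seed": config.seed}
    return table, truth


def simulate_niche(config: NicheSimConfig):
    """Niche-filtered communities along an environmental gradient.

    Expected abundance of taxon j in sample i is a Gaussian response
    ``exp(-(env_i - opt_j)^2 / (2 tol^2))`` around the taxon's optimum,
    perturbed by lognormal noise, then sampled as multinomial counts.
    Narrow tolerances give strong environmental filtering.
    """
    rng = np.random.default_rng(config.seed)
    env = (
        np.asarray(config.gradient, dtype=float)
        if config.gradient is not None
        else np.linspace(0.0, 1.0, config.n_samples)
    )
    n_samples = len(env)
    optima = rng.uniform(0.0, 1.0, size=config.n_taxa)
    response = np.exp(
        -((env[:, None] - optima[None, :]) ** 2)
        / (2.0 * config.tolerance**2)
    )
    noise = rng.lognormal(0.0, config.noise_sd,
                          size=(n_samples, config.n_taxa))
    expected = response * noise + 1e-12
    expected /= expected.sum(axis=1, keepdims=True)
    counts = rng.multinomial(config.depth, expected)
    table = CountTable(
        [f"S{i:04d}" for i in range(n_samples)],
        [f"t{j:04d}" for j in range(config.n_taxa)],
        counts,
    )
    truth = {"model": "niche", "tolerance": config.tolerance,
             "optima": optima.tolist(), "gradient": env.tolist(),
             "seed": config.seed}
    return table, truth


def simulate_modular(config: ModularNetSimConfig):
    """Module-structured abundances with planted labels.

    One latent Gaussian factor per module drives all its taxa; the
    additive noise standard deviation ``sqrt(1/rho - 1)`` sets the
    within-module latent (Pearson) correlation to the configured
    target, while between-module pairs are independent.  Latent series
    are mapped to positive abundances by exponentiation and row
    renormalization, which preserves within-sample ranks.

    ``n_background`` extra taxa with independent latent series pad the
    community, as the many module-free taxa of real profiles do.  They
    buffer the compositional closure: with few modules and no
    background, the shared row-sum denominator would induce strong
    spurious negative correlation between modules.  Background taxa
    carry module label -1 in the truth record.
    """
    rng = np.random.default_rng(config.seed)
    n_mod_taxa = config.n_modules * config.taxa_per_module
    n_taxa = n_mod_taxa + config.n_background
    noise_sd = math.sqrt(1.0 / config.correlation - 1.0)
    factors = rng.standard_normal((config.n_samples, config.n_modules))
    latent = np.repeat(factors, config.taxa_per_module, axis=1)
    latent = latent + noise_sd * rng.standard_normal(
        (config.n_samples, n_mod_taxa)
    )
    background = rng.standard_normal((config.n_samples,
                                      config.n_background))
    latent = np.concatenate([latent, background], axis=1)
    raw = np.exp(latent)
    abundance = raw / raw.sum(axis=1, keepdims=True)
    labels = np.concatenate([
        np.repeat(np.arange(config.n_modules), config.taxa_per_module),
        np.full(config.n_background, -1),
    ])
    table = AbundanceTable(
        [f"S{i:04d}" for i in range(config.n_samples)],
        [f"t{j:04d}" for j in range(n_taxa)],
        abundance,
    )
    truth = {"model": "modular", "module_of": {t: int(m) for t, m in
                                              zip(table.taxon_ids, labels)},
             "correlation": config.correlation, "seed": config.seed}
    return table, truth


def _destination(lat: float, lon: float, bearing_deg: float,
                 distance_km: float):
    """Great-circle destination point (spherical Earth)."""
    delta = distance_km / EARTH_RADIUS_KM
    theta = math.radians(bearing_deg)
    phi1, lam1 = math.radians(lat), math.radians(lon)
    phi2 = math.asin(
        math.sin(phi1) * math.cos(delta)
        + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    )
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    return math.degrees(phi2), (math.degrees(lam2) + 540.0) % 360.0 - 180.0


def simulate_transect(config: TransectSimConfig):
    """Transect with decaying compositional and gene-pool overlap.

    Samples sit at evenly spaced distances along a single great-circle
    bearing from the origin, with altitude falling linearly from the
    high reference end — a ladder-like profile.  Composition performs a
    log-abundance random walk with per-km step variance ``drift``; each
    sample carries ``gene_pool`` genes, where a reference-pool gene is
    retained at distance x with probability ``exp(-gene_decay * x)``
    (independently per sample) and losses are replaced by sample-
    private novel genes.  The expected shared-gene count between the
    reference end and a sample at distance x is therefore
    ``gene_pool * exp(-gene_decay * x)``.

    Returns ``(metadata, AbundanceTable, GenePresenceMatrix, truth)``.
    Regions are labelled by distance tercile ("Tibet", "Ladder2",
    "Ladder3") so that reference-anchored pair selection can be
    exercised end to end.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    dist = np.linspace(0.0, config.total_km, n)
    alt = np.linspace(config.max_altitude_m, config.min_altitude_m, n)

    # composition: random walk in log-abundance space along the transect
    base = np.log(log_series_abundances(config.n_taxa))
    walk = np.empty((n, config.n_taxa))
    walk[0] = base
    for i in range(1, n):
        step_var = config.drift * (dist[i] - dist[i - 1])
        walk[i] = walk[i - 1] + rng.normal(
            0.0, math.sqrt(step_var), size=config.n_taxa
        )
    raw = np.exp(walk - walk.max(axis=1, keepdims=True))
    abundance = raw / raw.sum(axis=1, keepdims=True)

    sample_ids = [f"T{i:04d}" for i in range(n)]
    table = AbundanceTable(
        sample_ids, [f"t{j:04d}" for j in range(config.n_taxa)], abundance
    )

    # genes: exponential retention of the reference pool
    pool = [f"g{k:06d}" for k in range(config.gene_pool)]
    rows = []
    novel_counter = 0
    gene_index: dict[str, int] = {g: k for k, g in enumerate(pool)}
    columns = list(pool)
    for i in range(n):
        keep = rng.random(config.gene_pool) < math.exp(
            -config.gene_decay * dist[i]
        )
        present = [pool[k] for k in np.flatnonzero(keep)]
        n_novel = config.gene_pool - len(present)
        for _ in range(n_novel):
            gid = f"novel{novel_counter:07d}"
            novel_counter += 1
            gene_index[gid] = len(columns)
            columns.append(gid)
            present.append(gid)
        rows.append(present)
    presence = np.zeros((n, len(columns)), dtype=bool)
    for i, present in enumerate(rows):
        presence[i, [gene_index[g] for g in present]] = True
    genes = GenePresenceMatrix(sample_ids, columns, presence)

    # metadata: coordinates on the great circle, ladder-like regions
    coords = [_destination(*config.origin, config.bearing_deg, x)
              for x in dist]
    terciles = np.quantile(dist, [1 / 3, 2 / 3])
    region = np.where(dist <= terciles[0], "Tibet",
                      np.where(dist <= terciles[1], "Ladder2", "Ladder3"))
    metadata = pd.DataFrame(
        {
            "region": region,
            "ecosystem": config.ecosystem,
            "latitude": [c[0] for c in coords],
            "longitude": [c[1] for c in coords],
            "altitude_m": alt,
            "distance_km": dist,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = {
        "model": "transect",
        "drift": config.drift,
        "gene_decay": config.gene_decay,
        "gene_pool": config.gene_pool,
        "distances_km": dist.tolist(),
        "seed": config.seed,
    }
    return metadata, table, genes, truth
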
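"""Synthetic landscapes, individuals and genotypes for the full pipeline.

The generator emulates the statistical structure the analysis assumes: a
smooth elevation surface built from randomly placed hills; a 7-class
land-use map with strongly skewed, forest-dominated class shares laid out in
spatially aggregated patches (real landscape features cluster into patches,
so classes are carved out of a smoothed random field by rank thresholding,
not sampled i.i.d. per cell); individuals placed in habitat cells; and
genotypes whose expected pairwise dissimilarity grows with an *effective
cost*

    D_eff(i, j) = Euclidean_km(i, j) + beta * count_{ibr_class}(i, j)

— the same straight-line transect cost metric the downstream tests score, so
the signal planted is exactly the signal under test.  Genotypes come from a
latent-Gaussian model: per locus, latent vectors are drawn from a zero-mean
multivariate normal whose correlation is *calibrated* so that the expected
Bray-Curtis dissimilarity between two individuals rises linearly with their
effective cost (see :func:`latent_correlation`); each latent value is
quantile-binned into equiprobable allele classes and two independent draws
per locus give the diploid genotype.  ``beta = 0`` yields a pure
isolation-by-distance world.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GenerationError
from .genotypes import GenotypeTable, write_genepop, write_locations_csv
from .rasters import LANDUSE_CLASSES, LANDUSE_CODES, LandscapeRaster, write_ascii_grid
from .transects import PairNetwork, build_network

# Class shares of the emulated study region (forest-dominated temperate
# landscape; grid counts in millions: forest 89458, grass 28120, farmland
# 17834, urban 2170, open water 722, special matrix 72, wetland 25).
_TABLE_COUNTS = {
    "forest": 89_458, "grass_field": 28_120, "farmland": 17_834,
    "urban": 2_170, "open_water": 722, "special_matrix": 72, "wetland": 25,
}
DEFAULT_LANDUSE_PROPORTIONS: dict[str, float] = {
    k: v / sum(_TABLE_COUNTS.values()) for k, v in _TABLE_COUNTS.items()
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic study region.

    ``sex_ratio`` is the male fraction; ``beta`` is the true per-cell cost
    (km-equivalents) of the resistant class ``ibr_class``; ``decay_lambda``
    (km) is the effective cost at which the latent genetic correlation
    reaches zero — ``None`` (default) scales it to the landscape's largest
    pairwise cost; ``noise_sd`` is non-spatial latent noise (it sets the
    correlation ceiling ``1 / (1 + noise_sd^2)`` for coincident pairs).
    ``beta_female``, when set, gives females their own cost multiplier (a
    pair's beta is the mean of its members'), which emulates sex-biased
    landscape sensitivity.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    n_individuals: int = 100
    sex_ratio: float = 0.7
    n_loci: int = 12
    alleles_per_locus: int = 8
    landuse_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_LANDUSE_PROPORTIONS))
    habitat_classes: tuple[str, ...] = ("forest",)
    ibr_class: str = "farmland"
    beta: float = 0.0
    beta_female: float | None = None
    decay_lambda: float | None = None
    noise_sd: float = 0.6
    seed: int = 0
    # elevation surface
    elevation_base: float = 200.0
    n_hills: int = 6
    hill_amplitude: float = 400.0
    hill_sigma_km: float = 10.0
    elevation_noise_sd: float = 0.0
    # land-use patch scale (cells) for the smoothed-field thresholding
    patch_sigma: float = 3.0
    distinct_cells: bool = True

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ConfigurationError("grid must be at least 2x2")
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ConfigurationError("counts must be positive")
        if self.alleles_per_locus < 2:
            raise ConfigurationError("need at least 2 alleles per locus")
        if not 0 <= self.sex_ratio <= 1:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        if self.beta < 0 or (self.beta_female is not None and self.beta_female < 0):
            raise ConfigurationError("beta must be nonnegative")
        if self.decay_lambda is not None and self.decay_lambda <= 0:
            raise ConfigurationError("decay_lambda must be positive")
        if self.noise_sd < 0 or self.elevation_noise_sd < 0:
            raise ConfigurationError("noise SDs must be nonnegative")
        props = self.landuse_proportions
        unknown = set(props) - set(LANDUSE_CODES)
        if unknown:
            raise ConfigurationError(f"unknown land-use classes: {sorted(unknown)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"land-use proportions must sum to 1, got {sum(props.values())!r}"
            )
        if any(p < 0 for p in props.values()):
            raise ConfigurationError("proportions must be nonnegative")
        bad_hab = set(self.habitat_classes) - set(LANDUSE_CODES)
        if bad_hab:
            raise ConfigurationError(f"unknown habitat classes: {sorted(bad_hab)}")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generation stage
    return np.random.default_rng([int(config.seed), stream])


def generate_elevation(config: SyntheticConfig) -> LandscapeRaster:
    """Smooth positive elevation surface: base + random Gaussian hills.

    With zero hill amplitude and zero noise the raster is constant at the
    base elevation; all values stay within
    ``[base, base + sum(hill amplitudes) + noise]``.
    """
    rng = _rng(config, 1)
    rows = np.arange(config.grid_rows)[:, None] + 0.5
    cols = np.arange(config.grid_cols)[None, :] + 0.5
    values = np.full((config.grid_rows, config.grid_cols), config.elevation_base)
    for _ in range(config.n_hills):
        cy = rng.uniform(0, config.grid_rows)
        cx = rng.uniform(0, config.grid_cols)
        amp = rng.uniform(0.3, 1.0) * config.hill_amplitude
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        values = values + amp * np.exp(-d2 / (2 * config.hill_sigma_km ** 2))
    if config.elevation_noise_sd > 0:
        values = values + np.abs(rng.normal(0, config.elevation_noise_sd, values.shape))
    return LandscapeRaster(values=values, kind="elevation")


def generate_landuse(config: SyntheticConfig) -> LandscapeRaster:
    """Categorical 7-class land-use raster with patchy, skewed classes.

    A white-noise field is smoothed (Gaussian kernel, ``patch_sigma``
    cells) and cells are assigned to classes by field-value rank so that
    realized class counts match the requested proportions to within one
    cell of rounding — and are therefore spatially aggregated.
    """
    rng = _rng(config, 2)
    shape = (config.grid_rows, config.grid_cols)
    n_cells = shape[0] * shape[1]
    field_vals = ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=config.patch_sigma, mode="reflect")
    order = np.argsort(field_vals, axis=None, kind="stable")
    # integer class counts: floor + largest remainders, summing to n_cells
    props = [config.landuse_proportions.get(LANDUSE_CLASSES[c], 0.0)
             for c in sorted(LANDUSE_CLASSES)]
    raw = np.array(props) * n_cells
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for k in np.argsort(-remainder)[: n_cells - counts.sum()]:
        counts[k] += 1
    codes = np.empty(n_cells, dtype=int)
    start = 0
    for code, cnt in zip(sorted(LANDUSE_CLASSES), counts):
        codes[order[start:start + cnt]] = code
        start += cnt
    return LandscapeRaster(values=codes.reshape(shape), kind="landuse")


def place_individuals(config: SyntheticConfig, landuse: LandscapeRaster
                      ) -> GenotypeTable:
    """Place individuals uniformly over habitat cells and assign sexes.

    Returns a genotype table with locations and sexes only (no loci yet).
    With ``distinct_cells`` each individual occupies its own cell.
    """
    rng = _rng(config, 3)
    habitat_codes = {LANDUSE_CODES[c] for c in config.habitat_classes}
    mask = np.isin(landuse.values, list(habitat_codes))
    cells = np.argwhere(mask)
    if config.distinct_cells and len(cells) < config.n_individuals:
        raise GenerationError(
            f"only {len(cells)} habitat cells for {config.n_individuals} "
            "individuals with distinct-cell placement"
        )
    if len(cells) == 0:
        raise GenerationError("no habitat cells available")
    chosen = rng.choice(len(cells), size=config.n_individuals,
                        replace=not config.distinct_cells)
    locations = [tuple(int(v) for v in cells[k]) for k in chosen]
    n_males = round(config.n_individuals * config.sex_ratio)
    sexes = np.array(["M"] * n_males + ["F"] * (config.n_individuals - n_males))
    rng.shuffle(sexes)
    n_digits = max(3, len(str(config.n_individuals)))
    ids = [f"ind{k + 1:0{n_digits}d}" for k in range(config.n_individuals)]
    return GenotypeTable(
        ids=ids, loci=[],
        calls=np.zeros((config.n_individuals, 0, 2), dtype=int),
        sex=list(sexes), location=locations,
    )


def effective_cost_matrix(config: SyntheticConfig, table: GenotypeTable,
                          network: PairNetwork) -> np.ndarray:
    """True effective cost D_eff = Euclid + beta * resistant-cell count.

    With ``beta_female`` set, a pair's beta is the mean of its members'
    sex-specific betas (females ``beta_female``, everyone else ``beta``).
    """
    ibr_code = LANDUSE_CODES[config.ibr_class]
    n = table.n
    betas = np.array([
        config.beta_female if (config.beta_female is not None and s == "F")
        else config.beta
        for s in table.sex
    ])
    index = {v: i for i, v in enumerate(table.ids)}
    d_eff = np.zeros((n, n))
    for (a, b), p in network.profiles.items():
        i, j = index[a], index[b]
        pair_beta = 0.5 * (betas[i] + betas[j])
        v = p.euclid_km + pair_beta * p.landuse_counts[ibr_code]
        d_eff[i, j] = d_eff[j, i] = v
    return d_eff


_COV_JITTER = 1e-8

# cache of dissimilarity response curves, keyed by alleles_per_locus
_PHI_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_PHI_SEED = 987654321
_PHI_SAMPLES = 120_000


def dissimilarity_response(alleles_per_locus: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """phi: latent pair correlation -> expected per-locus Bray-Curtis.

    For two diploid individuals whose latent values share correlation rho
    (two independent field draws per locus, quantile-binned into
    ``alleles_per_locus`` equiprobable alleles), returns knots ``rho`` and
    the Monte-Carlo estimate of the expected per-locus dissimilarity
    ``1 - E[multiset allele overlap] / 2``.  Deterministic (fixed internal
    seed); cached per allele count.
    """
    key = int(alleles_per_locus)
    if key in _PHI_CACHE:
        return _PHI_CACHE[key]
    from scipy.stats import norm
    rng = np.random.default_rng(_PHI_SEED)
    edges = norm.ppf(np.arange(1, key) / key)
    rho_knots = np.linspace(0.0, 0.995, 40)
    u = rng.standard_normal((4, _PHI_SAMPLES))
    m = _PHI_SAMPLES
    phi = np.empty_like(rho_knots)
    for t, rho in enumerate(rho_knots):
        s = math.sqrt(1.0 - rho ** 2)
        a1a = np.searchsorted(edges, u[0])
        a1b = np.searchsorted(edges, u[2])
        a2a = np.searchsorted(edges, rho * u[0] + s * u[1])
        a2b = np.searchsorted(edges, rho * u[2] + s * u[3])
        c1 = np.zeros((m, key), dtype=np.int8)
        c2 = np.zeros((m, key), dtype=np.int8)
        rows = np.arange(m)
        np.add.at(c1, (rows, a1a), 1)
        np.add.at(c1, (rows, a1b), 1)
        np.add.at(c2, (rows, a2a), 1)
        np.add.at(c2, (rows, a2b), 1)
        overlap = np.minimum(c1, c2).sum(axis=1)
        phi[t] = 1.0 - overlap.mean() / 2.0
    _PHI_CACHE[key] = (rho_knots, phi)
    return rho_knots, phi


def latent_correlation(config: SyntheticConfig, table: GenotypeTable,
                       network: PairNetwork) -> np.ndarray:
    """Latent correlation matrix planted so E[Bray-Curtis] is linear in cost.

    The construction has three steps.  (1) The effective cost D_eff is
    embedded into Euclidean space (classical multidimensional scaling): the
    resistance-deformed geography.  (2) The planted pairwise cost is the
    true D_eff (rescaled to the embedding's range) plus the embedding's
    non-Euclidean remainder orthogonalized against {1, Euclid, count} —
    landscape texture that keeps the correlation matrix near positive
    semi-definite without leaking into either matrix under test.  (3) The
    correlation profile is the inverse of the dissimilarity response
    ``phi``, so the expected genetic distance rises *linearly* from
    ``phi(1/(1 + noise_sd^2))`` (coincident pairs) to ``phi(rho_floor)`` at
    the largest cost; ``decay_lambda``, when set, is the cost (km) at which
    the correlation would reach ``rho_floor = 0`` (it must then cover the
    landscape's cost range).
    """
    d_eff = effective_cost_matrix(config, table, network)
    n = table.n
    iu = np.triu_indices(n, k=1)
    if n < 3 or float(d_eff[iu].max()) <= 0:
        # degenerate world (all individuals coincident): flat correlation
        c_max = 1.0 / (1.0 + config.noise_sd ** 2)
        corr = np.full((n, n), c_max)
        np.fill_diagonal(corr, 1.0)
        return corr
    centre = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * centre @ (d_eff ** 2) @ centre
    try:
        eigval, eigvec = np.linalg.eigh(gram)
    except np.linalg.LinAlgError as exc:
        raise GenerationError(f"effective-cost embedding failed: {exc}") from None
    pos = eigval > 1e-9 * max(float(eigval.max()), 1.0)
    if not pos.any():
        raise GenerationError(
            "effective-cost matrix admits no Euclidean embedding component"
        )
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    diff = coords[:, None, :] - coords[None, :, :]
    d_emb = np.sqrt((diff ** 2).sum(axis=2))

    ibr_code = LANDUSE_CODES[config.ibr_class]
    index = {v: i for i, v in enumerate(table.ids)}
    dmat = np.zeros((n, n))
    cmat = np.zeros((n, n))
    for (a, b), p in network.profiles.items():
        i, j = index[a], index[b]
        dmat[i, j] = dmat[j, i] = p.euclid_km
        cmat[i, j] = cmat[j, i] = p.landuse_counts[ibr_code]
    dv, cv, ev, costv = dmat[iu], cmat[iu], d_emb[iu], d_eff[iu]
    design = np.vstack([np.ones_like(dv), dv, cv]).T
    coef, *_ = np.linalg.lstsq(design, ev, rcond=None)
    texture = ev - design @ coef  # orthogonal to {1, Euclid, count}
    fit_sd = float((design @ coef).std())
    cost_sd = float(costv.std())
    scale = fit_sd / cost_sd if cost_sd > 0 else 1.0
    planted = scale * costv + texture
    cost = np.zeros((n, n))
    cost[iu] = planted
    cost = cost + cost.T
    cost -= cost.min()  # affine shift; absorbed by the calibration below
    np.fill_diagonal(cost, 0.0)
    cost_max = float(cost.max())
    if config.decay_lambda is not None:
        lam = config.decay_lambda * scale
        if lam < cost_max:
            raise GenerationError(
                f"decay_lambda ({config.decay_lambda:g} km, {lam:g} scaled) "
                f"must cover the largest planted cost ({cost_max / scale:g} km)"
            )
        cost_max = lam

    rho_knots, phi = dissimilarity_response(config.alleles_per_locus)
    c_max = 1.0 / (1.0 + config.noise_sd ** 2)
    e_near = float(np.interp(c_max, rho_knots, phi))
    e_far = float(phi[0])  # rho = 0
    target = e_near + (e_far - e_near) * cost / cost_max
    # invert phi (decreasing in rho)
    corr = np.interp(target, phi[::-1], rho_knots[::-1])
    np.fill_diagonal(corr, 1.0)
    return corr


def simulate_genotypes(config: SyntheticConfig, table: GenotypeTable,
                       network: PairNetwork) -> GenotypeTable:
    """Draw diploid genotypes whose dissimilarity tracks the effective cost.

    Per locus, two independent latent vectors are drawn from a zero-mean
    multivariate normal with the calibrated correlation of
    :func:`latent_correlation` and quantile-binned into
    ``alleles_per_locus`` equiprobable alleles; the two draws give the
    diploid genotype.  Deterministic given the config seed.
    """
    rng = _rng(config, 4)
    corr = latent_correlation(config, table, network)
    eig_min = float(np.linalg.eigvalsh(corr).min())
    if eig_min < -1.0:
        raise GenerationError(
            f"latent correlation too far from positive semi-definite "
            f"(min eigenvalue {eig_min:.3f})"
        )
    nugget = max(0.0, -eig_min) + _COV_JITTER
    try:
        chol = np.linalg.cholesky(corr + nugget * np.eye(table.n))
    except np.linalg.LinAlgError as exc:
        raise GenerationError(
            f"latent correlation not positive definite after nugget repair: {exc}"
        ) from None
    marginal_sd = math.sqrt(1.0 + nugget)
    from scipy.stats import norm
    k = config.alleles_per_locus
    edges = norm.ppf(np.arange(1, k) / k, scale=marginal_sd)
    calls = np.zeros((table.n, config.n_loci, 2), dtype=int)
    for l in range(config.n_loci):
        for copy in range(2):
            z = chol @ rng.standard_normal(table.n)
            calls[:, l, copy] = np.searchsorted(edges, z) + 1
    loci = [f"locus{l + 1:02d}" for l in range(config.n_loci)]
    return GenotypeTable(
        ids=list(table.ids), loci=loci, calls=calls,
        sex=list(table.sex), location=list(table.location),
    )


def generate_world(config: SyntheticConfig
                   ) -> tuple[LandscapeRaster, LandscapeRaster, GenotypeTable, PairNetwork]:
    """Run the full generation chain: rasters, placements, network, genotypes."""
    elevation = generate_elevation(config)
    landuse = generate_landuse(config)
    table = place_individuals(config, landuse)
    locations = {ind: table.location[i] for i, ind in enumerate(table.ids)}
    network = build_network(locations, elevation, landuse)
    table = simulate_genotypes(config, table, network)
    return elevation, landuse, table, network


def write_bundle(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a world and write it as .asc / .csv / GENEPOP files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    elevation, landuse, table, _ = generate_world(config)
    paths = {
        "elevation": out / "elevation.asc",
        "landuse": out / "landuse.asc",
        "locations": out / "locations.csv",
        "genotypes": out / "genotypes.gen",
    }
    write_ascii_grid(elevation, paths["elevation"])
    write_ascii_grid(landuse, paths["landuse"])
    write_locations_csv(table, paths["locations"])
    write_genepop(table, paths["genotypes"], title="synthetic landscape genotypes")
    return paths
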
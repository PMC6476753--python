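"""Orchestration: strata, screens, decision rules, end-to-end runs.

The analysis asks, for each candidate landscape feature, whether it explains
genetic distance beyond plain geographic separation.  The decision rule (a
causal-modelling triad on Mantel tests) is:

* a feature acts as **resistance** (or **barrier**, with presence/absence
  matrices) when G x R|Dis is significant (p < alpha) while G x Dis|R is
  negative or not significant (p > alpha);
* otherwise the feature has **no support**.

Screens replicate over three strata — all pairs, male pairs, female pairs —
each on independently rebuilt genetic-distance matrices and transect
networks.  Significance is strict (p = alpha exactly counts as not
significant).  No multiplicity correction is applied across screen rows;
alpha is configurable.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (CollinearityError, ConfigurationError,
                     DegenerateMatrixError, LandresError)
from .genotypes import (GenotypeTable, GeneticDistanceMatrix, attach_locations,
                        bray_curtis_matrix, marker_summary, read_genepop,
                        read_locations_csv)
from .mantel import MantelResult, mantel_test, partial_mantel_test
from .matrices import (ELEVATION_PARAMS, ResistanceWeightGrid, barrier_matrix,
                       combined_resistance_matrix, distance_matrix,
                       elevation_matrix, resistance_matrix)
from .rasters import LANDUSE_CLASSES, read_ascii_grid
from .synthetic import SyntheticConfig, generate_world
from .transects import PairNetwork, build_network

STRATA = ("all", "males", "females")
VERDICTS = ("resistance", "barrier", "no_support")


@dataclass
class ScreenRow:
    """One model row of a Table-2/3/4-shaped screen."""

    stratum: str
    model: str               # land-use class name, elevation param, "null", "combined"
    weight: float | None
    r_simple: float = float("nan")
    p_simple: float = float("nan")
    r_partial_model: float = float("nan")   # G x R|Dis  (or G x B|Dis)
    p_partial_model: float = float("nan")
    r_partial_dist: float = float("nan")    # G x Dis|R  (or G x Dis|B)
    p_partial_dist: float = float("nan")
    beats_null: bool = False
    verdict: str = "no_support"
    testable: bool = True
    note: str = ""


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end run (file inputs or synthetic world)."""

    genotypes_path: str | None = None
    locations_path: str | None = None
    elevation_path: str | None = None
    landuse_path: str | None = None
    synthetic: SyntheticConfig | None = None
    weight_grid: ResistanceWeightGrid = field(default_factory=ResistanceWeightGrid)
    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0
    resistance_base: str = "add_distance"
    locus_exclusions: tuple[str, ...] = ()
    strata: tuple[str, ...] = STRATA
    out_dir: str = "landres_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ConfigurationError("n_perm must be >= 99")
        for s in self.strata:
            if s not in STRATA:
                raise ConfigurationError(f"unknown stratum {s!r}")


def _seed_for(base: int, *tags: int) -> list[int]:
    # reproducible independent stream per (run, stage, row, test)
    return [int(base)] + [int(t) for t in tags]


def stratify(table: GenotypeTable, stratum: str) -> GenotypeTable:
    """Subset the table to a sex stratum ('all' is the identity)."""
    if stratum == "all":
        return table
    if stratum not in STRATA:
        raise ConfigurationError(f"unknown stratum {stratum!r}")
    want = "M" if stratum == "males" else "F"
    keep = [i for i, s in enumerate(table.sex) if s == want]
    if not keep:
        raise LandresError(f"stratum {stratum!r} is empty")
    return table.subset(keep)


def classify_resistance(p_model_given_dis: float, r_dist_given_model: float,
                        p_dist_given_model: float, alpha: float = 0.05) -> str:
    """Resistance verdict from the partial-Mantel triad.

    'resistance' iff G x R|Dis is significant (p < alpha) and G x Dis|R is
    negative or not significant (p > alpha); boundary values (p == alpha)
    count as not significant.
    """
    if p_model_given_dis < alpha and (
            r_dist_given_model < 0 or p_dist_given_model > alpha):
        return "resistance"
    return "no_support"


def classify_barrier(p_model_given_dis: float, r_dist_given_model: float,
                     p_dist_given_model: float, alpha: float = 0.05) -> str:
    """Barrier verdict: same triad logic with presence/absence matrices."""
    if p_model_given_dis < alpha and (
            r_dist_given_model < 0 or p_dist_given_model > alpha):
        return "barrier"
    return "no_support"


def landform_screen(G: GeneticDistanceMatrix, network: PairNetwork,
                    config: PipelineConfig, stratum: str = "all"
                    ) -> list[ScreenRow]:
    """Null (Dis) plus the four elevation-parameter simple Mantel rows."""
    dis = distance_matrix(network)
    null_res = mantel_test(G, dis, n_perm=config.n_perm,
                           seed=_seed_for(config.seed, 1, 0))
    rows = [ScreenRow(stratum=stratum, model="null", weight=None,
                      r_simple=null_res.r, p_simple=null_res.p)]
    for k, param in enumerate(ELEVATION_PARAMS, start=1):
        row = ScreenRow(stratum=stratum, model=f"elev_{param}", weight=None)
        try:
            m = elevation_matrix(network, param)
            res = mantel_test(G, m, n_perm=config.n_perm,
                              seed=_seed_for(config.seed, 1, k))
            row.r_simple, row.p_simple = res.r, res.p
            row.beats_null = res.r > null_res.r
        except (DegenerateMatrixError, LandresError) as exc:
            row.testable = False
            row.note = str(exc)
        rows.append(row)
    return rows


def _triad(G, model_matrix, dis, config: PipelineConfig, tags: tuple[int, ...]
           ) -> tuple[MantelResult, MantelResult, MantelResult]:
    simple = mantel_test(G, model_matrix, n_perm=config.n_perm,
                         seed=_seed_for(config.seed, *tags, 0))
    part_model = partial_mantel_test(G, model_matrix, dis, n_perm=config.n_perm,
                                     seed=_seed_for(config.seed, *tags, 1))
    part_dist = partial_mantel_test(G, dis, model_matrix, n_perm=config.n_perm,
                                    seed=_seed_for(config.seed, *tags, 2))
    return simple, part_model, part_dist


def landuse_screen(G: GeneticDistanceMatrix, network: PairNetwork,
                   config: PipelineConfig, mode: str, stratum: str = "all"
                   ) -> list[ScreenRow]:
    """Resistance (7 classes x weight grid + combined) or barrier (7 classes).

    Rows whose model matrix is degenerate (class absent from every transect,
    or perfectly collinear with distance) are marked untestable rather than
    raising.
    """
    if mode not in ("resistance", "barrier"):
        raise ConfigurationError(f"mode must be 'resistance' or 'barrier', got {mode!r}")
    dis = distance_matrix(network)
    null_res = mantel_test(G, dis, n_perm=config.n_perm,
                           seed=_seed_for(config.seed, 2, 0))
    rows = [ScreenRow(stratum=stratum, model="null", weight=None,
                      r_simple=null_res.r, p_simple=null_res.p)]
    stage = 3 if mode == "resistance" else 4

    def run_row(row: ScreenRow, matrix, tags) -> None:
        try:
            simple, pm, pdist = _triad(G, matrix, dis, config, tags)
        except (DegenerateMatrixError, CollinearityError) as exc:
            row.testable = False
            row.note = str(exc)
            return
        row.r_simple, row.p_simple = simple.r, simple.p
        row.r_partial_model, row.p_partial_model = pm.r, pm.p
        row.r_partial_dist, row.p_partial_dist = pdist.r, pdist.p
        row.beats_null = simple.r > null_res.r
        classify = classify_resistance if mode == "resistance" else classify_barrier
        row.verdict = classify(pm.p, pdist.r, pdist.p, config.alpha)

    if mode == "barrier":
        for code in sorted(LANDUSE_CLASSES):
            row = ScreenRow(stratum=stratum, model=LANDUSE_CLASSES[code], weight=None)
            run_row(row, barrier_matrix(network, code), (stage, code))
            rows.append(row)
        return rows

    for code in sorted(LANDUSE_CLASSES):
        for w_idx, weight in enumerate(config.weight_grid.weights):
            row = ScreenRow(stratum=stratum, model=LANDUSE_CLASSES[code],
                            weight=float(weight))
            run_row(row, resistance_matrix(network, code, weight,
                                           config.resistance_base),
                    (stage, code, w_idx))
            rows.append(row)
    # combined model: classes whose best (argmax r_simple, ties to smallest
    # weight) row passes the resistance rule, each at its best weight
    members = []
    for code in sorted(LANDUSE_CLASSES):
        best = best_row(rows, LANDUSE_CLASSES[code])
        if best is not None and best.verdict == "resistance":
            members.append((code, best.weight))
    if members:
        label = "combined(" + "+".join(
            f"{LANDUSE_CLASSES[c]}@{w:g}" for c, w in members) + ")"
        row = ScreenRow(stratum=stratum, model=label, weight=None)
        run_row(row, combined_resistance_matrix(network, members,
                                                config.resistance_base),
                (stage, 99))
        rows.append(row)
    return rows


def best_row(rows: list[ScreenRow], model: str) -> ScreenRow | None:
    """The model's best-weight row: argmax simple r, ties to smallest weight."""
    cand = [r for r in rows if r.model == model and r.testable
            and np.isfinite(r.r_simple)]
    if not cand:
        return None
    return max(cand, key=lambda r: (r.r_simple, -(r.weight or 0)))


def class_verdicts(rows: list[ScreenRow]) -> dict[str, str]:
    """Class-level verdicts from each land-use class's best row."""
    out = {}
    for code in sorted(LANDUSE_CLASSES):
        name = LANDUSE_CLASSES[code]
        best = best_row(rows, name)
        out[name] = best.verdict if best is not None else "untestable"
    return out


def screen_to_dataframe(rows: list[ScreenRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows])


def _log(msg: str) -> None:
    print(f"[landres] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """End-to-end run: inputs -> networks -> screens -> report bundle on disk.

    Returns a dict with the in-memory tables and screen rows; writes the
    network TSV, model matrices, per-stratum screen tables, marker summary
    and a JSON run manifest under ``config.out_dir``.  Deterministic given
    the config seed.
    """
    t0 = time.time()
    if config.synthetic is None and not all(
            [config.genotypes_path, config.locations_path,
             config.elevation_path, config.landuse_path]):
        raise ConfigurationError(
            "either a synthetic config or all four input paths are required"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        _log("generating synthetic world")
        elevation, landuse, table, _ = generate_world(config.synthetic)
    else:
        _log("reading inputs")
        table = read_genepop(config.genotypes_path)
        table = attach_locations(table, read_locations_csv(config.locations_path))
        elevation = read_ascii_grid(config.elevation_path, kind="elevation")
        landuse = read_ascii_grid(config.landuse_path, kind="landuse")
    if config.locus_exclusions:
        table = table.drop_loci(config.locus_exclusions)

    marker_summary(table).to_csv(out / "marker_summary.tsv", sep="\t", index=False)

    report: dict = {"config": config, "strata": {}}
    for stratum in config.strata:
        t_stratum = time.time()
        sub = stratify(table, stratum)
        locations = {ind: sub.location[i] for i, ind in enumerate(sub.ids)}
        if any(loc is None for loc in locations.values()):
            raise LandresError("all individuals need grid locations")
        network = build_network(locations, elevation, landuse)
        G = bray_curtis_matrix(sub)
        G.to_tsv(out / f"G_{stratum}.tsv")
        distance_matrix(network).to_tsv(out / f"Dis_{stratum}.tsv")
        network.to_tsv(out / f"network_{stratum}.tsv")
        landform = landform_screen(G, network, config, stratum)
        resistance = landuse_screen(G, network, config, "resistance", stratum)
        barrier = landuse_screen(G, network, config, "barrier", stratum)
        screen_to_dataframe(landform).to_csv(
            out / f"landform_{stratum}.tsv", sep="\t", index=False)
        screen_to_dataframe(resistance).to_csv(
            out / f"resistance_{stratum}.tsv", sep="\t", index=False)
        screen_to_dataframe(barrier).to_csv(
            out / f"barrier_{stratum}.tsv", sep="\t", index=False)
        report["strata"][stratum] = {
            "n": sub.n, "landform": landform, "resistance": resistance,
            "barrier": barrier,
            "class_verdicts": class_verdicts(resistance),
        }
        _log(f"stratum {stratum}: n={sub.n}, "
             f"{time.time() - t_stratum:.1f}s")

    manifest = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "resistance_base": config.resistance_base,
        "weight_grid": list(config.weight_grid.weights),
        "strata": {s: report["strata"][s]["n"] for s in config.strata},
        "locus_exclusions": list(config.locus_exclusions),
        "synthetic": (asdict(config.synthetic)
                      if config.synthetic is not None else None),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    _log(f"done in {time.time() - t0:.1f}s -> {out}")
    return report
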
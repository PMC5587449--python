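"""Synthetic inputs with known ground truth, plus the packaged reference table.

Everything the pipeline consumes can be generated here with the generating
parameters in hand:

* per-species temperature samples from Normal densities whose flank
  inflections are known in closed form (mu - sigma on the cold axis,
  mu + sigma on the hot axis), so niche estimation is testable as a
  parameter-recovery problem;
* small monthly raster stacks with analytically specified cell values, in
  the same text dialect the climate module reads;
* Brownian-motion trait evolution on trees (random or supplied), the model
  under which Blomberg's K is calibrated to 1;
* the published per-species niche table for 23 Glossophaginae nectar-
  feeding bat species plus the mormoopid outgroup, shipped as packaged
  data.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable

import dendropy
import numpy as np
import pandas as pd

from .climate import GridSpec, ThermalProfile, write_ascii_grid
from .errors import ParameterError, ScenarioError
from .niche import ThermalNiche
from .occurrences import LocalityRecord

_MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True)
class SpeciesScenario:
    """Generating parameters for one synthetic species.

    Cold-axis temperatures are drawn from Normal(mu_cold, sigma_cold),
    hot-axis from Normal(mu_hot, sigma_hot); pairs violating
    t_cold <= t_hot are redrawn. The implied true tolerance-zone limits
    are the analytic density inflections mu_cold - sigma_cold and
    mu_hot + sigma_hot.
    """

    name: str
    mu_cold: float
    sigma_cold: float
    mu_hot: float
    sigma_hot: float
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.sigma_cold <= 0 or self.sigma_hot <= 0:
            raise ParameterError("sigma must be > 0")
        if self.n < 15:
            raise ParameterError("scenario needs n >= 15 localities")

    @property
    def true_stz_lower(self) -> float:
        return self.mu_cold - self.sigma_cold

    @property
    def true_stz_upper(self) -> float:
        return self.mu_hot + self.sigma_hot


def gen_species_profiles(
    scenario: SpeciesScenario,
) -> tuple[list[ThermalProfile], ThermalNiche]:
    """Draw one species' thermal profiles and return them with the truth.

    The returned niche has analytic STZ limits and *realized* SRZ limits
    (the sample extremes — by construction the quantity the pipeline
    defines them to be). STZ truths are clamped into the realized SRZ
    interval in the (small-n) cases where an extreme falls inside them.
    """
    sig = max(scenario.sigma_cold, scenario.sigma_hot)
    if scenario.mu_hot - scenario.mu_cold < -5.0 * sig:
        raise ScenarioError(
            "hot-axis mean lies more than 5 sigma below the cold-axis mean; "
            "the t_cold <= t_hot constraint cannot be satisfied by resampling"
        )
    rng = np.random.default_rng(scenario.seed)
    cold = rng.normal(scenario.mu_cold, scenario.sigma_cold, scenario.n)
    hot = rng.normal(scenario.mu_hot, scenario.sigma_hot, scenario.n)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = cold > hot
        if not bad.any():
            break
        k = int(bad.sum())
        cold[bad] = rng.normal(scenario.mu_cold, scenario.sigma_cold, k)
        hot[bad] = rng.normal(scenario.mu_hot, scenario.sigma_hot, k)
    else:
        raise ScenarioError("resampling failed to satisfy t_cold <= t_hot")
    profiles = [
        ThermalProfile(
            locality=LocalityRecord(
                species=scenario.name,
                longitude=-100.0 + 1e-4 * i,
                latitude=20.0,
                source_id=f"syn{i}",
            ),
            t_cold=float(c),
            t_hot=float(h),
        )
        for i, (c, h) in enumerate(zip(cold, hot))
    ]
    srz_lower = float(cold.min())
    srz_upper = float(hot.max())
    stz_lower = min(max(scenario.true_stz_lower, srz_lower), srz_upper)
    stz_upper = max(min(scenario.true_stz_upper, srz_upper), stz_lower)
    truth = ThermalNiche(srz_lower, stz_lower, stz_upper, srz_upper)
    return profiles, truth


def gen_raster_stack(
    out_dir: str | Path,
    grid: GridSpec,
    tmin_fn: Callable[[int, float, float], float],
    tmax_fn: Callable[[int, float, float], float],
    scale: float = 0.1,
    quantize: bool = True,
    nodata: float = -9999.0,
) -> tuple[list[Path], list[Path]]:
    """Write 24 monthly ESRI ASCII grids with analytically specified values.

    ``tmin_fn(month, lon, lat)`` / ``tmax_fn`` give the value in °C at a
    cell centre for month 1..12. Stored values are ``value / scale``,
    rounded to integers when ``quantize`` (the stored-tenths dialect:
    scale 0.1 bounds the round-trip error by 0.05 °C).

    Returns the (tmin_paths, tmax_paths) lists, month-ordered.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lon_centers = grid.xllcorner + grid.cellsize * (np.arange(grid.ncols) + 0.5)
    lat_centers = grid.ymax - grid.cellsize * (np.arange(grid.nrows) + 0.5)
    paths: dict[str, list[Path]] = {"tmin": [], "tmax": []}
    for kind, fn in (("tmin", tmin_fn), ("tmax", tmax_fn)):
        for month in range(1, 13):
            vals = np.array(
                [[fn(month, lon, lat) for lon in lon_centers] for lat in lat_centers],
                dtype=float,
            )
            stored = vals / scale
            fmt = "%.6g"
            if quantize:
                stored = np.round(stored)
                fmt = "%d"
            path = out_dir / f"{kind}{month:02d}.asc"
            write_ascii_grid(path, stored, grid, nodata=nodata, fmt=fmt)
            paths[kind].append(path)
    return paths["tmin"], paths["tmax"]


def gen_random_tree(
    n_tips: int, seed: int, mean_branch_length: float = 1.0
) -> dendropy.Tree:
    """Random rooted bifurcating tree with exponential branch lengths.

    Topology by uniform random sequential joining of subtrees; tip labels
    T1..Tn; every branch length strictly positive.
    """
    if n_tips < 2:
        raise ParameterError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = tns.new_taxon(label=f"T{i + 1}")
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.exponential(mean_branch_length)) + 1e-3
        b.edge.length = float(rng.exponential(mean_branch_length)) + 1e-3
        nodes = [nd for k, nd in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    tree.seed_node = nodes[0]
    return tree


def gen_bm_traits(
    tree: dendropy.Tree,
    root_value: float,
    rate: float,
    seed: int,
    include_internal: bool = False,
):
    """Brownian-motion trait evolution along the tree, root to tips.

    Each node's value is its parent's plus Normal(0, rate * branch length).
    ``rate`` is the Brownian variance per unit branch length (°C² per unit);
    rate 0 propagates the root value unchanged. Returns a tip-label ->
    value map, or (tips, internal) maps when ``include_internal``.
    """
    if rate < 0:
        raise ParameterError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    tips: dict[str, float] = {}
    internal: dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            values[id(nd)] = float(root_value)
        else:
            bl = nd.edge.length
            if bl is None or bl < 0:
                raise ParameterError("Brownian simulation requires branch lengths >= 0")
            values[id(nd)] = values[id(nd.parent_node)] + float(
                rng.normal(0.0, np.sqrt(rate * bl))
            )
        if nd.is_leaf():
            tips[nd.taxon.label if nd.taxon else nd.label] = values[id(nd)]
        else:
            internal[id(nd)] = values[id(nd)]
    if include_internal:
        from .phylo import label_internal_nodes

        label_internal_nodes(tree)
        internal_by_label = {
            nd.label: internal[id(nd)]
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf()
        }
        return tips, internal_by_label
    return tips


def load_table1_fixture(include_outgroup: bool = True) -> pd.DataFrame:
    """The published per-species niche table (23 bat species + outgroup).

    Columns: species, clade, n, srz_lower, stz_lower, stz_upper, srz_upper,
    breadth, stabilized (whether the species' temperature variance
    stabilised with sample size), outgroup.
    """
    with resources.files("thermoniche.data").joinpath(
        "glossophaginae_niche_table.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df["stabilized"] = df["stabilized"].astype(bool)
    df["outgroup"] = df["outgroup"].astype(bool)
    df["breadth"] = df["srz_upper"] - df["srz_lower"]
    if not include_outgroup:
        df = df[~df["outgroup"]].reset_index(drop=True)
    return df
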
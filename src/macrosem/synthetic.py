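"""Synthetic trees, environmental fields, ranges, and structural cell tables.

Everything here is generated under known ground truth so that the assembly,
metric, and model-fitting stages have a parameter-recovery surface: the
birth-death tree emulates a time-calibrated phylogeny at desk scale,
Gaussian-smoothed white-noise fields emulate gridded climate layers,
spreading-dye ranges emulate digitized range maps, and the structural cell
table realizes a known causal model with SAR-correlated errors.

Every operation is a pure function of its inputs and seed; a master seed
spawns per-component substreams so components can be regenerated
independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec
from .sar import sar_error_sample
from .spatial import SpatialWeights, build_weights

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TrueParams",
    "simulate_bd_tree",
    "simulate_env_field",
    "simulate_structural_cell_table",
    "simulate_ranges",
]

# substream indices off the master seed, fixed so that components are
# independently regenerable
_STREAMS = {"tree": 0, "fields": 1, "ranges": 2, "errors": 3}


def substream(master_seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component random substream from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STREAMS[component],))
    return np.random.default_rng(ss)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic study.

    ``true_direct_effects`` maps predictor (exogenous layer or endogenous
    variable) to its standardized coefficient on the response;
    ``true_endogenous_effects`` maps each endogenous variable to the
    coefficients of the exogenous layers that generate it.
    """

    n_species: int = 120
    birth_rate: float = 0.5       # events/Myr
    death_rate: float = 0.1       # events/Myr
    grid_rows: int = 20
    grid_cols: int = 20
    cell_size: float = 100.0      # km
    env_autocorr_range: dict[str, float] = field(
        default_factory=lambda: {"aet": 300.0, "temp_seasonality": 300.0,
                                 "precip_seasonality": 300.0}
    )  # km per layer
    true_direct_effects: dict[str, float] = field(
        default_factory=lambda: {"aet": 0.36, "temp_seasonality": 0.18,
                                 "mean_dr": 0.10}
    )
    true_endogenous_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"mean_dr": {"temp_seasonality": 0.5}}
    )
    sar_lambda: float = 0.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        if not abs(self.sar_lambda) < 1:
            raise ValueError("|sar_lambda| must be < 1")
        if self.grid_rows * self.grid_cols < 9:
            raise ValueError("grid must have at least 9 cells")

    def grid(self) -> GridSpec:
        return GridSpec(self.grid_rows, self.grid_cols, self.cell_size)


@dataclass(frozen=True)
class TrueParams:
    """Generating coefficients of a structural cell table."""

    direct_effects: dict[str, float]
    endogenous_effects: dict[str, dict[str, float]]
    sar_lambda: float
    noise_sd: float
    response: str = "richness"


def simulate_bd_tree(
    birth_rate: float,
    death_rate: float,
    n_tips: int,
    seed: int,
    max_retries: int = 1000,
) -> dendropy.Tree:
    """Forward birth-death simulation conditioned on ``n_tips`` extant tips.

    A single stem lineage is run forward (Gillespie); the simulation stops
    at a uniform point inside the first inter-event interval during which
    exactly ``n_tips`` lineages are alive, extinct lineages are pruned, and
    unary nodes are suppressed.  Full extinction triggers a retry (up to
    ``max_retries``, then raises).  The result is rooted, ultrametric, with
    positive branch lengths and tips labelled ``s1..sN`` in order of birth.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    total_rate = birth_rate + death_rate
    p_birth = birth_rate / total_rate
    for _ in range(max_retries):
        # node records: (parent_index, birth_time); -1 = stem root
        parent = [-1]
        btime = [0.0]
        children: list[list[int]] = [[]]
        alive = [0]
        t = 0.0
        failed = False
        while len(alive) < n_tips:
            t += rng.exponential(1.0 / (total_rate * len(alive)))
            idx = alive[int(rng.integers(len(alive)))]
            if rng.random() < p_birth:
                for _child in range(2):
                    parent.append(idx)
                    btime.append(t)
                    children[idx].append(len(parent) - 1)
                    children.append([])
                    alive.append(len(parent) - 1)
                alive.remove(idx)
            else:
                alive.remove(idx)
                if not alive:
                    failed = True
                    break
        if failed:
            continue
        # stop uniformly inside the interval during which the count is n_tips
        dt_next = rng.exponential(1.0 / (total_rate * len(alive)))
        present = t + rng.uniform(0.0, dt_next)
        return _assemble_tree(parent, btime, children, alive, present)
    raise RuntimeError(
        f"birth-death simulation went extinct {max_retries} times before "
        f"reaching {n_tips} tips"
    )


def _assemble_tree(parent, btime, children, alive, present) -> dendropy.Tree:
    alive_set = set(alive)
    # survivors[i]: does lineage i have an extant descendant (or is extant)?
    survives = [False] * len(parent)
    order = sorted(range(len(parent)), key=lambda i: btime[i], reverse=True)
    for i in order:
        survives[i] = i in alive_set or any(survives[c] for c in children[i])

    def newick(i: int) -> tuple[str, float]:
        """Subtree string and the time at which lineage i terminates."""
        live_children = [c for c in children[i] if survives[c]]
        if i in alive_set:
            return f"s{_tip_number(i)}", present
        if len(live_children) == 1:  # suppress unary passage through i
            sub, end = newick(live_children[0])
            return sub, end
        parts = []
        split_time = btime[live_children[0]]
        for c in live_children:
            sub, _ = newick(c)
            parts.append(f"{sub}:{_branch(c, split_time=None)}")
        return "(" + ",".join(parts) + ")", split_time

    # branch length of the subtree headed by c = (its end time) - (its start)
    def _branch(c: int, split_time) -> str:
        start = btime[c]
        node = c
        # walk through unary passages: the subtree's visible start is the
        # birth of c; its end is the next surviving split or the present
        end = _end_time(node)
        return f"{end - start:.12f}"

    def _end_time(i: int) -> float:
        while True:
            if i in alive_set:
                return present
            live = [c for c in children[i] if survives[c]]
            if len(live) >= 2:
                return btime[live[0]]
            i = live[0]

    tip_counter = {}

    def _tip_number(i: int) -> int:
        if i not in tip_counter:
            tip_counter[i] = len(tip_counter) + 1
        return tip_counter[i]

    # number extant tips in birth order for reproducible labels
    for i in sorted(alive_set, key=lambda j: (btime[j], j)):
        _tip_number(i)

    root = 0
    # the visible crown root is the first surviving split from the stem
    while True:
        live = [c for c in children[root] if survives[c]]
        if root in alive_set or len(live) >= 2:
            break
        root = live[0]
    if root in alive_set:
        raise RuntimeError("degenerate simulation: single surviving lineage")
    sub, _ = newick(root)
    tree = dendropy.Tree.get(data=sub + ";", schema="newick", rooting="default-rooted")
    return tree


def simulate_env_field(
    grid: GridSpec,
    autocorr_range: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Spatially autocorrelated standardized field on the full grid.

    White noise is smoothed with a Gaussian kernel of scale
    ``autocorr_range`` (in cells) and the result standardized to mean 0,
    sd 1 (population).  ``autocorr_range = 0`` returns standardized white
    noise.  Returns a flat row-major array over all grid cells.
    """
    if autocorr_range < 0:
        raise ValueError("autocorr_range must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.normal(size=(grid.n_rows, grid.n_cols))
    if autocorr_range > 0:
        fieldv = ndimage.gaussian_filter(noise, sigma=autocorr_range, mode="reflect")
    else:
        fieldv = noise
    fieldv = (fieldv - fieldv.mean()) / fieldv.std()
    return fieldv.ravel()


def simulate_structural_cell_table(
    grid: GridSpec,
    config: SimulationConfig,
    weights: SpatialWeights | None = None,
) -> tuple[pd.DataFrame, TrueParams]:
    """Cell table generated under a known structural model with SAR errors.

    Exogenous layers are independent standardized fields.  Each endogenous
    variable is a linear combination of its assigned exogenous layers plus a
    SAR(lambda) error; the response is the linear combination of the direct
    exogenous effects and the endogenous effects plus its own SAR(lambda)
    error.  SAR errors are drawn as (I - lambda W)^{-1} eps with eps i.i.d.
    normal(0, noise_sd).  Returns the table (indexed by retained cell id)
    and the generating :class:`TrueParams`.
    """
    if weights is None:
        weights = build_weights(grid, scheme="queen")
    ev = weights.eigenvalues()
    lo = 1.0 / ev.min() if ev.min() < 0 else -np.inf
    hi = 1.0 / ev.max() if ev.max() > 0 else np.inf
    if not lo < config.sar_lambda < hi:
        raise ValueError(
            f"sar_lambda = {config.sar_lambda} outside the admissible "
            f"interval ({lo:.4f}, {hi:.4f}) of the weight matrix"
        )
    rng_fields = substream(config.seed, "fields")
    rng_err = substream(config.seed, "errors")
    exo_names = sorted(
        set(config.env_autocorr_range)
        | {p for p in config.true_direct_effects if p not in config.true_endogenous_effects}
        | {p for eff in config.true_endogenous_effects.values() for p in eff}
    )
    table = {}
    for name in exo_names:
        rng_km = config.env_autocorr_range.get(name, 0.0)
        sigma_cells = rng_km / grid.cell_size
        table[name] = simulate_env_field(grid, sigma_cells, rng_fields)[grid.retained]
    endo_values = {}
    for endo in sorted(config.true_endogenous_effects):
        coefs = config.true_endogenous_effects[endo]
        val = sum(c * table[p] for p, c in coefs.items())
        val = val + sar_error_sample(weights, config.sar_lambda, config.noise_sd, rng_err)
        endo_values[endo] = val
        table[endo] = val
    resp = np.zeros(weights.n)
    for pred, c in config.true_direct_effects.items():
        resp = resp + c * (endo_values[pred] if pred in endo_values else table[pred])
    resp = resp + sar_error_sample(weights, config.sar_lambda, config.noise_sd, rng_err)
    table["richness"] = resp
    df = pd.DataFrame(table, index=pd.Index(grid.retained, name="cell_id"))
    truth = TrueParams(
        direct_effects=dict(config.true_direct_effects),
        endogenous_effects={k: dict(v) for k, v in config.true_endogenous_effects.items()},
        sar_lambda=config.sar_lambda,
        noise_sd=config.noise_sd,
    )
    return df, truth


def brownian_optima(tree, rng: np.random.Generator) -> dict[str, float]:
    """Unit-rate Brownian niche optima per tip (preorder accumulation of
    N(0, branch length) increments); only relative values are meaningful."""
    optima = {}
    node_vals = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_vals[node] = 0.0
        else:
            node_vals[node] = node_vals[node.parent_node] + rng.normal(
                0.0, np.sqrt(node.edge.length)
            )
        if node.is_leaf():
            optima[node.taxon.label] = node_vals[node]
    return optima


def simulate_ranges(
    tree: dendropy.Tree,
    grid: GridSpec,
    env_layer: np.ndarray,
    niche_sd: float,
    range_size_dist=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Spreading-dye ranges driven by niche optima evolved on the tree.

    Each species' environmental optimum evolves on the tree by unit-rate
    Brownian motion (only relative optima matter).  A species' range grows
    from the retained cell best matching ``optimum + N(0, niche_sd)`` by
    repeatedly accreting the free rook-adjacent neighbour whose environment
    best matches the optimum, until a drawn range size is reached; ranges
    are therefore cell-connected and every species occupies at least one
    cell.  Sizes exceeding the number of retained cells are truncated with
    a warning.

    ``range_size_dist(rng, n)`` draws the target sizes (default: lognormal
    with median ~5% of retained cells, clipped to >= 1).  Returns the PAM as
    a 0/1 frame, retained cells x species.
    """
    ss = np.random.SeedSequence(seed)
    ss_opt, ss_place = ss.spawn(2)
    rng = np.random.default_rng(ss_place)
    retained = grid.retained
    n_cells = len(retained)
    env = np.asarray(env_layer, dtype=float)
    if env.shape[0] == grid.n_cells_total:
        env = env[retained]
    elif env.shape[0] != n_cells:
        raise ValueError("env layer length matches neither the full grid nor retained cells")

    optima = brownian_optima(tree, np.random.default_rng(ss_opt))
    species = sorted(optima)

    if range_size_dist is None:
        def range_size_dist(r, n):
            med = max(1.0, 0.05 * n_cells)
            return np.maximum(1, np.round(r.lognormal(np.log(med), 0.75, size=n))).astype(int)
    sizes = np.asarray(range_size_dist(rng, len(species)), dtype=int)
    if np.any(sizes > n_cells):
        logger.warning(
            "%d drawn range sizes exceed the %d retained cells; truncating",
            int(np.sum(sizes > n_cells)), n_cells,
        )
        sizes = np.minimum(sizes, n_cells)

    # rook neighbour lists among retained cells
    pos = {cid: i for i, cid in enumerate(retained)}
    rows, cols = grid.rowcol(retained)
    nbrs: list[list[int]] = [[] for _ in range(n_cells)]
    for i, cid in enumerate(retained):
        r, c = rows[i], cols[i]
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                j = pos.get(rr * grid.n_cols + cc)
                if j is not None:
                    nbrs[i].append(j)

    pam = np.zeros((n_cells, len(species)), dtype=np.int8)
    for s_idx, sp in enumerate(species):
        opt = optima[sp]
        target = opt + rng.normal(0.0, niche_sd) if niche_sd > 0 else opt
        seed_cell = int(np.argmin(np.abs(env - target)))
        occupied = {seed_cell}
        frontier = {j for j in nbrs[seed_cell]}
        while len(occupied) < sizes[s_idx]:
            frontier -= occupied
            if not frontier:
                break  # connected component exhausted
            cand = sorted(frontier)
            best = cand[int(np.argmin(np.abs(env[cand] - opt)))]
            occupied.add(best)
            frontier.update(nbrs[best])
        pam[sorted(occupied), s_idx] = 1
    return pd.DataFrame(pam, index=pd.Index(retained, name="cell_id"), columns=species)
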
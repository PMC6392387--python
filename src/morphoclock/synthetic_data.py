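"""Forward simulation of timetrees, relaxed-clock rates and Mk matrices.

The generator mirrors the inference model: trees come from a sampled
birth--death process conditioned on the tip count and rescaled to a target
root age; branch rates are iid lognormal; characters evolve under Mk with
continuous-gamma site rates; cells are masked at random; and optionally
only characters variable among the tips are retained, topping the matrix
up to a target size — the scoring practice that creates ascertainment
bias.

:func:`make_study_replica` bundles all of it into a replica of a
placental-mammal morphological-clock study: a 40-taxon extant-only matrix
in four anatomical partitions (cranial, dental, postcranial, soft tissue;
1,284/1,451/925/881 characters at full scale), with normal fossil
calibrations attached to compatible clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morph_matrix_io import MISSING, CharacterMatrix, PartitionScheme
from .time_tree_priors import (
    BirthDeathParams,
    CalibrationPrior,
    _bd_quantile,
    mammal_calibrations,
)
from .trees import TimeTree

__all__ = [
    "PartitionSimSpec",
    "SimulationSpec",
    "TruthTable",
    "StudyReplica",
    "simulate_timetree",
    "draw_branch_rates",
    "simulate_characters",
    "ascertainment_filter",
    "make_study_replica",
    "STUDY_PARTITION_SIZES",
]

#: full-scale anatomical partition sizes of the emulated study design
STUDY_PARTITION_SIZES = {
    "cranial": 1284,
    "dental": 1451,
    "postcranial": 925,
    "soft": 881,
}

#: among-partition rate multipliers (arbitrary heterogeneity knobs that the
#: partitioned model can exploit; not estimates of anatomical rates)
STUDY_RATE_MULTIPLIERS = {
    "cranial": 1.0,
    "dental": 1.5,
    "postcranial": 0.8,
    "soft": 1.2,
}

#: default state-count distribution: mostly binary with a thin tail to 10,
#: the empirical shape of discrete morphological matrices
DEFAULT_K_PROBS = {
    2: 0.70, 3: 0.20, 4: 0.05,
    5: 0.01, 6: 0.01, 7: 0.01, 8: 0.01, 9: 0.005, 10: 0.005,
}


@dataclass(frozen=True)
class PartitionSimSpec:
    """Per-partition simulation settings."""

    name: str
    n_characters: int
    rate_multiplier: float = 1.0
    k_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_K_PROBS))
    gamma_alpha: float | None = 1.0  # None = homogeneous site rates

    def __post_init__(self) -> None:
        if self.n_characters < 1:
            raise ValueError("partition needs at least one character")
        if self.rate_multiplier <= 0:
            raise ValueError("rate multiplier must be > 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Full study-replica simulation settings."""

    n_taxa: int = 40
    root_age: float = 180.0
    birth: float = 0.03
    death: float = 0.02
    sampling: float = 0.01
    clock_m: float = float(np.log(0.005))
    clock_s: float = 0.4
    partitions: tuple[PartitionSimSpec, ...] = ()
    missing_fraction: float = 0.3
    ascertainment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing fraction must be in [0, 1)")


@dataclass
class TruthTable:
    """Ground truth of one simulated replica."""

    ages: np.ndarray
    rates: dict[str, np.ndarray]
    char_k: np.ndarray
    clock_m: float
    clock_s: float
    partition_multipliers: dict[str, float]


@dataclass
class StudyReplica:
    tree: TimeTree
    matrix: CharacterMatrix
    scheme: PartitionScheme
    calibrations: list[CalibrationPrior]
    truth: TruthTable
    spec: SimulationSpec


# ---------------------------------------------------------------------------
# trees and rates


def simulate_timetree(
    n_taxa: int,
    root_age: float,
    birth: float = 0.03,
    death: float = 0.0,
    sampling: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> TimeTree:
    """Birth--death tree conditioned on the tip count and root age.

    The n-2 non-root divergence times are iid draws from the
    single-lineage age density of the sampled birth--death process on
    (0, root_age); the topology follows by splitting a uniformly chosen
    extant lineage at each successive divergence (the exchangeable shape
    of the conditioned process).
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(rng)
    params = BirthDeathParams(birth, death, sampling)
    inner = np.array(
        sorted(
            (_bd_quantile(u, root_age, params) for u in rng.random(n_taxa - 2)),
            reverse=True,
        )
    )
    ages_desc = np.concatenate(([root_age], inner))  # internal ages, oldest first

    # provisional ids: tips 0..n-1 created on the fly; internals n..2n-2
    n = n_taxa
    parent_of: dict[int, int] = {}
    kids: dict[int, list[int]] = {}
    next_tip = 0
    open_lineages: list[int] = []  # provisional node currently able to split

    def new_internal(i: int) -> int:
        return n + i

    root_id = new_internal(0)
    kids[root_id] = []
    open_lineages = [root_id, root_id]  # two daughter slots of the root
    owners = [root_id, root_id]
    # each entry of open_lineages is the parent whose daughter is still open
    for i in range(1, n - 1):
        j = int(rng.integers(len(owners)))
        par = owners.pop(j)
        node = new_internal(i)
        kids[par].append(node)
        parent_of[node] = par
        kids[node] = []
        owners.extend([node, node])
    for par in owners:
        kids[par].append(next_tip)
        parent_of[next_tip] = par
        next_tip += 1

    # renumber internals by ascending age so parents index above children
    order = np.argsort(ages_desc)  # ascending age: root last
    final_idx = {new_internal(int(i)): n + rank for rank, i in enumerate(order)}
    ages = np.zeros(2 * n - 1)
    children = np.zeros((n - 1, 2), dtype=np.int64)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    for i in range(n - 1):
        prov = new_internal(i)
        f = final_idx[prov]
        ages[f] = ages_desc[i]
        c = [final_idx.get(k, k) for k in kids[prov]]
        children[f - n] = c
        for cc in c:
            parent[cc] = f
    taxa = [f"taxon{i + 1:02d}" for i in range(n)]
    return TimeTree(taxa, parent, children, ages)


def draw_branch_rates(
    tree: TimeTree, m: float, s: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Per-node parent-edge rates, iid LogNormal(m, s); s=0 gives the
    strict-clock limit exp(m).  The root entry is a placeholder."""
    if s < 0:
        raise ValueError("s must be >= 0")
    rng = np.random.default_rng(rng)
    if s == 0:
        return np.full(tree.n_nodes, np.exp(m))
    rates = np.exp(rng.normal(m, s, size=tree.n_nodes))
    rates[tree.root] = np.exp(m)
    return rates


# ---------------------------------------------------------------------------
# characters


def _draw_k(k_probs: dict[int, float], size: int, rng) -> np.ndarray:
    ks = np.array(sorted(k_probs))
    p = np.array([k_probs[k] for k in ks], dtype=float)
    p /= p.sum()
    return rng.choice(ks, size=size, p=p)


def _evolve_columns(
    tree: TimeTree,
    nu_per_node: np.ndarray,
    kvec: np.ndarray,
    site_rates: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one state per (node, character) down the tree; returns the
    tip block.  Transitions use the Mk event construction: with
    probability exp(-k nu/(k-1)) the state is copied, otherwise it is
    redrawn uniformly from the k states."""
    C = len(kvec)
    states = np.zeros((tree.n_nodes, C), dtype=np.int16)
    states[tree.root] = np.floor(rng.random(C) * kvec).astype(np.int16)
    for v in reversed(range(tree.n_tips, tree.n_nodes)):  # preorder-ish: parents first
        for c in tree.children_of(v):
            nu = nu_per_node[c] * site_rates
            e = np.exp(-kvec * nu / (kvec - 1.0))
            redraw = rng.random(C) >= e
            new = states[v].copy()
            new[redraw] = np.floor(rng.random(redraw.sum()) * kvec[redraw]).astype(
                np.int16
            )
            states[c] = new
    return states[: tree.n_tips]


def simulate_characters(
    tree: TimeTree,
    rates: np.ndarray,
    partitions: list[PartitionSimSpec],
    missing_fraction: float = 0.0,
    rng: np.random.Generator | int | None = None,
    rates_by_partition: dict[str, np.ndarray] | None = None,
) -> tuple[CharacterMatrix, np.ndarray]:
    """Forward-simulate a partitioned matrix; returns (matrix, true k).

    ``rates`` is the shared per-node branch-rate vector; a partition's
    effective rate is ``rates * rate_multiplier`` unless an explicit
    per-partition vector is supplied in ``rates_by_partition``.
    """
    rng = np.random.default_rng(rng)
    dur = tree.branch_durations()
    blocks, kall, labels, ids = [], [], [], []
    count = 0
    for ps in partitions:
        r = (
            rates_by_partition[ps.name]
            if rates_by_partition is not None
            else rates * ps.rate_multiplier
        )
        nu = r * dur
        kvec = _draw_k(ps.k_probs, ps.n_characters, rng).astype(np.int64)
        if ps.gamma_alpha is None:
            srates = np.ones(ps.n_characters)
        else:
            srates = rng.gamma(ps.gamma_alpha, 1.0 / ps.gamma_alpha, ps.n_characters)
        tips = _evolve_columns(tree, nu, kvec, srates, rng)
        if missing_fraction > 0:
            mask = rng.random(tips.shape) < missing_fraction
            tips = np.where(mask, np.int16(MISSING), tips)
        blocks.append(tips)
        kall.append(kvec)
        labels.extend([ps.name] * ps.n_characters)
        count += ps.n_characters
    states = np.hstack(blocks)
    kvec = np.concatenate(kall)
    matrix = CharacterMatrix(
        taxa=list(tree.taxa),
        states=states,
        declared_k=kvec,
        partition_label=labels,
        char_id=[f"c{i + 1}" for i in range(states.shape[1])],
    )
    return matrix, kvec


def _variable_columns(states: np.ndarray) -> np.ndarray:
    """Boolean mask of columns with >= 2 distinct non-missing states."""
    out = np.zeros(states.shape[1], dtype=bool)
    for c in range(states.shape[1]):
        col = states[:, c]
        out[c] = len(np.unique(col[col != MISSING])) >= 2
    return out


def ascertainment_filter(
    matrix: CharacterMatrix,
    target_count: int | None = None,
    top_up: bool = False,
    resimulate=None,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 200,
) -> tuple[CharacterMatrix, float]:
    """Drop sample-invariant characters; optionally top up to a target.

    Returns the filtered matrix and the realised proportion of simulated
    characters that were discarded as invariant.  With ``top_up``, the
    ``resimulate(n, rng) -> CharacterMatrix`` callback supplies fresh
    characters from the same process until ``target_count`` variable ones
    have been collected (mimicking fixed-size character scoring); a
    degenerate process that never yields variable characters raises after
    ``max_attempts`` rounds.
    """
    rng = np.random.default_rng(rng)
    keep = _variable_columns(matrix.states)
    n_sim = matrix.n_chars
    n_var = int(keep.sum())
    out = matrix.select(keep)
    if top_up:
        if resimulate is None or target_count is None:
            raise ValueError("top_up requires target_count and a resimulate callback")
        attempts = 0
        while out.n_chars < target_count:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not collect {target_count} variable characters in "
                    f"{max_attempts} rounds (process nearly invariant?)"
                )
            extra = resimulate(max(target_count - out.n_chars, 8), rng)
            n_sim += extra.n_chars
            k2 = _variable_columns(extra.states)
            n_var += int(k2.sum())
            extra = extra.select(k2)
            out = _hcat(out, extra)
        out = out.select(np.arange(target_count))
    discarded = 1.0 - n_var / n_sim if n_sim else 0.0
    return out, discarded


def _hcat(a: CharacterMatrix, b: CharacterMatrix) -> CharacterMatrix:
    ids = [f"c{i + 1}" for i in range(a.n_chars + b.n_chars)]
    return CharacterMatrix(
        list(a.taxa),
        np.hstack([a.states, b.states]),
        np.concatenate([a.declared_k, b.declared_k]),
        list(a.partition_label) + list(b.partition_label),
        ids,
    )


# ---------------------------------------------------------------------------
# study replica


def default_study_spec(seed: int = 0, scale: float = 1.0, n_taxa: int = 40) -> SimulationSpec:
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    parts = []
    for name, size in STUDY_PARTITION_SIZES.items():
        n = int(round(scale * size))
        if n < 1:
            raise ValueError(f"scale {scale} leaves partition {name} empty")
        parts.append(
            PartitionSimSpec(
                name, n, rate_multiplier=STUDY_RATE_MULTIPLIERS[name], gamma_alpha=1.0
            )
        )
    return SimulationSpec(n_taxa=n_taxa, partitions=tuple(parts), seed=seed)


def make_study_replica(
    seed: int,
    scale: float = 1.0,
    n_taxa: int = 40,
    spec: SimulationSpec | None = None,
    n_extra_calibrations: int = 2,
) -> StudyReplica:
    """One fully seeded synthetic study replica.

    Partition sizes are ``round(scale *`` full sizes``)``; branch rates
    are drawn independently per partition (each anatomical unit follows
    its own realisation of the uncorrelated lognormal clock, centred at
    its rate multiplier); the matrix is ascertainment-filtered with
    top-up when the settings ask for it; the packaged calibration table supplies
    the root prior plus ``n_extra_calibrations`` internal-node priors
    attached to the clades whose true ages sit closest to the calibration
    means.
    """
    spec = spec or default_study_spec(seed, scale, n_taxa)
    rng = np.random.default_rng(spec.seed if spec.seed else seed)
    tree = simulate_timetree(
        spec.n_taxa, spec.root_age, spec.birth, spec.death, spec.sampling, rng
    )
    rates_by_partition = {
        ps.name: draw_branch_rates(
            tree, spec.clock_m + np.log(ps.rate_multiplier), spec.clock_s, rng
        )
        for ps in spec.partitions
    }

    # character-level ascertainment first (a character is scored because it
    # varies among the taxa), specimen-level missingness afterwards — so the
    # variable-characters-only conditioning matches the scoring process
    blocks = []
    for ps in spec.partitions:
        mat, kv = simulate_characters(
            tree, np.empty(0), [ps], 0.0, rng,
            rates_by_partition=rates_by_partition,
        )
        if spec.ascertainment:
            def resim(n, r, _ps=ps):
                m2, _ = simulate_characters(
                    tree, np.empty(0),
                    [PartitionSimSpec(_ps.name, n, _ps.rate_multiplier,
                                      dict(_ps.k_probs), _ps.gamma_alpha)],
                    0.0, rng,
                    rates_by_partition=rates_by_partition,
                )
                return m2
            mat, _ = ascertainment_filter(
                mat, target_count=ps.n_characters, top_up=True, resimulate=resim,
                rng=rng,
            )
        blocks.append(mat)
    matrix = blocks[0]
    for b in blocks[1:]:
        matrix = _hcat(matrix, b)
    if spec.missing_fraction > 0:
        mask = rng.random(matrix.states.shape) < spec.missing_fraction
        matrix.states = np.where(mask, np.int16(MISSING), matrix.states)
    scheme = PartitionScheme.from_labels(matrix)

    clade_tips = tree.clade_tips()
    table = mammal_calibrations()
    root_row = table.iloc[-1]  # crown calibration
    calibrations = [
        CalibrationPrior(
            str(root_row["name"]),
            frozenset(tree.taxa),
            float(root_row["mean_Ma"]),
            float(root_row["sd_Ma"]),
        )
    ]
    candidates = list(range(tree.n_tips, tree.root))
    rows = table.iloc[:-1].sample(
        n=min(n_extra_calibrations, len(table) - 1), random_state=seed % (2**31)
    )
    used: set[int] = set()
    for row in rows.itertuples(index=False):
        free = [v for v in candidates if v not in used]
        if not free:
            break
        v = min(free, key=lambda u: abs(tree.ages[u] - row.mean_Ma))
        used.add(v)
        taxa = frozenset(tree.taxa[i] for i in clade_tips[v])
        calibrations.append(
            CalibrationPrior(str(row.name), taxa, float(row.mean_Ma), float(row.sd_Ma))
        )

    truth = TruthTable(
        ages=tree.ages.copy(),
        rates=rates_by_partition,
        char_k=matrix.declared_k.copy(),
        clock_m=spec.clock_m,
        clock_s=spec.clock_s,
        partition_multipliers={
            ps.name: ps.rate_multiplier for ps in spec.partitions
        },
    )
    return StudyReplica(tree, matrix, scheme, calibrations, truth, spec)
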
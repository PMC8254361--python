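"""Tumor-evolution simulator: cell-division trees with copy-number accrual.

The generative model grows a binary cell-division tree from a single
diploid founder.  At each division one extant cell is chosen to divide
(uniformly by default, i.e. a Yule topology; a positive ``split_shape``
switches to a beta-splitting scheme in which each division hands its two
daughter lineages Beta(shape, shape)-distributed fractions of the parent's
division propensity, so small shapes give unbalanced trees and large
shapes near-symmetric ones).  Each daughter edge receives a Poisson number
of copy-number events; an event covers an exponentially sized genomic
segment (mean ``theta`` base pairs, truncated at the chromosome end),
placed uniformly on the genome, and adds or removes a geometrically
distributed number of copies (mean ``1/gain_p``).  Copy number is floored
at zero, and fully deleted bins are immune to later gains -- DNA that is
gone cannot re-amplify.

Leaves of the finished tree are the sampled cells; internal nodes are the
intermediate copy-number states, which no longer exist in the patient but
define the evolutionary (MRCA) distances between groups of cells.  The
scenario constructors turn one tree into the groupings used to validate
the spatial heterogeneity score: founder-progeny subsamples (spatial
segregation), random leaf assignment (spatial intermixing), and seeded
secondary trees (metastatic spread).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cnvdata import CNVMatrix


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """Chromosome lengths (bp) and the fixed bin size used for CN profiles."""

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int

    def __post_init__(self):
        if self.bin_size <= 0:
            raise SimulationError("bin_size must be positive")
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        if not chroms or any(l <= 0 for _, l in chroms):
            raise SimulationError("chromosome lengths must be positive")
        object.__setattr__(self, "chromosomes", chroms)
        lengths = np.array([l for _, l in chroms], dtype=np.int64)
        bp_offsets = np.concatenate([[0], np.cumsum(lengths)])
        nbins = np.array([-(-l // self.bin_size) for l in lengths])
        bin_offsets = np.concatenate([[0], np.cumsum(nbins)])
        object.__setattr__(self, "_lengths", lengths)
        object.__setattr__(self, "_bp_offsets", bp_offsets)
        object.__setattr__(self, "_bins_per_chrom", nbins)
        object.__setattr__(self, "_bin_offsets", bin_offsets)
        object.__setattr__(self, "_index",
                           {name: i for i, (name, _) in enumerate(chroms)})

    @property
    def total_bp(self) -> int:
        return int(self._bp_offsets[-1])

    @property
    def n_bins(self) -> int:
        return int(self._bin_offsets[-1])

    def index_of(self, chromosome: str) -> int:
        try:
            return self._index[str(chromosome)]
        except KeyError:
            raise SimulationError(f"unknown chromosome {chromosome!r}") from None

    def length_of(self, chromosome: str) -> int:
        return int(self._lengths[self.index_of(chromosome)])

    def locate(self, genome_pos: int) -> tuple[int, int]:
        """Map a genome-wide bp offset to (chromosome index, bp on chromosome)."""
        ci = int(np.searchsorted(self._bp_offsets, genome_pos, side="right")) - 1
        return ci, int(genome_pos - self._bp_offsets[ci])

    def bin_span(self, chromosome: str, start: int, length: int) -> tuple[int, int]:
        """Inclusive global bin index range overlapped by [start, start+length)."""
        ci = self.index_of(chromosome)
        off = int(self._bin_offsets[ci])
        return (off + start // self.bin_size,
                off + (start + length - 1) // self.bin_size)

    def bin_table(self) -> pd.DataFrame:
        """Bin coordinates (0-based half-open), clipped at chromosome ends."""
        rows = []
        for (name, length) in self.chromosomes:
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame(
                {"chromosome": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


#: approximate human autosome lengths (Mbp), 22 chromosomes, ~3.1 Gbp
_AUTOSOME_MBP = (248, 242, 198, 190, 181, 171, 159, 145, 138, 134, 135,
                 133, 114, 107, 102, 90, 83, 80, 59, 64, 47, 51)


def default_genome(bin_size: int = 500_000) -> Genome:
    """22 autosome-like chromosomes, ~3.1 Gbp, 500 kb bins (~6200 bins)."""
    return Genome(tuple((f"chr{i + 1}", mbp * 1_000_000)
                        for i, mbp in enumerate(_AUTOSOME_MBP)), bin_size)


def reduced_genome(bin_size: int = 100_000) -> Genome:
    """Single 100 Mbp chromosome, 100 kb bins (1000 bins); test/desk profile."""
    return Genome((("chr1", 100_000_000),), bin_size)


# ---------------------------------------------------------------------------
# events and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNAEvent:
    """One copy-number event: a signed copy delta over a genomic segment."""

    chromosome: str
    start: int       # bp, 0-based on the chromosome
    length: int      # bp, >= 1
    delta: int       # gained (+) or lost (-) copies, != 0

    def __post_init__(self):
        if self.length < 1:
            raise SimulationError("event length must be >= 1 bp")
        if self.delta == 0:
            raise SimulationError("event delta must be non-zero")


@dataclass(frozen=True)
class SimulationConfig:
    """Generation parameters for one simulated tree.

    ``theta`` is the expected CNA segment size in bp (exponential);
    ``gain_p`` the geometric parameter whose reciprocal is the expected
    number of copies gained or lost per event; ``events_per_division`` the
    Poisson mean number of events per daughter edge; ``loss_fraction`` the
    probability an event is a deletion; ``split_shape`` the beta-splitting
    parameter (0 = uniform choice of the dividing cell).
    """

    n_leaves: int
    theta: float = 2_500_000.0
    gain_p: float = 0.5
    events_per_division: float = 1.0
    loss_fraction: float = 0.5
    genome: Genome = field(default_factory=default_genome)
    seed: int | None = None
    split_shape: float = 0.0

    def __post_init__(self):
        if self.n_leaves < 2:
            raise SimulationError("n_leaves must be >= 2")
        if self.theta <= 0:
            raise SimulationError("theta must be positive")
        if not 0 < self.gain_p <= 1:
            raise SimulationError("gain_p must lie in (0, 1]")
        if not 0 <= self.loss_fraction <= 1:
            raise SimulationError("loss_fraction must lie in [0, 1]")
        if self.events_per_division < 0:
            raise SimulationError("events_per_division must be >= 0")
        if self.split_shape < 0:
            raise SimulationError("split_shape must be >= 0")
        if self.theta > self.genome.total_bp:
            raise SimulationError(
                f"theta={self.theta:g} bp exceeds the genome "
                f"({self.genome.total_bp} bp); infeasible event sizes")


def apply_event(genome_state: np.ndarray, event: CNAEvent,
                genome: Genome) -> np.ndarray:
    """Return a copy of ``genome_state`` with ``event`` applied.

    Every bin overlapped by the event gets ``CN := max(0, CN + delta)``;
    bins already at CN 0 are immune to gains.
    """
    if event.start < 0 or event.start + event.length > genome.length_of(
            event.chromosome):
        raise SimulationError(
            f"event {event} outside chromosome {event.chromosome}")
    state = np.array(genome_state, copy=True)
    _apply_event_inplace(state, event, genome)
    return state


def _apply_event_inplace(state: np.ndarray, event: CNAEvent,
                         genome: Genome) -> None:
    b0, b1 = genome.bin_span(event.chromosome, event.start, event.length)
    seg = state[b0:b1 + 1]
    if event.delta > 0:
        seg[seg > 0] += event.delta  # deleted DNA cannot re-amplify
    else:
        np.maximum(seg + event.delta, 0, out=seg)


def _sample_event(rng: np.random.Generator, config: SimulationConfig) -> CNAEvent:
    genome = config.genome
    pos = int(rng.integers(genome.total_bp))
    ci, start = genome.locate(pos)
    name, chrom_len = genome.chromosomes[ci]
    length = max(1, int(math.ceil(rng.exponential(config.theta))))
    length = min(length, chrom_len - start)  # truncate at the chromosome end
    magnitude = int(rng.geometric(config.gain_p))
    delta = -magnitude if rng.random() < config.loss_fraction else magnitude
    return CNAEvent(name, start, length, delta)


def _sample_edge_events(rng: np.random.Generator,
                        config: SimulationConfig) -> list[CNAEvent]:
    return [_sample_event(rng, config)
            for _ in range(rng.poisson(config.events_per_division))]


# ---------------------------------------------------------------------------
# the tree
# ---------------------------------------------------------------------------

class PhyloTree:
    """Simulated binary cell-division tree with per-edge CN events.

    Node ids are assigned in birth order (root = 0); ``division_order``
    records which node divided at each step, so the set of extant cells at
    any historical time point can be replayed.  Copy-number states are not
    stored per node: each edge keeps its event list and states are
    materialised on demand by replaying events from the root state
    (diploid unless the tree was seeded from another tree's cell).
    """

    def __init__(self, genome: Genome, parent: list[int],
                 children: list[list[int]],
                 edge_events: list[list[CNAEvent]],
                 division_order: list[int], root_state: np.ndarray,
                 config: SimulationConfig):
        self.genome = genome
        self.parent = parent
        self.children = children
        self.edge_events = edge_events
        self.division_order = division_order
        self.root_state = np.asarray(root_state, dtype=np.int32)
        self.config = config

    # -- structure -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaves(self) -> list[int]:
        """Leaf node ids in birth order."""
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def _check_node(self, node: int) -> None:
        if not 0 <= node < self.n_nodes:
            raise SimulationError(f"unknown node {node}")

    def depth(self, node: int) -> int:
        self._check_node(node)
        d = 0
        while self.parent[node] >= 0:
            node = self.parent[node]
            d += 1
        return d

    def mrca_distance(self, a: int, b: int) -> int:
        """Number of edges on the unique tree path between two nodes."""
        self._check_node(a)
        self._check_node(b)
        da, db = self.depth(a), self.depth(b)
        dist = 0
        while da > db:
            a = self.parent[a]
            da -= 1
            dist += 1
        while db > da:
            b = self.parent[b]
            db -= 1
            dist += 1
        while a != b:
            a = self.parent[a]
            b = self.parent[b]
            dist += 2
        return dist

    def subtree_leaves(self, node: int) -> list[int]:
        """Leaves under ``node`` (inclusive if it is a leaf), in birth order."""
        self._check_node(node)
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.children[v]:
                stack.extend(self.children[v])
            else:
                out.append(v)
        return sorted(out)

    def founders(self, k: int) -> list[int]:
        """The first ``k`` generated cells whose progenies partition the leaves.

        These are the extant cells after the first ``k - 1`` divisions
        (division = birth order), returned in birth order.
        """
        if not 1 <= k <= self.n_leaves:
            raise SimulationError(
                f"k must lie in [1, {self.n_leaves}], got {k}")
        extant = {0}
        for node in self.division_order[:k - 1]:
            extant.remove(node)
            extant.update(self.children[node])
        return sorted(extant)

    # -- copy-number states ---------------------------------------------

    def node_state(self, node: int) -> np.ndarray:
        """CN profile of one node (root state plus its path's events)."""
        self._check_node(node)
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(self.parent[path[-1]])
        state = self.root_state.copy()
        for v in reversed(path[:-1]):
            for ev in self.edge_events[v]:
                _apply_event_inplace(state, ev, self.genome)
        return state

    def _collect_states(self, wanted: Iterable[int]) -> dict[int, np.ndarray]:
        """States for many nodes in one depth-first replay from the root."""
        wanted = set(wanted)
        out: dict[int, np.ndarray] = {}
        stack: list[tuple[int, np.ndarray]] = [(0, self.root_state.copy())]
        while stack:
            node, state = stack.pop()
            if node in wanted:
                out[node] = state.copy()
            ch = self.children[node]
            if not ch:
                continue
            for c in ch[:-1]:
                cs = state.copy()
                for ev in self.edge_events[c]:
                    _apply_event_inplace(cs, ev, self.genome)
                stack.append((c, cs))
            last = ch[-1]
            for ev in self.edge_events[last]:
                _apply_event_inplace(state, ev, self.genome)
            stack.append((last, state))
        return out

    def leaves_to_matrix(self, sample_label: str = "sample",
                         cell_prefix: str = "cell") -> CNVMatrix:
        """One CNVMatrix row per leaf, in birth order."""
        leaves = self.leaves
        states = self._collect_states(leaves)
        X = np.vstack([states[l] for l in leaves])
        return CNVMatrix(X, self.genome.bin_table(),
                         [f"{cell_prefix}_{l}" for l in leaves], sample_label)

    def to_newick(self) -> str:
        """Topology-only Newick string with node ids and unit branch lengths."""
        def render(node: int) -> str:
            if not self.children[node]:
                return f"n{node}:1"
            inner = ",".join(render(c) for c in self.children[node])
            return f"({inner})n{node}:1"

        return render(0).rsplit(":", 1)[0] + ";"


def simulate_tree(config: SimulationConfig,
                  rng: np.random.Generator | None = None,
                  root_state: np.ndarray | None = None) -> PhyloTree:
    """Grow one cell-division tree to ``config.n_leaves`` leaves.

    Reproducible given ``config.seed`` (or an explicit ``rng``).
    ``root_state`` seeds the founder with an existing CN profile (used for
    metastatic trees); the default founder is diploid everywhere.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genome = config.genome
    if root_state is None:
        root_state = np.full(genome.n_bins, 2, dtype=np.int32)
    else:
        root_state = np.asarray(root_state, dtype=np.int32)
        if root_state.shape != (genome.n_bins,):
            raise SimulationError("root_state does not match the genome bins")

    parent = [-1]
    children: list[list[int]] = [[]]
    edge_events: list[list[CNAEvent]] = [[]]
    division_order: list[int] = []
    extant = [0]
    weighted = config.split_shape > 0
    weights = [1.0] if weighted else None

    while len(extant) < config.n_leaves:
        if weighted:
            w = np.asarray(weights)
            i = int(rng.choice(len(extant), p=w / w.sum()))
        else:
            i = int(rng.integers(len(extant)))
        node = extant[i]
        division_order.append(node)
        kids = []
        for _ in range(2):
            cid = len(parent)
            parent.append(node)
            children.append([])
            edge_events.append(_sample_edge_events(rng, config))
            kids.append(cid)
        children[node] = kids
        if weighted:
            v = float(rng.beta(config.split_shape, config.split_shape))
            w_node = weights[i]
            weights[i] = w_node * v
            weights.append(w_node * (1.0 - v))
        extant[i] = kids[0]
        extant.append(kids[1])

    return PhyloTree(genome, parent, children, edge_events, division_order,
                     root_state, config)


# ---------------------------------------------------------------------------
# scenario constructors
# ---------------------------------------------------------------------------

def scenario_hom(tree: PhyloTree, k: int = 5) -> np.ndarray:
    """Spatial-segregation grouping: one subsample per early founder.

    Each leaf is labelled by the founder (among the first ``k`` generated
    cells) whose progeny it belongs to, emulating subclones that settled
    into isolated niches very early in tumor growth.
    """
    founders = tree.founders(k)
    labels = np.empty(tree.n_leaves, dtype=object)
    leaf_pos = {l: i for i, l in enumerate(tree.leaves)}
    for j, f in enumerate(founders):
        leaves = tree.subtree_leaves(f)
        if not leaves:
            raise SimulationError(f"founder {f} left no leaves")
        for l in leaves:
            labels[leaf_pos[l]] = f"S{j + 1}"
    if any(l is None for l in labels):
        raise SimulationError("founder progenies do not cover all leaves")
    return labels.astype(str)


def scenario_het(tree: PhyloTree, k: int = 5,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Spatial-intermixing grouping: leaves shuffled into ``k`` subsamples."""
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.integers(k, size=tree.n_leaves)
    return np.array([f"S{d + 1}" for d in draws], dtype=str)


def scenario_metastasis(config: SimulationConfig,
                        seed_fraction: float = 0.25,
                        n_leaves_each: int = 500,
                        seed: int | None = None,
                        return_details: bool = False):
    """Primary tumor plus a metastasis seeded from one of its cells.

    The primary tree is grown to ``n_leaves_each`` leaves; when it had
    generated ``seed_fraction`` of that cell count, one extant cell is
    picked at random and its CN state founds a second tree grown, under
    the same event model, to ``n_leaves_each`` leaves.  ``seed_fraction``
    1/4 models early and 3/4 late metastatic spreading.  Returns the two
    leaf matrices labelled ``primary`` and ``metastasis``.
    """
    if not 0 < seed_fraction < 1:
        raise SimulationError("seed_fraction must lie in (0, 1)")
    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    rng_primary, rng_pick, rng_met = map(np.random.default_rng, ss.spawn(3))
    cfg = replace(config, n_leaves=n_leaves_each)
    primary = simulate_tree(cfg, rng=rng_primary)
    n_extant = max(2, round(seed_fraction * n_leaves_each))
    pool = primary.founders(n_extant)
    seed_node = pool[int(rng_pick.integers(len(pool)))]
    met = simulate_tree(cfg, rng=rng_met,
                        root_state=primary.node_state(seed_node))
    prim_mat = primary.leaves_to_matrix("primary", cell_prefix="p")
    met_mat = met.leaves_to_matrix("metastasis", cell_prefix="m")
    if return_details:
        return prim_mat, met_mat, {"primary_tree": primary, "met_tree": met,
                                   "seed_node": seed_node}
    return prim_mat, met_mat


def scenario_var(seed: int | None = None, n_leaves: int = 1000,
                 genome: Genome | None = None,
                 **config_kwargs):
    """Two samples from one tree with randomly drawn event parameters.

    Draws ``theta ~ U[500, 5e6]`` bp and ``gain_p ~ U[0.1, 0.9]``, grows a
    tree of ``n_leaves`` leaves and splits it at the root into two subtree
    samples.  Returns ``(sample_a, sample_b, theta, gain_p)``.
    """
    if genome is None:
        genome = reduced_genome()
    ss = np.random.SeedSequence(seed)
    rng_par, rng_tree = map(np.random.default_rng, ss.spawn(2))
    theta = float(rng_par.uniform(500, 5_000_000))
    gain_p = float(rng_par.uniform(0.1, 0.9))
    config = SimulationConfig(n_leaves=n_leaves, theta=theta, gain_p=gain_p,
                              genome=genome, **config_kwargs)
    tree = simulate_tree(config, rng=rng_tree)
    matrix = tree.leaves_to_matrix()
    left, right = tree.children[0]
    left_set = set(tree.subtree_leaves(left))
    mask = np.array([l in left_set for l in tree.leaves])
    sample_a = matrix.subset_cells(mask).with_sample_labels("S1")
    sample_b = matrix.subset_cells(~mask).with_sample_labels("S2")
    return sample_a, sample_b, theta, gain_p


def subtree_samples(tree: PhyloTree, first_k: int,
                    iqr_filter: bool = True) -> list[tuple[CNVMatrix, int]]:
    """One sample per early founder, optionally size-balanced.

    Tracks the subtrees rooted in the first ``first_k`` generated cells;
    with ``iqr_filter`` only the subtrees whose leaf count lies within
    [Q1, Q3] of the ``first_k`` counts are retained, which balances the
    sample cardinalities.  Returns ``(matrix, founder node id)`` pairs.
    """
    founders = tree.founders(first_k)
    groups = {f: tree.subtree_leaves(f) for f in founders}
    counts = np.array([len(groups[f]) for f in founders])
    keep = founders
    if iqr_filter:
        q1, q3 = np.percentile(counts, [25, 75])
        keep = [f for f, c in zip(founders, counts) if q1 <= c <= q3]
    matrix = tree.leaves_to_matrix()
    leaf_pos = {l: i for i, l in enumerate(tree.leaves)}
    out = []
    for f in keep:
        idx = np.array(sorted(leaf_pos[l] for l in groups[f]))
        out.append((matrix.subset_cells(idx).with_sample_labels(f"F{f}"), f))
    return out


def mrca_distance(tree: PhyloTree, root_a: int, root_b: int) -> int:
    """Edge count between two subtree roots on the parental tree."""
    return tree.mrca_distance(root_a, root_b)
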
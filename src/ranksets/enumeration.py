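"""Grid enumeration of partition-inducing gene sets.

The search tries every combination of partition size *s* (from a small
margin up to *n* minus that margin) and tolerance *t*.  At each (s, t) cell
every probe's top-*s* sample set is computed, probes whose sets differ by at
most *t* elements are joined by an edge, and the connected components of
that match graph — of at least a minimum size, six by default — are the
gene-set instances of the cell.

Left unchecked, large *t* merges everything into one component, so the
ceiling on *t* is set per *s* either by a fallback cap (``floor(s/2)``) or
by a sentinel stop rule: *t* is incremented from 0 until a designated
sentinel set (e.g. interferon genes) stops being a distinct object because
its component absorbs a designated foil probe (e.g. other immune genes).

Edges only accumulate as *t* grows, so components merge monotonically; a
spiral search (coarse steps refined around hits) provides fast
reconnaissance of where the non-trivial cells lie.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .dataio import ExpressionMatrix
from .partition import TopSampleSet, is_match, rank_order

__all__ = [
    "SentinelConfig",
    "GridConfig",
    "GeneSetInstance",
    "GeneSetEnumerator",
    "build_match_graph",
    "components_at",
    "consensus_samples",
    "t_max_for_s",
    "spiral_search",
    "enumerate_grid",
    "write_instances",
    "read_instances",
]

logger = logging.getLogger(__name__)

# above this many probes the pairwise overlap matrix is held sparse
_DENSE_PROBE_LIMIT = 4000


@dataclass(frozen=True)
class SentinelConfig:
    """Sentinel stop rule: probes that must remain a distinct component.

    ``sentinel_probes`` is the set to preserve (the interferon genes in the
    original breast-cancer runs); ``foil_probes`` are the probes it must not
    merge with (other immune genes).  The sentinel counts as merged at a
    cell when one component holds at least ``majority_fraction`` of the
    sentinel probes together with at least one foil probe.
    """

    sentinel_probes: tuple
    foil_probes: tuple
    majority_fraction: float = 0.5

    def __post_init__(self):
        if not 0 < self.majority_fraction <= 1:
            raise ValueError("majority_fraction must be in (0, 1]")
        if set(self.sentinel_probes) & set(self.foil_probes):
            raise ValueError("sentinel and foil probe lists must be disjoint")


@dataclass(frozen=True)
class GridConfig:
    """Parameters of the (s, t) grid search."""

    s_margin: int = 6
    s_step: int = 1
    min_set_size: int = 6
    t_start: int = 0
    t_cap: int | None = None  # fallback ceiling when no sentinel: floor(s/2)
    sentinel: SentinelConfig | None = None
    direction: str = "high"

    def __post_init__(self):
        if self.s_margin < 1 or self.s_step < 1:
            raise ValueError("s_margin and s_step must be >= 1")
        if self.min_set_size < 2:
            raise ValueError("min_set_size must be >= 2")
        if self.direction not in ("high", "low", "both"):
            raise ValueError("direction must be 'high', 'low' or 'both'")

    def s_range(self, n: int) -> range:
        return range(self.s_margin, n - self.s_margin + 1, self.s_step)

    def t_ceiling(self, s: int) -> int:
        cap = s // 2 if self.t_cap is None else self.t_cap
        return min(cap, s - 1)


@dataclass(frozen=True)
class GeneSetInstance:
    """One detected component at one (s, t) grid cell."""

    s: int
    t: int
    probes: tuple
    consensus_samples: frozenset
    cell_label: str
    direction: str = "high"

    def __post_init__(self):
        if list(self.probes) != sorted(self.probes):
            raise ValueError("instance probes must be sorted ascending by ID")
        if len(self.consensus_samples) != self.s:
            raise ValueError("consensus sample set must have size s")


def _as_matrix(X) -> ExpressionMatrix:
    if isinstance(X, ExpressionMatrix):
        return X
    X = np.asarray(X, dtype=float)
    width = len(str(max(X.shape[0] - 1, 1)))
    probes = [f"P{i:0{width}d}" for i in range(X.shape[0])]
    samples = [f"S{j}" for j in range(X.shape[1])]
    return ExpressionMatrix(probe_ids=probes, sample_ids=samples, values=X)


class _GridRunner:
    """Shared per-matrix state: rank orders, membership and overlap caches."""

    def __init__(self, m: ExpressionMatrix, direction: str = "high"):
        if m.has_missing():
            raise ValueError("matrix has missing entries; impute first")
        self.m = m
        values = m.values if direction == "high" else -m.values
        self.direction = direction
        self.n = m.n_samples
        self.G = m.n_probes
        self.orders = np.vstack([rank_order(values[i]) for i in range(self.G)])
        self._cache_s: int | None = None
        self._cache: tuple | None = None

    def membership(self, s: int) -> np.ndarray:
        M = np.zeros((self.G, self.n), dtype=bool)
        M[np.arange(self.G)[:, None], self.orders[:, :s]] = True
        return M

    def overlap(self, s: int):
        """G x G matrix of top-s set intersection sizes (cached per s).

        This is the inverted-index pair count: entry (i, j) sums, over the
        samples, the co-occurrence of probes i and j in the sample's list
        of selecting probes.
        """
        if self._cache_s == s:
            return self._cache
        M = self.membership(s)
        if self.G <= _DENSE_PROBE_LIMIT:
            ov = M.astype(np.int32) @ M.T.astype(np.int32)
        else:
            Ms = sp.csr_matrix(M, dtype=np.int32)
            ov = (Ms @ Ms.T).tocsr()
        self._cache_s, self._cache = s, (M, ov)
        return self._cache

    def component_labels(self, s: int, t: int) -> np.ndarray:
        _, ov = self.overlap(s)
        thresh = s - t
        if thresh <= 0:  # t >= s: every pair matches
            return np.zeros(self.G, dtype=int)
        if sp.issparse(ov):
            mask = ov.copy()
            mask.data = (mask.data >= thresh).astype(np.int8)
            mask.eliminate_zeros()
            adj = mask
        else:
            adj = sp.csr_matrix((ov >= thresh).astype(np.int8))
        _, labels = connected_components(adj, directed=False)
        return labels

    def components(self, s: int, t: int) -> list:
        """Connected components as lists of probe indices (size >= 2 edges
        arise naturally; singletons included)."""
        labels = self.component_labels(s, t)
        comps: dict = {}
        for i, lab in enumerate(labels):
            comps.setdefault(lab, []).append(i)
        return list(comps.values())

    def consensus(self, comp: list, s: int) -> frozenset:
        M, _ = self.overlap(s)
        freq = M[comp].sum(axis=0)
        rank_score = np.zeros(self.n)
        weights = np.arange(s, 0, -1, dtype=float)  # s - position
        for i in comp:
            rank_score[self.orders[i, :s]] += weights
        order = np.lexsort((np.arange(self.n), -rank_score, -freq))
        return frozenset(int(j) for j in order[:s])


def build_match_graph(partitions: list, t: int, method: str = "pruned") -> list:
    """Connected components of the match graph over top-sample sets.

    Returns a partition of ``range(len(partitions))`` as sorted lists of
    indices, ordered by smallest member.  ``method='pruned'`` counts pair
    overlaps through a sample → probes inverted index (a single sparse
    product) and thresholds at ``s - t``; ``method='naive'`` tests all
    probe pairs directly and is retained as the reference oracle.  Both
    return identical components.
    """
    if not partitions:
        return []
    s_values = {p.s for p in partitions}
    if len(s_values) > 1:
        raise ValueError(f"mixed partition sizes: {sorted(s_values)}")
    (s,) = s_values
    G = len(partitions)
    if method == "naive":
        g = nx.Graph()
        g.add_nodes_from(range(G))
        for i in range(G):
            for j in range(i + 1, G):
                if is_match(partitions[i], partitions[j], t):
                    g.add_edge(i, j)
        comps = [sorted(c) for c in nx.connected_components(g)]
    elif method == "pruned":
        if s - t <= 0:
            return [list(range(G))]
        n = 1 + max(max(p.samples) for p in partitions)
        M = np.zeros((G, n), dtype=bool)
        for i, p in enumerate(partitions):
            M[i, sorted(p.samples)] = True
        ov = sp.csr_matrix(M.astype(np.int32)) @ sp.csr_matrix(M.astype(np.int32)).T
        adj = ov.copy()
        adj.data = (adj.data >= s - t).astype(np.int8)
        adj.eliminate_zeros()
        _, labels = connected_components(adj, directed=False)
        comps_d: dict = {}
        for i, lab in enumerate(labels):
            comps_d.setdefault(lab, []).append(i)
        comps = [sorted(c) for c in comps_d.values()]
    else:
        raise ValueError(f"unknown method {method!r}")
    return sorted(comps, key=lambda c: c[0])


def consensus_samples(component: list) -> frozenset:
    """The s samples most frequently selected across a component's members.

    Ties in membership frequency are broken by higher total rank score
    (sum over members of ``s`` minus rank position), then ascending index.
    """
    if not component:
        raise ValueError("empty component")
    s_values = {p.s for p in component}
    if len(s_values) > 1:
        raise ValueError("component members have mixed s")
    (s,) = s_values
    n = 1 + max(max(p.samples) for p in component)
    freq = np.zeros(n)
    rank_score = np.zeros(n)
    for p in component:
        for pos, j in enumerate(p.rank_order):
            freq[j] += 1
            rank_score[j] += s - pos
    order = np.lexsort((np.arange(n), -rank_score, -freq))
    return frozenset(int(j) for j in order[:s])


def _instances_from_runner(
    runner: _GridRunner, s: int, t: int, cfg: GridConfig
) -> list:
    suffix = "" if runner.direction == "high" else "low"
    out = []
    for comp in runner.components(s, t):
        if len(comp) < cfg.min_set_size:
            continue
        probes = tuple(sorted(runner.m.probe_ids[i] for i in comp))
        out.append(
            GeneSetInstance(
                s=s,
                t=t,
                probes=probes,
                consensus_samples=runner.consensus(comp, s),
                cell_label=f"{s}t{t}{suffix}",
                direction=runner.direction,
            )
        )
    return sorted(out, key=lambda inst: inst.probes[0])


def components_at(
    m: ExpressionMatrix, s: int, t: int, cfg: GridConfig | None = None
) -> list:
    """Gene-set instances (components of size >= min_set_size) at one cell."""
    cfg = cfg or GridConfig()
    out = []
    for direction in (("high", "low") if cfg.direction == "both" else (cfg.direction,)):
        runner = _GridRunner(m, direction)
        out.extend(_instances_from_runner(runner, s, t, cfg))
    return out


def _sentinel_merged(runner: _GridRunner, s: int, t: int, cfg: GridConfig) -> bool:
    sent = cfg.sentinel
    idx = {p: i for i, p in enumerate(runner.m.probe_ids)}
    missing = [p for p in list(sent.sentinel_probes) + list(sent.foil_probes)
               if p not in idx]
    if missing:
        raise ValueError(f"sentinel/foil probes absent from matrix: {missing}")
    sent_idx = {idx[p] for p in sent.sentinel_probes}
    foil_idx = {idx[p] for p in sent.foil_probes}
    need = sent.majority_fraction * len(sent_idx)
    labels = runner.component_labels(s, t)
    for lab in {labels[i] for i in sent_idx}:
        members = set(np.flatnonzero(labels == lab))
        if len(members & sent_idx) >= need and members & foil_idx:
            return True
    return False


def t_max_for_s(m: ExpressionMatrix, s: int, cfg: GridConfig) -> int:
    """Largest t at which the sentinel set is still a distinct object.

    Scans t upward from ``t_start``; the first cell where a component holds
    a majority of the sentinel probes together with a foil probe stops the
    scan, and the previous t is returned (``t_start - 1`` when merged
    already at the start).  Without a sentinel the fallback cap applies.
    """
    if cfg.sentinel is None:
        return cfg.t_ceiling(s)
    direction = "high" if cfg.direction == "both" else cfg.direction
    return _t_max_scan(_GridRunner(m, direction), s, cfg)


def _t_max_scan(runner: _GridRunner, s: int, cfg: GridConfig) -> int:
    if not cfg.sentinel.sentinel_probes:
        raise ValueError("sentinel configured with no sentinel probes")
    for t in range(cfg.t_start, s):
        if _sentinel_merged(runner, s, t, cfg):
            return t - 1
    return s - 1


def enumerate_grid(m: ExpressionMatrix, cfg: GridConfig | None = None) -> list:
    """All gene-set instances over the full (s, t) grid.

    For each s in ``[s_margin, n - s_margin]`` (step ``s_step``) and each t
    from ``t_start`` up to the per-s ceiling, emits the components of size
    at least ``min_set_size``.  Ordering is deterministic: ascending s,
    then t, then smallest probe ID (low-direction cells after high when
    direction='both').
    """
    cfg = cfg or GridConfig()
    directions = ("high", "low") if cfg.direction == "both" else (cfg.direction,)
    runners = {d: _GridRunner(m, d) for d in directions}
    out = []
    for s in cfg.s_range(m.n_samples):
        if s < 1 or s > m.n_samples - 1:
            continue
        if cfg.sentinel is None:
            t_hi = cfg.t_ceiling(s)
        else:
            t_hi = _t_max_scan(runners[directions[0]], s, cfg)
        count = 0
        for direction in directions:
            runner = runners[direction]
            for t in range(cfg.t_start, t_hi + 1):
                inst = _instances_from_runner(runner, s, t, cfg)
                count += len(inst)
                out.extend(inst)
        logger.info("s=%d: t<=%d, %d instances", s, t_hi, count)
    return out


def spiral_search(
    m: ExpressionMatrix,
    cfg: GridConfig | None = None,
    coarse_s_step: int = 5,
    coarse_t_step: int = 3,
) -> list:
    """Reconnaissance scan: coarse (s, t) steps refined around hits.

    Returns the sorted list of (s, t) cells holding at least one instance
    among the coarse cells and the unit-step neighbourhoods of coarse hits.
    With both coarse steps equal to 1 this is the exhaustive scan.
    """
    cfg = cfg or GridConfig()
    if coarse_s_step < 1 or coarse_t_step < 1:
        raise ValueError("coarse steps must be >= 1")
    n = m.n_samples
    hits: set = set()
    checked: dict = {}
    direction = "high" if cfg.direction == "both" else cfg.direction
    runners: dict = {}

    def nonempty(s: int, t: int) -> bool:
        if (s, t) not in checked:
            if s not in runners:
                runners[s] = _GridRunner(m, direction)
            checked[(s, t)] = bool(
                _instances_from_runner(runners[s], s, t, cfg)
            )
        return checked[(s, t)]

    coarse_hits = []
    for s in range(cfg.s_margin, n - cfg.s_margin + 1, coarse_s_step):
        for t in range(cfg.t_start, cfg.t_ceiling(s) + 1, coarse_t_step):
            if nonempty(s, t):
                coarse_hits.append((s, t))
                hits.add((s, t))
    for s0, t0 in coarse_hits:
        for s in range(max(cfg.s_margin, s0 - coarse_s_step + 1),
                       min(n - cfg.s_margin, s0 + coarse_s_step - 1) + 1):
            for t in range(max(cfg.t_start, t0 - coarse_t_step + 1),
                           min(cfg.t_ceiling(s), t0 + coarse_t_step - 1) + 1):
                if nonempty(s, t):
                    hits.add((s, t))
    return sorted(hits)


def write_instances(instances: list, sample_ids: list, path) -> None:
    """Write instances as TSV: cell label, s, t, direction, probe list and
    consensus sample IDs (comma-joined)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("cell_label\ts\tt\tdirection\tprobes\tconsensus_samples\n")
        for inst in instances:
            samples = ",".join(
                sample_ids[j] for j in sorted(inst.consensus_samples)
            )
            fh.write(
                f"{inst.cell_label}\t{inst.s}\t{inst.t}\t{inst.direction}\t"
                f"{','.join(inst.probes)}\t{samples}\n"
            )


def read_instances(path, sample_ids: list) -> list:
    """Read back an instance TSV written by :func:`write_instances`."""
    index = {s: j for j, s in enumerate(sample_ids)}
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("cell_label"):
            raise ValueError(f"{path}: not an instance table")
        for line in fh:
            cell, s, t, direction, probes, samples = line.rstrip("\n").split("\t")
            out.append(
                GeneSetInstance(
                    s=int(s),
                    t=int(t),
                    probes=tuple(probes.split(",")),
                    consensus_samples=frozenset(
                        index[x] for x in samples.split(",")
                    ),
                    cell_label=cell,
                    direction=direction,
                )
            )
    return out


class GeneSetEnumerator(BaseEstimator):
    """Exhaustive rank-based enumeration of gene-set instances.

    Scikit-learn-style estimator over a probes × samples matrix: ``fit``
    runs the full (s, t) grid search and stores the detected instances.

    Parameters
    ----------
    s_margin : int, default=6
        Partition sizes run from ``s_margin`` to ``n - s_margin``.
    s_step : int, default=1
        Step between successive partition sizes.
    min_set_size : int, default=6
        Smallest component reported as a gene set.
    t_start : int, default=0
        First tolerance tried at each s (0 = perfect match).
    t_cap : int or None, default=None
        Fallback per-s tolerance ceiling when no sentinel is configured;
        None means ``floor(s/2)``.
    sentinel_probes, foil_probes : sequence of str or None
        Sentinel stop rule: raise t until the sentinel component absorbs a
        foil probe.
    majority_fraction : float, default=0.5
        Fraction of sentinel probes that must sit in one component for it
        to count as "the" sentinel set.
    direction : {'high', 'low', 'both'}, default='high'
        Match on top-s (up-regulation), bottom-s, or both.

    Attributes
    ----------
    instances_ : list of GeneSetInstance
        All instances, ordered by (s, t, smallest probe).
    n_cells_ : int
        Number of grid cells visited.
    probe_ids_ : list of str
    n_samples_ : int
    """

    def __init__(
        self,
        s_margin: int = 6,
        s_step: int = 1,
        min_set_size: int = 6,
        t_start: int = 0,
        t_cap: int | None = None,
        sentinel_probes=None,
        foil_probes=None,
        majority_fraction: float = 0.5,
        direction: str = "high",
    ):
        self.s_margin = s_margin
        self.s_step = s_step
        self.min_set_size = min_set_size
        self.t_start = t_start
        self.t_cap = t_cap
        self.sentinel_probes = sentinel_probes
        self.foil_probes = foil_probes
        self.majority_fraction = majority_fraction
        self.direction = direction

    def _config(self) -> GridConfig:
        sentinel = None
        if self.sentinel_probes:
            sentinel = SentinelConfig(
                sentinel_probes=tuple(self.sentinel_probes),
                foil_probes=tuple(self.foil_probes or ()),
                majority_fraction=self.majority_fraction,
            )
        return GridConfig(
            s_margin=self.s_margin,
            s_step=self.s_step,
            min_set_size=self.min_set_size,
            t_start=self.t_start,
            t_cap=self.t_cap,
            sentinel=sentinel,
            direction=self.direction,
        )

    def fit(self, X, y=None):
        """Run the grid enumeration on a probes × samples matrix."""
        m = _as_matrix(X)
        cfg = self._config()
        self.probe_ids_ = list(m.probe_ids)
        self.n_samples_ = m.n_samples
        self.instances_ = enumerate_grid(m, cfg)
        self.n_cells_ = sum(
            t_max_for_s(m, s, cfg) - cfg.t_start + 1
            for s in cfg.s_range(m.n_samples)
        )
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the instance list (clustering-style convenience)."""
        return self.fit(X).instances_
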
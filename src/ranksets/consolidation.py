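"""Consolidating gene-set instances into families and core sets.

The grid search typically detects the same underlying gene set at many
(s, t) cells, in versions that differ only marginally in membership — a
"gene set" is really a set of sets.  Consolidation links instances whose
probe sets are similar (single-linkage on Jaccard similarity) into
families, and squashes each family into a *core* set: the probes present
in at least half of the member instances.

Families whose core probes all map to a single gene symbol are flagged as
likely chip-design artifacts (one gene spotted several times can form a
"set" of its own); they are kept but marked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

__all__ = [
    "ConsolidationConfig",
    "GeneSetFamily",
    "FamilyConsolidator",
    "link_instances",
    "core_set",
    "flag_single_gene_artifact",
    "compare_across_datasets",
]


@dataclass(frozen=True)
class ConsolidationConfig:
    jaccard_threshold: float = 0.5
    core_fraction: float = 0.5

    def __post_init__(self):
        for name in ("jaccard_threshold", "core_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class GeneSetFamily:
    """Linked instances of one underlying gene set, plus its core."""

    family_id: str
    instances: list
    core_probes: tuple = ()
    label: str = ""
    artifact_flag: bool = False
    representative_samples: frozenset = field(default_factory=frozenset)

    @property
    def cells(self) -> list:
        return [inst.cell_label for inst in self.instances]

    @property
    def all_probes(self) -> tuple:
        out: set = set()
        for inst in self.instances:
            out.update(inst.probes)
        return tuple(sorted(out))


def _jaccard_adjacency(instances: list, threshold: float) -> sp.csr_matrix:
    probes = sorted({p for inst in instances for p in inst.probes})
    col = {p: j for j, p in enumerate(probes)}
    B = np.zeros((len(instances), len(probes)), dtype=bool)
    for i, inst in enumerate(instances):
        B[i, [col[p] for p in inst.probes]] = True
    inter = B.astype(np.int32) @ B.T.astype(np.int32)
    sizes = B.sum(axis=1).astype(np.int64)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sp.csr_matrix((jac >= threshold).astype(np.int8))


def link_instances(
    instances: list, cfg: ConsolidationConfig | None = None
) -> list:
    """Single-linkage grouping of instances with Jaccard >= threshold.

    Every instance lands in exactly one family.  Families are ordered by
    descending instance count, then by their smallest probe ID, and are
    returned with core set, representative samples and auto label unset
    (see :class:`FamilyConsolidator` for the full pipeline).
    """
    cfg = cfg or ConsolidationConfig()
    if not instances:
        return []
    adj = _jaccard_adjacency(instances, cfg.jaccard_threshold)
    _, labels = connected_components(adj, directed=False)
    groups: dict = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(instances[i])
    ordered = sorted(
        groups.values(),
        key=lambda g: (-len(g), min(p for inst in g for p in inst.probes)),
    )
    width = max(2, len(str(len(ordered))))
    return [
        GeneSetFamily(family_id=f"F{i:0{width}d}", instances=g)
        for i, g in enumerate(ordered)
    ]


def core_set(f: GeneSetFamily, cfg: ConsolidationConfig | None = None) -> tuple:
    """Probes appearing in at least ``core_fraction`` of a family's instances.

    The threshold is ``ceil(core_fraction * n_instances)`` occurrences; the
    result is sorted ascending by probe ID.  A fragmented family can have an
    empty core, in which case it is excluded from survival analysis.
    """
    cfg = cfg or ConsolidationConfig()
    if not f.instances:
        raise ValueError("empty family")
    need = int(np.ceil(cfg.core_fraction * len(f.instances)))
    counts: dict = {}
    for inst in f.instances:
        for p in inst.probes:
            counts[p] = counts.get(p, 0) + 1
    return tuple(sorted(p for p, c in counts.items() if c >= need))


def _representative_samples(f: GeneSetFamily) -> frozenset:
    # instances may sit at different s; take the median-size consensus of
    # the per-instance consensus sets, ranked by frequency then index
    sizes = sorted(inst.s for inst in f.instances)
    size = int(sizes[len(sizes) // 2])
    freq: dict = {}
    for inst in f.instances:
        for j in inst.consensus_samples:
            freq[j] = freq.get(j, 0) + 1
    ranked = sorted(freq, key=lambda j: (-freq[j], j))
    return frozenset(ranked[:size])


def flag_single_gene_artifact(f: GeneSetFamily, symbols: dict | None) -> bool:
    """True iff every core probe maps to one single non-empty gene symbol.

    A set realised exclusively by probes spotting the same gene carries no
    co-regulation signal beyond chip design.  An unannotated probe counts
    as a distinct symbol, so it never contributes to a single-gene flag;
    with no annotation at all the flag stays unset with a warning.
    """
    if symbols is None:
        warnings.warn("no symbol annotation; artifact flag left unset")
        return False
    core = f.core_probes or f.all_probes
    if not core:
        return False
    syms = {symbols.get(p, "") or f"<unannotated:{p}>" for p in core}
    if len(syms) != 1:
        return False
    (only,) = syms
    return not only.startswith("<unannotated:")


class FamilyConsolidator(BaseEstimator):
    """Link gene-set instances across grid cells and squash them to cores.

    Parameters
    ----------
    jaccard_threshold : float, default=0.5
        Minimum probe-set Jaccard similarity for two instances to be
        versions of the same set (single linkage).
    core_fraction : float, default=0.5
        A probe joins the core when it appears in at least this fraction
        of the family's instances.

    Attributes
    ----------
    families_ : list of GeneSetFamily
        Consolidated families with core probes, representative samples,
        auto labels (most frequent core symbol) and artifact flags.
    """

    def __init__(self, jaccard_threshold: float = 0.5, core_fraction: float = 0.5):
        self.jaccard_threshold = jaccard_threshold
        self.core_fraction = core_fraction

    def fit(self, instances, y=None, symbols: dict | None = None):
        cfg = ConsolidationConfig(
            jaccard_threshold=self.jaccard_threshold,
            core_fraction=self.core_fraction,
        )
        families = link_instances(list(instances), cfg)
        for f in families:
            f.core_probes = core_set(f, cfg)
            if not f.core_probes:
                warnings.warn(
                    f"family {f.family_id} has an empty core and will be "
                    "excluded from survival analysis"
                )
            f.representative_samples = _representative_samples(f)
            if symbols is not None:
                f.artifact_flag = flag_single_gene_artifact(f, symbols)
                syms = [symbols.get(p, "") for p in f.core_probes]
                syms = [s for s in syms if s]
                f.label = (
                    max(sorted(set(syms)), key=syms.count) if syms else f.family_id
                )
            else:
                f.label = f.family_id
        self.families_ = families
        return self

    def fit_predict(self, instances, y=None, symbols: dict | None = None):
        return self.fit(instances, symbols=symbols).families_


def consolidate(
    instances,
    jaccard_threshold: float = 0.5,
    core_fraction: float = 0.5,
    symbols: dict | None = None,
) -> list:
    """Functional wrapper over :class:`FamilyConsolidator`."""
    return FamilyConsolidator(
        jaccard_threshold=jaccard_threshold, core_fraction=core_fraction
    ).fit_predict(instances, symbols=symbols)


def _symbol_set(f: GeneSetFamily, symbols: dict | None) -> frozenset:
    core = f.core_probes or f.all_probes
    if symbols is None:
        return frozenset(core)
    return frozenset(symbols.get(p, "") or p for p in core)


def compare_across_datasets(
    fams_a: list,
    fams_b: list,
    symbols_a: dict | None = None,
    symbols_b: dict | None = None,
    threshold: float = 0.3,
) -> dict:
    """Greedy one-to-one alignment of two runs' families by shared symbols.

    Candidate pairs with symbol-level Jaccard >= ``threshold`` are matched
    best-first (ties by higher overlap count, then family order).  Returns
    ``{'matches': [(fam_a, fam_b, jaccard, overlap)], 'unmatched_a': [...],
    'unmatched_b': [...]}`` — the juxtaposition table of sets conserved
    across datasets or platforms.
    """
    sets_a = [_symbol_set(f, symbols_a) for f in fams_a]
    sets_b = [_symbol_set(f, symbols_b) for f in fams_b]
    candidates = []
    for i, sa in enumerate(sets_a):
        for j, sbb in enumerate(sets_b):
            inter = len(sa & sbb)
            union = len(sa | sbb)
            jac = inter / union if union else 0.0
            if jac >= threshold and inter > 0:
                candidates.append((-jac, -inter, i, j))
    candidates.sort()
    used_a: set = set()
    used_b: set = set()
    matches = []
    for njac, ninter, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((fams_a[i], fams_b[j], -njac, -ninter))
    return {
        "matches": matches,
        "unmatched_a": [f for i, f in enumerate(fams_a) if i not in used_a],
        "unmatched_b": [f for j, f in enumerate(fams_b) if j not in used_b],
    }
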
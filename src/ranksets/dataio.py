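"""Reading, writing and imputing expression matrices and clinical tables.

Two text dialects are supported for expression data: plain TSV (probe IDs in
the first column, sample IDs in the header row) and the GEO series-matrix
style in which ``!``-prefixed metadata lines surround the same table.  The
enumeration takes the full matrix as input — no variance filtering or gene
pre-selection is applied, and values are used on whatever scale the file
provides.

Missing entries are filled by gene-axis k-nearest-neighbour imputation
(donors are probe rows, distances Euclidean over the coordinates observed in
both rows, normalised per shared coordinate), the convention established for
microarray data.  The default is k = 10.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "KNNExpressionImputer",
    "impute_knn",
]

#: Tokens treated as missing values (case-insensitive), beyond the empty cell.
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})

_ER_MAP = {
    "er+": "positive", "+": "positive", "positive": "positive", "pos": "positive",
    "er-": "negative", "-": "negative", "negative": "negative", "neg": "negative",
}


@dataclass
class ExpressionMatrix:
    """A probes × samples matrix of real expression values.

    ``values[i, j]`` is the expression of probe ``probe_ids[i]`` in sample
    ``sample_ids[j]``; missing entries are NaN until imputed.  ``symbols``
    optionally maps probe IDs to gene symbols (one gene may be represented
    by several probes).
    """

    probe_ids: list
    sample_ids: list
    values: np.ndarray
    symbols: dict | None = None

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(c) for c in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            seen: set = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} ID: {i!r}")
                seen.add(i)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def checksum(self) -> str:
        """SHA-1 of the numeric content, recorded in run manifests."""
        h = hashlib.sha1()
        h.update("\t".join(self.probe_ids).encode())
        h.update("\t".join(self.sample_ids).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class ClinicalTable:
    """Per-sample survival follow-up and estrogen-receptor status.

    ``time`` is follow-up in years, ``event`` is 1 for the endpoint event
    (death or distant metastasis, whichever the cohort records) and 0 for
    censoring; ``er_status`` is ``positive``/``negative``/``unknown``.
    """

    sample_ids: list
    time: np.ndarray
    event: np.ndarray
    er_status: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs in clinical table")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not self.er_status:
            self.er_status = ["unknown"] * len(self.sample_ids)
        if not (len(self.sample_ids) == self.time.shape[0]
                == self.event.shape[0] == len(self.er_status)):
            raise ValueError("clinical table columns have unequal lengths")
        if (self.time < 0).any():
            row = int(np.flatnonzero(self.time < 0)[0])
            raise ValueError(f"negative survival time at row {row + 1}")
        bad = ~np.isin(self.event, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-binary event indicator at row {row + 1}")

    def align(self, sample_ids: list) -> "ClinicalTable":
        """Rows reordered to ``sample_ids``; matrix samples absent from the
        table get ``er_status='unknown'`` and NaN time (they are excluded
        from survival analysis); extra clinical rows are dropped with a
        warning."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        extra = [s for s in self.sample_ids if s not in set(sample_ids)]
        if extra:
            warnings.warn(
                f"{len(extra)} clinical rows not in the expression matrix "
                f"were dropped (e.g. {extra[0]!r})"
            )
        n = len(sample_ids)
        time = np.full(n, np.nan)
        event = np.zeros(n, dtype=int)
        er = ["unknown"] * n
        missing = 0
        for j, s in enumerate(sample_ids):
            i = index.get(str(s))
            if i is None:
                missing += 1
                continue
            time[j] = self.time[i]
            event[j] = self.event[i]
            er[j] = self.er_status[i]
        if missing:
            warnings.warn(
                f"{missing} matrix samples have no clinical row and are "
                "excluded from survival analysis"
            )
        out = ClinicalTable.__new__(ClinicalTable)
        out.sample_ids = [str(s) for s in sample_ids]
        out.time = time
        out.event = event
        out.er_status = er
        return out


def _is_missing(token: str) -> bool:
    return token.strip().strip('"').lower() in MISSING_TOKENS


def _parse_cell(token: str) -> float:
    token = token.strip().strip('"')
    if _is_missing(token):
        return np.nan
    try:
        return float(token)
    except ValueError:
        return np.nan  # non-numeric cells become missing entries


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a probes × samples expression matrix from text.

    Parameters
    ----------
    path : str or path-like
        Tab-delimited file; first column probe IDs, header row sample IDs.
    dialect : {'tsv', 'series_matrix'}
        ``series_matrix`` additionally skips ``!``-prefixed metadata lines
        (including the table begin/end markers of GEO series-matrix files).
    """
    if dialect not in ("tsv", "series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    header = None
    probe_ids: list = []
    rows: list = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if dialect == "series_matrix" and line.startswith("!"):
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().strip('"') for f in fields[1:]]
                n = len(header)
                continue
            if len(fields) != n + 1:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {n + 1}"
                )
            probe_ids.append(fields[0].strip().strip('"'))
            rows.append([_parse_cell(f) for f in fields[1:]])
    if header is None:
        raise ValueError(f"{path}: no table found")
    values = np.asarray(rows, dtype=float).reshape(len(probe_ids), len(header))
    return ExpressionMatrix(probe_ids=probe_ids, sample_ids=header, values=values)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write a matrix as plain TSV; round-trips numeric content exactly."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(m.sample_ids) + "\n")
        for i, pid in enumerate(m.probe_ids):
            cells = [
                "NA" if np.isnan(v) else repr(float(v)) for v in m.values[i]
            ]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


def _find_column(columns, candidates, what):
    lowered = {str(c).strip().lower(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    raise ValueError(f"clinical table has no {what} column (looked for {candidates})")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with named sample/time/event/ER columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    c_sample = _find_column(df.columns, ("sample", "sample_id", "id"), "sample")
    c_time = _find_column(df.columns, ("time", "survival_time", "followup"), "time")
    c_event = _find_column(df.columns, ("event", "status"), "event")
    try:
        c_er = _find_column(df.columns, ("er", "er_status"), "ER")
    except ValueError:
        c_er = None
    time = []
    event = []
    for row, tok in enumerate(df[c_time], start=1):
        try:
            t = float(tok)
        except ValueError:
            raise ValueError(f"non-numeric time at row {row}: {tok!r}")
        if t < 0:
            raise ValueError(f"negative survival time at row {row}: {tok!r}")
        time.append(t)
    for row, tok in enumerate(df[c_event], start=1):
        if tok.strip() not in ("0", "1"):
            raise ValueError(f"non-binary event at row {row}: {tok!r}")
        event.append(int(tok))
    er = []
    if c_er is not None:
        for tok in df[c_er]:
            key = tok.strip().lower()
            if _is_missing(key) or key == "unknown":
                er.append("unknown")
            else:
                er.append(_ER_MAP.get(key, "unknown"))
    return ClinicalTable(
        sample_ids=list(df[c_sample]), time=time, event=event, er_status=er
    )


def write_clinical(c: ClinicalTable, path) -> None:
    pd.DataFrame(
        {
            "sample_id": c.sample_ids,
            "time": c.time,
            "event": c.event,
            "er_status": c.er_status,
        }
    ).to_csv(path, sep="\t", index=False)


class KNNExpressionImputer(TransformerMixin, BaseEstimator):
    """Gene-axis k-nearest-neighbour imputation of missing expression values.

    For each missing entry (g, j) the imputed value is the mean, at column
    j, of the ``n_neighbors`` probe rows closest to row g that are observed
    at column j.  Distances are Euclidean over the coordinates observed in
    both rows, normalised by the number of shared coordinates, so rows with
    different missingness patterns are comparable.

    Parameters
    ----------
    n_neighbors : int, default=10
        Number of donor rows (the microarray convention is k = 10).

    Attributes
    ----------
    n_features_in_ : int
        Number of samples (columns) seen during fit.
    """

    def __init__(self, n_neighbors: int = 10):
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-d probes x samples array")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        self.fit(X)  # stateless per matrix: donors come from X itself
        nan = np.isnan(X)
        if not nan.any():
            return X.copy()
        if nan.all(axis=0).any():
            j = int(np.flatnonzero(nan.all(axis=0))[0])
            raise ValueError(f"sample column {j} is missing in every probe row")
        if nan.all(axis=1).any():
            i = int(np.flatnonzero(nan.all(axis=1))[0])
            raise ValueError(f"probe row {i} has no observed value")
        k = self.n_neighbors
        if k > X.shape[0] - 1:
            warnings.warn(
                f"n_neighbors={k} exceeds the {X.shape[0] - 1} available "
                "donor rows; using all donors"
            )
            k = max(X.shape[0] - 1, 1)
        # nan-Euclidean scaling (total/shared) ranks donors identically to
        # the per-shared-coordinate normalisation, so the sklearn imputer
        # produces exactly the donor means this convention specifies.
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        return imputer.fit_transform(X)


def impute_knn(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Return a copy of ``m`` with missing entries kNN-imputed (k donors)."""
    values = KNNExpressionImputer(n_neighbors=k).transform(m.values)
    return ExpressionMatrix(
        probe_ids=list(m.probe_ids),
        sample_ids=list(m.sample_ids),
        values=values,
        symbols=dict(m.symbols) if m.symbols else None,
    )
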
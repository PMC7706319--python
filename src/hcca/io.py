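"""Readers, writers and sample alignment for the file formats the tool touches.

Matrices are tab/comma-separated text with a sample-ID column and a feature-ID
header; interaction networks are STRING-style 3-column edge lists; gene
intervals are BED4+ (0-based half-open); genomic events and phenotypes are
small keyed TSVs.  Everything numeric is held in an :class:`OmicsMatrix`, a
thin sample x feature container with ID metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsMatrix",
    "InteractionNetwork",
    "GeneInterval",
    "GenomicEvent",
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_network",
    "read_intervals",
    "read_events",
    "read_phenotype",
    "write_phenotype",
    "align_samples",
]


@dataclass
class OmicsMatrix:
    """A sample-aligned numeric view: n samples x d features with IDs.

    Units are dataset-dependent (counts, z-scores, environmental
    measurements); the container enforces only shape/ID consistency and the
    absence of non-finite values.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample IDs for {n} rows"
            )
        if len(self.feature_ids) != d:
            raise ValueError(
                f"{len(self.feature_ids)} feature IDs for {d} columns"
            )
        for axis, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {axis} ID {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str = "") -> "OmicsMatrix":
        return cls(
            sample_ids=list(map(str, frame.index)),
            feature_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
            name=name,
        )

    def take_samples(self, order: list[str]) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in order]
        return replace(self, sample_ids=list(order), values=self.values[idx])

    def take_features(self, keep: list[str]) -> "OmicsMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in keep]
        return replace(self, feature_ids=list(keep), values=self.values[:, idx])


def _first_duplicate(items) -> str | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class InteractionNetwork:
    """Undirected weighted feature-interaction network (no self-loops).

    Edges are stored once per unordered pair with a nonnegative weight.
    """

    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def node_ids(self) -> list[str]:
        nodes: set[str] = set()
        for a, b in self.edges:
            nodes.update((a, b))
        return sorted(nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> None:
        if a == b:
            return
        if weight < 0:
            raise ValueError(f"negative edge weight {weight} on ({a}, {b})")
        key = (a, b) if a <= b else (b, a)
        prev = self.edges.get(key)
        if prev is None or weight > prev:
            self.edges[key] = float(weight)

    def adjacency(self, feature_ids: list[str]) -> np.ndarray:
        """Symmetric adjacency on a given feature ordering.

        Edges whose endpoints are not both in ``feature_ids`` are ignored.
        """
        pos = {f: i for i, f in enumerate(feature_ids)}
        A = np.zeros((len(feature_ids), len(feature_ids)))
        for (a, b), w in self.edges.items():
            ia, ib = pos.get(a), pos.get(b)
            if ia is None or ib is None:
                continue
            A[ia, ib] = w
            A[ib, ia] = w
        return A

    def normalized_laplacian(self, feature_ids: list[str]) -> np.ndarray:
        """L = I - D^{-1/2} A D^{-1/2}; isolated features get an identity row."""
        A = self.adjacency(feature_ids)
        deg = A.sum(axis=1)
        with np.errstate(divide="ignore"):
            dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
        L = np.eye(len(feature_ids)) - dinv[:, None] * A * dinv[None, :]
        return L


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus in BED convention: 0-based start, exclusive end."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.gene_id}: [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GenomicEvent:
    """A per-sample genomic event (mutation / methylated site) at a position."""

    sample_id: str
    chrom: str
    pos: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.count <= 0:
            raise ValueError(f"non-positive count {self.count}")


@dataclass
class RunConfig:
    """Bundle of the pipeline's tunable parameters.

    c_target is the desired condition number of the regularized within-view
    covariance (dimensionless, > 1); variance_percent drives the
    number-of-components rule; top_k_features / flank_bp configure the
    genomics preprocessor; the rest configure the prediction harness.
    """

    c_target: float = 4.0
    variance_percent: float = 85.0
    top_k_features: int = 5000
    flank_bp: int = 500
    test_fraction: float = 0.2
    n_repeats: int = 200
    n_loading_components: int = 2
    n_closest: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_target > 1:
            raise ValueError("c_target must be > 1")
        if not 0 < self.variance_percent <= 100:
            raise ValueError("variance_percent must be in (0, 100]")
        if self.top_k_features < 1:
            raise ValueError("top_k_features must be >= 1")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_loading_components < 1:
            raise ValueError("n_loading_components must be >= 1")
        if self.n_closest < 1:
            raise ValueError("n_closest must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(
    path,
    orientation: str = "samples_rows",
    missing: str = "error",
    name: str | None = None,
) -> OmicsMatrix:
    """Read a delimited numeric matrix with an ID column and a header row.

    Parameters
    ----------
    orientation:
        ``samples_rows`` if rows on disk are samples, ``features_rows`` if the
        file is transposed; the returned matrix is always samples x features.
    missing:
        ``error`` rejects any missing cell; ``drop_features`` removes
        features that contain missing entries (the policy used for the
        geoclimate table, where variables with gaps are discarded).
    """
    if orientation not in {"samples_rows", "features_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    if missing not in {"error", "drop_features"}:
        raise ValueError(f"unknown missing policy {missing!r}")
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    if orientation == "features_rows":
        frame = frame.T
    for axis, ids in (("sample", frame.index), ("feature", frame.columns)):
        dup = _first_duplicate(list(ids))
        if dup is not None:
            raise ValueError(f"{path}: duplicate {axis} ID {dup!r}")
    # coerce; flag the first non-numeric cell with coordinates
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {frame.iat[i, j]!r} at "
            f"row {frame.index[i]!r}, column {frame.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        if missing == "error":
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing value at row {frame.index[i]!r}, "
                f"column {frame.columns[j]!r} (use missing='drop_features')"
            )
        keep = numeric.columns[~numeric.isna().any(axis=0)]
        dropped = numeric.shape[1] - len(keep)
        logger.warning("%s: dropped %d features with missing entries", path, dropped)
        numeric = numeric[keep]
    return OmicsMatrix.from_frame(numeric, name=name or str(path))


def write_matrix(matrix: OmicsMatrix, path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def read_network(path, min_weight: float = 0.0) -> InteractionNetwork:
    """Read a 3-column (node, node, weight) edge list; weight defaults to 1.

    Self-loops are dropped, duplicate edges keep the maximum weight, and
    edges below ``min_weight`` are removed.  An empty file yields an empty
    network.
    """
    net = InteractionNetwork()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2-3 columns, got {len(parts)}")
            a, b = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
            else:
                w = 1.0
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {w}")
            if a == b:
                logger.debug("%s:%d: dropped self-loop on %r", path, lineno, a)
                continue
            net.add_edge(a, b, w)
    if min_weight > 0:
        net.edges = {k: w for k, w in net.edges.items() if w >= min_weight}
    return net


def write_network(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for (a, b), w in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_intervals(path) -> list[GeneInterval]:
    """Read BED4+ gene intervals; the name column becomes the gene ID.

    Multiple intervals sharing one gene ID are all kept (multi-exon style)
    and flagged in the log.
    """
    intervals: list[GeneInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, gene_id = parts[:4]
            strand = parts[5] if len(parts) >= 6 and parts[5] in {"+", "-"} else "."
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            try:
                iv = GeneInterval(gene_id, chrom, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if gene_id in seen:
                logger.info("%s:%d: additional interval for gene %r", path, lineno, gene_id)
            seen.add(gene_id)
            intervals.append(iv)
    return intervals


def read_events(path) -> list[GenomicEvent]:
    """Read per-sample genomic events: TSV (sample_id, chrom, pos[, count]).

    A header line is tolerated (detected by a non-integer position field).
    """
    events: list[GenomicEvent] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{lineno}: expected 3-4 columns")
            try:
                pos = int(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: non-integer position {parts[2]!r}") from None
            count = int(parts[3]) if len(parts) == 4 else 1
            try:
                events.append(GenomicEvent(parts[0], parts[1], pos, count))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return events


def read_phenotype(path) -> pd.Series:
    """Read a 2-column (sample_id, value) phenotype table."""
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, header=0)
    if frame.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, got {frame.shape[1]}")
    series = pd.Series(
        pd.to_numeric(frame.iloc[:, 1]).to_numpy(),
        index=frame.iloc[:, 0].astype(str),
        name=frame.columns[1],
    )
    dup = _first_duplicate(list(series.index))
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    return series


def write_phenotype(series: pd.Series, path) -> None:
    frame = series.rename_axis("sample_id").rename(series.name or "value")
    frame.to_csv(path, sep="\t", header=True)


def align_samples(
    views: list[OmicsMatrix], phenotype: pd.Series | None = None
):
    """Restrict all views (and the phenotype) to a shared, sorted sample order.

    The shared order is the sorted lexicographic intersection of all
    sample-ID sets; deterministic across runs.
    """
    if not views:
        raise ValueError("need at least one view")
    common = set(views[0].sample_ids)
    for v in views[1:]:
        common &= set(v.sample_ids)
    if phenotype is not None:
        common &= set(map(str, phenotype.index))
    if not common:
        counts = ", ".join(
            f"{v.name or i}: {v.n_samples}" for i, v in enumerate(views)
        )
        raise ValueError(f"no samples shared by all inputs (per-view counts: {counts})")
    order = sorted(common)
    aligned = [v.take_samples(order) for v in views]
    if phenotype is None:
        return aligned
    return aligned, phenotype.loc[order].astype(float)
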
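"""Readers and writers for the plain-text formats the pipeline touches.

All formats are line-oriented text with a fixed dialect:

* expression matrix — TSV, header row of sample ids, first column ``probe_id``,
  log2-scale intensities;
* sample annotations — TSV with columns ``sample_id``, ``group``, ``batch``,
  ``agent``;
* gene sets — standard GMT (name, description, members);
* PPI edges — two-column TSV of gene symbols, undirected;
* probe→gene map — two-column TSV, second column a comma-joined symbol list
  (empty = unmapped probe);
* tag lists — GRP dialect, one identifier per line, ``#`` comments ignored;
* combination tables — CSV with columns ``D1``, ``D2``, ``D12`` (effect
  fractions in [0, 1]) and an optional ``label`` column;
* ranked reference profiles — TSV with columns ``instance``, ``agent``,
  ``ranked_probes`` (comma-joined probe ids, rank 1 first).

Every reader validates its input eagerly and raises :class:`FormatError`
pointing at the offending identifier/line; every ``write_*``/``read_*`` pair
round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("vehicle", "treated", "comparator")


class FormatError(ValueError):
    """Raised when an on-disk file violates its dialect or an invariant."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A probes × samples log2-intensity matrix with per-sample annotations.

    ``annotations`` is indexed by sample id with columns ``group`` (one of
    ``vehicle``/``treated``/``comparator``), ``batch`` and ``agent``.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.probe_ids, "probe id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.annotations.index]
        if missing:
            raise FormatError(f"annotation missing for sample(s): {missing}")
        bad = set(self.annotations["group"]) - set(VALID_GROUPS)
        if bad:
            raise FormatError(f"unknown group label(s) {sorted(bad)}; expected {VALID_GROUPS}")
        # keep annotation rows aligned with the sample order
        self.annotations = self.annotations.loc[self.sample_ids, ["group", "batch", "agent"]]
        self.annotations.index.name = "sample_id"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            probe_ids=self.probe_ids,
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            annotations=self.annotations.loc[list(sample_ids)],
        )

    def groups(self) -> pd.Series:
        return self.annotations["group"]

    def batches(self) -> pd.Series:
        return self.annotations["batch"]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} {x!r}")
        seen.add(x)


def read_expression(path, annotation_path, log2_transform: bool = False) -> ExpressionMatrix:
    """Read an expression TSV plus its annotation sidecar.

    ``log2_transform`` applies log2(x + 1) on load for raw-scale input;
    matrices are otherwise assumed to be log2 scale already.
    """
    path, annotation_path = Path(path), Path(annotation_path)
    header: list[str] | None = None
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            probe_ids.append(fields[0])
            if len(fields) - 1 != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} values, got {len(fields) - 1}"
                )
            row = []
            for col, cell in enumerate(fields[1:]):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell at row {probe_ids[-1]!r}, "
                        f"column {header[col]!r}: {cell!r}"
                    ) from None
            rows.append(row)
    if header is None:
        raise FormatError(f"{path}: empty expression file")
    values = np.asarray(rows, dtype=float)
    if log2_transform:
        if np.any(values < 0):
            raise FormatError(f"{path}: negative intensities cannot be log2(x+1) transformed")
        values = np.log2(values + 1.0)

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    required = {"sample_id", "group", "batch", "agent"}
    if not required.issubset(ann.columns):
        raise FormatError(
            f"{annotation_path}: annotation columns {sorted(required)} required, "
            f"got {list(ann.columns)}"
        )
    _check_unique(list(ann["sample_id"]), "annotation sample id")
    ann = ann.set_index("sample_id")
    return ExpressionMatrix(probe_ids, header, values, ann)


def write_expression(matrix: ExpressionMatrix, path, annotation_path) -> None:
    path, annotation_path = Path(path), Path(annotation_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for pid, row in zip(matrix.probe_ids, matrix.values):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    ann = matrix.annotations.copy()
    ann.index.name = "sample_id"
    ann.to_csv(annotation_path, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets; iteration order follows insertion order."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise FormatError(f"duplicate gene set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


def read_gmt(path) -> GeneSetCollection:
    path = Path(path)
    collection = GeneSetCollection()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            collection.add(GeneSet(name, desc, frozenset(members)))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------


@dataclass
class PPIEdgeList:
    """Deduplicated undirected gene-symbol pairs; (A, B) ≡ (B, A), no self-loops."""

    edges: list[tuple[str, str]]
    n_self_loops_dropped: int = 0
    n_duplicates_collapsed: int = 0

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PPIEdgeList":
        seen: set[tuple[str, str]] = set()
        edges: list[tuple[str, str]] = []
        loops = dups = 0
        for a, b in pairs:
            if a == b:
                loops += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                dups += 1
                continue
            seen.add(key)
            edges.append(key)
        if loops:
            logger.warning("dropped %d self-loop edge(s)", loops)
        return cls(edges, loops, dups)

    def __len__(self) -> int:
        return len(self.edges)


def read_edges(path) -> PPIEdgeList:
    path = Path(path)
    pairs = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: edge line needs two columns")
            pairs.append((fields[0], fields[1]))
    return PPIEdgeList.from_pairs(pairs)


def write_edges(edges: PPIEdgeList, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for a, b in edges.edges:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Probe → gene maps
# ---------------------------------------------------------------------------


def read_probe_map(path) -> dict[str, list[str]]:
    """Two-column TSV: probe id, comma-joined gene symbols (empty = unmapped)."""
    path = Path(path)
    mapping: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            probe = fields[0]
            if probe in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate probe id {probe!r}")
            raw = fields[1] if len(fields) > 1 else ""
            symbols = [s for s in raw.split(",") if s]
            if any(not s.strip() for s in symbols):
                raise FormatError(f"{path}:{lineno}: blank gene symbol for probe {probe!r}")
            mapping[probe] = symbols
    return mapping


def write_probe_map(mapping: Mapping[str, Sequence[str]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for probe, symbols in mapping.items():
            fh.write(f"{probe}\t{','.join(symbols)}\n")


# ---------------------------------------------------------------------------
# Tag lists (GRP)
# ---------------------------------------------------------------------------


def read_tags(path) -> list[str]:
    path = Path(path)
    tags: list[str] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line.strip()
            if not tag or tag.startswith("#"):
                continue
            if tag in seen:
                raise FormatError(f"{path}:{lineno}: duplicate tag {tag!r}")
            seen.add(tag)
            tags.append(tag)
    return tags


def write_tags(tags: Sequence[str], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for tag in tags:
            fh.write(tag + "\n")


# ---------------------------------------------------------------------------
# Combination-assay tables
# ---------------------------------------------------------------------------


@dataclass
class CombinationTable:
    """Rows of per-arm effect fractions: drug 1 alone, drug 2 alone, combination."""

    table: pd.DataFrame  # columns label, D1, D2, D12

    def __post_init__(self) -> None:
        for col in ("D1", "D2", "D12"):
            vals = self.table[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1)) or not np.all(np.isfinite(vals)):
                bad = self.table.loc[(self.table[col] < 0) | (self.table[col] > 1)]
                raise FormatError(
                    f"effect fraction outside [0, 1] in column {col}: "
                    f"{bad[col].tolist()}"
                )

    def __len__(self) -> int:
        return len(self.table)


def read_combinations(path) -> CombinationTable:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"D1", "D2", "D12"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: combination CSV needs columns {sorted(required)}")
    if "label" not in df.columns:
        df.insert(0, "label", [f"row{i}" for i in range(len(df))])
    return CombinationTable(df[["label", "D1", "D2", "D12"]].copy())


def write_combinations(table: CombinationTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Ranked reference profiles
# ---------------------------------------------------------------------------


def read_profiles(path):
    """Read ranked reference profiles (TSV: instance, agent, ranked_probes)."""
    from .connectivity import RankedProfile

    path = Path(path)
    profiles = []
    seen: set[str] = set()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["instance", "agent", "ranked_probes"]:
            raise FormatError(f"{path}: expected header instance/agent/ranked_probes")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: profile line needs 3 columns")
            instance, agent, ranked = fields[0], fields[1], fields[2].split(",")
            if instance in seen:
                raise FormatError(f"{path}:{lineno}: duplicate instance {instance!r}")
            seen.add(instance)
            profiles.append(RankedProfile(instance, agent, ranked))
    return profiles


def write_profiles(profiles, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("instance\tagent\tranked_probes\n")
        for p in profiles:
            fh.write(f"{p.instance}\t{p.agent}\t{','.join(p.probes)}\n")
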
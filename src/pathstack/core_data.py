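"""Domain containers and flat-file I/O for expression matrices, labels and gene sets.

The package works on a genes × samples TPM matrix (``ExpressionDataset``), a
gene-set collection with an optional parent→child hierarchy
(``GeneSetCollection``), and plain ordered gene lists (``GeneList``), e.g. the
metabolic-enzyme universe that restricts the feature space.

Gene and sample identifiers are opaque, case-sensitive strings; no symbol or
accession mapping is attempted. Matrix orientation is always declared
explicitly by the caller — it is never sniffed from the file.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "GeneList",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_hierarchy",
    "restrict_to_gene_list",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionDataset:
    """A TPM expression matrix with optional per-sample class labels.

    Parameters
    ----------
    genes
        Ordered gene identifiers (rows of ``values``).
    samples
        Ordered sample identifiers (columns of ``values``).
    values
        Non-negative float matrix of shape ``(len(genes), len(samples))``.
    labels
        Optional mapping from sample identifier to class label. When present
        it must cover every sample.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)} genes, {len(self.samples)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        if self.labels is not None:
            self.labels = dict(self.labels)
            missing = [s for s in self.samples if s not in self.labels]
            if missing:
                raise ValueError(f"samples without a label: {missing[:5]}")

    # -- accessors ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return np.array([self.labels[s] for s in self.samples])

    def class_counts(self) -> dict[str, int]:
        y = self.label_array()
        uniq, cnt = np.unique(y, return_counts=True)
        return dict(zip(uniq.tolist(), cnt.tolist()))

    def with_labels(self, labels: Mapping[str, str]) -> "ExpressionDataset":
        return ExpressionDataset(self.genes, self.samples, self.values.copy(), dict(labels))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index(genes)
        return ExpressionDataset(
            [self.genes[i] for i in idx],
            self.samples,
            self.values[idx, :].copy(),
            None if self.labels is None else dict(self.labels),
        )

    def log2p(self) -> "ExpressionDataset":
        """Return a copy with values log2(TPM + 1)-transformed."""
        return ExpressionDataset(
            self.genes, self.samples, np.log2(self.values + 1.0), self.labels
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def validate_for_classification(self, min_per_class: int = 2) -> None:
        counts = self.class_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 distinct class labels")
        small = {k: v for k, v in counts.items() if v < min_per_class}
        if small:
            raise ValueError(f"classes with fewer than {min_per_class} samples: {small}")


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with an optional parent→child hierarchy."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    hierarchy: set[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if self.hierarchy is not None:
            for parent, child in self.hierarchy:
                if parent == child:
                    raise ValueError(f"hierarchy self-loop at {parent!r}")
                for p in (parent, child):
                    if p not in self.sets:
                        raise ValueError(f"hierarchy references unknown pathway {p!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        keep = list(names)
        sets = {n: set(self.sets[n]) for n in keep}
        hier = None
        if self.hierarchy is not None:
            hier = {(p, c) for p, c in self.hierarchy if p in sets and c in sets}
        return GeneSetCollection(sets, {n: self.descriptions.get(n, "") for n in keep}, hier)


@dataclass
class GeneList:
    """An ordered, de-duplicated list of gene identifiers."""

    identifiers: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        out = []
        for g in self.identifiers:
            if g not in seen:
                seen.add(g)
                out.append(g)
        self.identifiers = out

    def __len__(self) -> int:
        return len(self.identifiers)

    def __iter__(self):
        return iter(self.identifiers)

    def __contains__(self, g: str) -> bool:
        return g in set(self.identifiers)

    def as_set(self) -> set[str]:
        return set(self.identifiers)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, orientation: str = "genes-in-rows") -> ExpressionDataset:
    """Read a TSV/CSV expression matrix into genes × samples orientation.

    ``orientation`` declares how the file is laid out: ``"genes-in-rows"``
    (first column gene ids, header row sample ids) or ``"samples-in-rows"``
    (the transpose). The returned dataset is always genes × samples.
    """
    path = Path(path)
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row identifier {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate column identifier {dup!r} in {path}")
    try:
        num = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at row {df.index[i]!r}, column {col!r} "
                        f"in {path}: {cell!r}"
                    ) from None
        raise
    if num.isna().any().any():
        i, j = np.argwhere(num.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at row {num.index[i]!r}, column {num.columns[j]!r} in {path}"
        )
    if orientation == "samples-in-rows":
        num = num.T
    return ExpressionDataset(list(num.index), list(num.columns), num.to_numpy(dtype=float))


def write_expression(
    ds: ExpressionDataset, path: str | Path, orientation: str = "genes-in-rows"
) -> None:
    path = Path(path)
    df = ds.to_frame()
    if orientation == "samples-in-rows":
        df = df.T
    elif orientation != "genes-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=_sep_for(path))


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample, label); a header line is tolerated."""
    path = Path(path)
    mapping: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            rows.append((parts[0], parts[1]))
    if rows and rows[0][0].lower() in ("sample", "sample_id", "id"):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"label file {path} contains no entries")
    for sample, label in rows:
        if sample in mapping and mapping[sample] != label:
            raise ValueError(
                f"sample {sample!r} listed with conflicting labels "
                f"{mapping[sample]!r} and {label!r}"
            )
        mapping[sample] = label
    return mapping


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line — name, description, then gene fields."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    order: list[str] = []
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = [g for g in genes if g]
            sets[name] = set(dict.fromkeys(members))
            descriptions[name] = desc
            order.append(name)
    return GeneSetCollection({n: sets[n] for n in order}, descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.sets.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> GeneList:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise ValueError(f"gene list {path} is empty")
    return GeneList(ids)


def read_hierarchy(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column TSV of (parent, child) pathway pairs."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            if parts[0].lower() in ("parent", "parent_id") and lineno == 1:
                continue
            pairs.add((parts[0], parts[1]))
    return pairs


def restrict_to_gene_list(ds: ExpressionDataset, gl: GeneList) -> ExpressionDataset:
    """Restrict a dataset to the genes present in ``gl``, preserving dataset order.

    This implements the enzyme-universe restriction: classification features
    are drawn only from a curated list (e.g. metabolic enzyme genes), which is
    what makes downstream pathway interpretation possible.
    """
    keep_set = gl.as_set()
    keep = [g for g in ds.genes if g in keep_set]
    if not keep:
        raise ValueError("gene list shares no identifiers with the dataset")
    return ds.subset_genes(keep)


def round_half_even(x: float) -> int:
    """Banker's rounding of a non-negative real to int (used for subset sizes)."""
    return int(round(x))


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal-style half-up rounding, used when comparing to printed tables."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
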
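"""Domain types and file I/O for miRNA perturbation screens.

A *screen* is a matrix of log2 fold changes (perturbed vs. non-targeting
control) with miRNA mimics on the rows and antibody-level protein /
phosphoprotein readouts on the columns.  Phospho-antibodies are
distinguished by a ``_p`` suffix convention (e.g. ``GSK3B_pS9``).

Canonical on-disk formats are plain text: TSV for matrices, GMT for
pathway sets and GraphML / SIF / TSV for networks.  All exports are
deterministic (sorted, fixed attribute names) so that reruns diff
cleanly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ScreenMatrix",
    "DiscreteScreen",
    "PathwaySet",
    "ProliferationTable",
    "MiRNAAnnotation",
    "read_screen",
    "write_screen",
    "read_discrete",
    "write_discrete",
    "read_gmt",
    "write_gmt",
    "write_network",
    "read_network",
    "is_phospho",
]

_FLOAT_FMT = "%.10g"


def is_phospho(protein_id: str) -> bool:
    """True if an antibody id follows the ``_p<site>`` phospho convention."""
    return bool(re.search(r"_p[STY]?\d*", protein_id))


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ScreenMatrix:
    """miRNA × protein matrix of log2 fold changes vs. control.

    Invariants: all values finite, identifiers unique, shape consistent.
    """

    mirna_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray
    cell_line: str = ""
    screen_id: str = ""

    def __post_init__(self) -> None:
        self.mirna_ids = list(map(str, self.mirna_ids))
        self.protein_ids = list(map(str, self.protein_ids))
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.protein_ids, "protein")
        if self.values.shape != (len(self.mirna_ids), len(self.protein_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.mirna_ids)}, {len(self.protein_ids)}) identifiers"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at miRNA {self.mirna_ids[i]!r}, "
                f"protein {self.protein_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.mirna_ids, columns=self.protein_ids
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, cell_line: str = "", screen_id: str = ""
    ) -> "ScreenMatrix":
        return cls(
            mirna_ids=list(df.index.astype(str)),
            protein_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            cell_line=cell_line,
            screen_id=screen_id,
        )

    def subset(
        self,
        mirnas: Sequence[str] | None = None,
        proteins: Sequence[str] | None = None,
    ) -> "ScreenMatrix":
        """Row/column subset preserving the order given in the arguments."""
        df = self.to_frame()
        if mirnas is not None:
            df = df.loc[list(mirnas)]
        if proteins is not None:
            df = df[list(proteins)]
        return ScreenMatrix.from_frame(df, self.cell_line, self.screen_id)


@dataclass
class DiscreteScreen:
    """Three-state (−1 / 0 / +1) version of a screen with its threshold."""

    mirna_ids: list[str]
    protein_ids: list[str]
    states: np.ndarray
    threshold: float
    cell_line: str = ""
    screen_id: str = ""

    def __post_init__(self) -> None:
        self.mirna_ids = list(map(str, self.mirna_ids))
        self.protein_ids = list(map(str, self.protein_ids))
        self.states = np.asarray(self.states, dtype=np.int8)
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.protein_ids, "protein")
        if self.states.shape != (len(self.mirna_ids), len(self.protein_ids)):
            raise ValueError("state matrix shape does not match identifiers")
        if not np.isin(self.states, (-1, 0, 1)).all():
            raise ValueError("states must be in {-1, 0, +1}")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.states, index=self.mirna_ids, columns=self.protein_ids
        )

    def subset(
        self,
        mirnas: Sequence[str] | None = None,
        proteins: Sequence[str] | None = None,
    ) -> "DiscreteScreen":
        df = self.to_frame()
        if mirnas is not None:
            df = df.loc[list(mirnas)]
        if proteins is not None:
            df = df[list(proteins)]
        return DiscreteScreen(
            list(df.index),
            list(df.columns),
            df.to_numpy(),
            self.threshold,
            self.cell_line,
            self.screen_id,
        )


@dataclass(frozen=True)
class PathwaySet:
    """A named set of protein identifiers; proteins may belong to several."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")


@dataclass
class ProliferationTable:
    """Relative cell-number change per miRNA with optional group labels.

    ``group`` holds one of ``high`` / ``low`` / ``neither`` once binning
    has been applied (see :mod:`mirscreen.proliferation`), else ``""``.
    """

    mirna_ids: list[str]
    rel_change: np.ndarray
    group: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mirna_ids = list(map(str, self.mirna_ids))
        self.rel_change = np.asarray(self.rel_change, dtype=float)
        _check_unique(self.mirna_ids, "miRNA")
        if self.rel_change.shape != (len(self.mirna_ids),):
            raise ValueError("rel_change length does not match mirna_ids")
        if self.group is None:
            self.group = np.array([""] * len(self.mirna_ids), dtype=object)
        else:
            self.group = np.asarray(self.group, dtype=object)
            if self.group.shape != (len(self.mirna_ids),):
                raise ValueError("group length does not match mirna_ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rel_change": self.rel_change, "group": self.group},
            index=pd.Index(self.mirna_ids, name="mirna"),
        )


@dataclass(frozen=True)
class MiRNAAnnotation:
    """miRNA family membership and seed sequence (nt 2–8 of the mature miRNA)."""

    mirna_id: str
    family: str
    seed: str

    def __post_init__(self) -> None:
        if len(self.seed) not in (7, 8):
            raise ValueError(
                f"seed for {self.mirna_id!r} must be 7 or 8 nt, got {len(self.seed)}"
            )
        if set(self.seed) - set("ACGU"):
            raise ValueError(f"seed for {self.mirna_id!r} must be over A/C/G/U")


# ---------------------------------------------------------------------------
# TSV matrix I/O
# ---------------------------------------------------------------------------

def read_screen(path: str | Path, cell_line: str = "", screen_id: str = "") -> ScreenMatrix:
    """Read a TSV screen matrix (header = protein ids, first column = miRNA ids).

    Row and column order are preserved as in the file.  Duplicated ids or
    non-numeric cells raise ``ValueError`` naming the offending entry.
    """
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    _check_unique(header.rstrip("\n").split("\t")[1:], "protein")  # pandas mangles dupes
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    _check_unique(list(df.index.astype(str)), "miRNA")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}: "
            f"{df.iat[i, j]!r}"
        )
    return ScreenMatrix.from_frame(numeric, cell_line=cell_line, screen_id=screen_id)


def write_screen(screen: ScreenMatrix, path: str | Path) -> Path:
    path = Path(path)
    screen.to_frame().to_csv(path, sep="\t", float_format="%.17g", index_label="mirna")
    return path


def read_discrete(path: str | Path, cell_line: str = "", screen_id: str = "") -> DiscreteScreen:
    threshold = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# z_threshold:"):
        threshold = float(first.split(":", 1)[1])
    if threshold is None:
        raise ValueError(f"{path}: missing '# z_threshold:' header line")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return DiscreteScreen(
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
        df.to_numpy(dtype=np.int8),
        threshold,
        cell_line,
        screen_id,
    )


def write_discrete(screen: DiscreteScreen, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# z_threshold: {screen.threshold:.12g}\n")
        screen.to_frame().to_csv(fh, sep="\t", index_label="mirna")
    return path


# ---------------------------------------------------------------------------
# GMT pathway sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Parse a GMT file (name TAB description TAB member...), one set per line.

    Repeated names yield separate sets (no merging).  Lines with fewer
    than three fields raise ``ValueError`` with the line number.
    """
    out: list[PathwaySet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            out.append(
                PathwaySet(
                    name=fields[0],
                    description=fields[1],
                    members=frozenset(f for f in fields[2:] if f),
                )
            )
    return out


def write_gmt(pathways: Iterable[PathwaySet], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for ps in pathways:
            fh.write(
                "\t".join([ps.name, ps.description or "na", *sorted(ps.members)]) + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# Network exports
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("source", "target", "score", "sign")


def _sorted_edges(edges: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge table missing required columns: {missing}")
    return edges.sort_values(["source", "target"], kind="mergesort").reset_index(drop=True)


def write_network(edges: pd.DataFrame, path: str | Path, format: str = "graphml") -> Path:
    """Export an edge list with ``source, target, score, sign[, cluster]``.

    Output is byte-stable for identical input: edges are sorted by
    (source, target) and attribute names are fixed.
    """
    path = Path(path)
    if format not in ("graphml", "sif", "tsv"):
        raise ValueError(f"unknown network format: {format!r}")
    edges = _sorted_edges(edges) if len(edges) else edges
    if format == "tsv":
        cols = [c for c in ("source", "target", "score", "sign", "cluster") if c in edges.columns]
        out = edges[cols] if len(edges) else pd.DataFrame(columns=list(_EDGE_COLUMNS))
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path
    if format == "sif":
        with open(path, "w") as fh:
            for row in edges.itertuples(index=False):
                rel = "up" if getattr(row, "sign") > 0 else "down"
                fh.write(f"{row.source}\t{rel}\t{row.target}\n")
        return path
    g = nx.Graph()
    for row in (edges.itertuples(index=False) if len(edges) else ()):
        attrs = {"score": float(row.score), "sign": int(row.sign)}
        if hasattr(row, "cluster") and row.cluster is not None:
            attrs["cluster"] = str(row.cluster)
        g.add_edge(str(row.source), str(row.target), **attrs)
    nx.write_graphml(g, path)
    return path


def read_network(path: str | Path) -> pd.DataFrame:
    """Read a GraphML export back into a sorted edge table (round-trip helper)."""
    g = nx.read_graphml(path)
    rows = []
    for u, v, data in g.edges(data=True):
        row = {"source": u, "target": v}
        row.update(data)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["source", "target", "score", "sign", "cluster"])
    if len(df):
        # undirected edges may come back in either orientation
        flip = df["source"] > df["target"]
        df.loc[flip, ["source", "target"]] = df.loc[flip, ["target", "source"]].to_numpy()
        df = df.sort_values(["source", "target"], kind="mergesort").reset_index(drop=True)
    return df
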
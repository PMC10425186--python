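"""Reading and writing snapshot graph sets and result subgraphs.

A dynamic graph is represented as a :class:`SnapshotGraphSet`: an ordered
collection of T simple undirected :class:`networkx.Graph` objects over one
shared vertex namespace. The canonical on-disk form is plain edge-list TSV,
one file per snapshot (two columns: vertex_a, vertex_b) or one long-form
file with a snapshot column. Header lines must start with ``#``; rows are
tab-separated with a whitespace fallback. GraphML is supported as a
convenience via networkx.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .exceptions import ConfigError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SnapshotGraphSet",
    "load_snapshots",
    "load_snapshot_tsvs",
    "load_long_tsv",
    "load_graphml",
    "write_snapshots",
    "write_usnaps",
]


@dataclass
class SnapshotGraphSet:
    """T simple undirected snapshot graphs over a shared vertex namespace.

    Attributes
    ----------
    snapshots:
        Ordered list of ``networkx.Graph`` objects, one per snapshot.
        Snapshot indices used elsewhere in the package are 1-based.
    labels:
        One display label per snapshot (e.g. tumour stage names).
    """

    snapshots: list[nx.Graph]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.snapshots) < 2:
            raise ConfigError(
                f"a snapshot set needs at least 2 snapshots, got {len(self.snapshots)}; "
                "uniqueness relative to a single snapshot is vacuous"
            )
        if not self.labels:
            self.labels = [f"s{i}" for i in range(1, len(self.snapshots) + 1)]
        if len(self.labels) != len(self.snapshots):
            raise ConfigError(
                f"{len(self.labels)} labels for {len(self.snapshots)} snapshots"
            )
        for label, g in zip(self.labels, self.snapshots):
            if any(a == b for a, b in nx.selfloop_edges(g)):
                raise ConfigError(f"snapshot {label!r} contains self-loops")

    @property
    def T(self) -> int:
        """Number of snapshots."""
        return len(self.snapshots)

    @property
    def m(self) -> int:
        """Total edge count over all snapshots."""
        return sum(g.number_of_edges() for g in self.snapshots)

    @property
    def n(self) -> int:
        """Size of the shared vertex namespace (union over snapshots)."""
        return len(self.vertices)

    @property
    def vertices(self) -> set[str]:
        out: set[str] = set()
        for g in self.snapshots:
            out.update(g.nodes)
        return out


# ---------------------------------------------------------------------------
# loading


def _parse_edge_tsv(path: Path) -> nx.Graph:
    """Parse a two-column edge-list TSV into a simple graph.

    Duplicate rows and (a,b)/(b,a) pairs collapse to one edge; self-loop
    rows are dropped with a logged count; isolated vertices never arise
    (vertices exist only as edge endpoints).
    """
    g = nx.Graph()
    n_selfloops = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise InputError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise InputError(f"{path}:{lineno}: empty vertex label")
            if a == b:
                n_selfloops += 1
                continue
            g.add_edge(a, b)
    if n_selfloops:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_selfloops)
    if g.number_of_edges() == 0:
        logger.warning("%s: empty snapshot (no edges)", path)
    return g


def load_snapshot_tsvs(
    paths: Sequence[str | Path], labels: Sequence[str] | None = None
) -> SnapshotGraphSet:
    """Load one TSV edge list per snapshot, in the given order."""
    paths = [Path(p) for p in paths]
    graphs = [_parse_edge_tsv(p) for p in paths]
    if labels is None:
        labels = [p.stem for p in paths]
    return SnapshotGraphSet(graphs, list(labels))


def load_long_tsv(path: str | Path, snapshot_column: str = "snapshot") -> SnapshotGraphSet:
    """Load a single long-form TSV: vertex_a, vertex_b, snapshot.

    Snapshots are ordered by the lexical order of their labels; a header
    row starting with ``#`` may name the columns but is not required (the
    snapshot column is then taken to be the third).
    """
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    col_idx = 2
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                if snapshot_column in header:
                    col_idx = header.index(snapshot_column)
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) <= max(2, col_idx):
                raise InputError(
                    f"{path}:{lineno}: long format needs vertex_a, vertex_b "
                    f"and a snapshot column"
                )
            rows.append((fields[0].strip(), fields[1].strip(), fields[col_idx].strip()))
    snap_labels = sorted({r[2] for r in rows})
    if len(snap_labels) < 2:
        raise ConfigError(
            f"{path}: long-form input contains {len(snap_labels)} snapshot label(s); "
            "at least 2 are required"
        )
    graphs = {lab: nx.Graph() for lab in snap_labels}
    n_selfloops = 0
    for a, b, lab in rows:
        if a == b:
            n_selfloops += 1
            continue
        graphs[lab].add_edge(a, b)
    if n_selfloops:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_selfloops)
    return SnapshotGraphSet([graphs[lab] for lab in snap_labels], snap_labels)


def load_graphml(paths: Sequence[str | Path], labels: Sequence[str] | None = None) -> SnapshotGraphSet:
    """Load one GraphML file per snapshot. Isolated vertices are dropped."""
    paths = [Path(p) for p in paths]
    graphs = []
    for p in paths:
        raw = nx.read_graphml(p)
        g = nx.Graph()
        for a, b in raw.edges():
            if a != b:
                g.add_edge(str(a), str(b))
        graphs.append(g)
    if labels is None:
        labels = [p.stem for p in paths]
    return SnapshotGraphSet(graphs, list(labels))


def load_snapshots(
    source: str | Path | Sequence[str | Path],
    fmt: str = "auto",
    snapshot_column: str = "snapshot",
    manifest: str | Path | None = None,
) -> SnapshotGraphSet:
    """Load a snapshot graph set from TSV edge lists, long TSV, or GraphML.

    Parameters
    ----------
    source:
        A directory (all ``*.tsv`` files, lexical order), a list of files,
        or a single long-form TSV file.
    fmt:
        ``"tsv_per_snapshot"``, ``"tsv_long"``, ``"graphml"`` or ``"auto"``
        (directory or file list -> per-snapshot; single file -> long form).
    manifest:
        Optional JSON file holding a list of file names fixing snapshot
        order explicitly (overrides lexical order for a directory source).
    """
    if isinstance(source, (str, Path)):
        src = Path(source)
        if src.is_dir():
            if manifest is not None:
                names = json.loads(Path(manifest).read_text())
                paths = [src / name for name in names]
            else:
                paths = sorted(src.glob("*.tsv"))
            if fmt in ("auto", "tsv_per_snapshot"):
                if len(paths) < 2:
                    raise ConfigError(
                        f"{src}: found {len(paths)} snapshot TSV file(s); need at least 2"
                    )
                return load_snapshot_tsvs(paths)
            if fmt == "graphml":
                gpaths = sorted(src.glob("*.graphml"))
                return load_graphml(gpaths)
            raise ConfigError(f"format {fmt!r} incompatible with a directory source")
        if fmt in ("auto", "tsv_long"):
            return load_long_tsv(src, snapshot_column=snapshot_column)
        if fmt == "graphml":
            raise ConfigError("graphml format needs one file per snapshot (a list or directory)")
        raise ConfigError(f"format {fmt!r} incompatible with a single-file source")
    paths = list(source)
    if fmt == "graphml" or (fmt == "auto" and all(str(p).endswith(".graphml") for p in paths)):
        return load_graphml(paths)
    return load_snapshot_tsvs(paths)


# ---------------------------------------------------------------------------
# writing


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_snapshots(snapshots: SnapshotGraphSet, out_dir: str | Path) -> list[Path]:
    """Write one edge-list TSV per snapshot; file names sort in snapshot order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, (label, g) in enumerate(zip(snapshots.labels, snapshots.snapshots), 1):
        path = out_dir / f"snapshot_{i:02d}_{label}.tsv"
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("#vertex_a\tvertex_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
                fh.write(f"{a}\t{b}\n")
        written.append(path)
    return written


def write_usnaps(results: Iterable, out_dir: str | Path, graphml: bool = False) -> Path:
    """Write per-usnap edge TSVs plus a summary table.

    Each usnap goes to ``usnap_<rank>.tsv`` with columns vertex_a, vertex_b,
    weight, no_cond, u_specific. The summary (``summary.tsv`` and a JSON
    twin) has one row per usnap: rank, n_vertices, n_edges, density,
    exclusive_fraction, ranks d0, d1, ... densest-first.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    for us in results:
        path = out_dir / f"usnap_{us.rank}.tsv"
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("#vertex_a\tvertex_b\tweight\tno_cond\tu_specific\n")
            for (a, b), rec in sorted(us.edges.items()):
                fh.write(
                    f"{a}\t{b}\t{_fmt(rec.weight)}\t{rec.no_cond}\t"
                    f"{'true' if rec.u_specific else 'false'}\n"
                )
        if graphml:
            g = nx.Graph()
            for (a, b), rec in us.edges.items():
                g.add_edge(a, b, weight=rec.weight, no_cond=rec.no_cond,
                           u_specific=bool(rec.u_specific))
            nx.write_graphml(g, out_dir / f"usnap_{us.rank}.graphml")
        summary_rows.append(
            {
                "rank": us.rank,
                "n_vertices": us.n_vertices,
                "n_edges": us.n_edges,
                "density": us.density,
                "exclusive_fraction": us.exclusive_fraction,
            }
        )
    summary_path = out_dir / "summary.tsv"
    with open(summary_path, "wt", encoding="utf-8") as fh:
        fh.write("#rank\tn_vertices\tn_edges\tdensity\texclusive_fraction\n")
        for row in summary_rows:
            fh.write(
                f"{row['rank']}\t{row['n_vertices']}\t{row['n_edges']}\t"
                f"{_fmt(row['density'])}\t{_fmt(row['exclusive_fraction'])}\n"
            )
    with open(out_dir / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary_rows, fh, indent=2)
        fh.write("\n")
    return summary_path


def write_collapsed_tsv(gc, path: str | Path) -> Path:
    """Debug dump of a collapsed graph: vertex_a, vertex_b, no_cond, weight, u_specific."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#vertex_a\tvertex_b\tno_cond\tweight\tu_specific\n")
        for (a, b), rec in sorted(gc.edges.items()):
            fh.write(
                f"{a}\t{b}\t{rec.no_cond}\t{_fmt(rec.weight)}\t"
                f"{'true' if rec.u_specific else 'false'}\n"
            )
    return path
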
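"""Directed, binary, loop-free food webs and their on-disk formats.

A food web is a directed graph over labelled species in which an arc
``prey -> predator`` marks the direction of energy transfer.  Cannibalism
(self-loops) is excluded, arcs are unweighted, and species labels are unique
non-empty strings.

Two plain-text formats are supported:

* **edge-list CSV** (canonical): header ``prey,predator``, one arc per row.
  A species that takes part in no trophic interaction is recorded as a row
  with an empty ``predator`` field, so that files round-trip exactly even for
  webs with isolated species.
* **adjacency CSV**: first row and column carry species labels; cell
  ``(r, c) = 1`` means the row species is eaten by the column species.
"""

from __future__ import annotations

import csv
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ParseError, ValidationError

__all__ = ["FoodWeb", "read_foodweb", "write_foodweb", "write_graphml"]


class FoodWeb:
    """A directed, binary, loop-free trophic network.

    Parameters
    ----------
    species
        Unique, non-empty label strings; order fixes row/column order of
        ``adjacency``.
    adjacency
        ``n x n`` 0/1 array; entry ``(i, j) = 1`` means an arc ``i -> j``,
        i.e. prey ``i`` is eaten by predator ``j``.
    metadata
        Free-form mapping (e.g. ``region``, ``period``, ``source``).
    """

    __slots__ = ("species", "adjacency", "metadata")

    def __init__(
        self,
        species: Sequence[str],
        adjacency: np.ndarray,
        metadata: Mapping | None = None,
    ):
        species = tuple(str(s) for s in species)
        if len(species) < 2:
            raise ValidationError("a food web needs at least 2 species")
        if len(set(species)) != len(species):
            dupes = sorted({s for s in species if species.count(s) > 1})
            raise ValidationError(f"duplicate species labels: {dupes}")
        if any(not s for s in species):
            raise ValidationError("species labels must be non-empty")
        A = np.asarray(adjacency)
        n = len(species)
        if A.shape != (n, n):
            raise ValidationError(
                f"adjacency shape {A.shape} does not match {n} species"
            )
        if not np.isin(A, (0, 1)).all():
            raise ValidationError("adjacency entries must be exactly 0 or 1")
        A = A.astype(np.uint8)
        if np.diagonal(A).any():
            loops = [species[i] for i in np.flatnonzero(np.diagonal(A))]
            raise ValidationError(f"self-loops (cannibalism) not allowed: {loops}")
        self.species = species
        self.adjacency = A
        self.adjacency.setflags(write=False)
        self.metadata = dict(metadata or {})

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arcs(
        cls,
        species: Sequence[str],
        arcs: Iterable[tuple[str, str]],
        metadata: Mapping | None = None,
    ) -> "FoodWeb":
        """Build a web from ``(prey, predator)`` label pairs."""
        species = tuple(species)
        index = {s: i for i, s in enumerate(species)}
        A = np.zeros((len(species), len(species)), dtype=np.uint8)
        for prey, predator in arcs:
            try:
                A[index[prey], index[predator]] = 1
            except KeyError as exc:
                raise ValidationError(f"arc references unknown species {exc}") from exc
        return cls(species, A, metadata)

    # -- basic queries ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def n_arcs(self) -> int:
        return int(self.adjacency.sum())

    @property
    def density(self) -> float:
        """Connectance over ordered dyads, L / (n (n - 1))."""
        return self.n_arcs / (self.n * (self.n - 1))

    def arcs(self) -> list[tuple[str, str]]:
        """All arcs as ``(prey, predator)`` label pairs, row-major order."""
        rows, cols = np.nonzero(self.adjacency)
        return [(self.species[i], self.species[j]) for i, j in zip(rows, cols)]

    def in_degrees(self) -> np.ndarray:
        """Number of prey feeding each species (columns sums)."""
        return self.adjacency.sum(axis=0).astype(np.int64)

    def out_degrees(self) -> np.ndarray:
        """Number of predators eating each species (row sums)."""
        return self.adjacency.sum(axis=1).astype(np.int64)

    def equals(self, other: "FoodWeb") -> bool:
        """Order-insensitive equality on species labels and arc sets."""
        return set(self.species) == set(other.species) and set(self.arcs()) == set(
            other.arcs()
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        g.add_edges_from(self.arcs())
        g.graph.update(self.metadata)
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FoodWeb(n={self.n}, arcs={self.n_arcs})"


# -- file I/O ------------------------------------------------------------------

_FORMATS = ("edge-list", "adjacency")


def read_foodweb(path, format: str = "edge-list", metadata: Mapping | None = None) -> FoodWeb:
    """Read a food web from an edge-list or adjacency CSV.

    Arc orientation is prey -> predator as declared by each format's header.
    Malformed rows raise :class:`ParseError` naming the offending line;
    invariant violations (self-loops, duplicate labels) raise
    :class:`ValidationError`.
    """
    if format not in _FORMATS:
        raise ParseError(f"unknown format {format!r}; expected one of {_FORMATS}")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ParseError(f"{path}: empty file")
    if format == "edge-list":
        return _parse_edge_list(rows, path, metadata)
    return _parse_adjacency(rows, path, metadata)


def _parse_edge_list(rows, path, metadata) -> FoodWeb:
    header = [c.strip() for c in rows[0]]
    if header[:2] != ["prey", "predator"]:
        raise ParseError(f"{path}: line 1: expected header 'prey,predator'")
    species: list[str] = []
    seen: set[str] = set()

    def register(label: str):
        if label not in seen:
            seen.add(label)
            species.append(label)

    arcs: list[tuple[str, str]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields, got {len(row)}")
        prey, predator = row[0].strip(), row[1].strip()
        if not prey:
            raise ParseError(f"{path}: line {lineno}: empty prey label")
        register(prey)
        if predator == "":
            continue  # species-only row (isolated species)
        if prey == predator:
            raise ValidationError(
                f"{path}: line {lineno}: self-loop on {prey!r} (cannibalism excluded)"
            )
        register(predator)
        arcs.append((prey, predator))
    if len(arcs) != len(set(arcs)):
        dupes = sorted({a for a in arcs if arcs.count(a) > 1})
        raise ValidationError(f"{path}: duplicate arcs {dupes}")
    return FoodWeb.from_arcs(species, arcs, metadata)


def _parse_adjacency(rows, path, metadata) -> FoodWeb:
    header = [c.strip() for c in rows[0]]
    species = header[1:]
    if not species:
        raise ParseError(f"{path}: line 1: adjacency header lists no species")
    n = len(species)
    if len(rows) != n + 1:
        raise ParseError(f"{path}: expected {n + 1} rows, found {len(rows)}")
    A = np.zeros((n, n), dtype=np.uint8)
    for r, row in enumerate(rows[1:]):
        lineno = r + 2
        if len(row) != n + 1:
            raise ParseError(
                f"{path}: line {lineno}: expected {n + 1} fields, got {len(row)}"
            )
        if row[0].strip() != species[r]:
            raise ParseError(
                f"{path}: line {lineno}: row label {row[0]!r} does not match "
                f"header order ({species[r]!r})"
            )
        for c, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise ParseError(
                    f"{path}: line {lineno}: cell must be 0 or 1, got {cell!r}"
                )
            A[r, c] = int(cell)
    return FoodWeb(species, A, metadata)


def write_foodweb(web: FoodWeb, path, format: str = "edge-list") -> None:
    """Write a web so that :func:`read_foodweb` reproduces it exactly."""
    if format not in _FORMATS:
        raise ParseError(f"unknown format {format!r}; expected one of {_FORMATS}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        if format == "edge-list":
            w.writerow(["prey", "predator"])
            linked: set[str] = set()
            for prey, predator in web.arcs():
                linked.add(prey)
                linked.add(predator)
                w.writerow([prey, predator])
            for s in web.species:
                if s not in linked:
                    w.writerow([s, ""])
        else:
            w.writerow([""] + list(web.species))
            for i, s in enumerate(web.species):
                w.writerow([s] + [str(int(v)) for v in web.adjacency[i]])


def write_graphml(web: FoodWeb, path) -> None:
    """Export as GraphML with arc attribute ``direction='prey_to_predator'``."""
    import networkx as nx

    g = web.to_networkx()
    nx.set_edge_attributes(g, "prey_to_predator", "direction")
    nx.write_graphml(g, path)
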
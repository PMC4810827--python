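"""Directed triad census and motif z-scores against random-network nulls.

Each unordered triple of species falls into exactly one of the 16
directed-triad isomorphism classes (standard MAN labelling, ``003`` ...
``300``).  The 13 connected classes are reported as motifs; their observed
counts are compared against an empirical null distribution from either a
density-preserving (fixed arc count) or degree-preserving (checkerboard
swap) randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .foodweb import FoodWeb

__all__ = [
    "TRIAD_CLASSES",
    "TriadCensus",
    "MotifReport",
    "triad_census",
    "motif_zscores",
    "density_preserving_null",
    "degree_preserving_null",
]

#: all 16 directed-triad classes in conventional order
TRIAD_CLASSES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)
CONNECTED_CLASSES = tuple(c for c in TRIAD_CLASSES if c not in ("003", "012", "102"))

_CODE_TABLE: np.ndarray | None = None  # 64-entry dyad-code -> class-index table


def _build_code_table() -> np.ndarray:
    """Map each 6-bit triple configuration to its triad class.

    Bits (LSB first): x01, x10, x02, x20, x12, x21 on nodes {0, 1, 2}.
    The table is derived once from networkx's triadic census, which is the
    canonical implementation of the MAN classification.
    """
    import networkx as nx

    table = np.empty(64, dtype=np.int64)
    for code in range(64):
        g = nx.DiGraph()
        g.add_nodes_from([0, 1, 2])
        bits = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
        for b, (u, v) in enumerate(bits):
            if code >> b & 1:
                g.add_edge(u, v)
        census = nx.triadic_census(g)
        (label,) = [k for k, v in census.items() if v == 1]
        table[code] = TRIAD_CLASSES.index(label)
    return table


def _code_table() -> np.ndarray:
    global _CODE_TABLE
    if _CODE_TABLE is None:
        _CODE_TABLE = _build_code_table()
    return _CODE_TABLE


def triad_census_array(A: np.ndarray) -> dict[str, int]:
    """Census of a 0/1 adjacency matrix as a class -> count mapping."""
    from ._kernels import triad_census_counts

    counts = triad_census_counts(np.ascontiguousarray(A, dtype=np.uint8), _code_table())
    return {c: int(k) for c, k in zip(TRIAD_CLASSES, counts)}


@dataclass(frozen=True)
class TriadCensus:
    """Counts of the 16 directed-triad classes; they sum to C(n, 3)."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def connected(self) -> dict[str, int]:
        """Counts restricted to the 13 connected classes (the motifs)."""
        return {c: self.counts[c] for c in CONNECTED_CLASSES}

    def __getitem__(self, cls: str) -> int:
        return self.counts[cls]


def triad_census(web: FoodWeb) -> TriadCensus:
    """Classify every unordered species triple into its triad class.

    Webs with fewer than 3 species yield an all-zero census (total 0).
    """
    if web.n < 3:
        return TriadCensus({c: 0 for c in TRIAD_CLASSES})
    return TriadCensus(triad_census_array(web.adjacency))


# -- null models -----------------------------------------------------------------

def density_preserving_null(web: FoodWeb, rng: np.random.Generator) -> np.ndarray:
    """A uniform random digraph with the same node and arc count (no loops)."""
    n, L = web.n, web.n_arcs
    dyads = n * (n - 1)
    pick = rng.choice(dyads, size=L, replace=False)
    A = np.zeros((n, n), dtype=np.uint8)
    rows = pick // (n - 1)
    cols = pick % (n - 1)
    cols = cols + (cols >= rows)  # skip the diagonal
    A[rows, cols] = 1
    return A


def degree_preserving_null(
    web: FoodWeb, rng: np.random.Generator, swaps_per_arc: int = 10
) -> np.ndarray:
    """Checkerboard (2x2 swap) randomisation preserving both degree sequences.

    Attempts ``swaps_per_arc * L`` directed swaps (a->b, c->d) -> (a->d, c->b),
    rejecting any that would create a loop or an existing arc.
    """
    from ._kernels import checkerboard_swaps

    A = web.adjacency.copy()
    seed = int(rng.integers(2**31 - 1))
    checkerboard_swaps(A, swaps_per_arc * web.n_arcs, seed)
    return A


_NULLS = {
    "density-preserving": lambda web, rng: density_preserving_null(web, rng),
    "degree-preserving": lambda web, rng: degree_preserving_null(web, rng),
}


@dataclass(frozen=True)
class MotifReport:
    """Observed vs. null triad-class counts with z-scores.

    ``z = (observed - mean) / sd`` for each connected class; ``z`` is None
    (flagged undefined) when the null standard deviation is zero.
    """

    observed: Mapping[str, int]
    null_mean: Mapping[str, float]
    null_sd: Mapping[str, float]
    zscores: Mapping[str, float | None]
    null_model: str
    replicates: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "observed": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": {k: (np.nan if v is None else v) for k, v in self.zscores.items()},
            }
        )


def motif_zscores(
    web: FoodWeb,
    null: str = "density-preserving",
    replicates: int = 1000,
    seed: int = 0,
) -> MotifReport:
    """Motif analysis: observed triad counts vs. a random-network null.

    For each connected triad class the observed count is standardised against
    the empirical null distribution over ``replicates`` randomised webs.
    Deterministic given ``seed``.
    """
    if null not in _NULLS:
        raise ValidationError(f"unknown null model {null!r}; known: {sorted(_NULLS)}")
    if replicates < 2:
        raise ValidationError("need at least 2 null replicates")
    rng = np.random.default_rng(seed)
    observed = triad_census(web).connected()
    draw = _NULLS[null]
    samples = np.empty((replicates, len(CONNECTED_CLASSES)), dtype=np.float64)
    for r in range(replicates):
        counts = triad_census_array(draw(web, rng))
        samples[r] = [counts[c] for c in CONNECTED_CLASSES]
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    z: dict[str, float | None] = {}
    for k, c in enumerate(CONNECTED_CLASSES):
        z[c] = None if sd[k] == 0 else float((observed[c] - mean[k]) / sd[k])
    return MotifReport(
        observed=observed,
        null_mean=dict(zip(CONNECTED_CLASSES, mean)),
        null_sd=dict(zip(CONNECTED_CLASSES, sd)),
        zscores=z,
        null_model=null,
        replicates=replicates,
        seed=seed,
    )
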
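"""Configuration statistics of the food-web ERGM and their change statistics.

Every statistic ``z_s(G)`` is an exact function of a directed, binary,
loop-free graph ``G``.  The modelled statistics are the "alternating"
(geometrically weighted) forms standard in the ERGM literature, built from
the smoothing function

    g_lambda(d) = lambda * (1 - (1 - 1/lambda)**d),     lambda >= 1,

which is increasing and concave in the count ``d`` and curbs model
degeneracy relative to raw star/triangle counts.  Each modelled statistic has
an ecological reading under the prey -> predator arc orientation:

============================  =================================================
``arc``                       baseline tie propensity (count of arcs)
``reciprocity``               mutual predation (pairs eating each other)
``generalist``                alternating in-star: predators with many prey
``highly_predated``           alternating out-star: prey with many predators
``keystone``                  mixed alternating star: species with many prey
                              *and* many predators
``tri_trophic``               alternating two-path: prey -> consumer -> top
``apparent_competition``      two prey sharing a predator (common sink)
``exploitative_competition``  two predators sharing a prey (common source)
``omnivory``                  alternating transitive triangle (chain + shortcut)
``cyclic_triangle``           alternating cyclic closure (3-cycles)
============================  =================================================

Raw counterparts (``in_2star`` ... ``cyclic_triangle_raw``) and descriptive
statistics (triad-class counts, degree-spread measures) are registered for
goodness-of-fit use only; they carry no change statistic and cannot enter a
fitted model.

The change statistic ``delta_s(G, i, j) = z_s(G + ij) - z_s(G - ij)`` is the
kernel of both simulation and estimation; it is computed here from local
neighbourhood formulas in O(n) - O(n^2) per dyad and is verified in the test
suite against full recomputation of both graph variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .foodweb import FoodWeb

__all__ = [
    "ConfigurationStatistic",
    "ModelSpec",
    "compute_statistics",
    "change_statistics",
    "statistic_names",
    "baltic_model_spec",
    "common_motif_spec",
    "load_model_spec",
    "save_model_spec",
]

# Integer codes shared with the numba sampling kernel (see _kernels.py).
ARC, RECIPROCITY, GENERALIST, HIGHLY_PREDATED, KEYSTONE = 0, 1, 2, 3, 4
TRI_TROPHIC, APPARENT_COMP, EXPLOITATIVE_COMP, OMNIVORY, CYCLIC = 5, 6, 7, 8, 9
IN_2STAR, IN_3STAR, OUT_2STAR, OUT_3STAR = 10, 11, 12, 13
TWO_PATH, TRANSITIVE_RAW, CYCLIC_RAW = 14, 15, 16
# descriptive, compute-only statistics get codes >= 100
_TRIAD_BASE = 100
IN_DEGREE_SD, OUT_DEGREE_SD = 200, 201

#: the 13 connected directed-triad classes (standard MAN labelling)
CONNECTED_TRIAD_CLASSES = (
    "021D", "021U", "021C", "111D", "111U", "030T", "030C",
    "201", "120D", "120U", "120C", "210", "300",
)

_MODEL_CATALOGUE = {
    "arc": (ARC, False),
    "reciprocity": (RECIPROCITY, False),
    "generalist": (GENERALIST, True),
    "highly_predated": (HIGHLY_PREDATED, True),
    "keystone": (KEYSTONE, True),
    "tri_trophic": (TRI_TROPHIC, True),
    "apparent_competition": (APPARENT_COMP, True),
    "exploitative_competition": (EXPLOITATIVE_COMP, True),
    "omnivory": (OMNIVORY, True),
    "cyclic_triangle": (CYCLIC, True),
    "in_2star": (IN_2STAR, False),
    "in_3star": (IN_3STAR, False),
    "out_2star": (OUT_2STAR, False),
    "out_3star": (OUT_3STAR, False),
    "two_path": (TWO_PATH, False),
    "transitive_triangle_raw": (TRANSITIVE_RAW, False),
    "cyclic_triangle_raw": (CYCLIC_RAW, False),
}
_DESCRIPTIVE_CATALOGUE = {
    **{f"triad_{c}": (_TRIAD_BASE + k, False)
       for k, c in enumerate(CONNECTED_TRIAD_CLASSES)},
    "in_degree_sd": (IN_DEGREE_SD, False),
    "out_degree_sd": (OUT_DEGREE_SD, False),
}
CATALOGUE = {**_MODEL_CATALOGUE, **_DESCRIPTIVE_CATALOGUE}


def statistic_names(model_only: bool = False) -> tuple[str, ...]:
    """Registered statistic names (optionally only those usable in a model)."""
    return tuple(_MODEL_CATALOGUE if model_only else CATALOGUE)


@dataclass(frozen=True)
class ConfigurationStatistic:
    """A named network statistic with its smoothing weight.

    ``lam`` is the alternating/geometric weight lambda; it is stored as 1 for
    statistics that do not use it (arc, reciprocity, raw counts).
    """

    name: str
    lam: float = 2.0

    def __post_init__(self):
        if self.name not in CATALOGUE:
            raise ConfigurationError(
                f"unknown configuration {self.name!r}; "
                f"known: {', '.join(sorted(CATALOGUE))}"
            )
        if not self.uses_lambda:
            object.__setattr__(self, "lam", 1.0)
        elif self.lam < 1.0:
            raise ConfigurationError(f"{self.name}: lambda must be >= 1, got {self.lam}")

    @property
    def code(self) -> int:
        return CATALOGUE[self.name][0]

    @property
    def uses_lambda(self) -> bool:
        return CATALOGUE[self.name][1]

    @property
    def in_model_catalogue(self) -> bool:
        """Whether the statistic has a change statistic and may enter a model."""
        return self.name in _MODEL_CATALOGUE


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of configuration statistics defining an ERGM.

    Must contain the ``arc`` baseline (controls overall tie propensity) and
    only statistics with change statistics.
    """

    configurations: tuple[ConfigurationStatistic, ...]

    def __init__(self, configurations: Iterable[ConfigurationStatistic]):
        configs = tuple(configurations)
        names = [c.name for c in configs]
        if len(set(names)) != len(names):
            raise ConfigurationError("configuration names must be unique")
        if "arc" not in names:
            raise ConfigurationError("a model must include the 'arc' baseline")
        bad = [c.name for c in configs if not c.in_model_catalogue]
        if bad:
            raise ConfigurationError(
                f"descriptive statistics cannot enter a model: {bad}"
            )
        object.__setattr__(self, "configurations", configs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.configurations)

    @property
    def p(self) -> int:
        return len(self.configurations)

    def codes_and_lambdas(self) -> tuple[np.ndarray, np.ndarray]:
        codes = np.array([c.code for c in self.configurations], dtype=np.int64)
        lams = np.array([c.lam for c in self.configurations], dtype=np.float64)
        return codes, lams

    def index(self, name: str) -> int:
        return self.names.index(name)


def from_names(names: Sequence[str], lam: float = 2.0) -> ModelSpec:
    """Convenience constructor: a spec from names with a shared lambda."""
    return ModelSpec(ConfigurationStatistic(n, lam) for n in names)


def baltic_model_spec(lam: float = 2.0, exploitative: bool = True) -> ModelSpec:
    """The seven-configuration trophic model plus the arc baseline.

    This is the full model used throughout: generalist, highly-predated,
    keystone, omnivory, tri-trophic chain, apparent competition and
    (optionally) exploitative competition, with arc controlling density.
    """
    names = [
        "arc", "generalist", "highly_predated", "keystone",
        "omnivory", "tri_trophic", "apparent_competition",
    ]
    if exploitative:
        names.append("exploitative_competition")
    return from_names(names, lam)


def common_motif_spec(lam: float = 2.0) -> ModelSpec:
    """Arc plus the four most common three-node food-web motifs."""
    return from_names(
        ["arc", "tri_trophic", "omnivory",
         "apparent_competition", "exploitative_competition"], lam,
    )


# -- YAML round trip -------------------------------------------------------------

def load_model_spec(path) -> ModelSpec:
    """Load a model specification from YAML: a list of ``{name, lambda}``."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, list):
        raise ConfigurationError(f"{path}: expected a YAML list of configurations")
    configs = []
    for entry in doc:
        if isinstance(entry, str):
            configs.append(ConfigurationStatistic(entry))
        elif isinstance(entry, dict):
            configs.append(
                ConfigurationStatistic(entry["name"], float(entry.get("lambda", 2.0)))
            )
        else:
            raise ConfigurationError(f"{path}: bad entry {entry!r}")
    return ModelSpec(configs)


def save_model_spec(spec: ModelSpec, path) -> None:
    import yaml

    doc = [{"name": c.name, "lambda": float(c.lam)} for c in spec.configurations]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh)


# -- exact statistic values ------------------------------------------------------

def _g(d: np.ndarray, lam: float) -> np.ndarray:
    """Geometric smoothing g_lambda(d) = lambda (1 - (1 - 1/lambda)^d)."""
    return lam * (1.0 - (1.0 - 1.0 / lam) ** np.asarray(d, dtype=np.float64))


def _alt_star(deg: np.ndarray, lam: float) -> float:
    """Alternating k-star value: sum_v lam^2 [(1-1/lam)^d_v + d_v/lam - 1]."""
    d = deg.astype(np.float64)
    return float(np.sum(lam * lam * ((1.0 - 1.0 / lam) ** d + d / lam - 1.0)))


def _value(A: np.ndarray, code: int, lam: float, cache: dict) -> float:
    """Exact value of one statistic on adjacency matrix A (uint8, loop-free)."""
    n = A.shape[0]
    if "din" not in cache:
        cache["din"] = A.sum(axis=0).astype(np.int64)
        cache["dout"] = A.sum(axis=1).astype(np.int64)
    din, dout = cache["din"], cache["dout"]

    def L2():
        if "L2" not in cache:
            cache["L2"] = (A.astype(np.int64) @ A.astype(np.int64))
        return cache["L2"]

    if code == ARC:
        return float(A.sum())
    if code == RECIPROCITY:
        return float((A & A.T).sum()) / 2.0
    if code == GENERALIST:
        return _alt_star(din, lam)
    if code == HIGHLY_PREDATED:
        return _alt_star(dout, lam)
    if code == KEYSTONE:
        return float(np.sum(_g(din, lam) * _g(dout, lam)))
    if code == TRI_TROPHIC:
        m = L2().copy()
        np.fill_diagonal(m, 0)  # ordered pairs (a, b), a != b; g(0) = 0
        return float(np.sum(_g(m, lam)))
    if code == APPARENT_COMP:
        cs = A.astype(np.int64) @ A.T.astype(np.int64)
        iu = np.triu_indices(n, k=1)
        return float(np.sum(_g(cs[iu], lam)))
    if code == EXPLOITATIVE_COMP:
        cp = A.T.astype(np.int64) @ A.astype(np.int64)
        iu = np.triu_indices(n, k=1)
        return float(np.sum(_g(cp[iu], lam)))
    if code == OMNIVORY:
        return float(np.sum(_g(L2(), lam) * A))
    if code == CYCLIC:
        return float(np.sum(_g(L2().T, lam) * A))
    if code == IN_2STAR:
        return float(np.sum(din * (din - 1) // 2))
    if code == IN_3STAR:
        return float(np.sum(din * (din - 1) * (din - 2) // 6))
    if code == OUT_2STAR:
        return float(np.sum(dout * (dout - 1) // 2))
    if code == OUT_3STAR:
        return float(np.sum(dout * (dout - 1) * (dout - 2) // 6))
    if code == TWO_PATH:
        m = L2()
        return float(m.sum() - np.trace(m))
    if code == TRANSITIVE_RAW:
        return float(np.sum(L2() * A))
    if code == CYCLIC_RAW:
        m = L2()
        return float(np.sum(m.T * A)) / 3.0
    if _TRIAD_BASE <= code < _TRIAD_BASE + len(CONNECTED_TRIAD_CLASSES):
        from .census import triad_census_array

        counts = cache.get("triads")
        if counts is None:
            counts = cache["triads"] = triad_census_array(A)
        return float(counts[CONNECTED_TRIAD_CLASSES[code - _TRIAD_BASE]])
    if code == IN_DEGREE_SD:
        return float(np.std(din))
    if code == OUT_DEGREE_SD:
        return float(np.std(dout))
    raise ConfigurationError(f"unknown statistic code {code}")


def compute_values(web_or_A, stats: Sequence[ConfigurationStatistic]) -> np.ndarray:
    """Exact values of an arbitrary statistic list (model or descriptive)."""
    A = web_or_A.adjacency if isinstance(web_or_A, FoodWeb) else np.asarray(web_or_A)
    cache: dict = {}
    return np.array([_value(A, s.code, s.lam, cache) for s in stats], dtype=np.float64)


def compute_statistics(web: FoodWeb, spec: ModelSpec) -> np.ndarray:
    """Exact statistic vector z(G) for a model specification.

    Values are computed from closed forms on the full graph (never sampled);
    the arc entry is a non-negative integer.
    """
    return compute_values(web, spec.configurations)


# -- change statistics -----------------------------------------------------------

def change_statistics(
    web_or_A, spec: ModelSpec, i: int, j: int
) -> np.ndarray:
    """Change statistic vector delta(G, i, j) for toggling arc i -> j.

    Defined as z(G with arc present) - z(G with arc absent), independent of
    the arc's current state.  Computed from local neighbourhood formulas.
    """
    if i == j:
        raise ValidationError("self-loops are excluded; i must differ from j")
    A = web_or_A.adjacency if isinstance(web_or_A, FoodWeb) else np.asarray(web_or_A)
    if A[i, j]:
        A = A.copy()
        A[i, j] = 0
    codes, lams = spec.codes_and_lambdas()
    return _delta_numpy(A, i, j, codes, lams)


def _delta_numpy(A: np.ndarray, i: int, j: int, codes, lams) -> np.ndarray:
    """Reference (numpy) change statistics; assumes A[i, j] == 0, no loops."""
    n = A.shape[0]
    Ai = A.astype(np.int64)
    din = Ai.sum(axis=0)
    dout = Ai.sum(axis=1)
    L2 = Ai @ Ai  # L2[a, b] = number of two-paths a -> k -> b
    out = np.empty(len(codes), dtype=np.float64)
    for idx, (code, lam) in enumerate(zip(codes, lams)):
        r = 1.0 - 1.0 / lam
        if code == ARC:
            d = 1.0
        elif code == RECIPROCITY:
            d = float(A[j, i])
        elif code == GENERALIST:
            d = lam * (1.0 - r ** din[j])
        elif code == HIGHLY_PREDATED:
            d = lam * (1.0 - r ** dout[i])
        elif code == KEYSTONE:
            d = (lam * (1.0 - r ** din[i])) * r ** dout[i] + r ** din[j] * (
                lam * (1.0 - r ** dout[j])
            )
        elif code == TRI_TROPHIC:
            preds_of_j_via_i = (A[:, i] == 1) & (np.arange(n) != j)
            d = float(np.sum(r ** L2[preds_of_j_via_i, j]))
            targets = (A[j, :] == 1) & (np.arange(n) != i)
            d += float(np.sum(r ** L2[i, targets]))
        elif code == APPARENT_COMP:
            other_prey = (A[:, j] == 1) & (np.arange(n) != i)
            cs = Ai[i, :] @ Ai[other_prey, :].T  # common predators of i and b
            d = float(np.sum(r ** cs))
        elif code == EXPLOITATIVE_COMP:
            other_preds = (A[i, :] == 1) & (np.arange(n) != j)
            cp = Ai[:, j] @ Ai[:, other_preds]  # common prey of j and b
            d = float(np.sum(r ** cp))
        elif code == OMNIVORY:
            d = lam * (1.0 - r ** L2[i, j])
            first_leg = (A[i, :] == 1) & (A[j, :] == 1)
            d += float(np.sum(r ** L2[i, first_leg]))
            second_leg = (A[:, i] == 1) & (A[:, j] == 1)
            d += float(np.sum(r ** L2[second_leg, j]))
        elif code == CYCLIC:
            # C(a, b) = cycles through arc a -> b = L2[b, a]
            d = lam * (1.0 - r ** L2[j, i])
            closers = (A[j, :] == 1) & (A[:, i] == 1)
            ks = np.flatnonzero(closers)
            d += float(np.sum(r ** L2[ks, j]) + np.sum(r ** L2[i, ks]))
        elif code == IN_2STAR:
            d = float(din[j])
        elif code == IN_3STAR:
            d = float(din[j] * (din[j] - 1) // 2)
        elif code == OUT_2STAR:
            d = float(dout[i])
        elif code == OUT_3STAR:
            d = float(dout[i] * (dout[i] - 1) // 2)
        elif code == TWO_PATH:
            d = float(din[i] + dout[j] - 2 * A[j, i])
        elif code == TRANSITIVE_RAW:
            d = float(
                L2[i, j]
                + np.sum((A[i, :] == 1) & (A[j, :] == 1))
                + np.sum((A[:, i] == 1) & (A[:, j] == 1))
            )
        elif code == CYCLIC_RAW:
            d = float(np.sum((A[j, :] == 1) & (A[:, i] == 1)))
        else:
            raise ConfigurationError(
                f"statistic code {code} has no change statistic"
            )
        out[idx] = d
    return out
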
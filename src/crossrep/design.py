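"""Study design and dissimilarity-matrix containers.

The study layout mirrors a cross-modal category experiment: a fixed set of
stimulus categories (default 8), nested in superordinate categories
(default 4), with a small number of exemplar stimuli per category presented
in several acquisition runs. All analyses downstream index conditions through
the objects defined here so that category order — and therefore the order of
the vectorized upper triangle of every dissimilarity matrix — is fixed
study-wide.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical 8-category set (order fixed study-wide)
CATEGORIES_8 = (
    "human_vocal",
    "human_nonvocal",
    "bird",
    "mammal",
    "tool",
    "graspable",
    "environmental",
    "big_mechanical",
)

#: canonical 4 superordinate categories
CATEGORIES_4 = ("human", "animal", "manipulable", "big")

#: category index -> superordinate index
DEFAULT_CAT_TO_SUPER = (0, 0, 1, 1, 2, 2, 3, 3)


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the experiment.

    Defaults follow the reference configuration: 8 categories x 3 stimuli
    nested in 4 superordinate categories, 5 runs, and three groups of
    16/16/17 subjects (a sighted-visual group and two auditory groups).
    """

    n_categories: int = 8
    n_superordinate: int = 4
    stimuli_per_category: int = 3
    n_runs: int = 5
    group_sizes: dict = field(
        default_factory=lambda: {"SCv": 16, "EBa": 16, "SCa": 17}
    )
    category_names: tuple = CATEGORIES_8
    superordinate_names: tuple = CATEGORIES_4
    category_to_superordinate: tuple = DEFAULT_CAT_TO_SUPER

    def __post_init__(self):
        if self.n_categories < 1 or self.stimuli_per_category < 1 or self.n_runs < 1:
            raise ValueError("all design counts must be >= 1")
        if len(self.category_to_superordinate) != self.n_categories:
            raise ValueError("category_to_superordinate must map every category")
        mapped = set(self.category_to_superordinate)
        if mapped != set(range(self.n_superordinate)):
            raise ValueError(
                "category_to_superordinate must be surjective onto "
                f"range({self.n_superordinate}); got {sorted(mapped)}"
            )
        if len(self.category_names) != self.n_categories:
            raise ValueError("need one name per category")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")

    @property
    def n_stimuli(self) -> int:
        return self.n_categories * self.stimuli_per_category

    @property
    def n_pairs(self) -> int:
        """Number of unordered category pairs (upper-triangle length)."""
        return self.n_categories * (self.n_categories - 1) // 2

    @property
    def n_stimulus_pairs(self) -> int:
        n = self.n_stimuli
        return n * (n - 1) // 2

    @property
    def stimulus_categories(self) -> np.ndarray:
        """Category index of each stimulus (stimuli ordered by category)."""
        return np.repeat(np.arange(self.n_categories), self.stimuli_per_category)

    @property
    def stimulus_superordinates(self) -> np.ndarray:
        c2s = np.asarray(self.category_to_superordinate)
        return c2s[self.stimulus_categories]

    def to_dict(self) -> dict:
        return {
            "n_categories": self.n_categories,
            "n_superordinate": self.n_superordinate,
            "stimuli_per_category": self.stimuli_per_category,
            "n_runs": self.n_runs,
            "group_sizes": dict(self.group_sizes),
            "category_names": list(self.category_names),
            "superordinate_names": list(self.superordinate_names),
            "category_to_superordinate": list(self.category_to_superordinate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        for key in ("category_names", "superordinate_names", "category_to_superordinate"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def category_pairs(n_categories: int) -> list[tuple[int, int]]:
    """Fixed lexicographic order of unordered category pairs (i < j)."""
    return list(itertools.combinations(range(n_categories), 2))


def vectorize_dsm(matrix: np.ndarray) -> np.ndarray:
    """Upper triangle (diagonal excluded) in fixed lexicographic pair order."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("DSM must be square")
    i, j = np.triu_indices(matrix.shape[0], k=1)
    return matrix[i, j]


def square_from_vector(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_dsm`: symmetric matrix with zero diagonal."""
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a triangular number")
    out = np.zeros((n, n))
    i, j = np.triu_indices(n, k=1)
    out[i, j] = values
    out[j, i] = values
    return out


@lru_cache(maxsize=8)
def _pair_index_matrix(n_categories: int) -> np.ndarray:
    """(n, n) matrix mapping an unordered pair to its vector position."""
    m = np.full((n_categories, n_categories), -1, dtype=np.intp)
    for k, (i, j) in enumerate(category_pairs(n_categories)):
        m[i, j] = m[j, i] = k
    return m


@lru_cache(maxsize=8)
def _pair_arrays(n_categories: int):
    i, j = np.triu_indices(n_categories, k=1)
    return i, j


def permute_pair_vector_index(cat_perm: np.ndarray, n_categories: int) -> np.ndarray:
    """Index array realizing a category relabeling on a vectorized DSM.

    If ``v`` is a vectorized DSM and ``idx`` the returned array, ``v[idx]`` is
    the vectorization of the DSM with categories relabeled by ``cat_perm``
    (entry for pair (i, j) taken from pair (perm[i], perm[j])).
    """
    m = _pair_index_matrix(n_categories)
    i, j = _pair_arrays(n_categories)
    p = np.asarray(cat_perm)
    return m[p[i], p[j]]


@dataclass
class DSM:
    """Square symmetric dissimilarity matrix with zero diagonal.

    ``kind`` records provenance ("neural", "pitch", "hmaxC1", "behavioral",
    "planted", ...); ``meta`` holds the parameters that produced it.
    """

    matrix: np.ndarray
    labels: tuple
    kind: str = "generic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("DSM matrix must be square")
        if m.shape[0] != len(self.labels):
            raise ValueError("need one label per row")
        if not np.all(np.isfinite(m)):
            raise ValueError("DSM entries must be finite")
        if not np.allclose(m, m.T):
            raise ValueError("DSM must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("DSM diagonal must be zero")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def vector(self) -> np.ndarray:
        return vectorize_dsm(self.matrix)

    def permuted(self, cat_perm) -> "DSM":
        """Relabel conditions: row/column i of the result is row perm[i]."""
        p = np.asarray(cat_perm)
        return DSM(
            self.matrix[np.ix_(p, p)],
            tuple(np.asarray(self.labels, dtype=object)[p]),
            kind=self.kind,
            meta=dict(self.meta),
        )

    # ---- TSV + JSON sidecar round trip -------------------------------------
    def to_tsv(self, path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))
        df.to_csv(path, sep="\t", index_label="category")
        sidecar = {"kind": self.kind, "meta": _jsonable(self.meta)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_tsv(cls, path) -> "DSM":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="category",
                         float_precision="round_trip")
        side = path.with_suffix(path.suffix + ".json")
        kind, meta = "generic", {}
        if side.exists():
            d = json.loads(side.read_text())
            kind, meta = d.get("kind", "generic"), d.get("meta", {})
        return cls(df.to_numpy(), tuple(df.columns), kind=kind, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
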
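"""Contrast matrices for simultaneous log-odds-ratio comparisons.

A pair of row-centered contrast matrices defines the parameter vector of
interest: ``A`` (I x C) picks pairs of response categories whose log odds
are compared, ``B`` (J x G) picks the between-group comparisons.  The full
comparison map is the Kronecker product ``B (x) A`` applied to the stacked
vector of per-group log probabilities, yielding K = I*J log odds ratios,
ordered by group comparison and, within each, by category contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ContrastPair",
    "dunnett_matrix",
    "tukey_matrix",
    "grandmean_matrix",
    "kronecker_map",
    "star_matrices",
    "contrast_pair_from_config",
]


class ContrastError(ValueError):
    """Invalid contrast specification."""


def dunnett_matrix(k: int, reference: int = 1) -> np.ndarray:
    """Many-to-one (Dunnett-type) contrast matrix, shape (k-1, k).

    Row r compares the r-th non-reference level against the reference:
    -1 in the reference column, +1 in the compared column.  ``reference``
    is 1-based, matching the convention that level 1 is the control.
    """
    if k < 2:
        raise ContrastError(f"Dunnett contrasts need at least 2 levels, got {k}")
    if not 1 <= reference <= k:
        raise ContrastError(f"reference must be in 1..{k}, got {reference}")
    ref = reference - 1
    rows = []
    for j in range(k):
        if j == ref:
            continue
        row = np.zeros(k)
        row[ref] = -1.0
        row[j] = 1.0
        rows.append(row)
    return np.array(rows)


def tukey_matrix(k: int) -> np.ndarray:
    """All-pairwise (Tukey-type) contrast matrix, shape (k(k-1)/2, k).

    One row per unordered pair (a < b), -1 at a and +1 at b, rows in
    lexicographic pair order.
    """
    if k < 2:
        raise ContrastError(f"Tukey contrasts need at least 2 levels, got {k}")
    rows = []
    for a in range(k - 1):
        for b in range(a + 1, k):
            row = np.zeros(k)
            row[a] = -1.0
            row[b] = 1.0
            rows.append(row)
    return np.array(rows)


def grandmean_matrix(k: int) -> np.ndarray:
    """Each-level-versus-grand-mean contrasts, shape (k, k).

    Row r is (−1/k, …, (k−1)/k, …, −1/k) with the positive weight at
    level r, so row r estimates ``log-odds(level r) − mean over levels``.
    Rows sum to zero; note the k rows are linearly dependent (rank k−1).
    """
    if k < 2:
        raise ContrastError(f"grand-mean contrasts need at least 2 levels, got {k}")
    return np.eye(k) - np.full((k, k), 1.0 / k)


def _check_rows(mat: np.ndarray, name: str, strict: bool = True) -> None:
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise ContrastError(f"{name} must be a 2-D matrix with at least one row")
    if np.any(np.all(mat == 0, axis=1)):
        raise ContrastError(f"{name} contains an all-zero row")
    if strict and not np.allclose(mat.sum(axis=1), 0.0, atol=1e-10):
        raise ContrastError(
            f"rows of {name} must sum to 0 (pass validate=False to override)"
        )


@dataclass
class ContrastPair:
    """Within-category matrix A (I x C) and between-group matrix B (J x G).

    ``comparison_labels`` are generated as "<category contrast>: <group
    contrast>" in the order the Kronecker map produces: group comparisons
    j = 1..J outermost, category contrasts i = 1..I within each.
    """

    A: np.ndarray
    B: np.ndarray
    category_labels: list[str] | None = None
    group_labels: list[str] | None = None
    validate: bool = True
    a_labels: list[str] = field(init=False)
    b_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        _check_rows(self.A, "A", strict=self.validate)
        _check_rows(self.B, "B", strict=self.validate)
        if self.category_labels is None:
            self.category_labels = [f"c{i+1}" for i in range(self.A.shape[1])]
        if self.group_labels is None:
            self.group_labels = [f"g{i+1}" for i in range(self.B.shape[1])]
        if len(self.category_labels) != self.A.shape[1]:
            raise ContrastError("category_labels length must match columns of A")
        if len(self.group_labels) != self.B.shape[1]:
            raise ContrastError("group_labels length must match columns of B")
        self.a_labels = [_odds_label(row, self.category_labels) for row in self.A]
        self.b_labels = [_diff_label(row, self.group_labels) for row in self.B]

    @property
    def I(self) -> int:  # noqa: E743 - matches the field's standard symbol
        return self.A.shape[0]

    @property
    def J(self) -> int:
        return self.B.shape[0]

    @property
    def C(self) -> int:
        return self.A.shape[1]

    @property
    def G(self) -> int:
        return self.B.shape[1]

    @property
    def K(self) -> int:
        return self.I * self.J

    @property
    def comparison_labels(self) -> list[str]:
        return [f"{a}: {b}" for b in self.b_labels for a in self.a_labels]

    def subset(self, rows: list[int]) -> "ContrastSelection":
        """Explicit selection of comparison rows (0-based, in Kronecker order).

        Row removal is never automatic; callers opt in by index.
        """
        keep = list(rows)
        full = kronecker_map(self)
        labels = self.comparison_labels
        return ContrastSelection(full[keep], [labels[i] for i in keep])


@dataclass
class ContrastSelection:
    """A row subset of a Kronecker comparison map, with its labels."""

    matrix: np.ndarray
    labels: list[str]


def _odds_label(row: np.ndarray, names: list[str]) -> str:
    pos = [names[i] for i in np.flatnonzero(row > 0)]
    neg = [names[i] for i in np.flatnonzero(row < 0)]
    if len(pos) == 1 and len(neg) == 1:
        return f"{pos[0]}/{neg[0]}"
    return "+".join(pos) + "/" + "+".join(neg)


def _diff_label(row: np.ndarray, names: list[str]) -> str:
    pos = [names[i] for i in np.flatnonzero(row > 0)]
    neg = [names[i] for i in np.flatnonzero(row < 0)]
    return "+".join(pos) + "-" + "+".join(neg)


def kronecker_map(cp: ContrastPair) -> np.ndarray:
    """Full comparison matrix B (x) A, shape (I*J) x (G*C).

    Applied to the stacked vector (log pi_1, ..., log pi_G) it yields the
    vector of log odds ratios theta.
    """
    return np.kron(cp.B, cp.A)


def star_matrices(cp: ContrastPair) -> tuple[np.ndarray, np.ndarray]:
    """Reduced matrices (A*, B0) acting on the baseline-category parameters.

    A* drops the first (baseline-category) column of A; B0 zeroes the first
    (reference-group) column of B.  For any probability table,
    ``(B0 (x) A*) beta`` equals ``(B (x) A) . stacked log pi`` where beta is
    the baseline-category logit parameter vector (category 1 baseline,
    group 1 reference).
    """
    if cp.C < 2:
        raise ContrastError("A must have at least 2 columns")
    a_star = cp.A[:, 1:].copy()
    b0 = cp.B.copy()
    b0[:, 0] = 0.0
    return a_star, b0


_BUILTIN = {"dunnett": dunnett_matrix, "tukey": tukey_matrix, "grandmean": grandmean_matrix}


def _matrix_from_spec(spec: dict, k: int | None, name: str) -> np.ndarray:
    if "matrix" in spec:
        return np.asarray(spec["matrix"], dtype=float)
    ctype = spec.get("type")
    if ctype not in _BUILTIN:
        raise ContrastError(f"{name}: unknown contrast type {ctype!r}")
    if k is None:
        k = spec.get("levels")
    if k is None:
        raise ContrastError(f"{name}: number of levels not determinable")
    if ctype == "dunnett":
        return dunnett_matrix(k, spec.get("reference", 1))
    return _BUILTIN[ctype](k)


def contrast_pair_from_config(
    config: dict | str | Path,
    n_categories: int | None = None,
    n_groups: int | None = None,
    category_labels: list[str] | None = None,
    group_labels: list[str] | None = None,
) -> ContrastPair:
    """Build a ContrastPair from a config mapping or a JSON/YAML file.

    The config holds keys ``A`` and ``B``, each either
    ``{"type": "dunnett"|"tukey"|"grandmean", "reference": idx}`` or
    ``{"matrix": [[...]]}``, plus optional ``category_labels`` /
    ``group_labels`` and ``validate: false`` to admit non-centered rows.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith((".yaml", ".yml")):
            import yaml

            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    if not isinstance(config, dict) or "A" not in config or "B" not in config:
        raise ContrastError("contrast config must contain keys 'A' and 'B'")
    A = _matrix_from_spec(config["A"], n_categories, "A")
    B = _matrix_from_spec(config["B"], n_groups, "B")
    return ContrastPair(
        A,
        B,
        category_labels=config.get("category_labels", category_labels),
        group_labels=config.get("group_labels", group_labels),
        validate=config.get("validate", True),
    )
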
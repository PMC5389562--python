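"""Chromatic registration and two-channel spot colocalization.

The red (RNA) and green/yellow (protein) emission paths of a two-color
TIRF microscope are displaced relative to each other by chromatic
aberration. The correction used here is a planar affine transform
(6 parameters: 2x2 linear part + offset) estimated by least squares
from corresponding point pairs; protein spots are then mapped into the
RNA frame and paired with RNA spots by mutual nearest neighbors within
a match radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Affine2D", "MatchResult", "fit_transform", "colocalize"]


@dataclass(frozen=True)
class Affine2D:
    """Planar affine map x -> A @ x + b, in pixel units."""

    linear: tuple[tuple[float, float], tuple[float, float]]
    offset: tuple[float, float]
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.linear, dtype=float)
        if abs(np.linalg.det(a)) <= 1e-6:
            raise ValueError("linear part is (near-)singular")

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(((1.0, 0.0), (0.0, 1.0)), (0.0, 0.0))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ np.asarray(self.linear).T + np.asarray(self.offset)

    def inverse(self) -> "Affine2D":
        a = np.linalg.inv(np.asarray(self.linear))
        b = -a @ np.asarray(self.offset)
        return Affine2D(tuple(map(tuple, a)), tuple(b), self.rms_residual)

    def to_json(self) -> str:
        return json.dumps(
            {"linear": self.linear, "offset": self.offset,
             "rms_residual": self.rms_residual}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "Affine2D":
        d = json.loads(text)
        return cls(tuple(map(tuple, d["linear"])), tuple(d["offset"]),
                   d.get("rms_residual", 0.0))


@dataclass
class MatchResult:
    """Outcome of matching protein spots to RNA spots."""

    pairs: list[tuple[int, int, float]]  # (rna idx, protein idx, residual px)
    n_rna: int
    n_protein: int

    @property
    def colocalized_fraction(self) -> float:
        if self.n_rna == 0:
            return 0.0
        return len(self.pairs) / self.n_rna

    @property
    def unmatched_rna(self) -> list[int]:
        matched = {i for i, _, _ in self.pairs}
        return [i for i in range(self.n_rna) if i not in matched]


def fit_transform(
    reference: np.ndarray, moving: np.ndarray
) -> Affine2D:
    """Least-squares planar affine mapping ``moving`` -> ``reference``.

    Requires at least three non-collinear point pairs; reports the RMS
    residual of the fit.
    """
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    mov = np.atleast_2d(np.asarray(moving, dtype=float))
    if ref.shape != mov.shape or ref.shape[1] != 2:
        raise ValueError("need matching (n, 2) point arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    design = np.column_stack([mov, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("point pairs are collinear; affine fit is degenerate")
    coef, *_ = np.linalg.lstsq(design, ref, rcond=None)  # (3, 2)
    a = coef[:2].T
    b = coef[2]
    pred = design @ coef
    rms = float(np.sqrt(np.mean(np.sum((pred - ref) ** 2, axis=1))))
    return Affine2D(tuple(map(tuple, a)), tuple(b), rms)


def colocalize(
    rna_spots: np.ndarray,
    protein_spots: np.ndarray,
    transform: Affine2D | None = None,
    radius: float = 2.0,
) -> MatchResult:
    """Pair protein spots with RNA spots by mutual nearest neighbors.

    Protein coordinates are first pushed through ``transform`` into the
    RNA frame. A pair is kept iff each spot is the other's nearest
    neighbor and their distance is within ``radius``; conflicts are
    resolved greedily by ascending distance, so the pairing is
    deterministic and order-independent.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rna = np.atleast_2d(np.asarray(rna_spots, dtype=float)).reshape(-1, 2)
    prot = np.atleast_2d(np.asarray(protein_spots, dtype=float)).reshape(-1, 2)
    if rna.size == 0 or prot.size == 0:
        return MatchResult([], rna.shape[0], prot.shape[0])
    if transform is not None:
        prot = transform.apply(prot)

    tree_r = cKDTree(rna)
    tree_p = cKDTree(prot)
    d_rp, nn_of_rna = tree_p.query(rna, k=1)
    d_pr, nn_of_prot = tree_r.query(prot, k=1)

    candidates = []
    for i in range(rna.shape[0]):
        j = int(nn_of_rna[i])
        if int(nn_of_prot[j]) == i and d_rp[i] <= radius:
            candidates.append((float(d_rp[i]), i, j))
    candidates.sort()
    used_r: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for d, i, j in candidates:
        if i in used_r or j in used_p:
            continue
        used_r.add(i)
        used_p.add(j)
        pairs.append((i, j, d))
    pairs.sort()
    return MatchResult(pairs, rna.shape[0], prot.shape[0])
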
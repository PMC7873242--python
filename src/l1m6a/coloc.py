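"""RNA-FISH/IF colocalization: count protein-mRNA point pairs within a
distance threshold (default 330 nm, i.e. three 110-nm pixels).

Point lists come from upstream spot detection; this module only pairs
them.  Default matching is exclusive (one_to_one): candidate cross-pairs
within the threshold are taken greedily by ascending distance, each point
used at most once — puncta are distinct particles, so a punctum should not
be counted into two pairs.  ``any_within`` reports every pair within the
threshold for sensitivity analysis.  Distances are Euclidean, 3D when both
sets carry z (z-stacks), with a planar mode to ignore z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class PointSet:
    """Detected puncta of one channel in one cell, coordinates in nm."""

    cell: str
    xyz: np.ndarray                 # (n, 2) or (n, 3) float array, nm
    intensity: np.ndarray           # (n,)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] not in (2, 3):
            raise ValueError("xyz must be (n, 2) or (n, 3)")
        if not np.isfinite(self.xyz).all():
            raise ValueError("coordinates must be finite")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be >= 0")

    @classmethod
    def from_table(cls, df, cell: str, unit: str = "nm",
                   pixel_size_nm: float | None = None) -> "PointSet":
        """Build from a dataframe with x, y[, z], intensity columns.

        ``unit`` is ``nm`` or ``px``; pixel inputs require pixel_size_nm.
        """
        if unit == "px":
            if pixel_size_nm is None:
                raise ValueError("pixel coordinates require pixel_size_nm")
            scale = pixel_size_nm
        elif unit == "nm":
            scale = 1.0
        else:
            raise ValueError(f"unknown unit {unit!r}")
        cols = ["x", "y"] + (["z"] if "z" in df.columns else [])
        xyz = df[cols].to_numpy(dtype=float) * scale
        inten = df["intensity"].to_numpy(dtype=float) if "intensity" in df.columns \
            else np.zeros(len(df))
        return cls(cell, xyz, inten)

    def __len__(self):
        return len(self.xyz)


@dataclass
class ColocResult:
    cell: str
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    paired_intensities_a: list[float] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def match_colocalized(a: PointSet, b: PointSet, threshold: float = 330.0,
                      mode: str = "one_to_one", planar: bool = False) -> ColocResult:
    """Pair points of ``a`` and ``b`` within ``threshold`` nm.

    one_to_one: greedy nearest-first exclusive matching; any_within: all
    cross pairs within the threshold.  ``planar`` drops z from the distance
    (the threshold is quoted in lateral pixels).
    """
    if a.cell != b.cell:
        raise ValueError("point sets come from different cells")
    xa, xb = a.xyz, b.xyz
    if planar:
        xa, xb = xa[:, :2], xb[:, :2]
    elif xa.shape[1] != xb.shape[1]:
        raise ValueError("point sets mix 2D and 3D coordinates")

    result = ColocResult(a.cell)
    if len(a) == 0 or len(b) == 0:
        return result
    cand: list[tuple[float, int, int]] = []
    tree = cKDTree(xb)
    for i, neigh in enumerate(tree.query_ball_point(xa, r=threshold)):
        for j in sorted(neigh):
            d = float(np.linalg.norm(xa[i] - xb[j]))
            cand.append((d, i, j))
    cand.sort()

    if mode == "any_within":
        for d, i, j in cand:
            result.pairs.append((i, j, d))
    elif mode == "one_to_one":
        used_a: set[int] = set()
        used_b: set[int] = set()
        for d, i, j in cand:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            result.pairs.append((i, j, d))
        result.pairs.sort(key=lambda p: p[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    result.paired_intensities_a = [float(a.intensity[i]) for i, _, _ in result.pairs]
    return result
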
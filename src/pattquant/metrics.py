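"""Distances on 14-dimensional pattern space.

Two squared distances compare patterns x, y (14-vectors of replicate-
averaged indices):

* Mahalanobis:  d_N^2(x, y) = (x - y)^T S^{-1} (x - y), with S the sample
  covariance of all qualifying patterns pooled over body parts.  Invariant
  under any fixed invertible affine map of pattern space.
* Developmental Noise:  d_D^2(x, y) = sum_i w_i (x_i - y_i)^2 with
  w_i = 1 / mean_n(S_i^n), where S_i^n is the variance of index i between
  the two front-leg patterns of gecko n (only geckos with qualifying
  patterns on all four legs contribute).  Since each w_i carries the
  inverse squared unit of index i, the metric is unit (per-index scale)
  invariant; indices dominated by developmental noise are down-weighted.

Distances are reported as squares throughout, rescaled so that the mean
squared distance between leg patterns of two *different* individuals
equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .imaging import BodyPart
from .indices import INDEX_NAMES

__all__ = [
    "LEG_PARTS",
    "DistanceSpec",
    "IndexDataset",
    "fit_mahalanobis",
    "fit_devnoise",
    "squared_distance",
    "cross_squared_distances",
    "calibrate_scale",
    "within_between_summary",
]

LEG_PARTS = ("FL", "FR", "BL", "BR")


@dataclass
class DistanceSpec:
    """A fitted metric on pattern space."""

    kind: str  # "mahalanobis" or "devnoise"
    S_inv: Optional[np.ndarray] = None  # 14x14 SPD, mahalanobis only
    weights: Optional[np.ndarray] = None  # 14 positive reals, devnoise only
    scale_c: float = 1.0
    n_fit: int = 0
    geckos_for_weights: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "scale_c": self.scale_c, "n_fit": self.n_fit}
        if self.S_inv is not None:
            d["S_inv"] = self.S_inv.tolist()
        if self.weights is not None:
            d["weights"] = self.weights.tolist()
        if self.geckos_for_weights:
            d["geckos_for_weights"] = list(self.geckos_for_weights)
        return d


class IndexDataset:
    """Replicate-averaged index vectors, one row per (gecko, body part).

    Wraps a DataFrame with columns ``gecko_id``, ``body_part``,
    ``qualifying`` and the 14 index columns.  Only qualifying rows with no
    missing index values enter metric fitting and distance evaluation.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("gecko_id", "body_part", "qualifying", *INDEX_NAMES)
                   if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        df = df.copy()
        df["body_part"] = df["body_part"].map(lambda p: BodyPart(p).value)
        if df.duplicated(["gecko_id", "body_part"]).any():
            raise ValueError("at most one row per (gecko_id, body_part)")
        self.df = df

    def usable(self) -> pd.DataFrame:
        """Qualifying rows with a complete 14-vector."""
        q = self.df[self.df["qualifying"].astype(bool)]
        return q[~q[INDEX_NAMES].isna().any(axis=1)]

    def matrix(self) -> np.ndarray:
        return self.usable()[INDEX_NAMES].to_numpy(dtype=float)

    def vector(self, gecko_id: str, body_part: str) -> Optional[np.ndarray]:
        """The index vector for one (gecko, part), or None if unusable."""
        u = self.usable()
        row = u[(u["gecko_id"] == gecko_id) & (u["body_part"] == str(body_part))]
        if len(row) != 1:
            return None
        return row[INDEX_NAMES].to_numpy(dtype=float)[0]

    def part_vectors(self, body_part: str) -> Dict[str, np.ndarray]:
        """gecko_id -> usable index vector for one body part."""
        u = self.usable()
        sub = u[u["body_part"] == str(body_part)]
        return {
            g: v for g, v in zip(sub["gecko_id"], sub[INDEX_NAMES].to_numpy(float))
        }

    def geckos(self) -> List[str]:
        return sorted(self.df["gecko_id"].unique())


def fit_mahalanobis(data: IndexDataset) -> DistanceSpec:
    """Inverse sample covariance of all usable patterns pooled."""
    x = data.matrix()
    if len(x) < 2:
        raise ValueError("need at least 2 usable rows to fit a covariance")
    s = np.cov(x, rowvar=False)
    # regularize only when numerically singular
    if np.linalg.cond(s) > 1e12:
        s = s + (1e-8 * np.trace(s) / s.shape[0]) * np.eye(s.shape[0])
    s_inv = np.linalg.inv(s)
    s_inv = (s_inv + s_inv.T) / 2
    return DistanceSpec(kind="mahalanobis", S_inv=s_inv, n_fit=len(x))


def fit_devnoise(data: IndexDataset) -> DistanceSpec:
    """Weights from left-right front-leg variances.

    Only geckos with qualifying patterns on all four legs contribute.  For
    gecko n and index i the two front-leg values give the two-point sample
    variance S_i^n = (FL_i - FR_i)^2 / 2; w_i = 1 / mean_n(S_i^n).
    """
    by_part = {p: data.part_vectors(p) for p in LEG_PARTS}
    four_legged = sorted(
        set.intersection(*(set(by_part[p]) for p in LEG_PARTS))
    )
    if not four_legged:
        raise ValueError("no gecko has qualifying patterns on all four legs")
    diffs = np.array(
        [by_part["FL"][g] - by_part["FR"][g] for g in four_legged], dtype=float
    )
    mean_var = (diffs**2 / 2.0).mean(axis=0)
    zero = np.flatnonzero(mean_var == 0)
    if zero.size:
        names = [INDEX_NAMES[i] for i in zero]
        raise ValueError(
            f"index {names} identical across both front legs of every gecko; "
            "developmental-noise weight would be infinite"
        )
    return DistanceSpec(
        kind="devnoise",
        weights=1.0 / mean_var,
        n_fit=len(four_legged),
        geckos_for_weights=tuple(four_legged),
    )


def squared_distance(x: np.ndarray, y: np.ndarray, spec: DistanceSpec) -> float:
    """Scaled squared distance between two complete 14-vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("distance is undefined for vectors with missing entries")
    d = x - y
    if spec.kind == "mahalanobis":
        val = float(d @ spec.S_inv @ d)
    elif spec.kind == "devnoise":
        val = float(np.sum(spec.weights * d**2))
    else:
        raise ValueError(f"unknown metric kind {spec.kind!r}")
    return val * spec.scale_c


def cross_squared_distances(
    a: np.ndarray, b: np.ndarray, spec: DistanceSpec
) -> np.ndarray:
    """Matrix D with D[i, j] = scaled squared distance(a[i], b[j])."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if spec.kind == "mahalanobis":
        m = spec.S_inv
        aa = np.einsum("ij,jk,ik->i", a, m, a)
        bb = np.einsum("ij,jk,ik->i", b, m, b)
        ab = a @ m @ b.T
        d = aa[:, None] + bb[None, :] - 2 * ab
    elif spec.kind == "devnoise":
        diff = a[:, None, :] - b[None, :, :]
        d = np.sum(spec.weights * diff**2, axis=2)
    else:
        raise ValueError(f"unknown metric kind {spec.kind!r}")
    return np.maximum(d, 0.0) * spec.scale_c


def calibrate_scale(data: IndexDataset, spec: DistanceSpec) -> DistanceSpec:
    """Set scale_c so the mean between-individual leg squared distance is 1.

    The pool is every unordered pair of usable leg patterns (any of FL, FR,
    BL, BR) belonging to two different geckos.
    """
    u = data.usable()
    legs = u[u["body_part"].isin(LEG_PARTS)]
    if legs["gecko_id"].nunique() < 2:
        raise ValueError("calibration needs legs from at least two geckos")
    vecs = legs[INDEX_NAMES].to_numpy(float)
    geckos = legs["gecko_id"].to_numpy()
    base = DistanceSpec(
        kind=spec.kind, S_inv=spec.S_inv, weights=spec.weights, scale_c=1.0
    )
    d = cross_squared_distances(vecs, vecs, base)
    other = geckos[:, None] != geckos[None, :]
    iu = np.triu_indices(len(vecs), k=1)
    sel = other[iu]
    mean_between = float(d[iu][sel].mean())
    return DistanceSpec(
        kind=spec.kind,
        S_inv=spec.S_inv,
        weights=spec.weights,
        scale_c=1.0 / mean_between,
        n_fit=spec.n_fit,
        geckos_for_weights=spec.geckos_for_weights,
    )


def within_between_summary(
    data: IndexDataset, spec: DistanceSpec, pair: Tuple[str, str]
):
    """Within- vs between-individual squared distances for a part pair.

    Restricted to geckos with usable patterns on both parts A and B:
    within  = mean over geckos g of d^2(A_g, B_g);
    between = mean over unordered gecko pairs g != h of
              (d^2(A_g, B_h) + d^2(A_h, B_g)) / 2;
    ratio   = within / between (NaN when between is 0).

    Returns (mean_within, mean_between, ratio, n_within, n_between).
    """
    part_a, part_b = (BodyPart(p).value for p in pair)
    va = data.part_vectors(part_a)
    vb = data.part_vectors(part_b)
    common = sorted(set(va) & set(vb))
    if len(common) < 2:
        raise ValueError("need at least 2 geckos with both parts usable")
    a = np.array([va[g] for g in common])
    b = np.array([vb[g] for g in common])
    d = cross_squared_distances(a, b, spec)
    within = float(np.diagonal(d).mean())
    n = len(common)
    iu = np.triu_indices(n, k=1)
    between = float(((d[iu] + d.T[iu]) / 2).mean())
    ratio = within / between if between > 0 else float("nan")
    return within, between, ratio, n, n * (n - 1) // 2
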
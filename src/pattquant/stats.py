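"""Statistical analyses of pattern-index datasets.

Covers the downstream analyses of the pattern pipeline: one-sided
permutation tests on within- vs between-individual distance ratios,
pairwise Pearson correlations of indices (with permutation p-values),
within-individual correlations between body parts, PCA on the
standardized indices, coefficients of variation, replicate measurement
error, the sides x individuals mixed ANOVA used to separate fluctuating
asymmetry from measurement error, and the patterning-hierarchy check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging import BodyPart
from .indices import INDEX_NAMES
from .metrics import (
    DistanceSpec,
    IndexDataset,
    cross_squared_distances,
    squared_distance,
)

__all__ = [
    "PermutationResult",
    "AnovaTable",
    "STAR_THRESHOLDS",
    "stars",
    "permutation_test",
    "index_correlations",
    "bodypart_correlations",
    "pca_indices",
    "coefficient_of_variation",
    "replicate_error",
    "sides_anova",
    "hierarchy_check",
]

#: Significance star thresholds used in reports.
STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.00001)


def stars(p: float) -> str:
    """Significance stars for a p-value (****: p < 1e-5 ... *: p < 0.05)."""
    if np.isnan(p):
        return ""
    return "*" * sum(p < t for t in STAR_THRESHOLDS)


@dataclass
class PermutationResult:
    observed_ratio: float
    mean_within: float
    mean_between: float
    n_perm: int
    p_value: float
    seed: int
    null_mean: float
    null_q05: float
    null_q95: float
    n_geckos: int


@dataclass
class AnovaTable:
    """Two-way sides (fixed) x individuals (random) ANOVA with replicates."""

    ss: Dict[str, float]
    df: Dict[str, int]
    ms: Dict[str, float]
    F_sides: float
    F_individuals: float
    F_interaction: float
    p_sides: float
    p_individuals: float
    p_interaction: float


def permutation_test(
    data: IndexDataset,
    spec: DistanceSpec,
    pair: Tuple[str, str],
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """One-sided test that within-individual distances are smaller.

    The statistic is the ratio of mean within-individual to mean
    between-individual squared distance for the body-part pair.  The null
    is generated by uniformly permuting the gecko labels of the B-part
    vectors relative to the A-part vectors; the one-sided p-value (small
    ratios extreme) uses the +1 correction:
    p = (1 + #{null <= observed}) / (1 + n_perm).
    """
    part_a, part_b = (BodyPart(p).value for p in pair)
    va = data.part_vectors(part_a)
    vb = data.part_vectors(part_b)
    common = sorted(set(va) & set(vb))
    n = len(common)
    if n < 5:
        raise ValueError("permutation test needs >= 5 geckos with both parts")
    a = np.array([va[g] for g in common])
    b = np.array([vb[g] for g in common])
    d = cross_squared_distances(a, b, spec)
    total = d.sum()

    def ratio_for(perm: np.ndarray) -> float:
        w_sum = d[np.arange(n), perm].sum()
        between = (total - w_sum) / (n * (n - 1))
        within = w_sum / n
        return within / between if between > 0 else np.nan

    observed = ratio_for(np.arange(n))
    rng = np.random.default_rng(seed)
    null = np.array([ratio_for(rng.permutation(n)) for _ in range(n_perm)])
    p = (1 + np.sum(null <= observed)) / (1 + n_perm)
    w_sum = np.diagonal(d).sum()
    return PermutationResult(
        observed_ratio=float(observed),
        mean_within=float(w_sum / n),
        mean_between=float((total - w_sum) / (n * (n - 1))),
        n_perm=n_perm,
        p_value=float(p),
        seed=seed,
        null_mean=float(np.nanmean(null)),
        null_q05=float(np.nanquantile(null, 0.05)),
        null_q95=float(np.nanquantile(null, 0.95)),
        n_geckos=n,
    )


def _pearson_perm_p(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> Tuple[float, float]:
    """Pearson r and a two-sided permutation p-value (one variable shuffled)."""
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = len(x)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    null = (yc[perms] @ xc) / n
    p = (1 + np.sum(np.abs(null) >= abs(r) - 1e-12)) / (1 + n_perm)
    return r, float(p)


def index_correlations(
    data: IndexDataset,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> pd.DataFrame:
    """Pairwise Pearson correlations of the 14 indices over all usable rows.

    Returns a long DataFrame (index_a, index_b, r, p, stars).  p-values are
    two-sided, by permutation (default) or the parametric t approximation
    (``method="t"``).
    """
    x = data.matrix()
    if len(x) < 4:
        raise ValueError("need >= 4 usable rows for correlations")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(INDEX_NAMES)):
        for j in range(i + 1, len(INDEX_NAMES)):
            xi, yj = x[:, i], x[:, j]
            if method == "permutation":
                r, p = _pearson_perm_p(xi, yj, n_perm, rng)
            else:
                if np.std(xi) == 0 or np.std(yj) == 0:
                    r, p = float("nan"), float("nan")
                else:
                    r, p = sps.pearsonr(xi, yj)
            rows.append(
                {"index_a": INDEX_NAMES[i], "index_b": INDEX_NAMES[j],
                 "r": r, "p": p, "stars": stars(p)}
            )
    return pd.DataFrame(rows)


def bodypart_correlations(
    data: IndexDataset,
    n_perm: int = 1000,
    seed: int = 0,
    min_geckos: int = 4,
) -> pd.DataFrame:
    """Within-individual correlations between body parts, per index.

    For each unordered pair of the seven body parts and each index, the
    Pearson correlation over geckos carrying qualifying patterns on both
    parts.  Cells with fewer than ``min_geckos`` geckos are missing.
    Returns a long DataFrame (pair, index, r, p, n, stars).
    """
    rng = np.random.default_rng(seed)
    q = data.df[data.df["qualifying"].astype(bool)]
    parts = [p.value for p in BodyPart]
    rows = []
    for i in range(len(parts)):
        for j in range(i + 1, len(parts)):
            pa, pb = parts[i], parts[j]
            sub_a = q[q["body_part"] == pa].set_index("gecko_id")
            sub_b = q[q["body_part"] == pb].set_index("gecko_id")
            common = sub_a.index.intersection(sub_b.index)
            for name in INDEX_NAMES:
                va = sub_a.loc[common, name].to_numpy(float)
                vb = sub_b.loc[common, name].to_numpy(float)
                ok = ~np.isnan(va) & ~np.isnan(vb)
                if ok.sum() < min_geckos:
                    r, p, n = float("nan"), float("nan"), int(ok.sum())
                else:
                    r, p = _pearson_perm_p(va[ok], vb[ok], n_perm, rng)
                    n = int(ok.sum())
                rows.append(
                    {"pair": f"{pa}-{pb}", "index": name, "r": r, "p": p,
                     "n": n, "stars": stars(p)}
                )
    return pd.DataFrame(rows)


def pca_indices(data: IndexDataset) -> Tuple[np.ndarray, np.ndarray]:
    """PCA on the standardized indices (correlation-matrix eigenanalysis).

    Returns (loadings, explained_fraction): loadings[:, k] is the k-th
    component (unit vector over the 14 indices, its largest-magnitude
    entry made positive); fractions are non-increasing and sum to 1.
    """
    x = data.matrix()
    if len(x) < 3:
        raise ValueError("need >= 3 usable rows for a PCA")
    sd = x.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = [INDEX_NAMES[i] for i in const]
        raise ValueError(f"constant index column(s) {names}: PCA undefined")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    loadings = evecs[:, order]
    for k in range(loadings.shape[1]):
        imax = np.argmax(np.abs(loadings[:, k]))
        if loadings[imax, k] < 0:
            loadings[:, k] = -loadings[:, k]
    return loadings, evals / evals.sum()


def coefficient_of_variation(data: IndexDataset) -> pd.DataFrame:
    """Sample sd / mean per index, per body part and pooled ("ALL").

    Means of zero yield missing values.
    """
    u = data.usable()
    rows = {}
    groups = [(p.value, u[u["body_part"] == p.value]) for p in BodyPart]
    groups.append(("ALL", u))
    for label, sub in groups:
        vals = {}
        for name in INDEX_NAMES:
            v = sub[name].to_numpy(float)
            v = v[~np.isnan(v)]
            if len(v) < 2 or v.mean() == 0:
                vals[name] = float("nan")
            else:
                vals[name] = float(np.std(v, ddof=1) / v.mean())
        rows[label] = vals
    return pd.DataFrame(rows).T[INDEX_NAMES]


def replicate_error(
    per_replicate: pd.DataFrame, spec: DistanceSpec
) -> pd.DataFrame:
    """Measurement error from repeated photographs of the same region.

    ``per_replicate`` holds one row per (gecko_id, body_part, replicate)
    with the 14 index columns.  For each region the error is the mean
    squared distance of the replicate vectors from their centroid; this is
    aggregated per body part and set against (i) the part's mean
    between-individual squared distance of replicate-averaged vectors and
    (ii), for legs, the corresponding within-individual left-right
    distance.  Regions with a single complete replicate are skipped.
    """
    df = per_replicate.copy()
    df["body_part"] = df["body_part"].map(lambda p: BodyPart(p).value)
    complete = df[~df[INDEX_NAMES].isna().any(axis=1)]
    per_region_err: Dict[Tuple[str, str], float] = {}
    averaged: Dict[Tuple[str, str], np.ndarray] = {}
    for (g, p), sub in complete.groupby(["gecko_id", "body_part"]):
        vecs = sub[INDEX_NAMES].to_numpy(float)
        if len(vecs) < 2:
            continue
        centroid = vecs.mean(axis=0)
        err = np.mean(
            [squared_distance(v, centroid, spec) for v in vecs]
        )
        per_region_err[(g, p)] = float(err)
        averaged[(g, p)] = centroid

    rows = []
    for part in [p.value for p in BodyPart]:
        errs = [e for (g, p), e in per_region_err.items() if p == part]
        if not errs:
            continue
        vecs = {g: v for (g, p), v in averaged.items() if p == part}
        geckos = sorted(vecs)
        between = float("nan")
        if len(geckos) >= 2:
            m = np.array([vecs[g] for g in geckos])
            d = cross_squared_distances(m, m, spec)
            iu = np.triu_indices(len(geckos), k=1)
            between = float(d[iu].mean())
        within_lr = float("nan")
        lr = {"FL": "FR", "FR": "FL", "BL": "BR", "BR": "BL"}.get(part)
        if lr is not None:
            other = {g: v for (g, p), v in averaged.items() if p == lr}
            both = sorted(set(vecs) & set(other))
            if both:
                within_lr = float(
                    np.mean(
                        [squared_distance(vecs[g], other[g], spec) for g in both]
                    )
                )
        err = float(np.mean(errs))
        rows.append(
            {
                "body_part": part,
                "n_regions": len(errs),
                "error": err,
                "between": between,
                "ratio_between_to_error": between / err if err > 0 else float("nan"),
                "within_lr": within_lr,
                "ratio_within_to_error": within_lr / err if err > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def sides_anova(values: np.ndarray) -> AnovaTable:
    """Mixed two-way ANOVA on a (geckos, 2 sides, replicates) array.

    Sides are fixed, individuals random.  F_sides = MS_S / MS_SI tests
    directional asymmetry; F_interaction = MS_SI / MS_E tests
    nondirectional (fluctuating) asymmetry against measurement error;
    F_individuals = MS_I / MS_SI.  The design must be balanced.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3 or y.shape[1] != 2:
        raise ValueError("values must have shape (n_geckos, 2, n_replicates)")
    if np.isnan(y).any():
        raise ValueError("unbalanced design (missing cells) is not supported")
    n, _, r = y.shape
    if n < 2 or r < 2:
        raise ValueError("need >= 2 geckos and >= 2 replicates")
    grand = y.mean()
    mean_i = y.mean(axis=(1, 2))
    mean_s = y.mean(axis=(0, 2))
    mean_is = y.mean(axis=2)
    ss_i = 2 * r * np.sum((mean_i - grand) ** 2)
    ss_s = n * r * np.sum((mean_s - grand) ** 2)
    ss_is = r * np.sum((mean_is - mean_i[:, None] - mean_s[None, :] + grand) ** 2)
    ss_e = np.sum((y - mean_is[:, :, None]) ** 2)
    df = {"individuals": n - 1, "sides": 1, "interaction": n - 1,
          "error": 2 * n * (r - 1)}
    ss = {"individuals": float(ss_i), "sides": float(ss_s),
          "interaction": float(ss_is), "error": float(ss_e)}
    ms = {k: ss[k] / df[k] for k in ss}

    def _f(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    f_s = _f(ms["sides"], ms["interaction"])
    f_i = _f(ms["individuals"], ms["interaction"])
    f_si = _f(ms["interaction"], ms["error"])
    p_s = float(sps.f.sf(f_s, df["sides"], df["interaction"])) if np.isfinite(f_s) else float("nan")
    p_i = float(sps.f.sf(f_i, df["individuals"], df["interaction"])) if np.isfinite(f_i) else float("nan")
    p_si = float(sps.f.sf(f_si, df["interaction"], df["error"])) if np.isfinite(f_si) else float("nan")
    return AnovaTable(
        ss=ss, df=df, ms=ms,
        F_sides=float(f_s), F_individuals=float(f_i), F_interaction=float(f_si),
        p_sides=p_s, p_individuals=p_i, p_interaction=p_si,
    )


def hierarchy_check(presence: pd.DataFrame) -> dict:
    """Check the patterning hierarchy {head, tail} <- trunk <- legs.

    ``presence`` is indexed by gecko with boolean columns for the seven
    body parts.  Tests per gecko the implications (any leg patterned =>
    trunk patterned) and (trunk patterned => head and tail patterned) and
    reports violation counts and violators.
    """
    legs = presence[["FL", "FR", "BL", "BR"]].any(axis=1)
    trunk = presence["TR"].astype(bool)
    head_tail = presence["HD"].astype(bool) & presence["TA"].astype(bool)
    viol_leg = presence.index[legs & ~trunk].tolist()
    viol_trunk = presence.index[trunk & ~head_tail].tolist()
    return {
        "legs_imply_trunk": {
            "violations": len(viol_leg),
            "violating_geckos": [str(g) for g in viol_leg],
        },
        "trunk_implies_head_and_tail": {
            "violations": len(viol_trunk),
            "violating_geckos": [str(g) for g in viol_trunk],
        },
        "consistent": not viol_leg and not viol_trunk,
    }
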
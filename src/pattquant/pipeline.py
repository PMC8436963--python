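"""High-level pipeline: images -> indices -> distances -> statistics.

These functions tie the stage modules together and are what both the
command-line interface and the example scripts call.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats as pstats
from .config import RunConfig
from .imaging import BodyPart, RegionImage, binarize
from .indices import INDEX_NAMES, average_replicates, compute_indices
from .metrics import (
    LEG_PARTS,
    DistanceSpec,
    IndexDataset,
    calibrate_scale,
    cross_squared_distances,
    fit_devnoise,
    fit_mahalanobis,
)
from .spots import extract_spots

__all__ = [
    "measure_regions",
    "averaged_dataset",
    "fit_metrics",
    "pairwise_distances",
    "distance_summary",
    "stats_report",
]

log = logging.getLogger("pattquant")


def measure_regions(
    images: Iterable[RegionImage], config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Binarize and measure every region image; append replicate averages.

    Returns the indices table: one row per replicate plus one
    ``averaged=True`` row per (gecko, body part).  Non-qualifying patterns
    are retained with ``qualifying=False``.
    """
    config = config or RunConfig()
    by_region: Dict[Tuple[str, str], list] = {}
    for image in images:
        pattern = binarize(image)
        spotset = extract_spots(
            pattern,
            image,
            min_spot_px=config.min_spot_px,
            smooth_iterations=config.smooth_iterations,
        )
        idx = compute_indices(
            spotset, pattern, image, ee_convention=config.ee_convention
        )
        log.info(
            "%s %s r%d: T=%.1f (mu=%.1f sigma=%.1f, excl %d shadow / %d glare), "
            "%d spots (%d interior), qualifying=%s",
            image.gecko_id, image.body_part.value, image.replicate,
            pattern.report.T, pattern.report.mu, pattern.report.sigma,
            pattern.report.n_excluded_shadow, pattern.report.n_excluded_glare,
            spotset.n_all, spotset.n_interior, spotset.qualifying,
        )
        by_region.setdefault((image.gecko_id, image.body_part.value), []).append(idx)

    from .io import indices_to_frame

    records = []
    for key in sorted(by_region):
        reps = sorted(by_region[key], key=lambda r: r.replicate)
        records.extend(reps)
        records.append(average_replicates(reps))
    return indices_to_frame(records)


def averaged_dataset(indices_df: pd.DataFrame) -> IndexDataset:
    """The replicate-averaged rows of an indices table as an IndexDataset."""
    avg = indices_df[indices_df["averaged"].astype(bool)]
    return IndexDataset(avg[["gecko_id", "body_part", "qualifying", *INDEX_NAMES]])


def fit_metrics(data: IndexDataset) -> Dict[str, DistanceSpec]:
    """Fit and calibrate both metrics; devnoise is dropped with a warning
    when no gecko has qualifying patterns on all four legs."""
    specs = {}
    maha = calibrate_scale(data, fit_mahalanobis(data))
    specs["mahalanobis"] = maha
    try:
        specs["devnoise"] = calibrate_scale(data, fit_devnoise(data))
    except ValueError as e:
        log.warning("developmental-noise metric unavailable: %s", e)
    return specs


def pairwise_distances(
    data: IndexDataset, specs: Dict[str, DistanceSpec]
) -> pd.DataFrame:
    """All pairwise scaled squared distances between usable patterns."""
    u = data.usable()
    vecs = u[INDEX_NAMES].to_numpy(float)
    ids = list(zip(u["gecko_id"], u["body_part"]))
    rows = []
    for name, spec in specs.items():
        d = cross_squared_distances(vecs, vecs, spec)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append(
                    {
                        "gecko_a": ids[i][0], "part_a": ids[i][1],
                        "gecko_b": ids[j][0], "part_b": ids[j][1],
                        "metric": name,
                        "squared_distance_scaled": d[i, j],
                    }
                )
    return pd.DataFrame(rows)


def distance_summary(
    data: IndexDataset,
    specs: Dict[str, DistanceSpec],
    n_perm: int = 10000,
    seed: int = 0,
    min_geckos: int = 5,
) -> pd.DataFrame:
    """Within/between summary with permutation p-values per part pair."""
    parts = [p.value for p in BodyPart]
    rows = []
    for name, spec in specs.items():
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                pair = (parts[i], parts[j])
                try:
                    res = pstats.permutation_test(
                        data, spec, pair, n_perm=n_perm, seed=seed
                    )
                except ValueError as e:
                    log.info("skipping %s %s: %s", name, pair, e)
                    continue
                rows.append(
                    {
                        "metric": name,
                        "pair": f"{pair[0]}-{pair[1]}",
                        "mean_within": res.mean_within,
                        "mean_between": res.mean_between,
                        "ratio": res.observed_ratio,
                        "p_value": res.p_value,
                        "stars": pstats.stars(res.p_value),
                        "n_geckos": res.n_geckos,
                        "n_perm": res.n_perm,
                        "seed": res.seed,
                    }
                )
    return pd.DataFrame(rows)


def stats_report(
    indices_df: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """The full downstream statistical report as a JSON-serializable dict.

    Runs index and body-part correlations, PCA, coefficients of variation,
    replicate measurement error, the sides x individuals ANOVA for both
    leg pairs, and the patterning-hierarchy check.  Analyses whose
    preconditions fail are recorded as skipped with the reason.
    """
    data = averaged_dataset(indices_df)
    report: dict = {"seed": seed, "n_perm": n_perm, "skipped": {}}

    def _try(name, fn):
        try:
            report[name] = fn()
        except ValueError as e:
            report["skipped"][name] = str(e)
            log.warning("%s skipped: %s", name, e)

    _try(
        "index_correlations",
        lambda: pstats.index_correlations(data, n_perm=n_perm, seed=seed).to_dict(
            orient="records"
        ),
    )
    _try(
        "bodypart_correlations",
        lambda: pstats.bodypart_correlations(data, n_perm=n_perm, seed=seed).to_dict(
            orient="records"
        ),
    )

    def _pca():
        loadings, frac = pstats.pca_indices(data)
        return {
            "index_order": INDEX_NAMES,
            "loadings": loadings.tolist(),
            "explained_fraction": frac.tolist(),
        }

    _try("pca", _pca)
    _try(
        "coefficient_of_variation",
        lambda: pstats.coefficient_of_variation(data).to_dict(orient="index"),
    )

    def _replicate_error():
        reps = indices_df[~indices_df["averaged"].astype(bool)]
        reps = reps[reps["qualifying"].astype(bool)]
        spec = calibrate_scale(data, fit_mahalanobis(data))
        return pstats.replicate_error(reps, spec).to_dict(orient="records")

    _try("replicate_error", _replicate_error)

    def _anova(front: bool):
        left, right = ("FL", "FR") if front else ("BL", "BR")
        reps = indices_df[~indices_df["averaged"].astype(bool)]
        piv = {}
        out = {}
        for side in (left, right):
            sub = reps[reps["body_part"] == side]
            piv[side] = sub.pivot_table(
                index="gecko_id", columns="replicate", values=INDEX_NAMES
            )
        common = piv[left].index.intersection(piv[right].index)
        if len(common) < 2:
            raise ValueError(f"need >= 2 geckos with both {left} and {right}")
        for name in INDEX_NAMES:
            a = piv[left].loc[common, name].to_numpy(float)
            b = piv[right].loc[common, name].to_numpy(float)
            y = np.stack([a, b], axis=1)  # (n, 2, r)
            if np.isnan(y).any():
                continue
            t = pstats.sides_anova(y)
            out[name] = {
                "F_sides": t.F_sides,
                "F_individuals": t.F_individuals,
                "F_interaction": t.F_interaction,
                "p_sides": t.p_sides,
                "p_interaction": t.p_interaction,
            }
        if not out:
            raise ValueError("no index with complete balanced data")
        return out

    _try("anova_front_legs", lambda: _anova(True))
    _try("anova_back_legs", lambda: _anova(False))

    def _hierarchy():
        avg = indices_df[indices_df["averaged"].astype(bool)]
        presence = avg.pivot_table(
            index="gecko_id", columns="body_part", values="qualifying",
            aggfunc="first",
        ).fillna(False).astype(bool)
        for p in BodyPart:
            if p.value not in presence.columns:
                presence[p.value] = False
        return pstats.hierarchy_check(presence)

    _try("hierarchy", _hierarchy)
    return report
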
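"""File-format plumbing: images, masks, metadata tables, result files.

Conventions: photographs are 8-bit RGB PNG or TIFF; masks are
single-channel PNG (nonzero = inside the region); the metadata table is a
CSV with columns image_path, mask_path, gecko_id, body_part, replicate,
cm_per_pixel (paths relative to the CSV's directory).  Tabular results go
to CSV, nested results and fitted metric specifications to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, List, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .imaging import BinaryPattern, BodyPart, RegionImage
from .indices import INDEX_NAMES, PatternIndices
from .spots import SpotSet

__all__ = [
    "read_region_image",
    "iter_metadata",
    "write_cohort",
    "indices_to_frame",
    "write_indices_csv",
    "read_indices_csv",
    "write_debug_png",
]

METADATA_COLUMNS = [
    "image_path", "mask_path", "gecko_id", "body_part", "replicate", "cm_per_pixel",
]


def read_region_image(
    image_path,
    mask_path,
    body_part,
    gecko_id: str = "",
    replicate: int = 1,
    cm_per_pixel: float = 1.0,
) -> RegionImage:
    """Load one photograph plus its region mask."""
    pixels = iio.imread(image_path)
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    mask = np.asarray(iio.imread(mask_path))
    if mask.ndim == 3:
        mask = mask[:, :, 0]
    return RegionImage(
        pixels=pixels,
        mask=mask > 0,
        body_part=BodyPart(body_part),
        gecko_id=str(gecko_id),
        replicate=int(replicate),
        cm_per_pixel=float(cm_per_pixel),
    )


def iter_metadata(metadata_csv) -> Iterator[RegionImage]:
    """Yield RegionImages for every row of a metadata CSV."""
    path = Path(metadata_csv)
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata CSV is missing columns: {missing}")
    for row in df.itertuples(index=False):
        yield read_region_image(
            path.parent / row.image_path,
            path.parent / row.mask_path,
            body_part=row.body_part,
            gecko_id=row.gecko_id,
            replicate=row.replicate,
            cm_per_pixel=row.cm_per_pixel,
        )


def write_cohort(cohort, out_dir) -> Path:
    """Materialize a synthetic cohort as PNGs + metadata.csv + truth.json."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for img in cohort.images:
        stem = f"{img.gecko_id}_{img.body_part.value}_r{img.replicate}"
        img_name = f"images/{stem}.png"
        mask_name = f"images/{stem}_mask.png"
        iio.imwrite(out / img_name, img.pixels)
        iio.imwrite(out / mask_name, (img.mask * 255).astype(np.uint8))
        rows.append(
            {
                "image_path": img_name,
                "mask_path": mask_name,
                "gecko_id": img.gecko_id,
                "body_part": img.body_part.value,
                "replicate": img.replicate,
                "cm_per_pixel": img.cm_per_pixel,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        out / "metadata.csv", index=False
    )
    truth = {
        "cohort_spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cohort.spec).items()
        },
        "regions": cohort.truth.to_dict(orient="records"),
        "latents": cohort.latents.to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out / "metadata.csv"


def indices_to_frame(records: Iterable[PatternIndices]) -> pd.DataFrame:
    """One row per PatternIndices, in the indices.csv column layout."""
    rows = []
    for r in records:
        row = {
            "gecko_id": r.gecko_id,
            "body_part": r.body_part.value if r.body_part else "",
            "replicate": "" if r.replicate is None else r.replicate,
            "averaged": r.averaged,
            "qualifying": r.qualifying,
            "n_all": r.n_all,
            "n_interior": r.n_interior,
        }
        row.update({n: getattr(r, n) for n in INDEX_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def write_indices_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_indices_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["gecko_id"] = df["gecko_id"].astype(str)
    return df


def write_debug_png(spotset: SpotSet, path) -> None:
    """Render a spot set the way binarized patterns are usually shown:
    0 = background, 128 = boundary spot, 255 = interior spot."""
    out = np.zeros(spotset.pattern.mask.shape, dtype=np.uint8)
    for s in spotset.spots:
        out[s.pixels[:, 0], s.pixels[:, 1]] = 255 if s.interior else 128
    iio.imwrite(path, out)
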
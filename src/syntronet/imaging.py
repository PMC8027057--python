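"""Single-cell isotope quantification and two-channel colocalization statistics.

nanoSIMS rasters record per-pixel ion counts for 12C14N- and 15N12C-; the 15N
atom fraction of a region of interest (a single cell) is the ratio-of-sums
sum(15N12C-) / (sum(15N12C-) + sum(12C14N-)), reported as atom percent
(natural abundance ~0.36%). Cells are classified interior/exterior by the
distance from their centroid to the consortium boundary (default 10 um), to
resolve spatial gradients in diazotrophic activity.

For fluorescence images (e.g. 16S rRNA FISH vs nifH mRNA HCR-FISH channels),
colocalization is quantified with Pearson's cross-correlation coefficient of
pixel intensities and Manders' coefficients M1/M2 (fraction of each channel's
intensity found where the other channel is above threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, FormatError, ParameterError

logger = logging.getLogger(__name__)

#: Natural 15N abundance, as an atom fraction.
NATURAL_ABUNDANCE_15N = 0.0036


@dataclass(frozen=True)
class IonCountScene:
    """Per-pixel ion counts with a consortium mask and labeled single-cell ROIs.

    ``c14``/``c15`` are congruent nonnegative integer rasters for 12C14N- and
    15N12C-; ``roi_labels`` is an integer label image (0 = background) and
    ``roi_meta`` a table with columns roi_id / taxon / centroid_x_um /
    centroid_y_um.
    """

    c14: np.ndarray
    c15: np.ndarray
    pixel_size_um: float
    mask: np.ndarray
    roi_labels: np.ndarray
    roi_meta: pd.DataFrame

    def __post_init__(self):
        for name in ("c14", "c15", "roi_labels"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != self.c14.shape:
                raise FormatError(f"{name} raster not congruent with c14")
        if np.any(self.c14 < 0) or np.any(self.c15 < 0):
            raise FormatError("ion counts must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")

    @property
    def roi_ids(self) -> list[int]:
        return [int(i) for i in self.roi_meta["roi_id"]]


@dataclass(frozen=True)
class TwoChannelImage:
    """Two congruent nonnegative intensity rasters."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        if np.asarray(self.a).shape != np.asarray(self.b).shape:
            raise FormatError("channels must be congruent")
        if np.any(self.a < 0) or np.any(self.b < 0):
            raise FormatError("intensities must be nonnegative")


# ---------------------------------------------------------------------------
# 15N quantification


def atom_fraction(c15, c14):
    """15N atom fraction f = c15 / (c15 + c14); NaN (flagged) at zero total."""
    c15 = np.asarray(c15, dtype=float)
    c14 = np.asarray(c14, dtype=float)
    total = c15 + c14
    if np.any(total == 0):
        logger.warning("atom_fraction: zero total counts -> undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, c15 / np.where(total > 0, total, 1.0), np.nan)
    return float(f) if f.ndim == 0 else f


def roi_atom_percent(scene: IonCountScene, roi_id: int, method: str = "ratio_of_sums") -> float:
    """Atom percent 15N for one ROI.

    ``ratio_of_sums`` (default, Poisson-optimal weighting) pools counts over the
    ROI before taking the ratio; ``mean_of_ratios`` averages per-pixel fractions.
    """
    pix = scene.roi_labels == roi_id
    if not pix.any():
        raise ParameterError(f"ROI {roi_id} is empty or unknown")
    if method == "ratio_of_sums":
        f = atom_fraction(scene.c15[pix].sum(), scene.c14[pix].sum())
    elif method == "mean_of_ratios":
        f = float(np.nanmean(atom_fraction(scene.c15[pix], scene.c14[pix])))
    else:
        raise ParameterError(f"unknown method {method!r}")
    return 100.0 * f


def classify_interior_exterior(
    scene: IonCountScene, depth_threshold_um: float = 10.0
) -> dict[int, str]:
    """Label each ROI interior/exterior by centroid distance to the mask boundary.

    An ROI is interior iff the Euclidean distance from its centroid to the
    nearest pixel centre outside the consortium mask is >= the threshold
    (default 10 um). Centroids outside the mask are warned about and classified
    exterior.
    """
    outside = ~np.asarray(scene.mask, dtype=bool)
    oy, ox = np.nonzero(outside)
    px = scene.pixel_size_um
    out_x = (ox + 0.5) * px
    out_y = (oy + 0.5) * px
    labels: dict[int, str] = {}
    for row in scene.roi_meta.itertuples(index=False):
        rid = int(row.roi_id)
        cx, cy = float(row.centroid_x_um), float(row.centroid_y_um)
        j = int(cx / px)
        i = int(cy / px)
        in_mask = (
            0 <= i < scene.mask.shape[0]
            and 0 <= j < scene.mask.shape[1]
            and bool(scene.mask[i, j])
        )
        if not in_mask:
            logger.warning("ROI %d centroid outside consortium mask", rid)
            labels[rid] = "exterior"
            continue
        if out_x.size == 0:
            labels[rid] = "interior"  # mask fills the raster: no boundary in view
            continue
        dmin = float(np.sqrt((out_x - cx) ** 2 + (out_y - cy) ** 2).min())
        labels[rid] = "interior" if dmin >= depth_threshold_um else "exterior"
    return labels


def summarize_rois(
    scene: IonCountScene,
    depth_threshold_um: float = 10.0,
    method: str = "ratio_of_sums",
) -> pd.DataFrame:
    """Mean / dispersion / n of ROI atom percent per (taxon, region) group.

    Both the standard deviation across ROIs and the standard error are
    reported; empty groups are omitted. Region labels come from
    :func:`classify_interior_exterior`.
    """
    regions = classify_interior_exterior(scene, depth_threshold_um)
    records = []
    for row in scene.roi_meta.itertuples(index=False):
        rid = int(row.roi_id)
        records.append(
            {
                "taxon": row.taxon,
                "region": regions[rid],
                "atom_percent": roi_atom_percent(scene, rid, method=method),
            }
        )
    df = pd.DataFrame(records)
    out = (
        df.groupby(["taxon", "region"], as_index=False)
        .agg(
            n=("atom_percent", "size"),
            mean_atom_percent=("atom_percent", "mean"),
            sd_atom_percent=("atom_percent", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
        )
    )
    out["sem_atom_percent"] = out["sd_atom_percent"] / np.sqrt(out["n"])
    return out


# ---------------------------------------------------------------------------
# Colocalization


def pearson_coloc(img: TwoChannelImage, mask: np.ndarray | None = None) -> float:
    """Pearson cross-correlation of paired pixel intensities within a mask."""
    a = np.asarray(img.a, dtype=float)
    b = np.asarray(img.b, dtype=float)
    if mask is not None:
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        logger.warning("pearson_coloc: zero variance -> undefined (NaN)")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def manders_coloc(
    img: TwoChannelImage, t_a: float = 0.0, t_b: float = 0.0
) -> tuple[float, float]:
    """Manders coefficients: M1 = sum A where B > t_b / sum A, and vice versa."""
    a = np.asarray(img.a, dtype=float)
    b = np.asarray(img.b, dtype=float)
    if a.sum() == 0 or b.sum() == 0:
        raise DegenerateDataError("zero total intensity in a channel")
    m1 = float(a[b > t_b].sum() / a.sum())
    m2 = float(b[a > t_a].sum() / b.sum())
    return m1, m2


def intensity_scatter(img: TwoChannelImage, mask: np.ndarray | None = None) -> pd.DataFrame:
    """Paired (a, b) pixel intensities for scatterplot export."""
    a = np.asarray(img.a, dtype=float)
    b = np.asarray(img.b, dtype=float)
    if mask is not None:
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    return pd.DataFrame({"a": a, "b": b})


# ---------------------------------------------------------------------------
# I/O


def write_scene(scene: IonCountScene, tiff_path, roi_csv_path) -> None:
    """Multi-page TIFF (pages: c14, c15, mask, roi_labels) plus ROI metadata CSV."""
    import tifffile

    tifffile.imwrite(
        tiff_path,
        np.stack(
            [
                scene.c14.astype(np.int32),
                scene.c15.astype(np.int32),
                scene.mask.astype(np.int32),
                scene.roi_labels.astype(np.int32),
            ]
        ),
        photometric="minisblack",
        metadata={"pixel_size_um": scene.pixel_size_um},
    )
    scene.roi_meta.to_csv(roi_csv_path, index=False)


def read_scene(tiff_path, roi_csv_path, pixel_size_um: float | None = None) -> IonCountScene:
    import tifffile

    with tifffile.TiffFile(tiff_path) as tf:
        pages = tf.asarray()
        if pixel_size_um is None:
            meta = tf.shaped_metadata or tf.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            pixel_size_um = float(meta.get("pixel_size_um", 1.0))
    c14, c15, mask, labels = pages[0], pages[1], pages[2], pages[3]
    return IonCountScene(
        c14=c14.astype(np.int64),
        c15=c15.astype(np.int64),
        pixel_size_um=pixel_size_um,
        mask=mask.astype(bool),
        roi_labels=labels.astype(np.int64),
        roi_meta=pd.read_csv(roi_csv_path),
    )


def write_image(img: TwoChannelImage, tiff_path) -> None:
    import tifffile

    tifffile.imwrite(tiff_path, np.stack([img.a, img.b]).astype(np.float32))


def read_image(tiff_path) -> TwoChannelImage:
    import tifffile

    pages = tifffile.imread(tiff_path)
    return TwoChannelImage(a=pages[0], b=pages[1])
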
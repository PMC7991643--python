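"""Single-cell multi-marker quantification.

Cells are outlined with polygon ROIs (as produced by manual outlining
in an image-analysis tool), rasterized to pixel masks, and quantified:
per-marker mean and integrated fluorescence intensity plus a 12-feature
morphological profile per cell.  Downstream summaries are the
standardized (z-scored) intensity/feature table with per-variable
relative spread, an unsupervised hierarchical clustermap of variables x
cells displayed as fold change versus the row mean, and a PCA biplot
with loading vectors — the representation in which morphology-defined
phenotypes (spindle-shaped SS, rapidly self-renewing RS,
flattened-cuboidal FC) separate while phenotype-independent marker
expression does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from sklearn.decomposition import PCA as _SKPCA

from virtustain._geometry import rasterize_polygon, to_shapely
from virtustain.errors import ShapeError, ValidationError

__all__ = [
    "CellROI",
    "MorphologyFeatures",
    "CellRecord",
    "ClustermapResult",
    "PCAResult",
    "MORPHOLOGY_FEATURE_NAMES",
    "rasterize_roi",
    "measure_intensity",
    "measure_morphology",
    "build_cell_table",
    "standardize_table",
    "cluster_heatmap",
    "pca",
]

PHENOTYPE_LABELS = ("SS", "RS", "FC")

MORPHOLOGY_FEATURE_NAMES = (
    "cell_area",
    "cell_perimeter",
    "aspect_ratio",
    "circularity",
    "solidity",
    "eccentricity",
    "major_axis",
    "minor_axis",
    "nucleus_area",
    "nucleus_perimeter",
    "nucleus_to_cell_ratio",
    "nucleus_eccentricity",
)


@dataclass
class CellROI:
    """A manually outlined cell: outline polygon, optional nucleus,
    optional phenotype label (consumed as given, never computed)."""

    cell_id: str
    cell_polygon: np.ndarray
    nucleus_polygon: np.ndarray | None = None
    phenotype_label: str | None = None

    def __post_init__(self):
        cell = to_shapely(self.cell_polygon)
        if self.nucleus_polygon is not None:
            nuc = to_shapely(self.nucleus_polygon)
            if not cell.buffer(1e-6).contains(nuc):
                raise ValidationError(
                    f"{self.cell_id}: nucleus polygon not contained in cell polygon"
                )
        if self.phenotype_label is not None and (
            self.phenotype_label not in PHENOTYPE_LABELS
        ):
            raise ValidationError(f"unknown phenotype {self.phenotype_label!r}")


@dataclass
class MorphologyFeatures:
    cell_area: float
    cell_perimeter: float
    aspect_ratio: float
    circularity: float
    solidity: float
    eccentricity: float
    major_axis: float
    minor_axis: float
    nucleus_area: float
    nucleus_perimeter: float
    nucleus_to_cell_ratio: float
    nucleus_eccentricity: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in MORPHOLOGY_FEATURE_NAMES}


@dataclass
class CellRecord:
    """Quantified single cell: intensity summaries and morphology."""

    cell_id: str
    mean_intensity: dict[str, float]
    total_intensity: dict[str, float]
    morphology: MorphologyFeatures
    phenotype_label: str | None = None


@dataclass
class ClustermapResult:
    row_linkage: np.ndarray  # variables
    col_linkage: np.ndarray  # cells
    fold_change: pd.DataFrame  # variables x cells
    row_order: list[str]
    col_order: list[str]


@dataclass
class PCAResult:
    scores: np.ndarray  # cells x components
    loadings: pd.DataFrame  # variables x components
    explained_variance_ratio: np.ndarray
    component_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------

def rasterize_roi(roi: CellROI, field_size) -> tuple[np.ndarray, np.ndarray | None]:
    """Rasterize an ROI to (cell_mask, nucleus_mask) by the
    pixel-centre-in-polygon rule.  Deterministic."""
    cell_mask = rasterize_polygon(roi.cell_polygon, field_size)
    nucleus_mask = None
    if roi.nucleus_polygon is not None:
        nucleus_mask = rasterize_polygon(roi.nucleus_polygon, field_size)
    return cell_mask, nucleus_mask


def measure_intensity(image, mask) -> tuple[float, float]:
    """(mean, total) pixel intensity under a mask."""
    img = np.asarray(image, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ShapeError(f"image {img.shape} vs mask {m.shape}")
    if not m.any():
        raise ValidationError("empty mask")
    vals = img[m]
    return float(vals.mean()), float(vals.sum())


def _region(mask: np.ndarray):
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValidationError("empty mask")
    props = regionprops(sk_label(m))
    # keep the largest connected component; ROIs are simply connected
    return max(props, key=lambda p: p.area)


def measure_morphology(cell_mask, nucleus_mask=None) -> MorphologyFeatures:
    """All 12 morphology features of a (cell, nucleus) mask pair.

    Axes come from the second-moment (inertia-equivalent) ellipse of the
    mask; the perimeter is the boundary contour length; circularity is
    4*pi*area/perimeter^2.  Nucleus features are zero when no nucleus
    mask is given (ratio included).
    """
    rc = _region(cell_mask)
    area = float(rc.area)
    perim = float(rc.perimeter)
    major = float(rc.axis_major_length)
    minor = float(rc.axis_minor_length)
    if nucleus_mask is not None and np.asarray(nucleus_mask, dtype=bool).any():
        if not np.all(np.asarray(cell_mask, bool) | ~np.asarray(nucleus_mask, bool)):
            raise ValidationError("nucleus mask must be a subset of the cell mask")
        rn = _region(nucleus_mask)
        nucleus_area = float(rn.area)
        nucleus_perimeter = float(rn.perimeter)
        nucleus_ecc = float(rn.eccentricity)
    else:
        nucleus_area = nucleus_perimeter = nucleus_ecc = 0.0
    return MorphologyFeatures(
        cell_area=area,
        cell_perimeter=perim,
        aspect_ratio=major / minor if minor > 0 else np.inf,
        circularity=4.0 * np.pi * area / perim**2 if perim > 0 else 0.0,
        solidity=float(rc.solidity),
        eccentricity=float(rc.eccentricity),
        major_axis=major,
        minor_axis=minor,
        nucleus_area=nucleus_area,
        nucleus_perimeter=nucleus_perimeter,
        nucleus_to_cell_ratio=nucleus_area / area,
        nucleus_eccentricity=nucleus_ecc,
    )


def build_cell_table(
    images: dict[str, np.ndarray], rois: list[CellROI], field_size=None
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Quantify every ROI on every marker image.

    Returns the records plus a tidy DataFrame with one row per cell:
    cell_id, phenotype, mean/total intensity per marker and the 12
    morphology columns.
    """
    if not images:
        raise ValidationError("no marker images given")
    shapes = {im.shape for im in images.values()}
    if len(shapes) != 1:
        raise ShapeError("all marker images must share one shape")
    if field_size is None:
        field_size = next(iter(shapes))
    records = []
    rows = []
    for roi in rois:
        cmask, nmask = rasterize_roi(roi, field_size)
        if not cmask.any():
            raise ValidationError(f"{roi.cell_id}: ROI rasterizes to an empty mask")
        morph = measure_morphology(cmask, nmask)
        mean_i, total_i = {}, {}
        for marker, img in images.items():
            mean_i[marker], total_i[marker] = measure_intensity(img, cmask)
        rec = CellRecord(
            cell_id=roi.cell_id,
            mean_intensity=mean_i,
            total_intensity=total_i,
            morphology=morph,
            phenotype_label=roi.phenotype_label,
        )
        records.append(rec)
        row = {"cell_id": roi.cell_id, "phenotype": roi.phenotype_label}
        row.update({f"mean_{m}": v for m, v in mean_i.items()})
        row.update({f"total_{m}": v for m, v in total_i.items()})
        row.update(morph.as_dict())
        rows.append(row)
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------

def standardize_table(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Z-score each variable across cells.

    Returns (zmatrix, relative_spread, excluded) where
    ``relative_spread`` is sd/mean per variable in percent (the spread
    annotation of standardized intensity histograms) and ``excluded``
    lists zero-variance variables that were dropped with a warning
    record rather than producing NaN columns.
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c not in ("cell_id", "phenotype")
            and np.issubdtype(table[c].dtype, np.number)
        ]
    if len(table) < 2:
        raise ValidationError("need at least 2 cells to standardize")
    excluded = []
    keep = []
    for c in columns:
        sd = table[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            excluded.append(c)
        else:
            keep.append(c)
    sub = table[keep].astype(float)
    z = (sub - sub.mean()) / sub.std(ddof=1)
    rel = sub.std(ddof=1) / sub.mean() * 100.0
    return z, rel, excluded


def cluster_heatmap(
    zmatrix: pd.DataFrame,
    raw_matrix: pd.DataFrame,
    method: str = "average",
    metric: str = "correlation",
) -> ClustermapResult:
    """Unsupervised hierarchical clustering of variables and cells.

    Variables (rows of the display) and cells are clustered on the
    z-scored matrix with correlation distance (1 - Pearson) and average
    linkage by default; displayed values are the fold change of the raw
    values with respect to each variable's mean.  SciPy's linkage is
    deterministic with ties broken by index order.
    """
    if zmatrix.shape[0] < 2 or zmatrix.shape[1] < 2:
        raise ValidationError("need >= 2 cells and >= 2 variables")
    if zmatrix.isna().any().any() or raw_matrix.isna().any().any():
        raise ValidationError("NaN in clustering input")
    var_link = linkage(zmatrix.to_numpy().T, method=method, metric=metric)
    cell_link = linkage(zmatrix.to_numpy(), method=method, metric=metric)
    fold = raw_matrix.T.div(raw_matrix.T.mean(axis=1), axis=0)
    row_order = [zmatrix.columns[i] for i in leaves_list(var_link)]
    col_order = [str(zmatrix.index[i]) for i in leaves_list(cell_link)]
    return ClustermapResult(
        row_linkage=var_link,
        col_linkage=cell_link,
        fold_change=fold,
        row_order=row_order,
        col_order=list(col_order),
    )


def pca(zmatrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Principal components of the standardized cell x variable matrix.

    Loadings are the principal axes scaled by the standard deviation
    they explain (eigenvector * sqrt(eigenvalue)), the usual biplot
    convention.  Sign convention: the largest-magnitude loading of each
    component is positive, so results are invariant to row order.
    """
    x = zmatrix.to_numpy(dtype=float)
    n, p = x.shape
    if n_components >= n:
        raise ValidationError("need more cells than components")
    if n_components > min(n - 1, p):
        raise ValidationError(f"n_components={n_components} exceeds rank bound")
    sk = _SKPCA(n_components=n_components, svd_solver="full")
    scores = sk.fit_transform(x)
    comps = sk.components_  # components x variables
    for k in range(n_components):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] *= -1.0
            scores[:, k] *= -1.0
    loadings = comps.T * np.sqrt(sk.explained_variance_)
    names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=scores,
        loadings=pd.DataFrame(loadings, index=zmatrix.columns, columns=names),
        explained_variance_ratio=sk.explained_variance_ratio_,
        component_names=names,
    )
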
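"""Areal surface-texture analysis of cementum grayscale fields.

Treating grayscale as a height field turns a straightened cementum
patch into a surface whose texture changes at sexual maturity: adult
cementum packs more, narrower increments per unit area, giving higher
contrast, stronger anisotropy, and less noise than juvenile cementum.
This module quantifies that with the standard areal texture parameter
family (amplitude, spatial, hybrid, and functional/bearing-curve
measures, 21 in all), screens the measures for a juvenile-vs-adult
signal by per-dataset ANOVA, ordinates patches by PCA, and tests
whether the two life stages occupy distinct regions of texture space
via convex-hull overlap.

All measures operate on the mean-subtracted grayscale height field; a
full formula reference lives in ``docs/texture_measures.md``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .imgstack import StraightenedCementum
from .increments import PeakSet

__all__ = [
    "TexturePatch",
    "TextureSpace",
    "MEASURE_NAMES",
    "subsample_patches",
    "compute_features",
    "screen_measures",
    "texture_pca",
    "hull_separation",
]


@dataclass
class TexturePatch:
    """A rectangular cementum sample assigned to one life stage."""

    pixels: np.ndarray
    stage: str  # juvenile | adult | pre-cutoff | post-cutoff
    radial_extent_um: float = 0.0
    circumferential_extent_um: float = 0.0
    specimen_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("patch must be 2D")


@dataclass
class TextureSpace:
    """PCA ordination of a screened texture feature matrix."""

    measure_names: list[str]
    loadings: np.ndarray  # (n_measures, n_components), orthonormal columns
    scores: np.ndarray  # (n_patches, n_components)
    variance_explained: np.ndarray


#: the 21 areal texture measures, by group.
MEASURE_NAMES = [
    # amplitude
    "sa",  # arithmetic mean height
    "sq",  # RMS height
    "ssk",  # skewness
    "sku",  # kurtosis
    "sp",  # maximum peak height
    "sv",  # maximum valley depth
    "sz",  # total height range
    # spatial
    "sal",  # autocorrelation length (1/e decay)
    "str",  # texture aspect ratio (min/max decay length, 0..1)
    "std",  # dominant texture direction (degrees)
    # hybrid
    "sdq",  # RMS surface gradient
    "sdr",  # developed interfacial area ratio
    # functional (bearing curve)
    "sk",  # core height
    "spk",  # reduced peak height
    "svk",  # reduced valley depth
    "smr1",  # peak material ratio
    "smr2",  # valley material ratio
    # functional volumes (bearing-curve integrals)
    "vmp",  # peak material volume
    "vmc",  # core material volume
    "vvc",  # core void volume
    "vvv",  # valley void volume
]


def subsample_patches(
    region: StraightenedCementum,
    cutoff_year: int,
    peaks: PeakSet,
    hyaline_px: int = 3,
) -> tuple[TexturePatch, TexturePatch]:
    """Split a straightened region into equal juvenile and adult patches.

    The cutoff radius is the detected peak center of ``cutoff_year``.
    The juvenile patch runs from just outside the hyaline layer to the
    cutoff; the adult patch from the cutoff to the start of the final
    year of growth (the last detected peak), which is excluded because
    it may be incomplete.  Both patches take the shorter of the two
    radial extents, and a width of twice that length — clamped to the
    region width if the dataset is too small.
    """
    if cutoff_year < 1 or cutoff_year > peaks.count:
        raise ValueError(
            f"cutoff year {cutoff_year} outside recorded years (1..{peaks.count})"
        )
    step = float(np.mean(region.row_step_um))
    cutoff_row = int(round(peaks.peak_positions_um[cutoff_year - 1] / step))
    last_row = int(round(peaks.peak_positions_um[-1] / step))
    rows, cols = region.pixels.shape

    juv_extent = cutoff_row - hyaline_px
    adu_extent = min(last_row, rows) - cutoff_row
    radial = min(juv_extent, adu_extent)
    if radial < 4:
        raise ValueError("cutoff leaves too little cementum on one side")
    width = 2 * radial
    if width > cols:
        warnings.warn(
            f"subsample width clamped from {width} to {cols} px (small dataset)",
            stacklevel=2,
        )
        width = cols
    c0 = (cols - width) // 2
    juv = region.pixels[cutoff_row - radial : cutoff_row, c0 : c0 + width]
    adu = region.pixels[cutoff_row : cutoff_row + radial, c0 : c0 + width]
    mk = lambda px, stage: TexturePatch(
        pixels=px,
        stage=stage,
        radial_extent_um=radial * step,
        circumferential_extent_um=width * region.voxel_size_um,
        specimen_id=region.provenance[0] if region.provenance else "",
    )
    return mk(juv, "juvenile"), mk(adu, "adult")


# ---------------------------------------------------------------------------
# the 21 measures


def _bearing_curve(z: np.ndarray, n: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Height vs material ratio (Abbott-Firestone curve), descending."""
    heights = np.sort(z.ravel())[::-1]
    p = np.linspace(0.0, 1.0, heights.size)
    pi = np.linspace(0.0, 1.0, n)
    return pi, np.interp(pi, p, heights)


def _sk_family(z: np.ndarray) -> dict[str, float]:
    """Core/peak/valley decomposition of the bearing curve.

    The standard construction: slide a 40%-wide secant along the curve,
    take the flattest one, extend it to material ratios 0 and 1 to get
    the core bounds, then convert the corner areas into equivalent
    triangle heights (Spk, Svk) at the intersection ratios (Smr1, Smr2).
    """
    p, c = _bearing_curve(z)
    win = int(0.4 * (p.size - 1))
    slopes = (c[win:] - c[:-win]) / 0.4
    i0 = int(np.argmax(slopes))  # slopes are negative; max = flattest
    slope = slopes[i0]
    y0 = c[i0] - slope * p[i0]  # intercept at p = 0
    y1 = y0 + slope  # at p = 1
    sk = y0 - y1

    above = c > y0
    smr1 = float(p[above][-1]) if above.any() else 0.0
    below = c < y1
    smr2 = float(p[below][0]) if below.any() else 1.0

    a1 = float(np.trapezoid(np.clip(c - y0, 0, None), p))
    a2 = float(np.trapezoid(np.clip(y1 - c, 0, None), p))
    spk = 2.0 * a1 / smr1 if smr1 > 0 else 0.0
    svk = 2.0 * a2 / (1.0 - smr2) if smr2 < 1 else 0.0

    # material/void volumes at the standard 10% / 80% ratios
    def vm(q):
        m = p <= q
        return float(np.trapezoid(np.clip(c[m] - np.interp(q, p, c), 0, None), p[m]))

    def vv(q):
        m = p >= q
        return float(np.trapezoid(np.clip(np.interp(q, p, c) - c[m], 0, None), p[m]))

    return {
        "sk": sk,
        "spk": spk,
        "svk": svk,
        "smr1": smr1,
        "smr2": smr2,
        "vmp": vm(0.10),
        "vmc": vm(0.80) - vm(0.10),
        "vvc": vv(0.10) - vv(0.80),
        "vvv": vv(0.80),
    }


def _acf2d(z: np.ndarray) -> np.ndarray:
    """Normalized, centered 2D autocorrelation via FFT."""
    f = np.fft.fft2(z)
    acf = np.real(np.fft.ifft2(f * np.conj(f))) / z.size
    acf /= acf.flat[0]
    return np.fft.fftshift(acf)


def _decay_lengths(acf: np.ndarray, n_angles: int = 72, thresh: float = 1.0 / np.e):
    """Per-direction distance at which the ACF first drops below 1/e."""
    rows, cols = acf.shape
    cr, cc = rows // 2, cols // 2
    rmax = min(cr, cc) - 1
    if rmax < 2:
        return None
    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    radii = np.arange(1, rmax + 1)
    lengths = np.empty(n_angles)
    for k, th in enumerate(angles):
        rr = cr + radii * np.sin(th)
        cc_ = cc + radii * np.cos(th)
        vals = acf[np.round(rr).astype(int), np.round(cc_).astype(int)]
        below = np.nonzero(vals < thresh)[0]
        lengths[k] = radii[below[0]] if below.size else float(rmax)
    return lengths


def compute_features(patch: TexturePatch | np.ndarray) -> pd.Series:
    """Compute the 21 areal texture measures on one patch.

    Operates on the mean-subtracted grayscale height field.  A constant
    patch has zero amplitude everywhere; its shape-dependent measures
    (skewness, kurtosis, autocorrelation measures) are flagged NaN.
    """
    px = patch.pixels if isinstance(patch, TexturePatch) else np.asarray(patch, float)
    if px.shape[0] < 16 or px.shape[1] < 16:
        raise ValueError("patch must be at least 16x16 px")
    z = px - px.mean()
    out: dict[str, float] = {}

    sq = float(np.sqrt(np.mean(z**2)))
    out["sa"] = float(np.mean(np.abs(z)))
    out["sq"] = sq
    out["ssk"] = float(np.mean(z**3) / sq**3) if sq > 0 else np.nan
    out["sku"] = float(np.mean(z**4) / sq**4) if sq > 0 else np.nan
    out["sp"] = float(z.max())
    out["sv"] = float(-z.min())
    out["sz"] = out["sp"] + out["sv"]

    if sq > 0:
        acf = _acf2d(z)
        lengths = _decay_lengths(acf)
        if lengths is None:
            out["sal"] = out["str"] = np.nan
        else:
            out["sal"] = float(lengths.min())
            out["str"] = float(lengths.min() / lengths.max())
        power = np.abs(np.fft.fftshift(np.fft.fft2(z))) ** 2
        power[power.shape[0] // 2, power.shape[1] // 2] = 0.0  # remove DC
        imax = np.unravel_index(int(np.argmax(power)), power.shape)
        dy = imax[0] - power.shape[0] // 2
        dx = imax[1] - power.shape[1] // 2
        # texture direction is perpendicular to the dominant spatial frequency
        out["std"] = float(np.degrees(np.arctan2(dy, dx) + np.pi / 2) % 180.0)
    else:
        out["sal"] = out["str"] = out["std"] = np.nan

    gy, gx = np.gradient(z)
    out["sdq"] = float(np.sqrt(np.mean(gx**2 + gy**2)))
    out["sdr"] = float(np.mean(np.sqrt(1.0 + gx**2 + gy**2) - 1.0))

    if sq > 0:
        out.update(_sk_family(z))
    else:
        out.update(
            {k: 0.0 for k in ("sk", "spk", "svk", "vmp", "vmc", "vvc", "vvv")}
        )
        out.update({"smr1": np.nan, "smr2": np.nan})

    return pd.Series(out, index=MEASURE_NAMES, dtype=float)


# ---------------------------------------------------------------------------
# screening, ordination, hull test


def screen_measures(
    datasets: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    stage_column: str = "stage",
) -> tuple[list[str], pd.DataFrame]:
    """Retain measures that separate the life stages in *every* dataset.

    Each dataset is a DataFrame of per-patch features with a stage
    column (two levels).  A one-way ANOVA is run per measure per
    dataset; a measure is retained iff ``p < alpha`` everywhere.
    Zero-variance measures (and measures with missing values) are
    excluded with a notice.

    Returns ``(retained_names, anova_table)`` where the table holds
    one row per (dataset, measure) with F and p.
    """
    measures = [m for m in MEASURE_NAMES if all(m in df.columns for df in datasets.values())]
    rows = []
    retained = []
    for m in measures:
        ok_everywhere = True
        for name, df in datasets.items():
            groups = [g[m].to_numpy() for _, g in df.groupby(stage_column)]
            if len(groups) != 2:
                raise ValueError(f"dataset {name!r} must have exactly two stages")
            vals = np.concatenate(groups)
            if np.any(~np.isfinite(vals)) or np.all(vals == vals[0]):
                warnings.warn(
                    f"measure {m!r} degenerate in dataset {name!r}; excluded",
                    stacklevel=2,
                )
                ok_everywhere = False
                rows.append({"dataset": name, "measure": m, "F": np.nan, "p": np.nan})
                continue
            F, p = stats.f_oneway(*groups)
            rows.append({"dataset": name, "measure": m, "F": float(F), "p": float(p)})
            if not p < alpha:
                ok_everywhere = False
        if ok_everywhere:
            retained.append(m)
    return retained, pd.DataFrame(rows)


def texture_pca(features: pd.DataFrame) -> TextureSpace:
    """PCA of a (patches x measures) matrix, z-scored column-wise.

    Columns are standardized (correlation-matrix PCA) before a singular
    value decomposition.  Loadings are orthonormal; variance explained
    sums to 1 over the retained components.  Zero-variance columns are
    dropped, and rank deficiency reduces the component count with a
    notice.  Component signs are fixed so each loading vector's
    largest-magnitude entry is positive.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 patches for PCA")
    X = features.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping zero-variance measures: "
            f"{[c for c, k in zip(features.columns, keep) if not k]}",
            stacklevel=2,
        )
    names = [c for c, k in zip(features.columns, keep) if k]
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(Xz, full_matrices=False)
    tol = S.max() * max(Xz.shape) * np.finfo(float).eps
    rank = int(np.sum(S > tol))
    ncomp = min(rank, len(features) - 1, len(names))
    if ncomp < min(len(features) - 1, len(names)):
        warnings.warn(f"rank-deficient matrix; retaining {ncomp} components", stacklevel=2)
    U, S, Vt = U[:, :ncomp], S[:ncomp], Vt[:ncomp]
    # deterministic sign: largest |loading| positive per component
    for k in range(ncomp):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = S**2
    return TextureSpace(
        measure_names=names,
        loadings=Vt.T,
        scores=U * S,
        variance_explained=var / var.sum(),
    )


def hull_separation(
    space: TextureSpace | np.ndarray,
    labels,
    threshold: float = 0.05,
) -> tuple[float, bool]:
    """Convex-hull overlap of two labeled groups in the PC1-PC2 plane.

    overlap = area(hull_A ∩ hull_B) / area(hull_A ∪ hull_B); the groups
    are called *distinct* when overlap < ``threshold``.  Degenerate
    (collinear) hulls fall back to a 1D segment-overlap measure.

    Returns ``(overlap_fraction, distinct)``.
    """
    from shapely.geometry import MultiPoint

    scores = space.scores if isinstance(space, TextureSpace) else np.asarray(space)
    pts = scores[:, :2] if scores.shape[1] >= 2 else np.column_stack(
        [scores[:, 0], np.zeros(len(scores))]
    )
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("hull_separation needs exactly two groups")
    hulls = []
    for lab in uniq:
        sub = pts[labels == lab]
        if len(sub) < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 points")
        hulls.append(MultiPoint([tuple(p) for p in sub]).convex_hull)
    inter = hulls[0].intersection(hulls[1])
    union = hulls[0].union(hulls[1])
    if union.area > 0:
        overlap = inter.area / union.area
    elif union.length > 0:  # collinear: compare segment lengths
        overlap = inter.length / union.length
    else:  # both groups are single points
        overlap = 1.0 if inter.is_empty is False else 0.0
    return float(overlap), bool(overlap < threshold)
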
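"""Annual increment detection and growth-layer-group measurement.

The measurement model: a radial grayscale transect through straightened
AEFC cementum shows one peak per year of life (the thick light,
favorable-season increment) separated by dark troughs.  Because both
overall brightness and band amplitude drift with radial depth, the
transect is split into five segments of equal length and a peak must
exceed its own segment's mean + 1 SD to count.  Life span is the number
of such peaks; annual width is the distance between consecutive peak
centers; the interval beyond the last peak (the final, possibly
incomplete year) is never reported as a width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import multimode

import numpy as np
import pandas as pd

from .imgstack import StraightenedCementum

__all__ = [
    "TransectProfile",
    "PeakSet",
    "IncrementSeries",
    "TaxonGrowthSeries",
    "extract_transects",
    "detect_peaks",
    "measure_widths",
    "specimen_lifespan",
    "filter_cohort",
    "pool_taxon",
]


@dataclass
class TransectProfile:
    """Mean grayscale along one 10-pixel-thick radial transect."""

    values: np.ndarray
    positions_um: np.ndarray
    transect_index: int = 0
    vts_index: int = 0
    specimen_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.values.shape != self.positions_um.shape:
            raise ValueError("values and positions must have equal length")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class PeakSet:
    """Detected light-increment centers for one transect."""

    peak_positions_um: np.ndarray
    segment_stats: list[tuple[float, float]]  # per-segment (mean, SD)
    degenerate: bool = False

    def __post_init__(self):
        self.peak_positions_um = np.asarray(self.peak_positions_um, dtype=float)

    @property
    def count(self) -> int:
        return int(self.peak_positions_um.size)


@dataclass
class IncrementSeries:
    """Per-year growth-layer-group widths for one transect.

    ``widths_um[i]`` is the width of year ``i+1``.  The count of GLGs
    (= peaks) exceeds the number of measured widths by one because the
    final year of life cannot be shown to be complete.
    """

    widths_um: np.ndarray
    glg_count: int
    specimen_id: str = ""
    transect_index: int = 0
    vts_index: int = 0

    def __post_init__(self):
        self.widths_um = np.asarray(self.widths_um, dtype=float)
        if self.widths_um.size and np.any(self.widths_um <= 0):
            raise ValueError("widths must be positive")

    @property
    def complete_years(self) -> int:
        return max(self.glg_count - 1, 0)


@dataclass
class TaxonGrowthSeries:
    """Per-year pooled growth for one taxon (years with n >= 3 only)."""

    taxon: str
    years: np.ndarray
    mean_width_um: np.ndarray
    sd_width_um: np.ndarray
    n_specimens: np.ndarray
    mass_g: float
    msgr: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "taxon": self.taxon,
            "year": self.years,
            "mean_width_um": self.mean_width_um,
            "sd_width_um": self.sd_width_um,
            "n_specimens": self.n_specimens,
            "mass_g": self.mass_g,
        }
        if self.msgr is not None:
            d["msgr"] = self.msgr
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------


def extract_transects(
    region: StraightenedCementum,
    n_transects: int = 8,
    thickness_px: int = 10,
    vts_index: int = 0,
    specimen_id: str = "",
) -> list[TransectProfile]:
    """Cut evenly spaced radial transects from a straightened region.

    Each transect value is the mean over ``thickness_px`` adjacent
    columns at a given radial row.  With exactly
    ``n_transects * thickness_px`` columns the bands tile the region;
    wider regions spread the bands evenly.  If the region is too narrow
    the count is reduced (error below 3).
    """
    rows, cols = region.pixels.shape
    if cols < 3 * thickness_px:
        raise ValueError(
            f"region of {cols} columns cannot host 3 transects of {thickness_px} px"
        )
    if cols < n_transects * thickness_px:
        new_n = cols // thickness_px
        warnings.warn(
            f"region of {cols} columns too narrow for {n_transects} transects; "
            f"reduced to {new_n}",
            stacklevel=2,
        )
        n_transects = new_n
    spacing = cols // n_transects
    offset = (spacing - thickness_px) // 2
    out = []
    img = region.pixels.astype(float)
    for k in range(n_transects):
        c0 = k * spacing + offset
        band = img[:, c0 : c0 + thickness_px]
        step = float(np.mean(region.row_step_um[c0 : c0 + thickness_px]))
        out.append(
            TransectProfile(
                values=band.mean(axis=1),
                positions_um=np.arange(rows, dtype=float) * step,
                transect_index=k,
                vts_index=vts_index,
                specimen_id=specimen_id,
            )
        )
    return out


def _segment_slices(n: int, n_segments: int) -> list[slice]:
    """Equal-count segments; remainder samples go to the last segment."""
    size = n // n_segments
    slices = [slice(k * size, (k + 1) * size) for k in range(n_segments - 1)]
    slices.append(slice((n_segments - 1) * size, n))
    return slices


def detect_peaks(
    profile: TransectProfile,
    n_segments: int = 5,
    min_separation_um: float | None = None,
    min_segment_sd_fraction: float = 0.25,
) -> PeakSet:
    """Detect annual light increments with the segmented mean+SD rule.

    The transect is split into ``n_segments`` segments of equal sample
    count (remainder to the last).  A candidate peak is a maximal run of
    consecutive samples exceeding (segment mean + segment SD); a run
    that straddles a boundary is judged against the segment containing
    the run's maximum.  The peak center is the grayscale-weighted
    centroid of the run (sub-voxel).  Peaks closer than
    ``min_separation_um`` (default two voxels) are merged into the
    higher one.

    Segments whose SD falls below ``min_segment_sd_fraction`` of the
    whole profile's SD are treated as featureless (the dark, still
    incomplete final year of a short-lived specimen): their local
    threshold sits just above the noise floor, so without this guard
    any noise wiggle would register as an annual increment.  Runs
    peaking in a featureless segment are discarded.

    A constant (zero-SD) profile yields zero peaks with the
    ``degenerate`` flag set.
    """
    v = profile.values
    x = profile.positions_um
    n = v.size
    if n < 3 * n_segments:
        raise ValueError(
            f"profile of {n} samples too short for {n_segments} segments of >= 3"
        )
    if min_separation_um is None:
        min_separation_um = 2.0 * float(np.median(np.diff(x)))

    slices = _segment_slices(n, n_segments)
    stats = [(float(v[s].mean()), float(v[s].std(ddof=0))) for s in slices]
    if all(sd == 0 for _, sd in stats):
        return PeakSet(np.array([]), stats, degenerate=True)

    seg_of = np.empty(n, dtype=int)
    for k, s in enumerate(slices):
        seg_of[s] = k
    thresh = np.array([m + sd for m, sd in stats])
    above = v > thresh[seg_of]

    # maximal runs of supra-threshold samples
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    global_sd = float(v.std(ddof=0))
    featureless = np.array(
        [sd < min_segment_sd_fraction * global_sd for _, sd in stats]
    )

    # re-evaluate each run against the segment holding its maximum: a run
    # that straddles a boundary is judged (and extended) by that one
    # threshold, so a plateau is not cut where the segments happen to meet
    intervals: list[tuple[int, int]] = []
    for i, j in runs:
        seg = seg_of[i + int(np.argmax(v[i : j + 1]))]
        if featureless[seg] or v[i : j + 1].max() <= thresh[seg]:
            continue
        while i > 0 and v[i - 1] > thresh[seg]:
            i -= 1
        while j < n - 1 and v[j + 1] > thresh[seg]:
            j += 1
        if intervals and i <= intervals[-1][1]:
            intervals[-1] = (
                min(i, intervals[-1][0]),
                max(j, intervals[-1][1]),
            )
        else:
            intervals.append((i, j))

    peaks: list[tuple[float, float]] = []  # (position, height of run max)
    for i, j in intervals:
        w = v[i : j + 1]
        pos = float(np.sum(w * x[i : j + 1]) / np.sum(w))
        peaks.append((pos, float(w.max())))

    # merge peaks closer than min_separation, keeping the higher one
    peaks.sort(key=lambda p: p[0])
    merged: list[tuple[float, float]] = []
    for pos, h in peaks:
        if merged and pos - merged[-1][0] < min_separation_um:
            if h > merged[-1][1]:
                merged[-1] = (pos, h)
        else:
            merged.append((pos, h))

    return PeakSet(np.array([p for p, _ in merged]), stats)


def measure_widths(
    peaks: PeakSet,
    specimen_id: str = "",
    transect_index: int = 0,
    vts_index: int = 0,
) -> IncrementSeries:
    """Peak-to-peak distances = annual growth-layer-group widths.

    ``widths_um[i] = position[i+1] - position[i]``; with fewer than two
    peaks the width list is empty and the GLG count passes through.
    The interval beyond the last peak (final year of life) is not
    reported.
    """
    pos = peaks.peak_positions_um
    widths = np.diff(pos) if pos.size >= 2 else np.array([])
    return IncrementSeries(
        widths_um=widths,
        glg_count=peaks.count,
        specimen_id=specimen_id,
        transect_index=transect_index,
        vts_index=vts_index,
    )


def specimen_lifespan(all_series: list[IncrementSeries]) -> tuple[int, float]:
    """Consensus life span (years) for one specimen.

    The consensus is the mode of the GLG counts across all transects
    (up to 8 transects x 9 VTS = 72); ties go to the *higher* count,
    since missed peaks (noise swallowing a band) are more common than
    spurious ones after merging.  Returns ``(consensus, sd_of_counts)``.
    """
    if not all_series:
        raise ValueError("need at least one increment series")
    counts = [s.glg_count for s in all_series]
    consensus = max(multimode(counts))
    return int(consensus), float(np.std(counts, ddof=0))


def filter_cohort(
    metadata: pd.DataFrame,
    min_genus: int = 3,
    min_ordinal: int = 5,
) -> pd.DataFrame:
    """Apply the preservation and minimum-sample rules to a cohort.

    Keeps preservational categories "a" and "b" only (category "c" —
    diagenetically altered or artifact-ridden — is excluded from every
    analysis), then keeps taxa with at least ``min_genus`` specimens
    identified at genus level, or ``min_ordinal`` specimens identified
    only to ordinal level (column ``rank``; default "genus" when
    absent).
    """
    df = metadata.copy()
    if "category" in df.columns:
        df = df[df["category"].isin(["a", "b"])]
    if "rank" not in df.columns:
        df = df.assign(rank="genus")
    keep_taxa = []
    for taxon, grp in df.groupby("taxon"):
        rank = grp["rank"].iloc[0]
        need = min_ordinal if rank == "ordinal" else min_genus
        if len(grp) >= need:
            keep_taxa.append(taxon)
    return df[df["taxon"].isin(keep_taxa)].reset_index(drop=True)


def pool_taxon(
    series: list[IncrementSeries],
    taxon: str,
    mass_g: float,
    min_specimens: int = 3,
) -> TaxonGrowthSeries:
    """Pool per-year widths across the specimens of one taxon.

    Widths are averaged *within* each specimen first (across its
    transects and VTS), then the per-year mean and SD are taken across
    specimen means.  Years covered by fewer than ``min_specimens``
    specimens are dropped — growth curves are only interpretable where
    several individuals survive.
    """
    rows = []
    for s in series:
        for year, w in enumerate(s.widths_um, start=1):
            rows.append({"specimen_id": s.specimen_id, "year": year, "width_um": w})
    if not rows:
        raise ValueError(f"taxon {taxon!r}: no measured widths to pool")
    df = pd.DataFrame(rows)
    per_spec = (
        df.groupby(["specimen_id", "year"], as_index=False)["width_um"].mean()
    )
    g = per_spec.groupby("year")["width_um"]
    pooled = pd.DataFrame(
        {"mean": g.mean(), "sd": g.std(ddof=1).fillna(0.0), "n": g.size()}
    ).reset_index()
    pooled = pooled[pooled["n"] >= min_specimens]
    if pooled.empty:
        raise ValueError(
            f"taxon {taxon!r}: no year of life reaches n >= {min_specimens} specimens"
        )
    return TaxonGrowthSeries(
        taxon=taxon,
        years=pooled["year"].to_numpy(),
        mean_width_um=pooled["mean"].to_numpy(),
        sd_width_um=pooled["sd"].to_numpy(),
        n_specimens=pooled["n"].to_numpy(),
        mass_g=mass_g,
    )
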
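"""Histogram-intersection similarity networks from regional GMV samples.

One subject's modulated gray-matter-volume (GMV) voxel values, grouped into 90
atlas regions, are turned into a symmetric 90x90 similarity matrix. Each
region's value distribution is summarised as a normalized 25-bin histogram and
the edge between regions i and j is the histogram intersection

    s_ij = sum_k min(h_i(k), h_j(k)) / sum_k h_i(k),

which equals ``sum_k min`` for normalized histograms, is symmetric and lies in
[0, 1] (1 = identical distributions, 0 = disjoint support).

The binning range is not uniquely determined by the method, so two policies
are provided: ``"pair-pooled"`` (default; per pair, 25 equal-width bins
spanning the pooled min..max of the two regions' values, matching the pairwise
histogram-distance framing) and ``"subject-global"`` (one shared range across
all 90 regions). Bins are half-open with the last bin closed, the numpy
convention, so total mass is always 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionalHistogram",
    "build_histogram",
    "histogram_intersection",
    "build_similarity_matrix",
    "extract_region_values",
    "write_similarity_matrix",
    "read_similarity_matrix",
]

N_BINS = 25

BINNING_POLICIES = ("pair-pooled", "subject-global")


@dataclass(frozen=True)
class RegionalHistogram:
    """Normalized histogram of one region's voxel-wise GMV distribution."""

    region_index: int
    bin_edges: np.ndarray  # (n_bins + 1,), strictly increasing
    masses: np.ndarray     # (n_bins,), non-negative, sums to 1

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        masses = np.asarray(self.masses, dtype=float)
        if edges.ndim != 1 or masses.ndim != 1 or edges.size != masses.size + 1:
            raise ValueError("bin_edges must have one more entry than masses")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(masses < 0) or not np.isfinite(masses).all():
            raise ValueError("histogram masses must be finite and non-negative")
        total = masses.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"histogram masses must sum to 1, got {total!r}")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "masses", masses)

    @property
    def n_bins(self) -> int:
        return self.masses.size


def build_histogram(values, n_bins: int = N_BINS, edges=None,
                    region_index: int = 0) -> RegionalHistogram:
    """Bin GMV values into a normalized histogram.

    Parameters
    ----------
    values : array-like
        Finite voxel values (>= 1 required).
    n_bins : int
        Number of equal-width bins (default 25).
    edges : array-like of length n_bins + 1, optional
        Strictly increasing bin edges spanning all values. When omitted, 25
        equal-width bins over [min(values), max(values)] are used (a single
        repeated value gets a unit-width bin around it).

    Bins are right-open except the last, which is closed, so every in-range
    value lands in exactly one bin.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot build a histogram from an empty value set")
    if not np.isfinite(v).all():
        raise ValueError("histogram input contains non-finite values")
    if edges is None:
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.asarray(edges, dtype=float)
        if edges.size != n_bins + 1:
            raise ValueError(f"expected {n_bins + 1} edges, got {edges.size}")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if v.min() < edges[0] or v.max() > edges[-1]:
            raise ValueError("values fall outside the bin-edge span")
    counts, _ = np.histogram(v, bins=edges)
    return RegionalHistogram(region_index, edges, counts / v.size)


def histogram_intersection(h_i: RegionalHistogram, h_j: RegionalHistogram) -> float:
    """Histogram-intersection similarity of two regional histograms.

    Requires identical bin edges. Returns
    ``sum_k min(h_i(k), h_j(k)) / sum_k h_i(k)``; since regional histograms are
    normalized the denominator is 1 and the result is symmetric in (i, j).
    """
    if h_i.n_bins != h_j.n_bins:
        raise ValueError("histograms have different bin counts")
    if not np.array_equal(h_i.bin_edges, h_j.bin_edges):
        raise ValueError("histograms were built on different bin edges")
    return float(np.minimum(h_i.masses, h_j.masses).sum() / h_i.masses.sum())


def _as_region_arrays(region_values) -> list[np.ndarray]:
    """Accept a SubjectMorphometry, a dict keyed 1..R, or a sequence."""
    if hasattr(region_values, "region_values"):
        region_values = region_values.region_values
    if isinstance(region_values, dict):
        keys = sorted(region_values)
        region_values = [region_values[k] for k in keys]
    arrays = [np.asarray(v, dtype=float).ravel() for v in region_values]
    for r, a in enumerate(arrays, start=1):
        if a.size < 2:
            raise ValueError(f"region {r}: needs at least 2 values")
        if not np.isfinite(a).all() or (a < 0).any():
            raise ValueError(f"region {r}: values must be finite and non-negative")
    return arrays


def build_similarity_matrix(region_values, binning_policy: str = "pair-pooled",
                            n_bins: int = N_BINS, trim: tuple | None = None) -> np.ndarray:
    """Build the symmetric RxR histogram-intersection similarity matrix.

    Parameters
    ----------
    region_values : SubjectMorphometry, dict or sequence of 1-D arrays
        Per-region voxel GMV samples.
    binning_policy : {"pair-pooled", "subject-global"}
        Range policy for the 25 equal-width bins (see module docstring).
    trim : (low_pct, high_pct), optional
        Percentile trim applied per region before binning (off by default; no
        outlier trimming is assumed in the upstream morphometry).

    Returns
    -------
    (R, R) float array, symmetric, off-diagonal entries in [0, 1], diagonal 1.
    """
    if binning_policy not in BINNING_POLICIES:
        raise ValueError(f"unknown binning policy {binning_policy!r}; "
                         f"choose from {BINNING_POLICIES}")
    arrays = _as_region_arrays(region_values)
    if trim is not None:
        lo_p, hi_p = trim
        trimmed = []
        for a in arrays:
            lo, hi = np.percentile(a, [lo_p, hi_p])
            keep = a[(a >= lo) & (a <= hi)]
            trimmed.append(keep if keep.size >= 2 else a)
        arrays = trimmed
    n_reg = len(arrays)
    mins = np.array([a.min() for a in arrays])
    maxs = np.array([a.max() for a in arrays])

    if binning_policy == "subject-global":
        lo, hi = mins.min(), maxs.max()
        edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else None
        hists = np.empty((n_reg, n_bins))
        for r, a in enumerate(arrays):
            if edges is None:
                hists[r] = 0.0
                hists[r, 0] = 1.0
            else:
                hists[r] = np.histogram(a, bins=edges)[0] / a.size
        sim = np.minimum(hists[:, None, :], hists[None, :, :]).sum(axis=2)
        np.fill_diagonal(sim, 1.0)
        return sim

    # pair-pooled: region i's histogram depends on the partner j, so build the
    # (R, R, n_bins) tensor H[i, j] = hist of region i on pair (i, j) edges.
    pair_lo = np.minimum(mins[:, None], mins[None, :])
    pair_hi = np.maximum(maxs[:, None], maxs[None, :])
    width = pair_hi - pair_lo
    H = np.empty((n_reg, n_reg, n_bins))
    offsets = np.arange(n_reg) * n_bins
    for i, a in enumerate(arrays):
        w = width[i]
        safe_w = np.where(w > 0, w, 1.0)
        # same bin assignment as np.histogram with equal-width edges: floor of
        # the scaled position, top edge folded into the last (closed) bin
        idx = ((a[:, None] - pair_lo[i]) / safe_w * n_bins).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)
        idx[:, w == 0] = 0
        counts = np.bincount((idx + offsets).ravel(), minlength=n_reg * n_bins)
        H[i] = counts.reshape(n_reg, n_bins) / a.size
    sim = np.minimum(H, H.transpose(1, 0, 2)).sum(axis=2)
    np.fill_diagonal(sim, 1.0)
    return sim


def extract_region_values(gm_volume, atlas_labels, n_regions: int = 90) -> dict:
    """Collect per-region voxel value multisets from a labeled volume.

    ``gm_volume`` and ``atlas_labels`` are 3-D arrays (or nibabel images, or
    paths to NIfTI files) on the same voxel grid; atlas labels are integers in
    {0} U {1..n_regions}, 0 meaning background. Returns ``{label: 1-D array}``
    for every label 1..n_regions; an empty region is an error.
    """
    gm = _as_volume(gm_volume)
    atlas = _as_volume(atlas_labels)
    if gm.shape != atlas.shape:
        raise ValueError(f"shape mismatch: GM volume {gm.shape} vs atlas {atlas.shape}")
    labels = np.unique(atlas)
    if labels.min() < 0 or labels.max() > n_regions:
        raise ValueError(f"atlas labels must lie in 0..{n_regions}, "
                         f"found {labels.min()}..{labels.max()}")
    if np.any(atlas != np.round(atlas)):
        raise ValueError("atlas labels must be integers")
    out = {}
    flat_gm = np.asarray(gm, dtype=float).ravel()
    flat_atlas = np.asarray(atlas).ravel().astype(int)
    for r in range(1, n_regions + 1):
        vals = flat_gm[flat_atlas == r]
        if vals.size == 0:
            raise ValueError(f"empty region: atlas label {r} has no voxels")
        out[r] = vals
    return out


def _as_volume(obj) -> np.ndarray:
    if isinstance(obj, (str,)) or hasattr(obj, "__fspath__"):
        import nibabel as nib

        obj = nib.load(obj)
    if hasattr(obj, "get_fdata"):
        obj = obj.get_fdata()
    arr = np.asarray(obj)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {arr.shape}")
    return arr


def write_similarity_matrix(matrix: np.ndarray, path, labels=None) -> None:
    """Write a similarity matrix as TSV with region labels as header row/col."""
    import pandas as pd

    matrix = np.asarray(matrix, dtype=float)
    if labels is None:
        from .regions import aal90_table

        labels = (list(aal90_table()["abbreviation"]) if matrix.shape[0] == 90
                  else [f"R{i}" for i in range(1, matrix.shape[0] + 1)])
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.17g")


def read_similarity_matrix(path):
    """Read a matrix written by :func:`write_similarity_matrix`.

    Returns ``(matrix, labels)``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), list(df.columns)
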
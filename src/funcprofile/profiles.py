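"""Pattern classes in segment (mean, SD) space and per-subject function
profiles.

The feature space is the rectangle [0, M] x [0, S], where M and S are
the maximum segment mean and SD over a reference segment set.  It is
partitioned into half-open cells [i*w, (i+1)*w) x [j*w, (j+1)*w) of a
single interval width w on both axes; the top cell on each axis is
closed above so that M and S themselves are representable.  A segment
is an instance of the cell its (mean, SD) falls in.

A subject's function profile is the length-J vector of average minutes
per day spent in each pattern class over the subject's valid days:
a_j = (1/K) * sum_k t_jk, with t_jk the minutes in class j on day k.
Because every wear minute of a valid day lies in exactly one segment
and every segment in exactly one class, the profile entries sum to the
subject's mean daily wear minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PatternClassGrid:
    """Partition of (mean, SD) space into width-w rectangular classes."""

    interval_width: float
    max_mean: float   # M over the reference segment set
    max_sd: float     # S over the reference segment set
    n_mean_bins: int
    n_sd_bins: int

    @property
    def n_classes(self) -> int:
        return self.n_mean_bins * self.n_sd_bins

    def class_label(self, mean_bin: int, sd_bin: int) -> str:
        w = self.interval_width
        return (
            f"m{_fmt(mean_bin * w)}_{_fmt((mean_bin + 1) * w)}"
            f"_s{_fmt(sd_bin * w)}_{_fmt((sd_bin + 1) * w)}"
        )

    @property
    def labels(self) -> list[str]:
        return [
            self.class_label(i, j)
            for i in range(self.n_mean_bins)
            for j in range(self.n_sd_bins)
        ]

    def flat_index(self, mean_bin: int, sd_bin: int) -> int:
        return mean_bin * self.n_sd_bins + sd_bin


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def build_grid(segments: pd.DataFrame, interval_width: float) -> PatternClassGrid:
    """Grid from a reference (training) segment collection.

    M and S are maxima of the reference segments' means and SDs; bin
    counts are floor(M/w)+1 so the maxima land in the top bins.
    """
    if interval_width <= 0:
        raise ValueError("interval_width must be positive")
    if len(segments) == 0:
        raise ValueError("cannot build a grid from an empty segment set")
    max_mean = float(segments["mean"].max())
    max_sd = float(segments["sd"].max())
    w = float(interval_width)
    return PatternClassGrid(
        interval_width=w,
        max_mean=max_mean,
        max_sd=max_sd,
        n_mean_bins=int(max_mean // w) + 1,
        n_sd_bins=int(max_sd // w) + 1,
    )


def assign_class(mean, sd, grid: PatternClassGrid):
    """(mean-bin, sd-bin) of a segment; vectorized over array inputs.

    Values beyond the reference maxima (possible when the grid was
    built on training segments only) clip to the top bins.
    """
    mean = np.asarray(mean, dtype=np.float64)
    sd = np.asarray(sd, dtype=np.float64)
    if (mean < 0).any() or (sd < 0).any():
        raise ValueError("segment mean and sd must be nonnegative")
    w = grid.interval_width
    mb = np.minimum(np.floor(mean / w).astype(np.int64), grid.n_mean_bins - 1)
    sb = np.minimum(np.floor(sd / w).astype(np.int64), grid.n_sd_bins - 1)
    if mb.ndim == 0:
        return int(mb), int(sb)
    return mb, sb


def function_profile(
    segments: pd.DataFrame, grid: PatternClassGrid, n_valid_days: int
) -> np.ndarray:
    """Average daily minutes per pattern class for one subject.

    ``segments`` holds the subject's segments on valid days; days with
    no segments contribute zeros through the division by K.
    """
    if n_valid_days < 1:
        raise ValueError("subject has no valid days; exclude upstream")
    a = np.zeros(grid.n_classes, dtype=np.float64)
    if len(segments):
        mb, sb = assign_class(
            segments["mean"].to_numpy(), segments["sd"].to_numpy(), grid
        )
        flat = mb * grid.n_sd_bins + sb
        np.add.at(a, flat, segments["duration"].to_numpy(dtype=np.float64))
    return a / n_valid_days


def profile_table(
    segments: pd.DataFrame,
    grid: PatternClassGrid,
    valid_days: pd.Series,
) -> pd.DataFrame:
    """Profiles for all subjects as one row each.

    ``valid_days`` maps subject_id -> K; subjects with K = 0 are
    excluded.  Columns: subject_id, K, then one column per class.
    """
    rows = []
    ids = []
    ks = []
    by_subject = dict(tuple(segments.groupby("subject_id", sort=True)))
    for sid, k in valid_days.sort_index().items():
        if k < 1:
            continue
        segs = by_subject.get(sid, segments.iloc[0:0])
        rows.append(function_profile(segs, grid, int(k)))
        ids.append(sid)
        ks.append(int(k))
    out = pd.DataFrame(rows, columns=grid.labels)
    out.insert(0, "K", ks)
    out.insert(0, "subject_id", ids)
    return out


def drop_sparse_classes(
    profiles: pd.DataFrame, min_support: int = 10
) -> pd.DataFrame:
    """Drop profile columns with fewer than ``min_support`` subjects
    having nonzero time; smooth estimation needs support."""
    keep = []
    for col in profiles.columns:
        if col in ("subject_id", "K"):
            keep.append(col)
            continue
        if int((profiles[col] > 0).sum()) >= min_support:
            keep.append(col)
    return profiles[keep]


def chebyshev_bounds(
    mean_interval: tuple[float, float],
    sd_interval: tuple[float, float],
    k: float,
) -> tuple[float, float, float]:
    """Chebyshev tail bound for the counts of a pattern class.

    With mu and sigma the midinterval values of the class's mean and SD
    intervals, P(|X - mu| > k*sigma) < 1/k^2, so at least 1 - 1/k^2 of
    the counts lie in (mu - k*sigma, mu + k*sigma).  Returns the two
    endpoints and the probability lower bound.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    mu = 0.5 * (mean_interval[0] + mean_interval[1])
    sigma = 0.5 * (sd_interval[0] + sd_interval[1])
    return mu - k * sigma, mu + k * sigma, 1.0 - 1.0 / k**2
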
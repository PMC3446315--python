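"""CpG-density-corrected methylation scoring for MeDIP-seq.

MeDIP enrichment at a locus depends jointly on methylation and on how many
CpGs the fragment can present to the antibody, so raw read density
overstates methylation in CpG-dense regions.  This module implements the
standard correction: tile the genome in overlapping bins (500 bp, 250 bp
step), count reads per bin, compute a *coupling factor* CF (CpGs within a
maximal distance of the bin), fit a calibration curve of mean signal vs CF
over its ascending range, and score each bin by its signal relative to the
CF-expected signal, scaled into [0, 1] (the *relative methylation score*,
rms).

The transform is a self-contained analog of the MEDIPS procedure (linear
fit on the ascending calibration range, ratio-to-expected, 99th-percentile
scaling); bit-compatibility with MEDIPS is not promised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("medipkit")

DEFAULT_BIN_SIZE = 500
DEFAULT_STEP = 250
DEFAULT_MAX_DISTANCE = 500
EPS = 1e-6


# ---------------------------------------------------------------------------
# Bin grid
# ---------------------------------------------------------------------------

@dataclass
class BinGrid:
    """Overlapping bins tiling each chromosome with a fixed step.

    Bins start at 0, step, 2*step, ...; each bin is
    [s, min(s + bin_size, L)).  ``offsets`` gives the slice of the flat
    arrays belonging to each chromosome.
    """

    chroms: list
    chrom_lengths: dict
    bin_size: int
    step: int
    starts: np.ndarray
    ends: np.ndarray
    bin_chrom_index: np.ndarray  # per-bin index into chroms
    offsets: dict = field(repr=False)  # chrom -> (lo, hi) slice into flat arrays

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def chrom_slice(self, chrom: str) -> slice:
        lo, hi = self.offsets[chrom]
        return slice(lo, hi)

    def bin_ids(self) -> list:
        chroms = np.asarray(self.chroms, dtype=object)[self.bin_chrom_index]
        return [f"{c}:{s}-{e}" for c, s, e in zip(chroms, self.starts, self.ends)]


def make_bins(
    chrom_lengths: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    step: int = DEFAULT_STEP,
) -> BinGrid:
    """Tile every chromosome with overlapping bins."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not 0 < step <= bin_size:
        raise ValueError(
            f"step ({step}) must satisfy 0 < step <= bin_size ({bin_size}); "
            "a larger step would leave gaps"
        )
    chroms = list(chrom_lengths)
    starts, ends, cidx = [], [], []
    offsets = {}
    for ci, chrom in enumerate(chroms):
        L = int(chrom_lengths[chrom])
        s = np.arange(0, max(L, 1), step, dtype=np.int64)
        s = s[s < L]
        if len(s) == 0:
            s = np.array([0], dtype=np.int64)
        e = np.minimum(s + bin_size, L)
        lo = sum(len(x) for x in starts)
        offsets[chrom] = (lo, lo + len(s))
        starts.append(s)
        ends.append(e)
        cidx.append(np.full(len(s), ci, dtype=np.int64))
    return BinGrid(
        chroms=chroms,
        chrom_lengths=dict(chrom_lengths),
        bin_size=bin_size,
        step=step,
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        bin_chrom_index=np.concatenate(cidx),
        offsets=offsets,
    )


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------

def count_reads_in_bins(reads: pd.DataFrame, grid: BinGrid) -> tuple[np.ndarray, int]:
    """Count reads per bin by the midpoint rule.

    Each read is assigned to every bin containing its midpoint, so on the
    half-overlapping grid a read contributes to at most bin_size/step bins
    and is never counted twice within the non-overlapping half-grid.

    Returns (counts per bin, number of reads skipped as off-chromosome).
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    n_skipped = 0
    for chrom, sub in reads.groupby("chrom"):
        if chrom not in grid.offsets:
            n_skipped += len(sub)
            continue
        lo, hi = grid.offsets[chrom]
        L = grid.chrom_lengths[chrom]
        mid = (sub["start"].to_numpy(np.int64) + sub["end"].to_numpy(np.int64)) // 2
        ok = (mid >= 0) & (mid < L)
        n_skipped += int((~ok).sum())
        mid = mid[ok]
        n_chrom_bins = hi - lo
        # bins with start s = k*step satisfying s <= mid < s + bin_size
        k_hi = mid // grid.step
        k_lo = np.maximum((mid - grid.bin_size) // grid.step + 1, 0)
        max_span = grid.bin_size // grid.step + 1
        for off in range(max_span):
            k = k_hi - off
            sel = (k >= k_lo) & (k >= 0) & (k < n_chrom_bins)
            if sel.any():
                np.add.at(counts, lo + k[sel], 1)
    if n_skipped:
        logger.warning("count_reads_in_bins: skipped %d off-chromosome reads", n_skipped)
    return counts, n_skipped


def rpm(counts: np.ndarray, total: float | None = None) -> np.ndarray:
    """Reads per million: count * 1e6 / total library count."""
    total = float(counts.sum()) if total is None else float(total)
    if total <= 0:
        return np.zeros_like(counts, dtype=float)
    return counts * 1e6 / total


# ---------------------------------------------------------------------------
# Coupling factor
# ---------------------------------------------------------------------------

def coupling_factor(
    grid: BinGrid,
    cpg_positions: Mapping[str, np.ndarray],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> np.ndarray:
    """CpG count within ``max_distance`` of each bin.

    CF(bin) = #{CpG positions p : bin.start - max_distance <= p <
    bin.end + max_distance}.  With max_distance 0 this reduces to CpGs
    inside the bin.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    cf = np.zeros(grid.n_bins, dtype=np.int64)
    for chrom, (lo, hi) in grid.offsets.items():
        pos = np.asarray(cpg_positions.get(chrom, ()), dtype=np.int64)
        if len(pos) == 0:
            continue
        s = grid.starts[lo:hi] - max_distance
        e = grid.ends[lo:hi] + max_distance
        cf[lo:hi] = np.searchsorted(pos, e, side="left") - np.searchsorted(pos, s, side="left")
    return cf


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Mean signal vs integer CF level over the ascending range.

    ``levels``/``mean_rpm`` hold the (pooled) calibration points up to the
    level of maximal mean signal (cf_hi, the ascending portion).  A
    least-squares line ``intercept + slope * CF`` over the same range
    validates the CpG dependence (the slope must be positive for
    normalization to be meaningful) and summarizes the curve; the expected
    signal used for scoring interpolates the empirical calibration points,
    since the capture efficiency saturates with CpG density and a straight
    line would leave a systematic density-dependent residual.
    """

    intercept: float
    slope: float
    cf_lo: float
    cf_hi: float
    levels: np.ndarray
    mean_rpm: np.ndarray

    def expected(self, cf: np.ndarray) -> np.ndarray:
        """CF-expected signal: interpolated calibration curve, constant
        beyond [cf_lo, cf_hi] (CF above the fit range is capped)."""
        sel = self.levels <= self.cf_hi
        return np.interp(
            np.minimum(cf, self.cf_hi), self.levels[sel], self.mean_rpm[sel]
        )

    def linear_expected(self, cf: np.ndarray) -> np.ndarray:
        """The fitted straight line (diagnostic summary of the curve)."""
        return self.intercept + self.slope * np.minimum(cf, self.cf_hi)


def calibration_curve(
    rpm_values: np.ndarray,
    cf: np.ndarray,
    min_bins_per_level: int = 10,
) -> CalibrationCurve:
    """Fit the signal-vs-CpG-density calibration curve.

    CF values are rounded to integer levels; sparse adjacent levels (fewer
    than ``min_bins_per_level`` bins) are pooled.  The least-squares line is
    fitted over levels from CF >= 1 up to the level of maximal mean signal.
    Raises if fewer than two usable levels remain or the slope is not
    positive (no CpG dependence: normalization would be meaningless).
    """
    rpm_values = np.asarray(rpm_values, dtype=float)
    levels_int = np.rint(np.asarray(cf, dtype=float)).astype(np.int64)
    keep = levels_int >= 1
    if keep.sum() == 0:
        raise ValueError("calibration_curve: no bins with CF >= 1")
    uniq, inv = np.unique(levels_int[keep], return_inverse=True)
    sums = np.bincount(inv, weights=rpm_values[keep])
    cnts = np.bincount(inv)

    # pool adjacent sparse levels (ascending) until each point has enough bins
    pooled_level, pooled_mean, pooled_n = [], [], []
    acc_s = acc_c = acc_lc = 0.0
    for lv, s, c in zip(uniq, sums, cnts):
        acc_s += s
        acc_c += c
        acc_lc += lv * c
        if acc_c >= min_bins_per_level:
            pooled_level.append(acc_lc / acc_c)
            pooled_mean.append(acc_s / acc_c)
            pooled_n.append(acc_c)
            acc_s = acc_c = acc_lc = 0.0
    if acc_c > 0 and pooled_level:
        # fold the trailing remainder into the last point
        n_prev = pooled_n[-1]
        pooled_level[-1] = (pooled_level[-1] * n_prev + acc_lc) / (n_prev + acc_c)
        pooled_mean[-1] = (pooled_mean[-1] * n_prev + acc_s) / (n_prev + acc_c)
        pooled_n[-1] = n_prev + acc_c
    levels = np.asarray(pooled_level, dtype=float)
    means = np.asarray(pooled_mean, dtype=float)
    if len(levels) < 2:
        raise ValueError(
            f"calibration_curve: only {len(levels)} usable CF level(s); "
            "need >= 2"
        )
    i_max = int(np.argmax(means))
    if i_max == 0:
        raise ValueError("calibration_curve: mean signal is maximal at the "
                         "lowest CF level; no ascending range to fit")
    fit_l = levels[: i_max + 1]
    fit_m = means[: i_max + 1]
    slope, intercept = np.polyfit(fit_l, fit_m, 1)
    if slope <= 0:
        raise ValueError(
            "calibration_curve: non-positive slope; signal shows no CpG "
            "dependence, coupling-factor normalization is meaningless"
        )
    return CalibrationCurve(
        intercept=float(intercept),
        slope=float(slope),
        cf_lo=float(fit_l[0]),
        cf_hi=float(fit_l[-1]),
        levels=levels,
        mean_rpm=means,
    )


# ---------------------------------------------------------------------------
# Relative methylation score
# ---------------------------------------------------------------------------

def rms_normalize(
    rpm_values: np.ndarray,
    cf: np.ndarray,
    calib: CalibrationCurve,
    quantile: float = 0.99,
    eps: float = EPS,
) -> np.ndarray:
    """CpG-density-corrected relative methylation score in [0, 1].

    raw = rpm / max(eps, expected signal at min(CF, CF_hi));
    rms = min(raw / Q(raw), 1) with Q the ``quantile`` (default 99th
    percentile, robust to outliers) over bins with CF > 0.  Bins with
    CF = 0 get NaN: with no CpGs no MeDIP signal is expected, so the score
    is undefined there.
    """
    rpm_values = np.asarray(rpm_values, dtype=float)
    cf = np.asarray(cf, dtype=float)
    expected = np.maximum(calib.expected(cf), eps)
    raw = rpm_values / expected
    valid = cf > 0
    rms = np.full(len(raw), np.nan)
    if valid.any():
        q = np.quantile(raw[valid], quantile)
        if q <= 0:
            rms[valid] = 0.0
        else:
            rms[valid] = np.minimum(raw[valid] / q, 1.0)
    return rms


def normalize_counts(
    counts: np.ndarray,
    cf: np.ndarray,
    min_bins_per_level: int = 10,
    quantile: float = 0.99,
) -> tuple[np.ndarray, np.ndarray, CalibrationCurve]:
    """Convenience path: counts -> (rpm, rms, calibration) for one sample."""
    r = rpm(counts)
    calib = calibration_curve(r, cf, min_bins_per_level)
    return r, rms_normalize(r, cf, calib, quantile), calib


# ---------------------------------------------------------------------------
# bedGraph output
# ---------------------------------------------------------------------------

def step_window_values(scores: np.ndarray, grid: BinGrid) -> dict:
    """Per-chromosome values on the non-overlapping step windows.

    Each step window [k*step, (k+1)*step) is covered by up to
    bin_size/step overlapping bins; its value is the nan-mean of those bin
    scores (NaN when all covering bins are flagged missing).
    """
    out = {}
    span = grid.bin_size // grid.step  # bins overlapping one step window
    for chrom, (lo, hi) in grid.offsets.items():
        vals = scores[lo:hi]
        L = grid.chrom_lengths[chrom]
        n_win = int(np.ceil(L / grid.step))
        acc = np.zeros(n_win)
        cnt = np.zeros(n_win)
        for b in range(hi - lo):
            v = vals[b]
            if np.isnan(v):
                continue
            w_lo = b
            w_hi = min(b + span, n_win)
            acc[w_lo:w_hi] += v
            cnt[w_lo:w_hi] += 1
        win = np.full(n_win, np.nan)
        nz = cnt > 0
        win[nz] = acc[nz] / cnt[nz]
        out[chrom] = win
    return out


def write_bedgraph(scores: np.ndarray, grid: BinGrid, path) -> None:
    """Write scores as a bedGraph track on non-overlapping step windows.

    Adjacent windows with equal values are merged into one line; windows
    whose covering bins are all missing are omitted.
    """
    windows = step_window_values(scores, grid)
    with open(path, "w") as fh:
        for chrom in grid.chroms:
            win = windows[chrom]
            L = grid.chrom_lengths[chrom]
            run_start = None
            run_val = None
            for k, v in enumerate(win):
                s = k * grid.step
                e = min(s + grid.step, L)
                if np.isnan(v):
                    if run_start is not None:
                        fh.write(f"{chrom}\t{run_start}\t{s}\t{run_val:g}\n")
                        run_start = None
                    continue
                if run_start is None:
                    run_start, run_val = s, v
                elif v != run_val:
                    fh.write(f"{chrom}\t{run_start}\t{s}\t{run_val:g}\n")
                    run_start, run_val = s, v
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{L}\t{run_val:g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph file into a DataFrame (chrom, start, end, value)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, v = line.split("\t")
            rows.append((c, int(s), int(e), float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
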
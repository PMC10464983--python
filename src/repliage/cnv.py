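"""Sliding-window copy-number quantification from genome resequencing.

Reads are counted in overlapping windows (genome default 25 kb spaced
every 5 kb; rDNA default 1 kb spaced every 200 bp), windows overlapping
exclusion masks (Ty elements/LTRs, mitochondrial DNA, ENA and CUP1 loci)
are dropped from all statistics, size factors are estimated by
median-of-ratios over unmasked windows outside the rDNA zone, and
aged/reference ratio tracks are reported per window.  A read is assigned
to every window containing its start position.  Coordinates are 1-based
inclusive internally; BED input is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOME_WINDOW = 25_000
GENOME_STEP = 5_000
RDNA_WINDOW = 1_000
RDNA_STEP = 200


class CNVError(ValueError):
    pass


def make_windows(
    chrom_sizes: dict[str, int],
    size: int = GENOME_WINDOW,
    step: int = GENOME_STEP,
) -> pd.DataFrame:
    """Sliding windows at starts 1, 1+step, ... fully inside each chromosome.

    Chromosomes shorter than *size* contribute zero windows (warned).
    """
    if not (size >= step > 0):
        raise CNVError("require size >= step > 0")
    frames = []
    for chrom, length in chrom_sizes.items():
        if length < size:
            logger.warning("chromosome %s (length %d) shorter than window "
                           "size %d; no windows", chrom, length, size)
            continue
        starts = np.arange(1, length - size + 2, step, dtype=int)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + size - 1,
        }))
    if not frames:
        windows = pd.DataFrame(columns=["chrom", "start", "end"])
        windows["masked"] = pd.Series(dtype=bool)
        return windows
    windows = pd.concat(frames, ignore_index=True)
    windows["masked"] = False
    return windows


def read_bed(path: str) -> pd.DataFrame:
    """BED3 intervals converted to 1-based inclusive (chrom, start, end)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"],
                      dtype={0: str})
    bed["start"] = bed["start"].astype(int) + 1
    bed["end"] = bed["end"].astype(int)
    return bed


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """1-based inclusive intervals written as BED3 (0-based half-open)."""
    out = intervals.copy()
    out["start"] = out["start"] - 1
    out[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                          index=False)


def apply_masks(windows: pd.DataFrame, masks: pd.DataFrame) -> pd.DataFrame:
    """Mark windows overlapping any mask interval by >= 1 bp as masked.

    *masks* has 1-based inclusive chrom/start/end rows (see
    :func:`read_bed` for BED input).
    """
    out = windows.copy()
    if masks is None or len(masks) == 0:
        return out
    masked = out["masked"].values.copy()
    for chrom, group in masks.groupby("chrom"):
        sel = out["chrom"] == chrom
        if not sel.any():
            continue
        w_start = out.loc[sel, "start"].values
        w_end = out.loc[sel, "end"].values
        hit = np.zeros(len(w_start), bool)
        for m_start, m_end in zip(group["start"].values, group["end"].values):
            hit |= (w_start <= m_end) & (w_end >= m_start)
        masked[np.flatnonzero(sel.values)] |= hit
    out["masked"] = masked
    return out


def count_reads(windows: pd.DataFrame, reads: pd.DataFrame) -> pd.Series:
    """Count read start positions per window (one sample).

    *reads* has columns ``chrom`` and ``pos`` (1-based start positions).
    A read is counted in every window containing its start, so
    overlapping windows each count it.  Reads on chromosomes absent from
    the window set are skipped (logged with a count).
    """
    counts = np.zeros(len(windows), dtype=int)
    known = set(windows["chrom"].unique())
    skipped = 0
    for chrom, group in reads.groupby("chrom"):
        if chrom not in known:
            skipped += len(group)
            continue
        pos = np.sort(group["pos"].values.astype(int))
        sel = (windows["chrom"] == chrom).values
        starts = windows.loc[sel, "start"].values
        ends = windows.loc[sel, "end"].values
        counts[sel] = (np.searchsorted(pos, ends, side="right")
                       - np.searchsorted(pos, starts, side="left"))
    if skipped:
        # routine when the window set covers a sub-region (e.g. rDNA track)
        logger.debug("count_reads: skipped %d reads on chromosomes without "
                     "windows", skipped)
    return pd.Series(counts, index=windows.index, name="count")


@dataclass
class WindowTrack:
    """Windows plus per-sample raw counts, normalised counts and ratios."""
    windows: pd.DataFrame
    counts: pd.DataFrame                      # windows x samples, raw
    normalized: pd.DataFrame | None = None
    ratios: pd.DataFrame | None = None        # vs the reference sample
    size_factors: pd.Series | None = None
    reference: str | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_reads(cls, windows: pd.DataFrame,
                   reads_by_sample: dict[str, pd.DataFrame]) -> "WindowTrack":
        counts = pd.DataFrame(
            {name: count_reads(windows, reads) for name, reads in
             reads_by_sample.items()})
        return cls(windows=windows.copy(), counts=counts)


def _window_overlaps_region(windows: pd.DataFrame, region) -> np.ndarray:
    chrom, lo, hi = region
    return ((windows["chrom"] == chrom)
            & (windows["start"] <= hi) & (windows["end"] >= lo)).values


def normalize_and_ratio(
    track: WindowTrack,
    reference_sample: str,
    rdna_region: tuple | None = None,
) -> WindowTrack:
    """Size-factor normalise window counts and compute ratios to reference.

    Size factors are median-of-ratios estimated over unmasked windows
    excluding any overlapping the rDNA zone, so copy-neutral windows
    anchor the factors and genuine amplifications (rDNA, ChrXIIr) survive
    normalisation.  Masked windows get no normalised value; windows with
    zero reference counts get an undefined (NaN) ratio.
    """
    if reference_sample not in track.counts.columns:
        raise CNVError(f"reference sample {reference_sample!r} not in track")
    windows = track.windows
    eligible = ~windows["masked"].values
    if rdna_region is not None:
        eligible &= ~_window_overlaps_region(windows, rdna_region)
    sub = track.counts.values[eligible].astype(float)
    positive = (sub > 0).all(axis=1)
    if not positive.any():
        raise CNVError("no unmasked window has nonzero counts in all samples")
    logs = np.log(sub[positive])
    log_ref = logs.mean(axis=1)
    factors = pd.Series(
        np.exp(np.median(logs - log_ref[:, None], axis=0)),
        index=track.counts.columns, name="size_factor")

    normalized = track.counts / factors
    normalized[windows["masked"].values] = np.nan
    ref = normalized[reference_sample]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = normalized.div(ref, axis=0)
    ratios[ref <= 0] = np.nan
    n_undef = int((eligible & (track.counts[reference_sample].values == 0)).sum())
    if n_undef:
        logger.warning("normalize_and_ratio: %d unmasked windows have zero "
                       "reference counts; ratios undefined", n_undef)
    return WindowTrack(windows=windows.copy(), counts=track.counts.copy(),
                       normalized=normalized, ratios=ratios,
                       size_factors=factors, reference=reference_sample,
                       meta=dict(track.meta))


def region_median_ratio(track: WindowTrack, sample: str, region,
                        contained: bool = True) -> float:
    """Median ratio for *sample* over windows in a (chrom, start, end) region.

    With ``contained`` (default) only windows fully inside the region
    count; otherwise any overlapping window does.
    """
    if track.ratios is None:
        raise CNVError("track has no ratios; run normalize_and_ratio first")
    chrom, lo, hi = region
    w = track.windows
    if contained:
        sel = ((w["chrom"] == chrom) & (w["start"] >= lo)
               & (w["end"] <= hi)).values
    else:
        sel = _window_overlaps_region(w, region)
    sel &= ~w["masked"].values
    vals = track.ratios.loc[sel, sample].dropna()
    if len(vals) == 0:
        raise CNVError(f"no usable windows in region {region}")
    return float(vals.median())


def rdna_track(
    reads_by_sample: dict[str, pd.DataFrame],
    rdna_region: tuple,
    genome_track: WindowTrack | None = None,
    size: int = RDNA_WINDOW,
    step: int = RDNA_STEP,
    reference_sample: str | None = None,
) -> WindowTrack:
    """rDNA-zone window track (1 kb / 200 bp default) with ratios.

    Size factors are taken from an already-normalised genome-wide track
    when given (they are estimated from non-rDNA windows there);
    otherwise raw library totals outside the rDNA are used.
    """
    chrom, lo, hi = rdna_region
    if hi - lo + 1 < size:
        raise CNVError("rDNA region shorter than the window size")
    starts = np.arange(lo, hi - size + 2, step, dtype=int)
    windows = pd.DataFrame({"chrom": chrom, "start": starts,
                            "end": starts + size - 1})
    windows["masked"] = False
    track = WindowTrack.from_reads(windows, reads_by_sample)
    if genome_track is not None and genome_track.size_factors is not None:
        factors = genome_track.size_factors.reindex(track.counts.columns)
        reference_sample = reference_sample or genome_track.reference
    else:
        totals = {
            name: float(((reads["chrom"] != chrom)
                         | (reads["pos"] < lo) | (reads["pos"] > hi)).sum())
            for name, reads in reads_by_sample.items()}
        totals = pd.Series(totals)
        factors = totals / np.exp(np.mean(np.log(totals)))
    if reference_sample is None:
        raise CNVError("reference_sample required")
    normalized = track.counts / factors
    ref = normalized[reference_sample]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = normalized.div(ref, axis=0)
    ratios[ref <= 0] = np.nan
    return WindowTrack(windows=windows, counts=track.counts,
                       normalized=normalized, ratios=ratios,
                       size_factors=pd.Series(factors), reference=reference_sample)


def write_ratio_tsv(track: WindowTrack, path: str) -> None:
    """bedGraph-style TSV of per-window ratios (one column per sample)."""
    if track.ratios is None:
        raise CNVError("track has no ratios")
    out = pd.concat([track.windows, track.ratios.add_prefix("ratio_")], axis=1)
    out.to_csv(path, sep="\t", index=False)
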
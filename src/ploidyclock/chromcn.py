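"""Chromosome-level copy-number screening from low-pass binned coverage.

Workflow (mirrors reference-normalised low-pass CNV screening of
near-tetraploid clones): per-bin sample/reference count ratios are
median-scaled so the genome-wide median maps to the baseline ploidy
(default 4), rounded half-up to integer copy number, lightly smoothed
and segmented into runs, and each chromosome is summarised by its
modal copy number — the integer state occupying the greatest summed
base-pair length. A clone's karyotype is compared to a reference
clone's chromosome by chromosome; any modal difference counts as one
chromosomal alteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .exceptions import ValidationError

DEFAULT_BASELINE_PLOIDY = 4
DEFAULT_MIN_SEG_BINS = 10
SMOOTH_WINDOW_BINS = 5


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer, halves away from zero toward +inf."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass
class ChromCNReport:
    """Per-chromosome modal copy numbers for one clone."""

    sample_id: str
    modal_cn: dict[str, int]
    baseline_ploidy: int = DEFAULT_BASELINE_PLOIDY
    altered: dict[str, bool] = field(default_factory=dict)

    def compare(self, reference: "ChromCNReport") -> "ChromCNReport":
        """Flag chromosomes whose modal CN differs from ``reference``."""
        if set(self.modal_cn) != set(reference.modal_cn):
            raise ValidationError("chromosome sets differ between sample and reference")
        altered = {c: self.modal_cn[c] != reference.modal_cn[c] for c in self.modal_cn}
        return ChromCNReport(self.sample_id, dict(self.modal_cn),
                             self.baseline_ploidy, altered)

    @property
    def n_altered(self) -> int:
        return sum(self.altered.values())

    def as_dict(self) -> dict:
        return {
            "sample": self.sample_id,
            "baseline_ploidy": self.baseline_ploidy,
            "modal_cn": dict(sorted(self.modal_cn.items())),
            "altered": dict(sorted(self.altered.items())),
            "n_altered": self.n_altered,
        }


def _check_shared_binning(sample: pd.DataFrame, reference: pd.DataFrame):
    key = ["chrom", "start", "end"]
    if len(sample) != len(reference) or not (
        sample[key].reset_index(drop=True).equals(reference[key].reset_index(drop=True))
    ):
        raise ValidationError("sample and reference tracks must share identical binning")


def normalize_and_call(
    sample: pd.DataFrame,
    reference: pd.DataFrame,
    baseline_ploidy: int = DEFAULT_BASELINE_PLOIDY,
) -> pd.DataFrame:
    """Per-bin integer copy number from sample/reference count ratios.

    Ratios are scaled by their genome-wide median so the typical bin
    sits at ``baseline_ploidy``, then rounded half-up (``cn``); the
    unrounded estimate is kept alongside (``cn_frac``) so segmentation
    can re-estimate copy number from many bins at once. Bins with zero
    reference count are masked (NaN) and excluded downstream.
    Scale-invariant: multiplying all sample counts by a constant does
    not change the calls. Assumes the majority of the genome sits at
    the baseline ploidy (the usual median-centering assumption).
    """
    _check_shared_binning(sample, reference)
    out = sample[["chrom", "start", "end"]].copy()
    s = sample["count"].to_numpy(dtype=float)
    r = reference["count"].to_numpy(dtype=float)
    masked = r <= 0
    ratio = np.divide(s, r, out=np.full_like(s, np.nan), where=~masked)
    if np.isnan(ratio).all():
        raise ValidationError("no usable bins: every reference bin is zero")
    scale = np.nanmedian(ratio)
    if not (scale > 0):
        raise ValidationError("non-positive median ratio; tracks incomparable")
    ok = ~np.isnan(ratio)
    if ok.mean() < 0.5:
        raise ValidationError(
            f"only {ok.mean():.0%} of bins are usable (<50%); reference track too sparse"
        )
    # refine the scale on chromosomes whose provisional modal call sits at
    # the baseline: the mean ratio there is unbiased even under skewed
    # count noise, where the genome-wide median is not
    cn0 = round_half_up(baseline_ploidy * ratio[ok] / scale)
    chroms = sample["chrom"].to_numpy()[ok]
    baseline_mask = np.zeros(ok.sum(), dtype=bool)
    for c in pd.unique(chroms):
        sel = chroms == c
        vals, counts = np.unique(cn0[sel], return_counts=True)
        if vals[np.argmax(counts)] == baseline_ploidy:
            baseline_mask |= sel
    if baseline_mask.any():
        scale = float(ratio[ok][baseline_mask].mean())
    frac = np.full_like(ratio, np.nan)
    frac[ok] = np.maximum(baseline_ploidy * ratio[ok] / scale, 0.0)
    cn = np.full_like(ratio, np.nan)
    cn[ok] = round_half_up(frac[ok])
    out["cn"] = cn
    out["cn_frac"] = frac
    return out


def segment_cn(bins: pd.DataFrame, min_seg_bins: int = DEFAULT_MIN_SEG_BINS
               ) -> pd.DataFrame:
    """Merge per-bin calls into segments of constant integer CN.

    Per chromosome: median-smooth the bin CNs (window 5 bins), take
    maximal runs of identical rounded value, absorb runs shorter than
    ``min_seg_bins`` into their longer neighbour, then re-estimate each
    segment's copy number as the rounded mean of the unrounded per-bin
    estimates (``cn_frac``, when available) — averaging across a
    segment's bins is what makes the call robust to per-bin noise.
    Masked (NaN) bins are dropped before smoothing.
    Returns (chrom, start, end, cn) rows.
    """
    rows = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.dropna(subset=["cn"])
        if sub.empty:
            continue
        frac = (sub["cn_frac"].to_numpy(dtype=float)
                if "cn_frac" in sub.columns else sub["cn"].to_numpy(dtype=float))
        smooth = frac
        if len(frac) >= SMOOTH_WINDOW_BINS:
            smooth = median_filter(frac, size=SMOOTH_WINDOW_BINS, mode="nearest")
        runs = _runs(round_half_up(smooth))
        runs = _absorb_short_runs(runs, min_seg_bins)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i0, i1, _ in runs:
            cn = int(round_half_up(frac[i0:i1].mean()))
            rows.append((chrom, int(starts[i0]), int(ends[i1 - 1]), cn))
    # re-merge neighbours whose re-estimated CN coincides
    merged = []
    for row in rows:
        if merged and merged[-1][0] == row[0] and merged[-1][2] == row[1] \
                and merged[-1][3] == row[3]:
            merged[-1] = (row[0], merged[-1][1], row[2], row[3])
        else:
            merged.append(row)
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "cn"])


def _runs(vals: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs as (start_idx, end_idx_exclusive, value)."""
    runs = []
    i = 0
    while i < len(vals):
        j = i
        while j < len(vals) and vals[j] == vals[i]:
            j += 1
        runs.append((i, j, int(vals[i])))
        i = j
    return runs


def _absorb_short_runs(runs, min_seg_bins):
    """Merge runs shorter than ``min_seg_bins`` into the longer neighbour,
    shortest first; ties go to the left neighbour."""
    runs = list(runs)
    while len(runs) > 1:
        lengths = [b - a for a, b, _ in runs]
        shortest = min(range(len(runs)), key=lambda k: (lengths[k], k))
        if lengths[shortest] >= min_seg_bins:
            break
        left = runs[shortest - 1] if shortest > 0 else None
        right = runs[shortest + 1] if shortest < len(runs) - 1 else None
        if right is None or (left is not None and
                             (left[1] - left[0]) >= (right[1] - right[0])):
            merged = (left[0], runs[shortest][1], left[2])
            runs[shortest - 1:shortest + 1] = [merged]
        else:
            merged = (runs[shortest][0], right[1], right[2])
            runs[shortest:shortest + 2] = [merged]
        # re-merge adjacent runs that now share a value
        i = 0
        while i < len(runs) - 1:
            if runs[i][2] == runs[i + 1][2]:
                runs[i:i + 2] = [(runs[i][0], runs[i + 1][1], runs[i][2])]
            else:
                i += 1
    return runs


def modal_chromosome_cn(segments: pd.DataFrame) -> int:
    """The copy number occupying the greatest summed segment length.

    Ties break toward the lower copy number.
    """
    if segments.empty:
        raise ValidationError("modal CN undefined without segments")
    lengths = (segments["end"] - segments["start"]).groupby(segments["cn"]).sum()
    best = lengths.max()
    return int(min(cn for cn, l in lengths.items() if l == best))


def karyotype(
    sample: pd.DataFrame,
    reference: pd.DataFrame,
    sample_id: str = "clone",
    baseline_ploidy: int = DEFAULT_BASELINE_PLOIDY,
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
) -> ChromCNReport:
    """Full path: normalise, segment, and summarise modal CN per chromosome."""
    bins = normalize_and_call(sample, reference, baseline_ploidy)
    segs = segment_cn(bins, min_seg_bins)
    modal = {
        chrom: modal_chromosome_cn(sub)
        for chrom, sub in segs.groupby("chrom", sort=False)
    }
    return ChromCNReport(sample_id, modal, baseline_ploidy)


def count_alterations(sample_report: ChromCNReport,
                      reference_report: ChromCNReport) -> int:
    """Number of chromosomes whose modal CN differs from the reference."""
    return sample_report.compare(reference_report).n_altered
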
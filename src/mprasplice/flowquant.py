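"""Protein-level splicing values and noise strength from bin-sorted reads.

A variant's distribution of reads across the 16 expression bins is a proxy
for its single-cell distribution of log2(GFP/mCherry). The module applies
the quality-filter cascade (in this fixed order):

1. variants with fewer than 200 reads across bins are removed;
2. bins with fewer than 5 reads, or holding <2% of the variant's reads, are
   zeroed;
3. bins surrounded by zeros (isolated bins) are zeroed;
4. the variant is discarded if the retained normalized mass after zeroing is
   below 30% of the pre-filter mass.

Profiles are then smoothed with a Savitzky-Golay filter for peak QC only;
variants without exactly one peak are disregarded. The splicing value and
variance are read-weighted moments of the per-bin median log2(GFP/mCherry),
computed from the UNSMOOTHED normalized profile; noise strength is
variance / mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

N_BINS = 16


@dataclass
class FilterParams:
    min_total_reads: int = 200
    min_bin_reads: int = 5
    min_bin_fraction: float = 0.02
    min_retained_mass: float = 0.30
    sg_window: int = 5
    sg_order: int = 2
    peak_delta: float = 0.05


@dataclass
class ProteinResult:
    variant_id: str
    splicing_value: Optional[float]
    variance: Optional[float]
    noise_strength: Optional[float]
    n_peaks: int
    qc_flags: Set[str] = field(default_factory=set)


def normalize_profile(
    raw: np.ndarray,
    bin_read_totals: Optional[np.ndarray] = None,
    bin_population_fractions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-variant bin weights.

    When per-bin sequencing totals and population fractions are available,
    reads are first depth-corrected (variant reads / bin total x bin
    population share), mirroring samples mixed at their population ratios;
    otherwise the variant's raw per-bin fraction is used. The result is
    normalized to sum to 1.
    """
    raw = np.asarray(raw, dtype=float)
    if bin_read_totals is not None and bin_population_fractions is not None:
        totals = np.asarray(bin_read_totals, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(totals > 0, raw / totals, 0.0) * np.asarray(
                bin_population_fractions, dtype=float
            )
    else:
        w = raw.copy()
    s = w.sum()
    return w / s if s > 0 else w


def filter_bin_profile(
    raw: np.ndarray,
    params: FilterParams = FilterParams(),
    bin_read_totals: Optional[np.ndarray] = None,
    bin_population_fractions: Optional[np.ndarray] = None,
) -> Tuple[Optional[np.ndarray], Set[str]]:
    """Apply the four-step filter cascade to a raw bin profile.

    Returns ``(weights, qc_flags)`` where ``weights`` is the renormalized
    16-vector of unsmoothed weights, or None when the variant is discarded.
    """
    raw = np.asarray(raw)
    flags: Set[str] = set()
    total = int(raw.sum())
    if total < params.min_total_reads:
        return None, {"low_total_reads"}

    kept = raw.astype(float).copy()
    # step 2: low-count / low-fraction bins
    low = (kept < params.min_bin_reads) | (kept / total < params.min_bin_fraction)
    kept[low] = 0.0
    # step 3: isolated bins (zero-valued neighbors on both existing sides)
    nz = kept > 0
    padded = np.concatenate([[False], nz, [False]])
    isolated = nz & ~padded[:-2] & ~padded[2:]
    if isolated.any():
        flags.add("isolated_bins")
        kept[isolated] = 0.0
    if low.any():
        flags.add("zeroed_bins")
    # step 4: retained-mass test on normalized weights
    w_before = normalize_profile(raw, bin_read_totals, bin_population_fractions)
    mask = kept > 0
    retained = w_before[mask].sum()
    if retained < params.min_retained_mass:
        flags.add("low_retained_mass")
        return None, flags
    w = np.where(mask, w_before, 0.0)
    s = w.sum()
    if s == 0:
        flags.add("empty_profile")
        return None, flags
    return w / s, flags


def smooth_profile(normalized: np.ndarray, params: FilterParams = FilterParams()) -> np.ndarray:
    """Savitzky-Golay smoothing (window 5, order 2 by default), clipped at 0."""
    sm = savgol_filter(np.asarray(normalized, dtype=float), params.sg_window, params.sg_order)
    return np.clip(sm, 0.0, None)


def detect_peaks(smoothed: np.ndarray, delta: float = 0.05) -> List[int]:
    """Delta-threshold peak scan.

    A position is a maximum peak if it holds the running maximal value and
    was preceded (to the left, since the last registered peak) by a value
    lower by at least ``delta``. The peak is registered once the profile
    drops ``delta`` below the candidate, or at the end of the scan.
    """
    v = np.asarray(smoothed, dtype=float)
    peaks: List[int] = []
    mx, mx_pos = -np.inf, -1
    mn_since = np.inf  # running minimum since the last registered peak
    mn_before_mx = np.inf  # value of that minimum when the candidate was set
    for i, x in enumerate(v):
        if x > mx:
            mx, mx_pos = x, i
            mn_before_mx = mn_since
        if x < mn_since:
            mn_since = x
        fell = x <= mx - delta
        rose = mx - mn_before_mx >= delta
        if fell and (rose or not peaks):
            peaks.append(mx_pos)
            mx, mx_pos = x, i
            mn_since = x
            mn_before_mx = x
    # trailing candidate: qualifies on the preceded-by-lower-value rule alone
    if mx_pos >= 0 and mx - mn_before_mx >= delta and (not peaks or peaks[-1] != mx_pos):
        peaks.append(mx_pos)
    return peaks


def compute_protein_moments(
    weights: np.ndarray, bin_medians: np.ndarray
) -> Tuple[float, float, Optional[float], Set[str]]:
    """Read-weighted mean ("splicing value"), variance and noise strength.

    Moments use the unsmoothed normalized weights, with each bin represented
    by the median log2(GFP/mCherry) of the cells sorted into it. Noise
    strength (variance/mean) is undefined and flagged for non-positive means.
    """
    w = np.asarray(weights, dtype=float)
    m = np.asarray(bin_medians, dtype=float)
    if w.shape != m.shape:
        raise ValueError("weights and bin medians must align")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be normalized to sum to 1")
    mean = float((w * m).sum())
    var = float((w * (m - mean) ** 2).sum())
    flags: Set[str] = set()
    if mean <= 0:
        flags.add("nonpositive_mean")
        return mean, var, None, flags
    return mean, var, var / mean, flags


def process_profile(
    variant_id: str,
    raw: np.ndarray,
    bin_medians: np.ndarray,
    params: FilterParams = FilterParams(),
    bin_read_totals: Optional[np.ndarray] = None,
    bin_population_fractions: Optional[np.ndarray] = None,
) -> ProteinResult:
    """Filter cascade -> smoothing -> peak QC -> weighted moments for one variant."""
    weights, flags = filter_bin_profile(
        raw, params, bin_read_totals, bin_population_fractions
    )
    if weights is None:
        return ProteinResult(variant_id, None, None, None, 0, flags)
    smoothed = smooth_profile(weights, params)
    peaks = detect_peaks(smoothed, params.peak_delta)
    if len(peaks) != 1:
        flags.add("no_peak" if not peaks else "multiple_peaks")
        return ProteinResult(variant_id, None, None, None, len(peaks), flags)
    mean, var, noise, mflags = compute_protein_moments(weights, bin_medians)
    flags |= mflags
    return ProteinResult(variant_id, mean, var, noise, 1, flags)


def quantify_profiles(
    profiles: pd.DataFrame,
    bin_medians: Sequence[float],
    params: FilterParams = FilterParams(),
    depth_correct: bool = True,
    bin_population_fractions: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Run the protein quantification over a variant x bin read-count table.

    ``profiles`` holds a ``variant_id`` column plus ``bin_1..bin_N`` counts.
    With ``depth_correct`` the observed per-bin read totals stand in for the
    sequencing depths and, unless given, the population fractions.
    """
    bin_cols = [c for c in profiles.columns if c.startswith("bin_")]
    counts = profiles[bin_cols].to_numpy(dtype=np.int64)
    medians = np.asarray(bin_medians, dtype=float)
    totals = counts.sum(axis=0).astype(float) if depth_correct else None
    fracs = None
    if depth_correct:
        fracs = (
            np.asarray(bin_population_fractions, dtype=float)
            if bin_population_fractions is not None
            else totals / totals.sum()
        )
    rows = []
    for vid, raw in zip(profiles["variant_id"], counts):
        res = process_profile(vid, raw, medians, params, totals, fracs)
        rows.append(
            {
                "variant_id": res.variant_id,
                "splicing_value": np.nan if res.splicing_value is None else res.splicing_value,
                "variance": np.nan if res.variance is None else res.variance,
                "noise_strength": np.nan if res.noise_strength is None else res.noise_strength,
                "n_peaks": res.n_peaks,
                "qc_flags": ",".join(sorted(res.qc_flags)),
            }
        )
    return pd.DataFrame(rows)
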
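"""Cell-to-cell splicing-noise statistics.

Noise strength (variance/mean of the bin-read distribution) depends
systematically on mean splicing value and on expression level. The module
removes that dependency by fitting a generalized additive model — a spline
term on the splicing value, a linear term on log2(RNA/DNA) expression — and
treats the residual from the fit as the variant's noise measure ("noise
residual").

Whether noise levels are sequence-encoded is tested per identical-sequence
group (>= 8 members) by comparing the group's residual variance against
variances of many random, size- and splicing-value-matched variant sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

MIN_COMPLETE_CASES = 50


@dataclass
class NoiseFit:
    fitted: np.ndarray
    residuals: np.ndarray
    alpha: float
    index: np.ndarray  # positions of complete cases in the input


@dataclass
class EncodingTestResult:
    group_id: str
    observed_variance: float
    null_fraction: float
    n_random: int
    pool_size: int


def fit_noise_model(
    splicing_values: Sequence[float],
    expressions: Sequence[float],
    noise_strengths: Sequence[float],
    df: int = 20,
    degree: int = 3,
    alpha: Optional[float] = None,
) -> NoiseFit:
    """Fit noise strength ~ spline(splicing value) + linear(expression).

    The spline basis has ``df`` B-spline functions with a second-order
    difference penalty; the penalty weight is chosen by generalized
    cross-validation unless given. Residuals (observed minus fitted) are
    returned for the complete cases; their mean is ~0 by construction since
    the intercept is unpenalized.
    """
    sv = np.asarray(splicing_values, dtype=float)
    ex = np.asarray(expressions, dtype=float)
    ns = np.asarray(noise_strengths, dtype=float)
    mask = np.isfinite(sv) & np.isfinite(ex) & np.isfinite(ns)
    if mask.sum() < MIN_COMPLETE_CASES:
        raise ValueError(
            f"need >= {MIN_COMPLETE_CASES} complete cases, got {int(mask.sum())}"
        )
    x = sv[mask]
    smoother = BSplines(x[:, None], df=[df], degree=[degree])
    exog = sm.add_constant(pd.DataFrame({"expression": ex[mask]}))
    if alpha is None:
        gam = GLMGam(ns[mask], exog=exog, smoother=smoother, alpha=[1.0])
        try:
            alpha = float(gam.select_penweight()[0][0])
        except Exception:  # GCV search can fail on degenerate inputs
            alpha = 1.0
    model = GLMGam(ns[mask], exog=exog, smoother=smoother, alpha=[alpha])
    res = model.fit()
    fitted = np.asarray(res.fittedvalues)
    resid = ns[mask] - fitted
    return NoiseFit(fitted=fitted, residuals=resid, alpha=float(alpha), index=np.where(mask)[0])


def sequence_encoding_test(
    groups: Mapping[str, Sequence[int]],
    splicing_values: Sequence[float],
    noise_residuals: Sequence[float],
    n_random: int = 10000,
    window: float = 0.5,
    min_pool: int = 50,
    seed: int = 0,
) -> List[EncodingTestResult]:
    """Randomization test for DNA-encoded noise levels.

    ``groups`` maps a group id to the indices of its members (identical
    variable-region sets, >= 8 members). For each group the variance of
    member noise residuals is compared to variances of ``n_random`` random
    sets of equal size drawn from non-member variants whose splicing value
    lies within ``window`` of the group mean (falling back to the nearest
    ``min_pool`` variants when the window pool is too small). The reported
    null fraction is the share of random sets with a variance smaller than
    the observed one.
    """
    sv = np.asarray(splicing_values, dtype=float)
    res = np.asarray(noise_residuals, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    all_idx = np.arange(len(sv))
    valid = np.isfinite(sv) & np.isfinite(res)
    for gid, members in groups.items():
        members = np.asarray(list(members), dtype=int)
        if len(members) < 8:
            raise ValueError(f"group {gid} has fewer than 8 members")
        obs_var = float(np.var(res[members], ddof=1))
        center = float(np.mean(sv[members]))
        member_mask = np.zeros(len(sv), dtype=bool)
        member_mask[members] = True
        pool_mask = valid & ~member_mask & (np.abs(sv - center) <= window)
        pool = all_idx[pool_mask]
        if len(pool) < max(len(members), min_pool):
            # nearest-N fallback
            cand = all_idx[valid & ~member_mask]
            order = np.argsort(np.abs(sv[cand] - center), kind="stable")
            pool = cand[order[: max(len(members), min_pool)]]
        if len(pool) < len(members):
            raise ValueError(f"matching pool for group {gid} smaller than the group")
        k = len(members)
        null_vars = np.empty(n_random)
        pool_res = res[pool]
        for i in range(n_random):
            pick = rng.choice(len(pool), size=k, replace=False)
            null_vars[i] = np.var(pool_res[pick], ddof=1)
        out.append(
            EncodingTestResult(
                group_id=str(gid),
                observed_variance=obs_var,
                null_fraction=float(np.mean(null_vars < obs_var)),
                n_random=n_random,
                pool_size=int(len(pool)),
            )
        )
    return out


def rna_protein_correlations(table: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix over complete cases per pair.

    Typical columns: RNA splicing ratio, protein splicing value, expression,
    intronic GC and relative intronic GC.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    return table[cols].corr(method="pearson")


def differential_hexamer_correlation(
    hexamer_counts: pd.DataFrame,
    rna_ratios: Sequence[float],
    protein_values: Sequence[float],
) -> pd.DataFrame:
    """Per-hexamer difference between RNA and protein readout correlations.

    For every hexamer column the Pearson correlation with the RNA splicing
    ratio and with the protein splicing value is computed over variants with
    both readouts; the table reports ``delta_r = r_rna - r_protein`` ranked
    by its magnitude. Zero-variance hexamers get correlation 0.
    """
    rna = np.asarray(rna_ratios, dtype=float)
    prot = np.asarray(protein_values, dtype=float)
    mask = np.isfinite(rna) & np.isfinite(prot)
    X = hexamer_counts.to_numpy(dtype=float)[mask]
    rna, prot = rna[mask], prot[mask]
    n = len(rna)
    if n < 3:
        raise ValueError("need at least 3 variants with both readouts")

    def corr_with(y: np.ndarray) -> np.ndarray:
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sx = np.sqrt((Xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
        return np.where(sx > 0, r, 0.0)

    r_rna = corr_with(rna)
    r_prot = corr_with(prot)
    out = pd.DataFrame(
        {
            "hexamer": hexamer_counts.columns,
            "r_rna": r_rna,
            "r_protein": r_prot,
            "delta_r": r_rna - r_prot,
        }
    )
    return out.sort_values("delta_r", key=np.abs, ascending=False).reset_index(drop=True)
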
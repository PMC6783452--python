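"""Synthetic-data generator emulating a splicing MPRA readout.

The generator plants known sequence->splicing effects and cell-to-cell
variability, then emulates the three measurement channels of the assay:

* per-variant RNA isoform read counts (spliced vs unspliced, or the
  type-appropriate outcome pair) plus RNA/DNA expression reads,
* per-variant read profiles across 16 expression bins obtained by sorting a
  pooled cell population on log2(GFP/mCherry), with bin boundaries placed at
  population quantiles so that every bin holds between 1% and 10% of cells,
* a truth table holding the latent quantities the quantification modules
  are expected to recover.

All randomness flows from one seed; runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._dna import decode


@dataclass
class SimConfig:
    """Study conditions for the synthetic assay."""

    n_variants: int = 2000
    read_depth_rna: int = 10000
    cells_per_variant: int = 5000
    reads_per_variant_bins: int = 2000
    n_bins: int = 16
    bin_occupancy_bounds: tuple = (0.01, 0.10)
    effect_sizes: Dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    rna_noise_sd: float = 0.5
    # saturating RNA->protein link: protein = a + b * tanh(r / c)
    protein_a: float = 2.5
    protein_b: float = 2.5
    protein_c: float = 2.0
    # cell-to-cell SD of log2(GFP/mCherry): LogNormal, clipped
    sigma_log_mean: float = float(np.log(0.4))
    sigma_log_sd: float = 0.5
    sigma_bounds: tuple = (0.1, 1.0)
    expression_mean: float = 0.0
    expression_sd: float = 0.5
    noise_encoded: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bin_occupancy_bounds
        if not lo < hi:
            raise ValueError("bin occupancy bounds must be ordered")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if not lo <= 1.0 / self.n_bins <= hi:
            raise ValueError(
                f"equal-population binning with {self.n_bins} bins is outside "
                f"the occupancy bounds {self.bin_occupancy_bounds}"
            )


def _scrub_restriction_sites(seq: str, rng, protected=()) -> str:
    """Mutate single bases until no excluded restriction site remains,
    leaving the canonical splice-site dinucleotides untouched."""
    from .motifs import RESTRICTION_SITES

    sites = [s for ss in RESTRICTION_SITES.values() for s in ss]
    keep = set()
    for p in protected:
        keep.update((p, p + 1, p - 2, p - 1))
    for _ in range(200):
        hit = None
        for s in sites:
            i = seq.find(s)
            if i >= 0:
                hit = (i, len(s))
                break
        if hit is None:
            return seq
        i, m = hit
        pos = next((j for j in range(i, i + m) if j not in keep), i)
        old = seq[pos]
        new = "ACGT"[int(rng.integers(0, 4))]
        while new == old:
            new = "ACGT"[int(rng.integers(0, 4))]
        seq = seq[:pos] + new + seq[pos + 1 :]
    raise RuntimeError("could not scrub restriction sites")  # pragma: no cover


def random_contexts(
    n: int,
    splicing_type: str = "retained_intron",
    seed: int = 0,
    length: int = 162,
    intron_bounds: tuple = (70, 118),
) -> List["SpliceContext"]:
    """Generate plausible random contexts: an intron of realistic length
    (70-118 nt) with GT..AG ends, flanked by exonic sequence, or the
    type-equivalent layout for the other splicing types."""
    from .libdesign import VARIABLE_BUDGET, SpliceContext

    length = min(length, VARIABLE_BUDGET[splicing_type])
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        intron_len = int(rng.integers(intron_bounds[0], min(intron_bounds[1], length - 20) + 1))
        donor = int(rng.integers(8, length - intron_len - 7))
        acceptor = donor + intron_len
        seq = decode(rng.integers(0, 4, size=length, dtype=np.uint8))
        # canonical intron ends
        seq = seq[:donor] + "GT" + seq[donor + 2 :]
        seq = seq[: acceptor - 2] + "AG" + seq[acceptor:]
        seq = _scrub_restriction_sites(seq, rng, protected=(donor, acceptor))
        ctx = SpliceContext(
            context_id=f"ctx{i:04d}",
            splicing_type=splicing_type,
            sequence=seq,
            splice_site_positions=[donor, acceptor],
            reading_frame_offset=int(rng.integers(0, 3)),
        )
        out.append(ctx)
    return out


def plant_truth(
    manifest: pd.DataFrame,
    features: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Plant latent per-variant truths.

    The true RNA log2 splicing ratio is a linear combination of the feature
    columns named in ``config.effect_sizes`` plus Gaussian noise; the true
    protein splicing value follows via a saturating tanh link; cell-to-cell
    SD sigma is drawn per identical-sequence group when ``noise_encoded``
    (so identical variable regions share their planted noise level), else
    independently per variant.

    ``manifest`` needs columns ``variant_id`` and ``variable_region``;
    ``features`` is indexed by variant_id.
    """
    missing = [f for f in config.effect_sizes if f not in features.columns]
    if missing:
        raise KeyError(f"effect features missing from feature matrix: {missing}")
    rng = np.random.default_rng(config.seed)
    vids = manifest["variant_id"].to_numpy()
    X = features.loc[vids]
    r = np.full(len(vids), config.intercept, dtype=float)
    for feat, coef in config.effect_sizes.items():
        col = X[feat].to_numpy(dtype=float)
        sd = col.std()
        if sd > 0:
            col = (col - col.mean()) / sd
        r = r + coef * col
    r = r + rng.normal(0.0, config.rna_noise_sd, size=len(vids))
    protein = config.protein_a + config.protein_b * np.tanh(r / config.protein_c)

    seqs = manifest["variable_region"].to_numpy()
    sigma = np.empty(len(vids))
    if config.noise_encoded:
        groups = pd.Series(range(len(vids))).groupby(seqs, sort=True)
        for _, idx in groups.groups.items():
            s = float(
                np.clip(
                    np.exp(rng.normal(config.sigma_log_mean, config.sigma_log_sd)),
                    *config.sigma_bounds,
                )
            )
            sigma[np.asarray(idx)] = s
    else:
        sigma = np.clip(
            np.exp(rng.normal(config.sigma_log_mean, config.sigma_log_sd, len(vids))),
            *config.sigma_bounds,
        )
    expression = rng.normal(config.expression_mean, config.expression_sd, len(vids))
    return pd.DataFrame(
        {
            "variant_id": vids,
            "true_rna_logratio": r,
            "true_protein_value": protein,
            "true_sigma": sigma,
            "true_expression": expression,
            "noise_encoded": config.noise_encoded,
        }
    )


def simulate_rna_reads(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Emulate isoform-resolved RNA sequencing and RNA/DNA expression reads.

    Total isoform reads per variant are Poisson around the configured depth;
    the first-outcome count is Binomial with success probability
    ``2**r / (1 + 2**r)`` so the planted log ratio is recovered in
    expectation. DNA reads are Poisson at depth; RNA reads are Poisson at
    ``depth * 2**expression``.
    """
    rng = np.random.default_rng(config.seed + 1)
    r = truth["true_rna_logratio"].to_numpy()
    p = 1.0 / (1.0 + np.exp2(-r))
    total = rng.poisson(config.read_depth_rna, size=len(r))
    up = rng.binomial(total, p)
    down = total - up
    dna = rng.poisson(config.read_depth_rna, size=len(r))
    rna = rng.poisson(config.read_depth_rna * np.exp2(truth["true_expression"].to_numpy()))
    return pd.DataFrame(
        {
            "variant_id": truth["variant_id"],
            "count_iso_up": up,
            "count_iso_down": down,
            "rna_reads": rna,
            "dna_reads": dna,
        }
    )


def compute_bin_boundaries(values: np.ndarray, config: SimConfig) -> np.ndarray:
    """Equal-population quantile boundaries for the sorted-bin experiment.

    Returns the ``n_bins - 1`` inner boundaries. Equal-population bins hold
    ``1/n_bins`` of cells each, which respects the 1-10% occupancy bounds for
    16 bins (validated in SimConfig).
    """
    qs = np.linspace(0, 1, config.n_bins + 1)[1:-1]
    return np.quantile(values, qs)


def simulate_sorted_bins(truth: pd.DataFrame, config: SimConfig):
    """Sort a simulated cell population into expression bins and sequence them.

    Cells of each variant draw log2(GFP/mCherry) values from
    Normal(true_protein_value, true_sigma^2). Pooled-population quantile
    boundaries define the bins; per-bin sequencing depth is proportional to
    the bin's share of cells (samples mixed at their population ratios), and
    reads within a bin are Multinomial across variants proportional to their
    cell counts.

    Returns ``(profiles, bin_medians, boundaries)``: a variant x bin read
    count DataFrame, the per-bin median cell value, and the inner boundaries.
    """
    rng = np.random.default_rng(config.seed + 2)
    mu = truth["true_protein_value"].to_numpy()
    sigma = truth["true_sigma"].to_numpy()
    n_var, n_cells = len(mu), config.cells_per_variant
    values = rng.normal(mu[:, None], sigma[:, None], size=(n_var, n_cells))
    boundaries = compute_bin_boundaries(values.ravel(), config)
    bin_idx = np.searchsorted(boundaries, values)  # (n_var, n_cells) in [0, n_bins)

    cell_counts = np.zeros((n_var, config.n_bins), dtype=np.int64)
    for b in range(config.n_bins):
        cell_counts[:, b] = (bin_idx == b).sum(axis=1)

    flat = values.ravel()
    flat_bins = bin_idx.ravel()
    order = np.argsort(flat_bins, kind="stable")
    sorted_vals = flat[order]
    splits = np.searchsorted(flat_bins[order], np.arange(1, config.n_bins))
    bin_medians = np.array(
        [np.median(chunk) if len(chunk) else np.nan for chunk in np.split(sorted_vals, splits)]
    )

    total_reads = config.reads_per_variant_bins * n_var
    bin_cells = cell_counts.sum(axis=0)
    bin_fractions = bin_cells / bin_cells.sum()
    profiles = np.zeros((n_var, config.n_bins), dtype=np.int64)
    for b in range(config.n_bins):
        depth_b = int(round(total_reads * bin_fractions[b]))
        if depth_b == 0 or bin_cells[b] == 0:
            continue
        p = cell_counts[:, b] / bin_cells[b]
        profiles[:, b] = rng.multinomial(depth_b, p)

    prof_df = pd.DataFrame(
        profiles,
        columns=[f"bin_{i + 1}" for i in range(config.n_bins)],
    )
    prof_df.insert(0, "variant_id", truth["variant_id"].to_numpy())
    medians = pd.DataFrame(
        {"bin": np.arange(1, config.n_bins + 1), "median_log2_ratio": bin_medians}
    )
    return prof_df, medians, boundaries


def simulate_assay(manifest: pd.DataFrame, features: pd.DataFrame, config: SimConfig):
    """Run the full generative model; returns (truth, isoform counts,
    bin profiles, bin medians, boundaries)."""
    truth = plant_truth(manifest, features, config)
    iso = simulate_rna_reads(truth, config)
    profiles, medians, boundaries = simulate_sorted_bins(truth, config)
    return truth, iso, profiles, medians, boundaries
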
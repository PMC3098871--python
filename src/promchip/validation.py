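"""Ground-truth validation experiments for the pipeline.

Each function runs one self-contained experiment on synthetic data with
known truth and returns the measured quantity: Monte-Carlo agreement of
the binding-event shape, exact inversion of the noiseless forward model,
type-I calibration of the empirical peak p-values, end-to-end recovery of
planted binding events, motif-cutoff calibration against exhaustive
enumeration, planted-motif fraction recovery, cyclic-loess behaviour on
constructed inputs, the exact permutation test, and agreement of the
enrichment p-values with an independent Fisher's-exact oracle.  All
experiments are deterministic given their seed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import chip, expression, motifs, synthetic
from .peaks import (
    FragmentLengthDist,
    PromoterPeakFitter,
    fit_peak,
    llr_statistic,
    peak_shape,
    permutation_null_llrs,
)

__all__ = [
    "peak_shape_mc_deviation",
    "noiseless_inversion_errors",
    "type_i_calibration",
    "end_to_end_recovery",
    "motif_cutoff_bounds",
    "motif_planting_recovery",
    "loess_offset_pair_residual",
    "loess_dye_bias_convergence",
    "permutation_null_rate",
    "enrichment_oracle_max_rel_diff",
    "sharp_motif",
]


def peak_shape_mc_deviation(n_fragments: int = 1_000_000, seed=0) -> float:
    """Max |s(d) - Monte-Carlo coverage| over all d for the default shape.

    The oracle drops ``n_fragments`` fragments with uniform 200-700 bp
    lengths, places the bound site uniformly within each, and counts how
    often position site+d is still covered.
    """
    dist = FragmentLengthDist.uniform()
    shape = peak_shape(dist)
    rng = np.random.default_rng(seed)
    lengths = rng.integers(200, 701, size=n_fragments)
    site = rng.uniform(0.0, lengths)
    ds = np.arange(0, dist.max_length + 1)
    # sort the distance from site to fragment end once; coverage at d is
    # the fraction of fragments with site + d inside
    slack = np.sort(lengths - site)
    frac_covered = 1.0 - np.searchsorted(slack, ds) / n_fragments
    return float(np.max(np.abs(shape(ds) - frac_covered)))


def noiseless_inversion_errors(n_configs: int = 100, seed=0, grid_step: int = 25):
    """Exact recovery of (center, fold, baseline) from noiseless ratios.

    Returns ``(max center error, max |f| relative error, max |b| relative
    error)`` over random on-grid configurations.
    """
    shape = peak_shape(FragmentLengthDist.uniform())
    rng = np.random.default_rng(seed)
    err_c = err_f = err_b = 0.0
    for _ in range(n_configs):
        # contiguous tile: 4-6 probes with jittered ~300 bp steps on the
        # candidate grid, so every in-span centre is within the shape's reach
        n = int(rng.integers(4, 7))
        steps = grid_step * rng.integers(10, 15, size=n - 1)  # 250-350 bp
        start = int(rng.integers(-2000, 800 - int(steps.sum()) + 1))
        offsets = (start + np.concatenate([[0], np.cumsum(steps)])).astype(float)
        grid = np.arange(offsets.min(), offsets.max() + 1, grid_step)
        c_true = float(rng.choice(grid))
        f_true = float(rng.uniform(1.5, 10.0))
        b_true = float(rng.uniform(0.5, 2.0))
        ratios = b_true * (1.0 + (f_true - 1.0) * shape(offsets - c_true))
        c, f, b, _, _ = fit_peak(zip(offsets, ratios), shape, grid_step)
        err_c = max(err_c, abs(c - c_true))
        err_f = max(err_f, abs(f - f_true) / f_true)
        err_b = max(err_b, abs(b - b_true) / b_true)
    return err_c, err_f, err_b


def type_i_calibration(
    n_promoters: int = 1000, n_perm: int = 199, noise_sd_log2: float = 0.1, seed=0
):
    """Empirical peak p-values on pure-noise promoters.

    Returns ``(fraction of p < 0.05, KS uniformity p-value)``.
    """
    shape = peak_shape(FragmentLengthDist.uniform())
    ss = np.random.SeedSequence(seed)
    s_layout, s_sim, s_perm = ss.spawn(3)
    layout = synthetic.generate_layout(n_promoters, s_layout)
    truth = synthetic.make_chip_truth(layout, 0.0, 1.0, "null", 0)
    arrays = synthetic.simulate_chip_arrays(
        layout, truth, noise_sd_log2=noise_sd_log2, n_replicates=1, seed=s_sim,
        shape=shape,
    )
    ratios = arrays.ratios("null", 1)
    pvals = []
    for (_, sub), child in zip(
        ratios.groupby("gene_id", sort=True), s_perm.spawn(n_promoters)
    ):
        offs = sub["offset_bp"].to_numpy()
        r = sub["ratio"].to_numpy()
        fitter = PromoterPeakFitter(offs, shape)
        _, _, _, rss1, rss0 = fitter.fit_many(r[None, :])
        llr = float(llr_statistic(rss0, rss1, fitter.n)[0])
        null = permutation_null_llrs(fitter, r, n_perm, np.random.default_rng(child))
        pvals.append((1 + np.count_nonzero(null >= llr)) / (n_perm + 1))
    pvals = np.asarray(pvals)
    ks = stats.kstest(pvals, "uniform").pvalue
    return float((pvals < 0.05).mean()), float(ks)


def end_to_end_recovery(
    n_genes: int = 500,
    bound_fraction: float = 0.10,
    fold: float = 3.0,
    noise_sd_log2: float = 0.1,
    n_replicates: int = 3,
    n_perm: int = 199,
    seed=0,
):
    """Sensitivity and false-discovery proportion of the full peak caller.

    Simulates ``n_genes`` promoters with ``bound_fraction`` carrying a
    planted event of the given fold, calls peaks with the standard
    thresholds (p < 0.01, height > 1.5, >= 2 of 3 replicates) and compares
    against the truth table.
    """
    shape = peak_shape(FragmentLengthDist.uniform())
    ss = np.random.SeedSequence(seed)
    s_layout, s_truth, s_sim, s_call = ss.spawn(4)
    layout = synthetic.generate_layout(n_genes, s_layout)
    truth = synthetic.make_chip_truth(layout, bound_fraction, fold, "stimulated", s_truth)
    arrays = synthetic.simulate_chip_arrays(
        layout, truth, noise_sd_log2=noise_sd_log2, n_replicates=n_replicates,
        seed=s_sim, shape=shape,
    )
    calls = chip.call_condition(arrays, shape, "stimulated", n_perm=n_perm, seed=s_call)
    planted = set(truth.loc[truth["true_fold"] > 1, "gene_id"])
    called = {c.gene_id for c in calls if c.passes}
    tp = len(called & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return sensitivity, fdp


def _enumerated_scores(matrix: motifs.MotifMatrix) -> np.ndarray:
    seqs = np.array(list(itertools.product(range(4), repeat=matrix.width)))
    return np.sort(matrix.score_sequences(seqs))


def motif_cutoff_bounds(
    matrix: motifs.MotifMatrix,
    alpha: float = 0.05,
    n_samples: int = 10000,
    seed=0,
    confidence: float = 0.99,
):
    """Sampled cutoff plus the exact order-statistic confidence bounds.

    For motif widths small enough to enumerate (<= 8), returns
    ``(cutoff, lower, upper)`` where lower/upper are the exact population
    quantiles at ``1 - alpha -/+ z * sqrt(alpha (1-alpha) / n)``; a correctly
    sampled cutoff falls inside with the stated confidence.
    """
    cutoff = motifs.calibrate_cutoff(matrix, alpha=alpha, n_samples=n_samples, seed=seed)
    scores = _enumerated_scores(matrix)
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    half = z * np.sqrt(alpha * (1 - alpha) / n_samples)
    lo = np.quantile(scores, max(1 - alpha - half, 0.0), method="higher")
    hi = np.quantile(scores, min(1 - alpha + half, 1.0), method="higher")
    return float(cutoff), float(lo), float(hi)


def sharp_motif(width: int = 12, consensus_weight: float = 97.0) -> motifs.MotifMatrix:
    """High-information benchmark matrix around the GTCT Smad-box core."""
    consensus = ("GTCTAGACGGCT" * 3)[:width]
    counts = np.ones((width, 4))
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = consensus_weight
    return motifs.MotifMatrix.from_counts(counts, name="benchmark_sharp")


def motif_planting_recovery(
    n_regions: int = 300,
    plant_fraction: float = 0.70,
    alpha: float = 1e-4,
    n_samples: int = 200_000,
    seed=0,
):
    """Fraction of 201 bp regions with a hit when 70% carry a planted motif.

    Plants instances inside the regions of a random ``plant_fraction`` of
    genes and scans all regions at a stringent calibrated cutoff.  Returns
    ``(observed fraction, null fraction)`` where the null fraction is
    measured on the unplanted regions (the per-region family-wise
    background rate).
    """
    matrix = sharp_motif()
    ss = np.random.SeedSequence(seed)
    s_cut, s_layout, s_pick, s_seq = ss.spawn(4)
    cutoff = motifs.calibrate_cutoff(matrix, alpha=alpha, n_samples=n_samples, seed=s_cut)
    matrix = matrix.with_cutoff(cutoff)
    layout = synthetic.generate_layout(n_regions, s_layout)
    genes = list(layout["gene_id"].unique())
    spans = layout.groupby("gene_id")["offset_bp"].agg(["min", "max"])
    rng = np.random.default_rng(s_pick)
    n_plant = int(round(plant_fraction * len(genes)))
    plant_in = set(rng.choice(genes, size=n_plant, replace=False))
    centers = {
        g: int(rng.integers(spans.loc[g, "min"], spans.loc[g, "max"] + 1)) for g in genes
    }
    windows = {g: (centers[g] - 80, centers[g] + 80) for g in plant_in}
    seqs, _ = synthetic.generate_promoter_sequences(
        layout, matrix, plant_in, seed=s_seq, plant_window=windows
    )
    lo = synthetic.PROMOTER_SPAN[0]
    regions, null_regions = {}, {}
    for g in genes:
        i = centers[g] - lo
        regions[g] = seqs[g][max(0, i - 100) : i + 101]
        if g not in plant_in:
            null_regions[g] = regions[g]
    frac, _ = motifs.fraction_with_hit(regions, matrix)
    null_frac, _ = motifs.fraction_with_hit(null_regions, matrix)
    return frac, null_frac


def loess_offset_pair_residual(n_probes: int = 2000, offset_log2: float = 1.0, seed=0):
    """|mean M| after normalizing a pair differing by a constant log2 offset."""
    rng = np.random.default_rng(seed)
    base = rng.normal(8.0, 1.5, n_probes)
    long = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n_probes)] * 2,
            "gene_id": [f"g{i}" for i in range(n_probes)] * 2,
            "intensity": np.concatenate([2.0**base, 2.0 ** (base + offset_log2)]),
            "time_h": 0,
            "arm": "DMSO",
            "replicate": [1] * n_probes + [2] * n_probes,
        }
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        mat = expression.ExpressionMatrix.from_long(long)
        norm, _, _, _ = expression.cyclic_loess_normalize(mat, seed=seed)
    V = norm.values.to_numpy()
    return float(abs((V[:, 0] - V[:, 1]).mean()))


def loess_dye_bias_convergence(
    n_genes: int = 2000, dye_bias: float = 0.3, noise_sd_log2: float = 0.25, seed=0,
    epsilon: float = 0.01,
):
    """Iterations to convergence on smooth intensity-dependent array bias.

    Returns ``(n_iterations, converged)`` for the full 24-array design with
    no differential expression (the pure normalization scenario).
    """
    ss = np.random.SeedSequence(seed)
    s_sim, s_loess = ss.spawn(2)
    truth = synthetic.make_expression_truth(
        [f"E{i:05d}" for i in range(n_genes)], 0, 0, seed=0
    )
    long, _ = synthetic.simulate_expression_timecourse(
        truth, dye_bias=dye_bias, noise_sd_log2=noise_sd_log2, seed=s_sim
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        mat = expression.ExpressionMatrix.from_long(long)
        _, n_iter, converged, _ = expression.cyclic_loess_normalize(
            mat, epsilon=epsilon, seed=s_loess
        )
    return n_iter, bool(converged)


def permutation_null_rate(n_genes: int = 1000, level: float = 0.1, seed=0):
    """Type-I rate of the exact 3-vs-3 permutation test on null data."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_genes):
        p = expression.permutation_de_test(rng.normal(size=3), rng.normal(size=3))
        hits += p <= level + 1e-9
    return hits / n_genes


def enrichment_oracle_max_rel_diff(n_tables: int = 100, seed=0):
    """Max relative difference of enrichment p-values vs scipy's Fisher test."""
    from .integration import fisher_enrichment

    rng = np.random.default_rng(seed)
    universe = [f"g{i}" for i in range(400)]
    worst = 0.0
    for _ in range(n_tables):
        n_data = int(rng.integers(10, 150))
        n_set = int(rng.integers(5, 100))
        dataset = set(rng.choice(universe, n_data, replace=False))
        gene_set = list(rng.choice(universe, n_set, replace=False))
        res = fisher_enrichment(dataset, {"S": gene_set}, universe).iloc[0]
        k = int(res["overlap"])
        table = [[k, int(res["set_size"]) - k],
                 [n_data - k, len(universe) - n_set - n_data + k]]
        _, p_oracle = stats.fisher_exact(table, alternative="greater")
        worst = max(worst, abs(res["pvalue"] - p_oracle) / p_oracle)
    return worst
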
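"""Time-course expression normalization and permutation differential testing.

One-colour arrays from a 3-replicate x 4-timepoint (0/2/12/24 h) x 2-arm
(vehicle vs SMAD3-inhibitor) design are log2 transformed, normalized
across arrays by cyclic loess -- iteratively removing the
intensity-dependent trend of M (log2 ratio) on A (mean log2 intensity)
between every pair of arrays, fitted on a random probe subset -- then
probe intensities are averaged into gene values, each gene is expressed
relative to its 0 h baseline per arm (the log-scale equivalent of dividing
by the geometric mean of the 0 h replicates), and timepoints are compared
with a two-sided permutation test on the replicate labels, enumerated
exactly when the group sizes allow.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInputError

__all__ = [
    "ExpressionMatrix",
    "GeneTimecourse",
    "cyclic_loess_normalize",
    "summarize_probes_to_genes",
    "normalize_to_baseline",
    "permutation_de_test",
    "adjust_pvalues",
    "delta_delta_ct",
    "test_timepoint",
]

#: enumerate the permutation null exactly up to this many splits
EXACT_SPLIT_LIMIT = 1000


@dataclass
class ExpressionMatrix:
    """Probe x array grid of log2 intensities with design metadata.

    ``values``: DataFrame indexed by probe_id, one column per array id.
    ``arrays``: DataFrame indexed by array id with ``time_h``, ``arm``,
    ``replicate``.  ``probe_to_gene``: Series probe_id -> gene_id.
    """

    values: pd.DataFrame
    arrays: pd.DataFrame
    probe_to_gene: pd.Series

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression matrix contains non-finite log2 values")
        for col in ("time_h", "arm", "replicate"):
            if col not in self.arrays.columns:
                raise ValueError(f"array metadata lacks column {col!r}")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a long table (probe_id, gene_id, intensity, time_h, arm, replicate).

        Intensities are linear-scale and must be positive; they are log2
        transformed here.
        """
        required = {"probe_id", "gene_id", "intensity", "time_h", "arm", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long table lacks columns {sorted(missing)}")
        if (df["intensity"] <= 0).any():
            raise ValueError("intensities must be positive before log transform")
        df = df.copy()
        df["array_id"] = (
            df["arm"].astype(str) + "_" + df["time_h"].astype(str) + "h_r"
            + df["replicate"].astype(str)
        )
        values = df.pivot(index="probe_id", columns="array_id", values="intensity")
        if values.isna().any().any():
            raise ValueError("incomplete design: some probes missing on some arrays")
        arrays = (
            df[["array_id", "time_h", "arm", "replicate"]]
            .drop_duplicates()
            .set_index("array_id")
            .loc[values.columns]
        )
        probe_to_gene = df.drop_duplicates("probe_id").set_index("probe_id")["gene_id"]
        return cls(np.log2(values), arrays, probe_to_gene.loc[values.index])


@dataclass
class GeneTimecourse:
    """Gene x array log2 ratios relative to the 0 h baseline of each arm."""

    values: pd.DataFrame  # genes x array ids
    arrays: pd.DataFrame

    def replicate_values(self, arm: str, time_h) -> pd.DataFrame:
        ids = self.arrays.index[
            (self.arrays["arm"] == arm) & (self.arrays["time_h"] == time_h)
        ]
        return self.values[ids]


def cyclic_loess_normalize(
    matrix: ExpressionMatrix,
    subset_size: int = 5000,
    epsilon: float = 0.01,
    max_iter: int = 10,
    span: float = 0.4,
    seed=0,
    damping: float = 0.8,
):
    """Cyclic loess normalization across all array pairs.

    For each pair of arrays a local-linear smoother of M on A is fitted to
    a random probe subset (drawn once per run) and its prediction at every
    probe, scaled by ``damping``, is split evenly between the two arrays
    (half subtracted from one, half added to the other, log2 scale).  One
    iteration cycles all pairs; iteration stops when the largest single
    adjustment drops below ``epsilon`` or after ``max_iter`` iterations.

    The damping factor (default 0.8) keeps the cyclic fixed-point
    iteration contractive: local smoothers can slightly amplify modes in
    sparse regions of the A axis, and cycling hundreds of pairs compounds
    that into a slow divergence when corrections are applied at full
    strength.

    Returns ``(normalized matrix, n_iterations, converged, max_change_history)``.
    """
    if not 0.0 < damping <= 1.0:
        raise ValueError("damping must lie in (0, 1]")
    V = matrix.values.to_numpy().copy()
    n_probes, n_arrays = V.shape
    if n_arrays < 2:
        raise ValueError("need at least 2 arrays to normalize")
    rng = np.random.default_rng(seed)
    k = min(subset_size, n_probes)
    if k < subset_size:
        import warnings

        warnings.warn(
            f"subset_size {subset_size} exceeds probe count {n_probes}; using all probes",
            stacklevel=2,
        )
    subset = rng.choice(n_probes, size=k, replace=False)
    history = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        max_change = 0.0
        for i, j in combinations(range(n_arrays), 2):
            M = V[:, i] - V[:, j]
            A = 0.5 * (V[:, i] + V[:, j])
            As = A[subset]
            if np.ptp(As) == 0.0:  # flat MA plot; nothing to fit
                continue
            # fit on the subset, then interpolate the curve at every probe;
            # plain local-linear fits (no robustness reweighting) keep the
            # cycle stable -- reweighting responds to the residual noise and
            # feeds back across pairs
            curve = lowess(M[subset], As, frac=span, it=0, delta=0.01 * np.ptp(As))
            fit = damping * np.interp(A, curve[:, 0], curve[:, 1])
            fit = np.nan_to_num(fit, nan=0.0)
            V[:, i] -= fit / 2.0
            V[:, j] += fit / 2.0
            max_change = max(max_change, float(np.max(np.abs(fit)) / 2.0))
        history.append(max_change)
        if max_change < epsilon:
            converged = True
            break
    out = ExpressionMatrix(
        pd.DataFrame(V, index=matrix.values.index, columns=matrix.values.columns),
        matrix.arrays,
        matrix.probe_to_gene,
    )
    return out, n_iter, converged, history


def summarize_probes_to_genes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Average each gene's probe log2 values per array (gene x array)."""
    gene = matrix.probe_to_gene.loc[matrix.values.index]
    return matrix.values.groupby(gene.to_numpy()).mean().rename_axis("gene_id")


def normalize_to_baseline(gene_matrix: pd.DataFrame, arrays: pd.DataFrame) -> GeneTimecourse:
    """Express each gene relative to its arm's 0 h mean (log2 scale).

    Subtracting the mean 0 h log2 value is the log-scale equivalent of
    dividing by the geometric mean of the 0 h replicate intensities, so
    the baseline-normalized values average 0 at 0 h per gene and arm.
    """
    out = gene_matrix.copy()
    for arm in arrays["arm"].unique():
        arm_ids = arrays.index[arrays["arm"] == arm]
        base_ids = arrays.index[(arrays["arm"] == arm) & (arrays["time_h"] == 0)]
        if len(base_ids) == 0:
            raise ValueError(f"arm {arm!r} has no 0 h arrays")
        baseline = gene_matrix[base_ids].mean(axis=1)
        out[arm_ids] = gene_matrix[arm_ids].sub(baseline, axis=0)
    return GeneTimecourse(out, arrays)


def permutation_de_test(values_t1, values_t2, n_perm: int | None = None, seed=0) -> float:
    """Two-sided permutation p-value for a mean difference between groups.

    When the number of distinct label splits ``C(n1+n2, n1)`` is small
    (<= 1000) the null is enumerated exactly and
    ``p = #{splits with |mean diff| >= |observed|} / #splits`` (the
    identity split always counts, so p >= 1/#splits); otherwise ``n_perm``
    random label shuffles are drawn and
    ``p = (1 + #{|null| >= |observed|}) / (n_perm + 1)``.
    """
    x = np.asarray(values_t1, dtype=np.float64)
    y = np.asarray(values_t2, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 replicates per group")
    pooled = np.concatenate([x, y])
    n1, n = x.size, x.size + y.size
    observed = abs(x.mean() - y.mean())
    n_splits = comb(n, n1)
    if n_splits <= EXACT_SPLIT_LIMIT:
        count = 0
        idx = np.arange(n)
        for group1 in combinations(idx, n1):
            g1 = np.array(group1)
            mask = np.zeros(n, dtype=bool)
            mask[g1] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            if stat >= observed - 1e-12:
                count += 1
        return count / n_splits
    if n_perm is None or n_perm < 99:
        raise ValueError("need n_perm >= 99 when sampling permutations")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n1].mean() - perm[n1:].mean()) >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` or ``bh`` (step-up FDR)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise EmptyInputError("no p-values to adjust")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def test_timepoint(
    tc: GeneTimecourse, arm: str, time_h, baseline_time_h=0, n_perm: int | None = None, seed=0
) -> pd.DataFrame:
    """Permutation-test every gene between two timepoints of one arm.

    Returns a DataFrame (gene_id, log2_change, pvalue) where
    ``log2_change`` is the mean difference ``time_h - baseline_time_h``.
    """
    later = tc.replicate_values(arm, time_h)
    base = tc.replicate_values(arm, baseline_time_h)
    rows = []
    ss = np.random.SeedSequence(seed)
    for gene, child in zip(later.index, ss.spawn(len(later.index))):
        x = later.loc[gene].to_numpy()
        y = base.loc[gene].to_numpy()
        p = permutation_de_test(x, y, n_perm=n_perm, seed=child)
        rows.append({"gene_id": gene, "log2_change": x.mean() - y.mean(), "pvalue": p})
    return pd.DataFrame(rows)


def delta_delta_ct(ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
    """Relative qPCR quantification.

    ``dCt = Ct_target - Ct_reference`` within each condition;
    ``ddCt = dCt_treated - dCt_control``; fold change = ``2 ** -ddCt``.
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(ddct), float(2.0 ** (-ddct))
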
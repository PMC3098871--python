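"""ChIP x expression integration and gene-set over-representation.

Binding calls from two conditions are joined to the expression time
course in one table per gene; genes are ranked by the binding change
(stimulated minus basal consensus height), and gene lists are tested for
over-representation in user-supplied GMT collections with the one-tailed
hypergeometric (Fisher's exact) test, reporting for each set the pathway
ratio -- the fraction of the set's genes recovered in the data set --
alongside the p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LayoutConsistencyError
from .chip import calls_to_frame

__all__ = ["build_integrated_table", "top_k", "fisher_enrichment"]


def _height_frame(calls, label: str) -> pd.DataFrame:
    if calls is None or len(calls) == 0:
        return pd.DataFrame(columns=["gene_id", label]).set_index("gene_id")
    df = calls_to_frame(calls)
    if df["gene_id"].duplicated().any():
        raise LayoutConsistencyError(f"duplicate gene rows in {label} binding calls")
    return df.set_index("gene_id")[["consensus_height"]].rename(
        columns={"consensus_height": label}
    )


def build_integrated_table(calls_basal, calls_stimulated, timecourse) -> pd.DataFrame:
    """Outer-join binding heights with per-gene expression log2 ratios.

    One row per gene with ``height_basal``, ``height_stimulated``,
    ``binding_delta = height_stimulated - height_basal`` (where both
    exist), and the replicate-mean log2 ratio for every (arm, timepoint)
    as ``log2_<arm>_<t>h``.  Sorted by ``binding_delta`` descending with
    missing deltas last, ties broken by gene id.  Genes absent from a
    source carry NaN in that source's columns.
    """
    hb = _height_frame(calls_basal, "height_basal")
    hs = _height_frame(calls_stimulated, "height_stimulated")
    table = hb.join(hs, how="outer")
    table["binding_delta"] = table["height_stimulated"] - table["height_basal"]

    if timecourse is not None:
        expr = timecourse.values
        if expr.index.duplicated().any():
            raise LayoutConsistencyError("duplicate gene rows in expression time course")
        meta = timecourse.arrays
        for arm in sorted(meta["arm"].unique()):
            for t in sorted(meta["time_h"].unique()):
                ids = meta.index[(meta["arm"] == arm) & (meta["time_h"] == t)]
                table = table.join(
                    expr[ids].mean(axis=1).rename(f"log2_{arm}_{t}h"), how="outer"
                )
    table = table.rename_axis("gene_id").reset_index()
    table = table.sort_values(
        ["binding_delta", "gene_id"], ascending=[False, True], na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def top_k(table: pd.DataFrame, k: int = 57) -> pd.DataFrame:
    """First ``k`` genes by binding change (table is already sorted)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        import warnings

        warnings.warn(f"k={k} exceeds table size {len(table)}; returning all rows",
                      stacklevel=2)
        return table.copy()
    return table.head(k).copy()


def fisher_enrichment(dataset, sets, universe) -> pd.DataFrame:
    """One-tailed over-representation of ``dataset`` in each gene set.

    For a set with ``K`` members in the universe (size ``N``) and a data
    set of ``n`` genes, the p-value is the hypergeometric upper tail
    ``P(X >= overlap)``; the ratio is ``overlap / K`` (the fraction of the
    set recovered).  Sets are intersected with the universe first; results
    are sorted by p-value ascending, ties by set name.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    dataset = set(dataset)
    if not dataset <= universe:
        raise ValueError("dataset must be a subset of the universe")
    N, n = len(universe), len(dataset)
    rows = []
    for name, members in sets.items():
        in_univ = set(members) & universe
        K = len(in_univ)
        k = len(in_univ & dataset)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "dataset_size": n,
                "universe_size": N,
                "ratio": (k / K) if K else float("nan"),
                "pvalue": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["neg_log10_p"] = -np.log10(df["pvalue"])
    return df.sort_values(["pvalue", "set_name"], kind="mergesort").reset_index(drop=True)
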
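"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study design the pipeline targets: promoter
tiling arrays of 4--6 probes per gene at roughly 300 bp spacing spanning
-2000..+800 bp around the TSS, two-colour ChIP arrays with binding events
whose footprint follows the sheared-fragment coverage model, promoter
sequences with motif instances planted at recorded positions, one-colour
expression time courses (3 replicates x 0/2/12/24 h x vehicle/inhibitor
arms) with intensity-dependent dye bias, and GMT gene-set collections with
one deliberately enriched set.  Every planted signal is returned in a
machine-readable truth table; no untracked signal is injected, and every
generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import LayoutConsistencyError
from .io import ChipArraySet
from .motifs import MotifMatrix, reverse_complement
from .peaks import FragmentLengthDist, PeakShape, peak_shape

__all__ = [
    "generate_layout",
    "make_chip_truth",
    "simulate_chip_arrays",
    "generate_promoter_sequences",
    "make_expression_truth",
    "simulate_expression_timecourse",
    "generate_gene_sets",
    "PROMOTER_SPAN",
    "DEFAULT_TIMES",
    "DEFAULT_ARMS",
]

#: Tiled promoter span relative to the TSS (closed interval, bp).
PROMOTER_SPAN = (-2000, 800)
DEFAULT_TIMES = (0, 2, 12, 24)
DEFAULT_ARMS = ("DMSO", "SIS3")


def generate_layout(n_genes: int, seed) -> pd.DataFrame:
    """Generate a promoter tiling layout.

    Each gene receives 4--6 probes on a jittered ~300 bp grid (consecutive
    offsets 250--350 bp apart), all within -2000..+800 bp of the TSS.

    Returns a DataFrame with columns ``probe_id``, ``gene_id``,
    ``offset_bp``.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    rng = np.random.default_rng(seed)
    lo, hi = PROMOTER_SPAN
    rows = []
    for g in range(n_genes):
        gene = f"G{g:05d}"
        n_probes = int(rng.integers(4, 7))
        steps = rng.integers(250, 351, size=n_probes - 1)
        span = int(steps.sum())
        start = int(rng.integers(lo, hi - span + 1))
        offsets = start + np.concatenate([[0], np.cumsum(steps)])
        for i, off in enumerate(offsets):
            rows.append({"probe_id": f"{gene}_P{i}", "gene_id": gene, "offset_bp": int(off)})
    return pd.DataFrame(rows)


def make_chip_truth(
    layout: pd.DataFrame,
    bound_fraction: float,
    fold: float,
    condition: str,
    seed,
    on_grid: int | None = None,
) -> pd.DataFrame:
    """Plant binding events in a random subset of genes.

    One row per gene: ``fold = 1`` encodes "no event"; planted centres are
    uniform within each gene's tiled span (snapped to the candidate-centre
    grid of step ``on_grid`` bp from the gene's first probe, if given).
    """
    rng = np.random.default_rng(seed)
    genes = layout["gene_id"].unique()
    n_bound = int(round(bound_fraction * genes.size))
    bound = set(rng.choice(genes, size=n_bound, replace=False))
    spans = layout.groupby("gene_id")["offset_bp"].agg(["min", "max"])
    rows = []
    for gene in genes:
        lo, hi = int(spans.loc[gene, "min"]), int(spans.loc[gene, "max"])
        if gene in bound:
            center = int(rng.integers(lo, hi + 1))
            if on_grid:
                center = lo + on_grid * int(round((center - lo) / on_grid))
                center = min(center, hi)
            rows.append({"gene_id": gene, "true_center": center, "true_fold": float(fold),
                         "condition": condition})
        else:
            rows.append({"gene_id": gene, "true_center": 0, "true_fold": 1.0,
                         "condition": condition})
    return pd.DataFrame(rows)


def simulate_chip_arrays(
    layout: pd.DataFrame,
    truth: pd.DataFrame,
    frag_dist: FragmentLengthDist | None = None,
    noise_sd_log2: float = 0.1,
    n_replicates: int = 3,
    seed=0,
    background: float = 500.0,
    shape: PeakShape | None = None,
) -> ChipArraySet:
    """Forward-simulate two-colour ChIP arrays from planted events.

    The expected IP/mock ratio at a probe ``x`` bp from the TSS of a gene
    with a planted event (centre ``c``, fold ``f``) is
    ``1 + (f - 1) * s(x - c)`` with ``s`` the fragment-coverage profile;
    multiplicative log-normal noise of sd ``noise_sd_log2`` (log2 scale) is
    applied independently per probe, replicate and channel, and the mock
    channel is centred at a common ``background`` intensity.
    """
    if noise_sd_log2 < 0:
        raise ValueError("noise_sd_log2 must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    unknown = set(truth["gene_id"]) - set(layout["gene_id"])
    if unknown:
        raise LayoutConsistencyError(f"truth references genes absent from layout: {sorted(unknown)[:5]}")
    if shape is None:
        shape = peak_shape(frag_dist or FragmentLengthDist.uniform())
    rng = np.random.default_rng(seed)
    tables = {}
    for condition, tr in truth.groupby("condition", sort=True):
        tr = tr.set_index("gene_id")
        merged = layout.merge(
            tr[["true_center", "true_fold"]], left_on="gene_id", right_index=True, how="left"
        )
        center = merged["true_center"].fillna(0).to_numpy(dtype=np.float64)
        fold = merged["true_fold"].fillna(1.0).to_numpy(dtype=np.float64)
        mu = 1.0 + (fold - 1.0) * shape(merged["offset_bp"].to_numpy() - center)
        for rep in range(1, n_replicates + 1):
            ip_noise = 2.0 ** rng.normal(0.0, noise_sd_log2, size=mu.size)
            mock_noise = 2.0 ** rng.normal(0.0, noise_sd_log2, size=mu.size)
            df = layout.copy()
            df["ip_intensity"] = background * mu * ip_noise
            df["mock_intensity"] = background * mock_noise
            tables[(condition, rep)] = df
    return ChipArraySet(layout=layout, tables=tables)


def generate_promoter_sequences(
    layout: pd.DataFrame,
    motif: MotifMatrix,
    plant_in,
    background_gc: float = 0.41,
    seed=0,
    span=PROMOTER_SPAN,
    plant_window=None,
):
    """Random promoter sequences with motif instances planted in chosen genes.

    One sequence per gene covers the tiled span (``span``, closed, relative
    to the TSS).  Background bases are i.i.d. with GC fraction
    ``background_gc``.  Each gene in ``plant_in`` receives one instance
    sampled position-wise from the motif's frequency matrix, inserted on a
    random strand at a recorded position (restricted to ``plant_window``
    offsets when given; either one ``(lo, hi)`` pair for all genes or a
    mapping gene -> ``(lo, hi)``, e.g. windows around planted binding-event
    centres).

    Returns ``(sequences, truth)`` where ``sequences`` maps gene to string
    and ``truth`` records gene, planted offset (of the instance start,
    relative to the TSS), strand and the instance sequence; unplanted genes
    are absent from the truth table.
    """
    if motif is None or motif.width == 0:
        raise ValueError("a non-empty motif matrix is required")
    if not 0.0 < background_gc < 1.0:
        raise ValueError("background_gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = span
    length = hi - lo + 1
    p = np.array([(1 - background_gc) / 2, background_gc / 2,
                  background_gc / 2, (1 - background_gc) / 2])
    bases = np.array(list("ACGT"))
    plant_in = set(plant_in)
    w = motif.width

    def window_for(gene):
        if plant_window is None:
            wlo, whi = lo, hi
        elif hasattr(plant_window, "get"):
            wlo, whi = plant_window[gene]
        else:
            wlo, whi = plant_window
        return max(wlo, lo), min(whi, hi - w + 1)

    sequences, truth_rows = {}, []
    for gene in layout["gene_id"].unique():
        seq = bases[rng.choice(4, size=length, p=p)]
        if gene in plant_in:
            instance = "".join(
                "ACGT"[i] for i in (rng.random((w, 1)) < motif.freq.cumsum(axis=1)).argmax(axis=1)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            win_lo, win_hi = window_for(gene)
            offset = int(rng.integers(win_lo, win_hi + 1))
            planted = instance if strand == "+" else reverse_complement(instance)
            idx = offset - lo
            seq[idx : idx + w] = list(planted)
            truth_rows.append(
                {"gene_id": gene, "offset": offset, "strand": strand, "instance": instance}
            )
        sequences[gene] = "".join(seq)
    return sequences, pd.DataFrame(truth_rows, columns=["gene_id", "offset", "strand", "instance"])


def make_expression_truth(
    gene_ids,
    n_up: int,
    n_down: int,
    effect_profile=(0.0, 1.0, 1.5, 2.0),
    sis3_attenuation: float = 0.0,
    seed=0,
    times=DEFAULT_TIMES,
) -> pd.DataFrame:
    """Assign up/down/null regulation to genes.

    ``effect_profile`` gives the log2 effect per timepoint for an
    up-regulated gene (negated for down-regulated genes); the 0 h entry
    must be 0.  ``sis3_attenuation`` multiplies every effect in the
    inhibitor arm (0 = complete block of the response).
    """
    gene_ids = list(gene_ids)
    if n_up + n_down > len(gene_ids):
        raise ValueError("more regulated genes requested than genes available")
    profile = np.asarray(effect_profile, dtype=np.float64)
    if profile.size != len(times) or profile[0] != 0.0:
        raise ValueError("effect_profile must have one entry per timepoint, 0 at 0 h")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(gene_ids), size=n_up + n_down, replace=False)
    direction = {}
    for i in chosen[:n_up]:
        direction[gene_ids[i]] = "up"
    for i in chosen[n_up:]:
        direction[gene_ids[i]] = "down"
    rows = []
    for gene in gene_ids:
        d = direction.get(gene, "null")
        sign = {"up": 1.0, "down": -1.0, "null": 0.0}[d]
        row = {"gene_id": gene, "direction": d, "sis3_attenuation": sis3_attenuation}
        for t, e in zip(times, profile):
            row[f"effect_{t}h"] = sign * e
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_expression_timecourse(
    truth: pd.DataFrame,
    probes_per_gene: int = 3,
    dye_bias: float = 0.3,
    noise_sd_log2: float = 0.25,
    seed=0,
    times=DEFAULT_TIMES,
    arms=DEFAULT_ARMS,
    n_replicates: int = 3,
):
    """Forward-simulate one-colour expression arrays from planted effects.

    Each array (arm x timepoint x replicate) measures
    ``log2 intensity = gene baseline + probe affinity + arm-scaled
    timepoint effect + smooth intensity-dependent array bias + noise``.
    The inhibitor arm's effects are multiplied by each gene's
    ``sis3_attenuation``.  ``dye_bias`` is the amplitude bound of the
    per-array smooth bias (log2); 0 disables it.

    Returns ``(long_table, truth)`` with columns ``probe_id, gene_id,
    intensity, time_h, arm, replicate`` (linear-scale intensities).
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    if not times or not arms or 0 not in times:
        raise ValueError("design must include both arms and a 0 h timepoint")
    for t in times:
        if f"effect_{t}h" not in truth.columns:
            raise ValueError(f"truth lacks effect column for {t} h")
    rng = np.random.default_rng(seed)
    genes = truth["gene_id"].tolist()
    baseline = rng.normal(8.0, 1.5, size=len(genes))
    probe_aff = rng.normal(0.0, 0.3, size=(len(genes), probes_per_gene))
    atten = truth["sis3_attenuation"].to_numpy(dtype=np.float64)
    effects = {t: truth[f"effect_{t}h"].to_numpy(dtype=np.float64) for t in times}
    rows = []
    for arm in arms:
        arm_scale = atten if arm == "SIS3" else np.ones_like(atten)
        for t in times:
            for rep in range(1, n_replicates + 1):
                amp = rng.uniform(-dye_bias, dye_bias) if dye_bias > 0 else 0.0
                for gi, gene in enumerate(genes):
                    signal = baseline[gi] + effects[t][gi] * arm_scale[gi]
                    for pj in range(probes_per_gene):
                        x = signal + probe_aff[gi, pj]
                        bias = amp * np.sin((x - 8.0) / 2.0)
                        noise = rng.normal(0.0, noise_sd_log2) if noise_sd_log2 > 0 else 0.0
                        rows.append(
                            {
                                "probe_id": f"{gene}_E{pj}",
                                "gene_id": gene,
                                "intensity": 2.0 ** (x + bias + noise),
                                "time_h": t,
                                "arm": arm,
                                "replicate": rep,
                            }
                        )
    return pd.DataFrame(rows), truth


def generate_gene_sets(
    n_sets: int,
    set_sizes,
    enriched_set,
    universe,
    seed=0,
    overlap_fraction: float = 0.8,
) -> dict:
    """Random gene sets over ``universe``, one heavily overlapping ``enriched_set``.

    The first set draws ``overlap_fraction`` of its members from
    ``enriched_set`` (the rest uniformly from outside it); remaining sets
    are uniform draws from the universe.
    """
    universe = list(universe)
    if np.isscalar(set_sizes):
        set_sizes = [int(set_sizes)] * n_sets
    if len(set_sizes) != n_sets:
        raise ValueError("set_sizes must have one entry per set")
    if any(s < 1 for s in set_sizes):
        raise ValueError("set sizes must be >= 1")
    if any(s > len(universe) for s in set_sizes):
        raise ValueError("set size exceeds universe size")
    enriched = [g for g in universe if g in set(enriched_set)]
    rng = np.random.default_rng(seed)
    sets = {}
    for i, size in enumerate(set_sizes):
        name = f"SET_{i:03d}"
        if i == 0 and enriched:
            n_in = min(int(round(overlap_fraction * size)), len(enriched))
            inside = list(rng.choice(enriched, size=n_in, replace=False))
            outside_pool = [g for g in universe if g not in set(enriched)]
            n_out = min(size - n_in, len(outside_pool))
            outside = list(rng.choice(outside_pool, size=n_out, replace=False))
            sets[name] = sorted(inside + outside)
        else:
            sets[name] = sorted(rng.choice(universe, size=size, replace=False))
    return sets
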
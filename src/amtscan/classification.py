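"""Pooling of standardised Tajima's D and trait-class assignment of outliers.

Per-window Z-scores of Tajima's D are averaged (unweighted) over the
anadromous and the resident populations separately. Outlier windows are
then split by pool-wise tertiles into four selection-regime trait classes:

* ``LA_LR``  low in both pools -> opposing directional selection
  (migration-propensity loci)
* ``LA_MHR`` low anadromous only -> directional selection in migrants,
  relaxed in residents (migratory-lifestyle loci)
* ``MHA_LR`` low resident only -> directional selection in residents
  (residency loci)
* ``MHA_MHR`` neither low -> candidate balancing / relaxed selection

"Low" means at or below the lower tertile of the respective pooled-score
distribution; by default the tertiles are computed on the outlier windows
themselves (an alternative reference distribution can be supplied).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import PopulationPanel, ValidationError

TRAIT_CLASSES = ("LA_LR", "LA_MHR", "MHA_LR", "MHA_MHR")

# expected class shares under a random two-way tertile partition
CLASS_CHANCE_SHARE = {
    "LA_LR": 1.0 / 9.0,
    "LA_MHR": 2.0 / 9.0,
    "MHA_LR": 2.0 / 9.0,
    "MHA_MHR": 4.0 / 9.0,
}


def pool_window_scores(
    z_records: pd.DataFrame, panel: PopulationPanel, value_col: str = "z_td"
) -> pd.DataFrame:
    """Mean standardised score per window over the anadromous/resident pools.

    ``z_records`` is the per-population window track with a ``value_col``
    column (missing entries dropped from the mean). Returns one row per
    window with ``mean_z_A``, ``mean_z_R`` and the number of contributing
    populations per pool.
    """
    df = z_records.copy()
    df["ecotype"] = [panel.ecotype_of(p) for p in df["pop"]]
    out = None
    for eco in ("A", "R"):
        sub = df[df["ecotype"] == eco]
        grp = sub.groupby(["contig", "start", "end"], sort=False)[value_col].agg(
            [("mean", "mean"), ("n", lambda s: int(np.isfinite(s).sum()))]
        )
        grp = grp.rename(columns={"mean": f"mean_z_{eco}", "n": f"n_pops_{eco}"})
        out = grp if out is None else out.join(grp)
    return out.reset_index()


def tertile_trait_classes(
    pooled: pd.DataFrame,
    reference: pd.DataFrame | None = None,
) -> pd.Series:
    """Assign each outlier window to one of the four trait classes.

    Tertile cut points are computed per pool on ``reference`` (defaults to
    ``pooled`` itself, i.e. the outlier-window distribution). A window is
    "low" in a pool when its pooled score is at or below the lower-tertile
    cut point (inclusive). Windows lacking a finite pooled score in either
    pool are rejected.
    """
    if len(pooled) < 3:
        raise ValidationError("need >= 3 outlier windows to form tertiles")
    ref = pooled if reference is None else reference
    if not (np.isfinite(pooled["mean_z_A"]).all() and np.isfinite(pooled["mean_z_R"]).all()):
        raise ValidationError("pooled scores must be finite in both pools for classification")
    cut_a = float(np.quantile(ref["mean_z_A"].dropna().to_numpy(), 1.0 / 3.0))
    cut_r = float(np.quantile(ref["mean_z_R"].dropna().to_numpy(), 1.0 / 3.0))
    low_a = pooled["mean_z_A"].to_numpy() <= cut_a
    low_r = pooled["mean_z_R"].to_numpy() <= cut_r
    labels = np.where(
        low_a,
        np.where(low_r, "LA_LR", "LA_MHR"),
        np.where(low_r, "MHA_LR", "MHA_MHR"),
    )
    return pd.Series(labels, index=pooled.index, name="trait_class")


def assign_genes_to_windows(windows: pd.DataFrame, genes, flank: int = 10_000):
    """Genes intersecting each window extended by ``flank`` on both sides.

    Intersection is half-open: a gene ending exactly at ``start - flank``
    is not assigned. Returns ``(per_window, union)`` where ``per_window``
    maps row index -> sorted gene-id list and ``union`` is the deduplicated
    gene set over all windows.
    """
    per_window: dict[int, list[str]] = {}
    union: set[str] = set()
    by_contig: dict[str, list] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for idx, row in windows.iterrows():
        lo = row["start"] - flank
        hi = row["end"] + flank
        hits = [
            g.gene_id
            for g in by_contig.get(row["contig"], [])
            if g.start < hi and g.end > lo
        ]
        hits.sort()
        per_window[idx] = hits
        union.update(hits)
    return per_window, union


def gene_overlap_test(set_a, set_b, universe, n_perm: int = 10_000, seed: int | None = None):
    """Overlap of two gene sets: hypergeometric tail and permutation p-value.

    The permutation null resamples ``|set_a|``-sized sets uniformly from
    the universe and recomputes the overlap with ``set_b``;
    p = (1 + #{overlap* >= observed}) / (n_perm + 1).
    """
    universe = list(dict.fromkeys(universe))
    ua = set(set_a)
    ub = set(set_b)
    if not ua <= set(universe) or not ub <= set(universe):
        raise ValidationError("gene sets must be subsets of the universe")
    observed = len(ua & ub)
    M, K, N = len(universe), len(ua), len(ub)
    p_hyper = float(hypergeom.sf(observed - 1, M, K, N))
    rng = np.random.default_rng(seed)
    uni = np.array(universe)
    in_b = np.isin(uni, list(ub))
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(len(uni), size=K, replace=False)
        if int(in_b[draw].sum()) >= observed:
            hits += 1
    p_perm = (1 + hits) / (n_perm + 1)
    return p_hyper, p_perm
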
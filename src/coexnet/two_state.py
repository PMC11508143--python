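"""Normal-state vs. stress-state centrality comparison and key hub genes.

The two condition-specific networks are generally of different size and
density, so raw centralities are not comparable. Each measure is first
scaled by its within-network maximum (so the most central gene in each
network scores 1), a gene absent from a network scores 0 there, and the
centrality change is the difference in percentage points,
``delta% = (c_stress - c_normal) * 100``, bounded in [-100, 100]. A gene
absent under control that becomes the strongest hub under stress therefore
scores near +100. Key hub genes are genes that (a) appear in the global
network and (b) gain more than a threshold (default 80 percentage points) in
degree centrality; the count of the four measures (DG, BW, CN, CC) clearing
the same threshold annotates each key gene.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

MEASURES = ("DG", "BW", "CN", "CC")


def normalize_centrality(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each centrality column by its within-network maximum.

    An all-zero column is left as zeros. The input must be non-empty.
    """
    if table.empty:
        raise ValueError("cannot normalize an empty centrality table")
    out = table.loc[:, list(MEASURES)].astype(float).copy()
    for m in MEASURES:
        top = out[m].max()
        if top > 0:
            out[m] = out[m] / top
    return out


def centrality_change(normal: pd.DataFrame, saline: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-measure centrality change between two normalized tables.

    Rows are the union of genes from both networks; a gene missing from one
    network has centrality 0 there. Columns: ``n_<m>``, ``s_<m>`` and
    ``d<m>`` (the change in percentage points) for each measure, plus
    ``in_normal`` / ``in_saline`` presence flags.
    """
    genes = normal.index.union(saline.index)
    out = pd.DataFrame(index=genes)
    out.index.name = "gene_id"
    for m in MEASURES:
        cn = normal[m].reindex(genes).fillna(0.0) if m in normal else pd.Series(0.0, index=genes)
        cs = saline[m].reindex(genes).fillna(0.0) if m in saline else pd.Series(0.0, index=genes)
        out[f"n_{m}"] = cn
        out[f"s_{m}"] = cs
        out[f"d{m}"] = (cs - cn) * 100.0
    out["in_normal"] = genes.isin(normal.index)
    out["in_saline"] = genes.isin(saline.index)
    return out


def identify_key_genes(
    changes: pd.DataFrame,
    global_nodes: Iterable,
    modules: pd.Series | None = None,
    threshold: float = 80.0,
) -> pd.DataFrame:
    """Key hub genes: present in the global network with dDG > threshold.

    "Surpassed" is read strictly, so a change of exactly ``threshold`` does
    not qualify. ``n_measures_passed`` counts how many of DG/BW/CN/CC exceed
    the same threshold (at least 1 by construction). Genes are annotated with
    their module label ("grey" when unknown).
    """
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    global_nodes = set(global_nodes)
    mask = changes.index.isin(global_nodes) & (changes["dDG"] > threshold)
    keys = changes.loc[mask].copy()
    passed = np.zeros(len(keys), dtype=int)
    for m in MEASURES:
        passed += (keys[f"d{m}"] > threshold).to_numpy(dtype=int)
    out = pd.DataFrame(index=keys.index)
    out.index.name = "gene_id"
    if modules is not None:
        out["module"] = modules.reindex(out.index).fillna("grey")
    else:
        out["module"] = "grey"
    out["n_measures_passed"] = passed
    for m in MEASURES:
        out[f"d{m}"] = keys[f"d{m}"]
    return out.sort_values("dDG", ascending=False)


def key_gene_summary(modules: pd.Series, key_genes: pd.DataFrame) -> pd.DataFrame:
    """Per-module bookkeeping: total genes, key genes and key-gene percentage.

    Mirrors a modules-by-key-genes summary table; the final column "total"
    aggregates over all modules. Percentages are rounded to one decimal.
    """
    module_order = [m for m in pd.unique(modules)]
    counts = modules.value_counts()
    rows = {}
    for m in module_order:
        total = int(counts[m])
        n_keys = int((key_genes["module"] == m).sum())
        rows[m] = (total, n_keys)
    grand_total = int(sum(t for t, _ in rows.values()))
    grand_keys = int(len(key_genes))
    rows["total"] = (grand_total, grand_keys)
    out = pd.DataFrame(rows, index=["total_genes", "key_genes"]).T
    out["percentage"] = (100.0 * out["key_genes"] / out["total_genes"]).round(1)
    out.index.name = "module"
    return out
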
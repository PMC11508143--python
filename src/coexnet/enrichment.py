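"""Hypergeometric over-representation analysis of module gene sets.

For a module of n genes drawn from a universe of N annotated genes, a term
with K members and an observed overlap of k genes is scored by the
hypergeometric upper tail P(X >= k), the standard one-sided
over-representation test. P-values are adjusted across all (module, term)
pairs with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexnet.io import AnnotationMap


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    module_genes: Mapping[str, Iterable] | Iterable,
    annotations: AnnotationMap,
    universe: Iterable | None = None,
) -> pd.DataFrame:
    """Over-representation of one or several modules against an annotation map.

    Parameters
    ----------
    module_genes : mapping of module label -> gene ids, or a single gene set.
    annotations : AnnotationMap from a GMT file.
    universe : background gene ids; default is every gene that appears in the
        annotation map. Terms are intersected with the universe and modules
        must be subsets of it.

    Returns
    -------
    Long DataFrame (module, term_id, term_name, namespace, kx, n, K, N, p,
    p_adjusted) sorted by adjusted then raw p, BH-adjusted across the whole
    table.
    """
    if not isinstance(module_genes, Mapping):
        module_genes = {"module": module_genes}
    universe = set(universe) if universe is not None else set(annotations.all_genes())
    if not universe:
        raise ValueError("empty gene universe")
    N = len(universe)
    rows = []
    for label, genes in module_genes.items():
        genes = set(genes)
        outside = genes - universe
        if outside:
            raise ValueError(
                f"module {label!r} has {len(outside)} gene(s) outside the universe, "
                f"e.g. {sorted(map(str, outside))[:5]}"
            )
        n = len(genes)
        for gs in annotations:
            term = gs.genes & universe
            K = len(term)
            if K == 0:
                continue
            kx = len(genes & term)
            rows.append(
                {
                    "module": label,
                    "term_id": gs.term_id,
                    "term_name": gs.name,
                    "namespace": gs.namespace,
                    "kx": kx,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p": hypergeom_pvalue(kx, N, K, n),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["module", "term_id", "term_name", "namespace", "kx", "n", "K", "N", "p"],
    )
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"])
        out = out.sort_values(["p_adjusted", "p", "term_id"]).reset_index(drop=True)
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out
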
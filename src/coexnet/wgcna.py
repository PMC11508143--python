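"""Unsigned weighted co-expression networks, modules and module-trait tests.

The network model: pairwise Pearson correlation r of gene expression across
samples, soft-thresholded into an adjacency a = |r|^beta. The power beta is
the smallest integer at which the network's degree distribution approximates
scale-free topology (signed fit index R^2 >= 0.9 by default). Topological
overlap (TOM) augments each edge with shared-neighbour weight, and modules
are branches of an average-linkage dendrogram of the TOM dissimilarity
1 - TOM, subject to a minimum module size. Each module is summarized by its
eigengene (first principal component over samples), which is correlated
against binary condition x time indicators to give module-trait
relationships with Student-t p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

#: WGCNA-style size-ranked module colour sequence; "grey" is reserved for
#: unassigned genes.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)
UNASSIGNED = "grey"


def pearson_correlation(x: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation of a genes x samples matrix."""
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples for meaningful correlations")
    variances = x.var(axis=1, ddof=1)
    flat = variances.index[variances == 0].tolist()
    if flat:
        raise ValueError(
            "zero-variance gene(s) cannot be correlated (should have been "
            f"filtered): {', '.join(map(str, flat[:10]))}"
        )
    r = np.corrcoef(x.to_numpy(dtype=float))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=x.index, columns=x.index)


def soft_adjacency(r: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency a = |r|^beta."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    return np.abs(r) ** beta


def connectivity(a: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum_{j != i} a[i, j]."""
    vals = a.to_numpy(dtype=float)
    k = vals.sum(axis=1) - np.diag(vals)
    return pd.Series(k, index=a.index, name="connectivity")


def scale_free_fit(a: pd.DataFrame, nbins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of an adjacency matrix.

    Connectivities are histogrammed into ``nbins`` equal-width bins;
    log10(mean frequency) is regressed on log10(mean connectivity) over the
    occupied bins. Returns ``(signed_r2, slope)`` where
    ``signed_r2 = -sign(slope) * R^2``, so a scale-free (decreasing) degree
    distribution scores positively.
    """
    k = connectivity(a).to_numpy()
    if np.isclose(k.max(), k.min()):
        raise ValueError("degenerate network: all connectivities equal")
    edges = np.linspace(k.min(), k.max(), nbins + 1)
    # assign each k to a bin; right edge of the last bin is inclusive
    idx = np.clip(np.digitize(k, edges[1:-1], right=False), 0, nbins - 1)
    log_k, log_freq = [], []
    for b in range(nbins):
        members = k[idx == b]
        if members.size == 0:
            continue
        mean_k = members.mean()
        if mean_k <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_freq.append(np.log10(members.size / k.size))
    if len(log_k) < 2:
        raise ValueError("fewer than 2 occupied connectivity bins")
    fit = stats.linregress(log_k, log_freq)
    r2 = float(fit.rvalue**2)
    slope = float(fit.slope)
    return -np.sign(slope) * r2, slope


@dataclass
class SoftThresholdReport:
    """Per-power scale-free statistics and the selected soft threshold."""

    table: pd.DataFrame  # power, signed_r2, slope, mean_k, median_k, max_k
    power: int
    r2_cut: float
    reached_cut: bool

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["chosen"] = out["power"] == self.power
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def pick_soft_threshold(
    x: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_cut: float = 0.9,
    nbins: int = 10,
) -> SoftThresholdReport:
    """Choose the soft threshold as the smallest power whose signed scale-free
    fit index reaches ``r2_cut``; fall back to the best-fitting power (flagged
    via ``reached_cut=False``) if none does.
    """
    powers = list(powers)
    if not powers or any(b2 <= b1 for b1, b2 in zip(powers, powers[1:])):
        raise ValueError("powers must be a non-empty ascending sequence")
    r = pearson_correlation(x)
    abs_r = np.abs(r.to_numpy())
    rows = []
    for beta in powers:
        a = pd.DataFrame(abs_r**beta, index=r.index, columns=r.columns)
        k = connectivity(a)
        try:
            signed_r2, slope = scale_free_fit(a, nbins=nbins)
        except ValueError:
            signed_r2, slope = np.nan, np.nan
        rows.append(
            {
                "power": beta,
                "signed_r2": signed_r2,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(k.median()),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    ok = table["signed_r2"] >= r2_cut
    if ok.any():
        power = int(table.loc[ok, "power"].iloc[0])
        reached = True
    else:
        power = int(table.loc[table["signed_r2"].idxmax(), "power"])
        reached = False
    return SoftThresholdReport(table=table, power=power, r2_cut=r2_cut, reached_cut=reached)


def tom_similarity(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix.

    t[i,j] = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj (u != i, j) and k the connectivity; t[i,i] = 1.
    """
    vals = a.to_numpy(dtype=float).copy()
    np.fill_diagonal(vals, 0.0)
    l = vals @ vals
    k = vals.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - vals
    t = (l + vals) / denom
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=a.index, columns=a.columns)


def cluster_modules(
    tom: pd.DataFrame,
    min_module_size: int = 35,
    cut_height: float | None = None,
) -> pd.Series:
    """Detect modules by average-linkage clustering of the TOM dissimilarity.

    The dendrogram of ``1 - TOM`` is cut at ``cut_height`` (default: 0.99 x
    the maximum merge height); resulting clusters smaller than
    ``min_module_size`` are labelled "grey", and the rest are renamed, in
    decreasing size order, to the conventional colour sequence starting at
    "turquoise". Deterministic: ties in size are broken by first gene
    position.
    """
    n = tom.shape[0]
    if min_module_size > n:
        raise ValueError(
            f"min_module_size={min_module_size} exceeds gene count {n}"
        )
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0  # guard tiny asymmetries
    z = linkage(squareform(dissim, checks=False), method="average")
    if cut_height is None:
        cut_height = 0.99 * float(z[:, 2].max())
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=tom.index, name="module", dtype=object)
    # order clusters by decreasing size, ties by first occurrence
    sizes: dict[int, int] = {}
    first_pos: dict[int, int] = {}
    for pos, c in enumerate(raw):
        sizes[c] = sizes.get(c, 0) + 1
        first_pos.setdefault(c, pos)
    big = [c for c in sizes if sizes[c] >= min_module_size]
    big.sort(key=lambda c: (-sizes[c], first_pos[c]))
    for rank, c in enumerate(big):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        labels.iloc[raw == c] = color
    return labels


def module_eigengene(x: pd.DataFrame, members: Iterable) -> pd.Series:
    """First-principal-component summary of a module's expression profile.

    ``x`` is genes x samples; the member genes are z-scored per gene and the
    first right singular vector (one score per sample) is returned with unit
    Euclidean norm, sign-oriented so that its correlation with the module's
    mean expression profile is non-negative.
    """
    members = list(members)
    missing = [g for g in members if g not in x.index]
    if missing:
        raise KeyError(f"module member(s) not in expression matrix: {missing[:10]}")
    if len(members) < 2:
        raise ValueError("a module needs at least 2 genes for an eigengene")
    sub = x.loc[members].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_profile = x.loc[members].mean(axis=0).to_numpy()
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    return pd.Series(e, index=x.columns, name="eigengene")


def module_eigengenes(x: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """Eigengenes for every non-grey module; columns ordered by module size."""
    out = {}
    counts = modules.value_counts()
    for label in sorted(counts.index, key=lambda m: (-counts[m], m)):
        if label == UNASSIGNED:
            continue
        members = modules.index[modules == label]
        out[label] = module_eigengene(x, members)
    return pd.DataFrame(out, index=x.columns)


def trait_design(sheet: pd.DataFrame) -> pd.DataFrame:
    """Binary condition x time indicator columns (ct_0h ... ss_48h)."""
    prefix = {"control": "ct", "salt": "ss"}
    design = {}
    for cond in ("control", "salt"):
        for t in sorted(sheet.loc[sheet["condition"] == cond, "time_h"].unique()):
            t_str = f"{t:g}"
            col = f"{prefix[cond]}_{t_str}h"
            design[col] = (
                (sheet["condition"] == cond) & (sheet["time_h"] == t)
            ).astype(int).to_numpy()
    return pd.DataFrame(design, index=sheet["sample_id"].to_numpy())


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via Student t with n-2 df.

    t = r * sqrt((n-2) / (1-r^2)); |r| = 1 (or an underflowing p) reports the
    smallest positive normal float rather than 0.
    """
    if n < 4:
        raise ValueError("need at least 4 samples")
    floor = float(np.finfo(float).tiny)
    if 1.0 - r * r <= 0:
        return floor
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    return float(min(max(p, floor), 1.0))


def module_trait_relationships(
    eigengenes: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Correlate each module eigengene with each trait indicator.

    Returns a long table (module, trait, r, p); a constant indicator yields
    NaN r and p (correlation undefined).
    """
    if eigengenes.shape[0] < 4:
        raise ValueError("module-trait relationships need at least 4 samples")
    design = design.loc[eigengenes.index]
    n = eigengenes.shape[0]
    rows = []
    for module in eigengenes.columns:
        e = eigengenes[module].to_numpy(dtype=float)
        for trait in design.columns:
            d = design[trait].to_numpy(dtype=float)
            if np.all(d == d[0]):
                rows.append({"module": module, "trait": trait, "r": np.nan, "p": np.nan})
                continue
            r = float(np.corrcoef(e, d)[0, 1])
            rows.append(
                {"module": module, "trait": trait, "r": r, "p": correlation_pvalue(r, n)}
            )
    return pd.DataFrame(rows)


class WGCNA(BaseEstimator, TransformerMixin):
    """Weighted co-expression network + module detection as a transformer.

    Fit on a samples x genes expression matrix; genes (features) are
    clustered into modules and ``transform`` projects samples onto the module
    eigengene space (analogous to sklearn's ``FeatureAgglomeration``, with
    PCA-style scores per cluster).

    Parameters
    ----------
    power : int or None
        Soft threshold; None selects it by the scale-free criterion.
    powers : sequence of int
        Candidate powers scanned when ``power`` is None.
    r2_cut : float
        Signed scale-free fit index required of the chosen power.
    min_module_size : int
        Branches smaller than this are left unassigned ("grey").
    cut_height : float or None
        Static dendrogram cut height; None uses 0.99 x max merge height.
    compute_tom : bool
        If False, cluster on adjacency dissimilarity instead of TOM
        (debugging aid; the standard workflow keeps True).

    Attributes
    ----------
    power_ : chosen soft threshold.
    soft_threshold_ : SoftThresholdReport (present also when power was fixed).
    correlation_, adjacency_, tom_ : gene x gene DataFrames.
    labels_ : ndarray of module colour labels, one per gene.
    modules_ : dict mapping module colour -> list of gene ids (non-grey).
    eigengenes_ : samples x modules DataFrame of eigengene scores.
    """

    def __init__(
        self,
        power: int | None = None,
        powers: Sequence[int] = tuple(range(1, 21)),
        r2_cut: float = 0.9,
        min_module_size: int = 35,
        cut_height: float | None = None,
        compute_tom: bool = True,
    ):
        self.power = power
        self.powers = powers
        self.r2_cut = r2_cut
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.compute_tom = compute_tom

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        x = X.T  # genes x samples
        self.soft_threshold_ = pick_soft_threshold(
            x, powers=self.powers, r2_cut=self.r2_cut
        )
        self.power_ = int(self.power) if self.power is not None else self.soft_threshold_.power
        self.correlation_ = pearson_correlation(x)
        self.adjacency_ = soft_adjacency(self.correlation_, self.power_)
        sim = tom_similarity(self.adjacency_) if self.compute_tom else self.adjacency_
        self.tom_ = sim
        labels = cluster_modules(
            sim, min_module_size=self.min_module_size, cut_height=self.cut_height
        )
        self.labels_ = labels.to_numpy(dtype=object)
        self.module_assignment_ = labels
        self.modules_ = {
            m: list(labels.index[labels == m])
            for m in pd.unique(labels)
            if m != UNASSIGNED
        }
        self.eigengenes_ = module_eigengenes(x, labels)
        # per-module projection state for transform()
        self._proj = {}
        for m, members in self.modules_.items():
            sub = x.loc[members].to_numpy(dtype=float)
            mu = sub.mean(axis=1)
            sd = sub.std(axis=1, ddof=1)
            sd[sd == 0] = 1.0
            z = (sub - mu[:, None]) / sd[:, None]
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            w = u[:, 0]
            e = vt[0]
            mean_profile = sub.mean(axis=0)
            if np.corrcoef(e, mean_profile)[0, 1] < 0:
                w = -w
            self._proj[m] = (np.asarray(members, dtype=object), mu, sd, w)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Project samples onto the fitted module eigengene directions."""
        check_is_fitted(self, "modules_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(
                np.asarray(X, dtype=float), columns=self.feature_names_in_
            )
        scores = {}
        for m, (members, mu, sd, w) in self._proj.items():
            z = (X.loc[:, members].to_numpy(dtype=float) - mu) / sd
            s = z @ w
            norm = np.linalg.norm(s)
            scores[m] = s / norm if norm > 0 else s
        return pd.DataFrame(scores, index=X.index)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "modules_")
        return np.asarray(list(self.modules_), dtype=object)
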
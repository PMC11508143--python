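"""Synthetic two-condition time-course count matrices with planted structure.

The generator emulates the study design the pipeline targets: 2 conditions
(control / salt) x 6 time points (0, 3, 6, 12, 24, 48 h) x 3 replicates = 36
libraries. Genes belong to co-expression modules driven by a shared latent
module activity — a maximally decorrelated random trajectory over time plus
per-sample noise — scaled by per-gene loadings, with Gaussian gene-level
noise on the log2 scale. Counts are drawn negative-binomially around
``2**(baseline + latent)`` times a log-normal library-size factor, matching
the median-of-ratios normalization upstream.

Stress-specific modules have their loadings zeroed under control, so their
genes are pure noise in the control samples: the planted phenomenon is
differential *connectivity*, not differential mean. The planted
stress-emergent hubs are the majority core of each stress module carrying
the top-decile loadings of the whole transcriptome; under a soft threshold
near 10 an edge landscape is essentially binary (a gene either joins a
dense block or detaches), so hub-ness is planted at the block level: stress
blocks are absent from the control network and are the maximal-degree
structure of the stress network, which is exactly what the two-state
centrality-change criterion is supposed to recover. Constitutive modules
correlate moderately — enough to cluster in the 36-sample global topology
yet too weakly to pass the 0.1 TOM edge threshold within an 18-sample
state network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

BACKGROUND = "background"


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults give 1,000 genes: 6 modules of 80 (the last two stress-specific,
    each with a 50-gene planted-hub core carrying the top-decile loadings of
    the transcriptome) plus 520 background genes, across 36 samples.
    """

    n_genes: int = 1000
    n_modules: int = 6
    genes_per_module: int = 80
    conditions: tuple[str, ...] = ("control", "salt")
    time_points_h: tuple[float, ...] = (0, 3, 6, 12, 24, 48)
    replicates: int = 3
    stress_modules: tuple[int, ...] = (5, 6)  # 1-based module indices
    n_hubs_per_stress_module: int = 50
    loading_mean: float = 0.8  # constitutive-module genes
    loading_sd: float = 0.1
    stress_loading_mean: float = 1.55  # non-hub stress-module genes
    stress_loading_sd: float = 0.1
    hub_loading_mean: float = 2.0  # planted hubs (top-decile loadings)
    hub_loading_sd: float = 0.15
    noise_sd: float = 0.5  # gene-level latent noise, log2 scale
    stress_noise_sd: float = 0.5  # noise for non-hub stress genes
    activity_sd: float = 0.25  # per-sample module-activity noise
    nb_dispersion: float = 0.01
    baseline_log2_range: tuple[float, float] = (7.0, 11.0)
    depth_sd: float = 0.15  # log-normal library-size factor sd
    seed: int = 0

    def __post_init__(self):
        n_module_genes = self.n_modules * self.genes_per_module
        if n_module_genes > self.n_genes:
            raise ValueError(
                f"n_modules * genes_per_module = {n_module_genes} exceeds "
                f"n_genes = {self.n_genes}"
            )
        bad = [m for m in self.stress_modules if not 1 <= m <= self.n_modules]
        if bad:
            raise ValueError(f"stress_modules out of range 1..{self.n_modules}: {bad}")
        if self.n_hubs_per_stress_module > self.genes_per_module:
            raise ValueError("n_hubs_per_stress_module exceeds genes_per_module")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for name in ("noise_sd", "stress_noise_sd", "activity_sd", "nb_dispersion", "depth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are supported")

    @property
    def n_background(self) -> int:
        return self.n_genes - self.n_modules * self.genes_per_module

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * len(self.time_points_h) * self.replicates

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in (
            "conditions",
            "time_points_h",
            "stress_modules",
            "baseline_log2_range",
        ):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth exported with each simulated dataset."""

    modules: pd.Series  # gene_id -> module label ("M1".. or "background")
    hubs: tuple[str, ...]  # planted stress-emergent hub gene ids
    activity: pd.DataFrame  # module x sample latent activity

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "module": self.modules,
                "is_hub": self.modules.index.isin(self.hubs),
            }
        )
        df.rename_axis("gene_id").to_csv(path, sep="\t")


def _module_trajectories(
    rng: np.random.Generator, n_points: int, n_modules: int
) -> np.ndarray:
    """Maximally decorrelated trajectories, one row per module.

    Distinct modules must have distinguishable activity profiles, otherwise
    they are one module in all but name. Centered profiles over T time points
    live in a (T-1)-dimensional space, so up to T of them can only reach a
    pairwise correlation of exactly -1/(T-1) — the centered-simplex bound.
    The rows are the vertices of that simplex, randomly rotated within the
    centered subspace, then standardized: every pair of module activities has
    correlation -1/(T-1) exactly, for any seed.
    """
    if n_modules > n_points:
        raise ValueError(
            f"cannot plant {n_modules} distinguishable module trajectories "
            f"on {n_points} time points"
        )
    # centered simplex: rows of I - J/T span the centered subspace
    simplex = np.eye(n_points) - 1.0 / n_points
    # orthonormal basis of the centered subspace (T-1 columns)
    basis = np.linalg.svd(simplex)[0][:, : n_points - 1]
    rotation, _ = np.linalg.qr(rng.normal(size=(n_points - 1, n_points - 1)))
    rotated = simplex @ basis @ rotation @ basis.T
    traj = rotated[:n_modules]
    traj = traj - traj.mean(axis=1, keepdims=True)
    sd = traj.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return traj / sd


def simulate_experiment(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (counts, sample_sheet, truth); deterministic under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    prefix = {"control": "ct", "salt": "ss"}

    sheet_rows = []
    for cond in cfg.conditions:
        for t in cfg.time_points_h:
            for rep in range(1, cfg.replicates + 1):
                sheet_rows.append(
                    {
                        "sample_id": f"{prefix.get(cond, cond)}_{t:g}h_r{rep}",
                        "condition": cond,
                        "time_h": t,
                        "replicate": rep,
                    }
                )
    sheet = pd.DataFrame(sheet_rows)
    n_samples = len(sheet)
    time_idx = {t: i for i, t in enumerate(cfg.time_points_h)}

    module_names = [f"M{m}" for m in range(1, cfg.n_modules + 1)]
    stress = {f"M{m}" for m in cfg.stress_modules}

    # latent module activity per sample: trajectory + per-sample noise;
    # stress-specific modules are silent (exactly zero) under control.
    # Trajectories are maximally decorrelated per condition so modules stay
    # distinguishable.
    traj = {
        cond: _module_trajectories(rng, len(cfg.time_points_h), cfg.n_modules)
        for cond in cfg.conditions
    }
    activity = np.zeros((cfg.n_modules, n_samples))
    for mi, mod in enumerate(module_names):
        for si, row in sheet.iterrows():
            cond = row["condition"]
            if mod in stress and cond == "control":
                continue
            activity[mi, si] = traj[cond][mi][time_idx[row["time_h"]]] + rng.normal(
                0.0, cfg.activity_sd
            )
    activity_df = pd.DataFrame(
        activity, index=module_names, columns=sheet["sample_id"].to_numpy()
    )

    # gene bookkeeping: module genes first, then background
    gene_ids, gene_module, loadings = [], [], []
    hubs: list[str] = []
    g = 0
    for mi, mod in enumerate(module_names):
        n_hub = cfg.n_hubs_per_stress_module if mod in stress else 0
        for within in range(cfg.genes_per_module):
            gid = f"g{g:04d}"
            gene_ids.append(gid)
            gene_module.append(mod)
            if mod in stress:
                if within < n_hub:
                    lam = rng.normal(cfg.hub_loading_mean, cfg.hub_loading_sd)
                    hubs.append(gid)
                else:
                    lam = rng.normal(cfg.stress_loading_mean, cfg.stress_loading_sd)
            else:
                lam = rng.normal(cfg.loading_mean, cfg.loading_sd)
            loadings.append(max(lam, 0.05))
            g += 1
    for _ in range(cfg.n_background):
        gene_ids.append(f"g{g:04d}")
        gene_module.append(BACKGROUND)
        loadings.append(0.0)
        g += 1
    loadings = np.asarray(loadings)
    module_of = pd.Series(gene_module, index=gene_ids, name="module")

    # latent log2 expression; non-hub stress genes carry extra gene-level
    # noise so their mutual correlation stays moderate despite high loadings
    module_idx = {mod: mi for mi, mod in enumerate(module_names)}
    hub_set = set(hubs)
    gene_noise = np.array(
        [
            cfg.stress_noise_sd
            if (mod in stress and gid not in hub_set)
            else cfg.noise_sd
            for gid, mod in zip(gene_ids, gene_module)
        ]
    )
    latent = rng.normal(size=(cfg.n_genes, n_samples)) * gene_noise[:, None]
    for gi, (gid, mod) in enumerate(zip(gene_ids, gene_module)):
        if mod == BACKGROUND:
            continue
        lam_row = np.full(n_samples, loadings[gi])
        if mod in stress:
            # stress emergence: zero loadings under control
            lam_row = np.where(
                sheet["condition"].to_numpy() == "control", 0.0, lam_row
            )
        latent[gi] += lam_row * activity[module_idx[mod]]

    baseline = rng.uniform(*cfg.baseline_log2_range, size=cfg.n_genes)
    depth = np.exp(rng.normal(0.0, cfg.depth_sd, size=n_samples))
    mean = (2.0 ** (baseline[:, None] + latent)) * depth[None, :]

    if cfg.nb_dispersion > 0:
        size = 1.0 / cfg.nb_dispersion
        p = size / (size + mean)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mean)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"),
        columns=sheet["sample_id"].to_numpy(),
    )

    truth = SimTruth(modules=module_of, hubs=tuple(hubs), activity=activity_df)
    return counts_df, sheet, truth


def evaluate_recovery(
    truth: SimTruth,
    modules: pd.Series | None = None,
    key_genes: pd.DataFrame | None = None,
    include_background: bool = False,
) -> dict:
    """Score inferred modules and key genes against the planted truth.

    Returns a dict with ``ari`` (adjusted Rand index between the true and
    inferred partitions; background genes excluded unless
    ``include_background``), ``hub_recall`` and ``hub_precision`` (of planted
    hubs among the identified key genes; precision is None when no key gene
    was called).
    """
    out: dict = {}
    if modules is not None:
        genes = truth.modules.index.intersection(modules.index)
        true_labels = truth.modules.loc[genes]
        inferred = modules.loc[genes]
        if not include_background:
            keep = true_labels != BACKGROUND
            true_labels, inferred = true_labels[keep], inferred[keep]
        out["ari"] = float(adjusted_rand_score(true_labels, inferred)) if len(true_labels) else float("nan")
        out["n_genes_compared"] = int(len(true_labels))
    if key_genes is not None:
        called = set(key_genes.index)
        planted = set(truth.hubs)
        hit = called & planted
        out["hub_recall"] = len(hit) / len(planted) if planted else float("nan")
        out["hub_precision"] = len(hit) / len(called) if called else None
        out["n_key_genes"] = len(called)
        out["n_planted_hubs"] = len(planted)
    return out
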
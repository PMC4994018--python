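"""Synthetic multi-omic cohorts with planted subtype structure.

Emulates the shape of the study data this package analyses: a large
large tumor cohort and a small cell-line panel, both carrying
log2-scale mRNA and microRNA matrices with k sample clusters, cluster-specific
elevated gene blocks, cluster-specific miR shifts, a drug-response panel with
cluster-selective compounds, gene sets drawn from cluster signatures, a
transcription factor whose binding sites mark one cluster's up-miR promoters,
and a planted miR->target linear repression.

The generative model is additive Gaussian on the log2 scale:

    x_gi = baseline_g + delta * [g in signature(cluster(i))] + eps,
    eps ~ N(0, noise_sd^2)

Baselines are drawn once per feature and shared across both cohorts; the two
cohorts differ only in their sample draws and noise, so cross-cohort
intersection logic can be exercised. A configurable fraction of genes gets a
strongly negative baseline so the log2<0 expression filter has work to do.

Determinism: every component draws from `numpy.random.default_rng(master_seed
+ offset)` with a fixed, documented offset per component (see `_SEED_OFFSETS`),
so adding a component never perturbs earlier draws and identical
(config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "Study",
    "generate_multiomic_truth",
    "generate_twin_cohorts",
    "generate_drug_table",
    "generate_gene_sets",
    "generate_tfbs_annotation",
    "generate_target_couplings",
    "simulate_study",
    "write_study",
]

# Fixed sub-seed offsets per generator component.  New components must append,
# never renumber, so existing draws stay stable across package versions.
_SEED_OFFSETS = {
    "baselines": 0,
    "mrna_noise_a": 1,
    "mirna_noise_a": 2,
    "mrna_noise_b": 3,
    "mirna_noise_b": 4,
    "drug": 5,
    "gene_sets": 6,
    "tfbs": 7,
    "couplings_a": 8,
    "couplings_b": 9,
}

_MOD = 2**31  # keep derived seeds in int32 range


def _rng(master_seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng((int(master_seed) + _SEED_OFFSETS[component]) % _MOD)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure generator.

    All expression quantities are on the log2 scale; drug responses are
    -log10 GI50 (molar), so +1 means tenfold more potent.
    """

    k: int = 3
    n_per_cluster: int = 20          # tumor-cohort samples per cluster
    n_genes: int = 600
    sig_size: int = 40               # signature genes per cluster
    delta_expr: float = 2.0          # log2 shift of signature genes in-cluster
    baseline_mean: float = 3.0
    baseline_sd: float = 1.5
    frac_low: float = 0.05           # fraction of genes with baseline << 0
    low_baseline_mean: float = -4.0
    low_baseline_sd: float = 0.5
    noise_sd: float = 0.7
    # microRNA block
    n_mirs: int = 150
    mirs_up: int = 4                 # up-shifted miRs per cluster
    mirs_down: int = 4
    delta_mir: float = 1.5
    # drug panel (on the cell-line cohort)
    n_compounds: int = 30
    n_cells_per_cluster: int = 8     # 3x8 = 24-line panel
    gi50_baseline_mean: float = 6.0  # ~1 uM potency
    gi50_baseline_sd: float = 0.5
    gi50_noise_sd: float = 0.25
    delta_drug: float = 1.0
    # miR->target coupling block
    beta_coupling: float = 1.5
    coupling_noise_sd: float = 0.2
    n_decoy_targets: int = 15
    # TF annotation block
    n_decoy_tfs: int = 25
    master_seed: int = 0

    def validate(self) -> None:
        counts = {
            "k": self.k,
            "n_per_cluster": self.n_per_cluster,
            "n_genes": self.n_genes,
            "sig_size": self.sig_size,
            "n_mirs": self.n_mirs,
            "mirs_up": self.mirs_up,
            "mirs_down": self.mirs_down,
            "n_compounds": self.n_compounds,
            "n_cells_per_cluster": self.n_cells_per_cluster,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.sig_size * self.k > self.n_genes:
            raise ValueError(
                f"sig_size*k = {self.sig_size * self.k} exceeds n_genes = {self.n_genes}"
            )
        if (self.mirs_up + self.mirs_down) * self.k > self.n_mirs:
            raise ValueError("per-cluster miR effect sets exceed n_mirs")
        if self.n_compounds < self.k:
            raise ValueError("need at least one compound per cluster")
        for name in ("delta_expr", "delta_mir", "delta_drug", "beta_coupling"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("noise_sd", "gi50_noise_sd", "coupling_noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_low < 1.0:
            raise ValueError("frac_low must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted parameters that acceptance checks score against."""

    k: int
    labels: pd.Series                      # tumor-cohort sample -> cluster (1..k)
    labels_cellline: pd.Series             # cell-line cohort sample -> cluster
    signature_genes: dict[int, list[str]]  # cluster -> gene ids (disjoint)
    mir_effects: list[tuple[str, int, float]]      # (mir, cluster, log2 shift)
    drug_effects: list[tuple[str, int, float]] = field(default_factory=list)
    enriched_sets: dict[int, str] = field(default_factory=dict)
    planted_tf: tuple[str, int] | None = None      # (tf id, cluster)
    target_couplings: list[tuple[str, str, float]] = field(default_factory=list)
    planted_mir: str | None = None                 # the coupling miR
    predicted_targets: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "k": self.k,
            "labels": self.labels.astype(int).to_dict(),
            "labels_cellline": self.labels_cellline.astype(int).to_dict(),
            "signature_genes": {str(c): list(g) for c, g in self.signature_genes.items()},
            "mir_effects": [list(e) for e in self.mir_effects],
            "drug_effects": [list(e) for e in self.drug_effects],
            "enriched_sets": {str(c): s for c, s in self.enriched_sets.items()},
            "planted_tf": list(self.planted_tf) if self.planted_tf else None,
            "target_couplings": [list(e) for e in self.target_couplings],
            "planted_mir": self.planted_mir,
            "predicted_targets": list(self.predicted_targets),
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _cluster_labels(prefix: str, k: int, n_per_cluster: int) -> pd.Series:
    ids = [f"{prefix}{i:03d}" for i in range(k * n_per_cluster)]
    labels = np.repeat(np.arange(1, k + 1), n_per_cluster)
    return pd.Series(labels, index=ids, name="cluster")


def _draw_baselines(config: SimulationConfig, rng: np.random.Generator,
                    n: int) -> np.ndarray:
    base = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    n_low = int(round(config.frac_low * n))
    if n_low:
        low = rng.normal(config.low_baseline_mean, config.low_baseline_sd, size=n_low)
        idx = rng.choice(n, size=n_low, replace=False)
        base[idx] = low
    return base


def _expression_cohort(baselines: np.ndarray, feature_ids: list[str],
                       labels: pd.Series,
                       effects: dict[str, list[tuple[int, float]]],
                       noise_sd: float, rng: np.random.Generator) -> pd.DataFrame:
    lab = labels.to_numpy()
    X = baselines[:, None] + rng.normal(0.0, noise_sd, size=(len(feature_ids), len(labels)))
    pos = {f: i for i, f in enumerate(feature_ids)}
    for feat, recs in effects.items():
        for cluster, shift in recs:
            X[pos[feat], lab == cluster] += shift
    return pd.DataFrame(X, index=pd.Index(feature_ids, name="feature"),
                        columns=labels.index)


def _planted_structure(config: SimulationConfig):
    """Deterministic layout of signature genes and miR effect sets."""
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    mirs = [f"miR-{i:03d}" for i in range(config.n_mirs)]
    signature = {
        c: genes[(c - 1) * config.sig_size: c * config.sig_size]
        for c in range(1, config.k + 1)
    }
    gene_effects: dict[str, list[tuple[int, float]]] = {}
    for c, sig in signature.items():
        for g in sig:
            gene_effects.setdefault(g, []).append((c, config.delta_expr))

    mir_effects: list[tuple[str, int, float]] = []
    block = config.mirs_up + config.mirs_down
    for c in range(1, config.k + 1):
        start = (c - 1) * block
        for m in mirs[start: start + config.mirs_up]:
            mir_effects.append((m, c, config.delta_mir))
        for m in mirs[start + config.mirs_up: start + block]:
            mir_effects.append((m, c, -config.delta_mir))

    # The coupling miR mirrors the miR-29b expression pattern: high in cluster 1,
    # low in cluster k (only meaningful when k >= 2 and deltas are non-zero).
    planted_mir = mirs[0]  # first up-miR of cluster 1
    if config.k >= 2 and config.delta_mir != 0:
        mir_effects.append((planted_mir, config.k, -config.delta_mir))

    mir_effect_map: dict[str, list[tuple[int, float]]] = {}
    for m, c, s in mir_effects:
        mir_effect_map.setdefault(m, []).append((c, s))
    return genes, mirs, signature, gene_effects, mir_effects, mir_effect_map, planted_mir


def generate_multiomic_truth(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate the tumor-cohort mRNA and miRNA matrices plus planted truth.

    Returns feature-by-sample log2 DataFrames.  When ``delta_expr`` and
    ``delta_mir`` are both 0 the truth carries empty effect lists (null model).
    """
    config.validate()
    (genes, mirs, signature, gene_effects, mir_effects,
     mir_effect_map, planted_mir) = _planted_structure(config)

    labels = _cluster_labels("S", config.k, config.n_per_cluster)
    labels_cl = _cluster_labels("CL", config.k, config.n_cells_per_cluster)

    rng_base = _rng(config.master_seed, "baselines")
    gene_base = _draw_baselines(config, rng_base, config.n_genes)
    mir_base = rng_base.normal(config.baseline_mean, config.baseline_sd,
                               size=config.n_mirs)

    mrna = _expression_cohort(gene_base, genes, labels,
                              gene_effects if config.delta_expr != 0 else {},
                              config.noise_sd, _rng(config.master_seed, "mrna_noise_a"))
    mirna = _expression_cohort(mir_base, mirs, labels,
                               mir_effect_map if config.delta_mir != 0 else {},
                               config.noise_sd, _rng(config.master_seed, "mirna_noise_a"))

    truth = SyntheticTruth(
        k=config.k,
        labels=labels,
        labels_cellline=labels_cl,
        signature_genes={c: list(s) for c, s in signature.items()}
        if config.delta_expr != 0 else {c: [] for c in signature},
        mir_effects=mir_effects if config.delta_mir != 0 else [],
        planted_mir=planted_mir if config.delta_mir != 0 else None,
    )
    return mrna, mirna, truth


@dataclass
class Study:
    """A twin-cohort synthetic study with every downstream fixture attached."""

    config: SimulationConfig
    truth: SyntheticTruth
    mrna: pd.DataFrame           # tumor cohort, genes x samples
    mirna: pd.DataFrame
    mrna_cellline: pd.DataFrame  # cell-line cohort, same features
    mirna_cellline: pd.DataFrame
    drug: pd.DataFrame | None = None         # compounds x cell lines
    gene_sets: dict[str, list[str]] | None = None
    tfbs: pd.DataFrame | None = None         # columns mir_id, tf_id


def generate_twin_cohorts(config: SimulationConfig) -> Study:
    """Two cohorts drawn from one truth: shared baselines and effects,
    independent samples and noise."""
    mrna, mirna, truth = generate_multiomic_truth(config)

    (genes, mirs, _sig, gene_effects, _mir_effects,
     mir_effect_map, _pm) = _planted_structure(config)
    rng_base = _rng(config.master_seed, "baselines")
    gene_base = _draw_baselines(config, rng_base, config.n_genes)
    mir_base = rng_base.normal(config.baseline_mean, config.baseline_sd,
                               size=config.n_mirs)

    mrna_b = _expression_cohort(gene_base, genes, truth.labels_cellline,
                                gene_effects if config.delta_expr != 0 else {},
                                config.noise_sd, _rng(config.master_seed, "mrna_noise_b"))
    mirna_b = _expression_cohort(mir_base, mirs, truth.labels_cellline,
                                 mir_effect_map if config.delta_mir != 0 else {},
                                 config.noise_sd, _rng(config.master_seed, "mirna_noise_b"))
    return Study(config=config, truth=truth, mrna=mrna, mirna=mirna,
                 mrna_cellline=mrna_b, mirna_cellline=mirna_b)


def generate_drug_table(
    labels: pd.Series, config: SimulationConfig,
) -> tuple[pd.DataFrame, list[tuple[str, int, float]]]:
    """-log10 GI50 panel over the labeled cell lines.

    One compound per cluster is planted ``delta_drug`` more potent in that
    cluster; remaining compounds are flat.  Returns (table, drug_effects).
    """
    if labels.empty:
        raise ValueError("labels must be nonempty")
    config.validate()
    rng = _rng(config.master_seed, "drug")
    compounds = [f"CMPD{i:02d}" for i in range(config.n_compounds)]
    base = rng.normal(config.gi50_baseline_mean, config.gi50_baseline_sd,
                      size=config.n_compounds)
    lab = labels.to_numpy()
    D = base[:, None] + rng.normal(0.0, config.gi50_noise_sd,
                                   size=(config.n_compounds, len(labels)))
    effects: list[tuple[str, int, float]] = []
    if config.delta_drug != 0:
        for c in range(1, config.k + 1):
            D[c - 1, lab == c] += config.delta_drug
            effects.append((compounds[c - 1], c, config.delta_drug))
    table = pd.DataFrame(D, index=pd.Index(compounds, name="compound"),
                         columns=labels.index)
    return table, effects


def generate_gene_sets(truth: SyntheticTruth, n_random: int = 20,
                       set_size: int = 25, seed: int = 0,
                       all_genes: list[str] | None = None) -> dict[str, list[str]]:
    """One planted set per cluster (subset of its signature) plus random sets.

    Also records ``truth.enriched_sets``.  ``all_genes`` defaults to the union
    of ids implied by the signatures; pass the full matrix index for realistic
    random sets.
    """
    if not any(truth.signature_genes.values()):
        raise ValueError("truth has no signature genes to sample from")
    rng = np.random.default_rng(int(seed) % _MOD)
    if all_genes is None:
        all_genes = sorted({g for s in truth.signature_genes.values() for g in s})
    sets: dict[str, list[str]] = {}
    for c, sig in truth.signature_genes.items():
        if set_size > len(sig):
            raise ValueError(f"set_size {set_size} > signature size {len(sig)}")
        name = f"PLANTED_CLUSTER{c}"
        sets[name] = sorted(rng.choice(sig, size=set_size, replace=False))
        truth.enriched_sets[c] = name
    if set_size > len(all_genes):
        raise ValueError("set_size exceeds available genes")
    for j in range(n_random):
        sets[f"RANDOM{j:03d}"] = sorted(
            rng.choice(all_genes, size=set_size, replace=False))
    return sets


def generate_tfbs_annotation(truth: SyntheticTruth, n_decoy_tfs: int = 25,
                             seed: int = 0,
                             background_genes: list[str] | None = None,
                             ) -> pd.DataFrame:
    """miR-promoter -> TF binding annotation with one planted TF.

    TF ids are gene ids: the planted TF is a signature gene of the planted
    cluster (hence elevated there in both cohorts by construction); decoy TFs
    are drawn from ``background_genes`` (genes outside every signature) so
    their expression is flat across clusters.  The planted TF is annotated to
    the promoters of every up-miR of the planted cluster; decoys to 1-3
    random miRs each.  Returns a two-column (mir_id, tf_id) DataFrame.
    """
    if not truth.mir_effects:
        raise ValueError("truth has no miR effects; nothing to annotate")
    rng = np.random.default_rng(int(seed) % _MOD)
    planted_cluster = 1
    planted_tf = truth.signature_genes[planted_cluster][0]
    truth.planted_tf = (planted_tf, planted_cluster)

    up_mirs = [m for m, c, s in truth.mir_effects
               if c == planted_cluster and s > 0]
    all_mirs = sorted({m for m, _c, _s in truth.mir_effects})
    rows = [(m, planted_tf) for m in up_mirs]
    if background_genes:
        pool = [g for g in background_genes
                if all(g not in s for s in truth.signature_genes.values())]
        decoys = list(rng.choice(pool, size=min(n_decoy_tfs, len(pool)),
                                 replace=False))
    else:
        decoys = [f"TFDECOY{i:03d}" for i in range(n_decoy_tfs)]
    for tf in decoys:
        n_bind = int(rng.integers(1, 4))
        for m in rng.choice(all_mirs, size=n_bind, replace=False):
            rows.append((str(m), tf))
    return pd.DataFrame(rows, columns=["mir_id", "tf_id"])


def generate_target_couplings(
    mirna: pd.DataFrame, config: SimulationConfig,
    truth: SyntheticTruth, component: str = "couplings_a",
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Rows to append to the mRNA matrix: one planted miR target plus decoys.

    The planted target follows ``c - beta_coupling * miR + noise`` against the
    planted miR's per-sample expression; decoys are independent noise at the
    same marginal scale.  Records couplings and the predicted-target list in
    ``truth``.
    """
    mir_id = truth.planted_mir
    if mir_id is None or mir_id not in mirna.index:
        raise KeyError(f"planted miR {mir_id!r} not present in miRNA matrix")
    rng = _rng(config.master_seed, component)
    m = mirna.loc[mir_id].to_numpy()
    const = config.baseline_mean + config.beta_coupling * float(m.mean())
    rows, ids = [], []
    planted_gene = "TGT000"
    rows.append(const - config.beta_coupling * m
                + rng.normal(0, config.coupling_noise_sd, size=m.size))
    ids.append(planted_gene)
    spread = config.beta_coupling * float(m.std()) or 1.0
    for j in range(1, config.n_decoy_targets + 1):
        ids.append(f"TGT{j:03d}")
        rows.append(config.baseline_mean
                    + rng.normal(0, spread, size=m.size)
                    + rng.normal(0, config.coupling_noise_sd, size=m.size))
    appended = pd.DataFrame(np.vstack(rows),
                            index=pd.Index(ids, name="feature"),
                            columns=mirna.columns)
    couplings = [(mir_id, planted_gene, config.beta_coupling)]
    truth.target_couplings = couplings
    truth.predicted_targets = list(ids)
    return appended, couplings


def simulate_study(config: SimulationConfig) -> Study:
    """Full fixture set: twin cohorts, drug panel, gene sets, TFBS annotation
    and miR->target couplings appended to both mRNA matrices."""
    study = generate_twin_cohorts(config)
    truth = study.truth
    study.drug, truth.drug_effects = generate_drug_table(
        truth.labels_cellline, config)
    if truth.signature_genes.get(1):
        study.gene_sets = generate_gene_sets(
            truth, set_size=min(25, config.sig_size),
            seed=config.master_seed + _SEED_OFFSETS["gene_sets"],
            all_genes=list(study.mrna.index))
    if truth.mir_effects:
        study.tfbs = generate_tfbs_annotation(
            truth, n_decoy_tfs=config.n_decoy_tfs,
            seed=config.master_seed + _SEED_OFFSETS["tfbs"],
            background_genes=list(study.mrna.index))
        tgt_a, _ = generate_target_couplings(study.mirna, config, truth,
                                             "couplings_a")
        tgt_b, _ = generate_target_couplings(study.mirna_cellline, config,
                                             truth, "couplings_b")
        study.mrna = pd.concat([study.mrna, tgt_a])
        study.mrna_cellline = pd.concat([study.mrna_cellline, tgt_b])
    return study


def write_study(study: Study, outdir: str | Path) -> None:
    """Serialize a study to TSV/GMT/JSON files under ``outdir``."""
    from . import io as sio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_matrix(study.mrna, out / "mrna_tumor.tsv")
    sio.write_matrix(study.mirna, out / "mirna_tumor.tsv")
    sio.write_matrix(study.mrna_cellline, out / "mrna_cellline.tsv")
    sio.write_matrix(study.mirna_cellline, out / "mirna_cellline.tsv")
    sio.write_labels(study.truth.labels, out / "labels_tumor.tsv")
    sio.write_labels(study.truth.labels_cellline, out / "labels_cellline.tsv")
    if study.drug is not None:
        sio.write_matrix(study.drug, out / "gi50.tsv")
    if study.gene_sets is not None:
        sio.write_gmt(study.gene_sets, out / "gene_sets.gmt")
    if study.tfbs is not None:
        study.tfbs.to_csv(out / "tfbs.tsv", sep="\t", index=False)
    if study.truth.predicted_targets:
        (out / "predicted_targets.txt").write_text(
            "\n".join(study.truth.predicted_targets) + "\n")
    study.truth.to_json(out / "truth.json")
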
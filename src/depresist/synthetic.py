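"""Synthetic cancer-cell-line panels with planted, recoverable structure.

The generator emulates the statistical shape of a DepMap-style multi-omic
panel: a latent per-line drug-sensitivity axis drives (i) the drug-response
AUC (low AUC = sensitive), (ii) the expression of a planted signature gene
set (high in sensitive lines), (iii) enrichment of in-domain oncogenic
("class V"-like) mutations among sensitive lines, and (iv) knockout-effect
scores depressed selectively in the resistant or sensitive extreme.  Truth
labels for every planted element ship alongside the data so downstream
stages can be scored.

All generators are pure functions of (recipe, seed): the same seed yields a
bit-identical panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import PanelBundle, intersect_bundle

# residue interval used for planted in-domain mutations (kinase-domain stand-in)
_DOMAIN = (688, 875)
_IN_DOMAIN_CHANGES = ["L858R", "S768I", "L861Q", "G719S"]
_OUT_DOMAIN_CHANGES = ["A289V", "R108K", "G598V", "E114K"]


@dataclass
class PanelRecipe:
    """Parameters of the planted panel.

    Defaults are the study conditions every recovery experiment assumes:
    300 lines, a 50-gene planted sensitivity signature with unit coupling
    (``beta_sig``), class-V mutations on 10% of lines with a 30% chance of
    landing in the sensitive tail (``mut_ppv``), and one planted
    resistant-selective plus one sensitive-selective dependency gene.
    """

    n_lines: int = 300
    n_genes: int = 1000
    signature_size: int = 50
    n_decoy_sets: int = 9
    decoy_set_size: int = 50
    beta_sig: float = 1.0
    expr_noise_sd: float = 1.0
    auc_noise_sd: float = 0.3
    frac_classV: float = 0.10
    mut_ppv: float = 0.30
    background_mut_rate: float = 0.10   # per-line chance of a non-class-V variant
    tail_fraction: float = 0.10         # "sensitive tail" = lowest-AUC decile
    dep_genes: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {"DEP_R": ("R", -1.0), "DEP_S": ("S", -1.0)}
    )
    dep_baseline_sd: float = 0.15
    n_drugs: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.frac_classV < 1:
            raise ValueError(f"frac_classV must be in (0,1), got {self.frac_classV}")
        if self.beta_sig < 0:
            raise ValueError(f"beta_sig must be >= 0, got {self.beta_sig}")
        if self.signature_size > self.n_genes:
            raise ValueError("planted signature larger than n_genes")


@dataclass
class SyntheticPanel:
    """A generated panel plus the ground truth planted into it."""

    bundle: PanelBundle
    truth: dict

    @property
    def latent_sensitivity(self) -> pd.Series:
        return self.truth["latent"]


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _line_names(n: int) -> list[str]:
    return [f"CL{i:04d}" for i in range(n)]


def generate_panel(recipe: PanelRecipe | None = None, seed: int | None = None) -> SyntheticPanel:
    """Generate a panel with planted sensitivity structure.

    The latent axis ``s_i ~ N(0,1)`` sets AUC = 0.5 s_i + noise, so low s is
    sensitive.  Planted-signature genes get expression ``baseline -
    beta_sig * s_i + noise`` on the log2(TPM+1) scale; all other genes are
    noise around a gene-specific baseline.  Class-V-like mutations (in-domain,
    oncogenic) go to the low-AUC tail with probability ``mut_ppv``, else to a
    uniformly random line.  Planted dependency genes get their effect score
    shifted by the stated depth only in the designated AUC-extreme group.
    """
    recipe = recipe or PanelRecipe()
    if seed is not None:
        recipe = PanelRecipe(**{**recipe.__dict__, "seed": seed})
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    n, g = recipe.n_lines, recipe.n_genes
    lines = _line_names(n)
    genes = _gene_names(g)

    s = rng.standard_normal(n)
    latent = pd.Series(s, index=lines, name="latent_sensitivity")

    # drug-response AUC: one latent axis, per-drug noise (drugs behave comparably)
    auc = 0.5 * s[:, None] + recipe.auc_noise_sd * rng.standard_normal((n, recipe.n_drugs))
    drugs = [f"EGFRi_{i + 1}" for i in range(recipe.n_drugs)]
    responses = pd.DataFrame(auc, index=lines, columns=drugs)
    mean_auc = responses.mean(axis=1)

    # expression, log2(TPM+1)-like scale
    baseline = rng.uniform(2.0, 8.0, size=g)
    expr = baseline[:, None] + recipe.expr_noise_sd * rng.standard_normal((g, n))
    sig_genes = genes[: recipe.signature_size]
    expr[: recipe.signature_size, :] -= recipe.beta_sig * s[None, :]
    expression = pd.DataFrame(expr, index=genes, columns=lines)

    # planted signature set plus decoys drawn from the remaining genes
    sets: dict[str, list[str]] = {"PLANTED_SIG": list(sig_genes)}
    pool = np.array(genes[recipe.signature_size:])
    for i in range(recipe.n_decoy_sets):
        members = rng.choice(pool, size=min(recipe.decoy_set_size, pool.size), replace=False)
        sets[f"DECOY_{i + 1}"] = sorted(members.tolist())

    # mutations: class-V carriers biased toward the sensitive (low-AUC) tail
    order = np.argsort(mean_auc.to_numpy(), kind="stable")
    tail_size = max(1, int(np.floor(recipe.tail_fraction * n)))
    tail = order[:tail_size]
    n_classv = max(1, int(np.floor(recipe.frac_classV * n)))
    classv_lines: list[int] = []
    available_tail = list(tail)
    available_all = list(range(n))
    for _ in range(n_classv):
        if rng.random() < recipe.mut_ppv and available_tail:
            idx = available_tail.pop(rng.integers(len(available_tail)))
        else:
            idx = available_all[rng.integers(len(available_all))]
        if idx not in classv_lines:
            classv_lines.append(idx)
        if idx in available_tail:
            available_tail.remove(idx)
    records = []
    for idx in classv_lines:
        change = _IN_DOMAIN_CHANGES[rng.integers(len(_IN_DOMAIN_CHANGES))]
        records.append((lines[idx], "EGFR", change, True))
    # background variants spread over the remaining classes, uniform over lines
    for idx in range(n):
        if idx in classv_lines or rng.random() >= recipe.background_mut_rate:
            continue
        kind = rng.integers(3)
        if kind == 0:       # outside domain, not oncogenic (class II)
            records.append((lines[idx], "EGFR", _OUT_DOMAIN_CHANGES[rng.integers(4)], False))
        elif kind == 1:     # outside domain, oncogenic (class III)
            records.append((lines[idx], "EGFR", _OUT_DOMAIN_CHANGES[rng.integers(4)], True))
        else:               # inside domain, not oncogenic (class IV)
            records.append((lines[idx], "EGFR", _IN_DOMAIN_CHANGES[rng.integers(4)], False))
    mutations = pd.DataFrame(records, columns=["cell_line", "gene", "protein_change", "oncogenic"])

    # knockout effect scores: ~0 baseline, planted genes depressed in one extreme
    dep_names = list(recipe.dep_genes)
    effect_genes = genes + [d for d in dep_names if d not in genes]
    effects = recipe.dep_baseline_sd * rng.standard_normal((len(effect_genes), n))
    effects_df = pd.DataFrame(effects, index=effect_genes, columns=lines)
    sens_group = [lines[i] for i in order[:tail_size]]
    res_group = [lines[i] for i in order[-tail_size:]]
    for gene_name, (side, depth) in recipe.dep_genes.items():
        target = res_group if side == "R" else sens_group
        effects_df.loc[gene_name, target] += depth

    bundle = intersect_bundle(expression, responses, mutations, effects_df)
    truth = {
        "latent": latent,
        "planted_sets": sets,
        "signature_genes": list(sig_genes),
        "classV_lines": sorted(lines[i] for i in classv_lines),
        "sensitive_tail": sorted(sens_group),
        "resistant_tail": sorted(res_group),
        "dep_genes": dict(recipe.dep_genes),
        "recipe": recipe,
    }
    return SyntheticPanel(bundle=bundle, truth=truth)


# canonical condition-mean profiles for the 5-cluster perturbation experiment;
# cluster 2 is the "up on drug, reversed by the combination" pattern
_PROFILES_K5 = np.array(
    [
        [0.0, -2.0, 0.0],   # down on drug, restored by inhibitor
        [0.0, 2.0, 0.0],    # up on drug, reversed by inhibitor
        [0.0, 2.0, 2.0],    # up on drug, persists
        [0.0, -2.0, -2.0],  # down on drug, persists
        [0.0, 0.0, 2.0],    # responds only to the combination
    ]
)


def generate_perturbation_experiment(
    n_genes: int = 500,
    conditions: Sequence[str] = ("vehicle", "drug", "drug_inhibitor"),
    n_replicates: int = 3,
    k_clusters: int = 5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Expression for a 3-condition perturbation with planted gene clusters.

    Each cluster has a distinct condition-mean profile; replicates add i.i.d.
    noise.  Returns (matrix genes x samples, truth) where truth carries the
    gene->cluster map, the per-cluster profiles, the planted per-cluster gene
    sets, and the index of the "reversed-by-inhibitor" cluster.
    """
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(seed)
    n_cond = len(conditions)
    if k_clusters == 5 and n_cond == 3:
        profiles = _PROFILES_K5.copy()
    else:
        profiles = np.zeros((k_clusters, n_cond))
        for i in range(k_clusters):
            profiles[i] = 2.0 * rng.choice([-1.0, 0.0, 1.0], size=n_cond)
            while any(np.allclose(profiles[i], profiles[j]) for j in range(i)):
                profiles[i] = 2.0 * rng.choice([-1.0, 0.0, 1.0], size=n_cond)
    labels = rng.integers(k_clusters, size=n_genes)
    means = profiles[labels]  # genes x conditions
    data = np.repeat(means, n_replicates, axis=1)
    data = data + noise_sd * rng.standard_normal(data.shape)
    samples = [f"{c}_{r + 1}" for c in conditions for r in range(n_replicates)]
    genes = _gene_names(n_genes)
    matrix = pd.DataFrame(data, index=genes, columns=samples)
    cluster_sets = {
        f"CLUSTER_SET_{k + 1}": [genes[i] for i in np.flatnonzero(labels == k)]
        for k in range(k_clusters)
    }
    truth = {
        "labels": pd.Series(labels + 1, index=genes, name="cluster"),
        "profiles": pd.DataFrame(profiles, columns=list(conditions),
                                 index=[f"cluster_{k + 1}" for k in range(k_clusters)]),
        "cluster_sets": cluster_sets,
        "reversed_cluster": 2 if (k_clusters == 5 and n_cond == 3) else None,
        "conditions": list(conditions),
        "n_replicates": n_replicates,
    }
    return matrix, truth


def generate_survival_cohort(
    n: int = 500,
    hr: float = 1.0,
    alteration_freq: float = 0.2,
    censor_rate: float = 0.2,
    baseline_hazard: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Exponential survival cohort with a binary alteration flag.

    Event times are exponential with hazard ``baseline_hazard`` for unaltered
    subjects and ``hr * baseline_hazard`` for altered ones.  Censoring is an
    independent exponential clock whose rate gives P(censor before event) =
    ``censor_rate`` in the unaltered group; ``censor_rate=0`` disables it.
    """
    if hr <= 0:
        raise ValueError("hr must be > 0")
    if not 0 < alteration_freq < 1:
        raise ValueError("alteration_freq must be in (0,1)")
    rng = np.random.default_rng(seed)
    altered = rng.random(n) < alteration_freq
    hazard = np.where(altered, hr * baseline_hazard, baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        cens_hazard = baseline_hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / cens_hazard, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    table = pd.DataFrame(
        {
            "subject": [f"P{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "group": altered.astype(int),
        }
    )
    truth = {"hr": hr, "baseline_hazard": baseline_hazard, "altered": altered}
    return table, truth
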
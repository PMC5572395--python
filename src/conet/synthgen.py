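"""Synthetic multi-condition expression data with known ground truth.

Every pipeline stage is exercised on generated data: multi-condition
TPM-like expression with planted correlation modules (a one-factor model per
module), TF-driven co-regulation (targets of the same causal TF share an
additive latent factor), a protein-interaction network partially placed
within modules, a reaction->enzyme map whose planted subsystem draws its
enzymes from a module that loses its shared factor in the disease condition,
a hub gene with condition-specific and ubiquitous partners, and
negative-binomial counts with planted fold changes.

The latent model for a module member is ``x = sqrt(rho) * f_m +
sqrt(1 - rho) * eps`` with the module factor f_m and noise eps standard
normal per sample, so the within-module latent correlation is exactly rho.
Latent values are mapped to a positive TPM-like scale by the fixed monotone
transform ``exp(b_g + sigma * x)`` with a per-gene baseline b_g; Pearson
correlations computed downstream on the emitted scale are therefore slightly
attenuated relative to rho but preserve the ranking of pair strengths.

Each generator consumes its own RNG stream split from the master seed, so
adding or re-running one generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coexnet import ExpressionMatrix
from .coreg import PhysicalNetwork
from .rxncluster import ReactionEnzymeMap

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "gen_expression",
    "gen_regulatory_network",
    "gen_ppin",
    "gen_reaction_map",
    "gen_hub_dataset",
    "gen_counts",
    "SyntheticStudy",
    "generate_study",
]

_TPM_SIGMA = 0.7
_BASELINE_LOG_MEAN = np.log(50.0)
_BASELINE_LOG_SD = 1.0

# named RNG streams split from the master seed, one per generator
_STREAMS = ("expression", "regulatory", "ppin", "reactions", "hub", "counts")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic data.

    Defaults emulate a desk-scale version of a multi-tissue RNA-seq study:
    a few hundred genes, four conditions (three tissues plus one disease
    cohort), strongly correlated planted modules, a handful of causal TFs
    among decoys, and overdispersed counts.
    """

    n_genes: int = 400
    n_conditions: int = 4
    samples_per_condition: int = 120
    n_modules: int = 4
    module_size: int = 30
    module_correlation: float = 0.8
    n_tfs: int = 33
    n_causal_tfs: int = 3
    targets_per_tf: int = 15
    tf_effect: float = 2.0
    ppin_density: float = 0.02
    ppin_within_module_fraction: float = 0.5
    n_reactions: int = 150
    enzymes_per_reaction: tuple[int, int] = (1, 3)
    n_subsystems: int = 6
    hub_partner_count: int = 5
    hub_background_genes: int = 100
    de_fraction: float = 0.05
    de_fold_change: float = 4.0
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_conditions": self.n_conditions,
            "samples_per_condition": self.samples_per_condition,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
            "n_tfs": self.n_tfs,
            "n_causal_tfs": self.n_causal_tfs,
            "targets_per_tf": self.targets_per_tf,
            "n_reactions": self.n_reactions,
            "n_subsystems": self.n_subsystems,
            "hub_partner_count": self.hub_partner_count,
        }
        for name, v in counts.items():
            if not np.isfinite(v) or int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")
        for name in ("module_correlation", "tf_effect", "ppin_density",
                     "ppin_within_module_fraction", "de_fraction",
                     "de_fold_change", "nb_dispersion"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0 <= self.module_correlation < 1:
            raise ValueError("module_correlation must be in [0, 1)")
        if self.samples_per_condition < 3:
            raise ValueError("need at least 3 samples per condition")
        if self.de_fold_change <= 0:
            raise ValueError("de_fold_change must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 < self.ppin_density <= 1:
            raise ValueError("ppin_density must be in (0, 1]")
        lo, hi = self.enzymes_per_reaction
        if not (1 <= lo <= hi):
            raise ValueError("enzymes_per_reaction range invalid")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit in the gene universe")
        if self.n_causal_tfs > self.n_tfs:
            raise ValueError("n_causal_tfs exceeds n_tfs")
        if self.targets_per_tf > self.n_genes:
            raise ValueError("targets_per_tf exceeds n_genes")

    @property
    def conditions(self) -> list[str]:
        """Condition labels; the last condition is the disease cohort."""
        tissues = [f"tissue{i + 1:02d}" for i in range(self.n_conditions - 1)]
        return tissues + ["disease"]

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]

    @property
    def disease_condition(self) -> str:
        return self.conditions[-1]

    def rng(self, stream: str) -> np.random.Generator:
        """The named generator's own RNG stream, split from the master seed."""
        idx = _STREAMS.index(stream)
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[idx])


@dataclass
class GroundTruth:
    """Planted structure labels shared by all generators."""

    conditions: list[str] = field(default_factory=list)
    gene_module: dict[str, str] = field(default_factory=dict)
    modules: dict[str, list[str]] = field(default_factory=dict)
    causal_tf_targets: dict[str, list[str]] = field(default_factory=dict)
    decoy_tfs: list[str] = field(default_factory=list)
    decorrelated_module: dict[str, str] = field(default_factory=dict)
    planted_subsystem: str = ""
    regulated_subsystem: str = ""
    hub_gene: str = ""
    hub_specific_partners: list[str] = field(default_factory=list)
    hub_ubiquitous_partners: list[str] = field(default_factory=list)
    hub_specific_condition: str = ""
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> log2 fc

    @property
    def causal_tfs(self) -> list[str]:
        return sorted(self.causal_tf_targets)

    def hub_partners(self, condition: str) -> set[str]:
        partners = set(self.hub_ubiquitous_partners)
        if condition == self.hub_specific_condition:
            partners |= set(self.hub_specific_partners)
        return partners

    def to_json_dict(self) -> dict:
        return asdict(self)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _tpm_scale(latent: np.ndarray, baselines: np.ndarray) -> np.ndarray:
    """Fixed monotone map from the latent scale to positive TPM-like values."""
    return np.exp(baselines[:, None] + _TPM_SIGMA * latent)


def gen_expression(
    config: SynthConfig,
) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Per-condition TPM-like matrices with planted modules and TF effects.

    Module members load on a shared per-condition factor with weight
    sqrt(rho); the first module loses its factor in the disease condition
    (the planted decorrelation).  TFs are genes too: each matrix carries one
    row per TF, a causal TF's expression being its own regulatory factor and
    a decoy's plain noise.  Targets of each causal TF (drawn from a pool of
    background genes) receive the factor additively with weight ``tf_effect``
    and are then rescaled to unit latent variance, so a pair of targets
    sharing k equally weighted TFs has latent correlation
    k*w^2 / (1 + k*w^2) — strictly increasing in k.
    """
    rng = config.rng("expression")
    genes = _gene_ids(config.n_genes)
    truth = GroundTruth(conditions=config.conditions)

    module_ids = [f"M{i + 1}" for i in range(config.n_modules)]
    pos = 0
    for m in module_ids:
        members = genes[pos : pos + config.module_size]
        truth.modules[m] = members
        for g in members:
            truth.gene_module[g] = m
        pos += config.module_size
    background = genes[pos:]
    truth.decorrelated_module[config.disease_condition] = module_ids[0]

    # causal TF target assignment: drawn from a limited background pool so
    # that pairs sharing 2+ TFs actually occur
    pool = background[: min(len(background), 4 * config.targets_per_tf)]
    if len(pool) < config.targets_per_tf:
        pool = genes[: config.targets_per_tf]
    causal_tfs = [f"TF{i + 1:02d}" for i in range(config.n_causal_tfs)]
    for tf in causal_tfs:
        targets = rng.choice(pool, size=config.targets_per_tf, replace=False)
        truth.causal_tf_targets[tf] = sorted(targets)
    truth.decoy_tfs = [
        f"TF{i + 1:02d}" for i in range(config.n_causal_tfs, config.n_tfs)
    ]

    all_rows = genes + causal_tfs + truth.decoy_tfs
    row_index = {g: i for i, g in enumerate(all_rows)}
    baselines = rng.normal(_BASELINE_LOG_MEAN, _BASELINE_LOG_SD, size=len(all_rows))
    rho = config.module_correlation
    w = config.tf_effect
    s = config.samples_per_condition
    # latent variance of each gene after additive TF factors, for rescaling
    n_bound = np.zeros(len(all_rows))
    for tf in causal_tfs:
        for g in truth.causal_tf_targets[tf]:
            n_bound[row_index[g]] += 1
    scale = np.sqrt(1.0 + n_bound * w**2)

    matrices: dict[str, ExpressionMatrix] = {}
    for cond in config.conditions:
        latent = rng.normal(size=(len(all_rows), s))  # iid noise for everyone
        for m in module_ids:
            if truth.decorrelated_module.get(cond) == m:
                continue  # planted loss of co-expression in the disease
            factor = rng.normal(size=s)
            idx = [row_index[g] for g in truth.modules[m]]
            latent[idx] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * latent[idx]
        for tf in causal_tfs:
            tf_factor = rng.normal(size=s)
            latent[row_index[tf]] = tf_factor  # the TF's own expression
            idx = [row_index[g] for g in truth.causal_tf_targets[tf]]
            latent[idx] = latent[idx] + w * tf_factor
        latent = latent / scale[:, None]
        values = _tpm_scale(latent, baselines)
        samples = [f"{cond}_s{j:03d}" for j in range(s)]
        matrices[cond] = ExpressionMatrix(
            values=pd.DataFrame(values, index=all_rows, columns=samples),
            condition=cond,
            unit="TPM",
        )

    # planted differential expression (realized in gen_counts)
    if config.de_fold_change != 1.0:
        n_de = int(round(config.de_fraction * config.n_genes))
        de_genes = rng.choice(genes, size=n_de, replace=False)
        lfc = np.log2(config.de_fold_change)
        for i, g in enumerate(sorted(de_genes)):
            truth.de_genes[g] = lfc if i % 2 == 0 else -lfc
    return matrices, truth


def gen_regulatory_network(config: SynthConfig, truth: GroundTruth) -> PhysicalNetwork:
    """Directed TF->target edge list: causal TFs plus expression-silent decoys."""
    if config.targets_per_tf > config.n_genes:
        raise ValueError("targets_per_tf exceeds the gene universe")
    if not truth.causal_tf_targets:
        raise ValueError("run gen_expression first (causal TF effects live there)")
    rng = config.rng("regulatory")
    genes = _gene_ids(config.n_genes)
    edges: list[tuple[str, str]] = []
    for tf in truth.causal_tfs:
        for g in truth.causal_tf_targets[tf]:
            edges.append((tf, g))
    # decoys bind unstructured genes: outside planted modules and outside the
    # causal target pool, so their co-binding carries no co-expression signal
    causal_targets = {g for t in truth.causal_tf_targets.values() for g in t}
    decoy_pool = [
        g for g in genes if g not in truth.gene_module and g not in causal_targets
    ]
    if len(decoy_pool) < config.targets_per_tf:
        decoy_pool = genes
    for tf in truth.decoy_tfs:
        targets = rng.choice(decoy_pool, size=config.targets_per_tf, replace=False)
        for g in sorted(targets):
            edges.append((tf, g))
    return PhysicalNetwork(kind="regulatory", edges=edges)


def gen_ppin(config: SynthConfig, truth: GroundTruth) -> PhysicalNetwork:
    """Undirected protein-pair edges, a fraction placed within modules.

    The edge count is ``round(density * C(n_genes, 2))``; a configured
    fraction of edges joins genes of the same planted module (hence
    co-expressed partners), the rest are uniform random pairs.
    """
    if not 0 < config.ppin_density <= 1:
        raise ValueError("ppin_density must be in (0, 1]")
    rng = config.rng("ppin")
    genes = _gene_ids(config.n_genes)
    n_pairs = config.n_genes * (config.n_genes - 1) // 2
    n_edges = int(round(config.ppin_density * n_pairs))
    n_edges = max(1, min(n_edges, n_pairs))
    n_within = int(round(config.ppin_within_module_fraction * n_edges))

    chosen: set[tuple[str, str]] = set()
    module_list = [m for m in sorted(truth.modules) if len(truth.modules[m]) >= 2]
    attempts = 0
    while len(chosen) < n_within and module_list and attempts < 50 * n_within:
        attempts += 1
        m = module_list[rng.integers(len(module_list))]
        members = truth.modules[m]
        i, j = rng.choice(len(members), size=2, replace=False)
        a, b = members[i], members[j]
        chosen.add((min(a, b), max(a, b)))
    while len(chosen) < n_edges:
        i, j = rng.integers(0, config.n_genes, size=2)
        if i == j:
            continue
        a, b = genes[i], genes[j]
        chosen.add((min(a, b), max(a, b)))
    return PhysicalNetwork(kind="ppi", edges=sorted(chosen))


def gen_reaction_map(config: SynthConfig, truth: GroundTruth) -> ReactionEnzymeMap:
    """Reaction->enzyme assignments with one subsystem planted in a module.

    The planted subsystem's reactions draw their enzymes from the module that
    is decorrelated in the disease condition, so its reaction cluster is
    highly co-expressed in the reference tissue and falls apart in disease.
    With at least 3 subsystems, a second "regulated" subsystem draws its
    enzymes from the causal-TF target pool, producing a reaction cluster
    whose enzymes are enriched in high-importance TF binding.  Other
    reactions draw enzymes uniformly from the gene universe.
    """
    lo, hi = config.enzymes_per_reaction
    if not (1 <= lo <= hi):
        raise ValueError("enzymes_per_reaction range invalid")
    rng = config.rng("reactions")
    genes = _gene_ids(config.n_genes)
    planted_module = truth.decorrelated_module.get(config.disease_condition)
    planted_pool = truth.modules.get(planted_module, genes)
    regulated_pool = sorted(
        {g for targets in truth.causal_tf_targets.values() for g in targets}
    )

    subsystems = [f"S{i + 1:02d}" for i in range(config.n_subsystems)]
    planted_subsystem = subsystems[0]
    truth.planted_subsystem = planted_subsystem
    n_planted = max(2, config.n_reactions // config.n_subsystems)
    use_regulated = config.n_subsystems >= 3 and regulated_pool
    regulated_subsystem = subsystems[1] if use_regulated else ""
    truth.regulated_subsystem = regulated_subsystem
    n_regulated = n_planted if use_regulated else 0

    enzymes: dict[str, tuple[str, ...]] = {}
    subsystem: dict[str, str] = {}
    n_free = config.n_subsystems - 1 - (1 if use_regulated else 0)
    for i in range(config.n_reactions):
        rxn = f"R{i + 1:04d}"
        n_enz = int(rng.integers(lo, hi + 1))
        if i < n_planted:
            pool = planted_pool
            subsystem[rxn] = planted_subsystem
        elif i < n_planted + n_regulated:
            pool = regulated_pool
            subsystem[rxn] = regulated_subsystem
        elif n_free > 0:
            pool = genes
            subsystem[rxn] = subsystems[
                config.n_subsystems - n_free + int(rng.integers(n_free))
            ]
        else:
            pool = genes
            subsystem[rxn] = planted_subsystem
        n_enz = min(n_enz, len(pool))
        picked = rng.choice(len(pool), size=n_enz, replace=False)
        enzymes[rxn] = tuple(sorted(pool[k] for k in picked))
    return ReactionEnzymeMap(enzymes=enzymes, subsystem=subsystem)


def gen_hub_dataset(
    config: SynthConfig, truth: GroundTruth
) -> dict[str, ExpressionMatrix]:
    """Expression matrices in which a hub gene has condition-specific partners.

    The hub correlates (at the module correlation) with its "specific"
    partners only in the disease condition and with its "ubiquitous" partners
    in every condition.  A few deliberately low-expressed correlated genes
    (below 1 TPM) exercise the expression floor of the neighborhood step.
    """
    rng = config.rng("hub")
    rho = config.module_correlation
    k = config.hub_partner_count
    specific = [f"SP{i + 1:02d}" for i in range(k)]
    ubiquitous = [f"UP{i + 1:02d}" for i in range(k)]
    low = [f"LOW{i + 1:02d}" for i in range(3)]
    bg = [f"bg{i + 1:04d}" for i in range(config.hub_background_genes)]
    genes = ["HUB"] + specific + ubiquitous + low + bg

    truth.hub_gene = "HUB"
    truth.hub_specific_partners = specific
    truth.hub_ubiquitous_partners = ubiquitous
    truth.hub_specific_condition = config.disease_condition

    baselines = np.full(len(genes), _BASELINE_LOG_MEAN)
    # low-expression genes sit well below the 1 TPM floor
    for i, g in enumerate(genes):
        if g.startswith("LOW"):
            baselines[i] = np.log(0.2)
    s = config.samples_per_condition
    out: dict[str, ExpressionMatrix] = {}
    for cond in config.conditions:
        hub_factor = rng.normal(size=s)
        latent = rng.normal(size=(len(genes), s))
        latent[0] = hub_factor
        for i, g in enumerate(genes):
            if g in ("HUB",) or g.startswith("bg"):
                continue
            couples = (
                g.startswith("UP")
                or g.startswith("LOW")
                or (g.startswith("SP") and cond == truth.hub_specific_condition)
            )
            if couples:
                latent[i] = np.sqrt(rho) * hub_factor + np.sqrt(1 - rho) * latent[i]
        values = _tpm_scale(latent, baselines)
        samples = [f"{cond}_s{j:03d}" for j in range(s)]
        out[cond] = ExpressionMatrix(
            values=pd.DataFrame(values, index=genes, columns=samples),
            condition=cond,
            unit="TPM",
        )
    return out


def gen_counts(
    config: SynthConfig,
    truth: GroundTruth,
    group_sizes: tuple[int, int] = (93, 93),
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts with planted fold changes in the "high" group.

    Per-gene means follow the reference-condition expression scale; counts
    are NB with dispersion ``nb_dispersion`` (var = mu + a*mu^2) and mild
    sample-depth variation.  Genes in the planted DE set have their mean
    multiplied by the signed fold change in the high group.
    """
    rng = config.rng("counts")
    genes = _gene_ids(config.n_genes)
    n_high, n_low = group_sizes
    if n_high < 2 or n_low < 2:
        raise ValueError("both groups need at least 2 samples")
    base_mean = 2.0 * np.exp(
        rng.normal(_BASELINE_LOG_MEAN, _BASELINE_LOG_SD, size=config.n_genes)
    )
    fold = np.ones(config.n_genes)
    for i, g in enumerate(genes):
        if g in truth.de_genes:
            fold[i] = 2.0 ** truth.de_genes[g]
    depth = np.exp(rng.normal(0.0, 0.1, size=n_high + n_low))
    mu = np.empty((config.n_genes, n_high + n_low))
    mu[:, :n_high] = (base_mean * fold)[:, None] * depth[:n_high]
    mu[:, n_high:] = base_mean[:, None] * depth[n_high:]
    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    samples = [f"hi_s{i:03d}" for i in range(n_high)] + [
        f"lo_s{i:03d}" for i in range(n_low)
    ]
    frame = pd.DataFrame(counts, index=genes, columns=samples)
    labels = pd.Series(
        ["high"] * n_high + ["low"] * n_low, index=samples, name="group"
    )
    return frame, labels


@dataclass
class SyntheticStudy:
    """Bundle of everything one seed generates."""

    config: SynthConfig
    truth: GroundTruth
    expression: dict[str, ExpressionMatrix]
    regulatory: PhysicalNetwork
    ppin: PhysicalNetwork
    reaction_map: ReactionEnzymeMap
    hub_expression: dict[str, ExpressionMatrix]
    counts: pd.DataFrame
    count_groups: pd.Series


def generate_study(config: SynthConfig) -> SyntheticStudy:
    """Run every generator off one master seed and return the bundle."""
    expression, truth = gen_expression(config)
    regulatory = gen_regulatory_network(config, truth)
    ppin = gen_ppin(config, truth)
    reaction_map = gen_reaction_map(config, truth)
    hub_expression = gen_hub_dataset(config, truth)
    counts, groups = gen_counts(config, truth)
    return SyntheticStudy(
        config=config,
        truth=truth,
        expression=expression,
        regulatory=regulatory,
        ppin=ppin,
        reaction_map=reaction_map,
        hub_expression=hub_expression,
        counts=counts,
        count_groups=groups,
    )
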
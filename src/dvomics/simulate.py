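"""Synthetic data generators for every pipeline input.

The generators emulate the statistical structure of a label-free quantitative
proteomics study of dorso-ventral (DV) patterning mutants: a wild type plus
four mutant genotypes (dorsalized D, lateralized L, and two ventralized
genotypes Vtl and Vsp) measured with nested biological x technical replicates.
Wild-type abundance of each entity is, by construction, the region-proportion
weighted linear-scale mixture of the three regional abundances, so the linear
mixing model holds exactly at zero noise. Measurements are log-normal around
class means, and values below a detection threshold are recorded missing
(missing-not-at-random, emulating proteins undetected because of low
abundance).

Spatial RNA atlases are generated as smooth bump profiles of the DV angle, and
annotated protein-protein interaction networks come with an is_a ontology DAG,
kinase-class labels and planted functional modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import OntologyDAG

GENOTYPES = ("WT", "D", "L", "Vtl", "Vsp")
MUTANTS = ("D", "L", "Vtl", "Vsp")
#: regulation categories: region set where an entity is elevated
CATEGORIES = ("D", "L", "V", "DL", "DV", "LV", "ubiquitous")
#: which of the three regions each category is "on" in
_CATEGORY_REGIONS = {
    "D": ("D",),
    "L": ("L",),
    "V": ("V",),
    "DL": ("D", "L"),
    "DV": ("D", "V"),
    "LV": ("L", "V"),
    "ubiquitous": ("D", "L", "V"),
}
#: atlas reference genes and the canonical pattern each carries
REFERENCE_GENES = {
    "D": ["dpp"],
    "L": ["sog", "soxN"],
    "V": ["twist"],
    "DL": ["crb"],
    "DV": ["net"],
    "LV": ["neur"],
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-design parameters for the proteome/phosphoproteome simulators.

    Defaults mirror the study design: five genotypes, two biological and three
    technical replicates, a 0.4/0.4/0.2 dorsal/lateral/ventral split of the DV
    axis, and log2 intensities in the typical MaxQuant LFQ range.
    """

    n_entities: int = 1000
    #: ~30% of entities carry a designed regional class (roughly the fraction
    #: of proteins that test significant across genotypes); the rest are
    #: nominally ubiquitous, varying only through the mild regional modulation
    class_fractions: dict = field(
        default_factory=lambda: {
            "D": 0.05,
            "L": 0.05,
            "V": 0.05,
            "DL": 0.05,
            "DV": 0.05,
            "LV": 0.05,
            "ubiquitous": 0.70,
        }
    )
    proportions_true: tuple = (0.4, 0.4, 0.2)
    effect_size: float = 3.0
    #: per-entity effects are uniform in effect_size * [1-jitter, 1+jitter];
    #: regulated regional markers span a severalfold range, they are not one
    #: shared step
    effect_jitter: float = 0.3
    #: sd of mild per-entity regional modulation (log2) applied to every
    #: expressed region, including nominally ubiquitous proteins — real
    #: maternal proteins are not perfectly flat along the axis. The WT mixture
    #: is computed from the modulated regional values, so the linear model
    #: still holds exactly at zero measurement noise.
    regional_sd: float = 0.25
    noise_sd_bio: float = 0.25
    noise_sd_tech: float = 0.35
    dropout_log2_threshold: float = 20.0
    n_bio_reps: int = 2
    n_tech_reps: int = 3
    #: fraction of regulated entities with restricted expression (linear
    #: abundance exactly zero outside their domain, like Snail/Twist)
    restricted_fraction: float = 0.1
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    # phosphoproteome layer
    n_sites: int = 0
    #: fraction of sites carrying regional regulation independent of host
    #: abundance (drawn from the regulated categories)
    fraction_independent: float = 0.7
    #: relative weight of ubiquitous entities when drawing site hosts —
    #: differentially phosphorylated sites sit mostly on stably expressed
    #: proteins
    phospho_host_ubiquitous_bias: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_entities < 1:
            raise ConfigurationError("n_entities must be >= 1")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_fractions sum to {total}, not 1")
        unknown = set(self.class_fractions) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
        for name in ("noise_sd_bio", "noise_sd_tech"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.proportions_true) != 3:
            raise ConfigurationError("proportions_true must have 3 components")
        if not 0 <= self.restricted_fraction <= 1:
            raise ConfigurationError("restricted_fraction must be in [0, 1]")
        if not 0 <= self.effect_jitter < 1:
            raise ConfigurationError("effect_jitter must be in [0, 1)")
        if not 0 <= self.fraction_independent <= 1:
            raise ConfigurationError("fraction_independent must be in [0, 1]")


@dataclass
class GroundTruth:
    """Ground-truth labels emitted alongside each simulated dataset."""

    category: pd.Series | None = None  # entity -> regulation category
    baseline_log2: pd.Series | None = None  # entity -> baseline log2 intensity
    restricted: pd.Series | None = None  # entity -> bool (off regions absent)
    host: pd.Series | None = None  # phosphosite -> host entity
    independent: pd.Series | None = None  # phosphosite -> host-independent flag
    spatial_class: pd.Series | None = None  # gene -> true spatial class
    module: pd.Series | None = None  # node -> planted module id (-1 = none)
    module_term: dict | None = None  # module id -> planted ontology term
    degree_sequence: pd.Series | None = None  # node -> target degree


class LinkageError(KeyError):
    """A phosphosite references a host entity absent from the proteome."""


def _assign_categories(n: int, fractions: dict, rng: np.random.Generator) -> np.ndarray:
    """Deterministic counts per category (largest-remainder rounding), shuffled."""
    cats = [c for c in CATEGORIES if fractions.get(c, 0) > 0]
    raw = np.array([fractions[c] * n for c in cats])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i % len(cats)]] += 1
    labels = np.repeat(cats, counts)
    rng.shuffle(labels)
    return labels


def _regional_log2(
    categories: np.ndarray,
    baseline: np.ndarray,
    restricted: np.ndarray,
    effect: np.ndarray,
) -> pd.DataFrame:
    """True log2 abundance per entity in each pure region (D, L, V).

    Off regions sit at baseline, on regions at baseline + the entity's own
    effect; restricted entities are fully absent (-inf log2 = zero linear)
    outside their domain.
    """
    n = len(categories)
    out = np.empty((n, 3))
    for j, region in enumerate(("D", "L", "V")):
        on = np.array([region in _CATEGORY_REGIONS[c] for c in categories])
        ubiq = categories == "ubiquitous"
        col = np.where(on & ~ubiq, baseline + effect, baseline)
        col = np.where(~on & restricted, -np.inf, col)
        out[:, j] = col
    return pd.DataFrame(out, columns=["D", "L", "V"])


def _measure(
    true_log2: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    index: pd.Index,
) -> pd.DataFrame:
    """Add nested replicate noise and apply the MNAR dropout threshold.

    ``true_log2`` has one column per genotype; the result has a (genotype,
    bio_rep, tech_rep) MultiIndex over columns with NaN for missing cells.
    """
    cols = pd.MultiIndex.from_tuples(
        [
            (g, b, t)
            for g in true_log2.columns
            for b in range(1, config.n_bio_reps + 1)
            for t in range(1, config.n_tech_reps + 1)
        ],
        names=["genotype", "bio_rep", "tech_rep"],
    )
    n = len(true_log2)
    values = np.empty((n, len(cols)))
    for k, (g, b, t) in enumerate(cols):
        values[:, k] = true_log2[g].to_numpy()
    # bio noise shared across tech reps of the same (genotype, bio rep)
    bio_noise = rng.normal(
        0.0, config.noise_sd_bio, (n, len(true_log2.columns), config.n_bio_reps)
    )
    tech_noise = rng.normal(0.0, config.noise_sd_tech, (n, len(cols)))
    for k, (g, b, t) in enumerate(cols):
        gi = list(true_log2.columns).index(g)
        values[:, k] += bio_noise[:, gi, b - 1] + tech_noise[:, k]
    values[values < config.dropout_log2_threshold] = np.nan
    values[~np.isfinite(true_log2.to_numpy()).repeat(
        config.n_bio_reps * config.n_tech_reps, axis=1
    )] = np.nan
    return pd.DataFrame(values, index=index, columns=cols)


def _entity_matrix(
    categories: np.ndarray,
    baseline: np.ndarray,
    restricted: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    index: pd.Index,
) -> pd.DataFrame:
    n = len(categories)
    effect = config.effect_size * (
        1.0 + config.effect_jitter * (2.0 * rng.random(n) - 1.0)
    )
    regional = _regional_log2(categories, baseline, restricted, effect)
    if config.regional_sd > 0:
        modulation = rng.normal(0.0, config.regional_sd, (n, 3))
        regional += modulation  # -inf stays -inf for restricted-off regions
    a, b, c = config.proportions_true
    linear = np.exp2(regional.to_numpy())  # -inf -> 0
    wt_linear = a * linear[:, 0] + b * linear[:, 1] + c * linear[:, 2]
    with np.errstate(divide="ignore"):
        wt_log2 = np.log2(wt_linear)
    true_log2 = pd.DataFrame(
        {
            "WT": wt_log2,
            "D": regional["D"].to_numpy(),
            "L": regional["L"].to_numpy(),
            "Vtl": regional["V"].to_numpy(),
            "Vsp": regional["V"].to_numpy(),
        }
    )
    return _measure(true_log2, config, rng, index)


def simulate_proteome(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a proteome intensity matrix for WT + four DV mutants.

    Returns a log2 intensity matrix (entities x (genotype, bio_rep, tech_rep)
    MultiIndex columns, NaN = undetected) and the ground truth. Before noise,
    the wild-type linear intensity of every entity equals the
    ``proportions_true``-weighted mixture of its three regional intensities,
    and both ventralized genotypes carry the pure ventral value.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    index = pd.Index(
        [f"P{i:05d}" for i in range(config.n_entities)], name="entity"
    )
    categories = _assign_categories(config.n_entities, config.class_fractions, rng)
    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_entities
    )
    regulated = categories != "ubiquitous"
    restricted = regulated & (rng.random(config.n_entities) < config.restricted_fraction)
    matrix = _entity_matrix(categories, baseline, restricted, config, rng, index)
    truth = GroundTruth(
        category=pd.Series(categories, index=index, name="category"),
        baseline_log2=pd.Series(baseline, index=index, name="baseline_log2"),
        restricted=pd.Series(restricted, index=index, name="restricted"),
    )
    return matrix, truth


def simulate_phosphoproteome(
    config: SimConfig, proteome_truth: GroundTruth
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate phosphosite intensities linked to host proteins.

    ``config.n_sites`` sites are distributed over the proteome's entities.
    A ``fraction_independent`` of sites draws its own regulation category
    (independent of host abundance, the no-correlation regime); the rest
    inherit the host's category. Site ids follow
    ``ProteinAccession_Residue_Position``.
    """
    config.validate()
    if proteome_truth.category is None:
        raise LinkageError("proteome ground truth with categories required")
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_sites
    if n == 0:
        empty = pd.DataFrame(
            index=pd.Index([], name="site"),
            columns=pd.MultiIndex.from_arrays(
                [[], [], []], names=["genotype", "bio_rep", "tech_rep"]
            ),
            dtype=float,
        )
        return empty, GroundTruth(
            category=pd.Series(dtype=object), host=pd.Series(dtype=object)
        )
    entities = proteome_truth.category.index.to_numpy()
    host_w = np.where(
        proteome_truth.category.to_numpy() == "ubiquitous",
        config.phospho_host_ubiquitous_bias,
        1.0,
    )
    hosts = rng.choice(entities, size=n, replace=True, p=host_w / host_w.sum())
    host_cat = proteome_truth.category.loc[hosts].to_numpy()
    independent = rng.random(n) < config.fraction_independent
    regulated_fracs = {
        c: f for c, f in config.class_fractions.items() if c != "ubiquitous"
    }
    total = sum(regulated_fracs.values())
    if total <= 0:
        regulated_fracs = {"D": 1.0}
        total = 1.0
    own_cat = _assign_categories(
        n, {c: f / total for c, f in regulated_fracs.items()}, rng
    )
    categories = np.where(independent, own_cat, host_cat)
    residues = rng.choice(["S", "T", "Y"], size=n, p=[0.75, 0.2, 0.05])
    # positions are unique within each host so site ids never collide
    positions = np.empty(n, dtype=int)
    order = pd.Series(range(n)).groupby(pd.Series(hosts)).cumcount().to_numpy()
    positions = order * 7 + rng.integers(1, 8, size=n)
    index = pd.Index(
        [f"{h}_{r}_{p}" for h, r, p in zip(hosts, residues, positions)], name="site"
    )
    baseline = rng.normal(
        config.baseline_log2_mean - 2.0, config.baseline_log2_sd, n
    )
    regulated = categories != "ubiquitous"
    restricted = regulated & (rng.random(n) < config.restricted_fraction)
    matrix = _entity_matrix(categories, baseline, restricted, config, rng, index)
    truth = GroundTruth(
        category=pd.Series(categories, index=index, name="category"),
        baseline_log2=pd.Series(baseline, index=index, name="baseline_log2"),
        restricted=pd.Series(restricted, index=index, name="restricted"),
        host=pd.Series(hosts, index=index, name="host"),
        independent=pd.Series(independent, index=index, name="independent"),
    )
    return matrix, truth


# --- spatial atlas ----------------------------------------------------------


def _bump(theta: np.ndarray, center: float, kappa: float = 4.0) -> np.ndarray:
    """Smooth von-Mises-style bump of the DV angle, peak 1 at ``center``."""
    return np.exp(kappa * (np.cos(theta - center) - 1.0))


def reference_profiles(theta: np.ndarray) -> pd.DataFrame:
    """The six canonical DV expression patterns over positions.

    Ventral peaks at angle 0, dorsal at pi, lateral on both sides (pi/2 and
    3pi/2); two-domain patterns are sums of the single-domain bumps.
    """
    d = _bump(theta, np.pi)
    l = 0.5 * (_bump(theta, np.pi / 2) + _bump(theta, 3 * np.pi / 2))
    v = _bump(theta, 0.0)
    return pd.DataFrame(
        {"D": d, "L": l, "V": v, "DL": d + l, "DV": d + v, "LV": l + v}
    ).T


def simulate_atlas(
    n_genes: int,
    n_positions: int,
    seed: int,
    noise_sd: float = 0.1,
    classes: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a spatial RNA atlas (gene x DV position expression matrix).

    Returns (atlas, position angles, ground truth). The canonical reference
    genes (dpp, sog, soxN, twist, crb, net, neur) carry their pattern exactly;
    the remaining genes are a pattern plus Gaussian noise. ``classes`` can
    plant a spatial class per gene name (overriding ``n_genes``), e.g. to tie
    atlas genes to the regulation categories of a simulated proteome.
    """
    if (n_genes < 1 and classes is None) or n_positions < 1:
        raise ConfigurationError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2 * np.pi, n_positions, endpoint=False)
    patterns = reference_profiles(theta)
    rows, names, cls = [], [], []
    for cat, genes in REFERENCE_GENES.items():
        for g in genes:
            rows.append(patterns.loc[cat].to_numpy())
            names.append(g)
            cls.append(cat)
    cats = list(patterns.index)
    if classes is None:
        classes = pd.Series(
            [cats[int(rng.integers(len(cats)))] for _ in range(n_genes)],
            index=[f"g{i:05d}" for i in range(n_genes)],
        )
    unknown = set(classes) - set(cats)
    if unknown:
        raise ConfigurationError(f"unknown spatial classes: {sorted(unknown)}")
    for name, c in classes.items():
        rows.append(patterns.loc[c].to_numpy() + rng.normal(0, noise_sd, n_positions))
        names.append(str(name))
        cls.append(c)
    classes = cls
    atlas = pd.DataFrame(rows, index=pd.Index(names, name="gene"))
    truth = GroundTruth(
        spatial_class=pd.Series(classes, index=atlas.index, name="spatial_class")
    )
    return atlas, pd.Series(theta, name="dv_angle"), truth


# --- annotated PPI network + ontology ---------------------------------------


def simulate_ppi_ontology(
    n_nodes: int,
    n_terms: int,
    seed: int,
    n_modules: int = 3,
    module_size: int = 10,
    frac_tyrosine_kinase: float = 0.05,
    frac_other_kinase: float = 0.2,
    weight_floor: float = 0.05,
) -> tuple[nx.Graph, OntologyDAG, GroundTruth]:
    """Simulate a weighted, annotated scale-free PPI network with an ontology.

    The ontology is a random is_a tree with a single root; each planted module
    is a near-clique whose members share a dedicated (high-information) term,
    so in-module pairs have high Resnik similarity. Edge weights are the
    Resnik similarity of the endpoints (floored at ``weight_floor`` to keep
    the graph connected); nodes carry a kinase partition label.
    """
    if n_nodes < 2 or n_terms < 2:
        raise ConfigurationError("counts must be >= 2")
    if n_modules * module_size > n_nodes:
        raise ConfigurationError("modules larger than the network")
    rng = np.random.default_rng(seed)

    terms = [f"T{k:04d}" for k in range(n_terms)]
    parents = {terms[k]: terms[int(rng.integers(k))] for k in range(1, n_terms)}
    # reserve the highest-index terms (leaves of the random tree with high
    # probability) as planted module terms
    module_terms = {m: terms[n_terms - 1 - m] for m in range(n_modules)}

    nodes = [f"N{i:04d}" for i in range(n_nodes)]
    module = np.full(n_nodes, -1)
    for m in range(n_modules):
        module[m * module_size : (m + 1) * module_size] = m

    general = [t for t in terms[1:] if t not in set(module_terms.values())]
    annotations: dict[str, set[str]] = {}
    for i, node in enumerate(nodes):
        ann = set(rng.choice(general, size=min(2, len(general)), replace=False))
        if module[i] >= 0:
            ann.add(module_terms[module[i]])
        annotations[node] = ann

    dag = OntologyDAG.from_parent_map(terms, parents, root=terms[0])
    dag.set_annotations(annotations)

    # scale-free backbone + dense planted modules
    g_int = nx.barabasi_albert_graph(n_nodes, 2, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(g_int, dict(enumerate(nodes)))
    for m in range(n_modules):
        members = [nodes[i] for i in range(n_nodes) if module[i] == m]
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                graph.add_edge(u, v)
    for u, v in graph.edges:
        graph.edges[u, v]["weight"] = max(dag.resnik(u, v), weight_floor)

    n_tyr = max(1, int(round(frac_tyrosine_kinase * n_nodes)))
    n_kin = max(1, int(round(frac_other_kinase * n_nodes)))
    shuffled = list(nodes)
    rng.shuffle(shuffled)
    partition = {}
    for i, node in enumerate(shuffled):
        if i < n_tyr:
            partition[node] = "tyrosine-kinase"
        elif i < n_tyr + n_kin:
            partition[node] = "other-kinase"
        else:
            partition[node] = "other"
    nx.set_node_attributes(graph, partition, "partition")
    nx.set_node_attributes(
        graph, {n: sorted(annotations[n]) for n in nodes}, "annotations"
    )

    truth = GroundTruth(
        module=pd.Series(module, index=pd.Index(nodes, name="node"), name="module"),
        module_term=module_terms,
        degree_sequence=pd.Series(
            dict(graph.degree()), name="target_degree"
        ),
    )
    return graph, dag, truth
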
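"""Non-stationary sequence simulation and synthetic multi-gene studies.

The simulator draws a root state per site and evolves it along each branch
under a reversible exchangeability matrix paired with *branch-specific*
equilibrium frequencies, so base composition can drift toward different
GC contents in different parts of the tree.  This is the classic recipe
for producing compositional attraction artifacts: fast-evolving lineages
pushed toward a shared GC content acquire convergent states that standard
stationary models misread as shared ancestry.

Two entry points matter:

* :func:`lba_validation_scenario` builds the 8-taxon two-partition design
  used to validate rate-based site filtering (long stem branches with
  GC-rich equilibria on opposite sides of the true root split).
* :func:`synthetic_study_generator` emulates a multi-gene phylogenomic
  study at desk scale: short genes, block-wise missing taxa, among-gene
  rate variation, a GC-biased clade, and a fraction of genes drawn from a
  conflicting topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Alignment, GenePartitionSet
from .substmodel import NT_STATES, SubstitutionModel, transition_matrix
from .trees import Tree, random_topology

__all__ = [
    "SimPartition",
    "SimScenario",
    "StudyConfig",
    "gc_freqs",
    "simulate_nonstationary",
    "lba_validation_scenario",
    "synthetic_study_generator",
]


def gc_freqs(gc: float) -> np.ndarray:
    """ACGT frequencies with the given GC content, AT and GC split evenly."""
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


@dataclass
class SimPartition:
    """One simulated partition: a tree with branch lengths, a site count,
    and equilibrium frequencies per branch (keyed by the leaf set below
    the branch; unlisted branches use the scenario default)."""

    name: str
    tree: Tree
    n_sites: int
    edge_freqs: dict[frozenset, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("partition length must be >= 1")
        for v in self.edge_freqs.values():
            if abs(float(np.sum(v)) - 1.0) > 1e-9 or np.any(np.asarray(v) < 0):
                raise ValueError("edge frequencies must lie on the simplex")


@dataclass
class SimScenario:
    """A full simulation design: partitions plus shared substitution terms."""

    partitions: list[SimPartition]
    exchangeabilities: np.ndarray = field(default_factory=lambda: np.ones(6))
    root_freqs: np.ndarray = field(default_factory=lambda: gc_freqs(0.5))
    default_freqs: np.ndarray = field(default_factory=lambda: gc_freqs(0.5))
    site_rate_alpha: float | None = None
    site_rate_mixture: tuple | None = None   # ((rate, weight), ...), mean 1
    true_topology: Tree | None = None
    lba_topology: Tree | None = None


def _clade_below(node) -> frozenset:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.name)
        stack.extend(n.children)
    return frozenset(out)


def _simulate_partition(part: SimPartition, scenario: SimScenario,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = part.n_sites
    base = SubstitutionModel(scenario.exchangeabilities, gc_freqs(0.5))
    if scenario.site_rate_mixture is not None:
        rates_w = np.asarray(scenario.site_rate_mixture, float)
        w = rates_w[:, 1] / rates_w[:, 1].sum()
        site_rates = rates_w[rng.choice(len(w), size=n, p=w), 0]
    elif scenario.site_rate_alpha is not None:
        a = scenario.site_rate_alpha
        site_rates = rng.gamma(a, 1.0 / a, size=n)
    else:
        site_rates = np.ones(n)
    root_states = rng.choice(4, size=n, p=np.asarray(scenario.root_freqs, float))
    states: dict[int, np.ndarray] = {id(part.tree.root): root_states}
    leaves: dict[str, np.ndarray] = {}
    for node in reversed(part.tree.postorder()):  # preorder
        if node.parent is not None:
            pi = part.edge_freqs.get(_clade_below(node), scenario.default_freqs)
            t = node.length if node.length is not None else 0.0
            lam, u, uinv = base.eigensystem(freqs_override=np.asarray(pi, float))
            parent_states = states[id(node.parent)]
            child = np.empty(n, dtype=int)
            e = np.exp(np.multiply.outer(t * site_rates, lam))  # (n, ns)
            for s in range(4):
                mask = parent_states == s
                if not mask.any():
                    continue
                rows = np.clip((u[s] * e[mask]) @ uinv, 0.0, None)  # (m, ns)
                cum = np.cumsum(rows, axis=1)
                draw = rng.random(int(mask.sum())) * cum[:, -1]
                child[mask] = (draw[:, None] >= cum).sum(axis=1)
            states[id(node)] = child
        if node.is_leaf or (node is part.tree.root and node.name):
            leaves[node.name] = states[id(node)]
    leaves["__site_rates__"] = site_rates
    return leaves


def simulate_nonstationary(scenario: SimScenario,
                           seed: int | np.random.Generator = 0,
                           return_site_rates: bool = False):
    """Simulate an alignment under branch-specific equilibrium frequencies.

    Sites are i.i.d. within each partition (optionally with Gamma per-site
    rate multipliers); partitions are concatenated in order and recorded in
    the partition map.  With `return_site_rates`, the drawn multipliers are
    returned alongside the alignment.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    taxa = scenario.partitions[0].tree.leaf_names
    chars = np.array(list(NT_STATES))
    blocks, partitions, pos = [], {}, 0
    all_rates = []
    for part in scenario.partitions:
        if set(part.tree.leaf_names) != set(taxa):
            raise ValueError("partitions must share a taxon set")
        leaves = _simulate_partition(part, scenario, rng)
        all_rates.append(leaves.pop("__site_rates__"))
        blocks.append(np.stack([chars[leaves[t]] for t in taxa]))
        partitions[part.name] = (pos + 1, pos + part.n_sites)
        pos += part.n_sites
    aln = Alignment(list(taxa), np.concatenate(blocks, axis=1), partitions, "nt")
    if return_site_rates:
        return aln, np.concatenate(all_rates)
    return aln


# ------------------------------------------------------ validation design
_TREE_1000 = (
    "(((A1:0.05,A2:0.05):0.3,(B1:0.05,B2:0.05):0.02):0.05,"
    "((C1:0.05,C2:0.05):0.02,(D1:0.05,D2:0.05):0.3):0.05);"
)
_TREE_500 = (
    "(((A1:0.05,A2:0.05):0.5,(B1:0.05,B2:0.05):0.02):0.05,"
    "((C1:0.05,C2:0.05):0.02,(D1:0.05,D2:0.05):0.5):0.05);"
)


def lba_validation_scenario(gc_rich: float = 0.8,
                            gc_base: float = 0.5,
                            site_rate_alpha: float = 0.3,
                            ts_tv: float = 4.0) -> SimScenario:
    """The 8-taxon long-branch-attraction validation design.

    Two partitions (1000 bp and 500 bp) share a balanced topology of four
    two-taxon clades; the A and D stems are long (0.3 and 0.5 expected
    substitutions/site respectively) and those stems plus the clades they
    subtend evolve toward GC-rich equilibria, while all other branches stay
    at the base composition.  Among-site rate variation is strong (Gamma
    shape `site_rate_alpha`) and a shared transition/transversion bias
    `ts_tv` applies on every branch.  Under these conditions saturated,
    compositionally convergent sites pull reconstruction toward the
    artifactual grouping of the two GC-rich, fast clades (A with D).
    """
    rich = gc_freqs(gc_rich)
    rich_clades = [
        frozenset({"A1", "A2"}), frozenset({"A1"}), frozenset({"A2"}),
        frozenset({"D1", "D2"}), frozenset({"D1"}), frozenset({"D2"}),
    ]
    parts = []
    for name, nwk, n in (("p1000", _TREE_1000, 1000), ("p500", _TREE_500, 500)):
        parts.append(
            SimPartition(
                name, Tree.from_newick(nwk), n,
                {c: rich for c in rich_clades},
            )
        )
    true_topo = Tree.from_newick("(((A1,A2),(B1,B2)),((C1,C2),(D1,D2)));")
    lba_topo = Tree.from_newick("(((A1,A2),(D1,D2)),((B1,B2),(C1,C2)));")
    # exchangeability order: AC, AG, AT, CG, CT, GT
    exch = np.array([1.0, ts_tv, 1.0, 1.0, ts_tv, 1.0])
    return SimScenario(
        partitions=parts,
        exchangeabilities=exch,
        root_freqs=gc_freqs(gc_base),
        default_freqs=gc_freqs(gc_base),
        site_rate_alpha=site_rate_alpha,
        true_topology=true_topo,
        lba_topology=lba_topo,
    )


# ------------------------------------------------------ multi-gene study
def _occupancy_keep_prob(n_taxa: int, min_taxa: int, occupancy: float) -> float:
    """Per-taxon keep probability such that E[max(Binomial(n, p), m)] / n
    equals the occupancy target (the floor m biases a naive p upward)."""
    from scipy.optimize import brentq
    from scipy.stats import binom

    target = occupancy * n_taxa
    if target <= min_taxa:
        return 1e-6  # floor dominates; occupancy ~ min_taxa / n_taxa
    if occupancy >= 1.0 - 1e-9:
        return 1.0

    def gap(p):
        k = np.arange(n_taxa + 1)
        return float(
            (np.maximum(k, min_taxa) * binom.pmf(k, n_taxa, p)).sum() - target
        )

    return float(brentq(gap, 1e-6, 1.0 - 1e-9, xtol=1e-10))


@dataclass
class StudyConfig:
    """Desk-scale emulation of a multi-gene vertebrate-style matrix.

    Defaults give ~450-bp genes, ~50% matrix occupancy (block-wise missing
    taxa), log-normal among-gene rate variation, one GC-shifted clade and a
    fifth of genes drawn from a conflicting (NNI-neighboring) topology.
    """

    n_taxa: int = 12
    n_genes: int = 20
    mean_gene_length: int = 450
    gene_length_sd: int = 90
    occupancy: float = 0.5
    rate_log_sd: float = 0.6
    alt_topology_fraction: float = 0.2
    gc_offset: float = 0.15
    mean_branch_length: float = 0.08
    min_taxa_per_gene: int = 4


def synthetic_study_generator(
    config: StudyConfig | None = None, seed: int = 0
) -> tuple[GenePartitionSet, dict]:
    """Generate a multi-gene study fixture plus a truth record.

    Genes are simulated on a master random topology (or an NNI-perturbed
    alternative for a configured fraction), with per-gene rate multipliers
    scaling all branch lengths and one clade evolving toward elevated GC.
    Taxa are then deleted block-wise per gene to hit the occupancy target.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    taxa = [f"t{i + 1:02d}" for i in range(config.n_taxa)]
    master = random_topology(taxa, rng, config.mean_branch_length)
    neighbors = master.nni_neighbors()
    alt = neighbors[int(rng.integers(len(neighbors)))]

    # pick a clade of 2..n/2 taxa from the master tree for the GC offset
    rooted = master.reroot_at_leaf()
    clades = [
        _clade_below(n)
        for n in rooted.postorder()
        if n.parent is not None and not n.is_leaf
    ]
    clades = [c for c in clades if 2 <= len(c) <= config.n_taxa // 2]
    gc_clade = sorted(clades, key=len)[-1] if clades else frozenset(taxa[:2])
    rich = gc_freqs(0.5 + config.gc_offset)
    keep_prob = _occupancy_keep_prob(
        config.n_taxa, config.min_taxa_per_gene, config.occupancy
    )

    genes: dict[str, Alignment] = {}
    truth_genes = {}
    for g in range(config.n_genes):
        name = f"gene{g + 1:03d}"
        length = int(
            np.clip(rng.normal(config.mean_gene_length, config.gene_length_sd),
                    150, None)
        )
        length -= length % 3
        rate = float(rng.lognormal(0.0, config.rate_log_sd))
        use_alt = bool(rng.random() < config.alt_topology_fraction)
        topo = (alt if use_alt else master).copy()
        for e in topo.edges():
            e.length = (e.length or 0.0) * rate
        edge_freqs = {
            c: rich
            for n in topo.reroot_at_leaf().postorder()
            if n.parent is not None
            for c in [_clade_below(n)]
            if c <= gc_clade
        }
        part = SimPartition(name, topo, length, edge_freqs)
        scen = SimScenario([part], np.ones(6), gc_freqs(0.5), gc_freqs(0.5))
        full = simulate_nonstationary(scen, rng)
        k = max(
            int(rng.binomial(config.n_taxa, keep_prob)),
            config.min_taxa_per_gene,
        )
        keep = sorted(
            rng.choice(config.n_taxa, size=k, replace=False).tolist()
        )
        keep = [taxa[i] for i in keep]
        idx = [full.taxa.index(t) for t in keep]
        genes[name] = Alignment(keep, full.matrix[idx], {name: (1, length)}, "nt")
        truth_genes[name] = {
            "length": length,
            "rate_multiplier": rate,
            "topology": "alternative" if use_alt else "master",
            "taxa": keep,
        }
    truth = {
        "seed": seed,
        "master_topology": master.to_newick(),
        "alternative_topology": alt.to_newick(),
        "gc_clade": sorted(gc_clade),
        "occupancy_target": config.occupancy,
        "genes": truth_genes,
    }
    return GenePartitionSet(genes, taxa), truth
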
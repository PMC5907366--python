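"""Synthetic alignments with the statistical structure mito-phylogenomic
bias diagnostics are built to detect.

The kernel is HKY (transition/transversion ratio kappa, arbitrary
equilibrium frequencies) evolved along a tree by matrix exponentials,
with three bias axes layered on top:

* codon-position rate multipliers (third >> first > second, the canonical
  mitochondrial pattern);
* per-site rate classes with retained truth labels (e.g. a fast class that
  saturates and becomes homoplastic);
* nonstationary composition shifts: a branch and everything below it
  switches to new equilibrium frequencies, emulating a lineage-specific
  AT-enrichment such as the fast, AT-rich clade contrast seen in
  heteropteran mitochondrial genomes.

Codon mode evolves whole codons: single-nucleotide HKY rates are
multiplied by omega when the change is nonsynonymous (NCBI table 5) and
zeroed when it would create a stop codon, i.e. purifying selection with
strength 1 - omega.  All randomness flows from one seed through one
generator; regeneration from (spec, seed) is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.linalg import expm
from Bio.Data import CodonTable

from .seq_io import Alignment, AlignmentError, PartitionEntry, PartitionScheme

_NUC = "ACGT"


@dataclass(frozen=True)
class RateClass:
    proportion: float
    multiplier: float
    label: str = ""


@dataclass
class SimulationSpec:
    """Everything needed to regenerate a dataset deterministically."""

    seed: int
    n_taxa: int = 30
    genes: tuple[tuple[str, int], ...] = (("gene1", 600),)
    kappa: float = 4.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    #: per codon position {1,2,3} rate multipliers
    position_rates: dict[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 1.0, 3: 1.0})
    #: extra site-rate classes (proportions must sum to 1)
    rate_classes: tuple[RateClass, ...] = (RateClass(1.0, 1.0, "base"),)
    #: (clade taxon labels, new equilibrium frequencies); the shift applies
    #: on the branch above the clade's MRCA and is inherited below it
    shifts: tuple[tuple[frozenset, tuple[float, float, float, float]], ...] = ()
    #: None = nucleotide mode; a number = codon mode with that omega
    omega: float | None = None
    genetic_code: int = 5
    tree: dendropy.Tree | None = None
    mean_branch_length: float = 0.05
    #: terminal-branch multipliers by taxon label (long-branch taxa)
    terminal_stretch: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(c.proportion for c in self.rate_classes) - 1) > 1e-9:
            raise AlignmentError("rate-class proportions must sum to 1")
        for f in (self.freqs, *[s[1] for s in self.shifts]):
            if abs(sum(f) - 1) > 1e-9 or min(f) <= 0:
                raise AlignmentError(f"invalid frequency vector {f}")
        if any(c.multiplier < 0 for c in self.rate_classes):
            raise AlignmentError("rate multipliers must be >= 0")
        if self.omega is not None and not 0 <= self.omega <= 10:
            raise AlignmentError(f"omega must be in [0, 10], got {self.omega}")
        if self.omega is not None:
            for _, n in self.genes:
                if n % 3:
                    raise AlignmentError("codon mode needs gene lengths % 3 == 0")


@dataclass
class SimulatedDataset:
    alignment: Alignment
    tree: dendropy.Tree
    partition: PartitionScheme
    #: per-site rate-class label (truth for enrichment checks)
    site_class: np.ndarray
    #: per-site total rate multiplier actually applied
    site_rate: np.ndarray
    clade_map: dict[str, set[str]]
    spec: SimulationSpec


def random_tree(n_taxa: int, rng: np.random.Generator,
                mean_branch_length: float = 0.05,
                labels: list[str] | None = None) -> dendropy.Tree:
    """Random binary rooted tree by sequential joining, exponential branch
    lengths, labels t01..tNN unless given."""
    if labels is None:
        labels = [f"t{i + 1:02d}" for i in range(n_taxa)]
    newick = _random_subtree(list(labels), rng, mean_branch_length) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    tree.seed_node.edge.length = None
    return tree


def _random_subtree(labels: list[str], rng: np.random.Generator,
                    mean_bl: float) -> str:
    """Newick fragment (with a branch length on its root edge)."""
    nodes = [f"{lab}:{rng.exponential(mean_bl):.8f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = f"({nodes[i]},{nodes[j]}):{rng.exponential(mean_bl):.8f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [joined]
    return nodes[0]


def two_clade_tree(clade_a: list[str], clade_b: list[str],
                   rng: np.random.Generator,
                   mean_branch_length: float = 0.05) -> dendropy.Tree:
    """Random tree in which ``clade_a`` and ``clade_b`` are sister clades
    (so composition shifts can target a genuine clade)."""
    sa = _random_subtree(clade_a, rng, mean_branch_length)
    sb = _random_subtree(clade_b, rng, mean_branch_length)
    tree = dendropy.Tree.get(data=f"({sa},{sb});", schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _hky_q(freqs, kappa: float) -> np.ndarray:
    """HKY rate matrix, rows = source base (ACGT), mean rate 1."""
    pi = np.asarray(freqs, dtype=float)
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -(pi * np.diag(q)).sum()
    if rate <= 0:
        raise AlignmentError("degenerate rate matrix")
    return q / rate


def _sample_markov(parent: np.ndarray, P: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    cum = P.cumsum(axis=1)
    u = rng.random(len(parent))
    return (u[:, None] > cum[parent]).sum(axis=1)


def _shift_nodes(tree: dendropy.Tree, spec: SimulationSpec) -> dict:
    """Map node -> frequency vector active on its subtree (incl. its edge)."""
    out = {}
    for clade, freqs in spec.shifts:
        labels = sorted(clade)
        unknown = set(labels) - {lf.taxon.label for lf in tree.leaf_node_iter()}
        if unknown:
            raise AlignmentError(f"shift clade taxa not in tree: {sorted(unknown)}")
        node = (tree.mrca(taxon_labels=labels) if len(labels) > 1 else
                next(lf for lf in tree.leaf_node_iter()
                     if lf.taxon.label == labels[0]))
        out[node] = tuple(freqs)
    return out


def _site_layout(spec: SimulationSpec, rng: np.random.Generator):
    genes, cpos = [], []
    entries, start = [], 0
    for name, n in spec.genes:
        genes += [name] * n
        cpos += [(i % 3) + 1 for i in range(n)]
        entries.append(PartitionEntry(name, start, start + n))
        start += n
    n_sites = len(genes)
    props = [c.proportion for c in spec.rate_classes]
    cls = rng.choice(len(spec.rate_classes), size=n_sites, p=props)
    cpos = np.array(cpos)
    rate = (np.array([spec.rate_classes[c].multiplier for c in cls])
            * np.array([spec.position_rates[p] for p in cpos]))
    return (np.array(genes, dtype=object), cpos, cls, rate,
            PartitionScheme(entries))


def _resolve_tree(spec: SimulationSpec, rng: np.random.Generator):
    tree = (spec.tree.clone(depth=1) if spec.tree is not None
            else random_tree(spec.n_taxa, rng, spec.mean_branch_length))
    tree.is_rooted = True  # evolution runs from the seed node
    for lf in tree.leaf_node_iter():
        stretch = spec.terminal_stretch.get(lf.taxon.label)
        if stretch:
            lf.edge.length *= stretch
    return tree


def simulate_nucleotide(spec: SimulationSpec) -> SimulatedDataset:
    """Evolve nucleotide sites along the tree under (possibly shifted) HKY."""
    if spec.omega is not None:
        raise AlignmentError("spec has codon mode on; use simulate_codon")
    rng = np.random.default_rng(spec.seed)
    tree = _resolve_tree(spec, rng)
    gene, cpos, cls, rate, parts = _site_layout(spec, rng)
    n_sites = len(gene)
    shift_at = _shift_nodes(tree, spec)
    uniq_rates = np.unique(rate)
    pcache: dict = {}

    def P(freqs, r, t):
        key = (freqs, round(r, 12), round(t, 12))
        if key not in pcache:
            pcache[key] = (np.eye(4) if r * t == 0
                           else expm(_hky_q(freqs, spec.kappa) * r * t))
        return pcache[key]

    root_pi = np.asarray(spec.freqs)
    states = {tree.seed_node: rng.choice(4, size=n_sites, p=root_pi)}
    freqs_at = {tree.seed_node: tuple(spec.freqs)}
    seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            freqs = shift_at.get(node, freqs_at[node.parent_node])
            freqs_at[node] = freqs
            parent = states[node.parent_node]
            child = np.empty(n_sites, dtype=np.int64)
            t = node.edge.length or 0.0
            for r in uniq_rates:
                msk = rate == r
                child[msk] = _sample_markov(parent[msk], P(freqs, float(r), t), rng)
            states[node] = child
        if node.is_leaf():
            seqs[node.taxon.label] = states[node]
    taxa = sorted(seqs)
    matrix = np.array([[_NUC[s] for s in seqs[t]] for t in taxa], dtype="<U1")
    aln = Alignment(taxa, matrix, "DNA", gene, cpos)
    labels = np.array([spec.rate_classes[c].label or str(c) for c in cls],
                      dtype=object)
    return SimulatedDataset(aln, tree, parts, labels, rate, {}, spec)


def _sense_codons(code_id: int):
    ct = CodonTable.unambiguous_dna_by_id[code_id]
    codons = [a + b + c for a in _NUC for b in _NUC for c in _NUC]
    sense = [c for c in codons if c not in ct.stop_codons]
    aa = {c: ct.forward_table[c] for c in sense}
    return sense, aa


def _codon_q(freqs, kappa: float, omega: float, code_id: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Rate matrix on sense codons; returns (Q, stationary, codon list)."""
    sense, aa = _sense_codons(code_id)
    pi_n = np.asarray(freqs)
    idx = {c: i for i, c in enumerate(sense)}
    n = len(sense)
    q = np.zeros((n, n))
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for c in sense:
        for pos in range(3):
            for alt in _NUC:
                if alt == c[pos]:
                    continue
                c2 = c[:pos] + alt + c[pos + 1:]
                if c2 not in idx:
                    continue  # stop codon: forbidden
                r = pi_n[_NUC.index(alt)]
                if (c[pos], alt) in transitions:
                    r *= kappa
                if aa[c] != aa[c2]:
                    r *= omega
                q[idx[c], idx[c2]] = r
    np.fill_diagonal(q, -q.sum(axis=1))
    pi_c = np.array([np.prod([pi_n[_NUC.index(ch)] for ch in c]) for c in sense])
    pi_c /= pi_c.sum()
    rate = -(pi_c * np.diag(q)).sum()
    if rate > 0:
        q = q / rate
    return q, pi_c, sense


def simulate_codon(spec: SimulationSpec) -> SimulatedDataset:
    """Evolve codons under HKY x purifying selection (omega)."""
    if spec.omega is None:
        raise AlignmentError("spec has no omega; use simulate_nucleotide")
    rng = np.random.default_rng(spec.seed)
    tree = _resolve_tree(spec, rng)
    gene, cpos, cls, rate, parts = _site_layout(spec, rng)
    n_sites = len(gene)
    # rate classes apply per codon: use the class of the codon's first site
    codon_first = np.arange(0, n_sites, 3)
    codon_cls = cls[codon_first]
    codon_rate = np.array([spec.rate_classes[c].multiplier for c in codon_cls])
    n_codons = len(codon_first)
    shift_at = _shift_nodes(tree, spec)
    uniq = np.unique(codon_rate)
    qcache: dict = {}
    pcache: dict = {}

    def QP(freqs):
        if freqs not in qcache:
            qcache[freqs] = _codon_q(freqs, spec.kappa, spec.omega,
                                     spec.genetic_code)
        return qcache[freqs]

    def P(freqs, r, t):
        key = (freqs, round(float(r), 12), round(t, 12))
        if key not in pcache:
            q, _, _ = QP(freqs)
            pcache[key] = (np.eye(q.shape[0]) if r * t == 0
                           else expm(q * r * t))
        return pcache[key]

    _, pi_c, sense = QP(tuple(spec.freqs))
    states = {tree.seed_node: rng.choice(len(sense), size=n_codons, p=pi_c)}
    freqs_at = {tree.seed_node: tuple(spec.freqs)}
    seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            freqs = shift_at.get(node, freqs_at[node.parent_node])
            freqs_at[node] = freqs
            parent = states[node.parent_node]
            child = np.empty(n_codons, dtype=np.int64)
            t = node.edge.length or 0.0
            for r in uniq:
                msk = codon_rate == r
                child[msk] = _sample_markov(parent[msk], P(freqs, r, t), rng)
            states[node] = child
        if node.is_leaf():
            seqs[node.taxon.label] = states[node]
    taxa = sorted(seqs)
    matrix = np.array([list("".join(sense[s] for s in seqs[t])) for t in taxa],
                      dtype="<U1")
    aln = Alignment(taxa, matrix, "DNA", gene, cpos)
    labels = np.array([spec.rate_classes[c].label or str(c)
                       for c in np.repeat(codon_cls, 3)], dtype=object)
    return SimulatedDataset(aln, tree, parts, labels,
                            np.repeat(codon_rate, 3), {}, spec)


# -- canned benchmark scenarios ----------------------------------------

#: base composition: AT-rich the way insect mt-genomes are
_BASE_FREQS = (0.33, 0.17, 0.13, 0.37)          # AT = 0.70
_AT_RICH = (0.41, 0.10, 0.08, 0.41)             # AT = 0.82

SCENARIOS = ("homogeneous", "shifted_clade", "lba_with_fast_sites",
             "two_gene_rates")


def _clade_labels(prefix_range) -> frozenset:
    return frozenset(f"t{i:02d}" for i in prefix_range)


def make_benchmark_scenario(name: str, seed: int) -> SimulatedDataset:
    """Canned simulation specs exercising each diagnostic.

    homogeneous        stationary HKY, one rate regime: the calm null.
    shifted_clade      60 taxa, a 12-taxon clade switched to AT-rich
                       equilibria: positive control for composition tests.
    lba_with_fast_sites~30 taxa, 30% of sites at 10x rate plus convergent
                       AT shifts on two long, unrelated terminal branches:
                       breaks NJ, the CI filter's end-to-end test bed.
    two_gene_rates     two equal-length genes at 5x rate contrast for the
                       removal-ratio pattern.
    """
    if name == "homogeneous":
        spec = SimulationSpec(
            seed=seed, n_taxa=30,
            genes=(("gene1", 600), ("gene2", 600)),
            kappa=4.0, freqs=_BASE_FREQS,
            position_rates={1: 1.0, 2: 0.5, 3: 3.0},
            mean_branch_length=0.04)
        ds = simulate_nucleotide(spec)
    elif name == "shifted_clade":
        clade = _clade_labels(range(1, 13))
        background = [f"t{i:02d}" for i in range(13, 61)]
        rng = np.random.default_rng(seed)
        tree = two_clade_tree(sorted(clade), background, rng, 0.05)
        spec = SimulationSpec(
            seed=seed, n_taxa=60, tree=tree,
            genes=(("gene1", 900), ("gene2", 900)),
            kappa=4.0, freqs=_BASE_FREQS,
            position_rates={1: 1.0, 2: 0.4, 3: 5.0},
            shifts=((clade, _AT_RICH),),
            mean_branch_length=0.05)
        ds = simulate_nucleotide(spec)
        ds.clade_map = {"shifted": set(clade), "background": set(background)}
    elif name == "lba_with_fast_sites":
        rng = np.random.default_rng(seed)
        tree = _lba_tree(rng)
        true_clade = _clade_labels(range(16, 31))
        spec = SimulationSpec(
            seed=seed, n_taxa=30, tree=tree,
            genes=(("gene1", 1500), ("gene2", 1500)),
            kappa=4.0, freqs=_BASE_FREQS,
            position_rates={1: 1.0, 2: 1.0, 3: 1.0},
            rate_classes=(RateClass(0.7, 1.0, "slow"),
                          RateClass(0.3, 10.0, "fast")),
            shifts=((frozenset({"t01"}), _AT_RICH),
                    (frozenset({"t16"}), _AT_RICH)))
        ds = simulate_nucleotide(spec)
        ds.clade_map = {"true_clade": set(true_clade)}
    elif name == "two_gene_rates":
        spec = SimulationSpec(
            seed=seed, n_taxa=30,
            genes=(("gene_fast", 600), ("gene_slow", 600)),
            kappa=4.0, freqs=_BASE_FREQS,
            position_rates={1: 1.0, 2: 1.0, 3: 1.0},
            rate_classes=(RateClass(1.0, 1.0, "base"),),
            mean_branch_length=0.06)
        # 5x contrast is carried by a gene-level multiplier: implemented as
        # rate classes aligned with the gene layout
        ds = _two_gene_dataset(spec)
    else:
        raise AlignmentError(
            f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return ds


def _two_gene_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Gene-level 5x rate contrast (gene_fast vs gene_slow)."""
    rng = np.random.default_rng(spec.seed)
    tree = _resolve_tree(spec, rng)
    fast_spec = replace(spec, seed=spec.seed + 1,
                        tree=tree, genes=(("gene_fast", spec.genes[0][1]),),
                        rate_classes=(RateClass(1.0, 5.0, "fast_gene"),))
    slow_spec = replace(spec, seed=spec.seed + 2,
                        tree=tree, genes=(("gene_slow", spec.genes[1][1]),),
                        rate_classes=(RateClass(1.0, 1.0, "slow_gene"),))
    fast = simulate_nucleotide(fast_spec)
    slow = simulate_nucleotide(slow_spec)
    taxa = fast.alignment.taxa
    matrix = np.concatenate([fast.alignment.matrix,
                             slow.alignment.matrix[
                                 [slow.alignment.taxa.index(t) for t in taxa]]],
                            axis=1)
    gene = np.concatenate([fast.alignment.gene, slow.alignment.gene])
    cpos = np.concatenate([fast.alignment.codon_pos, slow.alignment.codon_pos])
    nf = fast.alignment.n_sites
    parts = PartitionScheme([
        PartitionEntry("gene_fast", 0, nf),
        PartitionEntry("gene_slow", nf, nf + slow.alignment.n_sites)])
    aln = Alignment(taxa, matrix, "DNA", gene, cpos)
    return SimulatedDataset(aln, tree, parts,
                            np.concatenate([fast.site_class, slow.site_class]),
                            np.concatenate([fast.site_rate, slow.site_rate]),
                            {}, spec)


def _lba_tree(rng: np.random.Generator) -> dendropy.Tree:
    """31 leaves: outgroup 'og'; clade A = t01..t15 (t01 stretched), true
    clade B = t16..t30 (t16 stretched); short internal edges so the two
    stretched, compositionally convergent terminals attract."""

    def caterpillar(labels, tip, internal):
        if len(labels) == 1:
            return f"{labels[0]}:{tip:.6f}"
        return (f"({labels[0]}:{tip:.6f},"
                f"{caterpillar(labels[1:], tip, internal)}):{internal:.6f}")

    a_labels = [f"t{i:02d}" for i in range(1, 16)]
    b_labels = [f"t{i:02d}" for i in range(16, 31)]
    jitter = rng.uniform(0.9, 1.1)
    tip, internal = 0.05 * jitter, 0.025 * jitter
    newick = (f"(({caterpillar(a_labels, tip, internal)}:{internal:.6f},"
              f"{caterpillar(b_labels, tip, internal)}:{internal:.6f})"
              f":{internal:.6f},og:{0.3 * jitter:.6f});")
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    # stretch the two attracting terminals
    for lf in tree.leaf_node_iter():
        if lf.taxon.label in ("t01", "t16"):
            lf.edge.length *= 6.0
    return tree


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, str]:
    """Serialise alignment/tree/partition/clade map/spec next to each other."""
    import json
    import os

    from . import seq_io

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "alignment": os.path.join(out_dir, "alignment.fasta"),
        "tree": os.path.join(out_dir, "tree.nwk"),
        "partition": os.path.join(out_dir, "partition.txt"),
        "clades": os.path.join(out_dir, "clades.txt"),
        "spec": os.path.join(out_dir, "sim_spec.json"),
        "site_truth": os.path.join(out_dir, "site_truth.tsv"),
    }
    seq_io.write_alignment(ds.alignment, paths["alignment"])
    seq_io.write_tree(ds.tree, paths["tree"])
    seq_io.write_partition(ds.partition, paths["partition"])
    with open(paths["clades"], "w") as fh:
        for name, members in ds.clade_map.items():
            fh.write(f"{name}: {','.join(sorted(members))}\n")
    with open(paths["spec"], "w") as fh:
        d = {k: v for k, v in vars(ds.spec).items() if k != "tree"}
        d["shifts"] = [[sorted(c), list(f)] for c, f in d["shifts"]]
        d["rate_classes"] = [vars(c) for c in d["rate_classes"]]
        d["genes"] = [list(g) for g in d["genes"]]
        json.dump(d, fh, indent=1, default=str)
    with open(paths["site_truth"], "w") as fh:
        fh.write("site\tgene\tcodon_pos\trate_class\trate\n")
        for i in range(ds.alignment.n_sites):
            fh.write(f"{i}\t{ds.alignment.gene[i]}\t{ds.alignment.codon_pos[i]}"
                     f"\t{ds.site_class[i]}\t{ds.site_rate[i]:g}\n")
    return paths
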
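"""Per-site parsimony signal and consistency-index filtering.

For each alignment site the minimum conceivable number of changes is
m = max(0, distinct unambiguous states - 1) and s is the parsimony step
count on a fixed reference topology (generalised Fitch/Hartigan, exact on
multifurcating trees).  The per-site consistency index CI = m/s measures
homoplasy: CI = 1 means the site fits the tree perfectly, CI < 1 means
extra, convergent changes.  Sites with CI below a threshold (0.3 by
convention) are read as weak phylogenetic signal and removed; invariant
sites (s = 0) are assigned CI = 1 and always retained, so signal-free but
harmless sites never inflate the removal arithmetic.

Gaps and '?' are missing data: a missing leaf contributes the full state
set to the Fitch recursion and can never force a step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .seq_io import Alignment, AlignmentError, prune_to_taxa


def _state_bitmasks(a: Alignment) -> tuple[list[str], np.ndarray]:
    """Encode the matrix as per-leaf state-set bitmasks (uint32).

    Concrete alphabet characters map to singleton sets; anything else
    (gap, '?', IUPAC ambiguity) is the full set.
    """
    states = sorted(a.concrete_states())
    full = (1 << len(states)) - 1
    masks = np.full(a.matrix.shape, full, dtype=np.uint32)
    for k, s in enumerate(states):
        masks[a.matrix == s] = np.uint32(1 << k)
    return states, masks


def fitch_steps_matrix(tree: dendropy.Tree, taxa: list[str],
                       leaf_sets: np.ndarray, n_states: int) -> np.ndarray:
    """Parsimony step counts for every column at once.

    ``leaf_sets`` is (n_taxa, n_sites) of state-set bitmasks ordered as
    ``taxa``.  Multifurcations are scored directly by the Hartigan count:
    at each internal node, steps += (number of children) - (maximum number
    of children whose sets share a state); the node keeps the states
    achieving that maximum.  The count is invariant to root placement.
    """
    index = {t: i for i, t in enumerate(taxa)}
    n_sites = leaf_sets.shape[1]
    steps = np.zeros(n_sites, dtype=np.int64)
    node_sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in index:
                raise AlignmentError(f"tree leaf {label!r} absent from alignment")
            node_sets[node] = leaf_sets[index[label]]
            continue
        children = [node_sets.pop(c) for c in node.child_nodes()]
        if len(children) == 1:  # knuckle (e.g. rooted degree-1 seed)
            node_sets[node] = children[0]
            continue
        counts = np.zeros((n_states, n_sites), dtype=np.int32)
        for k in range(n_states):
            bit = np.uint32(1 << k)
            for ch in children:
                counts[k] += (ch & bit) != 0
        kmax = counts.max(axis=0)
        steps += len(children) - kmax
        sets = np.zeros(n_sites, dtype=np.uint32)
        for k in range(n_states):
            sets |= (counts[k] == kmax).astype(np.uint32) << np.uint32(k)
        node_sets[node] = sets
    return steps


def fitch_steps(site_states: dict[str, str | set[str] | None],
                tree: dendropy.Tree,
                state_space: list[str] | None = None) -> int:
    """Parsimony step count for a single character.

    ``site_states`` maps every tree leaf to a state, a set of states
    (ambiguity), or None/'-'/'?' for missing (= the full state set).
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing_leaves = set(leaves) - set(site_states)
    if missing_leaves:
        raise AlignmentError(f"leaves absent from alignment: {sorted(missing_leaves)}")
    if state_space is None:
        pool: set[str] = set()
        for v in site_states.values():
            if v is None or v in ("-", "?"):
                continue
            pool |= set(v) if isinstance(v, (set, frozenset)) else {v}
        state_space = sorted(pool) if pool else ["A"]
    k = len(state_space)
    full = (1 << k) - 1
    idx = {s: i for i, s in enumerate(state_space)}
    sets = np.empty((len(leaves), 1), dtype=np.uint32)
    for i, leaf in enumerate(leaves):
        v = site_states[leaf]
        if v is None or v in ("-", "?"):
            sets[i, 0] = full
        else:
            members = set(v) if isinstance(v, (set, frozenset)) else {v}
            mask = 0
            for s in members:
                mask |= 1 << idx[s]
            sets[i, 0] = mask
    return int(fitch_steps_matrix(tree, leaves, sets, k)[0])


@dataclass
class FilterConfig:
    tree: dendropy.Tree
    ci_threshold: float = 0.3
    outgroup: set[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_threshold <= 1.0:
            raise AlignmentError(
                f"ci_threshold must be in [0, 1], got {self.ci_threshold}")


def site_signals(a: Alignment, cfg: FilterConfig) -> pd.DataFrame:
    """Per-site (m, s, CI, retained) against the reference topology.

    The tree is pruned to the alignment's taxa (every alignment taxon must
    be a tree leaf).  Columns: site (0-based), gene, codon_pos, m, s, CI,
    retained.
    """
    leaf_labels = {lf.taxon.label for lf in cfg.tree.leaf_node_iter()}
    shared = [t for t in a.taxa if t in leaf_labels]
    missing = set(a.taxa) - leaf_labels
    if missing:
        raise AlignmentError(f"alignment taxa absent from tree: {sorted(missing)}")
    if len(shared) < 4:
        raise AlignmentError(f"need >= 4 shared taxa, have {len(shared)}")
    tree = prune_to_taxa(cfg.tree, shared)
    states, masks = _state_bitmasks(a)
    s = fitch_steps_matrix(tree, a.taxa, masks, len(states))
    # m: distinct concrete states among leaves, minus 1
    distinct = np.zeros(a.n_sites, dtype=np.int64)
    for k in range(len(states)):
        distinct += ((masks == np.uint32(1 << k)).any(axis=0)).astype(np.int64)
    m = np.maximum(distinct - 1, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(s > 0, m / np.maximum(s, 1), 1.0)
    retained = ci >= cfg.ci_threshold
    return pd.DataFrame({
        "site": np.arange(a.n_sites), "gene": a.gene,
        "codon_pos": a.codon_pos, "m": m, "s": s, "CI": ci,
        "retained": retained,
    })


def apply_filter(a: Alignment, signals: pd.DataFrame,
                 ) -> tuple[Alignment, np.ndarray]:
    """Drop non-retained sites; returns (filtered alignment, removed mask)."""
    if len(signals) != a.n_sites:
        raise AlignmentError("signals do not align with the alignment sites")
    removed = ~signals["retained"].to_numpy()
    if removed.all():
        raise AlignmentError(
            "filter removed every site; review the CI threshold")
    return a.take_sites(~removed), removed


def removal_summary(removed: np.ndarray, a: Alignment) -> pd.DataFrame:
    """Per-gene removal bookkeeping at site and codon granularity.

    ``codons_fully_removed`` counts codons with all three positions removed
    (the "complete amino acids" reading); ``codons_partially_removed``
    counts codons with at least one position removed.  Both ratios are
    reported because the two conventions differ.
    """
    removed = np.asarray(removed, dtype=bool)
    rows = []
    for g in a.genes():
        idx = np.where(a.gene == g)[0]
        rem = removed[idx]
        n_codons = len(idx) // 3
        by_codon = rem[:n_codons * 3].reshape(n_codons, 3)
        full = int(by_codon.all(axis=1).sum())
        partial = int(by_codon.any(axis=1).sum())
        rows.append({
            "gene": g, "sites_total": len(idx), "sites_removed": int(rem.sum()),
            "site_removal_ratio": rem.mean() if len(idx) else np.nan,
            "codons_total": n_codons, "codons_fully_removed": full,
            "codons_partially_removed": partial,
            "aa_removal_ratio_full": full / n_codons if n_codons else np.nan,
            "aa_removal_ratio_any": partial / n_codons if n_codons else np.nan,
        })
    out = pd.DataFrame(rows)
    total = {
        "gene": "ALL", "sites_total": int(out["sites_total"].sum()),
        "sites_removed": int(out["sites_removed"].sum()),
        "site_removal_ratio": out["sites_removed"].sum() / max(out["sites_total"].sum(), 1),
        "codons_total": int(out["codons_total"].sum()),
        "codons_fully_removed": int(out["codons_fully_removed"].sum()),
        "codons_partially_removed": int(out["codons_partially_removed"].sum()),
        "aa_removal_ratio_full": out["codons_fully_removed"].sum() / max(out["codons_total"].sum(), 1),
        "aa_removal_ratio_any": out["codons_partially_removed"].sum() / max(out["codons_total"].sum(), 1),
    }
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def is_monophyletic(tree: dendropy.Tree, taxa: set[str],
                    outgroup: set[str] | str) -> bool:
    """True iff, after rooting on the outgroup, some node's descendant leaf
    set equals ``taxa`` exactly."""
    if isinstance(outgroup, str):
        outgroup = {outgroup}
    taxa = set(taxa)
    if taxa & outgroup:
        raise AlignmentError("outgroup overlaps the queried taxon set")
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing_og = outgroup - leaf_labels
    if missing_og:
        raise AlignmentError(f"outgroup taxa not in tree: {sorted(missing_og)}")
    if not taxa <= leaf_labels:
        raise AlignmentError(f"taxa not in tree: {sorted(taxa - leaf_labels)}")
    t = tree.clone(depth=1)
    t.is_rooted = True
    if len(outgroup) == 1:
        og_node = next(lf for lf in t.leaf_node_iter()
                       if lf.taxon.label in outgroup)
    else:
        og_node = t.mrca(taxon_labels=sorted(outgroup))
    if og_node.parent_node is not None:
        t.reroot_at_edge(og_node.edge, update_bipartitions=False,
                         suppress_unifurcations=True)
    for node in t.preorder_node_iter():
        if {lf.taxon.label for lf in node.leaf_iter()} == taxa:
            return True
    return False
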
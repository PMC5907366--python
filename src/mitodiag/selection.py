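"""Nei-Gojobori (1986) Ka/Ks and clade branch-length summaries.

The NG86 counting method: each codon contributes synonymous-site fractions
(number of synonymous single-nucleotide changes at each position / 3,
averaged over the two sequences); observed differences are resolved by
averaging over all minimal substitution pathways with equal weights,
excluding pathways that pass through stop codons; proportions are
Jukes-Cantor corrected, d = -3/4 ln(1 - 4/3 p).  Changes that would create
a stop codon count as nonsynonymous in site counting, which preserves the
N + S = 3 x codons bookkeeping.  omega = Ka/Ks < 1 reads as purifying
selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .seq_io import Alignment, AlignmentError

_NUC = "ACGT"


@lru_cache(maxsize=None)
def _code(table: int):
    ct = CodonTable.unambiguous_dna_by_id[table]
    aa = dict(ct.forward_table)
    for stop in ct.stop_codons:
        aa[stop] = "*"
    return aa


@lru_cache(maxsize=None)
def _syn_fraction(codon: str, table: int) -> float:
    """Sum over the 3 positions of the synonymous fraction of changes."""
    aa = _code(table)
    if aa[codon] == "*":
        raise AlignmentError(f"stop codon {codon} has no site fractions")
    syn = 0
    for pos in range(3):
        for alt in _NUC:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if aa[mutant] == aa[codon] and aa[mutant] != "*":
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def _pathway_counts(ca: str, cb: str, table: int) -> tuple[float, float, int]:
    """(syn diffs, nonsyn diffs, usable pathways) averaged over minimal
    pathways between two sense codons, skipping pathways through stops."""
    aa = _code(table)
    positions = [k for k in range(3) if ca[k] != cb[k]]
    sd = nd = 0.0
    usable = 0
    for order in itertools.permutations(positions):
        cur = ca
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if aa[nxt] == "*":
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if not ok:
            continue
        usable += 1
        for c0, c1 in steps:
            if aa[c0] == aa[c1]:
                sd += 1
            else:
                nd += 1
    if usable:
        sd /= usable
        nd /= usable
    return sd, nd, usable


@dataclass
class KaKsRecord:
    gene: str
    taxon_a: str
    taxon_b: str
    codons: int
    codons_skipped: int
    N: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    omega: float


def _jc(p: float) -> float:
    if not np.isfinite(p):
        return np.nan
    if p >= 0.75:
        return np.nan
    return -0.75 * np.log(1 - 4.0 * p / 3.0)


def ng86(seq_a: str, seq_b: str, table: int = 5, gene: str = "",
         taxon_a: str = "a", taxon_b: str = "b") -> KaKsRecord:
    """NG86 Ka/Ks for two equal-length in-frame coding sequences.

    Codons containing non-ACGT characters in either sequence, or that are
    stop codons, or whose every minimal pathway passes through a stop, are
    skipped and tallied in ``codons_skipped``.
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}")
    if len(seq_a) % 3:
        raise AlignmentError(f"length {len(seq_a)} not divisible by 3")
    aa = _code(table)
    s_a = s_b = sd = nd = 0.0
    used = skipped = 0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k:k + 3].upper(), seq_b[k:k + 3].upper()
        if any(ch not in _NUC for ch in ca + cb):
            skipped += 1
            continue
        if aa[ca] == "*" or aa[cb] == "*":
            skipped += 1
            continue
        if ca != cb:
            psd, pnd, usable = _pathway_counts(ca, cb, table)
            if usable == 0:
                skipped += 1
                continue
            sd += psd
            nd += pnd
        used += 1
        s_a += _syn_fraction(ca, table)
        s_b += _syn_fraction(cb, table)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * used - s_sites
    ps = sd / s_sites if s_sites > 0 else np.nan
    pn = nd / n_sites if n_sites > 0 else np.nan
    ka, ks = _jc(pn), _jc(ps)
    omega = ka / ks if np.isfinite(ks) and ks > 0 and np.isfinite(ka) else np.nan
    return KaKsRecord(gene, taxon_a, taxon_b, used, skipped, n_sites, s_sites,
                      nd, sd, pn, ps, ka, ks, omega)


def _gene_codon_columns(a: Alignment, gene: str) -> np.ndarray:
    idx = np.where(a.gene == gene)[0]
    if len(idx) % 3:
        raise AlignmentError(f"gene {gene} length {len(idx)} not divisible by 3")
    return idx


def ka_vs_reference(a: Alignment, reference_taxon: str, table: int = 5,
                    clade_map: dict[str, set[str]] | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise NG86 of every taxon against a reference, per gene plus a
    concatenated all-gene record; optional clade means of Ka.

    Returns (records, clade_means); clade_means is None without a map.
    """
    if reference_taxon not in a.taxa:
        raise AlignmentError(f"reference taxon {reference_taxon!r} not in alignment")
    ref = a.sequence(reference_taxon)
    records = []
    gene_cols = {g: _gene_codon_columns(a, g) for g in a.genes()}
    for taxon in a.taxa:
        if taxon == reference_taxon:
            continue
        seq = a.sequence(taxon)
        for g, idx in gene_cols.items():
            ra = "".join(ref[i] for i in idx)
            rb = "".join(seq[i] for i in idx)
            records.append(ng86(ra, rb, table, g, reference_taxon, taxon))
        all_idx = np.concatenate(list(gene_cols.values()))
        records.append(ng86("".join(ref[i] for i in all_idx),
                            "".join(seq[i] for i in all_idx),
                            table, "ALL_PCG", reference_taxon, taxon))
    df = pd.DataFrame([vars(r) for r in records])
    clade_df = None
    if clade_map:
        rows = []
        for clade, members in clade_map.items():
            sub = df[(df["taxon_b"].isin(members)) & (df["gene"] == "ALL_PCG")]
            if len(sub):
                rows.append({"clade": clade, "n_taxa": len(sub),
                             "mean_Ka": sub["Ka"].mean(),
                             "mean_Ks": sub["Ks"].mean(),
                             "mean_omega": sub["omega"].mean()})
        clade_df = pd.DataFrame(rows)
    return df, clade_df


def gene_kaks(a: Alignment, table: int = 5, mode: str = "all_pairs",
              reference_taxon: str | None = None) -> pd.DataFrame:
    """Per-gene pooled Ka, Ks, Ka/Ks.

    ``mode='all_pairs'`` pools NG86 counts over every taxon pair;
    ``mode='reference'`` pools over pairs against ``reference_taxon`` only.
    Pooling sums Nd, Sd, N, S before the Jukes-Cantor correction.
    """
    if mode not in ("all_pairs", "reference"):
        raise AlignmentError(f"unknown mode {mode!r}")
    if mode == "reference" and reference_taxon not in a.taxa:
        raise AlignmentError("reference mode needs a reference_taxon in the alignment")
    pairs = ([(reference_taxon, t) for t in a.taxa if t != reference_taxon]
             if mode == "reference" else
             [(a.taxa[i], a.taxa[j]) for i in range(a.n_taxa)
              for j in range(i + 1, a.n_taxa)])
    rows = []
    for g in a.genes():
        idx = _gene_codon_columns(a, g)
        tot = dict(N=0.0, S=0.0, Nd=0.0, Sd=0.0, codons=0, skipped=0)
        seqs = {t: a.sequence(t) for t in a.taxa}
        for ta, tb in pairs:
            sa = "".join(seqs[ta][i] for i in idx)
            sb = "".join(seqs[tb][i] for i in idx)
            r = ng86(sa, sb, table, g, ta, tb)
            tot["N"] += r.N
            tot["S"] += r.S_sites
            tot["Nd"] += r.Nd
            tot["Sd"] += r.Sd
            tot["codons"] += r.codons
            tot["skipped"] += r.codons_skipped
        pn = tot["Nd"] / tot["N"] if tot["N"] > 0 else np.nan
        ps = tot["Sd"] / tot["S"] if tot["S"] > 0 else np.nan
        ka, ks = _jc(pn), _jc(ps)
        omega = ka / ks if np.isfinite(ks) and ks > 0 and np.isfinite(ka) else np.nan
        rows.append({"gene": g, "n_pairs": len(pairs), "pN": pn, "pS": ps,
                     "Ka": ka, "Ks": ks, "omega": omega,
                     "codons_skipped": tot["skipped"], "mode": mode})
    return pd.DataFrame(rows)


@dataclass
class CladeBranchSummary:
    clade: str
    n_taxa: int
    monophyletic: bool
    stem_length: float
    mean_terminal_length: float
    mean_mrca_to_tip: float


def clade_branch_summary(tree: dendropy.Tree,
                         clades: dict[str, set[str]]) -> pd.DataFrame:
    """Three branch-length summaries per clade.

    The notion "branch length of a clade" is ambiguous, so all three
    candidates are reported: the stem branch above the clade's MRCA (0 at
    the root), the mean terminal branch over members, and the mean
    MRCA-to-tip path length.  Non-monophyletic taxon sets are flagged but
    still summarised.
    """
    tree.is_rooted = True  # MRCA is taken relative to the seed node
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    rows = []
    for clade, members in clades.items():
        unknown = set(members) - set(leaves)
        if unknown:
            raise AlignmentError(f"clade {clade}: unknown taxa {sorted(unknown)}")
        members = sorted(members)
        mrca = (tree.mrca(taxon_labels=members) if len(members) > 1
                else leaves[members[0]])
        mono = ({lf.taxon.label for lf in mrca.leaf_iter()} == set(members)
                if len(members) > 1 else True)
        stem = mrca.edge.length if mrca.parent_node is not None else 0.0
        if stem is None:
            raise AlignmentError(f"clade {clade}: stem branch has no length")
        term = [leaves[t].edge.length for t in members]
        if any(b is None for b in term):
            raise AlignmentError(f"clade {clade}: terminal branch without length")
        depth = []
        for t in members:
            node, acc = leaves[t], 0.0
            while node is not mrca:
                acc += node.edge.length
                node = node.parent_node
            depth.append(acc)
        rows.append(CladeBranchSummary(clade, len(members), mono, float(stem),
                                       float(np.mean(term)), float(np.mean(depth))))
    return pd.DataFrame([vars(r) for r in rows])
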
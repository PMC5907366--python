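"""Compositional-heterogeneity diagnostics.

Three layers, matching how mito-phylogenomic datasets are usually vetted:

* per-taxon base/state counts and AT content;
* the R x C chi-squared homogeneity test on the taxon x state count table,
  runnable per gene, per codon position and on RY-recoded data (tail-area
  P < 0.05 read as compositionally heterogeneous);
* a per-taxon permutation Z-score: the L1 deviation of each taxon's state
  frequencies from the global frequencies, referenced against a null built
  by permuting characters within each alignment column across taxa.  The
  null keeps per-site composition fixed while destroying lineage-specific
  composition, so Z > 2 flags a lineage whose composition cannot be
  explained by site effects alone.  This is a desk-scale analogue of the
  posterior-predictive compositional check usually run in PhyloBayes under
  CAT+GTR, and outputs are labelled ``permutation_z`` so the two are never
  conflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seq_io import Alignment, AlignmentError, PartitionScheme, ry_recode


def composition_table(a: Alignment, mask: np.ndarray | None = None,
                      exclude_taxa: set[str] | None = None) -> pd.DataFrame:
    """Per-taxon counts and frequencies over non-missing characters.

    ``mask`` selects sites (boolean or index array); missing/ambiguous
    characters are excluded from counting.  For DNA an ``AT`` column gives
    (A+T)/(A+C+G+T).  Taxa with zero countable characters keep their row
    with NaN frequencies.
    """
    states = sorted(a.concrete_states())
    m = a.matrix if mask is None else a.matrix[:, np.asarray(mask)]
    keep = [i for i, t in enumerate(a.taxa) if t not in (exclude_taxa or set())]
    counts = {s: (m[keep] == s).sum(axis=1) for s in states}
    df = pd.DataFrame(counts, index=[a.taxa[i] for i in keep])
    total = df.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = df.div(total, axis=0)
    freq.columns = [f"f_{s}" for s in states]
    out = pd.concat([df, freq], axis=1)
    out["total"] = total
    if a.alphabet == "DNA":
        with np.errstate(invalid="ignore", divide="ignore"):
            out["AT"] = (df["A"] + df["T"]) / total
    out.index.name = "taxon"
    return out


@dataclass
class HomogeneityResult:
    scope: str
    gene: str
    codon_position: str
    statistic: float
    df: int
    p_value: float
    n_taxa: int
    n_states: int

    @property
    def heterogeneous(self) -> bool:
        return self.p_value < 0.05


def chi2_homogeneity(counts: pd.DataFrame, scope: str = "dataset",
                     gene: str = "all", codon_position: str = "all",
                     ) -> HomogeneityResult:
    """R x C contingency chi-squared on a taxon x state count table.

    State columns whose total is zero are dropped (df adjusted); taxon rows
    with zero total are dropped likewise.  No continuity correction.
    """
    state_cols = [c for c in counts.columns
                  if len(c) == 1 and counts[c].dtype.kind in "iu"]
    tab = counts[state_cols].to_numpy(dtype=float)
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    r, c = tab.shape
    if r < 2 or c < 2:
        raise AlignmentError("need >= 2 taxa and >= 2 states with nonzero totals")
    stat, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return HomogeneityResult(scope, gene, codon_position, float(stat), int(df),
                             float(p), r, c)


def chi2_by_gene_and_position(a: Alignment, parts: PartitionScheme | None = None,
                              exclude_taxa: set[str] | None = None,
                              ry_positions: set[int] | None = None,
                              ) -> pd.DataFrame:
    """Chi-squared homogeneity per (gene x {all,1,2,3}) plus dataset rows.

    ``ry_positions`` adds RY-recoded re-tests of the named codon positions
    (the PCGRY1 / PCGRY3 layout).  A Benjamini-Hochberg ``p_bh`` column is
    appended as an extra, clearly-labelled output; the ``heterogeneous``
    flag itself uses the uncorrected P < 0.05 rule.
    """
    results: list[HomogeneityResult] = []

    def _rows(aln: Alignment, scope: str) -> None:
        pos_values = ["all", 1, 2, 3] if (aln.codon_pos > 0).any() else ["all"]
        for pos in pos_values:
            pmask = (np.ones(aln.n_sites, bool) if pos == "all"
                     else aln.codon_pos == pos)
            for g in ["all"] + aln.genes():
                gmask = np.ones(aln.n_sites, bool) if g == "all" else aln.gene == g
                mask = pmask & gmask
                if not mask.any():
                    continue
                ct = composition_table(aln, mask, exclude_taxa)
                try:
                    results.append(chi2_homogeneity(ct, scope, g, str(pos)))
                except AlignmentError:
                    continue

    _rows(a, "nt")
    if ry_positions:
        recoded = ry_recode(a, ry_positions)
        for pos in sorted(ry_positions):
            pmask = recoded.codon_pos == pos
            for g in ["all"] + recoded.genes():
                gmask = (np.ones(recoded.n_sites, bool) if g == "all"
                         else recoded.gene == g)
                mask = pmask & gmask
                if not mask.any():
                    continue
                ct = composition_table(recoded, mask, exclude_taxa)
                try:
                    results.append(chi2_homogeneity(ct, f"RY{pos}", g, str(pos)))
                except AlignmentError:
                    continue

    df = pd.DataFrame([{
        "scope": r.scope, "gene": r.gene, "codon_position": r.codon_position,
        "statistic": r.statistic, "df": r.df, "p": r.p_value,
        "heterogeneous": r.heterogeneous,
    } for r in results])
    df["p_bh"] = _benjamini_hochberg(df["p"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


@dataclass
class TaxonHeterogeneityZ:
    table: pd.DataFrame          # taxon, d, null_mean, null_sd, Z, flag
    replicates: int
    seed: int
    method: str = "permutation_z"

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flag"]])


def taxon_z_scores(a: Alignment, replicates: int = 500, seed: int = 0,
                   exclude_taxa: set[str] | None = None) -> TaxonHeterogeneityZ:
    """Permutation Z-score for lineage-specific composition.

    d_t = sum over states |f_t,state - fbar_state| with fbar the global
    frequency vector; the null permutes characters within each column
    across taxa.  Z_t = (d_t - mean_null)/sd_null, with Z_t = 0 when the
    null sd is 0; Z > 2 flags the taxon as compositionally heterogeneous.
    """
    if replicates < 100:
        raise AlignmentError("need >= 100 replicates for a stable null")
    states = sorted(a.concrete_states())
    keep = [i for i, t in enumerate(a.taxa) if t not in (exclude_taxa or set())]
    taxa = [a.taxa[i] for i in keep]
    # integer codes, -1 = missing/ambiguous
    codes = np.full(a.matrix[keep].shape, -1, dtype=np.int8)
    for k, s in enumerate(states):
        codes[a.matrix[keep] == s] = k

    def _d(mat: np.ndarray) -> np.ndarray:
        cnt = np.stack([(mat == k).sum(axis=1) for k in range(len(states))], 1)
        tot = cnt.sum(axis=1, keepdims=True)
        gtot = cnt.sum(axis=0)
        gf = gtot / gtot.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            f = cnt / tot
        f = np.where(tot > 0, f, gf)  # empty taxon deviates by 0
        return np.abs(f - gf).sum(axis=1)

    d_obs = _d(codes)
    rng = np.random.default_rng(seed)
    null = np.empty((replicates, len(taxa)))
    for r in range(replicates):
        null[r] = _d(rng.permuted(codes, axis=0))
    mean, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (d_obs - mean) / sd
    z = np.where(sd > 0, z, 0.0)
    table = pd.DataFrame({
        "d": d_obs, "null_mean": mean, "null_sd": sd, "Z": z, "flag": z > 2,
    }, index=pd.Index(taxa, name="taxon"))
    return TaxonHeterogeneityZ(table, replicates, seed)
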
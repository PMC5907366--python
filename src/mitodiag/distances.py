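"""Pairwise distances and substitution-saturation regressions.

Transitions are A<->G and C<->T; any cross-class difference is a
transversion.  Pairs are compared only at sites where both taxa carry a
concrete base; ambiguity codes are skipped, never fractionally counted.
The K2P distance is undefined (NaN, excluded from fits and flagged in the
output) once the observed proportions leave the model's domain, which is
itself a saturation symptom.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .seq_io import Alignment, AlignmentError

_PURINE = ("A", "G")
_PYRIMIDINE = ("C", "T")


def pairwise_distances(a: Alignment, mask: np.ndarray | None = None,
                       ) -> pd.DataFrame:
    """Per-pair S, V, P, Q, p-distance and K2P distance.

    K2P: d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q); NaN when either log argument
    is <= 0.  Pairs with zero comparable sites get NaN distances.
    """
    if a.alphabet != "DNA":
        raise AlignmentError("pairwise distances require a DNA alignment")
    m = a.matrix if mask is None else a.matrix[:, np.asarray(mask)]
    is_pur = np.isin(m, _PURINE)
    is_pyr = np.isin(m, _PYRIMIDINE)
    concrete = is_pur | is_pyr
    rows = []
    for i in range(a.n_taxa):
        for j in range(i + 1, a.n_taxa):
            both = concrete[i] & concrete[j]
            n = int(both.sum())
            diff = both & (m[i] != m[j])
            # transition: both purine or both pyrimidine, yet different
            s = int((diff & ((is_pur[i] & is_pur[j]) |
                             (is_pyr[i] & is_pyr[j]))).sum())
            v = int(diff.sum()) - s
            if n == 0:
                p = q = pd_ = k2p = np.nan
            else:
                p, q = s / n, v / n
                pd_ = (s + v) / n
                w1, w2 = 1 - 2 * p - q, 1 - 2 * q
                k2p = (-0.5 * np.log(w1) - 0.25 * np.log(w2)
                       if w1 > 0 and w2 > 0 else np.nan)
            rows.append((a.taxa[i], a.taxa[j], n, s, v, p, q, pd_, k2p))
    return pd.DataFrame(rows, columns=[
        "taxon_a", "taxon_b", "sites_compared", "S", "V", "P", "Q",
        "p_dist", "k2p"])


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf x leaf path-length sums (square symmetric table)."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            head = edge.head_node
            name = (head.taxon.label if head.taxon else
                    f"internal node above {{{', '.join(l.taxon.label for l in head.leaf_iter())}}}")
            raise AlignmentError(f"missing branch length on edge to {name}")
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            d = pdm.patristic_distance(taxa[la], taxa[lb])
            out.loc[la, lb] = out.loc[lb, la] = d
    out.index.name = "taxon"
    return out


@dataclass
class SaturationFit:
    x_name: str
    y_name: str
    partition: str
    slope: float
    intercept: float
    r2: float
    n_pairs: int
    n_excluded: int


def saturation_fit(x, y, x_name: str = "x", y_name: str = "y",
                   partition: str = "all") -> SaturationFit:
    """OLS of y on x over pairs where both are defined.

    The slope is the saturation readout: the shallower the increase of the
    observed quantity with the reference distance, the more saturated the
    partition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n_excl = int((~ok).sum())
    if ok.sum() < 3:
        raise AlignmentError("need >= 3 defined (x, y) pairs for a fit")
    if np.ptp(x[ok]) == 0:
        raise AlignmentError("x values are constant; slope undefined")
    res = stats.linregress(x[ok], y[ok])
    return SaturationFit(x_name, y_name, partition, float(res.slope),
                         float(res.intercept), float(res.rvalue ** 2),
                         int(ok.sum()), n_excl)


def saturation_report(a: Alignment, tree: dendropy.Tree | None = None,
                      by_codon_position: bool = True) -> pd.DataFrame:
    """Per-partition saturation fits.

    Always fits S-vs-K2P and V-vs-K2P (the DAMBE-style plot); when a tree
    with branch lengths is supplied, adds observed-P-distance vs patristic
    distance (y = p_dist, x = patristic; orientation stated in the output
    columns, not implied).
    """
    part_masks: dict[str, np.ndarray | None] = {"all": None}
    if by_codon_position and (a.codon_pos > 0).any():
        for p in (1, 2, 3):
            part_masks[f"pos{p}"] = a.codon_pos == p
    patr = None
    if tree is not None:
        patr = patristic_distances(tree)
    fits = []
    for label, mask in part_masks.items():
        d = pairwise_distances(a, mask)
        for yvar in ("S", "V"):
            try:
                fits.append(saturation_fit(d["k2p"], d[yvar] / d["sites_compared"],
                                           "k2p", f"{yvar}_prop", label))
            except AlignmentError:
                continue
        if patr is not None:
            x = [patr.loc[ta, tb] for ta, tb in zip(d["taxon_a"], d["taxon_b"])]
            try:
                fits.append(saturation_fit(x, d["p_dist"],
                                           "patristic", "p_dist", label))
            except AlignmentError:
                continue
    return pd.DataFrame([vars(f) for f in fits])
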
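"""Workflow orchestration: the diagnostics bundle, the CI filter run, a
neighbor-joining recovery check, and a machine-readable run manifest.

Every run writes TSV tables with ``#``-prefixed header comments carrying
parameter provenance, plus a ``manifest.json`` recording input digests,
parameters, seeds and outputs, sufficient to replay the run and verify
byte-identical deterministic outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
import tempfile

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from . import composition as comp
from . import distances as dist
from . import parsimony as pars
from . import selection as sel
from .seq_io import (Alignment, AlignmentError, PartitionScheme,
                     read_alignment, read_partition, read_tree,
                     write_alignment)


def read_clade_map(path) -> dict[str, set[str]]:
    """Plain-text clade map: one ``name: taxon1,taxon2,...`` line per clade."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise AlignmentError(f"bad clade-map line {lineno}: {line!r}")
            name, members = line.split(":", 1)
            out[name.strip()] = {m.strip() for m in members.split(",") if m.strip()}
    return out


# -- neighbor joining ---------------------------------------------------

def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Neighbor joining on a complete symmetric distance table.

    Deterministic: ties in the Q criterion resolve lexicographically by the
    sorted label pair.  Negative branch-length estimates are clamped to 0.
    Undefined (NaN) entries are an error — they come from saturated pairs
    excluded upstream.
    """
    labels = sorted(distances.index)
    if list(distances.columns.sort_values()) != labels:
        raise AlignmentError("distance table must be square with matching labels")
    D = {a: {b: float(distances.loc[a, b]) for b in labels} for a in labels}
    for a in labels:
        for b in labels:
            if a != b and not np.isfinite(D[a][b]):
                raise AlignmentError(
                    f"undefined distance {a}-{b}; saturated pairs are excluded "
                    "by pairwise_distances and cannot enter NJ")
    if len(labels) < 3:
        raise AlignmentError("need >= 3 taxa for NJ")
    sub = {a: f"{a}" for a in labels}
    active = list(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * D[a][b] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        la = 0.5 * D[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = D[a][b] - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        u = f"__u{counter}"
        counter += 1
        D[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
            D[u][c] = D[c][u] = max(duc, 0.0)
        sub[u] = f"({sub[a]}:{la:.10g},{sub[b]}:{lb:.10g})"
        active = [c for c in active if c not in (a, b)] + [u]
    a, b, c = active
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    newick = (f"({sub[a]}:{max(la, 0):.10g},{sub[b]}:{max(lb, 0):.10g},"
              f"{sub[c]}:{max(lc, 0):.10g});")
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def k2p_matrix(a: Alignment, fallback_p_dist: bool = False) -> pd.DataFrame:
    """Square K2P distance table from pairwise_distances.

    ``fallback_p_dist`` substitutes the uncorrected p-distance for pairs
    whose K2P is undefined (outside the model domain), which keeps NJ
    runnable on heavily saturated data; the substitution count is noted by
    the caller's manifest.
    """
    pw = dist.pairwise_distances(a)
    labels = sorted(a.taxa)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for _, row in pw.iterrows():
        d = row["k2p"]
        if not np.isfinite(d) and fallback_p_dist:
            d = row["p_dist"]
        out.loc[row["taxon_a"], row["taxon_b"]] = d
        out.loc[row["taxon_b"], row["taxon_a"]] = d
    out.index.name = "taxon"
    return out


# -- manifest -----------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, stage: str, params: dict):
        self.data = {
            "tool": "mitodiag", "version": __version__, "stage": stage,
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "params": params, "inputs": {}, "outputs": {},
        }

    def add_input(self, name: str, path) -> None:
        self.data["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def add_output(self, name: str, path) -> None:
        self.data["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False,
                  float_format="%.10g", na_rep="NA")


# -- orchestrated runs --------------------------------------------------

def run_diagnostics(alignment_path, partition_path, out_dir,
                    tree_path=None, outgroup: set[str] | None = None,
                    reference_taxon: str | None = None,
                    clade_map_path=None, replicates: int = 500,
                    seed: int = 0, ry_positions: set[int] = frozenset({1, 3}),
                    ) -> dict:
    """Composition + chi-squared (+RY re-tests) + Z-scores + distances +
    saturation + Ka/Ks + clade branch lengths, with one manifest."""
    os.makedirs(out_dir, exist_ok=True)
    params = dict(outgroup=sorted(outgroup) if outgroup else None,
                  reference_taxon=reference_taxon, replicates=replicates,
                  seed=seed, ry_positions=sorted(ry_positions))
    man = Manifest("diagnostics", params)
    man.add_input("alignment", alignment_path)
    man.add_input("partition", partition_path)
    parts = read_partition(partition_path)
    a = read_alignment(alignment_path, parts)
    tree = None
    if tree_path is not None:
        man.add_input("tree", tree_path)
        tree = read_tree(tree_path)
    clade_map = None
    if clade_map_path is not None:
        man.add_input("clade_map", clade_map_path)
        clade_map = read_clade_map(clade_map_path)
    outputs: dict[str, str] = {}
    stage = "composition"
    try:
        ct = comp.composition_table(a, exclude_taxa=outgroup)
        p = os.path.join(out_dir, "composition.tsv")
        _write_tsv(ct.reset_index(), p, [f"mitodiag {__version__} composition",
                                         f"excluded outgroup: {params['outgroup']}"])
        outputs["composition"] = p

        stage = "chi2"
        chi = comp.chi2_by_gene_and_position(a, parts, exclude_taxa=outgroup,
                                             ry_positions=ry_positions)
        p = os.path.join(out_dir, "chi2.tsv")
        _write_tsv(chi, p, ["R x C chi-squared homogeneity; P < 0.05 = heterogeneous",
                            "p_bh = Benjamini-Hochberg adjusted (extra column)"])
        outputs["chi2"] = p

        stage = "taxon_z_scores"
        z = comp.taxon_z_scores(a, replicates=replicates, seed=seed,
                                exclude_taxa=outgroup)
        p = os.path.join(out_dir, "zscores.tsv")
        _write_tsv(z.table.reset_index(), p,
                   [f"method = {z.method} (within-column permutation null; "
                    "desk-scale analogue of a posterior-predictive check)",
                    f"replicates = {z.replicates}, seed = {z.seed}",
                    "flag: Z > 2 = compositionally heterogeneous"])
        outputs["zscores"] = p

        stage = "distances"
        pw = dist.pairwise_distances(a)
        p = os.path.join(out_dir, "distances.tsv")
        _write_tsv(pw, p, ["pairwise S/V counts, P, Q, p-distance, K2P"])
        outputs["distances"] = p

        stage = "saturation"
        sat = dist.saturation_report(a, tree)
        p = os.path.join(out_dir, "saturation.tsv")
        _write_tsv(sat, p, [
            "OLS saturation fits; shallower slope = more saturation",
            "orientation: y-variable regressed on x-variable as named",
            f"patristic reference tree: {tree_path if tree_path else 'none supplied'}"])
        outputs["saturation"] = p

        if reference_taxon is not None:
            stage = "kaks"
            rec, clade_kaks = sel.ka_vs_reference(a, reference_taxon,
                                                  clade_map=clade_map)
            p = os.path.join(out_dir, "kaks_reference.tsv")
            _write_tsv(rec, p, [f"NG86 vs reference {reference_taxon} "
                                "(Jukes-Cantor corrected)"])
            outputs["kaks_reference"] = p
            gk = sel.gene_kaks(a, mode="reference",
                               reference_taxon=reference_taxon)
            p = os.path.join(out_dir, "gene_kaks.tsv")
            _write_tsv(gk, p, ["per-gene pooled NG86 Ka/Ks"])
            outputs["gene_kaks"] = p
            if clade_kaks is not None:
                p = os.path.join(out_dir, "clade_kaks.tsv")
                _write_tsv(clade_kaks, p, ["clade mean Ka/Ks vs reference"])
                outputs["clade_kaks"] = p

        if tree is not None and clade_map:
            stage = "clade_branches"
            cb = sel.clade_branch_summary(tree, clade_map)
            p = os.path.join(out_dir, "clade_branches.tsv")
            _write_tsv(cb, p, ["three candidate clade branch-length summaries"])
            outputs["clade_branches"] = p
    except Exception as exc:
        raise RuntimeError(
            f"diagnostics stage {stage!r} failed: {exc}; partial outputs "
            f"kept in {out_dir}") from exc
    for name, p in outputs.items():
        man.add_output(name, p)
    mp = os.path.join(out_dir, "manifest.json")
    man.write(mp)
    outputs["manifest"] = mp
    return outputs


def run_filter(alignment_path, partition_path, tree_path, out_dir,
               ci_threshold: float = 0.3, outgroup: set[str] | None = None,
               clade_map_path=None, nj_check: bool = True) -> dict:
    """CI-threshold site filtering with removal summaries and an optional
    NJ clade-recovery check on the pre/post alignments."""
    os.makedirs(out_dir, exist_ok=True)
    params = dict(ci_threshold=ci_threshold,
                  outgroup=sorted(outgroup) if outgroup else None,
                  nj_check=nj_check)
    man = Manifest("ci_filter", params)
    for name, p in (("alignment", alignment_path), ("partition", partition_path),
                    ("tree", tree_path)):
        man.add_input(name, p)
    parts = read_partition(partition_path)
    a = read_alignment(alignment_path, parts)
    tree = read_tree(tree_path)
    clade_map = read_clade_map(clade_map_path) if clade_map_path else {}
    if clade_map_path:
        man.add_input("clade_map", clade_map_path)
    outputs: dict[str, str] = {}
    stage = "site_signals"
    try:
        cfg = pars.FilterConfig(tree=tree, ci_threshold=ci_threshold,
                                outgroup=outgroup)
        sig = pars.site_signals(a, cfg)
        p = os.path.join(out_dir, "site_signals.tsv")
        _write_tsv(sig, p, [f"per-site parsimony signal, CI threshold {ci_threshold}",
                            "invariant sites (s=0) keep CI=1 and are retained"])
        outputs["site_signals"] = p

        stage = "apply_filter"
        filtered, removed = pars.apply_filter(a, sig)
        p = os.path.join(out_dir, "filtered.fasta")
        write_alignment(filtered, p)
        outputs["filtered_alignment"] = p

        stage = "removal_summary"
        summ = pars.removal_summary(removed, a)
        p = os.path.join(out_dir, "removal_summary.tsv")
        _write_tsv(summ, p, ["full = all 3 codon positions removed; "
                             "any = >= 1 position removed"])
        outputs["removal_summary"] = p

        if nj_check and clade_map and outgroup:
            stage = "nj_check"
            rows = []
            for label, aln in (("unfiltered", a), ("filtered", filtered)):
                t = nj_tree(k2p_matrix(aln, fallback_p_dist=True))
                for clade, members in clade_map.items():
                    members = set(members) - set(outgroup)
                    rows.append({
                        "alignment": label, "clade": clade,
                        "monophyletic": pars.is_monophyletic(t, members,
                                                             outgroup)})
            p = os.path.join(out_dir, "monophyly.tsv")
            _write_tsv(pd.DataFrame(rows), p,
                       ["NJ (K2P, p-distance fallback for undefined pairs) "
                        "clade recovery before/after filtering"])
            outputs["monophyly"] = p
        elif nj_check and not clade_map:
            pass  # no clades declared: NJ check skipped
    except Exception as exc:
        raise RuntimeError(
            f"filter stage {stage!r} failed: {exc}; partial outputs kept in "
            f"{out_dir}") from exc
    for name, p in outputs.items():
        man.add_output(name, p)
    mp = os.path.join(out_dir, "manifest.json")
    man.write(mp)
    outputs["manifest"] = mp
    return outputs


def replay(manifest_path) -> bool:
    """Re-run the stage recorded in a manifest into a temp dir and verify
    every deterministic output is byte-identical."""
    with open(manifest_path) as fh:
        man = json.load(fh)
    params = man["params"]
    inputs = {k: v["path"] for k, v in man["inputs"].items()}
    with tempfile.TemporaryDirectory() as tmp:
        if man["stage"] == "diagnostics":
            run_diagnostics(
                inputs["alignment"], inputs["partition"], tmp,
                tree_path=inputs.get("tree"),
                outgroup=set(params["outgroup"]) if params["outgroup"] else None,
                reference_taxon=params["reference_taxon"],
                clade_map_path=inputs.get("clade_map"),
                replicates=params["replicates"], seed=params["seed"],
                ry_positions=set(params["ry_positions"]))
        elif man["stage"] == "ci_filter":
            run_filter(
                inputs["alignment"], inputs["partition"], inputs["tree"], tmp,
                ci_threshold=params["ci_threshold"],
                outgroup=set(params["outgroup"]) if params["outgroup"] else None,
                clade_map_path=inputs.get("clade_map"),
                nj_check=params["nj_check"])
        else:
            raise AlignmentError(f"unknown stage {man['stage']!r}")
        for name, rec in man["outputs"].items():
            new = os.path.join(tmp, os.path.basename(rec["path"]))
            if _sha256(new) != rec["sha256"]:
                return False
    return True
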
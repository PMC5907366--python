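"""Alignment, partition and tree I/O plus derived-dataset construction.

The in-memory :class:`Alignment` is a character matrix (taxa x sites) with
per-site gene / codon-position annotation.  Derived datasets mirror the
standard mito-phylogenomic workflow: codon-position subsets (PCG12-style),
RY recoding of selected positions (PCG13-RY-style), and amino-acid
translation under the invertebrate mitochondrial code.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

DNA_STATES = ("A", "C", "G", "T")
RY_STATES = ("R", "Y")
AA_STATES = tuple("ACDEFGHIKLMNPQRSTVWY")
#: gap and '?' are interchangeable "missing" everywhere downstream
MISSING = ("-", "?")

_CONCRETE = {"DNA": set(DNA_STATES), "RY": set(RY_STATES), "AA": set(AA_STATES)}


class AlignmentError(ValueError):
    """Raised for structurally inconsistent alignment input."""


@dataclass
class PartitionEntry:
    """One partition line. Coordinates are 0-based half-open internally.

    ``stride`` is 3 for RAxML ``a-b\\3`` codon lines (the entry then covers
    every third site and annotates codon position = ``frame``), else 1.
    """

    gene: str
    start: int
    end: int
    frame: int = 1
    stride: int = 1

    def sites(self) -> np.ndarray:
        return np.arange(self.start, self.end, self.stride)


@dataclass
class PartitionScheme:
    entries: list[PartitionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for e in self.entries:
            if e.start < 0 or e.end <= e.start:
                raise AlignmentError(f"bad range for {e.gene}: {e.start}-{e.end}")
            if e.stride == 1:
                for s, t in seen:
                    if e.start < t and s < e.end:
                        raise AlignmentError(f"overlapping partition range at {e.gene}")
                seen.append((e.start, e.end))
            if e.stride == 1 and (e.end - e.start) % 3 != 0:
                raise AlignmentError(
                    f"gene {e.gene} length {e.end - e.start} not divisible by 3"
                )

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def total_sites(self) -> int:
        return max(e.end for e in self.entries)

    def annotate(self, n_sites: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (gene, codon position) arrays; '' / 0 for unannotated."""
        gene = np.full(n_sites, "", dtype=object)
        cpos = np.zeros(n_sites, dtype=int)
        for e in self.entries:
            if e.end > n_sites:
                raise AlignmentError(
                    f"partition {e.gene} range {e.start + 1}-{e.end} exceeds "
                    f"alignment length {n_sites}"
                )
            idx = e.sites()
            gene[idx] = e.gene
            if e.stride == 1:
                cpos[idx] = ((np.arange(len(idx)) + e.frame - 1) % 3) + 1
            else:
                cpos[idx] = e.frame
        return gene, cpos


_PART_RE = re.compile(
    r"^\s*(?:DNA|AA|[A-Z]+)\s*,\s*(?P<name>\S+)\s*=\s*"
    r"(?P<start>\d+)\s*-\s*(?P<end>\d+)\s*(?:\\(?P<stride>\d))?\s*$"
)


def read_partition(path_or_text) -> PartitionScheme:
    """Parse RAxML-style partition lines ("DNA, ND2 = 1-1023[\\3]").

    File coordinates are 1-based inclusive and converted here.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        text = open(path_or_text).read() if "\n" not in str(path_or_text) and "=" not in str(path_or_text) else str(path_or_text)
    entries = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _PART_RE.match(line)
        if m is None:
            raise AlignmentError(f"unparseable partition line {lineno}: {line!r}")
        stride = int(m["stride"]) if m["stride"] else 1
        start1, end1 = int(m["start"]), int(m["end"])
        frame = 1
        if stride == 3:
            # codon line: the offset within the frame is the codon position
            frame = ((start1 - 1) % 3) + 1
        entries.append(
            PartitionEntry(m["name"], start1 - 1, end1, frame=frame, stride=stride)
        )
    if not entries:
        raise AlignmentError("empty partition definition")
    return PartitionScheme(entries)


def write_partition(parts: PartitionScheme, path) -> None:
    with open(path, "w") as fh:
        for e in parts.entries:
            tail = f"\\{e.stride}" if e.stride != 1 else ""
            fh.write(f"DNA, {e.gene} = {e.start + 1}-{e.end}{tail}\n")


@dataclass
class Alignment:
    """Taxa x sites character matrix with per-site annotation.

    ``matrix`` is a numpy '<U1' array; ``gene``/``codon_pos`` have one entry
    per site (codon position 0 = unannotated).  ``alphabet`` is one of
    ``DNA``, ``RY``, ``AA``.
    """

    taxa: list[str]
    matrix: np.ndarray
    alphabet: str = "DNA"
    gene: np.ndarray | None = None
    codon_pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise AlignmentError("matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dup}")
        n = self.matrix.shape[1]
        if self.gene is None:
            self.gene = np.full(n, "", dtype=object)
        if self.codon_pos is None:
            self.codon_pos = np.zeros(n, dtype=int)
        self.gene = np.asarray(self.gene, dtype=object)
        self.codon_pos = np.asarray(self.codon_pos, dtype=int)
        if len(self.gene) != n or len(self.codon_pos) != n:
            raise AlignmentError("annotation length does not match site count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    def concrete_states(self) -> set[str]:
        return _CONCRETE[self.alphabet]

    def is_missing(self) -> np.ndarray:
        """Boolean mask of non-concrete (missing or ambiguous) characters."""
        conc = self.concrete_states()
        return ~np.isin(self.matrix, sorted(conc))

    def take_sites(self, idx) -> "Alignment":
        idx = np.asarray(idx)
        return Alignment(
            list(self.taxa),
            self.matrix[:, idx],
            self.alphabet,
            self.gene[idx],
            self.codon_pos[idx],
        )

    def genes(self) -> list[str]:
        out, seen = [], set()
        for g in self.gene:
            if g and g not in seen:
                seen.add(g)
                out.append(g)
        return out


def read_alignment(path, partition: PartitionScheme | None = None,
                   alphabet: str = "DNA") -> Alignment:
    """Read a FASTA alignment, uppercase it, map U->T, annotate by partition."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    taxa, rows = [], []
    length = None
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"ragged alignment: taxon {rec.id!r} has length {len(seq)}, "
                f"expected {length}"
            )
        taxa.append(rec.id)
        rows.append(list(seq))
    matrix = np.array(rows, dtype="<U1")
    gene = cpos = None
    if partition is not None:
        gene, cpos = partition.annotate(length)
    return Alignment(taxa, matrix, alphabet, gene, cpos)


def write_alignment(a: Alignment, path) -> None:
    fh = path if hasattr(path, "write") else open(path, "w")
    try:
        for i, t in enumerate(a.taxa):
            fh.write(f">{t}\n{''.join(a.matrix[i])}\n")
    finally:
        if fh is not path:
            fh.close()


def subset_by_codon_position(a: Alignment, keep: set[int]) -> Alignment:
    """Keep sites whose codon position is in ``keep`` (order preserved)."""
    if a.alphabet != "DNA":
        raise AlignmentError("codon-position subsetting requires a DNA alignment")
    if not keep:
        raise AlignmentError("empty codon-position set")
    if not set(keep) <= {1, 2, 3}:
        raise AlignmentError(f"codon positions must be in {{1,2,3}}: {sorted(keep)}")
    if (a.codon_pos == 0).any():
        raise AlignmentError("alignment has unannotated sites")
    return a.take_sites(np.isin(a.codon_pos, sorted(keep)))


#: RY recoding map; cross-class ambiguity collapses to missing
_RY_MAP = {"A": "R", "G": "R", "R": "R", "C": "Y", "T": "Y", "Y": "Y",
           "-": "-", "?": "?"}


def ry_recode(a: Alignment, positions: set[int] | None = None) -> Alignment:
    """Recode purines to R and pyrimidines to Y at the given codon positions.

    Ambiguity codes spanning both classes (N, S, W, K, M, ...) become '?'
    because RY coding cannot resolve them; sites at other codon positions
    pass through unchanged.  ``positions=None`` recodes every site.
    """
    if a.alphabet == "AA":
        raise AlignmentError("cannot RY-recode an amino-acid alignment")
    m = a.matrix.copy()
    if positions is None:
        site_mask = np.ones(a.n_sites, dtype=bool)
    else:
        site_mask = np.isin(a.codon_pos, sorted(positions))
    sub = m[:, site_mask]
    out = np.full(sub.shape, "?", dtype="<U1")
    for src, dst in _RY_MAP.items():
        out[sub == src] = dst
    m[:, site_mask] = out
    return Alignment(list(a.taxa), m, "RY", a.gene.copy(), a.codon_pos.copy())


def translate(a: Alignment, table: int = 5) -> Alignment:
    """Translate per gene under an NCBI genetic code (default 5, invertebrate
    mitochondrial).  Codons containing missing/ambiguous characters become
    'X'; internal stops warn and translate to '*'.  Annotations collapse to
    (gene, position 0).
    """
    if a.alphabet != "DNA":
        raise AlignmentError("translation requires a DNA alignment")
    code = CodonTable.unambiguous_dna_by_id[table]
    fwd = dict(code.forward_table)
    for stop in code.stop_codons:
        fwd[stop] = "*"
    cols, genes = [], []
    for g in a.genes():
        idx = np.where(a.gene == g)[0]
        if len(idx) % 3:
            raise AlignmentError(f"gene {g} length {len(idx)} not divisible by 3")
        for c0 in range(0, len(idx), 3):
            tri = a.matrix[:, idx[c0:c0 + 3]]
            col = np.empty(a.n_taxa, dtype="<U1")
            for i in range(a.n_taxa):
                codon = "".join(tri[i])
                if any(ch not in "ACGT" for ch in codon):
                    col[i] = "X"
                else:
                    aa = fwd[codon]
                    if aa == "*":
                        warnings.warn(
                            f"internal stop codon {codon} in gene {g}, taxon "
                            f"{a.taxa[i]}, codon {c0 // 3 + 1}"
                        )
                    col[i] = aa
            cols.append(col)
            genes.append(g)
    matrix = np.stack(cols, axis=1)
    return Alignment(list(a.taxa), matrix, "AA",
                     np.array(genes, dtype=object), np.zeros(len(genes), int))


# -- trees --------------------------------------------------------------

def read_tree(path_or_str) -> dendropy.Tree:
    """Read a Newick tree (labels preserved verbatim, no underscore munging)."""
    kwargs = dict(schema="newick", preserve_underscores=True)
    try:
        if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
            return dendropy.Tree.get(data=path_or_str, **kwargs)
        return dendropy.Tree.get(path=str(path_or_str), **kwargs)
    except Exception as exc:  # dendropy raises several parse error types
        raise AlignmentError(f"Newick parse error: {exc}") from exc


def write_tree(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def prune_to_taxa(tree: dendropy.Tree, taxa) -> dendropy.Tree:
    """Copy of ``tree`` retaining only the listed leaves (never invents any)."""
    taxa = set(taxa)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = taxa - leaf_labels
    if missing:
        raise AlignmentError(f"taxa absent from tree: {sorted(missing)}")
    t = tree.clone(depth=1)
    t.retain_taxa_with_labels(sorted(taxa))
    return t
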
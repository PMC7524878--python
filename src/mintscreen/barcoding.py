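"""Accession authentication from plastid barcode sequences.

The authentication workflow mirrors standard plant-barcoding practice for the
*psbA-trnH* intergenic spacer: merge the forward and reverse Sanger reads,
trim the merged sequence to the region between the amplification primers,
compute pairwise distances on the (pre-aligned) barcodes, build a
neighbor-joining tree with bootstrap support, root it on an outgroup, and
flag accessions whose declared species conflicts with the species of the
well-supported clade they fall in.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = "ACGT"
ALPHABET = set("ACGTN-")
_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

#: primer pair amplifying the psbA-trnH intergenic spacer (Sang/Tate universal
#: primers, the standard pair for this marker)
PSBA_PRIMER = "GTTATGCATGAACGTAATGCTC"
TRNH_PRIMER = "CGCGCATGGTGGATTCACAATCC"

#: weakest bootstrap support still considered interpretable for flagging
DEFAULT_MIN_SUPPORT = 65.0


class MergeError(ValueError):
    """Raised when paired reads share no acceptable overlap."""


class TrimError(ValueError):
    """Raised when a primer cannot be located; carries the primer role."""

    def __init__(self, primer_role: str, max_mismatch: int):
        self.primer_role = primer_role
        super().__init__(
            f"{primer_role} primer not found within {max_mismatch} mismatches"
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# sequence containers
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A barcode sequence with its accession id and declared taxon."""

    id: str
    residues: str
    declared_taxon: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Equal-length sequence records (a pre-computed multiple alignment)."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal record lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def columns(self) -> np.ndarray:
        """Residues as a (n_records, length) character array."""
        return np.array([list(r.residues) for r in self.records])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        idx = rng.integers(0, self.length, size=self.length)
        chars = self.columns()[:, idx]
        return Alignment(
            [
                SequenceRecord(r.id, "".join(row), r.declared_taxon)
                for r, row in zip(self.records, chars)
            ]
        )


def read_fasta_alignment(path, labels: dict[str, str] | None = None) -> Alignment:
    """Load an aligned FASTA; optional accession -> declared-taxon labels."""
    from Bio import SeqIO

    labels = labels or {}
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper(), labels.get(rec.id, ""))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return Alignment(records)


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


# ---------------------------------------------------------------------------
# read merging and primer trimming
# ---------------------------------------------------------------------------

def merge_reads(
    forward: SequenceRecord,
    reverse: SequenceRecord,
    min_overlap: int = 20,
    min_identity: float = 0.8,
) -> SequenceRecord:
    """Merge a forward read with the reverse-complemented reverse read.

    All relative offsets of the two reads are scanned; the offset maximizing
    the number of matching overlap positions wins (ties: longer overlap, then
    smaller offset). The merge fails unless the best overlap spans at least
    ``min_overlap`` positions of which at least ``min_identity`` agree —
    without the identity floor any two unrelated reads would "merge" into a
    run of ``N``. Disagreeing overlap positions become ``N``; positions
    covered by only one read are taken from that read.
    """
    f = forward.residues
    r = reverse_complement(reverse.residues)
    nf, nr = len(f), len(r)

    best = None  # (matches, overlap_len, -offset)
    best_offset = None
    for offset in range(-(nr - 1), nf):
        lo = max(0, offset)
        hi = min(nf, offset + nr)
        if hi - lo <= 0:
            continue
        overlap = hi - lo
        matches = sum(1 for i in range(lo, hi) if f[i] == r[i - offset])
        key = (matches, overlap, -offset)
        if best is None or key > best:
            best = key
            best_offset = offset

    if best is None or best[1] < min_overlap:
        raise MergeError(
            f"best overlap ({0 if best is None else best[1]} nt) shorter than "
            f"min_overlap={min_overlap}"
        )
    if best[0] < min_identity * best[1]:
        raise MergeError(
            f"best overlap identity {best[0]}/{best[1]} below {min_identity:.0%}"
        )

    offset = best_offset
    start = min(0, offset)
    end = max(nf, offset + nr)
    out = []
    for pos in range(start, end):
        in_f = 0 <= pos < nf
        in_r = 0 <= pos - offset < nr
        if in_f and in_r:
            bf, br = f[pos], r[pos - offset]
            out.append(bf if bf == br else "N")
        elif in_f:
            out.append(f[pos])
        else:
            out.append(r[pos - offset])
    return SequenceRecord(forward.id, "".join(out), forward.declared_taxon)


def _best_primer_hit(seq: str, primer: str, max_mismatch: int) -> int | None:
    """Leftmost minimal-mismatch occurrence start, or None if over budget."""
    k = len(primer)
    best_pos, best_mm = None, None
    for pos in range(len(seq) - k + 1):
        mm = sum(1 for a, b in zip(seq[pos : pos + k], primer) if a != b)
        if best_mm is None or mm < best_mm:
            best_pos, best_mm = pos, mm
            if mm == 0:
                break
    if best_mm is None or best_mm > max_mismatch:
        return None
    return best_pos


def trim_to_primers(
    seq: SequenceRecord,
    fwd_primer: str = PSBA_PRIMER,
    rev_primer: str = TRNH_PRIMER,
    max_mismatch: int = 1,
) -> SequenceRecord:
    """Trim to the insert strictly between the primer annealing sites.

    Keeps the region from the first nucleotide downstream of the forward
    primer to the nucleotide preceding the (reverse-complemented) reverse
    primer. Coordinates are 0-based half-open internally.
    """
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    s = seq.residues
    fpos = _best_primer_hit(s, fwd_primer, max_mismatch)
    if fpos is None:
        raise TrimError("forward", max_mismatch)
    insert_start = fpos + len(fwd_primer)
    rc = reverse_complement(rev_primer)
    rpos = _best_primer_hit(s[insert_start:], rc, max_mismatch)
    if rpos is None:
        raise TrimError("reverse", max_mismatch)
    insert_end = insert_start + rpos
    if insert_end <= insert_start:
        raise TrimError("reverse", max_mismatch)
    return SequenceRecord(seq.id, s[insert_start:insert_end], seq.declared_taxon)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(v < 0):
            raise ValueError("negative distances")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def pairwise_distance(
    aln: Alignment, model: str = "p-distance"
) -> DistanceMatrix:
    """Pairwise distances under p-distance or Kimura 2-parameter.

    Sites with a gap or ``N`` in either sequence are excluded pair by pair
    (pairwise deletion).
    """
    if model not in ("p-distance", "K2P"):
        raise ValueError(f"unknown model {model!r}")
    n = len(aln.records)
    chars = aln.columns()
    valid = np.isin(chars, list(NUCLEOTIDES))
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = valid[i] & valid[j]
        m = int(ok.sum())
        if m == 0:
            raise ValueError(
                f"no comparable sites between {aln.records[i].id!r} "
                f"and {aln.records[j].id!r}"
            )
        a, b = chars[i][ok], chars[j][ok]
        if model == "p-distance":
            dij = float(np.mean(a != b))
        else:
            diff = a != b
            ts = sum(
                1 for x, y in zip(a[diff], b[diff])
                if frozenset((x, y)) in _TRANSITIONS
            )
            p = ts / m
            q = (int(diff.sum()) - ts) / m
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            if w1 <= 0 or w2 <= 0:
                raise ValueError(
                    f"K2P distance undefined (too divergent) for pair "
                    f"{aln.records[i].id!r}, {aln.records[j].id!r}"
                )
            dij = -0.5 * math.log(w1) - 0.25 * math.log(w2)
        d[i, j] = d[j, i] = dij
    return DistanceMatrix(aln.ids, d)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str = ""
    branch_length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]


class PhyloTree:
    """A (possibly unrooted) phylogeny with branch lengths and supports.

    Internally stored as a rooted node structure; an "unrooted" NJ tree is a
    structure whose root has three children. Bipartitions are reported in
    unrooted, canonical form so topologies can be compared regardless of the
    rooting.
    """

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = root.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels")

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    # -- topology ----------------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each canonicalized to the side
        not containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 2 <= len(below) <= len(all_leaves) - 2:
                side = below if ref not in below else all_leaves - below
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(side)
            return below

        walk(self.root)
        return out

    def clades(self) -> list[tuple[TreeNode, frozenset[str]]]:
        """(node, leafset) for every internal node of the rooted structure."""
        out = []

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            out.append((node, below))
            return below

        walk(self.root)
        return out

    # -- support annotation ------------------------------------------------

    def annotate_support(self, support: dict[frozenset[str], float]) -> None:
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        for node, below in self.clades():
            if node is self.root:
                continue
            side = below if ref not in below else all_leaves - below
            if side in support:
                node.support = support[side]

    # -- rooting -----------------------------------------------------------

    def root_on_outgroup(self, outgroup: str) -> "PhyloTree":
        """Return a copy rooted on the pendant branch of ``outgroup``."""
        if outgroup not in self.leaf_names:
            raise ValueError(f"outgroup {outgroup!r} not among leaves")

        def copy(node: TreeNode) -> TreeNode:
            return TreeNode(
                node.name,
                node.branch_length,
                node.support,
                [copy(c) for c in node.children],
            )

        # re-hang the tree from the outgroup leaf's edge
        parent_of: dict[int, tuple[TreeNode, TreeNode]] = {}
        root = copy(self.root)

        def index(node: TreeNode) -> None:
            for c in node.children:
                parent_of[id(c)] = (node, c)
                index(c)

        index(root)
        og = next(lf for lf in root.leaves() if lf.name == outgroup)

        def detach_upward(node: TreeNode) -> TreeNode:
            """Rebuild the tree hanging below `node` when its parent edge is
            reversed; returns the reversed-parent subtree."""
            if id(node) not in parent_of:
                return None  # was the old root
            parent, _ = parent_of[id(node)]
            parent.children = [c for c in parent.children if c is not node]
            up = detach_upward(parent)
            if up is not None:
                up.branch_length = parent.branch_length
                up.support = parent.support
                parent.children.append(up)
            if parent is root and len(parent.children) == 1:
                # suppress the degree-2 old root
                only = parent.children[0]
                only.branch_length += parent.branch_length if up is None else 0.0
                return only
            return parent

        half = og.branch_length / 2.0
        rest = detach_upward(og)
        og.branch_length = half
        # the outgroup pendant edge is split in two; its support is trivial
        rest.branch_length = half
        rest.support = None
        new_root = TreeNode("", 0.0, None, [og, rest])
        return PhyloTree(new_root, rooted=True)

    # -- serialization -----------------------------------------------------

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.branch_length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.branch_length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a Newick string (supports as internal node labels)."""
        pos = 0
        text = text.strip()

        def parse_node() -> TreeNode:
            nonlocal pos
            node = TreeNode()
            if text[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse_node())
                    if text[pos] == ",":
                        pos += 1
                    else:
                        break
                assert text[pos] == ")", f"expected ')' at {pos}"
                pos += 1
            # label
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            label = text[start:pos]
            if label:
                if node.is_leaf:
                    node.name = label
                else:
                    try:
                        node.support = float(label)
                    except ValueError:
                        node.name = label
            if pos < len(text) and text[pos] == ":":
                pos += 1
                start = pos
                while pos < len(text) and text[pos] not in ",();":
                    pos += 1
                node.branch_length = float(text[start:pos])
            return node

        root = parse_node()
        return cls(root, rooted=len(root.children) == 2)

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""

        def find(node: TreeNode, target: str, acc: list) -> list | None:
            if node.is_leaf:
                return list(acc) if node.name == target else None
            for c in node.children:
                acc.append(c)
                hit = find(c, target, acc)
                acc.pop()
                if hit is not None:
                    return hit
            return None

        pa = find(self.root, a, [])
        pb = find(self.root, b, [])
        if pa is None or pb is None:
            raise ValueError("leaf not found")
        k = 0
        while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
            k += 1
        return sum(n.branch_length for n in pa[k:]) + sum(
            n.branch_length for n in pb[k:]
        )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q-criterion is joined at every step; among ties
    the lexicographically smallest label pair wins. Negative branch-length
    estimates are clamped to zero with the excess transferred to the sister
    branch, so all reported branch lengths are non-negative.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: dict[str, TreeNode] = {lab: TreeNode(lab) for lab in dm.labels}
    # cluster sort key: smallest original label inside, for tie-breaking
    keys: dict[str, str] = {lab: lab for lab in dm.labels}
    d: dict[frozenset[str], float] = {}
    active = list(dm.labels)
    for i, j in itertools.combinations(range(n), 2):
        d[frozenset((dm.labels[i], dm.labels[j]))] = dm.values[i, j]

    counter = itertools.count()
    while len(active) > 2:
        m = len(active)
        r = {
            a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active
        }
        best_pair, best_q = None, None
        for a, b in itertools.combinations(sorted(active, key=keys.get), 2):
            q = (m - 2) * d[frozenset((a, b))] - r[a] - r[b]
            if best_q is None or q < best_q - 1e-12:
                best_q, best_pair = q, (a, b)
        a, b = best_pair
        dab = d[frozenset((a, b))]
        va = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        vb = dab - va
        # clamp negatives, moving the excess to the sister branch
        if va < 0:
            vb += va
            va = 0.0
        if vb < 0:
            va += vb
            vb = 0.0
        nodes[a].branch_length = va
        nodes[b].branch_length = vb
        new = TreeNode(children=[nodes[a], nodes[b]])
        new_label = f"__internal_{next(counter)}"
        nodes[new_label] = new
        keys[new_label] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_label, c))] = 0.5 * (
                d[frozenset((a, c))] + d[frozenset((b, c))] - dab
            )
        active = [c for c in active if c not in (a, b)] + [new_label]

    a, b = sorted(active, key=keys.get)
    dab = d[frozenset((a, b))]
    # final edge: hang one cluster off the other with the remaining distance
    na, nb = nodes[a], nodes[b]
    if na.is_leaf and nb.is_leaf:
        na.branch_length = dab / 2.0
        nb.branch_length = dab / 2.0
        root = TreeNode(children=[na, nb])
    elif nb.is_leaf:
        nb.branch_length = max(dab, 0.0)
        na.children.append(nb)
        root = na
    else:
        na.branch_length = max(dab, 0.0)
        nb.children.append(na)
        root = nb
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: Alignment,
    n_reps: int = 1000,
    rng_seed: int = 0,
    model: str = "p-distance",
    outgroup: str | None = None,
) -> PhyloTree:
    """NJ tree from the full alignment with column-bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of a bipartition is 100 x its frequency among replicate NJ trees.
    If ``outgroup`` is given the returned tree is rooted on its branch.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if outgroup is not None and outgroup not in aln.ids:
        raise ValueError(f"outgroup {outgroup!r} not in alignment")

    tree = neighbor_joining(pairwise_distance(aln, model))
    rng = np.random.default_rng(rng_seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        rep_tree = neighbor_joining(pairwise_distance(rep, model))
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    tree.annotate_support(support)
    tree.support_table = {bp: support.get(bp, 0.0) for bp in tree.bipartitions()}
    if outgroup is not None:
        rooted = tree.root_on_outgroup(outgroup)
        rooted.support_table = tree.support_table
        return rooted
    return tree


# ---------------------------------------------------------------------------
# mislabel flagging
# ---------------------------------------------------------------------------

@dataclass
class MislabelReport:
    accession: str
    declared: str
    status: str  # "ok" | "flagged" | "unresolved" | "untestable"
    inferred: str | None = None
    clade_support: float | None = None


def flag_mislabels(
    tree: PhyloTree,
    declared: dict[str, str],
    min_support: float = DEFAULT_MIN_SUPPORT,
    outgroup: str | None = None,
) -> list[MislabelReport]:
    """Flag accessions whose declared species conflicts with tree placement.

    Each species is first assigned a *reference clade*: among clades with
    bootstrap support >= ``min_support`` in which the species' declared
    members form a strict majority, the one containing most of them —
    largest clade on ties, so a planted foreigner sitting inside the clade
    stays inside the reference rather than shrinking it. A species whose
    declared members never dominate any supported clade (the
    intermixed-clade case) has no reference and its accessions are reported
    "unresolved". An accession is then

    - "ok" when it sits inside its declared species' reference clade,
    - "flagged" when it sits outside it but inside another species'
      reference clade (that species is reported as the inferred identity),
    - "untestable" when its declared species has no second accession to
      anchor a reference, yet the accession sits in another species' clade,
    - "unresolved" otherwise.

    Using reference clades rather than a per-leaf neighbor vote keeps a
    planted mislabel from corrupting the reference of the clade it landed
    in, which would otherwise flag its innocent nearest neighbor too.
    """
    leaves = set(tree.leaf_names)
    missing = leaves - set(declared)
    if missing:
        raise ValueError(f"no declared species for: {sorted(missing)}")
    if len(set(declared[l] for l in leaves)) < 2:
        raise ValueError("need at least 2 species to test labels")

    ingroup = [l for l in leaves if l != outgroup]
    species_counts: dict[str, int] = {}
    for leaf in ingroup:
        species_counts[declared[leaf]] = species_counts.get(declared[leaf], 0) + 1

    supported = [
        (node, frozenset(m for m in members if m != outgroup))
        for node, members in tree.clades()
        if node is not tree.root
        and (node.support if node.support is not None else 0.0) >= min_support
    ]

    reference: dict[str, tuple[frozenset[str], float]] = {}
    for sp in species_counts:
        best = None
        for node, members in supported:
            own = sum(1 for m in members if declared[m] == sp)
            foreign = len(members) - own
            if own <= foreign:
                continue
            key = (-own, -len(members))
            if best is None or key < best[0]:
                supp = node.support if node.support is not None else 0.0
                best = (key, members, supp)
        if best is not None:
            reference[sp] = (best[1], best[2])

    reports = []
    for leaf in sorted(ingroup):
        sp = declared[leaf]
        ref = reference.get(sp)
        if ref is not None and leaf in ref[0]:
            reports.append(MislabelReport(leaf, sp, "ok", sp, ref[1]))
            continue
        # smallest foreign reference clade containing this accession
        homes = sorted(
            (
                (len(members), other, members, supp)
                for other, (members, supp) in reference.items()
                if other != sp and leaf in members
            ),
        )
        if homes:
            _, other, _members, supp = homes[0]
            status = "untestable" if species_counts.get(sp, 0) <= 1 else "flagged"
            reports.append(MislabelReport(leaf, sp, status, other, supp))
        else:
            reports.append(MislabelReport(leaf, sp, "unresolved"))
    return reports
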
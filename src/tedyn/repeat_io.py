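"""Readers and writers for the formats the pipeline touches.

RepeatMasker ``.out``-dialect hit tables, FASTA libraries and copy sets,
dated Newick trees, genome-size tables and tab-separated result tables.
Coordinates are 1-based inclusive throughout, matching RepeatMasker
convention, so a hit's length is ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "RepeatHit",
    "TEFamily",
    "DatedTree",
    "Branch",
    "parse_rm_out",
    "write_rm_out",
    "read_fasta",
    "write_fasta",
    "read_tree",
    "read_genome_table",
    "write_genome_table",
    "hits_to_frame",
    "write_hits_tsv",
    "read_hits_tsv",
]

#: Recognized repeat classes.  RepeatMasker class/family strings are mapped
#: onto these by the prefix before "/"; Helitrons are rolling-circle (RC)
#: transposons and Penelope elements are treated as LINEs.
CLASS_LABELS = ("SINE", "LINE", "LTR", "DNA", "RC", "Unknown")

_CLASS_ALIASES = {
    "SINE": "SINE",
    "LINE": "LINE",
    "LTR": "LTR",
    "DNA": "DNA",
    "RC": "RC",
    "HELITRON": "RC",
    "PENELOPE": "LINE",
}


def parse_class_label(class_family: str) -> str:
    """Map a RepeatMasker class/family string to a canonical class label.

    The prefix before "/" is matched case-insensitively against the known
    classes; anything unrecognized becomes ``Unknown`` (and is excluded
    from class-level summaries downstream).
    """
    prefix = class_family.split("/", 1)[0].strip().rstrip("?").upper()
    return _CLASS_ALIASES.get(prefix, "Unknown")


@dataclass(frozen=True)
class RepeatHit:
    """One annotated TE insertion in one genome.

    ``divergence`` is the substitution distance to the family consensus as
    a fraction (RepeatMasker prints a percentage; the parser divides by
    100).  ``strand`` is ``+`` or ``-`` (the RepeatMasker ``C`` code is
    normalized to ``-``).
    """

    species_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    family_name: str
    class_label: str
    divergence: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid coordinates {self.start}-{self.end} (need end >= start >= 1)"
            )
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError(f"divergence {self.divergence} outside [0, 1]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TEFamily:
    """A named repeat consensus with class and superfamily labels."""

    name: str
    class_label: str
    superfamily: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"family {self.name}: empty consensus")
        bad = set(self.consensus.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"family {self.name}: invalid consensus characters {bad}")


@dataclass(frozen=True)
class Branch:
    """One edge of a dated tree, identified by the clade below it.

    ``branch_id`` is the tip label for terminal branches and the sorted
    "+"-joined tip labels for internal ones.  ``duration_myr`` is parent
    node age minus child node age; the root branch has no parent and is
    not represented.
    """

    branch_id: str
    tips: frozenset
    parent_age: float
    child_age: float

    @property
    def duration_myr(self) -> float:
        return self.parent_age - self.child_age

    @property
    def is_terminal(self) -> bool:
        return len(self.tips) == 1


def _branch_id(tips: Iterable[str]) -> str:
    tips = sorted(tips)
    return tips[0] if len(tips) == 1 else "+".join(tips)


class DatedTree:
    """A rooted, bifurcating, ultrametric species tree with node ages in Myr.

    Node ages are computed from branch lengths by subtraction from the
    root age (the maximum root-to-tip path length); tips sit at age 0.
    Ultrametricity is enforced within ``tolerance`` Myr.
    """

    def __init__(self, tree: dendropy.Tree, tolerance: float = 1e-6,
                 clades: Mapping[str, Iterable[str]] | None = None):
        self._tree = tree
        self.tolerance = tolerance
        leaves = tree.leaf_node_iter()
        self.tip_labels: list[str] = []
        for leaf in leaves:
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("tree has unlabeled tips")
            self.tip_labels.append(leaf.taxon.label)
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("duplicate tip labels")
        self.tip_labels.sort()

        depths: dict = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                bl = node.edge.length
                if bl is None:
                    raise ValueError("tree has a branch without a length")
                depths[node] = depths[node.parent_node] + bl
        tip_depths = [depths[n] for n in tree.leaf_node_iter()]
        root_age = max(tip_depths)
        if max(tip_depths) - min(tip_depths) > tolerance:
            raise ValueError(
                f"tree is not ultrametric: tip depths span "
                f"[{min(tip_depths):.6g}, {max(tip_depths):.6g}] Myr"
            )
        self._age: dict = {}
        self._tips_below: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._age[node] = 0.0
                self._tips_below[node] = frozenset([node.taxon.label])
            else:
                self._age[node] = root_age - depths[node]
                kids = node.child_nodes()
                self._tips_below[node] = frozenset().union(
                    *(self._tips_below[c] for c in kids)
                )
                if self._age[node] <= max(self._age[c] for c in kids) - tolerance:
                    raise ValueError("internal node not older than its children")
        self.root_age = root_age
        self.clades: dict[str, frozenset] = {}
        if clades:
            for name, tips in clades.items():
                tips = frozenset(tips)
                if not tips <= set(self.tip_labels):
                    raise ValueError(f"clade {name!r} lists unknown tips")
                self.clades[name] = tips

    # -- structure queries -------------------------------------------------

    def branches(self) -> list[Branch]:
        """Every non-root edge, as Branch records keyed by the clade below."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            tips = self._tips_below[node]
            out.append(Branch(
                branch_id=_branch_id(tips),
                tips=tips,
                parent_age=self._age[node.parent_node],
                child_age=self._age[node],
            ))
        return sorted(out, key=lambda b: b.branch_id)

    def branch(self, branch_id: str) -> Branch:
        for b in self.branches():
            if b.branch_id == branch_id:
                return b
        raise KeyError(branch_id)

    def mrca_tips(self, tips: Iterable[str]) -> frozenset:
        """Tip set of the smallest clade containing ``tips``."""
        want = frozenset(tips)
        if not want <= set(self.tip_labels):
            raise ValueError(f"unknown tips: {sorted(want - set(self.tip_labels))}")
        best = None
        for node in self._tree.postorder_node_iter():
            below = self._tips_below[node]
            if want <= below and (best is None or len(below) < len(best)):
                best = below
        return best

    def clade_tip_sets(self) -> list[frozenset]:
        """Tip sets of all clades (one per node, including single tips)."""
        return [self._tips_below[n] for n in self._tree.preorder_node_iter()]

    def node_ages(self) -> dict[str, float]:
        """Branch-id -> age of the node below that branch."""
        return {b.branch_id: b.child_age for b in self.branches()}

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def as_dendropy(self) -> dendropy.Tree:
        return self._tree


def read_tree(path_or_string, tolerance: float = 1e-6) -> DatedTree:
    """Read a Newick tree with branch lengths in Myr into a DatedTree.

    Accepts a path or a Newick string.  The tree must be rooted with
    labeled tips and be ultrametric within ``tolerance``.
    """
    text = str(path_or_string)
    if text.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=text, schema="newick",
                                 preserve_underscores=True)
    return DatedTree(tree, tolerance=tolerance)


# -- RepeatMasker .out ----------------------------------------------------

def parse_rm_out(path, species_id: str) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out``-dialect table into RepeatHit records.

    Standard column layout: score, %div, %del, %ins, scaffold, start, end,
    (left), strand, family, class/family, ...  Up to three header lines
    (and blank lines) are tolerated.  Divergence is stored as a fraction.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cols = line.split()
            # RepeatMasker headers: "SW perc perc ..." / "score div. del. ..."
            if lineno <= 3 and not cols[0].replace(".", "", 1).isdigit():
                continue
            if len(cols) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=11 columns, got {len(cols)}"
                )
            try:
                div_pct = float(cols[1])
                start = int(cols[5])
                end = int(cols[6])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed numeric field ({exc})")
            if start > end:
                raise ValueError(f"{path}: line {lineno}: start {start} > end {end}")
            strand = cols[8]
            if strand == "C":
                strand = "-"
            hits.append(RepeatHit(
                species_id=species_id,
                scaffold=cols[4],
                start=start,
                end=end,
                strand=strand,
                family_name=cols[9],
                class_label=parse_class_label(cols[10]),
                divergence=div_pct / 100.0,
            ))
    return hits


def write_rm_out(hits: Sequence[RepeatHit], path) -> None:
    """Serialize hits back to the ``.out`` dialect (round-trips with parse)."""
    with open(path, "w") as fh:
        fh.write("   SW   perc perc perc  query     position in query    "
                 "matching repeat\n")
        fh.write("score   div. del. ins.  sequence  begin end   (left)   "
                 "repeat    class/family\n")
        fh.write("\n")
        for h in hits:
            strand = "C" if h.strand == "-" else "+"
            cls = h.class_label if h.class_label != "Unknown" else "Unspecified"
            fh.write(
                f"{1000:>5d} {h.divergence * 100:.6f} 0.00 0.00 "
                f"{h.scaffold} {h.start} {h.end} (0) {strand} "
                f"{h.family_name} {cls}/{h.family_name} 1 {h.length_bp} (0) {1}\n"
            )


# -- FASTA ----------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.  Duplicate
    record ids raise.  An empty file yields an empty list.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                if name in seen:
                    raise ValueError(f"{path}: duplicate FASTA id {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.upper().replace("U", "T"))
        if name is not None:
            records.append((name, "".join(chunks)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# -- tables ----------------------------------------------------------------

def read_genome_table(path) -> dict[str, int]:
    """Read a species->genome-size TSV (columns: species_id, genome_size_bp)."""
    df = pd.read_csv(path, sep="\t")
    if not {"species_id", "genome_size_bp"} <= set(df.columns):
        raise ValueError(f"{path}: need columns species_id, genome_size_bp")
    sizes = dict(zip(df["species_id"], df["genome_size_bp"].astype(int)))
    for sp, n in sizes.items():
        if n <= 0:
            raise ValueError(f"{path}: nonpositive genome size for {sp}")
    return sizes


def write_genome_table(sizes: Mapping[str, int], path) -> None:
    pd.DataFrame(
        {"species_id": list(sizes), "genome_size_bp": list(sizes.values())}
    ).to_csv(path, sep="\t", index=False)


def hits_to_frame(hits: Sequence[RepeatHit]) -> pd.DataFrame:
    """Tabulate hits as a DataFrame (one row per insertion)."""
    return pd.DataFrame({
        "species_id": [h.species_id for h in hits],
        "scaffold": [h.scaffold for h in hits],
        "start": [h.start for h in hits],
        "end": [h.end for h in hits],
        "strand": [h.strand for h in hits],
        "family_name": [h.family_name for h in hits],
        "class_label": [h.class_label for h in hits],
        "divergence": [h.divergence for h in hits],
        "length_bp": [h.length_bp for h in hits],
    })


def write_hits_tsv(hits: Sequence[RepeatHit], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[RepeatHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        RepeatHit(
            species_id=r.species_id, scaffold=r.scaffold, start=int(r.start),
            end=int(r.end), strand=r.strand, family_name=r.family_name,
            class_label=r.class_label, divergence=float(r.divergence),
        )
        for r in df.itertuples()
    ]
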
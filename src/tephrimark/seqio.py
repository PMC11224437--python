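"""Sequence and tree I/O plus the shared data model.

All interval coordinates inside the package are 0-based half-open on the
forward strand of the stored contig; 1-based inclusive coordinates appear
only in written partition files and tabular reports.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio.SeqIO.FastaIO import SimpleFastaParser

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FastaError(ValueError):
    pass


class NewickError(ValueError):
    pass


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA file into an ordered ``{id: sequence}`` map.

    The record id is the header token up to the first whitespace; sequences
    are uppercased. Duplicate ids and empty records raise :class:`FastaError`.
    """
    records: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            rid = header.split()[0] if header.split() else ""
            if not rid:
                raise FastaError(f"{path}: record with empty id")
            if rid in records:
                raise FastaError(f"{path}: duplicate id {rid}")
            seq = seq.upper()
            if not seq:
                raise FastaError(f"{path}: empty record {rid}")
            records[rid] = seq
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class Genome:
    """A taxon label plus named contig sequences over {A,C,G,T,N}."""

    taxon: str
    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"{self.taxon}/{cid}: empty contig")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"{self.taxon}/{cid}: invalid characters {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def read_genome(path: str | Path, taxon: str) -> Genome:
    return Genome(taxon=taxon, contigs=read_fasta(path))


def read_manifest(path: str | Path) -> dict[str, Path]:
    """Two-column TSV (taxon, path) mapping taxon labels to FASTA files."""
    out: dict[str, Path] = {}
    base = Path(path).parent
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, p = line.split("\t")[:2]
            if taxon in out:
                raise ValueError(f"duplicate taxon {taxon} in manifest")
            fp = Path(p)
            out[taxon] = fp if fp.is_absolute() else base / fp
    return out


# ---------------------------------------------------------------------------
# Trees


class Tree:
    """Thin wrapper over a dendropy tree.

    ``support_scale`` records whether internal-node supports are on a 0-100
    (bootstrap) or 0-1 (posterior) scale; operations that average supports
    require a uniform scale.
    """

    def __init__(self, dtree: dendropy.Tree, support_scale: str | None = None):
        self.dtree = dtree
        self.support_scale = support_scale

    # -- basic accessors ---------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.dtree.leaf_node_iter()]

    @property
    def is_rooted(self) -> bool:
        return len(self.dtree.seed_node.child_nodes()) == 2

    def copy(self) -> "Tree":
        return Tree(self.dtree.clone(depth=1), self.support_scale)

    def root_to_tip_depths(self) -> dict[str, float]:
        out = {}
        for leaf in self.dtree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.dtree.preorder_edge_iter() if e.length
        )

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions as canonical leaf-label sets.

        Each split is represented by the side that excludes the
        lexicographically smallest leaf, so the representation does not
        depend on rooting. Polytomies are allowed.
        """
        leaves = frozenset(self.leaf_labels)
        n = len(leaves)
        anchor = min(leaves)
        splits: set[frozenset[str]] = set()
        clade: dict[int, frozenset[str]] = {}
        for node in self.dtree.postorder_node_iter():
            if node.is_leaf():
                clade[id(node)] = frozenset([node.taxon.label])
            else:
                cl = frozenset().union(*(clade[id(c)] for c in node.child_nodes()))
                clade[id(node)] = cl
                if 2 <= len(cl) <= n - 2:
                    splits.add(cl if anchor not in cl else leaves - cl)
        return frozenset(splits)

    def internal_supports(self) -> list[float]:
        vals = []
        for node in self.dtree.preorder_internal_node_iter(exclude_seed_node=True):
            if node.label is not None:
                try:
                    vals.append(float(node.label))
                except ValueError:
                    pass
        return vals

    def prune_to(self, labels: Iterable[str]) -> "Tree":
        keep = set(labels)
        t = self.dtree.extract_tree_with_taxa_labels(
            sorted(keep), suppress_unifurcations=True
        )
        return Tree(t, self.support_scale)

    # -- serialization -----------------------------------------------------
    def to_newick(self) -> str:
        s = self.dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        ).strip()
        return s

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({len(self.leaf_labels)} leaves, rooted={self.is_rooted})"


def parse_newick(text: str, support_scale: str | None = None) -> Tree:
    """Parse a Newick string; numeric internal labels become node supports."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse-error classes
        pos = ""
        for attr in ("col_num", "column"):
            v = getattr(exc, attr, None)
            if v is not None:
                pos = f" near column {v}"
                break
        raise NewickError(f"newick parse error{pos}: {exc}") from exc
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise NewickError("duplicate leaf labels")
    return Tree(dtree, support_scale)


def read_newick(path: str | Path, support_scale: str | None = None) -> Tree:
    return parse_newick(Path(path).read_text(), support_scale)


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Partition files


def write_partitions(
    partitions: list[tuple[str, int, int]],
    path: str | Path,
    datatype: str = "DNA",
) -> None:
    """Write RAxML-style partition lines ``DNA, <locus> = <start>-<end>``.

    Coordinates are 1-based inclusive; partitions must start at 1 and be
    contiguous, ascending and non-overlapping.
    """
    if not partitions:
        log.warning("write_partitions: empty partition list -> empty file %s", path)
        Path(path).write_text("")
        return
    expected = 1
    for lid, start, end in partitions:
        if start != expected:
            kind = "gap" if start > expected else "overlap"
            raise ValueError(f"{kind} at {expected} (partition {lid} starts at {start})")
        if end < start:
            raise ValueError(f"partition {lid}: end {end} < start {start}")
        expected = end + 1
    with open(path, "w") as fh:
        for lid, start, end in partitions:
            fh.write(f"{datatype}, {lid} = {start}-{end}\n")


_PART_RE = re.compile(r"^\s*(\w+)\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$")


def read_partitions(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        m = _PART_RE.match(line)
        if not m:
            raise ValueError(f"unparseable partition line: {line!r}")
        out.append((m.group(2), int(m.group(3)), int(m.group(4))))
    return out


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end
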
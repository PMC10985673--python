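"""Rank-annotated taxonomic tree: LCA, lineage projection, genome lengths.

Internal taxon IDs are 2-byte integers assigned deterministically (sorted
external taxid order, starting at 1); ID 0 is reserved for "unassigned" and
doubles as the empty value of the per-k-mer label array. Ranks follow the
seven canonical levels; nodes with other ranks are kept as "no rank"
pass-through nodes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["CANONICAL_RANKS", "TaxonNode", "TaxonomyTree"]

#: canonical ranks ordered lowest (most specific) to highest
CANONICAL_RANKS = ("species", "genus", "family", "order", "class", "phylum", "superkingdom")

_RANK_LEVEL = {r: i for i, r in enumerate(CANONICAL_RANKS)}

MAX_TAXA = 65536


@dataclass
class TaxonNode:
    id: int                 # internal 2-byte ID
    taxid: int              # external taxid
    parent: int             # internal parent ID (== id for the root)
    rank: str               # canonical rank or "no rank"
    name: str
    children: list[int] = field(default_factory=list)


class TaxonomyTree:
    """Validated single-rooted tree over at most 65 536 taxa."""

    def __init__(self, nodes: dict[int, TaxonNode], root_id: int):
        self.nodes = nodes
        self.root_id = root_id
        self._by_taxid = {n.taxid: n.id for n in nodes.values()}
        self._depth: dict[int, int] = {}
        self._compute_depths()
        self.genome_to_taxon: dict[str, int] = {}
        self.genome_lengths: dict[str, int] = {}
        self._taxa_at_rank: dict[str, list[int]] = {}
        for r in CANONICAL_RANKS:
            self._taxa_at_rank[r] = sorted(
                n.id for n in nodes.values() if n.rank == r
            )
        self._validate_ranks()

    # ------------------------------------------------------------ construction

    @classmethod
    def from_edges(
        cls, records: list[tuple[int, int, str, str]]
    ) -> "TaxonomyTree":
        """Build from (taxid, parent_taxid, rank, name) records.

        Internal IDs are assigned in sorted external-taxid order starting
        at 1. The root is the single record with ``taxid == parent_taxid``.
        Raises on cycles, multiple roots, or more than 65 536 taxa.
        """
        if len(records) > MAX_TAXA - 1:
            raise ValueError(f"too many taxa ({len(records)} > {MAX_TAXA - 1})")
        by_taxid = {}
        for taxid, parent, rank, name in records:
            if taxid in by_taxid:
                raise ValueError(f"duplicate taxid {taxid}")
            by_taxid[taxid] = (parent, rank if rank in _RANK_LEVEL else "no rank", name)
        internal = {taxid: i + 1 for i, taxid in enumerate(sorted(by_taxid))}
        nodes: dict[int, TaxonNode] = {}
        roots = []
        for taxid, (parent, rank, name) in by_taxid.items():
            if parent not in by_taxid:
                raise ValueError(f"parent taxid {parent} of {taxid} not in taxonomy")
            nid = internal[taxid]
            nodes[nid] = TaxonNode(nid, taxid, internal[parent], rank, name)
            if parent == taxid:
                roots.append(nid)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        for node in nodes.values():
            if node.id != root:
                nodes[node.parent].children.append(node.id)
        for node in nodes.values():
            node.children.sort()
        return cls(nodes, root)

    def _compute_depths(self) -> None:
        for nid in self.nodes:
            depth, cur, seen = 0, nid, set()
            while cur != self.root_id:
                if cur in seen:
                    raise ValueError(f"cycle detected at internal id {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent
                depth += 1
                if depth > len(self.nodes):
                    raise ValueError("cycle detected (walk exceeded node count)")
            self._depth[nid] = depth

    def _validate_ranks(self) -> None:
        # parent canonical rank must be strictly higher than the child's
        for node in self.nodes.values():
            if node.id == self.root_id or node.rank == "no rank":
                continue
            cur = self.nodes[node.parent]
            while cur.rank == "no rank" and cur.id != self.root_id:
                cur = self.nodes[cur.parent]
            if cur.rank != "no rank" and _RANK_LEVEL[cur.rank] <= _RANK_LEVEL[node.rank]:
                raise ValueError(
                    f"rank order violated: {cur.rank} is parent of {node.rank}"
                )

    # ---------------------------------------------------------------- queries

    def __contains__(self, taxon: int) -> bool:
        return taxon in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def id_of(self, taxid: int) -> int:
        return self._by_taxid[taxid]

    def depth(self, taxon: int) -> int:
        return self._depth[taxon]

    def lca(self, a: int, b: int) -> int:
        """Deepest common ancestor of two taxa (internal IDs). ID 0 acts
        as the identity element: lca(0, t) == t."""
        if a == 0:
            return b
        if b == 0:
            return a
        if a not in self.nodes or b not in self.nodes:
            raise KeyError(f"unknown taxon in lca({a}, {b})")
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a, da = self.nodes[a].parent, da - 1
        while db > da:
            b, db = self.nodes[b].parent, db - 1
        while a != b:
            a = self.nodes[a].parent
            b = self.nodes[b].parent
        return a

    def lineage(self, taxon: int) -> list[int]:
        """Path from the root down to ``taxon`` (inclusive)."""
        path = []
        cur = taxon
        while True:
            path.append(cur)
            if cur == self.root_id:
                break
            cur = self.nodes[cur].parent
        return path[::-1]

    def rank_of_lineage(self, taxon: int, rank: str) -> int | None:
        """Ancestor-or-self of ``taxon`` at canonical rank ``rank``, or
        None if the taxon sits above that rank or the rank is absent from
        its lineage."""
        if rank not in _RANK_LEVEL:
            raise ValueError(f"unknown rank {rank!r}")
        target = _RANK_LEVEL[rank]
        cur = taxon
        while True:
            node = self.nodes[cur]
            if node.rank in _RANK_LEVEL:
                level = _RANK_LEVEL[node.rank]
                if level == target:
                    return cur
                if level > target:
                    return None
            if cur == self.root_id:
                return None
            cur = node.parent

    def taxa_at_rank(self, rank: str) -> list[int]:
        return list(self._taxa_at_rank[rank])

    def children(self, taxon: int) -> list[int]:
        return list(self.nodes[taxon].children)

    def descendants(self, taxon: int) -> list[int]:
        out, stack = [], [taxon]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self.nodes[cur].children)
        return out

    # -------------------------------------------------------- genome metadata

    def attach_genomes(
        self, genome_to_taxid: dict[str, int], genome_lengths: dict[str, int]
    ) -> None:
        """Register reference genomes (by external taxid) and their lengths."""
        for gid, taxid in genome_to_taxid.items():
            if taxid not in self._by_taxid:
                raise KeyError(f"genome {gid!r} maps to unknown taxid {taxid}")
            self.genome_to_taxon[gid] = self._by_taxid[taxid]
        self.genome_lengths.update(genome_lengths)

    def mean_genome_length(self, taxon: int) -> float:
        """Mean reference genome length over the clade rooted at ``taxon``."""
        clade = set(self.descendants(taxon))
        lengths = [
            self.genome_lengths[gid]
            for gid, t in self.genome_to_taxon.items()
            if t in clade and gid in self.genome_lengths
        ]
        if not lengths:
            raise KeyError(f"no reference genome lengths under taxon {taxon}")
        return sum(lengths) / len(lengths)

    # ----------------------------------------------------------------- parsing

    @classmethod
    def from_ncbi_dump(cls, nodes_source, names_source=None) -> "TaxonomyTree":
        """Parse NCBI-dump-style nodes/names files (pipe-delimited
        ``taxid | parent | rank | ...`` rows)."""
        def rows(src):
            if isinstance(src, (str, Path)):
                text = Path(src).read_text()
            else:
                text = src.read()
            for line in text.splitlines():
                if not line.strip():
                    continue
                yield [f.strip() for f in line.rstrip("|\n\t ").split("|")]

        names: dict[int, str] = {}
        if names_source is not None:
            for fields in rows(names_source):
                taxid = int(fields[0])
                name_class = fields[3] if len(fields) > 3 else "scientific name"
                if taxid not in names or name_class == "scientific name":
                    names[taxid] = fields[1]
        records = []
        for fields in rows(nodes_source):
            taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            records.append((taxid, parent, rank, names.get(taxid, str(taxid))))
        return cls.from_edges(records)

    @classmethod
    def from_lineage_tsv(cls, source) -> tuple["TaxonomyTree", dict[str, int]]:
        """Parse the lineage TSV dialect: ``genome_id<TAB>lineage`` where
        lineage is ``rank:name`` tokens joined by ';', highest rank first.

        Node identity is the full path down to a name, so the same genus
        name under two families yields two nodes. External taxids are
        assigned deterministically from sorted paths. Returns the tree and
        the genome -> external taxid map (taxid of the last lineage node).
        """
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        paths: set[tuple[tuple[str, str], ...]] = set()
        genome_paths: dict[str, tuple[tuple[str, str], ...]] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            gid, lineage = line.rstrip("\n").split("\t")[:2]
            path = tuple(
                (tok.split(":", 1)[0], tok.split(":", 1)[1])
                for tok in lineage.split(";")
                if tok
            )
            genome_paths[gid] = path
            for i in range(1, len(path) + 1):
                paths.add(path[:i])
        # synthetic root (taxid 1) sits above the highest declared rank
        records = [(1, 1, "no rank", "root")]
        taxid_of = {p: i + 2 for i, p in enumerate(sorted(paths))}
        for p, taxid in taxid_of.items():
            parent = taxid_of[p[:-1]] if len(p) > 1 else 1
            rank, name = p[-1]
            records.append((taxid, parent, rank, name))
        tree = cls.from_edges(records)
        genome_to_taxid = {g: taxid_of[p] for g, p in genome_paths.items()}
        return tree, genome_to_taxid

    def to_lineage_tsv(self, fh=None) -> str:
        """Write one line per registered genome: genome_id <TAB> lineage."""
        lines = []
        for gid in sorted(self.genome_to_taxon):
            taxon = self.genome_to_taxon[gid]
            toks = [
                f"{self.nodes[t].rank}:{self.nodes[t].name}"
                for t in self.lineage(taxon)
                if self.nodes[t].rank in _RANK_LEVEL or t != self.root_id
            ]
            lines.append(f"{gid}\t{';'.join(toks)}")
        text = "\n".join(lines) + "\n"
        if fh is not None:
            fh.write(text)
        return text

    # -------------------------------------------------------------- save/load

    def to_json_dict(self) -> dict:
        return {
            "nodes": [
                [n.id, n.taxid, n.parent, n.rank, n.name]
                for n in sorted(self.nodes.values(), key=lambda n: n.id)
            ],
            "root_id": self.root_id,
            "genome_to_taxon": self.genome_to_taxon,
            "genome_lengths": self.genome_lengths,
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "TaxonomyTree":
        nodes = {
            nid: TaxonNode(nid, taxid, parent, rank, name)
            for nid, taxid, parent, rank, name in data["nodes"]
        }
        root = data["root_id"]
        for node in nodes.values():
            if node.id != root:
                nodes[node.parent].children.append(node.id)
        for node in nodes.values():
            node.children.sort()
        tree = cls(nodes, root)
        tree.genome_to_taxon = {k: int(v) for k, v in data["genome_to_taxon"].items()}
        tree.genome_lengths = {k: int(v) for k, v in data["genome_lengths"].items()}
        return tree
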
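"""Lowest-common-ancestor taxonomic assignment of OTUs from alignment hit tables.

An OTU's representative sequence is aligned (elsewhere) against a reference
nucleotide database; each high-scoring pair (HSP) links the OTU to a reference
accession, hence to a taxonomy node.  The LCA heuristic assigns the OTU to the
deepest node ancestral to every near-best match: HSPs below a bit-score floor
are dropped, only the best HSP per subject accession is kept, and of those only
HSPs scoring within a fractional window of the best score participate.  Percent
identity is then used secondarily to demote assignments the alignment evidence
cannot support at species or genus rank.

The module also implements the watershed-constrained re-assignment used for
short vertebrate barcodes (restricting ray-finned-fish matches to an expected
species list) and ordered post-hoc adjustments (remove / rename / merge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TaxonomyError",
    "HitRecord",
    "AssignmentParams",
    "TaxonAssignment",
    "TaxonomyDB",
    "load_taxonomy",
    "lowest_common_ancestor",
    "assign_otu",
    "constrained_reassign",
    "apply_taxon_adjustments",
    "Adjustment",
    "read_hit_table",
    "load_allowed_taxa",
    "PRESETS",
]


class TaxonomyError(ValueError):
    """Structural or lookup failure in a taxonomy database."""


# Canonical rank ladder, finest first.  NCBI lineages are rank-sparse; nodes
# with ranks outside this ladder (or "no rank") are treated as unranked.
RANK_LADDER = (
    "subspecies",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "kingdom",
    "superkingdom",
)
_RANK_INDEX = {r: i for i, r in enumerate(RANK_LADDER)}
_FAMILY_IDX = _RANK_INDEX["family"]


@dataclass(frozen=True)
class HitRecord:
    """One high-scoring pair linking an OTU to a reference taxon."""

    query_id: str
    subject_acc: str
    taxon_id: int
    bit_score: float
    pct_identity: float
    aln_length: int = 1

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError(f"bit_score must be >= 0, got {self.bit_score}")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(f"pct_identity outside [0, 100]: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")


@dataclass(frozen=True)
class AssignmentParams:
    """Thresholds governing one locus's LCA assignment.

    ``lca_window`` is the fractional score window: HSPs with bit score >=
    (1 - lca_window) * best participate in the LCA (closed at the boundary).
    """

    min_bitscore: float = 250.0
    lca_window: float = 0.05
    species_min_identity: float = 95.0
    genus_min_identity: float = 90.0
    allowed_taxa: frozenset[int] | None = None
    constraint_clade: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.lca_window <= 1:
            raise ValueError(f"lca_window must be in (0, 1], got {self.lca_window}")
        if not 0 <= self.genus_min_identity <= self.species_min_identity <= 100:
            raise ValueError(
                "require 0 <= genus_min_identity <= species_min_identity <= 100"
            )


#: Per-locus presets: COI and eukaryotic 16S use a 5% window with a bit-score
#: floor of 250; the short 12S locus uses a 2% window with a floor of 200 and a
#: watershed constraint within the ray-finned fishes.  The 12S constraint clade
#: must be resolved against the loaded taxonomy by name.
PRESETS: dict[str, dict] = {
    "coi": dict(min_bitscore=250.0, lca_window=0.05),
    "euk16s": dict(min_bitscore=250.0, lca_window=0.05),
    "12s": dict(min_bitscore=200.0, lca_window=0.02, constraint_clade_name="Actinopterygii"),
}


@dataclass
class TaxonAssignment:
    """Per-OTU assignment result with provenance."""

    query_id: str
    taxon_id: int | None
    assigned_rank: str | None = None
    taxon_name: str | None = None
    mean_identity: float | None = None
    n_contributing: int = 0
    demoted: bool = False
    notes: str = ""

    @property
    def assigned(self) -> bool:
        return self.taxon_id is not None


@dataclass
class _Node:
    parent: int
    rank: str
    name: str = ""


class TaxonomyDB:
    """Rooted taxonomy supporting ancestor-path queries and merged-id remapping."""

    def __init__(
        self,
        nodes: Mapping[int, tuple[int, str] | tuple[int, str, str]],
        names: Mapping[int, str] | None = None,
        merged: Mapping[int, int] | None = None,
    ):
        self._nodes: dict[int, _Node] = {}
        names = names or {}
        for tid, spec in nodes.items():
            parent, rank = spec[0], spec[1]
            name = spec[2] if len(spec) > 2 else names.get(tid, "")
            self._nodes[int(tid)] = _Node(int(parent), str(rank), str(name))
        self.merged: dict[int, int] = {int(k): int(v) for k, v in (merged or {}).items()}
        self._name_index: dict[str, int] | None = None
        self.root = self._validate()

    def _validate(self) -> int:
        roots = [tid for tid, n in self._nodes.items() if n.parent == tid]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        for tid, node in self._nodes.items():
            if node.parent not in self._nodes:
                raise TaxonomyError(f"node {tid} has unknown parent {node.parent}")
        # cycle check: every parent chain must reach the root
        for tid in self._nodes:
            seen = set()
            cur = tid
            while cur != root:
                if cur in seen:
                    raise TaxonomyError(f"cycle in parent chain at node {cur}")
                seen.add(cur)
                cur = self._nodes[cur].parent
        return root

    def __contains__(self, taxon_id: int) -> bool:
        try:
            self.resolve(taxon_id)
        except TaxonomyError:
            return False
        return True

    def __len__(self) -> int:
        return len(self._nodes)

    def resolve(self, taxon_id: int) -> int:
        """Map a possibly-merged id to its current node id."""
        tid = int(taxon_id)
        seen = set()
        while tid not in self._nodes:
            if tid in self.merged and tid not in seen:
                seen.add(tid)
                tid = self.merged[tid]
            else:
                raise TaxonomyError(f"taxon id {taxon_id} not resolvable")
        return tid

    def parent(self, taxon_id: int) -> int:
        return self._nodes[self.resolve(taxon_id)].parent

    def rank(self, taxon_id: int) -> str:
        return self._nodes[self.resolve(taxon_id)].rank

    def name(self, taxon_id: int) -> str:
        return self._nodes[self.resolve(taxon_id)].name

    def find_by_name(self, name: str) -> int:
        if self._name_index is None:
            self._name_index = {}
            for tid, node in self._nodes.items():
                if node.name:
                    self._name_index.setdefault(node.name, tid)
        try:
            return self._name_index[name]
        except KeyError:
            raise TaxonomyError(f"no taxon named {name!r}") from None

    def path_to_root(self, taxon_id: int) -> list[int]:
        """Node ids from the taxon itself up to and including the root."""
        tid = self.resolve(taxon_id)
        path = [tid]
        while tid != self.root:
            tid = self._nodes[tid].parent
            path.append(tid)
        return path

    def depth(self, taxon_id: int) -> int:
        return len(self.path_to_root(taxon_id)) - 1

    def is_within(self, taxon_id: int, clade: int) -> bool:
        return self.resolve(clade) in self.path_to_root(taxon_id)

    def ancestor_at_or_above(self, taxon_id: int, target_rank: str) -> int | None:
        """Nearest strict ancestor whose ladder rank is at least ``target_rank``
        but no coarser than family (the demotion cap); None if absent."""
        target_idx = _RANK_INDEX[target_rank]
        for anc in self.path_to_root(taxon_id)[1:]:
            idx = _RANK_INDEX.get(self._nodes[anc].rank)
            if idx is None:
                continue
            if idx >= target_idx:
                return anc if idx <= _FAMILY_IDX else None
        return None


def _read_dmp_or_tsv(source) -> list[list[str]]:
    """Read pipe-delimited taxdump lines or tab-separated toy lines."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "|" in line:
            fields = [f.strip() for f in line.rstrip("|").split("|")]
        else:
            fields = [f.strip() for f in line.split("\t")]
        rows.append(fields)
    return rows


def load_taxonomy(nodes_source, names_source=None, merged_source=None) -> TaxonomyDB:
    """Build a :class:`TaxonomyDB` from taxdump-dialect (or toy TSV) sources.

    ``nodes_source`` carries ``tax_id | parent_id | rank`` records; an optional
    fourth column is taken as the name for the toy dialect.  ``names_source``
    follows ``tax_id | name | unique name | name class`` and only scientific
    names are indexed.  ``merged_source`` carries ``old_id | new_id``.
    """
    nodes: dict[int, tuple[int, str, str]] = {}
    for fields in _read_dmp_or_tsv(nodes_source):
        tid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
        name = fields[3] if len(fields) > 3 and names_source is None else ""
        nodes[tid] = (parent, rank, name)
    names: dict[int, str] = {}
    if names_source is not None:
        for fields in _read_dmp_or_tsv(names_source):
            if len(fields) >= 4 and fields[3] != "scientific name":
                continue
            names[int(fields[0])] = fields[1]
        nodes = {
            tid: (p, r, names.get(tid, nm)) for tid, (p, r, nm) in nodes.items()
        }
    merged: dict[int, int] = {}
    if merged_source is not None:
        for fields in _read_dmp_or_tsv(merged_source):
            merged[int(fields[0])] = int(fields[1])
    return TaxonomyDB(nodes, merged=merged)


def lowest_common_ancestor(taxon_ids: Iterable[int], db: TaxonomyDB) -> int:
    """Deepest node ancestral to (or equal to) every input taxon."""
    ids = list(taxon_ids)
    if not ids:
        raise TaxonomyError("LCA of an empty taxon set is undefined")
    paths = [db.path_to_root(t) for t in ids]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # paths are ordered leaf -> root, so the first common node is the deepest
    for node in paths[0]:
        if node in common:
            return node
    raise TaxonomyError("no common ancestor found (disjoint trees?)")  # pragma: no cover


def _window_retain(hsps: Sequence[HitRecord], params: AssignmentParams) -> list[HitRecord]:
    """Floor-filter, reduce to best HSP per subject accession, then window."""
    kept = [h for h in hsps if h.bit_score >= params.min_bitscore]
    if not kept:
        return []
    best_per_subject: dict[str, HitRecord] = {}
    for h in kept:
        prev = best_per_subject.get(h.subject_acc)
        if prev is None or h.bit_score > prev.bit_score:
            best_per_subject[h.subject_acc] = h
    pool = list(best_per_subject.values())
    best = max(h.bit_score for h in pool)
    cutoff = (1.0 - params.lca_window) * best
    return [h for h in pool if h.bit_score >= cutoff]  # closed interval at cutoff


def assign_otu(
    hsps: Sequence[HitRecord], params: AssignmentParams, db: TaxonomyDB
) -> TaxonAssignment:
    """Assign one OTU by windowed LCA with identity-based demotion.

    Species-rank assignments require mean identity >= ``species_min_identity``
    over contributing HSPs, else they are demoted to the genus ancestor; genus
    rank (native or demoted) requires >= ``genus_min_identity``, else demotion
    to family.  Demotion never reports a rank above family: if no suitable
    ancestor exists at or below family the OTU is returned unassigned.
    """
    if not hsps:
        return TaxonAssignment(query_id="", taxon_id=None, notes="no HSPs")
    qids = {h.query_id for h in hsps}
    if len(qids) != 1:
        raise ValueError(f"HSPs span multiple query ids: {sorted(qids)}")
    qid = hsps[0].query_id

    retained = _window_retain(hsps, params)
    if not retained:
        return TaxonAssignment(qid, None, notes="no HSP above bit-score floor")
    taxa = {db.resolve(h.taxon_id) for h in retained}
    node = lowest_common_ancestor(taxa, db)
    mean_id = sum(h.pct_identity for h in retained) / len(retained)
    result = TaxonAssignment(
        qid,
        node,
        assigned_rank=db.rank(node),
        taxon_name=db.name(node),
        mean_identity=mean_id,
        n_contributing=len(retained),
    )

    def demote(to_rank: str, why: str) -> bool:
        anc = db.ancestor_at_or_above(result.taxon_id, to_rank)
        if anc is None:
            result.taxon_id = None
            result.assigned_rank = None
            result.taxon_name = None
            result.notes = f"{why}; no ancestor at or below family"
            return False
        result.taxon_id = anc
        result.assigned_rank = db.rank(anc)
        result.taxon_name = db.name(anc)
        result.demoted = True
        result.notes = (result.notes + "; " if result.notes else "") + why
        return True

    if result.assigned_rank == "species" and mean_id < params.species_min_identity:
        if not demote("genus", f"mean identity {mean_id:.1f} < {params.species_min_identity:g} at species"):
            return result
    if result.assigned_rank == "genus" and mean_id < params.genus_min_identity:
        demote("family", f"mean identity {mean_id:.1f} < {params.genus_min_identity:g} at genus")
    return result


def constrained_reassign(
    hsps: Sequence[HitRecord],
    allowed_taxa: Iterable[int],
    constraint_clade: int,
    params: AssignmentParams,
    db: TaxonomyDB,
    initial: TaxonAssignment | None = None,
) -> TaxonAssignment:
    """Re-evaluate an assignment after removing matches to unexpected taxa.

    Applies only when the initial assignment falls within ``constraint_clade``
    (e.g. Actinopterygii): HSPs to within-clade taxa whose lineage (self up to
    the clade) contains no allowed taxon are removed, and the LCA re-run on the
    remainder.  Assignments outside the clade are returned unchanged.
    """
    allowed = {db.resolve(t) for t in allowed_taxa}
    if not allowed:
        raise ValueError("allowed_taxa is empty while a constraint clade is set")
    clade = db.resolve(constraint_clade)
    if initial is None:
        initial = assign_otu(hsps, params, db)
    if not initial.assigned or not db.is_within(initial.taxon_id, clade):
        return initial

    def hsp_allowed(h: HitRecord) -> bool:
        path = db.path_to_root(h.taxon_id)
        if clade not in path:
            return True  # outside the clade: constraint does not apply
        for node in path:
            if node in allowed:
                return True
            if node == clade:
                break
        return False

    filtered = [h for h in hsps if hsp_allowed(h)]
    if not filtered:
        return TaxonAssignment(
            initial.query_id, None,
            notes="all matches excluded by allowed-taxa constraint",
        )
    out = assign_otu(filtered, params, db)
    if out.assigned:
        out.notes = (out.notes + "; " if out.notes else "") + "constrained re-assignment"
    return out


@dataclass(frozen=True)
class Adjustment:
    """One ordered post-hoc adjustment: match a taxon label or id, then act.

    ``action`` is one of ``remove`` (drop matching OTUs), ``rename`` (relabel
    to ``target``, an operational label), or ``merge_into`` (reassign to the
    taxon named ``target``, pooling downstream counts).
    """

    match: str | int
    action: str
    target: str | None = None

    def __post_init__(self) -> None:
        if self.action not in ("remove", "rename", "merge_into"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action in ("rename", "merge_into") and not self.target:
            raise ValueError(f"action {self.action!r} requires a target")


def apply_taxon_adjustments(
    assignments: Sequence[TaxonAssignment],
    adjustments: Sequence[Adjustment],
    db: TaxonomyDB | None = None,
) -> list[TaxonAssignment]:
    """Apply ordered remove / rename / merge adjustments to assignments.

    Raises if any adjustment matches nothing, listing the unmatched rules.
    """
    out = [replace(a) if isinstance(a, TaxonAssignment) else a for a in assignments]
    unmatched: list[Adjustment] = []
    for adj in adjustments:
        def matches(a: TaxonAssignment) -> bool:
            if isinstance(adj.match, int):
                return a.taxon_id == adj.match
            return a.taxon_name == adj.match
        hit = [a for a in out if a.assigned and matches(a)]
        if not hit:
            unmatched.append(adj)
            continue
        if adj.action == "remove":
            out = [a for a in out if a not in hit]
        elif adj.action == "rename":
            for a in hit:
                a.taxon_name = adj.target
                a.notes = (a.notes + "; " if a.notes else "") + f"renamed from {adj.match}"
        else:  # merge_into
            target_id = None
            if db is not None:
                try:
                    target_id = db.find_by_name(adj.target)
                except TaxonomyError:
                    target_id = None
            for a in hit:
                a.notes = (a.notes + "; " if a.notes else "") + f"merged from {a.taxon_name}"
                a.taxon_name = adj.target
                if target_id is not None:
                    a.taxon_id = target_id
                    a.assigned_rank = db.rank(target_id)
    if unmatched:
        raise ValueError(
            "adjustments matched no assignment: "
            + ", ".join(repr(a.match) for a in unmatched)
        )
    return out


# -- hit-table and allowed-list I/O -----------------------------------------

_OUTFMT6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(
    path, acc_to_taxid: Mapping[str, int] | None = None
) -> dict[str, list[HitRecord]]:
    """Read a 12-column tabular alignment file (plus optional ``staxid`` 13th
    column); a sidecar accession->taxid map is used when the column is absent.
    Returns HSPs grouped by query id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 12:
        if acc_to_taxid is None:
            raise ValueError("hit table lacks a taxid column and no accession map given")
        df.columns = _OUTFMT6_COLS
        df["staxid"] = df["sseqid"].map(acc_to_taxid)
        if df["staxid"].isna().any():
            missing = df.loc[df["staxid"].isna(), "sseqid"].unique()
            raise ValueError(f"accessions missing from taxid map: {list(missing)[:5]}")
    elif df.shape[1] == 13:
        df.columns = _OUTFMT6_COLS + ["staxid"]
    else:
        raise ValueError(f"expected 12 or 13 columns, got {df.shape[1]}")
    by_query: dict[str, list[HitRecord]] = {}
    for row in df.itertuples(index=False):
        by_query.setdefault(str(row.qseqid), []).append(
            HitRecord(
                query_id=str(row.qseqid),
                subject_acc=str(row.sseqid),
                taxon_id=int(row.staxid),
                bit_score=float(row.bitscore),
                pct_identity=float(row.pident),
                aln_length=int(row.length),
            )
        )
    return by_query


def load_allowed_taxa(path, db: TaxonomyDB) -> frozenset[int]:
    """Read an allowed-taxa list, one name or numeric id per line."""
    ids: set[int] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.add(db.resolve(int(line)) if line.isdigit() else db.find_by_name(line))
    return frozenset(ids)
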
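"""Count-table and taxonomy-file readers/writers and the sample-name grammar.

Count tables are TSV with the sample id in the first column and taxon labels
as the header row.  Sample names follow ``<samplerCode>_<initiationMinutes>``
with an optional ``(<replicate>)`` suffix for grab replicates (e.g.
``B_1425(2)``); a sidecar metadata TSV keyed by sample id overrides name
parsing.  Taxon metadata (locus per taxon) travels in a second sidecar.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .filtering import CountMatrix

__all__ = [
    "parse_sample_name",
    "read_count_table",
    "write_count_table",
    "write_toy_taxdump",
]

_NAME_RE = re.compile(r"^(?P<sampler>[A-Za-z][A-Za-z0-9]*)_(?P<minutes>\d+)"
                      r"(?:\((?P<rep>\d+)\))?$")


def parse_sample_name(name: str) -> dict:
    """Parse ``<sampler>_<minutes>[(<rep>)]`` into metadata fields."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"sample name {name!r} does not follow <sampler>_<minutes>[(rep)]")
    return {
        "sampler": m.group("sampler"),
        "initiation_time_min": int(m.group("minutes")),
        "replicate": int(m.group("rep")) if m.group("rep") else None,
    }


def read_count_table(
    path,
    sample_meta_path=None,
    taxon_meta_path=None,
    sampler_map: dict | None = None,
) -> CountMatrix:
    """Read a samples x taxa TSV into a validated :class:`CountMatrix`.

    Without a sidecar, sampler / time / replicate come from the sample-name
    grammar and ``sampler_map`` (code -> (site, method)) fills in the rest.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise ValueError(f"duplicate taxon columns: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.index.duplicated().any():
        raise ValueError("duplicate sample names")
    try:
        df = df.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cells in count table: {exc}") from exc

    if sample_meta_path is not None:
        meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0)
        meta["replicate"] = meta["replicate"].astype("object").where(meta["replicate"].notna(), None)
    else:
        rows = {s: parse_sample_name(s) for s in df.index}
        meta = pd.DataFrame.from_dict(rows, orient="index")
        if sampler_map:
            meta["site"] = meta["sampler"].map(lambda c: sampler_map[c][0])
            meta["method"] = meta["sampler"].map(lambda c: sampler_map[c][1])
    tmeta = None
    if taxon_meta_path is not None:
        tmeta = pd.read_csv(taxon_meta_path, sep="\t", index_col=0)
    return CountMatrix(df, meta, tmeta)


def write_count_table(
    matrix: CountMatrix, path, sample_meta_path=None, taxon_meta_path=None
) -> None:
    """Write the counts (and optionally the sidecars) as TSV."""
    matrix.counts.to_csv(path, sep="\t", index_label="sample")
    if sample_meta_path is not None and matrix.sample_meta is not None:
        matrix.sample_meta.to_csv(sample_meta_path, sep="\t", index_label="sample")
    if taxon_meta_path is not None and matrix.taxon_meta is not None:
        matrix.taxon_meta.to_csv(taxon_meta_path, sep="\t", index_label="taxon")


def write_toy_taxdump(db, directory) -> dict[str, Path]:
    """Emit nodes.dmp / names.dmp / merged.dmp in the pipe-delimited dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    nodes_lines, names_lines = [], []
    for tid in sorted(db._nodes):
        node = db._nodes[tid]
        nodes_lines.append(f"{tid}\t|\t{node.parent}\t|\t{node.rank}\t|")
        names_lines.append(f"{tid}\t|\t{node.name or tid}\t|\t\t|\tscientific name\t|")
    paths["nodes"] = directory / "nodes.dmp"
    paths["nodes"].write_text("\n".join(nodes_lines) + "\n")
    paths["names"] = directory / "names.dmp"
    paths["names"].write_text("\n".join(names_lines) + "\n")
    merged_lines = [f"{old}\t|\t{new}\t|" for old, new in sorted(db.merged.items())]
    paths["merged"] = directory / "merged.dmp"
    paths["merged"].write_text("\n".join(merged_lines) + ("\n" if merged_lines else ""))
    return paths
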
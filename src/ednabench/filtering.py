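"""OTU / taxon count-table retention, censoring, collapsing and normalization.

Counts are integer sequence reads in a samples x taxa matrix with per-sample
metadata (sampler code, site, sampling method, initiation time in minutes,
optional grab replicate index) and per-taxon metadata (barcode locus, optional
taxonomy id or precomputed genus/family labels).

Filters implemented:

* run-wide minimum count (a conservative alternative to singleton removal,
  guarding against cross-talk and PCR artifacts inflating diversity),
* per-locus representative-sequence length windows,
* cross-talk censoring (taxa appearing only as scattered singletons are
  presumed sequencer cross-talk between multiplexed samples),
* rank collapsing (bacteria to family, eukaryotes to genus, with operational
  labels for rank-sparse lineages),
* top-N restriction by library-normalized abundance, and counts-per-million.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import Adjustment, TaxonomyDB, TaxonomyError

__all__ = [
    "CountMatrix",
    "LengthRule",
    "DEFAULT_LENGTH_RULES",
    "filter_min_run_count",
    "filter_length",
    "censor_crosstalk",
    "collapse_rank",
    "top_n_by_abundance",
    "to_cpm",
    "adjust_taxa",
]

logger = logging.getLogger(__name__)

SAMPLE_META_COLUMNS = ("sampler", "site", "method", "initiation_time_min", "replicate")


@dataclass
class CountMatrix:
    """Integer sequence counts (samples x taxa) with sample and taxon metadata."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    taxon_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValueError("duplicate sample names in count matrix")
        if c.columns.duplicated().any():
            raise ValueError("duplicate taxon labels in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.sample_meta is not None:
            missing = set(c.index) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def meta_for(self, samples: Sequence[str] | None = None) -> pd.DataFrame:
        if self.sample_meta is None:
            raise ValueError("count matrix has no sample metadata")
        return self.sample_meta.loc[list(samples) if samples is not None else self.counts.index]

    def select_taxa(self, labels: Sequence[str]) -> "CountMatrix":
        labels = [t for t in self.taxa if t in set(labels)]
        tm = self.taxon_meta.loc[labels] if self.taxon_meta is not None else None
        return CountMatrix(self.counts[labels], self.sample_meta, tm)

    def select_samples(self, names: Sequence[str]) -> "CountMatrix":
        names = list(names)
        sm = self.sample_meta.loc[names] if self.sample_meta is not None else None
        return CountMatrix(self.counts.loc[names], sm, self.taxon_meta)

    def select_locus(self, locus: str) -> "CountMatrix":
        if self.taxon_meta is None or "locus" not in self.taxon_meta.columns:
            raise ValueError("taxon metadata with a 'locus' column is required")
        return self.select_taxa(self.taxon_meta.index[self.taxon_meta["locus"] == locus])


def filter_min_run_count(
    matrix: CountMatrix, min_total: int = 10, return_report: bool = False
):
    """Drop taxa with fewer than ``min_total`` counts over the whole run."""
    totals = matrix.counts.sum(axis=0)
    keep = totals[totals >= min_total].index
    removed = totals[totals < min_total]
    if len(keep) == 0:
        logger.warning("all %d taxa below run-wide minimum %d", len(totals), min_total)
    elif len(removed):
        logger.info("min-run-count filter removed %d taxa", len(removed))
    out = matrix.select_taxa(keep)
    if return_report:
        return out, removed.rename("run_total").to_frame()
    return out


@dataclass(frozen=True)
class LengthRule:
    """Inclusive [min_len, max_len] window on representative-sequence length."""

    min_len: int
    max_len: int | None = None

    def accepts(self, length: int) -> bool:
        if length < self.min_len:
            return False
        return self.max_len is None or length <= self.max_len


#: COI representatives spanned 312-379 nt (window excludes none by design);
#: 16S requires >= 350 nt; the short 12S barcode requires > 75 and <= 170 nt.
DEFAULT_LENGTH_RULES: dict[str, LengthRule] = {
    "COI": LengthRule(312, 379),
    "16S-bact": LengthRule(350),
    "16S-euk": LengthRule(350),
    "16S": LengthRule(350),
    "12S": LengthRule(76, 170),
}


def filter_length(
    otu_lengths: Mapping[str, int],
    locus: str | Mapping[str, str],
    rules: Mapping[str, LengthRule] | None = None,
) -> set[str]:
    """Keep-set of OTU ids whose representative length passes the locus window.

    ``locus`` is either one locus tag for all OTUs or a per-OTU mapping.
    """
    rules = rules if rules is not None else DEFAULT_LENGTH_RULES
    get_locus = (lambda o: locus) if isinstance(locus, str) else (lambda o: locus[o])
    keep: set[str] = set()
    for otu, length in otu_lengths.items():
        loc = get_locus(otu)
        if loc not in rules:
            raise ValueError(f"no length rule for locus {loc!r}")
        if rules[loc].accepts(int(length)):
            keep.add(otu)
    return keep


def censor_crosstalk(
    matrix: CountMatrix, min_total: int = 10, return_report: bool = False
):
    """Remove taxa consistent with sequencer cross-talk between samples.

    A taxon is retained iff its run-wide total is >= ``min_total`` AND it has
    two or more reads in at least one sample (i.e. is not exclusively made of
    per-sample singletons).
    """
    totals = matrix.counts.sum(axis=0)
    maxima = matrix.counts.max(axis=0)
    keep = matrix.counts.columns[(totals >= min_total) & (maxima >= 2)]
    removed = matrix.counts.columns.difference(keep)
    if len(removed):
        logger.info("cross-talk censor removed %d taxa", len(removed))
    out = matrix.select_taxa(keep)
    if return_report:
        report = pd.DataFrame(
            {"run_total": totals[removed], "max_per_sample": maxima[removed]}
        )
        return out, report
    return out


def _collapse_label(
    label: str,
    target_rank: str,
    taxon_meta: pd.DataFrame | None,
    db: TaxonomyDB | None,
) -> str | None:
    if taxon_meta is not None and target_rank in taxon_meta.columns:
        val = taxon_meta.at[label, target_rank]
        if isinstance(val, str) and val:
            return val
    if db is not None and taxon_meta is not None and "taxon_id" in taxon_meta.columns:
        tid = taxon_meta.at[label, "taxon_id"]
        if not pd.isna(tid):
            tid = db.resolve(int(tid))
            if db.rank(tid) == target_rank:
                return db.name(tid) or str(tid)
            for anc in db.path_to_root(tid):
                if db.rank(anc) == target_rank:
                    return db.name(anc) or str(anc)
            if target_rank == "family":
                # rank-sparse bacterial lineages: operational family from genus
                for anc in db.path_to_root(tid):
                    if db.rank(anc) == "genus":
                        return f"{db.name(anc)} incertae sedis"
    if "BOLD:" in label and target_rank == "genus":
        # species-level labels referenced only by a barcode-database accession
        return label.replace(" sp. ", " genus ")
    return None


def collapse_rank(
    matrix: CountMatrix, target_rank: str, db: TaxonomyDB | None = None
) -> CountMatrix:
    """Sum counts within each taxon's ancestor at ``target_rank``.

    Group labels come from, in order: a precomputed ``target_rank`` column in
    the taxon metadata; the taxonomy ancestor of ``taxon_id``; an operational
    "<genus> incertae sedis" family for family-less lineages; an operational
    genus for species labels that carry only a barcode-database accession.
    Conserves per-sample totals exactly.
    """
    groups: dict[str, str] = {}
    offenders: list[str] = []
    for label in matrix.taxa:
        g = _collapse_label(label, target_rank, matrix.taxon_meta, db)
        if g is None:
            offenders.append(label)
        else:
            groups[label] = g
    if offenders:
        raise TaxonomyError(
            f"no {target_rank}-level ancestor or label for: {offenders[:10]}"
        )
    collapsed = matrix.counts.T.groupby(matrix.counts.columns.map(groups)).sum().T
    tm = None
    if matrix.taxon_meta is not None and "locus" in matrix.taxon_meta.columns:
        locus = matrix.taxon_meta["locus"].groupby(
            matrix.taxon_meta.index.map(groups)
        ).first()
        tm = pd.DataFrame({"locus": locus})
        tm = tm.loc[collapsed.columns]
    return CountMatrix(collapsed, matrix.sample_meta, tm)


def to_cpm(matrix: CountMatrix, drop_zero_samples: bool = True) -> pd.DataFrame:
    """Counts-per-million normalization: cell / sample total * 1e6."""
    totals = matrix.counts.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        if not drop_zero_samples:
            raise ValueError(f"zero-total samples: {list(zero)}")
        logger.warning("dropping %d zero-total samples: %s", len(zero), list(zero))
    keep = totals.index[totals > 0]
    sub = matrix.counts.loc[keep]
    return sub.div(totals[keep], axis=0) * 1e6


def top_n_by_abundance(matrix: CountMatrix, n: int = 150) -> CountMatrix:
    """Restrict to the ``n`` most abundant taxa by summed cpm.

    Ties at the boundary are broken lexicographically by label (first kept),
    for reproducibility.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= len(matrix.taxa):
        if n > len(matrix.taxa):
            logger.warning("top-n %d exceeds taxon count %d", n, len(matrix.taxa))
        return matrix
    score = to_cpm(matrix).sum(axis=0)
    order = sorted(score.index, key=lambda t: (-score[t], t))
    return matrix.select_taxa(order[:n])


def adjust_taxa(matrix: CountMatrix, adjustments: Sequence[Adjustment]) -> CountMatrix:
    """Apply ordered remove / rename / merge_into adjustments to taxon columns.

    ``merge_into`` pools counts under the target label; unmatched rules raise.
    """
    counts = matrix.counts.copy()
    tm = matrix.taxon_meta.copy() if matrix.taxon_meta is not None else None
    unmatched = []
    for adj in adjustments:
        label = str(adj.match)
        if label not in counts.columns:
            unmatched.append(adj)
            continue
        if adj.action == "remove":
            counts = counts.drop(columns=[label])
            if tm is not None:
                tm = tm.drop(index=label)
        elif adj.action == "rename":
            counts = counts.rename(columns={label: adj.target})
            if tm is not None:
                tm = tm.rename(index={label: adj.target})
        else:  # merge_into
            if adj.target in counts.columns:
                counts[adj.target] = counts[adj.target] + counts[label]
                counts = counts.drop(columns=[label])
                if tm is not None:
                    tm = tm.drop(index=label)
            else:
                counts = counts.rename(columns={label: adj.target})
                if tm is not None:
                    tm = tm.rename(index={label: adj.target})
    if unmatched:
        raise ValueError(
            "adjustments matched no taxon: " + ", ".join(repr(a.match) for a in unmatched)
        )
    return CountMatrix(counts, matrix.sample_meta, tm)
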
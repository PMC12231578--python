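"""Allele calling and parent-normalized allele tables.

Each whitelisted read is globally aligned to its target-site reference and
collapsed into an allele keyed by its exact sequence.  Per-allele edit
counts follow detailed-allele-table convention: ``n_inserted`` /
``n_deleted`` are total inserted/deleted bases, ``n_mutated`` is the
substitution count, and events within the leftmost ``exclude_left``
reference bases are ignored (they may carry amplification-primer
artifacts).  Tables then go through singleton removal (single-read alleles
are dominated by sequencing error), Parent-frequency subtraction and
replicate reconciliation, yielding the ``mean_norm_freq`` used by every
downstream statistic.  Frequencies are carried in percent throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignedPair, global_align
from .seqs import hamming

EXCLUDE_LEFT = 5        # reference bases excluded from edit counting, left end
MIN_READS_PER_TARGET = 10

_COLUMNS = ["target_id", "allele_seq", "n_inserted", "n_deleted", "n_mutated",
            "reads", "freq"]


@dataclass
class AlleleTable:
    """Per-target allele rows for one sample (or reconciled replicates).

    ``target_totals`` holds whitelisted read counts per target (summed over
    replicates after reconciliation), used by the coverage filter.
    """

    sample: str
    replicate: int | None
    df: pd.DataFrame
    target_totals: dict[str, int] = field(default_factory=dict)

    def copy(self) -> "AlleleTable":
        return AlleleTable(self.sample, self.replicate, self.df.copy(),
                           dict(self.target_totals))


@lru_cache(maxsize=200_000)
def _cached_align(query: str, reference: str) -> AlignedPair:
    return global_align(query, reference)


def call_allele(alignment: AlignedPair, exclude_left: int = EXCLUDE_LEFT
                ) -> tuple[int, int, int]:
    """(n_inserted, n_deleted, n_mutated) from a global alignment.

    Events whose reference coordinate falls within the leftmost
    ``exclude_left`` bases are not counted; the rest of the amplicon is
    quantified in full (no right-side exclusion).
    """
    n_ins = n_del = n_mut = 0
    for ref_pos, kind, ref, alt in alignment.edit_ops():
        if ref_pos < exclude_left:
            continue
        if kind == "sub":
            n_mut += 1
        elif kind == "ins":
            n_ins += len(alt)
        elif kind == "del":
            n_del += len(ref)
    return n_ins, n_del, n_mut


def is_indel_free(query: str, reference: str) -> bool:
    """True iff the optimal global alignment contains no gaps.

    Fast path: equal-length sequences within Hamming distance 2 are always
    optimally aligned without gaps under the adopted scoring (converting two
    mismatches to matches gains at most 18 < 20, the cost of the cheapest
    insertion+deletion pair).
    """
    if len(query) == len(reference) and hamming(query, reference) <= 2:
        return True
    aln = _cached_align(query, reference)
    return "-" not in aln.ref_row and "-" not in aln.query_row


def _edit_counts(query: str, reference: str,
                 exclude_left: int) -> tuple[int, int, int]:
    if query == reference:
        return 0, 0, 0
    if len(query) == len(reference) and hamming(query, reference) <= 2:
        n_mut = sum(q != r and i >= exclude_left
                    for i, (q, r) in enumerate(zip(query, reference)))
        return 0, 0, n_mut
    return call_allele(_cached_align(query, reference), exclude_left)


def tabulate(
    reads_df: pd.DataFrame,
    references: Mapping[str, str],
    sample: str,
    replicate: int,
    min_reads_per_target: int = MIN_READS_PER_TARGET,
    exclude_left: int = EXCLUDE_LEFT,
) -> AlleleTable:
    """Group whitelisted reads into alleles and compute raw frequencies.

    ``reads_df`` needs columns ``target_id`` and ``seq``.  Targets with
    fewer than ``min_reads_per_target`` reads are omitted.  Within each
    retained target, freq = 100 x reads / total reads.
    """
    rows = []
    totals: dict[str, int] = {}
    if not reads_df.empty:
        for target_id, grp in reads_df.groupby("target_id", sort=True):
            total = len(grp)
            totals[str(target_id)] = total
            if total < min_reads_per_target:
                continue
            ref = references[target_id]
            for seq, count in grp["seq"].value_counts().items():
                n_ins, n_del, n_mut = _edit_counts(seq, ref, exclude_left)
                rows.append((target_id, seq, n_ins, n_del, n_mut,
                             int(count), 100.0 * count / total))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return AlleleTable(sample, replicate, df, totals)


def drop_singletons_renormalize(table: AlleleTable) -> AlleleTable:
    """Remove single-read alleles and recompute frequencies per target."""
    df = table.df[table.df["reads"] > 1].copy()
    out = []
    for target_id, grp in df.groupby("target_id", sort=True):
        total = grp["reads"].sum()
        if total == 0:
            continue
        grp = grp.copy()
        grp["freq"] = 100.0 * grp["reads"] / total
        out.append(grp)
    new_df = pd.concat(out, ignore_index=True) if out else df.iloc[0:0].copy()
    return AlleleTable(table.sample, table.replicate, new_df,
                       dict(table.target_totals))


def subtract_parent(sample_table: AlleleTable, parent_table: AlleleTable) -> AlleleTable:
    """Per-replicate parent normalization.

    ``norm_freq = max(0, freq - parent_freq)`` matching alleles by exact
    sequence within a target; alleles absent from the Parent subtract 0,
    and Parent-only alleles contribute no row.
    """
    if sample_table.replicate != parent_table.replicate:
        raise ValueError("parent and sample tables must share a replicate")
    parent_freq = {
        (t, a): f for t, a, f in zip(parent_table.df["target_id"],
                                     parent_table.df["allele_seq"],
                                     parent_table.df["freq"])
    }
    df = sample_table.df.copy()
    if not df.empty:
        parent_targets = set(parent_table.df["target_id"])
        missing = set(df["target_id"]) - parent_targets
        if missing:
            import warnings
            warnings.warn(
                f"{len(missing)} target(s) absent from Parent table; "
                "subtracting 0")
        pf = [parent_freq.get((t, a), 0.0)
              for t, a in zip(df["target_id"], df["allele_seq"])]
        df["norm_freq"] = np.maximum(0.0, df["freq"] - np.asarray(pf))
    else:
        df["norm_freq"] = pd.Series(dtype=float)
    return AlleleTable(sample_table.sample, sample_table.replicate, df,
                       dict(sample_table.target_totals))


def reconcile_replicates(tables: Sequence[AlleleTable]) -> AlleleTable:
    """Union alleles across replicates; missing-in-replicate means 0.

    ``mean_norm_freq`` averages the per-replicate normalized frequencies
    over all replicates.  Per-target read totals are summed across
    replicates (the coverage filter operates on that sum).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 replicates to reconcile")
    reps = [t.replicate for t in tables]
    if len(set(reps)) != len(reps):
        raise ValueError("duplicate replicate ids")
    frames = []
    for t in tables:
        f = t.df[["target_id", "allele_seq", "n_inserted", "n_deleted",
                  "n_mutated", "reads", "norm_freq"]].copy()
        f["replicate"] = t.replicate
        frames.append(f)
    allf = pd.concat(frames, ignore_index=True)
    n_reps = len(tables)
    if allf.empty:
        df = pd.DataFrame(columns=_COLUMNS[:5] + ["mean_norm_freq"])
    else:
        grouped = allf.groupby(["target_id", "allele_seq"], sort=True).agg(
            n_inserted=("n_inserted", "first"),
            n_deleted=("n_deleted", "first"),
            n_mutated=("n_mutated", "first"),
            reads=("reads", "sum"),
            sum_norm=("norm_freq", "sum"),
        ).reset_index()
        grouped["mean_norm_freq"] = grouped["sum_norm"] / n_reps
        df = grouped.drop(columns="sum_norm")
    totals: dict[str, int] = {}
    for t in tables:
        for tid, n in t.target_totals.items():
            totals[tid] = totals.get(tid, 0) + n
    return AlleleTable(tables[0].sample, None, df, totals)


def write_allele_table(table: AlleleTable, path: Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_allele_table(path: Path, sample: str = "",
                      replicate: int | None = None) -> AlleleTable:
    df = pd.read_csv(path, sep="\t")
    return AlleleTable(sample, replicate, df, {})
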
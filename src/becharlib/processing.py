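"""Read assignment, UMI extraction and triplet whitelist filtering.

Reads are assigned to their sgRNA (Read 2, exact or one-mismatch match to a
protospacer) and target site (Read 1 after UMI extraction, best local
alignment), then pass three filters: (1) unassignable target reads are
dropped, (2) improperly paired sgRNA/target reads are dropped, (3) reads are
grouped into (sgRNA, target, UMI) triplets and only triplets whitelisted in
the matching replicate's Parent sample are retained.  A triplet enters the
whitelist when strictly more than 90% of its Parent reads are free of
insertions/deletions — UMIs tag individual integrated cassettes, so a
Parent triplet rich in indels marks a cassette damaged during synthesis or
cloning, not an editing outcome.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import local_score
from .library import SgRNATargetPair
from .quantify import is_indel_free
from .seqs import hamming

WHITELIST_CLEAN_FRACTION = 0.90  # strict > ; share of indel-free Parent reads
MIN_PARENT_READS = 2             # triplet eligibility floor in the Parent
SCORE_FLOOR_FACTOR = 1.2         # x read length; local score floor (match=+2)
QC_UMI_THRESHOLD = 5             # strict > ; acceptable UMIs per pair


@dataclass(frozen=True)
class Triplet:
    """(sgRNA, target site, UMI) key — the unit of whitelist filtering."""

    sgrna_id: str
    target_id: str
    umi: str


@dataclass
class Whitelist:
    """Parent-derived set of acceptable triplets for one replicate."""

    accepted: set[Triplet]
    replicate: int

    def umi_counts(self) -> dict[str, int]:
        """Acceptable-UMI count per target pair."""
        counts: Counter[str] = Counter(t.target_id for t in self.accepted)
        return dict(counts)


def extract_umi(read1: str, umi_length: int = 7, primer: str = "") -> tuple[str, str] | None:
    """Split Read 1 into (UMI, trimmed target read).

    An optional fixed amplification-primer prefix is removed after the UMI.
    Returns None (drop) if the read is not longer than the UMI.
    """
    if len(read1) <= umi_length:
        return None
    umi, rest = read1[:umi_length], read1[umi_length:]
    if primer and rest.startswith(primer):
        rest = rest[len(primer):]
    return umi, rest


def assign_sgrna(read2: str, index: Mapping[str, str]) -> str | None:
    """Assign Read 2 to a protospacer allowing one mismatch.

    ``index`` maps protospacer sequence -> sgRNA id.  Returns None when no
    protospacer, or more than one, lies within Hamming distance 1.
    """
    hit = index.get(read2)
    if hit is not None:
        return hit
    candidates = [sid for proto, sid in index.items()
                  if len(proto) == len(read2) and hamming(proto, read2) <= 1]
    return candidates[0] if len(candidates) == 1 else None


class TargetIndex:
    """k-mer-seeded local-alignment assignment of target-site reads.

    Exact seed matches nominate candidate references; the best local
    alignment wins if its score clears ``SCORE_FLOOR_FACTOR x read length``
    and is not tied between references (ambiguity -> unassigned, since a
    misassigned read inflates apparent editing).
    """

    def __init__(self, references: Mapping[str, str], k: int = 16):
        if not references:
            raise ValueError("references must be nonempty")
        self.references = dict(references)
        self.k = k
        self._seeds: dict[str, set[str]] = defaultdict(set)
        for tid, seq in self.references.items():
            for i in range(0, len(seq) - k + 1, 4):
                self._seeds[seq[i:i + k]].add(tid)

    def _candidates(self, read: str) -> set[str]:
        cands: set[str] = set()
        step = max(1, (len(read) - self.k) // 8)
        for i in range(0, max(1, len(read) - self.k + 1), step):
            cands |= self._seeds.get(read[i:i + self.k], set())
        return cands or set(self.references)

    def assign(self, read: str) -> str | None:
        if not read:
            return None
        floor = SCORE_FLOOR_FACTOR * len(read)
        best_id, best, runner_up = None, float("-inf"), float("-inf")
        for tid in sorted(self._candidates(read)):
            score = local_score(read, self.references[tid])
            if score > best:
                best_id, runner_up, best = tid, best, score
            elif score > runner_up:
                runner_up = score
        if best < floor or best == runner_up:
            return None
        return best_id


def assign_target(trimmed_read1: str, index: TargetIndex) -> str | None:
    """Best-local-alignment target assignment (see :class:`TargetIndex`)."""
    return index.assign(trimmed_read1)


def check_pairing(sgrna_id: str, target_id: str, designed: Mapping[str, str]) -> bool:
    """True iff ``sgrna_id`` is the sgRNA designed for ``target_id``."""
    if target_id not in designed:
        raise ValueError(f"unknown target id: {target_id}")
    if sgrna_id not in set(designed.values()):
        raise ValueError(f"unknown sgRNA id: {sgrna_id}")
    return designed[target_id] == sgrna_id


@dataclass
class ProcessedReads:
    """Assigned, filtered reads for one sample/replicate plus drop log."""

    sample: str
    replicate: int
    df: pd.DataFrame  # read_id, sgrna_id, target_id, umi, seq
    drop_counts: dict[str, int] = field(default_factory=dict)

    def triplets(self) -> pd.Series:
        return self.df.apply(
            lambda r: Triplet(r.sgrna_id, r.target_id, r.umi), axis=1)


def process_reads(
    reads: Iterable[tuple[str, str, str]],
    library: Sequence[SgRNATargetPair],
    sample: str,
    replicate: int,
    umi_length: int = 7,
    primer: str = "",
    target_index: TargetIndex | None = None,
) -> ProcessedReads:
    """Run UMI extraction, sgRNA/target assignment and the pairing filter.

    Every dropped read is counted under exactly one reason
    (``short_read`` / ``unassigned_target`` / ``unassigned_sgrna`` /
    ``improper_pair``).
    """
    sgrna_index = {p.protospacer: p.pair_id for p in library}
    designed = {p.pair_id: p.pair_id for p in library}
    if target_index is None:
        target_index = TargetIndex({p.pair_id: p.target_site for p in library})

    drops: Counter[str] = Counter()
    rows = []
    target_cache: dict[str, str | None] = {}
    sgrna_cache: dict[str, str | None] = {}
    for read_id, r1, r2 in reads:
        ext = extract_umi(r1, umi_length, primer)
        if ext is None:
            drops["short_read"] += 1
            continue
        umi, trimmed = ext
        if trimmed not in target_cache:
            target_cache[trimmed] = assign_target(trimmed, target_index)
        target_id = target_cache[trimmed]
        if target_id is None:
            drops["unassigned_target"] += 1
            continue
        if r2 not in sgrna_cache:
            sgrna_cache[r2] = assign_sgrna(r2, sgrna_index)
        sgrna_id = sgrna_cache[r2]
        if sgrna_id is None:
            drops["unassigned_sgrna"] += 1
            continue
        if not check_pairing(sgrna_id, target_id, designed):
            drops["improper_pair"] += 1
            continue
        rows.append((read_id, sgrna_id, target_id, umi, trimmed))
    df = pd.DataFrame(rows, columns=["read_id", "sgrna_id", "target_id", "umi", "seq"])
    return ProcessedReads(sample, replicate, df, dict(drops))


def build_whitelist(
    parent: ProcessedReads,
    references: Mapping[str, str],
    clean_fraction: float = WHITELIST_CLEAN_FRACTION,
    min_reads: int = MIN_PARENT_READS,
) -> Whitelist:
    """Whitelist triplets whose Parent reads are >90% indel-free.

    Indel presence is determined by the allele-calling global alignment.
    Triplets with fewer than ``min_reads`` Parent reads are ineligible.
    """
    accepted: set[Triplet] = set()
    if parent.df.empty:
        import warnings
        warnings.warn("empty Parent sample: whitelist is empty")
        return Whitelist(accepted, parent.replicate)
    clean_cache: dict[tuple[str, str], bool] = {}
    grouped = parent.df.groupby(["sgrna_id", "target_id", "umi"], sort=False)
    for (sgrna_id, target_id, umi), grp in grouped:
        total = len(grp)
        if total < min_reads:
            continue
        ref = references[target_id]
        clean = 0
        for seq in grp["seq"]:
            key = (target_id, seq)
            if key not in clean_cache:
                clean_cache[key] = is_indel_free(seq, ref)
            clean += clean_cache[key]
        if clean / total > clean_fraction:  # strict >
            accepted.add(Triplet(sgrna_id, target_id, umi))
    return Whitelist(accepted, parent.replicate)


def apply_whitelist(sample: ProcessedReads, wl: Whitelist) -> ProcessedReads:
    """Retain only reads whose triplet is in the same replicate's whitelist."""
    if sample.replicate != wl.replicate:
        raise ValueError(
            f"whitelist from replicate {wl.replicate} cannot filter "
            f"replicate {sample.replicate}")
    if sample.df.empty:
        return ProcessedReads(sample.sample, sample.replicate, sample.df.copy(),
                              dict(sample.drop_counts))
    keys = set(wl.accepted)
    mask = [Triplet(s, t, u) in keys
            for s, t, u in zip(sample.df.sgrna_id, sample.df.target_id, sample.df.umi)]
    kept = sample.df[mask].reset_index(drop=True)
    drops = dict(sample.drop_counts)
    drops["not_whitelisted"] = int(len(sample.df) - len(kept))
    return ProcessedReads(sample.sample, sample.replicate, kept, drops)


def qc_umi_coverage(wl: Whitelist, library: Sequence[SgRNATargetPair]) -> pd.DataFrame:
    """Acceptable-UMI count per pair; ``covered`` marks pairs with >5 UMIs.

    The returned frame carries the covered fraction in ``attrs['fraction_covered']``.
    """
    counts = wl.umi_counts()
    df = pd.DataFrame({
        "pair_id": [p.pair_id for p in library],
        "n_acceptable_umis": [counts.get(p.pair_id, 0) for p in library],
    })
    df["covered"] = df["n_acceptable_umis"] > QC_UMI_THRESHOLD  # strict >
    df.attrs["fraction_covered"] = float(df["covered"].mean()) if len(df) else 0.0
    return df
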
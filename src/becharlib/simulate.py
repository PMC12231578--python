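"""Generative model for Parent and base-editor sequencing samples.

The simulator reproduces the statistical structure of a paired
sgRNA-target-site screen read out by amplicon sequencing:

* every (pair, UMI) combination represents one integrated cassette in a cell
  clone; the Parent sample sequences the unedited cassette, an editor sample
  sequences the cassette after exposure to the editor;
* editing happens once at the molecule level (heritable), sequencing error is
  applied independently to every read of that molecule;
* a deamination event picks a cytidine within the editor's PAM-relative
  window, biased by a sequence-context (motif) weight; with relative rate
  ``comp_ratio`` it instead deaminates a cytidine on the target strand (the
  strand annealing to the sgRNA), which the sequencer sees as a G>N change;
* the outcome base follows the editor's C>T:C>A:C>G spectrum, and an indel
  may be introduced with probability ``indel_rate``.

Read structure mirrors the screen's sequencing design: Read 1 = 7-nt UMI
followed by the target-site allele, Read 2 = the 20-nt sgRNA protospacer.
Ground truth is recorded per molecule so that every downstream statistic has
an independent recovery target.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library import SgRNATargetPair
from .seqs import iupac_match, random_dna, revcomp

_BYTE_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class EditorProfile:
    """Generative parameters of a simulated base editor.

    ``window_weights`` maps PAM-relative positions (PAM "N" = 0, protospacer
    -20..-1) to nonnegative sampling weights.  ``spectrum`` gives the
    C>T, C>A, C>G outcome probabilities (must sum to 1).  ``comp_ratio`` is
    the relative rate of target-strand deamination (0 disables it).
    ``motif_weights`` are (IUPAC 7-mer centred on the edited C, weight)
    pairs applied multiplicatively; first match wins, default weight 1.
    """

    name: str
    window_weights: Mapping[int, float]
    efficiency: float
    spectrum: tuple[float, float, float]
    comp_ratio: float = 0.0
    motif_weights: tuple[tuple[str, float], ...] = (("NWRCNNN", 3.0),)
    edits_per_allele: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.25, 3: 0.05})
    indel_rate: float = 0.0
    indel_size_dist: Mapping[int, float] = field(
        default_factory=lambda: {-2: 0.2, -1: 0.5, 1: 0.2, 2: 0.1})

    def __post_init__(self) -> None:
        if abs(sum(self.spectrum) - 1.0) > 1e-9:
            raise ValueError("spectrum must sum to 1")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        if any(w < 0 for w in self.window_weights.values()):
            raise ValueError("window weights must be >= 0")

    def motif_weight(self, context7: str) -> float:
        """Multiplicative weight for a 7-mer context centred on the edited C."""
        for pattern, weight in self.motif_weights:
            if len(context7) == 7 and all(
                iupac_match(b, c) for b, c in zip(context7, pattern)
            ):
                return weight
        return 1.0


@dataclass(frozen=True)
class SequencingModel:
    """Read-level error and depth model."""

    substitution_error_rate: float = 0.001
    position_ramp: float = 1.0  # error multiplier at the last cycle (linear)
    depth_per_triplet: float = 200.0
    umis_per_pair: int = 10
    umi_length: int = 7
    read1_cycles: int = 139  # UMI + up to 132 target bases
    read2_cycles: int = 20   # sgRNA protospacer (21 cycles, last base trimmed)

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated molecule (one pair-UMI cassette)."""

    pair_id: str
    umi: str
    molecule_id: str
    # each edit: (PAM-relative pos, ref base, alt base, deaminated strand)
    edits: tuple[tuple[int, str, str, str], ...]
    indel: str  # "" or e.g. "-12:del:AC" / "-10:ins:GT"

    @property
    def is_edited(self) -> bool:
        return bool(self.edits) or bool(self.indel)


@dataclass
class SimulatedSample:
    """In-memory FASTQ pair plus molecule-level ground truth."""

    name: str
    replicate: int
    reads: list[tuple[str, str, str]]  # (read_id, read1, read2)
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append({
                "pair_id": t.pair_id,
                "umi": t.umi,
                "molecule_id": t.molecule_id,
                "edits": ";".join(f"{p}:{r}>{a}:{s}" for p, r, a, s in t.edits),
                "indel": t.indel,
            })
        return pd.DataFrame(
            rows, columns=["pair_id", "umi", "molecule_id", "edits", "indel"])


def _spectrum_outcome(ref: str, cls: int) -> str:
    """Outcome base for spectrum class (0=C>T, 1=C>A, 2=C>G) at a C, or the
    complementary change at a G (target-strand deamination)."""
    if ref == "C":
        return "TAG"[cls]
    return "ATC"[cls]  # G>A, G>T, G>C mirror C>T, C>A, C>G


def draw_edited_molecule(
    pair: SgRNATargetPair,
    profile: EditorProfile,
    rng: np.random.Generator,
    umi: str = "",
    molecule_id: str = "",
) -> tuple[str, TruthRecord]:
    """Draw one molecule after editor exposure.

    Returns the allele in sequenced (top-strand) orientation plus its truth
    record.  Negative-control pairs bypass editing (the scrambled site cannot
    recruit the editor).  If the window contains no eligible cytidine the
    molecule is returned unedited.
    """
    site = pair.harmonized_site
    pam = pair.pam_start
    empty = TruthRecord(pair.pair_id, umi, molecule_id, (), "")

    if pair.is_negative_control or rng.random() >= profile.efficiency:
        return pair.target_site, empty

    positions: list[int] = []
    strands: list[str] = []
    weights: list[float] = []
    for pos, w in profile.window_weights.items():
        if w <= 0:
            continue
        idx = pam + pos
        if not 0 <= idx < len(site):
            continue
        base = site[idx]
        ctx = site[max(0, idx - 3): idx + 4] if idx >= 3 else ""
        if base == "C":
            positions.append(pos)
            strands.append("nontarget")
            weights.append(w * profile.motif_weight(ctx))
        elif base == "G" and profile.comp_ratio > 0:
            # cytidine on the target strand; context read on that strand
            positions.append(pos)
            strands.append("target")
            weights.append(w * profile.comp_ratio
                           * profile.motif_weight(revcomp(ctx) if len(ctx) == 7 else ""))

    edits: list[tuple[int, str, str, str]] = []
    mutable = list(site)
    if positions:
        ks = np.array(sorted(profile.edits_per_allele))
        kp = np.array([profile.edits_per_allele[k] for k in ks], dtype=float)
        k = int(rng.choice(ks, p=kp / kp.sum()))
        k = min(k, len(positions))
        wv = np.asarray(weights, dtype=float)
        chosen = rng.choice(len(positions), size=k, replace=False, p=wv / wv.sum())
        for ci in sorted(int(c) for c in chosen):
            pos, strand = positions[ci], strands[ci]
            idx = pam + pos
            ref = mutable[idx]
            cls = int(rng.choice(3, p=np.asarray(profile.spectrum)))
            alt = _spectrum_outcome(ref, cls)
            mutable[idx] = alt
            edits.append((pos, ref, alt, strand))

    indel_desc = ""
    if profile.indel_rate > 0 and rng.random() < profile.indel_rate:
        sizes = np.array(sorted(profile.indel_size_dist))
        sp = np.array([profile.indel_size_dist[s] for s in sizes], dtype=float)
        size = int(rng.choice(sizes, p=sp / sp.sum()))
        support = [p for p, w in profile.window_weights.items() if w > 0]
        pos = int(rng.choice(support)) if support else 0
        idx = min(max(pam + pos, 1), len(mutable) - 1)
        if size < 0:
            removed = "".join(mutable[idx: idx - size])
            del mutable[idx: idx - size]
            indel_desc = f"{pos}:del:{removed}"
        else:
            inserted = random_dna(size, 0.5, rng)
            mutable[idx:idx] = list(inserted)
            indel_desc = f"{pos}:ins:{inserted}"

    truth = TruthRecord(pair.pair_id, umi, molecule_id, tuple(edits), indel_desc)
    allele = "".join(mutable)
    if pair.strand == "bottom":
        allele = revcomp(allele)
    return allele, truth


def draw_umi_map(
    library: Sequence[SgRNATargetPair],
    umis_per_pair: int,
    umi_length: int,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Draw distinct UMIs per pair (collisions across pairs are allowed;
    the whitelist is keyed on the full triplet)."""
    umi_map: dict[str, list[str]] = {}
    for pair in library:
        seen: set[str] = set()
        while len(seen) < umis_per_pair:
            seen.add(random_dna(umi_length, 0.5, rng))
        umi_map[pair.pair_id] = sorted(seen)
    return umi_map


def _sequence_reads(molecule: str, depth: int, model: SequencingModel,
                    rng: np.random.Generator) -> list[str]:
    """Emit ``depth`` reads of ``molecule`` with per-base substitution error
    (optionally ramped along the read)."""
    if depth == 0:
        return []
    arr = np.frombuffer(molecule.encode(), dtype=np.uint8)
    length = arr.size
    rate = model.substitution_error_rate
    if rate == 0:
        return [molecule] * depth
    probs = np.full(length, rate)
    if model.position_ramp != 1.0 and length > 1:
        probs *= np.linspace(1.0, model.position_ramp, length)
    mask = rng.random((depth, length)) < probs
    tiled = np.tile(arr, (depth, 1))
    n_err = int(mask.sum())
    if n_err:
        # replace with one of the three other bases, uniformly
        cur = tiled[mask]
        shift = rng.integers(1, 4, size=n_err)
        code = np.searchsorted(_BYTE_BASES, cur)  # ACGT are sorted bytes
        tiled[mask] = _BYTE_BASES[(code + shift) % 4]
    return [row.tobytes().decode() for row in tiled]


def simulate_sample(
    library: Sequence[SgRNATargetPair],
    profile: EditorProfile | None,
    seq_model: SequencingModel,
    replicate_id: int,
    rng: np.random.Generator,
    umi_map: Mapping[str, Sequence[str]] | None = None,
    name: str | None = None,
) -> SimulatedSample:
    """Simulate one sample (Parent if ``profile`` is None).

    ``umi_map`` fixes the per-pair UMI assignment; pass the same map for the
    Parent and editor samples of a replicate, since they sequence the same
    integrated cassette library.
    """
    if not library:
        raise ValueError("library must be nonempty")
    if umi_map is None:
        umi_map = draw_umi_map(library, seq_model.umis_per_pair,
                               seq_model.umi_length, rng)
    sample_name = name or (profile.name if profile else "Parent")
    reads: list[tuple[str, str, str]] = []
    truths: list[TruthRecord] = []
    for pair in library:
        for umi in umi_map[pair.pair_id]:
            mol_id = f"{pair.pair_id}:{umi}"
            if profile is None:
                allele, truth = pair.target_site, TruthRecord(
                    pair.pair_id, umi, mol_id, (), "")
            else:
                allele, truth = draw_edited_molecule(
                    pair, profile, rng, umi=umi, molecule_id=mol_id)
            truths.append(truth)
            depth = int(rng.poisson(seq_model.depth_per_triplet))
            template1 = (umi + allele)[: seq_model.read1_cycles]
            template2 = pair.protospacer[: seq_model.read2_cycles]
            read1s = _sequence_reads(template1, depth, seq_model, rng)
            read2s = _sequence_reads(template2, depth, seq_model, rng)
            for i, (r1, r2) in enumerate(zip(read1s, read2s)):
                reads.append((f"{sample_name}.r{replicate_id}.{mol_id}.{i}", r1, r2))
    return SimulatedSample(sample_name, replicate_id, reads, truths)


# ---------------------------------------------------------------------------
# ground-truth summaries (parameter-recovery targets)

@dataclass
class TruthSummary:
    """Statistics computed from ground truth alone."""

    per_target_efficiency: dict[str, float]  # percent of molecules modified
    aggregate: dict[int, float]              # summed per-target edited fractions
    spectrum: tuple[float, float, float]     # C>T : C>A : C>G proportions
    comp_fraction: float                     # target-strand share of events
    window_support: tuple[int, int] | None   # min/max edited position
    n_events: int                            # total deamination events


def truth_summary(truths: Iterable[TruthRecord],
                  library: Sequence[SgRNATargetPair]) -> TruthSummary:
    """Recovery targets for the characterization stage, straight from truth."""
    by_target: dict[str, list[TruthRecord]] = {p.pair_id: [] for p in library}
    for t in truths:
        by_target.setdefault(t.pair_id, []).append(t)

    eff: dict[str, float] = {}
    agg: dict[int, float] = {}
    spec_counts = np.zeros(3)
    n_target_strand = 0
    n_events = 0
    positions: list[int] = []
    for pid, recs in by_target.items():
        n = len(recs)
        if n == 0:
            continue
        eff[pid] = 100.0 * sum(t.is_edited for t in recs) / n
        pos_counts: dict[int, int] = {}
        for t in recs:
            for pos, ref, alt, strand in t.edits:
                pos_counts[pos] = pos_counts.get(pos, 0) + 1
                positions.append(pos)
                n_events += 1
                if strand == "target":
                    n_target_strand += 1
                    base_change = {"A": 0, "T": 1, "C": 2}.get(alt)
                else:
                    base_change = {"T": 0, "A": 1, "G": 2}.get(alt)
                if base_change is not None:
                    spec_counts[base_change] += 1
        for pos, c in pos_counts.items():
            agg[pos] = agg.get(pos, 0.0) + c / n
    spectrum = tuple(spec_counts / spec_counts.sum()) if spec_counts.sum() else (0.0, 0.0, 0.0)
    support = (min(positions), max(positions)) if positions else None
    return TruthSummary(eff, agg, spectrum,
                        n_target_strand / n_events if n_events else 0.0,
                        support, n_events)


# ---------------------------------------------------------------------------
# presets and file output

def preset_profiles() -> dict[str, EditorProfile]:
    """Named editor presets spanning the qualitative editor classes:
    an aptamer-recruited wide-window editor, N-terminal fusions with and
    without target-strand editing, a high-indel nickase fusion, a narrow
    -18..-13 window editor, and an inactive-deaminase control."""
    spec = (67 / 101, 16 / 101, 18 / 101)  # C>T:C>A:C>G, normalized
    wide = {p: float(np.exp(-((p + 15) ** 2) / (2 * 15.0 ** 2)))
            for p in range(-45, 26)}
    mid = {p: float(np.exp(-((p + 14) ** 2) / (2 * 6.0 ** 2)))
           for p in range(-30, 6)}
    narrow = {p: 1.0 for p in range(-18, -12)}
    return {
        "aptamer_wide": EditorProfile(
            name="aptamer_wide", window_weights=wide, efficiency=0.15,
            spectrum=spec, comp_ratio=0.3, indel_rate=0.01),
        "nterm_fusion": EditorProfile(
            name="nterm_fusion", window_weights=mid, efficiency=0.45,
            spectrum=spec, comp_ratio=0.5, indel_rate=0.02),
        "nickase_fusion": EditorProfile(
            name="nickase_fusion",
            window_weights={p - 2: w for p, w in mid.items()},
            efficiency=0.5, spectrum=spec, comp_ratio=0.5,
            indel_rate=0.15),
        "narrow_window": EditorProfile(
            name="narrow_window", window_weights=narrow, efficiency=0.3,
            spectrum=spec, comp_ratio=0.0, indel_rate=0.02),
        "dead_deaminase": EditorProfile(
            name="dead_deaminase", window_weights=wide, efficiency=0.0,
            spectrum=(1.0, 0.0, 0.0)),
    }


def write_fastq_pair(sample: SimulatedSample, r1_path: Path, r2_path: Path) -> None:
    """Write the sample's reads as a gzipped FASTQ pair (constant quality)."""
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for read_id, r1, r2 in sample.reads:
            f1.write(f"@{read_id}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{read_id}\n{r2}\n+\n{'I' * len(r2)}\n")


def read_fastq_pair(r1_path: Path, r2_path: Path) -> list[tuple[str, str, str]]:
    """Read a gzipped FASTQ pair back into (read_id, read1, read2) tuples."""
    from Bio import SeqIO

    def _records(path):
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as handle:
            for rec in SeqIO.parse(handle, "fastq"):
                yield rec.id, str(rec.seq)

    reads = []
    for (id1, s1), (id2, s2) in zip(_records(r1_path), _records(r2_path)):
        if id1 != id2:
            raise ValueError(f"unpaired reads: {id1} vs {id2}")
        reads.append((id1, s1, s2))
    return reads
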
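"""Editor characterization statistics on normalized allele tables.

All statistics operate in a harmonized coordinate frame: target sites whose
sgRNA targets the bottom strand are reverse-complemented so every site reads
protospacer-forward, the PAM "N" is position 0 (GG at +1/+2) and the
protospacer occupies -20..-1.  In this frame a cytidine edit on the
displaced (non-target) strand appears as C>N and a cytidine edit on the
sgRNA-annealing (target) strand appears as G>N, termed complementary C>N
(CompC>N).

The statistics mirror the screen's analysis definitions:

* editing efficiency: per-target sum of normalized frequencies of modified
  alleles above 0.5%, optionally restricted to indel, C>N, CompC>N or
  window-defined allele classes;
* Aggregate Editing: per-position sum of substitution-record frequencies
  divided by 100, with a mu + 2*sigma cutoff from an inactive-deaminase
  control defining which positions count as edited;
* editing window: left- and right-most positions whose Aggregate Editing
  exceeds the cutoff;
* spectrum/purity: Aggregate Editing pooled by reference base and outcome;
* motif enrichment score: log2 likelihood ratio of a motif under the
  frequency-weighted 7-mer PWM around edited bases versus a GC-matched
  background;
* diversification: allele counts above 0.5% and Shannon entropy (nats)
  including the unmodified reference allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import global_align
from .library import SgRNATargetPair
from .quantify import EXCLUDE_LEFT, AlleleTable
from .seqs import IUPAC, revcomp

ALLELE_FREQ_CUTOFF = 0.5     # percent; strict >
MIN_TARGET_READS = 200       # summed across replicates; strict <200 removed
NARROW_WINDOW = (-18, -13)   # BE3-like window used for the in/out split
WINDOW_CUTOFF_SPLIT = 0.25   # strand-split analyses (aptamer recruitment)
WINDOW_CUTOFF_COMBINED = 0.5  # direct-fusion analyses (strands combined)

_BASES = ("A", "C", "G", "T")


def _freq_col(df: pd.DataFrame) -> str:
    for col in ("mean_norm_freq", "norm_freq", "freq"):
        if col in df.columns:
            return col
    raise ValueError("no frequency column in allele table")


# ---------------------------------------------------------------------------
# filters and harmonization

def coverage_filter(table: AlleleTable, min_reads: int = MIN_TARGET_READS) -> AlleleTable:
    """Drop targets with fewer than ``min_reads`` reads summed across
    replicates (boundary: exactly ``min_reads`` is retained)."""
    keep = {tid for tid, n in table.target_totals.items() if n >= min_reads}
    df = table.df[table.df["target_id"].isin(keep)].reset_index(drop=True)
    totals = {tid: n for tid, n in table.target_totals.items() if tid in keep}
    out = table.copy()
    out.df, out.target_totals = df, totals
    return out


def harmonize_strand(table: AlleleTable, library: Sequence[SgRNATargetPair]) -> AlleleTable:
    """Reverse-complement bottom-strand targets' alleles into the
    sgRNA-top orientation.  Idempotent."""
    out = table.copy()
    if out.df.attrs.get("harmonized"):
        return out
    strand = {p.pair_id: p.strand for p in library}
    unknown = set(out.df["target_id"]) - set(strand)
    if unknown:
        raise ValueError(f"targets not in library manifest: {sorted(unknown)[:3]}")
    out.df["allele_seq"] = [
        revcomp(seq) if strand[tid] == "bottom" else seq
        for tid, seq in zip(out.df["target_id"], out.df["allele_seq"])
    ]
    out.df.attrs["harmonized"] = True
    return out


# ---------------------------------------------------------------------------
# substitution records

def substitution_records(
    table: AlleleTable,
    library: Sequence[SgRNATargetPair],
    freq_cutoff: float = ALLELE_FREQ_CUTOFF,
) -> pd.DataFrame:
    """One row per substitution per retained allele.

    Positions are PAM-relative (negative = protospacer side); every row
    carries the full normalized frequency of its source allele.  The
    ``exclude_left`` sequenced-end bases stay excluded (for bottom-strand
    targets that end maps to the harmonized right edge).
    """
    table = harmonize_strand(table, library)
    pairs = {p.pair_id: p for p in library}
    fcol = _freq_col(table.df)
    rows = []
    for tup in table.df.itertuples():
        pair = pairs[tup.target_id]
        ref = pair.harmonized_site
        freq = getattr(tup, fcol)
        if freq <= freq_cutoff or tup.allele_seq == ref:
            continue
        lo, hi = _included_ref_range(pair)
        aln = global_align(tup.allele_seq, ref)
        for ref_pos, kind, r, a in aln.edit_ops():
            if kind != "sub" or not lo <= ref_pos < hi:
                continue
            rows.append((tup.target_id, tup.allele_seq,
                         ref_pos - pair.pam_start, r, a, freq))
    return pd.DataFrame(
        rows, columns=["target_id", "allele_seq", "pos", "ref", "alt", "freq"])


def _included_ref_range(pair: SgRNATargetPair) -> tuple[int, int]:
    """Harmonized-coordinate range kept for edit counting: the leftmost
    EXCLUDE_LEFT bases of the *sequenced* strand are excluded."""
    n = len(pair.target_site)
    if pair.strand == "top":
        return EXCLUDE_LEFT, n
    return 0, n - EXCLUDE_LEFT


def classify_allele(records: pd.DataFrame) -> str:
    """Classify an allele's substitutions: 'C>N', 'CompC>N', 'both', 'none'.

    Reference-C substitutions are C>N (non-target-strand deamination);
    reference-G substitutions are CompC>N (target-strand deamination).
    """
    has_cn = bool((records["ref"] == "C").any())
    has_comp = bool((records["ref"] == "G").any())
    if has_cn and has_comp:
        return "both"
    if has_cn:
        return "C>N"
    if has_comp:
        return "CompC>N"
    return "none"


def annotate_alleles(
    table: AlleleTable,
    library: Sequence[SgRNATargetPair],
    freq_cutoff: float = ALLELE_FREQ_CUTOFF,
    window: tuple[int, int] = NARROW_WINDOW,
) -> pd.DataFrame:
    """Per-allele annotation used by the efficiency breakdowns.

    Adds: ``is_reference``, ``has_indel``, ``edit_class`` and whether the
    allele carries a substitution inside/outside ``window``.
    """
    table = harmonize_strand(table, library)
    recs = substitution_records(table, library, freq_cutoff)
    by_allele = dict(tuple(recs.groupby(["target_id", "allele_seq"], sort=False))) \
        if not recs.empty else {}
    pairs = {p.pair_id: p for p in library}
    fcol = _freq_col(table.df)
    rows = []
    for tup in table.df.itertuples():
        ref = pairs[tup.target_id].harmonized_site
        sub = by_allele.get((tup.target_id, tup.allele_seq))
        if sub is None:
            sub = pd.DataFrame(columns=["pos", "ref", "alt"])
        in_win = bool(((sub["pos"] >= window[0]) & (sub["pos"] <= window[1])).any())
        out_win = bool(((sub["pos"] < window[0]) | (sub["pos"] > window[1])).any())
        rows.append({
            "target_id": tup.target_id,
            "allele_seq": tup.allele_seq,
            "freq": getattr(tup, fcol),
            "is_reference": tup.allele_seq == ref,
            "has_indel": (tup.n_inserted > 0) or (tup.n_deleted > 0),
            "edit_class": classify_allele(sub),
            "edit_in_window": in_win,
            "edit_out_window": out_win,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# efficiencies

_FILTERS = {
    "all": lambda df: ~df["is_reference"],
    "indel": lambda df: df["has_indel"],
    "C>N": lambda df: df["edit_class"].isin(["C>N", "both"]),
    "CompC>N": lambda df: df["edit_class"].isin(["CompC>N", "both"]),
    "window_in": lambda df: df["edit_in_window"],
    "window_out": lambda df: df["edit_out_window"],
}


def editing_efficiency(
    annotated: pd.DataFrame,
    which: str = "all",
    freq_cutoff: float = ALLELE_FREQ_CUTOFF,
) -> pd.Series:
    """Per-target efficiency (percent): sum of normalized frequencies of
    modified alleles above ``freq_cutoff`` matching the ``which`` filter."""
    if which not in _FILTERS:
        raise ValueError(f"unknown filter {which!r}")
    mask = (~annotated["is_reference"]) & (annotated["freq"] > freq_cutoff) \
        & _FILTERS[which](annotated)
    per_target = annotated[mask].groupby("target_id")["freq"].sum()
    return per_target.reindex(sorted(annotated["target_id"].unique()),
                              fill_value=0.0)


# ---------------------------------------------------------------------------
# aggregate editing, windows, spectrum

def aggregate_editing(records: pd.DataFrame) -> dict[int, float]:
    """Per-position Aggregate Editing: sum of substitution frequencies at
    each PAM-relative position, divided by 100."""
    if records.empty:
        return {}
    series = records.groupby("pos")["freq"].sum() / 100.0
    return {int(k): float(v) for k, v in series.items()}


def dead_control_cutoff(profile: Mapping[int, float]) -> float:
    """mu + 2*sigma of Aggregate Editing across positions of an
    inactive-deaminase control (population sigma)."""
    values = np.asarray(list(profile.values()), dtype=float)
    if values.size < 2:
        raise ValueError("need Aggregate Editing at >= 2 positions")
    return float(values.mean() + 2.0 * values.std(ddof=0))


def call_window(profile: Mapping[int, float], cutoff: float
                ) -> tuple[int, int] | None:
    """Left/right-most positions with Aggregate Editing strictly above
    ``cutoff``; interior sub-cutoff positions do not split the window."""
    above = [pos for pos, v in profile.items() if v > cutoff]
    if not above:
        return None
    return min(above), max(above)


def spectrum(records: pd.DataFrame, ref_base: str = "C"
             ) -> dict[str, float] | None:
    """Frequency-weighted outcome proportions for edits at ``ref_base``.

    For C: proportions of C>T, C>A, C>G (purity = C>T share).  For G the
    analogous CompC>N proportions (G>A mirrors C>T on the target strand).
    """
    sub = records[records["ref"] == ref_base]
    if sub.empty:
        return None
    totals = sub.groupby("alt")["freq"].sum()
    grand = float(totals.sum())
    order = {"C": ("T", "A", "G"), "G": ("A", "T", "C")}.get(ref_base)
    alts = order if order else tuple(sorted(totals.index))
    return {f"{ref_base}>{alt}": float(totals.get(alt, 0.0)) / grand
            for alt in alts}


def spectrum_purity(records: pd.DataFrame, ref_base: str = "C") -> float | None:
    """Share of the canonical transition (C>T, or G>A for CompC) among
    edits at ``ref_base``."""
    spec = spectrum(records, ref_base)
    if spec is None:
        return None
    canonical = {"C": "C>T", "G": "G>A"}.get(ref_base)
    return spec.get(canonical) if canonical else None


# ---------------------------------------------------------------------------
# motif PWM and enrichment score

@dataclass
class MotifPWM:
    """Frequency-weighted base probabilities at offsets -3..+3 around the
    edited base (offset 0)."""

    probs: pd.DataFrame  # index -3..3, columns A/C/G/T
    weight: float        # total allele frequency behind the PWM

    def column(self, offset: int) -> pd.Series:
        return self.probs.loc[offset]


def motif_pwm(
    records: pd.DataFrame,
    library: Sequence[SgRNATargetPair],
    ref_base: str = "C",
    complement_for_G: bool = False,
) -> MotifPWM:
    """Build the 7-mer PWM around edited bases with reference base
    ``ref_base``, weighting each 7-mer by its allele frequency.

    With ``complement_for_G`` the context of G edits is reverse-complemented
    so the edited base reads as C (the deaminated strand's view).  Records
    too close to the sequence edge for a full 7-mer are skipped.
    """
    sites = {p.pair_id: p for p in library}
    counts = pd.DataFrame(0.0, index=range(-3, 4), columns=list(_BASES))
    weight = 0.0
    for tup in records[records["ref"] == ref_base].itertuples():
        pair = sites[tup.target_id]
        ref = pair.harmonized_site
        idx = pair.pam_start + tup.pos
        if idx < 3 or idx + 4 > len(ref):
            continue
        context = ref[idx - 3: idx + 4]
        if ref_base == "G" and complement_for_G:
            context = revcomp(context)
        for offset, base in zip(range(-3, 4), context):
            counts.loc[offset, base] += tup.freq
        weight += tup.freq
    probs = counts.div(counts.sum(axis=1), axis=0) if weight > 0 else counts
    return MotifPWM(probs, weight)


def background_probability(motif: str, anchor_index: int,
                           background_gc: float = 0.52) -> float:
    """Probability of the motif's non-anchor positions under the GC
    background (equal split within G/C and within A/T)."""
    base_p = {
        "G": background_gc / 2, "C": background_gc / 2,
        "A": (1 - background_gc) / 2, "T": (1 - background_gc) / 2,
    }
    prob = 1.0
    for i, code in enumerate(motif.upper()):
        if i == anchor_index:
            continue
        prob *= sum(base_p[b] for b in IUPAC[code])
    return prob


def motif_es(pwm: MotifPWM, motif: str, anchor_index: int,
             background_gc: float = 0.52) -> float:
    """Motif enrichment score: log2(P_observed / P_background).

    ``motif`` is an IUPAC pattern anchored on the edited base at
    ``anchor_index`` (the anchor position itself is not scored).  Returns
    -inf when the motif is unobservable under the PWM (depleted beyond
    resolution).
    """
    if not 0 <= anchor_index < len(motif):
        raise ValueError("anchor_index outside motif")
    if len(motif) > 7:
        raise ValueError("motif wider than the -3..+3 context")
    p_obs = 1.0
    for i, code in enumerate(motif.upper()):
        if i == anchor_index:
            continue
        offset = i - anchor_index
        p_obs *= float(pwm.column(offset)[list(IUPAC[code])].sum())
    p_bg = background_probability(motif, anchor_index, background_gc)
    if p_obs == 0.0:
        return float("-inf")
    return math.log2(p_obs / p_bg)


# ---------------------------------------------------------------------------
# diversification and edits per allele

def diversity(
    table: AlleleTable,
    library: Sequence[SgRNATargetPair],
    freq_cutoff: float = ALLELE_FREQ_CUTOFF,
) -> pd.DataFrame:
    """Per-target allele count (> cutoff, excluding reference) and Shannon
    entropy in nats (including the reference allele).

    The reference allele's probability is the remaining frequency mass
    (100 - sum of retained non-reference frequencies)/100, so sub-cutoff
    alleles fold into the reference and probabilities sum to 1.
    """
    table = harmonize_strand(table, library)
    refs = {p.pair_id: p.harmonized_site for p in library}
    fcol = _freq_col(table.df)
    rows = []
    for target_id, grp in table.df.groupby("target_id", sort=True):
        ref = refs[target_id]
        nonref = grp[(grp["allele_seq"] != ref) & (grp[fcol] > freq_cutoff)]
        probs = (nonref[fcol] / 100.0).to_numpy()
        ref_p = max(0.0, 1.0 - probs.sum())
        ps = np.append(probs, ref_p)
        ps = ps[ps > 0]
        entropy = float(-(ps * np.log(ps)).sum())
        rows.append({"target_id": target_id, "n_alleles": len(nonref),
                     "entropy": entropy})
    return pd.DataFrame(rows, columns=["target_id", "n_alleles", "entropy"])


def edits_per_allele(
    table: AlleleTable,
    library: Sequence[SgRNATargetPair],
    freq_cutoff: float = ALLELE_FREQ_CUTOFF,
) -> pd.Series | None:
    """Distribution over substitution counts (``n_mutated``) among alleles
    above the cutoff with at least one substitution, weighted by allele
    frequency and normalized to 1."""
    table = harmonize_strand(table, library)
    refs = {p.pair_id: p.harmonized_site for p in library}
    df = table.df
    if df.empty:
        return None
    fcol = _freq_col(df)
    is_ref = [seq == refs[tid] for tid, seq in zip(df["target_id"], df["allele_seq"])]
    sub = df[(~np.asarray(is_ref)) & (df[fcol] > freq_cutoff) & (df["n_mutated"] >= 1)]
    if sub.empty:
        return None
    grouped = sub.groupby("n_mutated")[fcol].sum()
    return grouped / grouped.sum()


def metric_correlation(x: Mapping[str, float], y: Mapping[str, float],
                       exclusions: Iterable[str] = ()) -> float | None:
    """Pearson correlation between two per-editor summary maps after
    removing excluded editors; None if fewer than 3 shared points or a
    zero-variance input."""
    excluded = set(exclusions)
    keys = sorted((set(x) & set(y)) - excluded)
    if len(keys) < 3:
        return None
    xv = np.array([x[k] for k in keys], dtype=float)
    yv = np.array([y[k] for k in keys], dtype=float)
    if xv.std() == 0 or yv.std() == 0:
        return None
    r, _ = stats.pearsonr(xv, yv)
    return float(r)


def median_low(values: Iterable[float]) -> float | None:
    """Lower median (no interpolation for even counts)."""
    vals = sorted(values)
    if not vals:
        return None
    return float(vals[(len(vals) - 1) // 2])


# ---------------------------------------------------------------------------
# report

@dataclass
class EditorReport:
    """Full characterization of one editor sample."""

    editor: str
    n_targets: int
    per_target_efficiency: pd.DataFrame  # columns: all/indel/C>N/CompC>N/...
    median_efficiency: dict[str, float | None]
    aggregate: dict[int, float]
    window: tuple[int, int] | None
    window_cutoff: float
    spectrum_c: dict[str, float] | None
    spectrum_g: dict[str, float] | None
    purity: float | None
    es: dict[str, float]
    diversity: pd.DataFrame
    median_n_alleles: float | None
    median_entropy: float | None
    edits_per_allele: dict[int, float] | None
    pwm: MotifPWM | None = None

    def summary(self) -> dict:
        """JSON-serializable summary."""
        return {
            "editor": self.editor,
            "n_targets": self.n_targets,
            "median_efficiency": self.median_efficiency,
            "window": list(self.window) if self.window else None,
            "window_cutoff": self.window_cutoff,
            "spectrum_c": self.spectrum_c,
            "spectrum_g": self.spectrum_g,
            "purity": self.purity,
            "es": {k: (v if math.isfinite(v) else "depleted beyond resolution")
                   for k, v in self.es.items()},
            "median_n_alleles": self.median_n_alleles,
            "median_entropy": self.median_entropy,
            "edits_per_allele": self.edits_per_allele,
        }


#: default motifs scored in reports: AID's WRC preference around edited Cs
#: and its GYW mirror for target-strand (CompC) edits read as C-context.
DEFAULT_MOTIFS = {"WRC": ("WRC", 2), "TC": ("TC", 1), "GC": ("GC", 1)}


def characterize_editor(
    table: AlleleTable,
    library: Sequence[SgRNATargetPair],
    window_cutoff: float = WINDOW_CUTOFF_COMBINED,
    freq_cutoff: float = ALLELE_FREQ_CUTOFF,
    min_target_reads: int = MIN_TARGET_READS,
    background_gc: float = 0.52,
    motifs: Mapping[str, tuple[str, int]] = None,
) -> EditorReport:
    """Run the full characterization battery on a reconciled allele table."""
    motifs = dict(motifs) if motifs else dict(DEFAULT_MOTIFS)
    table = coverage_filter(table, min_target_reads)
    table = harmonize_strand(table, library)
    annotated = annotate_alleles(table, library, freq_cutoff)
    records = substitution_records(table, library, freq_cutoff)

    eff = pd.DataFrame({
        which: editing_efficiency(annotated, which, freq_cutoff)
        for which in _FILTERS
    }) if not annotated.empty else pd.DataFrame(columns=list(_FILTERS))
    medians = {which: median_low(eff[which]) if not eff.empty else None
               for which in _FILTERS}

    agg = aggregate_editing(records)
    window = call_window(agg, window_cutoff)
    spec_c = spectrum(records, "C") if not records.empty else None
    spec_g = spectrum(records, "G") if not records.empty else None
    purity = spectrum_purity(records, "C") if not records.empty else None
    pwm = motif_pwm(records, library, "C") if not records.empty else None
    es = {}
    if pwm is not None and pwm.weight > 0:
        es = {name: motif_es(pwm, pattern, anchor, background_gc)
              for name, (pattern, anchor) in motifs.items()}
    div = diversity(table, library, freq_cutoff)
    epa = edits_per_allele(table, library, freq_cutoff)

    return EditorReport(
        editor=table.sample,
        n_targets=int(table.df["target_id"].nunique()),
        per_target_efficiency=eff,
        median_efficiency=medians,
        aggregate=agg,
        window=window,
        window_cutoff=window_cutoff,
        spectrum_c=spec_c,
        spectrum_g=spec_g,
        purity=purity,
        es=es,
        diversity=div,
        median_n_alleles=median_low(div["n_alleles"]) if len(div) else None,
        median_entropy=median_low(div["entropy"]) if len(div) else None,
        edits_per_allele={int(k): float(v) for k, v in epa.items()} if epa is not None else None,
        pwm=pwm,
    )
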
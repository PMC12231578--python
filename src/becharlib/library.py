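"""Design of paired sgRNA / synthetic-target-site libraries.

Each designed unit couples a 20-nt sgRNA protospacer with a 104-bp synthetic
target site carrying that protospacer immediately 5' of an NGG PAM.  The PAM
"N" sits at the centre of the site and the flanking sequence is drawn at a
52% GC bias (human-genome-like).  Half of the sites are reverse-complemented
so that sgRNAs target either strand, and a configurable number of sites have
their embedded protospacer scrambled to act as negative controls that the
editor cannot be recruited to.  Sites and protospacers containing restriction
recognition sequences needed for cloning are rejected and resampled.

The designed library serves two roles downstream: ground truth for the read
simulator and the reference set for read assignment and allele calling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqs import is_dna, iupac_regex, random_dna, revcomp, hamming

#: BsmBI/Esp3I, BsaI and BlpI recognition sequences (standard references);
#: oligos carrying any of these outside the designed cloning sites would be
#: destroyed during library construction, so they are screened out.
DEFAULT_FORBIDDEN_SITES = ("CGTCTC", "GGTCTC", "GCTNAGC")

#: Linker placed between the protospacer and the target site; contains the
#: two BsmBI sites used to insert the sgRNA stem-loop during cloning.
LINKER = "GTTTGGAGACGGGATACCGTCTCTGATC"

#: Stand-in for the sgRNA stem-loop inserted in the second cloning round.
STEM_LOOP = "GTTTAAGAGCTATGCTGGAAACAGCATAGCAAGTTTAAATAAGGCTAGTCCGTTATCAACTTG"

_MAX_RESAMPLES = 1000


@dataclass(frozen=True)
class LibraryConfig:
    """Parameters controlling library design.

    ``gc_bias`` is the G+C fraction used for every randomly drawn base
    (flanks, PAM "N", protospacers); 0.52 mimics human genomic content.
    """

    n_pairs: int = 200
    n_negative_controls: int = 10
    target_length: int = 104
    protospacer_length: int = 20
    gc_bias: float = 0.52
    umi_length: int = 7
    linker: str = LINKER
    forbidden_sites: tuple[str, ...] = DEFAULT_FORBIDDEN_SITES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negative_controls > self.n_pairs:
            raise ValueError("n_negative_controls must be <= n_pairs")
        if self.target_length < self.protospacer_length + 3:
            raise ValueError("target_length must fit protospacer + PAM")
        if not 0.0 <= self.gc_bias <= 1.0:
            raise ValueError("gc_bias must be in [0, 1]")

    @property
    def pam_start(self) -> int:
        """0-based offset of the PAM 'N' on the protospacer-matching strand."""
        return self.target_length // 2


@dataclass(frozen=True)
class SgRNATargetPair:
    """One designed sgRNA-target site pair.

    ``target_site`` is the top strand as sequenced.  ``strand`` names the
    strand the sgRNA targets; for ``bottom`` pairs the protospacer+PAM lie on
    the reverse complement of ``target_site``.  ``pam_start`` is the 0-based
    offset of the PAM "N" on the protospacer-matching strand.
    """

    pair_id: str
    protospacer: str
    target_site: str
    strand: str  # "top" | "bottom"
    pam_start: int
    is_negative_control: bool = False

    @property
    def harmonized_site(self) -> str:
        """Target site oriented so the protospacer reads forward (sgRNA-top)."""
        return self.target_site if self.strand == "top" else revcomp(self.target_site)


def random_sequence(length: int, gc_bias: float, rng: np.random.Generator) -> str:
    """Draw a random DNA sequence with the configured GC bias."""
    return random_dna(length, gc_bias, rng)


def has_forbidden_site(seq: str, sites: Iterable[str]) -> bool:
    """True iff any IUPAC pattern in ``sites`` occurs in ``seq`` or its
    reverse complement."""
    if not is_dna(seq.upper()):
        raise ValueError("sequence contains non-DNA characters")
    seq = seq.upper()
    rc = revcomp(seq)
    for pattern in sites:
        regex = iupac_regex(pattern)
        if regex.search(seq) or regex.search(rc):
            return True
    return False


def _scramble(protospacer: str, rng: np.random.Generator) -> str:
    """Fisher-Yates shuffle of the protospacer, retried until the result is
    at Hamming distance >= 10 from the original (so the sgRNA cannot bind)."""
    bases = list(protospacer)
    for _ in range(_MAX_RESAMPLES):
        shuffled = bases.copy()
        rng.shuffle(shuffled)
        candidate = "".join(shuffled)
        if hamming(candidate, protospacer) >= 10:
            return candidate
    raise RuntimeError("could not scramble protospacer away from original")


def build_pair(
    protospacer: str,
    cfg: LibraryConfig,
    strand: str,
    is_control: bool,
    rng: np.random.Generator,
    pair_id: str = "pair",
) -> SgRNATargetPair:
    """Assemble one target site around ``protospacer`` with a centred NGG PAM.

    The PAM "N" is placed at offset ``target_length // 2`` with the
    protospacer immediately 5' of it; remaining positions are random at the
    configured GC bias.  ``bottom``-strand pairs have the finished site
    reverse-complemented (the sequenced top strand then carries the
    protospacer on its complement).  Control sites embed a scramble of the
    protospacer instead.  The site is rescreened against the forbidden
    restriction patterns and resampled on failure.
    """
    if strand not in ("top", "bottom"):
        raise ValueError("strand must be 'top' or 'bottom'")
    if len(protospacer) != cfg.protospacer_length:
        raise ValueError("protospacer length mismatch")
    if has_forbidden_site(protospacer, cfg.forbidden_sites):
        raise ValueError("protospacer carries a forbidden restriction site")

    pam_start = cfg.pam_start
    left_len = pam_start - cfg.protospacer_length
    right_len = cfg.target_length - pam_start - 3
    if left_len < 0 or right_len < 0:
        raise ValueError("target_length too short for centred PAM layout")

    for _ in range(_MAX_RESAMPLES):
        embedded = _scramble(protospacer, rng) if is_control else protospacer
        site = (
            random_sequence(left_len, cfg.gc_bias, rng)
            + embedded
            + random_sequence(1, cfg.gc_bias, rng)  # the PAM "N"
            + "GG"
            + random_sequence(right_len, cfg.gc_bias, rng)
        )
        if has_forbidden_site(site, cfg.forbidden_sites):
            continue
        if is_control and (protospacer in site or protospacer in revcomp(site)):
            continue
        target_site = site if strand == "top" else revcomp(site)
        return SgRNATargetPair(
            pair_id=pair_id,
            protospacer=protospacer,
            target_site=target_site,
            strand=strand,
            pam_start=pam_start,
            is_negative_control=is_control,
        )
    raise RuntimeError(f"site generation failed after {_MAX_RESAMPLES} attempts")


def design_library(cfg: LibraryConfig, rng: np.random.Generator | None = None) -> list[SgRNATargetPair]:
    """Design the full library: ``n_pairs`` pairs with unique protospacers,
    ``n_negative_controls`` scrambled controls, and half of the sites (floor)
    reverse-complemented so sgRNAs target either strand."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    protospacers: list[str] = []
    seen: set[str] = set()
    while len(protospacers) < cfg.n_pairs:
        cand = random_sequence(cfg.protospacer_length, cfg.gc_bias, rng)
        if cand in seen or has_forbidden_site(cand, cfg.forbidden_sites):
            continue
        seen.add(cand)
        protospacers.append(cand)

    width = max(4, len(str(cfg.n_pairs)))
    pairs: list[SgRNATargetPair] = []
    n_controls = cfg.n_negative_controls
    n_noncontrol = cfg.n_pairs - n_controls
    n_bottom = n_noncontrol // 2  # floor for odd counts
    for i, proto in enumerate(protospacers):
        is_control = i >= n_noncontrol
        if is_control:
            strand = "bottom" if (i - n_noncontrol) % 2 else "top"
        else:
            strand = "bottom" if i < n_bottom else "top"
        pairs.append(
            build_pair(proto, cfg, strand, is_control, rng,
                       pair_id=f"pair_{i:0{width}d}")
        )
    return pairs


def assemble_oligo(pair: SgRNATargetPair, umi: str, cfg: LibraryConfig) -> str:
    """Full oligo as synthesized: protospacer + linker (+ stem-loop) + UMI +
    target site, 5'->3'."""
    if len(umi) != cfg.umi_length:
        raise ValueError(f"UMI must be {cfg.umi_length} nt")
    return pair.protospacer + cfg.linker + STEM_LOOP + umi + pair.target_site


# ---------------------------------------------------------------------------
# on-disk representation

def write_library(pairs: Sequence[SgRNATargetPair], fasta_path: Path, manifest_path: Path) -> None:
    """Write target-site references as FASTA and the design manifest as TSV."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(p.target_site), id=p.pair_id, description="") for p in pairs]
    SeqIO.write(records, str(fasta_path), "fasta")
    manifest_frame(pairs).to_csv(manifest_path, sep="\t", index=False)


def manifest_frame(pairs: Sequence[SgRNATargetPair]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in pairs])[
        ["pair_id", "protospacer", "strand", "pam_start", "is_negative_control", "target_site"]
    ]


def read_manifest(manifest_path: Path) -> list[SgRNATargetPair]:
    df = pd.read_csv(manifest_path, sep="\t")
    return [
        SgRNATargetPair(
            pair_id=str(r.pair_id),
            protospacer=r.protospacer,
            target_site=r.target_site,
            strand=r.strand,
            pam_start=int(r.pam_start),
            is_negative_control=bool(r.is_negative_control),
        )
        for r in df.itertuples()
    ]
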
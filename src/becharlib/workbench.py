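"""End-to-end orchestration: design -> simulate -> process -> quantify ->
characterize, driven by one configuration object.

Every stage draws its randomness from a named per-stage seed derived from
the run seed, so a run is reproducible from its provenance block alone.
Stage boundaries log read/allele attrition so each filter's effect is
auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .characterize import (
    ALLELE_FREQ_CUTOFF,
    MIN_TARGET_READS,
    WINDOW_CUTOFF_COMBINED,
    WINDOW_CUTOFF_SPLIT,
    EditorReport,
    characterize_editor,
    dead_control_cutoff,
)
from .library import LibraryConfig, SgRNATargetPair, design_library, write_library
from .processing import (
    MIN_PARENT_READS,
    QC_UMI_THRESHOLD,
    WHITELIST_CLEAN_FRACTION,
    ProcessedReads,
    TargetIndex,
    apply_whitelist,
    build_whitelist,
    process_reads,
    qc_umi_coverage,
)
from .quantify import (
    MIN_READS_PER_TARGET,
    AlleleTable,
    drop_singletons_renormalize,
    reconcile_replicates,
    subtract_parent,
    tabulate,
    write_allele_table,
)
from .simulate import (
    EditorProfile,
    SequencingModel,
    SimulatedSample,
    draw_umi_map,
    preset_profiles,
    simulate_sample,
    truth_summary,
)

logger = logging.getLogger("becharlib")

_STAGES = ("design", "umis", "simulate", "process", "quantify", "characterize")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    The cutoffs default to the analysis' standard values: 0.5% allele
    frequency, 200-read target coverage, >90% indel-free whitelist rule,
    >5 acceptable UMIs for QC, and 0.25 / 0.5 Aggregate Editing window
    cutoffs (strand-split vs strand-combined analyses).
    """

    library: LibraryConfig = field(default_factory=LibraryConfig)
    profiles: dict[str, EditorProfile] = field(default_factory=dict)
    seq_model: SequencingModel = field(default_factory=SequencingModel)
    n_replicates: int = 2
    seed: int = 0
    allele_freq_cutoff: float = ALLELE_FREQ_CUTOFF
    min_target_reads: int = MIN_TARGET_READS
    min_reads_per_target_region: int = MIN_READS_PER_TARGET
    whitelist_clean_fraction: float = WHITELIST_CLEAN_FRACTION
    min_parent_reads: int = MIN_PARENT_READS
    qc_umi_threshold: int = QC_UMI_THRESHOLD
    window_cutoff_split: float = WINDOW_CUTOFF_SPLIT
    window_cutoff_combined: float = WINDOW_CUTOFF_COMBINED

    def stage_seeds(self) -> dict[str, int]:
        """Named per-stage seeds derived deterministically from the run seed."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_STAGES))
        return {name: int(child.generate_state(1)[0] % (2**31))
                for name, child in zip(_STAGES, children)}

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(config_to_dict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything a run produces, plus provenance for re-execution."""

    config: RunConfig
    library: list[SgRNATargetPair]
    reports: dict[str, EditorReport]
    qc: dict
    truth: dict[str, dict]  # editor -> truth-summary dict
    allele_tables: dict[str, AlleleTable]
    dead_cutoffs: dict[str, float]
    provenance: dict

    def summary(self) -> dict:
        return {
            "provenance": self.provenance,
            "qc": self.qc,
            "dead_control_cutoffs": self.dead_cutoffs,
            "editors": {name: rep.summary() for name, rep in self.reports.items()},
        }


# ---------------------------------------------------------------------------
# config serialization (plain key-value YAML)

def config_to_dict(cfg: RunConfig) -> dict:
    d = {
        "seed": cfg.seed,
        "n_replicates": cfg.n_replicates,
        "library": dataclasses.asdict(cfg.library),
        "seq_model": dataclasses.asdict(cfg.seq_model),
        "profiles": {},
        "cutoffs": {
            "allele_freq": cfg.allele_freq_cutoff,
            "min_target_reads": cfg.min_target_reads,
            "min_reads_per_target_region": cfg.min_reads_per_target_region,
            "whitelist_clean_fraction": cfg.whitelist_clean_fraction,
            "min_parent_reads": cfg.min_parent_reads,
            "qc_umi_threshold": cfg.qc_umi_threshold,
            "window_cutoff_split": cfg.window_cutoff_split,
            "window_cutoff_combined": cfg.window_cutoff_combined,
        },
    }
    d["library"]["forbidden_sites"] = list(cfg.library.forbidden_sites)
    for name, p in cfg.profiles.items():
        pd_ = dataclasses.asdict(p)
        pd_["window_weights"] = {int(k): float(v) for k, v in p.window_weights.items()}
        pd_["spectrum"] = list(p.spectrum)
        pd_["motif_weights"] = [[m, w] for m, w in p.motif_weights]
        pd_["edits_per_allele"] = {int(k): float(v) for k, v in p.edits_per_allele.items()}
        pd_["indel_size_dist"] = {int(k): float(v) for k, v in p.indel_size_dist.items()}
        d["profiles"][name] = pd_
    return d


def config_from_dict(d: Mapping) -> RunConfig:
    lib = dict(d.get("library", {}))
    if "forbidden_sites" in lib:
        lib["forbidden_sites"] = tuple(lib["forbidden_sites"])
    profiles = {}
    for name, pd_ in d.get("profiles", {}).items():
        if isinstance(pd_, str):  # preset name
            profiles[name] = dataclasses.replace(preset_profiles()[pd_], name=name)
            continue
        pd_ = dict(pd_)
        pd_["window_weights"] = {int(k): float(v) for k, v in pd_["window_weights"].items()}
        pd_["spectrum"] = tuple(pd_["spectrum"])
        pd_["motif_weights"] = tuple((m, float(w)) for m, w in pd_.get(
            "motif_weights", [["NWRCNNN", 3.0]]))
        if "edits_per_allele" in pd_:
            pd_["edits_per_allele"] = {int(k): float(v) for k, v in pd_["edits_per_allele"].items()}
        if "indel_size_dist" in pd_:
            pd_["indel_size_dist"] = {int(k): float(v) for k, v in pd_["indel_size_dist"].items()}
        profiles[name] = EditorProfile(**pd_)
    cut = d.get("cutoffs", {})
    return RunConfig(
        library=LibraryConfig(**lib),
        profiles=profiles,
        seq_model=SequencingModel(**d.get("seq_model", {})),
        n_replicates=int(d.get("n_replicates", 2)),
        seed=int(d.get("seed", 0)),
        allele_freq_cutoff=float(cut.get("allele_freq", ALLELE_FREQ_CUTOFF)),
        min_target_reads=int(cut.get("min_target_reads", MIN_TARGET_READS)),
        min_reads_per_target_region=int(cut.get("min_reads_per_target_region",
                                                MIN_READS_PER_TARGET)),
        whitelist_clean_fraction=float(cut.get("whitelist_clean_fraction",
                                               WHITELIST_CLEAN_FRACTION)),
        min_parent_reads=int(cut.get("min_parent_reads", MIN_PARENT_READS)),
        qc_umi_threshold=int(cut.get("qc_umi_threshold", QC_UMI_THRESHOLD)),
        window_cutoff_split=float(cut.get("window_cutoff_split", WINDOW_CUTOFF_SPLIT)),
        window_cutoff_combined=float(cut.get("window_cutoff_combined",
                                             WINDOW_CUTOFF_COMBINED)),
    )


def load_config(path: Path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: RunConfig, path: Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# the pipeline

def run_pipeline(cfg: RunConfig, outdir: Path | None = None) -> ReportBundle:
    """Run every stage in order and return the assembled report bundle.

    With ``outdir`` set, every intermediate (library FASTA/manifest, allele
    tables, QC, report JSON) is persisted there.
    """
    seeds = cfg.stage_seeds()
    logger.info("stage design: %d pairs", cfg.library.n_pairs)
    library = design_library(cfg.library, np.random.default_rng(seeds["design"]))
    references = {p.pair_id: p.target_site for p in library}
    target_index = TargetIndex(references)

    sim_rng = np.random.default_rng(seeds["simulate"])
    umi_rng = np.random.default_rng(seeds["umis"])

    # simulate and process per replicate; Parent and editor samples of a
    # replicate share the UMI map (same integrated cassette library)
    per_editor_tables: dict[str, list[AlleleTable]] = {n: [] for n in cfg.profiles}
    truths: dict[str, list] = {n: [] for n in cfg.profiles}
    qc: dict = {"replicates": {}}
    for rep in range(1, cfg.n_replicates + 1):
        umi_map = draw_umi_map(library, cfg.seq_model.umis_per_pair,
                               cfg.library.umi_length, umi_rng)
        parent_sim = simulate_sample(library, None, cfg.seq_model, rep, sim_rng,
                                     umi_map=umi_map, name="Parent")
        editor_sims: dict[str, SimulatedSample] = {}
        for name, profile in cfg.profiles.items():
            editor_sims[name] = simulate_sample(
                library, profile, cfg.seq_model, rep, sim_rng,
                umi_map=umi_map, name=name)
            truths[name].extend(editor_sims[name].truth)

        logger.info("stage process: replicate %d", rep)
        parent_proc = process_reads(parent_sim.reads, library, "Parent", rep,
                                    cfg.library.umi_length, target_index=target_index)
        wl = build_whitelist(parent_proc, references,
                             cfg.whitelist_clean_fraction, cfg.min_parent_reads)
        umi_qc = qc_umi_coverage(wl, library)
        parent_filt = apply_whitelist(parent_proc, wl)
        rep_qc = {
            "parent_reads_in": len(parent_sim.reads),
            "parent_reads_whitelisted": len(parent_filt.df),
            "parent_drops": parent_filt.drop_counts,
            "n_whitelisted_triplets": len(wl.accepted),
            "fraction_pairs_gt5_umis": umi_qc.attrs["fraction_covered"],
        }

        parent_table = drop_singletons_renormalize(
            tabulate(parent_filt.df, references, "Parent", rep,
                     cfg.min_reads_per_target_region))
        parent_norm = subtract_parent(parent_table, parent_table)

        for name, sim in editor_sims.items():
            proc = process_reads(sim.reads, library, name, rep,
                                 cfg.library.umi_length, target_index=target_index)
            filt = apply_whitelist(proc, wl)
            table = drop_singletons_renormalize(
                tabulate(filt.df, references, name, rep,
                         cfg.min_reads_per_target_region))
            per_editor_tables[name].append(subtract_parent(table, parent_table))
            rep_qc[f"{name}_reads_in"] = len(sim.reads)
            rep_qc[f"{name}_reads_whitelisted"] = len(filt.df)
        qc["replicates"][rep] = rep_qc
        qc.setdefault("parent_norm_max", 0.0)
        if not parent_norm.df.empty:
            qc["parent_norm_max"] = max(qc["parent_norm_max"],
                                        float(parent_norm.df["norm_freq"].max()))

    logger.info("stage characterize")
    reports: dict[str, EditorReport] = {}
    dead_cutoffs: dict[str, float] = {}
    reconciled: dict[str, AlleleTable] = {}
    truth_summaries: dict[str, dict] = {}
    for name in cfg.profiles:
        if cfg.n_replicates >= 2:
            table = reconcile_replicates(per_editor_tables[name])
        else:
            table = per_editor_tables[name][0].copy()
            table.df["mean_norm_freq"] = table.df["norm_freq"]
        reconciled[name] = table
        reports[name] = characterize_editor(
            table, library,
            window_cutoff=cfg.window_cutoff_combined,
            freq_cutoff=cfg.allele_freq_cutoff,
            min_target_reads=cfg.min_target_reads,
            background_gc=cfg.library.gc_bias,
        )
        if cfg.profiles[name].efficiency == 0.0 and reports[name].aggregate:
            dead_cutoffs[name] = dead_control_cutoff(reports[name].aggregate)
        ts = truth_summary(truths[name], library)
        truth_summaries[name] = {
            "median_efficiency": _median(list(ts.per_target_efficiency.values())),
            "spectrum": list(ts.spectrum),
            "comp_fraction": ts.comp_fraction,
            "window_support": list(ts.window_support) if ts.window_support else None,
            "n_events": ts.n_events,
        }

    provenance = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seeds": seeds,
    }
    bundle = ReportBundle(cfg, library, reports, qc, truth_summaries,
                          reconciled, dead_cutoffs, provenance)
    if outdir is not None:
        persist_bundle(bundle, Path(outdir))
    return bundle


def _median(values):
    from .characterize import median_low
    return median_low(values)


def persist_bundle(bundle: ReportBundle, outdir: Path) -> None:
    """Write the bundle: library FASTA+manifest, per-editor allele tables
    and metric TSVs, and the overall JSON report."""
    outdir.mkdir(parents=True, exist_ok=True)
    write_library(bundle.library, outdir / "references.fasta",
                  outdir / "manifest.tsv")
    save_config(bundle.config, outdir / "config.yaml")
    for name, table in bundle.allele_tables.items():
        write_allele_table(table, outdir / f"alleles_{name}.tsv")
    for name, rep in bundle.reports.items():
        rep.per_target_efficiency.to_csv(outdir / f"efficiency_{name}.tsv", sep="\t")
        rep.diversity.to_csv(outdir / f"diversity_{name}.tsv", sep="\t", index=False)
        if rep.pwm is not None:
            rep.pwm.probs.to_csv(outdir / f"pwm_{name}.tsv", sep="\t")
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle.summary(), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# fixtures

def make_fixture(size: str = "tiny", seed: int = 0,
                 profiles: Sequence[str] = ("narrow_window",)) -> RunConfig:
    """Pipeline configs used by the test-suite.

    ``tiny``: 5 pairs / 2 UMIs / 20 reads per triplet (seconds);
    ``small``: 50 pairs / 10 UMIs / 200 reads per triplet (minutes).
    """
    presets = preset_profiles()
    chosen = {name: presets[name] for name in profiles}
    if size == "tiny":
        # ~80 reads/target over 2 replicates; the coverage floor is scaled
        # to half the nominal per-target yield, as for the nominal design
        lib = LibraryConfig(n_pairs=5, n_negative_controls=1, seed=seed)
        model = SequencingModel(depth_per_triplet=20.0, umis_per_pair=2)
        return RunConfig(library=lib, profiles=chosen, seq_model=model,
                         seed=seed, min_target_reads=40)
    if size == "small":
        lib = LibraryConfig(n_pairs=50, n_negative_controls=2, seed=seed)
        model = SequencingModel(depth_per_triplet=200.0, umis_per_pair=10)
        return RunConfig(library=lib, profiles=chosen, seq_model=model, seed=seed)
    raise ValueError("size must be 'tiny' or 'small'")
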
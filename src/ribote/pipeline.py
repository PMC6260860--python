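"""End-to-end orchestration: config, stage scheduling, provenance.

``run_pipeline`` executes the enabled stages in dependency order on one
input bundle and writes every result table plus a run manifest (package
version, config hash, output checksums — no timestamps, so a rerun with
the same config and inputs is bit-identical for deterministic stages).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import de as de_mod
from . import enrichment as enrich_mod
from . import metagene as metagene_mod
from . import stoichiometry as stoich_mod
from . import te as te_mod
from . import utr as utr_mod
from .io_formats import (CONDITIONS, ValidationError, read_annotation,
                         read_bedgraph, read_counts, read_fasta,
                         write_annotation, write_bedgraph, write_counts,
                         write_fasta, write_tsv_results)
from .simulate import (SimConfig, simulate_annotation, simulate_counts,
                       simulate_coverage, simulate_genome,
                       simulate_utr_sequences)

ALL_STAGES = ("de", "te", "stoich", "utr", "metagene", "enrich")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and stage toggles for one pipeline run."""

    out_dir: str
    annotation: str | None = None
    counts: str | None = None
    samples: str | None = None
    genome: str | None = None
    coverage: dict | None = None        # condition -> {strand -> bedGraph path}
    terms: str | None = None            # two-column gene_id/term TSV
    groups: str | None = None           # two-column group/gene_id TSV
    lfc_threshold: float = 1.0
    sig_alpha: float = 0.05
    kappa_threshold: float = 0.4
    mrna_floor: float = 1.0
    ratio_tol: float = 1.5
    k_min: int = 3
    bins: tuple[int, int, int] = (20, 50, 20)
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})

    def __post_init__(self) -> None:
        if not 0 < self.sig_alpha < 1:
            raise ValidationError("sig_alpha must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValidationError("lfc_threshold must be >= 0")
        if not -1 <= self.kappa_threshold <= 1:
            raise ValidationError("kappa_threshold must be in [-1, 1]")
        if self.ratio_tol < 1:
            raise ValidationError("ratio_tol must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
        self.stages = {s: bool(self.stages.get(s, False)) for s in ALL_STAGES}
        self.bins = tuple(self.bins)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Stable hash of the analysis configuration (where results are
        written is not part of their provenance)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_STAGE_INPUTS = {
    "de": ("counts", "samples"),
    "te": ("counts", "samples"),
    "stoich": ("annotation", "counts", "samples"),
    "utr": ("annotation", "genome", "counts", "samples"),
    "metagene": ("annotation", "coverage"),
    "enrich": ("counts", "samples", "terms"),
}


def _validate_inputs(config: PipelineConfig) -> None:
    for stage, enabled in config.stages.items():
        if not enabled:
            continue
        for key in _STAGE_INPUTS[stage]:
            val = getattr(config, key)
            if val is None:
                raise ValidationError(
                    f"stage {stage!r} is enabled but input {key!r} is not set")
            paths = ([p for d in val.values() for p in d.values()]
                     if isinstance(val, dict) else [val])
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(
                        f"stage {stage!r}: input file not found: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns {output name: path} plus the manifest."""
    _validate_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    outputs: dict[str, Path] = {}
    summary: dict = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        write_tsv_results(df, path, version=__version__, config_hash=chash)
        outputs[name] = path

    counts = sf = dispersions = None
    need_counts = any(config.stages[s] for s in
                      ("de", "te", "stoich", "utr", "enrich"))
    if need_counts:
        counts = read_counts(config.counts, config.samples)
        sf = de_mod.estimate_size_factors(counts)
        group_labels = [f"{s.condition}:{s.assay}" for s in counts.samples]
        dispersions = de_mod.estimate_dispersions(counts, sf, group_labels)
    annotation = None
    if any(config.stages[s] for s in ("stoich", "utr", "metagene")):
        annotation = read_annotation(config.annotation)

    de_mrna = de_rpf = None
    if config.stages["de"]:
        de_mrna = de_mod.nb_wald_test(
            counts, sf, dispersions, assay="mRNA",
            lfc_threshold=config.lfc_threshold, sig_alpha=config.sig_alpha)
        de_rpf = de_mod.nb_wald_test(
            counts, sf, dispersions, assay="RPF",
            lfc_threshold=config.lfc_threshold, sig_alpha=config.sig_alpha)
        emit("de_mrna", de_mrna)
        emit("de_rpf", de_rpf)
        coords, var_frac = de_mod.pca_qc(counts, sf)
        pca = coords.reset_index(names="sample_id")
        emit("pca_coordinates", pca)
        summary["pca_variance_fractions"] = [float(v) for v in var_frac]
        sf_df = sf.as_series().rename("size_factor").reset_index()
        sf_df.columns = ["sample_id", "size_factor"]
        emit("size_factors", sf_df)

    te_table = None
    if config.stages["te"]:
        te_point = te_mod.compute_te(counts, sf, mrna_floor=config.mrna_floor)
        te_test = te_mod.te_interaction_test(counts, sf, dispersions)
        te_table = te_mod.classify_te(
            te_point, te_test, lfc_threshold=config.lfc_threshold,
            sig_alpha=config.sig_alpha)
        emit("te", te_table)
        if de_mrna is not None:
            rho, p = te_mod.buffering_correlation(de_mrna, te_table)
            summary["buffering_spearman_rho"] = rho
            summary["buffering_p"] = p
        summary["te_class_counts"] = \
            te_table["te_class"].value_counts().to_dict()

    if config.stages["stoich"]:
        pairs = stoich_mod.operon_pair_stats(annotation, counts, sf)
        emit("stoich_pairs", pairs)
        if len(pairs) >= 3:
            for cond in CONDITIONS:
                r, p = stoich_mod.pair_correlation(pairs, cond)
                summary[f"stoich_pearson_{cond}"] = r
                summary[f"stoich_pearson_p_{cond}"] = p
        if config.groups:
            groups = stoich_mod.read_groups_tsv(config.groups)
            rows = []
            for cond in CONDITIONS:
                gm, ratios, equi = stoich_mod.complex_ratio(
                    groups, counts, sf, cond, ratio_tol=config.ratio_tol)
                for a in gm.index:
                    for b in gm.index:
                        if a < b:
                            rows.append({"condition": cond, "group_a": a,
                                         "group_b": b,
                                         "ratio": float(ratios.loc[a, b]),
                                         "equimolar": bool(equi.loc[a, b])})
            emit("stoich_groups", pd.DataFrame(rows))

    if config.stages["utr"]:
        if te_table is None:
            raise ValidationError("utr stage requires the te stage")
        genome = read_fasta(config.genome)
        seqs = utr_mod.extract_utr5(annotation, genome)
        folds = {gid: utr_mod.fold_mfe(seq, gene_id=gid)
                 for gid, seq in seqs.items()}
        fold_df = pd.DataFrame(
            [{"gene_id": f.gene_id, "length": f.length,
              "structure": f.structure, "delta_g": f.delta_g,
              "flagged_short": f.flagged_short}
             for f in folds.values()])
        emit("utr_folds", fold_df)
        try:
            comparison = utr_mod.compare_classes(folds, te_table)
            summary["utr_delta_g_median_up"] = comparison.median_a
            summary["utr_delta_g_median_down"] = comparison.median_b
            summary["utr_wilcoxon_p"] = comparison.p
        except ValidationError:
            summary["utr_wilcoxon_p"] = None

    if config.stages["metagene"]:
        profiles_by_cond = {}
        for cond, strand_paths in config.coverage.items():
            tracks = [read_bedgraph(p, strand=strand)
                      for strand, p in sorted(strand_paths.items())]
            profiles_by_cond[cond] = metagene_mod.collect_profiles(
                tracks, annotation, bins=config.bins)
        result = metagene_mod.aggregate_and_compare(profiles_by_cond,
                                                    bins=config.bins)
        emit("metagene_profiles", metagene_mod.profiles_frame(result))
        emit("metagene_tests", result.region_tests)

    if config.stages["enrich"]:
        if de_mrna is None:
            raise ValidationError("enrich stage requires the de stage")
        gene_terms = enrich_mod.read_annotation_table(config.terms)
        for direction, mask in (("up", de_mrna["log2fc"] > 0),
                                ("down", de_mrna["log2fc"] < 0)):
            degs = set(de_mrna.loc[de_mrna["is_deg"] & mask, "gene_id"])
            table = enrich_mod.hypergeom_enrich(degs, gene_terms,
                                                k_min=config.k_min)
            sig = table[table["p_adj"] < config.sig_alpha]
            if len(sig):
                term_genes = enrich_mod.invert_annotation(gene_terms)
                clusters = enrich_mod.kappa_cluster(
                    {t: term_genes[t] for t in sig["term_id"]},
                    universe=degs or set(gene_terms),
                    kappa_threshold=config.kappa_threshold)
                table = table.merge(clusters, on="term_id", how="left")
            emit(f"enrichment_{direction}", table)

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True,
                                       default=float) + "\n")
    outputs["summary"] = summary_path

    manifest = {
        "version": __version__,
        "config_hash": chash,
        "config": asdict(config),
        "seed": config.seed,
        "outputs": {name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
                    for name, p in sorted(outputs.items())},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str) + "\n")
    outputs["manifest"] = manifest_path
    return {name: str(p) for name, p in outputs.items()}


def simulate_dataset(sim_config: SimConfig, out_dir) -> dict:
    """Write a complete synthetic dataset (annotation, counts, genome,
    coverage, term table, ground truth) ready for ``run_pipeline``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(sim_config)
    counts, truth = simulate_counts(sim_config, annotation)
    utr_seqs = simulate_utr_sequences(sim_config, annotation, truth)
    genome = simulate_genome(sim_config, annotation, utr_seqs)
    tracks = simulate_coverage(sim_config, annotation, truth)

    paths = {"annotation": out / "annotation.gff3",
             "counts": out / "counts.tsv",
             "samples": out / "samples.tsv",
             "genome": out / "genome.fasta",
             "terms": out / "terms.tsv",
             "truth": out / "truth.tsv"}
    write_annotation(annotation, paths["annotation"])
    write_counts(counts, paths["counts"], paths["samples"])
    write_fasta(genome, paths["genome"])
    with open(paths["terms"], "w") as fh:
        for g in annotation:
            for t in sorted(g.terms):
                fh.write(f"{g.gene_id}\t{t}\n")
    pd.DataFrame({
        "gene_id": truth.gene_ids,
        "base_mean": truth.base_mean,
        "lfc_condition": truth.lfc_condition,
        "lfc_assay": truth.lfc_assay,
        "lfc_te": truth.lfc_te,
        "dispersion": truth.dispersion,
        "is_de": truth.is_de,
        "is_te": truth.is_te,
        "te_class": truth.te_class,
        "operon_id": [o if o is not None else "." for o in truth.operon_id],
        "stem_length": [truth.stem_lengths.get(g, 0) for g in truth.gene_ids],
    }).to_csv(paths["truth"], sep="\t", index=False)
    coverage_paths: dict[str, dict[str, str]] = {}
    for (cond, strand), track in tracks.items():
        p = out / f"coverage_{cond}_{'plus' if strand == '+' else 'minus'}.bedgraph"
        write_bedgraph(track, p)
        coverage_paths.setdefault(cond, {})[strand] = str(p)
    result = {k: str(v) for k, v in paths.items()}
    result["coverage"] = coverage_paths
    return result
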
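"""End-to-end benchmark pipeline and run configuration.

``run_end_to_end`` wires registry → reference synthesis → probe design →
mock design → capture simulation → classification → evaluation, writes every
artifact plus a manifest into one run directory, and is bit-identical under
a fixed config and master seed.  Per-stage seeds are derived from the master
seed by hashing the stage name, so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import capture_sim, evaluate, mock_community, probe_design, read_classify
from .capture_sim import CaptureModel
from .errors import StageFailure
from .mock_community import MockDesign, synth_reference_set, synth_strain
from .read_classify import ProteinDB
from .target_registry import Registry, SequenceRecord, dereplicate

log = logging.getLogger("probecap")

STAGES = ("registry", "reference", "targets", "design", "mock", "capture", "classify", "evaluate")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**63)


@dataclass
class RunConfig:
    # scope
    registry_path: str | None = None
    families: list[str] | None = None  # None -> every registry family
    # target database synthesis
    n_variants_per_family: int = 8
    target_divergence: float = 0.10
    gene_codon_range: tuple[int, int] = (150, 320)

    def __post_init__(self):
        self.gene_codon_range = tuple(self.gene_codon_range)
    # probe design
    probe_length: int = 50
    max_probes: int = 6
    cluster_threshold: float = 0.80
    tm_target: float = 47.0
    # mock community
    n_strains: int = 6
    gc_low: float = 40.0
    gc_high: float = 65.0
    target_gc: float = 53.0
    strain_length: int = 12000
    gene_divergence: float = 0.10
    gc_ameliorate: bool = False
    # capture
    n_fragments: int = 3000
    mean_insert: float = 630.0
    sd_insert: float = 60.0
    read_length: int = 300
    error_rate: float = 0.0
    capture_model: dict = field(
        default_factory=lambda: {
            "p_max": 0.95,
            "kappa": 30.0,
            "x0": 0.8,
            "gamma0": 0.2,
            "gamma1": 1.0,
            "gc_bias_enabled": True,
        }
    )
    # classification
    min_identity: float = 60.0
    max_per_direction: int = 4
    max_overlap_aa: int = 15
    e_threshold: float = 0.001

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _load_registry(config: RunConfig) -> Registry:
    if config.registry_path:
        return Registry.from_yaml(config.registry_path)
    return Registry.default()


def run_end_to_end(config: RunConfig, master_seed: int, outdir: str | Path) -> dict:
    """Execute the full benchmark; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {stage: stage_seed(master_seed, stage) for stage in STAGES}
    manifest: dict = {
        "version": __version__,
        "master_seed": master_seed,
        "stage_seeds": seeds,
        "config": config.to_dict(),
        "counts": {},
        "warnings": [],
    }
    stage = "registry"
    try:
        registry = _load_registry(config)
        families = config.families or registry.names
        manifest["counts"]["families"] = len(registry)
        manifest["families"] = registry.names

        stage = "reference"
        refset = synth_reference_set(
            registry, seed=seeds["reference"], codon_range=tuple(config.gene_codon_range)
        )

        stage = "targets"
        targets: dict[str, list[SequenceRecord]] = {}
        for i, fam in enumerate(families):
            variants = refset.variants(
                fam,
                config.n_variants_per_family,
                config.target_divergence,
                seed=seeds["targets"] + i,
            )
            targets[fam] = dereplicate(variants)
        manifest["counts"]["target_sequences"] = sum(len(v) for v in targets.values())

        stage = "design"
        per_cluster = []
        n_clusters = 0
        for fam in families:
            seqs = targets[fam]
            lookup = {r.id: r.residues for r in seqs}
            for cluster in probe_design.cluster_sequences(seqs, config.cluster_threshold):
                n_clusters += 1
                per_cluster.append(
                    probe_design.design_probes(
                        cluster,
                        lookup,
                        family=fam,
                        k=config.probe_length,
                        max_probes=config.max_probes,
                        tm_target=config.tm_target,
                    )
                )
        panel = probe_design.assemble_panel(per_cluster)
        panel.write(outdir / "panel")
        manifest["counts"]["clusters"] = n_clusters
        manifest["counts"]["probes"] = len(panel)
        if len(panel) == 0:
            manifest["warnings"].append("empty probe panel: nothing will be captured")

        stage = "mock"
        rng = np.random.default_rng(seeds["mock"])
        strains, genomes, truth = [], {}, {}
        gcs = np.linspace(config.gc_low, config.gc_high, config.n_strains)
        for i in range(config.n_strains):
            genes = {}
            for j, fam in enumerate(families):
                if j % config.n_strains in (i, (i + 1) % config.n_strains):
                    genes[fam] = (int(rng.integers(1, 3)), config.gene_divergence)
            gene_bp = sum(len(refset[f].cds) * c for f, (c, _) in genes.items())
            length = max(config.strain_length, 2 * gene_bp)
            spec, genome, intervals = synth_strain(
                f"strain_{i:02d}",
                length,
                float(gcs[i]),
                genes,
                refset,
                seed=seeds["mock"] + 17 * (i + 1),
                gc_ameliorate=config.gc_ameliorate,
            )
            strains.append(spec)
            genomes[spec.name] = genome
            truth[spec.name] = intervals
        design = MockDesign.from_target_gc(strains, config.target_gc)
        design.to_json(outdir / "mock_design.json")
        mock_community.write_strains_tsv(strains, outdir / "strains.tsv")
        mock_community.write_truth_bed(truth, outdir / "truth.bed")
        mock_community.write_genomes_fasta(genomes, outdir / "genomes.fasta")
        manifest["counts"]["strains"] = len(strains)
        manifest["weighted_gc"] = design.weighted_gc

        stage = "capture"
        log.info("capture: sampling %d fragments", config.n_fragments)
        fragments = capture_sim.fragment_pool(
            design,
            genomes,
            config.n_fragments,
            mean_len=config.mean_insert,
            sd_len=config.sd_insert,
            seed=seeds["capture"],
            truth=truth,
        )
        model = CaptureModel(**config.capture_model)
        captured = capture_sim.hybridize(fragments, panel, model, seed=seeds["capture"] + 1)
        readset = capture_sim.sequence_reads(
            captured,
            read_len=config.read_length,
            error_rate=config.error_rate,
            seed=seeds["capture"] + 2,
        )
        readset.write_fastq(outdir / "captured")
        readset.write_provenance(outdir / "provenance.tsv")
        manifest["counts"]["fragments"] = len(fragments)
        manifest["counts"]["captured_fragments"] = len(captured)
        manifest["counts"]["read_pairs"] = len(readset)
        manifest["on_target_fraction"] = readset.on_target_fraction

        stage = "classify"
        log.info("classify: %d captured pairs", len(readset))
        db = ProteinDB(refset.protein_db()).calibrate(seed=seeds["classify"])
        reads = []
        read_truth: dict[str, str] = {}
        for pair in readset:
            for mate, seq in (("1", pair.seq1), ("2", pair.seq2)):
                rid = f"{pair.read_id}/{mate}"
                reads.append((rid, seq))
                fams = sorted(pair.truth_families)
                read_truth[rid] = fams[0] if fams else evaluate.BACKGROUND_LABEL
        hits, annotations = read_classify.classify_reads(
            reads,
            db,
            registry,
            min_identity=config.min_identity,
            max_per_direction=config.max_per_direction,
            max_overlap_aa=config.max_overlap_aa,
            e_max=config.e_threshold,
        )
        total_reads = max(1, len(reads))
        table = read_classify.tabulate(annotations, total_reads)
        read_classify.write_hits_tsv(hits, outdir / "hits.tsv")
        read_classify.write_annotations_tsv(annotations, outdir / "annotations.tsv")
        table.write_tsv(outdir / "abundance.tsv")
        manifest["counts"]["reads"] = len(reads)
        manifest["counts"]["annotated_reads"] = len(annotations)
        if not annotations:
            manifest["warnings"].append("no reads were annotated; abundance table is empty")

        stage = "evaluate"
        if len(table.rel_target) >= 3:
            report = evaluate.compare_abundance(design.expected_abundance, table)
        else:
            manifest["warnings"].append(
                "fewer than 3 observed families; correlation not computed"
            )
            report = evaluate.EvalReport(
                pearson_r=float("nan"),
                p_value=float("nan"),
                n_shared=len(table.rel_target),
                expected=design.expected_abundance,
                observed=table.rel_target,
                deviations={},
            )
        pr = evaluate.precision_recall(
            evaluate.annotations_to_predictions(annotations), read_truth, registry
        )
        report.precision = {f: p for f, (p, _) in pr.items()}
        report.recall = {f: r for f, (_, r) in pr.items()}
        report.to_json(outdir / "eval_report.json")
        manifest["pearson_r"] = None if np.isnan(report.pearson_r) else report.pearson_r
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        config.to_yaml(outdir / "config.yaml")
        return manifest
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "stage.txt").write_text(f"{stage}\n{exc}\n")
        raise StageFailure(stage, exc) from exc
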
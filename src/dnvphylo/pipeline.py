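"""End-to-end orchestration: reconstruct → vectors → centroids →
matrices → summed matrix → tree → natural graph.

Each stage writes its intermediate to the output directory, so any stage
can be re-run from its on-disk input, and a manifest records the SHA-256
checksum of every artifact; identical configuration and inputs give
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .aggregate import (
    PersonalVector,
    distance_matrix,
    group_by_population,
    personal_vector,
    population_centroids,
    read_panel,
    sum_matrices,
)
from .graph import build_natural_graph, write_graph
from .matrix import LabeledMatrix, write_matrix
from .nv import NV_COMPONENTS, divided_natural_vector
from .phylo import build_tree, root_with_outgroup, write_newick
from .reconstruct import reconstruct_cohort, reconstruct_haploid
from .sequences import NucleotideSequence, read_fasta, write_fasta
from .vcfio import read_vcf, vcf_samples

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Inputs are either per-chromosome VCFs plus a reference FASTA (one
    reference record per VCF, paired in order) — the reconstruction
    path — or per-chromosome FASTA cohorts of already-built sequences.
    ``panel_path`` maps samples to populations.
    """

    out_dir: Path
    panel_path: Path
    k: int = 4
    tree_method: str = "bionj"
    outgroup: Optional[str] = None
    excluded_populations: list[str] = field(default_factory=list)
    reference_fasta: Optional[Path] = None
    vcf_paths: list[Path] = field(default_factory=list)
    fasta_paths: list[Path] = field(default_factory=list)
    haploid: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tree_method not in ("upgma", "nj", "bionj"):
            raise ValueError(f"unknown tree_method {self.tree_method!r}")
        if bool(self.vcf_paths) == bool(self.fasta_paths):
            raise ValueError("provide either vcf_paths (with reference_fasta) "
                             "or fasta_paths, not both")
        if self.vcf_paths and self.reference_fasta is None:
            raise ValueError("vcf_paths requires reference_fasta")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a plain key=value config file; keyword overrides win."""
        kv: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        kwargs: dict = {}
        if "k" in kv:
            kwargs["k"] = int(kv["k"])
        if "tree_method" in kv:
            kwargs["tree_method"] = kv["tree_method"]
        if "outgroup" in kv:
            kwargs["outgroup"] = kv["outgroup"] or None
        if "excluded_populations" in kv:
            kwargs["excluded_populations"] = [
                p for p in kv["excluded_populations"].split(",") if p
            ]
        if "haploid" in kv:
            kwargs["haploid"] = kv["haploid"].lower() in ("1", "true", "yes")
        if "seed" in kv:
            kwargs["seed"] = int(kv["seed"])
        for key in ("out_dir", "panel_path", "reference_fasta"):
            if key in kv:
                kwargs[key] = Path(kv[key])
        for key in ("vcf_paths", "fasta_paths"):
            if key in kv:
                kwargs[key] = [Path(p) for p in kv[key].split(",") if p]
        kwargs.update(overrides)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_vectors(path: Path, vectors: list[PersonalVector], k: int) -> None:
    header = ["sample", "chromosome"] + [
        f"seg{s + 1}_{c}" for s in range(k) for c in NV_COMPONENTS
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for pv in vectors:
            fh.write(
                pv.sample + "\t" + pv.chromosome + "\t"
                + "\t".join(f"{x:.12g}" for x in pv.vector) + "\n"
            )


def _chromosome_vectors(
    config: RunConfig, chrom_name: str, sequences_by_sample: dict
) -> list[PersonalVector]:
    vectors = []
    for sample, seqs in sequences_by_sample.items():
        hap_vecs = [divided_natural_vector(s, config.k).flat() for s in seqs]
        vectors.append(personal_vector(hap_vecs, sample, chrom_name))
    return vectors


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (artifact paths + checksums)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = read_panel(config.panel_path)
    artifacts: list[Path] = []
    per_chrom_matrices: list[LabeledMatrix] = []

    def stage(name: str):
        logger.info("stage %s", name)
        return time.perf_counter()

    if config.vcf_paths:
        t0 = stage("reconstruct")
        references = read_fasta(config.reference_fasta)
        if len(references) != len(config.vcf_paths):
            raise ValueError(
                f"{len(references)} reference records but "
                f"{len(config.vcf_paths)} VCFs"
            )
        chrom_inputs = []
        for ref, vcf_path in zip(references, config.vcf_paths):
            records = read_vcf(vcf_path)
            samples = vcf_samples(vcf_path)
            chrom = records[0].chrom if records else ref.identifier
            if config.haploid:
                seqs = reconstruct_haploid(ref, records, samples)
                by_sample = {s.identifier: [s] for s in seqs}
                flat = list(seqs)
            else:
                pairs = reconstruct_cohort(ref, records, samples)
                by_sample = {p.sample: [p.hap_a, p.hap_b] for p in pairs}
                flat = [s for p in pairs for s in (p.hap_a, p.hap_b)]
            fa = out / f"reconstructed_{chrom}.fa"
            write_fasta(flat, fa)
            artifacts.append(fa)
            chrom_inputs.append((chrom, by_sample))
        logger.info("reconstruct done in %.2fs", time.perf_counter() - t0)
    else:
        chrom_inputs = []
        for fasta_path in config.fasta_paths:
            seqs = read_fasta(fasta_path)
            chrom = Path(fasta_path).stem
            chrom_inputs.append((chrom, {s.identifier: [s] for s in seqs}))

    t0 = stage("vectors+centroids+matrices")
    for chrom, by_sample in chrom_inputs:
        vectors = _chromosome_vectors(config, chrom, by_sample)
        vec_path = out / f"vectors_{chrom}.tsv"
        _write_vectors(vec_path, vectors, config.k)
        artifacts.append(vec_path)
        grouped = group_by_population(vectors, panel)
        for pop in config.excluded_populations:
            grouped.pop(pop, None)
        centroids = population_centroids(grouped)
        centroids.sort(key=lambda c: c.population)
        matrix = distance_matrix(centroids)
        mat_path = out / f"dist_{chrom}.tsv"
        write_matrix(matrix, mat_path)
        artifacts.append(mat_path)
        per_chrom_matrices.append(matrix)
    logger.info("matrices done in %.2fs", time.perf_counter() - t0)

    t0 = stage("sum+tree+graph")
    total = sum_matrices(per_chrom_matrices)
    total_path = out / "total_matrix.tsv"
    write_matrix(total, total_path)
    artifacts.append(total_path)

    tree = build_tree(total, config.tree_method)
    if config.outgroup:
        tree = root_with_outgroup(tree, config.outgroup)
    tree_path = out / "tree.nwk"
    write_newick(tree, tree_path)
    artifacts.append(tree_path)

    graph = build_natural_graph(total)
    dot_path = out / "graph.dot"
    tsv_path = out / "graph_edges.tsv"
    write_graph(graph, dot_path, tsv_path)
    artifacts.extend([dot_path, tsv_path])
    logger.info("tree+graph done in %.2fs", time.perf_counter() - t0)

    manifest = {
        "config": {
            "k": config.k,
            "tree_method": config.tree_method,
            "outgroup": config.outgroup,
            "excluded_populations": list(config.excluded_populations),
            "haploid": config.haploid,
        },
        "artifacts": {str(p.name): _sha256(p) for p in artifacts},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
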
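"""End-to-end orchestration: simulate -> HCAA -> search -> matrix ->
code call -> gene content -> genome statistics, with a manifest.

Every stage writes its outputs under the run directory and the manifest
records parameters, the seed, package version and a sha256 checksum per
output file, so a rerun with the same configuration is byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .code_infer import GeneticCodeCall, export_logo_matrix, infer_code
from .content import (
    OrthogroupMatrix,
    compute_retention,
    infer_ancestral_proteome,
    partition_losses,
)
from .errors import ConfigurationError, StageError
from .hcaa import (
    MarkerAlignment,
    consensus_column_map,
    consensus_sequence,
    identify_hcaa,
    read_alignment_fasta,
    write_alignment_fasta,
    write_hcaa_tsv,
)
from .search import (
    CodonObservationMatrix,
    accumulate,
    hits_to_frame,
    map_hcaa_to_codons,
    translated_search,
)
from .simulate import (
    SimConfig,
    generate_marker_families,
    generate_orthogroup_matrix,
    generate_target_genome,
    write_genome_fasta,
)
from .stats import gc_content, gc_skew

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "tinygenome_run"
    seed: int = 0
    # either simulate everything ...
    simulate: SimConfig | None = None
    # ... or point at real inputs
    genome_fasta: str | None = None
    alignment_fastas: list[str] = field(default_factory=list)
    orthogroup_tsv: str | None = None
    roles_yaml: str | None = None
    # stage parameters
    hcaa_threshold: float = 0.90
    score_threshold: float = 60.0
    stop_penalty: int = -4
    min_count: int = 10
    dominance: float = 0.8
    window: int = 10_000
    step: int = 1_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulate", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        if cfg.simulate is None:
            for name in ("genome_fasta",):
                p = getattr(cfg, name)
                if p is None:
                    raise ConfigurationError(
                        "config must set 'simulate' or provide input paths"
                    )
                if not Path(p).exists():
                    raise ConfigurationError(f"{name}: {p} does not exist")
            for p in cfg.alignment_fastas:
                if not Path(p).exists():
                    raise ConfigurationError(f"alignment file {p} does not exist")
        return cfg


def run_code_inference(
    genome: str,
    families: list[MarkerAlignment],
    hcaa_threshold: float = 0.90,
    score_threshold: float = 60.0,
    stop_penalty: int = -4,
    min_count: int = 10,
    dominance: float = 0.8,
) -> tuple[CodonObservationMatrix, GeneticCodeCall, list]:
    """HCAA scan + six-frame search + codon counting + code call.

    The search query for each family is its consensus sequence.  Returns
    the observation matrix, the genetic-code call and the retained hits.
    """
    observations = []
    all_hits = []
    for fam in families:
        hcaa = identify_hcaa(fam, hcaa_threshold)
        if not hcaa:
            continue
        query = consensus_sequence(fam)
        colmap = consensus_column_map(fam)
        hits = translated_search(
            genome,
            query,
            family_id=fam.family_id,
            query_id=f"{fam.family_id}|consensus",
            score_threshold=score_threshold,
            stop_penalty=stop_penalty,
        )
        all_hits.extend(hits)
        for hit in hits:
            observations.extend(map_hcaa_to_codons(hit, hcaa, colmap, genome))
    matrix = accumulate(observations)
    call = infer_code(matrix, min_count=min_count, dominance=dominance)
    return matrix, call, all_hits


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the manifest.

    A stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages are retained in the run directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("simulate",)
        },
        "stages": {},
        "outputs": {},
    }
    if config.simulate is not None:
        manifest["parameters"]["simulate"] = asdict(config.simulate)

    def record(name: str, path: Path) -> None:
        manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc is not None:
                    logger.error("stage %s: failed after %.2fs", name, dt)
                    raise StageError(name, exc) from exc
                manifest["stages"][name] = round(dt, 4)
                logger.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Timer()

    orthogroups = None
    roles = None
    with stage("inputs"):
        if config.simulate is not None:
            sim = config.simulate
            families, truth_cols = generate_marker_families(sim)
            genome, truth = generate_target_genome(families, sim, truth_cols)
            fam_dir = outdir / "families"
            fam_dir.mkdir(exist_ok=True)
            for fam in families:
                p = fam_dir / f"{fam.family_id}.fasta"
                write_alignment_fasta(fam, p)
                record("families", p)
            gpath = outdir / "genome.fasta"
            write_genome_fasta(genome, gpath)
            record("genome", gpath)
            tpath = outdir / "truth.gff3"
            truth.to_gff3(tpath)
            record("truth", tpath)
            og_df, og_roles, _ = generate_orthogroup_matrix(seed=sim.seed)
            orthogroups = OrthogroupMatrix(og_df, og_roles)
            opath, rpath = outdir / "orthogroups.tsv", outdir / "roles.yaml"
            orthogroups.to_tsv(opath, rpath)
            record("orthogroups", opath)
            record("roles", rpath)
        else:
            from Bio import SeqIO

            recs = list(SeqIO.parse(config.genome_fasta, "fasta"))
            genome = str(recs[0].seq).upper()
            families = [read_alignment_fasta(p) for p in config.alignment_fastas]
            if config.orthogroup_tsv and config.roles_yaml:
                orthogroups = OrthogroupMatrix.from_tsv(
                    config.orthogroup_tsv, config.roles_yaml
                )

    with stage("hcaa"):
        hcaa_all = []
        for fam in families:
            hcaa_all.extend(identify_hcaa(fam, config.hcaa_threshold))
        p = outdir / "hcaa.tsv"
        write_hcaa_tsv(hcaa_all, p)
        record("hcaa", p)

    with stage("search_and_count"):
        matrix, call, hits = run_code_inference(
            genome,
            families,
            hcaa_threshold=config.hcaa_threshold,
            score_threshold=config.score_threshold,
            stop_penalty=config.stop_penalty,
            min_count=config.min_count,
            dominance=config.dominance,
        )
        p = outdir / "hits.tsv"
        hits_to_frame(hits).to_csv(p, sep="\t", index=False)
        record("hits", p)
        p = outdir / "codon_matrix.tsv"
        matrix.to_tsv(p)
        record("matrix", p)

    with stage("code_call"):
        p = outdir / "code_call.json"
        call.to_json(p)
        record("code_call", p)
        p = outdir / "logo_matrix.tsv"
        export_logo_matrix(call, tsv_path=p)
        record("logo_matrix", p)
        manifest["code"] = {
            "selected_table": call.selected_table,
            "reassignments": [
                [r.codon, r.standard_meaning, r.inferred_meaning]
                for r in call.reassignments
            ],
            "total_sites": matrix.total_sites,
        }

    if orthogroups is not None:
        with stage("gene_content"):
            ancestral = infer_ancestral_proteome(orthogroups)
            ledger = partition_losses(ancestral, orthogroups)
            p = outdir / "gene_content.json"
            ledger.to_json(p)
            record("gene_content", p)
            manifest["gene_content"] = ledger.counts()

    with stage("stats"):
        window = min(config.window, len(genome))
        step = min(config.step, window)
        profile = gc_skew(genome, window=window, step=step)
        p = outdir / "gc_skew.tsv"
        profile.to_tsv(p)
        record("gc_skew", p)
        manifest["stats"] = {
            "genome_length": len(genome),
            "gc_content": gc_content(genome),
        }

    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
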
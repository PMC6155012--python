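"""End-to-end orchestration: configuration, seed handling, manifests.

A single global seed expands deterministically into per-stage seeds (a
SeedSequence spawned by stage index), so re-running one stage in isolation
reproduces the full-run result.  Each run writes a manifest recording the
config hash, per-output checksums and record counts; identical configs
reproduce identical checksums for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STAGES = ("simulate_cyto", "simulate_imc", "simulate_rep", "cyto",
          "distinct", "imc", "rep_qc", "clone", "overlap")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([global_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def digest(self) -> str:
        blob = json.dumps({"seed": self.seed, "stages": list(self.stages),
                           "params": self.params}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    counts: dict[str, int] = field(default_factory=dict)    # stage -> records
    wall_clock: dict[str, float] = field(default_factory=dict)

    def record(self, stage: str, path: Path, count: int | None = None) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        self.outputs[str(path)] = h
        if count is not None:
            self.counts[stage] = count

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         sort_keys=True))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the selected stages in dependency order on synthetic data.

    A thin driver over the library: simulate the three data arms, then run
    the suspension, distinctness, imaging, repertoire-QC, clonal and
    overlap analyses, writing each stage's tables under ``out_dir``.
    """
    from . import cytometry, distinctness, imc, overlap, repqc, synthetic

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.digest())
    p = config.params
    state: dict = {}

    def timed(stage):
        return stage in config.stages

    t0 = time.time()
    if timed("simulate_cyto"):
        table = synthetic.gen_cytometry_sample(
            synthetic.default_archetypes(),
            n_cells=p.get("n_cells", 5000),
            seed=stage_seed(config.seed, "simulate_cyto"))
        path = out / "cytometry_events.csv"
        synthetic.write_event_csv(table, path)
        manifest.record("simulate_cyto", path, table.n_events)
        state["cyto_table"] = table
        manifest.wall_clock["simulate_cyto"] = time.time() - t0

    if timed("simulate_rep"):
        t = time.time()
        cfg = synthetic.RepertoireSimConfig(
            n_clones=p.get("n_clones", 500),
            seed=stage_seed(config.seed, "simulate_rep"))
        rep = synthetic.gen_repertoire(cfg)
        path = out / "repertoire.tsv"
        synthetic.write_airr(rep, path)
        manifest.record("simulate_rep", path, len(rep))
        state["repertoire"] = rep
        manifest.wall_clock["simulate_rep"] = time.time() - t

    if timed("cyto") and "cyto_table" in state:
        t = time.time()
        from .panels import EMBED_MARKERS, default_subset_rules
        table = state["cyto_table"]
        seed = stage_seed(config.seed, "cyto")
        coords = cytometry.embed_2d(table, EMBED_MARKERS, seed=seed)
        graph = cytometry.cluster_nodes(coords, table,
                                        k=p.get("k", 100), seed=seed)
        _, labels = cytometry.assign_bubbles(graph, default_subset_rules())
        prof = cytometry.subset_medians(table, labels)
        path = out / "subset_assignments.csv"
        assign = table.data[["sample_id"]].copy()
        assign["node_id"] = graph.node_of_event
        assign["subset"] = labels.to_numpy()
        assign.to_csv(path, index=False)
        manifest.record("cyto", path, len(assign))
        prof.medians.to_csv(out / "subset_medians.tsv", sep="\t")
        manifest.record("cyto", out / "subset_medians.tsv")
        state["labels"] = labels
        state["profiles"] = prof
        manifest.wall_clock["cyto"] = time.time() - t

    if timed("distinct") and "cyto_table" in state:
        t = time.time()
        table = state["cyto_table"]
        truth = table.data["truth_subset"]
        parent = table.select((truth.isin(["naive", "precursor"])).to_numpy())
        focal = table.select((truth == "precursor").to_numpy())
        null = distinctness.bootstrap_null(
            parent, focal.n_events, B=p.get("B", 10_000),
            seed=stage_seed(config.seed, "distinct"))
        res = distinctness.significance_call(
            distinctness.zscore_markers(focal, null))
        path = out / "distinctness.tsv"
        res.table.to_csv(path, sep="\t", index=False)
        manifest.record("distinct", path, len(res.table))
        manifest.wall_clock["distinct"] = time.time() - t

    if timed("rep_qc") and "repertoire" in state:
        t = time.time()
        rep = state["repertoire"]
        kept, _ = repqc.functionality_filter(rep)
        kept, _ = repqc.apply_chimera_filter(kept)
        kept = repqc.annotate_mutations(kept)
        path = out / "repertoire_qc.tsv"
        synthetic.write_airr(kept, path)
        manifest.record("rep_qc", path, len(kept))
        state["repertoire_qc"] = kept
        manifest.wall_clock["rep_qc"] = time.time() - t

    if timed("clone") and "repertoire_qc" in state:
        t = time.time()
        from . import clonal
        rep = state["repertoire_qc"].copy()
        rep["clone_id"] = clonal.define_clones(rep)
        path = out / "repertoire_clones.tsv"
        synthetic.write_airr(rep, path)
        manifest.record("clone", path, int(rep["clone_id"].nunique()))
        state["clones"] = rep
        manifest.wall_clock["clone"] = time.time() - t

    if timed("overlap") and "clones" in state:
        t = time.time()
        rep = state["clones"]
        m = overlap.clone_abundance_matrix(rep)
        path = out / "clone_site_isotype.tsv"
        m.to_csv(path, sep="\t")
        manifest.record("overlap", path, len(m))
        manifest.wall_clock["overlap"] = time.time() - t

    manifest.write(out / "manifest.json")
    return manifest
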
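"""End-to-end orchestration: simulate → call → overlap → enrich → network.

One global seed drives every stage.  Stage seeds are derived as
``(seed * 1_000_003 + stage_offset) % 2**31`` with a fixed offset per
stage/bait, so any stage can be rerun standalone with the same seed it
received inside the pipeline.  The run writes a JSON manifest listing
every output file with its SHA-256 content hash; identical config and
seed yield an identical manifest.
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

from . import annotation, network, overlap, simulate as sim
from .enrichment import CallingParams, call_interactors, interactor_set
from .errors import CopreError
from .io_tables import write_experiment_table, write_results
from .simulate import SimConfig

logger = logging.getLogger(__name__)

_STAGE_OFFSETS = {"simulate": 11, "network": 47}


def derive_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (seed * 1_000_003 + _STAGE_OFFSETS.get(stage, 0) * 1009 + index) % (2**31)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; round-trips through YAML."""

    seed: int = 0
    outdir: str = "copre_run"
    log_level: str = "INFO"
    baits: tuple[str, ...] = ("let7_pd", "mir58_pd", "mir2_pd")
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    calling: dict = field(default_factory=dict)  # CallingParams overrides
    enrich: dict = field(default_factory=lambda: {"min_term_size": 2})
    network: dict = field(
        default_factory=lambda: {"n_permutations": 1000, "extra_edge_rate": 0.01}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "baits" in raw:
            raw["baits"] = tuple(raw["baits"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["baits"] = list(data["baits"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _synthetic_annotations(truth: sim.SimTruth) -> dict[str, set[str]]:
    """Deterministic annotation map for the demo: planted complex term on
    true interactors plus cyclic filler terms on everyone."""
    out: dict[str, set[str]] = {}
    for i in range(truth.config.n_proteins):
        pid = f"SIM{i:05d}"
        out[pid] = {f"filler:{i % 7}"}
        if pid in truth.true_interactors:
            out[pid].add("complex:planted")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; return the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    manifest: dict = {"stages": [], "files": {}, "seed": config.seed}
    params = CallingParams(**config.calling)

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)

    try:
        # simulate + call, per bait; half the planted interactors form a
        # complex core shared across every bait, emulating common co-factors
        base_cfg = SimConfig(**config.simulate)
        core_rng = np.random.default_rng(derive_seed(config.seed, "simulate", 997))
        core_idx = core_rng.choice(
            base_cfg.n_proteins, size=base_cfg.n_true_interactors // 2, replace=False
        )
        shared_core = tuple(f"SIM{i:05d}" for i in sorted(core_idx))

        calls_by_dataset: dict[str, set[str]] = {}
        truths: dict[str, sim.SimTruth] = {}
        lengths_by_bait = {}
        for i, bait in enumerate(config.baits):
            stage_seed = derive_seed(config.seed, "simulate", i)
            sim_cfg = SimConfig(
                **{**config.simulate, "seed": stage_seed,
                   "forced_true_interactors": shared_core}
            )
            table, records, truth = sim.simulate_experiment(sim_cfg)
            truths[bait] = truth
            lengths = {r.protein_id: r.length_aa for r in records}
            lengths_by_bait[bait] = lengths
            counts_path = outdir / f"{bait}.counts.tsv"
            write_experiment_table(table, counts_path)
            record(counts_path)

            calls = call_interactors(table, lengths, params)
            calls_path = outdir / f"{bait}.calls.tsv"
            write_results(
                calls, calls_path,
                parameters=dataclasses.asdict(params), seed=stage_seed,
            )
            record(calls_path)
            record(calls_path.with_suffix(".tsv.summary.json"))
            calls_by_dataset[bait] = interactor_set(calls)
            logger.info("%s: %d interactors called", bait, len(calls_by_dataset[bait]))
        manifest["stages"].append({"stage": "simulate+call", "status": "ok"})

        # overlap
        matrix = overlap.build_membership(calls_by_dataset)
        summary = overlap.summarize_overlap(matrix)
        overlap_path = outdir / "overlap.json"
        overlap_path.write_text(
            json.dumps(
                {
                    "union_size": summary.union_size,
                    "pattern_counts": {
                        "|".join(sorted(p)): c for p, c in sorted(
                            summary.pattern_counts.items(), key=lambda kv: sorted(kv[0])
                        )
                    },
                    "category_counts": summary.category_counts,
                    "at_least_2": overlap.count_at_least_k(matrix, 2),
                },
                sort_keys=True, indent=2,
            ) + "\n",
            encoding="utf-8",
        )
        record(overlap_path)
        manifest["stages"].append({"stage": "overlap", "status": "ok"})

        # enrichment on the first bait's calls against its simulated proteome
        first = config.baits[0]
        annotations = _synthetic_annotations(truths[first])
        results = annotation.enrich_terms(
            calls_by_dataset[first] & set(annotations),
            set(annotations),
            annotations,
            min_term_size=config.enrich.get("min_term_size", 2),
        )
        enrich_path = outdir / "enrichment.tsv"
        write_results(results, enrich_path, parameters=dict(config.enrich))
        record(enrich_path)
        record(enrich_path.with_suffix(".tsv.summary.json"))
        manifest["stages"].append({"stage": "enrich", "status": "ok"})

        # network: planted-complex edges + sparse random background
        net_seed = derive_seed(config.seed, "network")
        universe = sorted(lengths_by_bait[first])
        edges = _synthetic_edges(truths[first], universe,
                                 config.network.get("extra_edge_rate", 0.01), net_seed)
        enrichment = network.permutation_edge_test(
            edges,
            calls_by_dataset[first],
            universe,
            n_permutations=config.network.get("n_permutations", 1000),
            seed=net_seed,
        )
        net_path = outdir / "network.json"
        net_path.write_text(
            json.dumps(dataclasses.asdict(enrichment), sort_keys=True, indent=2) + "\n",
            encoding="utf-8",
        )
        record(net_path)
        manifest["stages"].append({"stage": "network", "status": "ok"})
        manifest["status"] = "ok"
    except CopreError as exc:
        manifest["stages"].append({"stage": "failed", "status": "error", "error": str(exc)})
        manifest["status"] = "error"
        _write_manifest(manifest, outdir)
        raise

    _write_manifest(manifest, outdir)
    return manifest


def _synthetic_edges(truth: sim.SimTruth, universe: list[str],
                     extra_edge_rate: float, seed: int) -> list[tuple[str, str]]:
    """Clique among planted interactors plus uniform background edges."""
    rng = np.random.default_rng(seed)
    members = sorted(truth.true_interactors)
    edges = [(a, b) for i, a in enumerate(members) for b in members[i + 1:]]
    n = len(universe)
    n_extra = int(extra_edge_rate * n * (n - 1) / 2)
    if n_extra:
        idx = rng.integers(0, n, size=(n_extra, 2))
        edges.extend(
            (universe[a], universe[b]) for a, b in idx if a != b
        )
    return edges


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
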
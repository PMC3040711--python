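"""End-to-end orchestration: distances -> percolation -> topology ->
null model -> intermediates -> hybrid scenarios -> threshold sweeps.

``run_full_analysis`` executes, for each metric (RD, SAD): the pairwise
matrix, the percolation profile and Dp, the threshold graph at Dp with node
statistics and the rewiring null model, and the intermediate-individual
report.  Optionally it then builds the four hybrid scenarios (F1, BC_spi,
BC_ves, BC_mixed), replacing the detected natural putative hybrids by the
same number of simulated ones, and sweeps the SAD network across a
threshold ladder.  Every run writes a machine-readable JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .distances import RD, SAD, pairwise_matrix
from .errors import HybnetError
from .genotype_io import GenotypeDataset, read_csv_genotypes, write_dataset
from .hybrid_sim import SCENARIOS
from .network_analysis import (
    build_graph,
    find_intermediates,
    node_statistics,
    percolation_profile,
    rewiring_null_model,
    threshold_sweep,
    write_graphml,
)
from .synthetic_data import inject_hybrids

log = logging.getLogger("hybnet.pipeline")

DEFAULT_SAD_SWEEP = (0.5, 0.39, 0.33, 0.28)


@dataclass
class RunConfig:
    seed: int = 0
    null_iterations: int = 1000
    scenarios: tuple[str, ...] = ()  # subset of SCENARIOS; empty = skip
    n_hybrids: int | None = None  # default: number of detected intermediates
    sad_sweep_thresholds: tuple[float, ...] = DEFAULT_SAD_SWEEP

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "scenarios" in data:
            data["scenarios"] = tuple(data["scenarios"])
        if "sad_sweep_thresholds" in data:
            data["sad_sweep_thresholds"] = tuple(data["sad_sweep_thresholds"])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "null_iterations": self.null_iterations,
            "scenarios": list(self.scenarios),
            "n_hybrids": self.n_hybrids,
            "sad_sweep_thresholds": list(self.sad_sweep_thresholds),
        }


@dataclass
class RunManifest:
    run_id: str
    input_path: str
    input_sha256: str
    config: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # name -> {wall_time_s, outputs}
    failed_stage: str | None = None

    def record(self, stage: str, wall_time: float, outputs: list[str]) -> None:
        self.stages[stage] = {
            "wall_time_s": round(wall_time, 4),
            "outputs": outputs,
        }

    def all_outputs(self) -> list[str]:
        return [p for st in self.stages.values() for p in st["outputs"]]

    def write(self, path: str | Path) -> None:
        data = {
            "run_id": self.run_id,
            "input_path": self.input_path,
            "input_sha256": self.input_sha256,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "failed_stage": self.failed_stage,
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(
    dataset_path: str | Path,
    config: RunConfig | None = None,
    outdir: str | Path = "hybnet_out",
) -> RunManifest:
    """Run the whole analysis on a CSV genotype table; returns the manifest.

    Any stage error aborts the run after writing a partial manifest naming
    the failed stage.
    """
    config = config or RunConfig()
    dataset_path = Path(dataset_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    input_hash = _sha256(dataset_path)
    run_id = hashlib.sha1(
        f"{input_hash}:{config.seed}:{__version__}".encode()
    ).hexdigest()[:12]
    manifest = RunManifest(
        run_id=run_id,
        input_path=str(dataset_path),
        input_sha256=input_hash,
        config=config.to_dict(),
        seed=config.seed,
        version=__version__,
    )
    manifest_path = outdir / "manifest.json"
    header = f"run_id={run_id} seed={config.seed} hybnet={__version__}"

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                outputs = fn()
            except HybnetError:
                manifest.failed_stage = name
                manifest.write(manifest_path)
                raise
            manifest.record(name, time.perf_counter() - t0, [str(p) for p in outputs])
            return outputs

        return deco

    dataset = read_csv_genotypes(dataset_path)
    log.info("loaded %d individuals, %d loci", len(dataset), dataset.n_loci)

    results: dict[str, dict] = {}
    for metric in (RD, SAD):
        mdir = outdir / metric.lower()
        mdir.mkdir(exist_ok=True)
        ctx: dict = {}

        @stage(f"{metric}.matrix")
        def _matrix(metric=metric, mdir=mdir, ctx=ctx):
            ctx["matrix"] = pairwise_matrix(dataset, metric)
            path = mdir / "matrix.tsv"
            ctx["matrix"].to_tsv(path, header=header)
            return [path]

        @stage(f"{metric}.percolation")
        def _percolation(metric=metric, mdir=mdir, ctx=ctx):
            ctx["profile"] = percolation_profile(ctx["matrix"])
            path = mdir / "percolation_profile.tsv"
            ctx["profile"].to_tsv(path, header=header)
            log.info("%s: Dp=%s (last connected: %s)", metric,
                     ctx["profile"].dp, ctx["profile"].dp_last_connected)
            return [path]

        @stage(f"{metric}.topology")
        def _topology(metric=metric, mdir=mdir, ctx=ctx):
            g = build_graph(ctx["matrix"], ctx["profile"].dp)
            ctx["graph"] = g
            ctx["stats"] = node_statistics(g)
            ctx["intermediates"] = find_intermediates(g)
            log.info(
                "%s graph at Dp: %d nodes, %d edges, <CC>=%.3f, %d intermediates",
                metric, g.number_of_nodes(), g.number_of_edges(),
                ctx["stats"].avg_clustering, len(ctx["intermediates"].ids),
            )
            gpath = mdir / "network_at_dp.graphml"
            write_graphml(g, gpath, ctx["stats"], ctx["intermediates"], run_id=run_id)
            spath = mdir / "node_stats.tsv"
            with open(spath, "w", encoding="utf-8") as fh:
                fh.write(f"# {header}\n")
                ctx["stats"].table.to_csv(fh, sep="\t", index=False)
            ipath = mdir / "intermediates.tsv"
            with open(ipath, "w", encoding="utf-8") as fh:
                fh.write(f"# {header} separates_species="
                         f"{ctx['intermediates'].separates_species}\n")
                ctx["intermediates"].table.to_csv(fh, sep="\t", index=False)
            return [gpath, spath, ipath]

        @stage(f"{metric}.null_model")
        def _null(metric=metric, mdir=mdir, ctx=ctx):
            null = rewiring_null_model(
                ctx["graph"], n_iter=config.null_iterations, seed=config.seed
            )
            ctx["null"] = null
            log.info("%s null: <CC_o>=%.3f sd=%.3f z=%s", metric,
                     null.mean_cc, null.sd_cc, null.z_score)
            path = mdir / "null_model.json"
            payload = {"run_id": run_id, **null.to_dict()}
            path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
            return [path]

        results[metric] = ctx

    if config.scenarios:
        sad_ctx = results[SAD]
        replace_ids = set(sad_ctx["intermediates"].ids)
        n_hyb = config.n_hybrids if config.n_hybrids is not None else len(replace_ids)
        for scenario in config.scenarios:
            if scenario not in SCENARIOS:
                raise HybnetError(f"unknown scenario {scenario!r}")
            sdir = outdir / f"scenario_{scenario.lower()}"
            sdir.mkdir(exist_ok=True)

            @stage(f"scenario.{scenario}")
            def _scenario(scenario=scenario, sdir=sdir):
                inj = inject_hybrids(
                    dataset, scenario, n_hyb, seed=config.seed,
                    replace_ids=replace_ids,
                )
                dpath = sdir / "dataset.csv"
                write_dataset(inj.dataset, dpath, format="csv")
                tpath = sdir / "truth.tsv"
                inj.write_truth(tpath)
                matrix = pairwise_matrix(inj.dataset, SAD)
                sweep = threshold_sweep(matrix, config.sad_sweep_thresholds)
                wpath = sdir / "sweep.tsv"
                with open(wpath, "w", encoding="utf-8") as fh:
                    fh.write(f"# {header} scenario={scenario}\n")
                    sweep.to_csv(fh, sep="\t", index=False)
                return [dpath, tpath, wpath]

    manifest.write(manifest_path)
    manifest.record("manifest", 0.0, [str(manifest_path)])
    manifest.write(manifest_path)
    return manifest
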
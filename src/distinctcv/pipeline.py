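"""End-to-end orchestration: simulate/partition/evaluate/compare in one run.

A :class:`RunConfig` (typically loaded from YAML) drives the stages; every
output lands in one directory together with a machine-readable manifest
recording the root seed, all parameters, package version and per-stage
timings, which suffices to reproduce any output exactly.  All randomness
flows from the single root seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .distinctness import (
    collection_distinctness,
    compute_pairwise_distances,
    distinctness_table,
)
from .evaluation import RegressionSpec, compare_methods, evaluate_collection
from .io import (
    read_expression,
    read_targets,
    write_expression,
    write_partitions,
    write_results,
    write_targets,
)
from .partitioners import SAConfig, clustered_kfold, random_kfold, sacv_generate
from .synthetic import SyntheticConfig, generate_conditions, generate_targets

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("distinctcv")


@dataclass
class RunConfig:
    """Configuration of a composite run.

    Either ``synthetic`` parameters (a dict of :class:`SyntheticConfig`
    overrides) or explicit ``expression``/``targets`` paths must be given.
    ``partitions`` is a list of dicts, each with a ``kind`` (rcv/ccv/sacv)
    plus that generator's parameters; ``methods`` lists the regressors to
    evaluate on every generated collection.
    """

    outdir: str
    seed: int = 0
    synthetic: Optional[dict] = None
    expression: Optional[str] = None
    targets: Optional[str] = None
    transpose: bool = False
    zscore_distances: bool = False
    global_zscore: bool = False
    partitions: list = field(default_factory=lambda: [{"kind": "rcv", "k": 6}])
    methods: list = field(default_factory=lambda: ["lars"])
    compare: Optional[list] = None  # [method_a, method_b]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def validate(self) -> None:
        if self.synthetic is None and (self.expression is None or self.targets is None):
            raise ValueError("config needs either synthetic parameters or input paths")
        for p in (self.expression, self.targets):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        for m in self.methods:
            RegressionSpec(method=m)  # validates the name
        if self.compare is not None:
            if len(self.compare) != 2 or any(m not in self.methods for m in self.compare):
                raise ValueError("compare must name two of the evaluated methods")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest that was written."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "distinctcv",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": [],
    }

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s: started", name)

        def done():
            dt = time.perf_counter() - t0
            manifest["stages"][name] = round(dt, 3)
            log.info("stage %s: finished in %.2fs", name, dt)

        return done

    def emit(path: Path) -> Path:
        manifest["outputs"].append(path.name)
        return path

    # --- data ---------------------------------------------------------
    done = stage("data")
    if config.synthetic is not None:
        syn = SyntheticConfig(**{**config.synthetic, "seed": config.seed})
        conditions, labels = generate_conditions(syn)
        targets, coeffs = generate_targets(conditions, labels, syn)
        write_expression(conditions, emit(outdir / "expression.tsv"))
        write_targets(targets, emit(outdir / "targets.tsv"))
        with open(emit(outdir / "labels.tsv"), "w") as fh:
            fh.write("condition_id\tcluster\n")
            for cid, lab in zip(conditions.condition_ids, labels):
                fh.write(f"{cid}\t{lab}\n")
        coeff_payload = {
            "gene_ids": list(targets.gene_ids),
            "feature_ids": list(conditions.feature_ids),
            "base": coeffs.base.tolist(),
            "per_cluster": {str(c): m.tolist() for c, m in coeffs.per_cluster.items()},
        }
        emit(outdir / "true_coefficients.json").write_text(
            json.dumps(coeff_payload) + "\n"
        )
    else:
        conditions = read_expression(config.expression, transpose=config.transpose)
        targets = read_targets(config.targets)
        targets.check_aligned(conditions)
    done()

    # --- distances ----------------------------------------------------
    done = stage("distances")
    distances = compute_pairwise_distances(
        conditions, zscore_features=config.zscore_distances
    )
    done()

    # --- partitions ---------------------------------------------------
    done = stage("partitions")
    collections: dict[str, object] = {}
    for j, pspec in enumerate(config.partitions):
        pspec = dict(pspec)
        kind = pspec.pop("kind")
        seed = pspec.pop("seed", config.seed + j)
        name = f"{kind}{j}"
        if kind == "rcv":
            coll = random_kfold(conditions.n_conditions, pspec.get("k", 6), seed)
        elif kind == "ccv":
            coll = clustered_kfold(conditions, pspec.get("k", 6), seed)
        elif kind == "sacv":
            sa = SAConfig(seed=seed, **pspec)
            coll, trace = sacv_generate(conditions, distances, sa)
            trace.to_csv(emit(outdir / f"{name}_trace.tsv"), sep="\t", index=False)
        else:
            raise ValueError(f"unknown partition kind {kind!r}")
        collections[name] = coll
        write_partitions(
            coll, conditions.condition_ids, emit(outdir / f"{name}_partitions.json"),
            seed=seed, meta=pspec,
        )
        distinctness_table(coll, distances, conditions.condition_ids).to_csv(
            emit(outdir / f"{name}_distinctness.tsv"), sep="\t", index=False
        )
        if coll.kind in ("rcv", "ccv"):
            log.info(
                "collection %s: distinctness %.4f",
                name,
                collection_distinctness(coll, distances),
            )
    done()

    # --- evaluation ---------------------------------------------------
    done = stage("evaluation")
    results: dict[tuple[str, str], object] = {}
    for name, coll in collections.items():
        for method in config.methods:
            spec = RegressionSpec(method=method, seed=config.seed)
            res = evaluate_collection(
                conditions, targets, coll, spec, distances,
                global_zscore=config.global_zscore,
            )
            results[(name, method)] = res
            write_results(res, emit(outdir / f"results_{name}_{method}.tsv"))
            if res.pooled_pcc is not None:
                res.pooled_pcc.to_csv(
                    emit(outdir / f"pooled_pcc_{name}_{method}.tsv"), sep="\t",
                    index_label="gene_id",
                )
    done()

    # --- comparison ---------------------------------------------------
    if config.compare is not None:
        done = stage("comparison")
        a, b = config.compare
        for name in collections:
            diff, summary = compare_methods(results[(name, a)], results[(name, b)])
            diff.to_csv(emit(outdir / f"compare_{name}_{a}_vs_{b}.tsv"), sep="\t", index=False)
            summary.to_csv(
                emit(outdir / f"compare_{name}_{a}_vs_{b}_summary.tsv"), sep="\t"
            )
        done()

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
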
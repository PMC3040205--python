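"""End-to-end orchestration: simulate -> estimate -> summarize -> totals ->
pairwise tests, with a manifest that makes any run reproducible."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._rng import subseed
from .datatypes import COLORS
from .disttest import bonferroni_threshold, pairwise_matrix
from .estimate import estimate_cohort
from .io import (
    load_table1_census,
    load_table2_means,
    read_census,
    read_genotypes,
    read_panel,
    write_ancestry,
    write_genotypes,
    write_panel,
    write_summary,
)
from .simulate import SimulationConfig, simulate_cohort, simulate_reference_panel
from .summary import summarize
from .total import total_ancestry_table

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one run; YAML-serializable.

    ``simulate`` holds the synthetic-data block (or None to read
    ``genotypes``/``panel`` from disk); ``census`` is ``"builtin"``, a CSV
    path, an inline {region: [white, brown, black]} mapping, or None to
    skip the total-ancestry stage. ``paper_tables`` short-circuits
    estimation and runs the weighting stage on the packaged printed tables.
    """

    seed: int = 0
    out_dir: str = "trimix_out"
    alpha: float = 0.05
    n_cycles: int = 10_000
    paper_tables: bool = False
    simulate: dict | None = None
    genotypes: str | None = None
    panel: str | None = None
    census: object = None
    estimate: dict = field(default_factory=dict)
    disttest_color: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_canonical_json(self) -> str:
        d = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        # out_dir and log_level do not affect the numbers; excluding them
        # keeps provenance headers identical across re-runs into new paths
        d = {
            k: getattr(self, k)
            for k in sorted(self.__dataclass_fields__)
            if k not in ("out_dir", "log_level")
        }
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def _simulation_config(block: dict, seed: int) -> SimulationConfig:
    cohorts = block.get("cohorts", [])
    sizes = {(c["region"], c["color"]): int(c["n"]) for c in cohorts}
    alphas = {(c["region"], c["color"]): tuple(map(float, c["dirichlet"])) for c in cohorts}
    return SimulationConfig(
        fst=float(block.get("fst", 0.15)),
        n_loci=int(block.get("n_loci", 40)),
        ancestral_freq_range=tuple(block.get("ancestral_freq_range", (0.1, 0.9))),
        dirichlet_params=alphas,
        cohort_sizes=sizes,
        seed=subseed(seed, "simulate"),
        fixed_differences=bool(block.get("fixed_differences", False)),
    )


def _census_frame(census) -> pd.DataFrame | None:
    if census is None:
        return None
    if census == "builtin":
        return load_table1_census()
    if isinstance(census, dict):
        return pd.DataFrame(
            [
                {"region": r, "white_pct": w, "brown_pct": b, "black_pct": bl}
                for r, (w, b, bl) in census.items()
            ]
        )
    return read_census(census)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    Every output file carries provenance comments (config hash + seed) and
    the manifest records enough to reproduce the run byte-for-byte. A stage
    failure aborts with the stage name prepended to the cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = [f"trimix {__version__}", f"config {config.config_hash()}", f"seed {config.seed}"]
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.to_canonical_json()),
        "config_hash": config.config_hash(),
        "outputs": [],
    }

    def _emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    current_stage = "setup"

    def _stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("stage: %s", name)

    try:
        if config.paper_tables:
            _stage("paper-tables")
            means = load_table2_means()
            census = load_table1_census()
            totals = total_ancestry_table(means, census)
            totals.to_csv(_emit("total_ancestry.csv"), index=False, float_format="%.10g")
            # pairwise comparisons are among the fully sampled regions
            n_regions = len(totals)
            n_pairs = n_regions * (n_regions - 1) // 2
            manifest["bonferroni_alpha"] = bonferroni_threshold(config.alpha, n_pairs)
            manifest["n_comparisons"] = n_pairs
        else:
            if config.simulate is not None:
                _stage("simulate")
                sim_cfg = _simulation_config(config.simulate, config.seed)
                panel = simulate_reference_panel(sim_cfg)
                cohort = simulate_cohort(panel, sim_cfg)
                genotypes = cohort.genotypes
                write_panel(panel, _emit("panel.tsv"), header_comments=provenance)
                write_genotypes(genotypes, _emit("genotypes.tsv"), header_comments=provenance)
                truth = pd.DataFrame(cohort.true_ancestry, columns=["european", "african", "amerindian"])
                truth.insert(0, "id", genotypes.individual_ids)
                truth.to_csv(_emit("true_ancestry.tsv"), sep="\t", index=False, float_format="%.10g")
            else:
                _stage("load")
                if not config.genotypes or not config.panel:
                    raise ValueError("either a simulate block or genotypes+panel paths are required")
                genotypes = read_genotypes(config.genotypes)
                panel = read_panel(config.panel)

            _stage("estimate")
            ancestries = estimate_cohort(
                genotypes,
                panel,
                tol=float(config.estimate.get("tol", 1e-8)),
                max_iter=int(config.estimate.get("max_iter", 2000)),
            )
            write_ancestry(ancestries, genotypes, _emit("ancestry.tsv"), header_comments=provenance)

            _stage("summarize")
            summaries = summarize(ancestries, genotypes.labels)
            write_summary(summaries, _emit("summary.csv"), header_comments=provenance)

            census = _census_frame(config.census)
            if census is not None:
                _stage("total-ancestry")
                rows = []
                for s in summaries:
                    rows.append(
                        {
                            "region": s.region,
                            "color": s.color,
                            "european_mean": s.mean[0],
                            "african_mean": s.mean[1],
                            "amerindian_mean": s.mean[2],
                        }
                    )
                totals = total_ancestry_table(pd.DataFrame(rows), census)
                totals.to_csv(_emit("total_ancestry.csv"), index=False, float_format="%.10g")

            _stage("disttest")
            groups: dict[str, list] = {}
            for av, (region, color) in zip(ancestries, genotypes.labels):
                if av.error is not None:
                    continue
                if config.disttest_color is not None:
                    if color != config.disttest_color:
                        continue
                    key = region
                else:
                    key = f"{region}/{color}"
                groups.setdefault(key, []).append(av)
            if len(groups) >= 2:
                results, mat = pairwise_matrix(
                    sorted(groups.items()),
                    n_cycles=config.n_cycles,
                    seed=subseed(config.seed, "disttest"),
                    alpha=config.alpha,
                )
                with open(_emit("distance_matrix.csv"), "w") as fh:
                    for line in provenance + [f"n_cycles {config.n_cycles}", f"alpha {config.alpha}"]:
                        fh.write(f"# {line}\n")
                    mat.to_csv(fh, float_format="%.10g")
                long = pd.DataFrame(
                    [
                        {
                            "cohort_a": r.cohort_a,
                            "cohort_b": r.cohort_b,
                            "D": r.D_obs,
                            "p_value": r.p_value,
                            "alpha_adjusted": r.alpha_adjusted,
                            "significant": r.significant,
                        }
                        for r in results
                    ]
                )
                with open(_emit("distance_pairs.csv"), "w") as fh:
                    for line in provenance + [f"n_cycles {config.n_cycles}", f"alpha {config.alpha}"]:
                        fh.write(f"# {line}\n")
                    long.to_csv(fh, index=False, float_format="%.10g")
            else:
                logger.info("fewer than 2 cohorts for distance testing; stage skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current_stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
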
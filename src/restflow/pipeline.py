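"""End-to-end orchestration: simulate or load a six-condition dataset, then
preprocess -> transform -> distributions -> groups -> enrichment -> sweep,
writing stage TSVs plus a machine-readable JSON report.

All randomness flows through the single configured seed, so a rerun with an
identical configuration produces a byte-identical report.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .distributions import abs_kde, ks_two_sample, relative_distribution
from .enrichment import GeneSetCollection, ora_report
from .groups import select_groups, sensitivity_sweep
from .preprocess import run_preprocess
from .synthetic import PlantedSet, RawDataset, SimConfig, generate_dataset, planted_collection
from .transform import flow_ratios, rotated_profile, summarize_geometry, time_average

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either ``simulate`` is set (synthetic mode) or the three input paths
    (``intensities``, ``detection_p``, ``annotations``) point to TSV files.
    A GMT path may be supplied in either mode; in synthetic mode it defaults
    to the generator's planted sets plus random decoys.
    """

    outdir: Path
    seed: int = 0
    simulate: SimConfig | None = None
    intensities: Path | None = None
    detection_p: Path | None = None
    annotations: Path | None = None
    gmt: Path | None = None
    floor: float | None = 10.0
    detection_alpha: float = 0.01
    quantile: bool = True
    fraction: float = 0.01
    sweep_sizes: tuple[int, int, int] = (5, 200, 5)  # min, max, step
    n_decoy_sets: int = 30
    alpha: float = 0.05

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("intensities", "detection_p", "annotations"):
                path = getattr(self, name)
                if path is None:
                    raise PipelineError(f"[config] {name} path required when not simulating")
                if not Path(path).exists():
                    raise PipelineError(f"[config] {name} path does not exist: {path}")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise PipelineError(f"[config] gene-set path does not exist: {self.gmt}")
        if self.simulate is None and self.gmt is None:
            raise PipelineError("[config] a GMT gene-set file is required when not simulating")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim = None
        if "simulate" in raw and raw["simulate"] is not None:
            sim_raw = dict(raw.pop("simulate"))
            planted = tuple(
                PlantedSet(**entry) for entry in sim_raw.pop("planted_sets", [])
            )
            sim = SimConfig(planted_sets=planted, **sim_raw)
        paths = {
            key: Path(raw.pop(key)) if raw.get(key) is not None else raw.pop(key, None)
            for key in ("intensities", "detection_p", "annotations", "gmt")
            if key in raw
        }
        if "sweep_sizes" in raw:
            raw["sweep_sizes"] = tuple(raw["sweep_sizes"])
        return cls(outdir=Path(raw.pop("outdir")), simulate=sim, **paths, **raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        value = float(obj)
        return value if np.isfinite(value) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _stage(name: str):
    def decorator(func):
        def wrapper(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-label with stage name
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapper

    return decorator


@_stage("distributions")
def _distribution_block(table: pd.DataFrame) -> dict:
    abs_x = np.abs(table["x"].to_numpy())
    abs_y = np.abs(table["y"].to_numpy())
    abs_xp = np.abs(table["x_prime"].to_numpy())
    abs_yp = np.abs(table["y_prime"].to_numpy())
    curves = {
        "abs_x": abs_kde(abs_x),
        "abs_y": abs_kde(abs_y),
        "abs_x_prime": abs_kde(abs_xp),
        "abs_y_prime": abs_kde(abs_yp),
    }
    ks_xy = ks_two_sample(abs_x, abs_y)
    ks_prime = ks_two_sample(abs_xp, abs_yp)
    rel_xy = relative_distribution(abs_y, abs_x)
    rel_prime = relative_distribution(abs_yp, abs_xp)

    def _decile_means(rel):
        n = rel.quantile_grid.size
        tenth = max(1, n // 10)
        return (
            float(np.mean(rel.rel_density[:tenth])),
            float(np.mean(rel.rel_density[-tenth:])),
        )

    low_xy, high_xy = _decile_means(rel_xy)
    low_prime, high_prime = _decile_means(rel_prime)
    summary = {
        "magnitudes": {
            name: {"mean_abs": c.mean_abs, "max_abs": c.max_abs, "bandwidth": c.bandwidth}
            for name, c in curves.items()
        },
        "ks": {
            "abs_x_vs_abs_y": {"D": ks_xy[0], "p": ks_xy[1]},
            "abs_x_prime_vs_abs_y_prime": {"D": ks_prime[0], "p": ks_prime[1]},
        },
        "relative_distribution": {
            "abs_y_vs_abs_x": {"lowest_decile_mean": low_xy, "highest_decile_mean": high_xy},
            "abs_y_prime_vs_abs_x_prime": {
                "lowest_decile_mean": low_prime,
                "highest_decile_mean": high_prime,
            },
        },
    }
    return {"summary": summary, "curves": curves, "rel": {"abs_y_vs_abs_x": rel_xy, "abs_y_prime_vs_abs_x_prime": rel_prime}}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write outputs under ``config.outdir``.

    Returns the report dict (also written to ``report.json``).  Any stage
    failure raises :class:`PipelineError` labeled with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- acquire data -----------------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        dataset: RawDataset = _stage("simulate")(generate_dataset)(sim)
        rio.write_dataset(dataset, outdir / "dataset")
    else:
        dataset = _stage("load")(rio.read_dataset)(
            config.intensities, config.detection_p, config.annotations
        )

    # --- preprocess -------------------------------------------------------
    profile = _stage("preprocess")(run_preprocess)(
        dataset.intensities,
        dataset.detection_p,
        dataset.annotations,
        floor=config.floor,
        alpha=config.detection_alpha,
        quantile=config.quantile,
    )
    rio.write_table(profile.log2_expr, outdir / "expression.tsv")

    # --- transform --------------------------------------------------------
    table = _stage("transform")(
        lambda expr: rotated_profile(time_average(flow_ratios(expr)))
    )(profile.log2_expr)
    table.insert(0, "gene", profile.symbols.reindex(table.index).to_numpy())
    rio.write_table(table, outdir / "ratios.tsv")
    geometry = _stage("transform")(summarize_geometry)(table)

    # --- distributions ----------------------------------------------------
    dist = _distribution_block(table)
    for name, curve in dist["curves"].items():
        rio.write_table(
            pd.DataFrame({"grid": curve.grid, "density": curve.density}).set_index("grid"),
            outdir / f"density_{name}.tsv",
        )
    for name, rel in dist["rel"].items():
        rio.write_table(
            pd.DataFrame(
                {"quantile": rel.quantile_grid, "rel_density": rel.rel_density}
            ).set_index("quantile"),
            outdir / f"reldist_{name}.tsv",
        )

    # --- groups -----------------------------------------------------------
    y_prime = pd.Series(
        table["y_prime"].to_numpy(), index=table["gene"].to_numpy(), name="y_prime"
    )
    signature = _stage("groups")(select_groups)(y_prime, fraction=config.fraction)
    (outdir / "group_a.txt").write_text("\n".join(signature.group_a) + "\n")
    (outdir / "group_b.txt").write_text("\n".join(signature.group_b) + "\n")
    rio.write_gmt(
        [("GROUP_A", signature.group_a), ("GROUP_B", signature.group_b)],
        outdir / "groups.gmt",
    )

    # --- gene-set collection ---------------------------------------------
    universe = [str(g) for g in y_prime.index]
    if config.gmt is not None:
        raw_sets = _stage("genesets")(rio.read_gmt)(config.gmt)
        collection = GeneSetCollection.from_sets(raw_sets, universe)
    else:
        collection = _stage("genesets")(planted_collection)(
            dataset, n_decoy_sets=config.n_decoy_sets, seed=config.seed + 1
        )
        collection = GeneSetCollection.from_sets(
            [(name, list(m)) for name, m in collection.sets.items()], universe
        )
        rio.write_gmt(collection, outdir / "gene_sets.gmt")

    # --- enrichment -------------------------------------------------------
    enrich = {}
    for label, genes in (("group_a", signature.group_a), ("group_b", signature.group_b)):
        report = _stage("enrichment")(ora_report)(genes, collection, alpha=config.alpha)
        rio.write_table(report.set_index("set"), outdir / f"enrichment_{label}.tsv")
        enrich[label] = report

    # --- sensitivity sweep ------------------------------------------------
    lo, hi, step = config.sweep_sizes
    sorted_all = y_prime.rename_axis("gene").reset_index()
    ranked_up = sorted_all[sorted_all["y_prime"] > 0].sort_values(
        ["y_prime", "gene"], ascending=[False, True], kind="stable"
    )["gene"].tolist()
    ranked_down = sorted_all[sorted_all["y_prime"] < 0].sort_values(
        ["y_prime", "gene"], ascending=[True, True], kind="stable"
    )["gene"].tolist()
    sweeps = {}
    for label, ranked in (("group_a", ranked_up), ("group_b", ranked_down)):
        sizes = [k for k in range(lo, hi + 1, step) if k <= len(ranked)]
        if len(sizes) < len(range(lo, hi + 1, step)):
            logger.warning("%s: sweep truncated to max size %d", label, sizes[-1] if sizes else 0)
        result = _stage("sweep")(sensitivity_sweep)(
            ranked, collection, sizes, alpha=config.alpha
        )
        rio.write_table(result.fdr, outdir / f"sweep_{label}.tsv")
        sweeps[label] = result

    # --- report -----------------------------------------------------------
    report = {
        "parameters": {
            "seed": config.seed,
            "floor": config.floor,
            "detection_alpha": config.detection_alpha,
            "quantile": config.quantile,
            "fraction": config.fraction,
            "sweep_sizes": list(config.sweep_sizes),
            "alpha": config.alpha,
            "simulated": config.simulate is not None,
        },
        "provenance": profile.provenance,
        "geometry": geometry,
        "distributions": dist["summary"],
        "groups": {
            "group_a_size": len(signature.group_a),
            "group_b_size": len(signature.group_b),
            "universe_size": signature.universe_size,
        },
        "enrichment": {
            label: frame.head(5)[["set", "k", "m", "p", "q", "significant"]].to_dict(
                orient="records"
            )
            for label, frame in enrich.items()
        },
        "sweep": {
            label: {
                "first_significant_size": result.first_significant_size,
                "min_fdr_size": result.min_fdr_size,
            }
            for label, result in sweeps.items()
        },
    }
    report = _jsonable(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    try:
        version = metadata.version("restflow")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    log_lines = [f"restflow {version}", f"seed {config.seed}"]
    log_lines += [f"{k} {v}" for k, v in sorted(report["parameters"].items())]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
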
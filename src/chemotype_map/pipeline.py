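"""Pipeline orchestration and resolved-configuration handling.

Runs the stages in study order — peak tables -> feature matrix -> Bray-Curtis
resemblance -> group-average dendrogram -> chemogroups; aligned FASTA ->
p-distances -> neighbor-joining tree -> phylogroups; then the metabogenomic
integration report.  Every intermediate is written so partial failures leave
inspectable output, and matrices are serialised at 4 decimal places (full
precision is kept in memory).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import chemotype, features, integrate, phylo

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-named failure of the end-to-end run."""


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its stage's default."""

    threshold: float = 10.0
    rt_window: tuple[float, float] = (10.0, 30.0)
    rt_tol: float = 0.10
    mass_tol: float = 1.0
    min_occurrence: int = 1
    cut_similarity: float = 50.0
    max_halogens: int = 8
    min_score: float = 0.95
    min_halogens: int = 2
    k_phylogroups: int = 2
    divergence_thresholds: dict = field(
        default_factory=lambda: dict(phylo.DIVERGENCE_THRESHOLDS_PCT)
    )
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        """Build a config from a flat mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise PipelineError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "rt_window" in kwargs:
            kwargs["rt_window"] = tuple(kwargs["rt_window"])
        return cls(**kwargs)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _round_matrix(m: pd.DataFrame, decimals: int = 4) -> pd.DataFrame:
    return m.round(decimals)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def run_pipeline(
    peaks_path,
    fasta_paths: Mapping[str, str] | None = None,
    design_path=None,
    out_dir=None,
    config: PipelineConfig | None = None,
) -> dict:
    """Execute features -> chemotype -> phylo -> integrate on file inputs.

    ``fasta_paths`` maps marker name to an aligned FASTA; markers that are
    missing are skipped with a warning so the chemical half of the study still
    completes.  Returns the integration report (with per-stage artefact paths
    when ``out_dir`` is given).
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(config.resolved(), indent=2, default=_json_default))
    logger.info("resolved configuration: %s", config.resolved())

    # --- features stage
    try:
        runs = features.read_peak_table(peaks_path)
        prepared = [
            features.prepare_run(r, config.threshold, config.rt_window) for r in runs
        ]
        table = features.match_features(
            prepared,
            rt_tol=config.rt_tol,
            mass_tol=config.mass_tol,
            min_occurrence=config.min_occurrence,
        )
    except Exception as exc:
        raise PipelineError(f"features stage failed: {exc}") from exc
    if out is not None:
        features.write_feature_table(out / "feature_table.csv", table)

    # --- chemotype stage
    try:
        dmatrix = chemotype.resemblance_matrix(table)
        dend = chemotype.upgma(dmatrix)
        chemo = chemotype.cut_dendrogram(dend, config.cut_similarity)
    except Exception as exc:
        raise PipelineError(f"chemotype stage failed: {exc}") from exc
    if out is not None:
        _round_matrix(100.0 * (1.0 - dmatrix)).to_csv(out / "similarity_pct.csv")
        pd.DataFrame(
            dend.merges, columns=["node_a", "node_b", "height", "size"]
        ).to_csv(out / "merges.tsv", sep="\t", index=False)
        (out / "dendrogram.nwk").write_text(chemotype.dendrogram_newick(dend) + "\n")
        integrate.write_assignment(out / "chemogroups.csv", chemo, "chemogroup")

    # --- phylo stage (optional per marker)
    phylogroups: dict[str, dict[str, str]] = {}
    divergence: dict[str, dict] = {}
    for marker, path in (fasta_paths or {}).items():
        if path is None or not Path(path).exists():
            logger.warning("no alignment for %s; skipping genetic analysis", marker)
            continue
        try:
            seqs = phylo.read_alignment(path)
            dm = phylo.distance_matrix(seqs)
            tree = phylo.neighbor_joining(dm)
            pg = phylo.assign_phylogroups(tree, k=config.k_phylogroups)
            divergence[marker] = phylo.divergence_report(
                dm,
                pg,
                marker=marker,
                threshold_pct=config.divergence_thresholds.get(marker),
            )
            phylogroups[marker] = pg
        except Exception as exc:
            raise PipelineError(f"phylo stage failed for {marker}: {exc}") from exc
        if out is not None:
            _round_matrix(100.0 * dm).to_csv(out / f"distances_{marker}_pct.csv")
            (out / f"tree_{marker}.nwk").write_text(tree.newick() + "\n")
            integrate.write_assignment(
                out / f"phylogroups_{marker}.csv", pg, "phylogroup"
            )

    # --- integrate stage
    design = None
    if design_path is not None and Path(design_path).exists():
        design = integrate.read_design(design_path)
    try:
        report = integrate.integration_report(chemo, phylogroups, design)
    except Exception as exc:
        raise PipelineError(f"integrate stage failed: {exc}") from exc
    report["divergence"] = divergence
    report["n_features"] = int(table.shape[1])
    report["config"] = config.resolved()
    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_json_default)
        )
        (out / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: dict) -> str:
    lines = [
        f"samples with chemical profiles: {report['coverage']['chemogroups']}",
        f"recurring features: {report['n_features']}",
        f"chemogroups: {len(report['chemogroup_sizes'])}",
    ]
    for cg, members in report["chemogroup_sizes"].items():
        lines.append(f"  {cg}: {', '.join(members)}")
    for marker, entry in report.get("markers", {}).items():
        conc = entry["concordance_chemo"]
        lines.append(
            f"{marker}: chemo-phylo adjusted Rand {conc['adjusted_rand']:.3f} "
            f"over {conc['n_shared']} samples"
        )
        for exc in entry["nesting_exceptions"]:
            lines.append(
                f"  exception: {exc['chemogroup']} spans {'/'.join(exc['phylogroups'])} "
                f"via {', '.join(exc['minority_members'])}"
            )
    if "site_purity" in report:
        purities = ", ".join(
            f"site {s}: {p:.2f}" for s, p in report["site_purity"].items()
        )
        lines.append(f"site purity — {purities}")
    for marker, div in report.get("divergence", {}).items():
        flag = div.get("conspecific")
        lines.append(
            f"{marker}: max divergence {div['max_overall_pct']:.2f}%"
            + (f" (conspecific at <= {div['threshold_pct']}%)" if flag else "")
        )
    return "\n".join(lines) + "\n"
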
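"""End-to-end orchestration: simulate -> CAI -> analyze -> cluster.

A :class:`RunConfig` either points at existing thickness/biomarker tables
or embeds a :class:`~cortasym.simulate.SimulationConfig`.  Enabled stages
run in order, writing tidy CSV tables into the output directory plus a
``manifest.json`` recording the package version, a hash of the full
configuration, the seed and the row count of every output.  The run is
single-process and fully deterministic: identical config + seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cai import DensitySettings, compute_cohort_cai
from .cluster import cluster_by_cai, cluster_composition, contrast_biomarkers
from .io import (
    BIOMARKER_COLUMNS,
    build_cohort_table,
    read_biomarkers,
    read_thickness_table,
    write_biomarkers,
    write_thickness_table,
)
from .simulate import SimulationConfig, simulate_cohort
from .stats import (
    biomarker_group_comparison,
    group_comparison,
    longitudinal_model,
    spearman_associations,
)

logger = logging.getLogger("cortasym")

ALL_STAGES = ("simulate", "cai", "analyze", "cluster")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` or ``thickness_path`` must be provided.
    """

    output_dir: str | Path = "cortasym_run"
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    simulation: SimulationConfig | None = None
    thickness_path: str | Path | None = None
    thickness_dialect: str = "wide_tsv"
    biomarker_path: str | Path | None = None
    density: DensitySettings = field(default_factory=DensitySettings)
    cluster_diseases: Sequence[str] = ("FTD", "AD")

    def validate(self) -> None:
        if (self.simulation is None) == (self.thickness_path is None):
            raise ValueError("provide either a simulation config or a thickness table path")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        # the hash covers everything that shapes the results; the output
        # location is deliberately excluded so identical runs to different
        # directories produce identical manifests
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj
        payload = encode(self)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, float_format: str = "%.12g") -> None:
    df.to_csv(path, index=False, float_format=float_format)
    manifest["outputs"][path.name] = int(len(df))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages; returns the output directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": {},
        "complete": False,
    }
    stage = "setup"
    try:
        biomarkers = None
        if config.simulation is not None:
            stage = "simulate"
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            logger.info("simulating cohort (seed=%d)", config.seed)
            records, biomarkers, truth = simulate_cohort(sim)
            if "simulate" in config.stages:
                write_thickness_table(records, outdir / "thickness_wide.tsv", "wide_tsv")
                manifest["outputs"]["thickness_wide.tsv"] = len(records)
                write_biomarkers(biomarkers, outdir / "biomarkers.csv")
                manifest["outputs"]["biomarkers.csv"] = len(biomarkers)
                _write(truth, outdir / "truth.csv", manifest)
        else:
            stage = "read"
            records = read_thickness_table(config.thickness_path, config.thickness_dialect)
            if config.biomarker_path is not None:
                biomarkers = read_biomarkers(config.biomarker_path)

        table = None
        if "cai" in config.stages:
            stage = "cai"
            logger.info("computing CAI for %d records", len(records))
            cai_df = compute_cohort_cai(records, config.density)
            _write(cai_df, outdir / "cai.csv", manifest)
            table = build_cohort_table(records, cai_df, biomarkers)
            _write(table, outdir / "cohort.csv", manifest)

        if "analyze" in config.stages:
            stage = "analyze"
            if table is None:
                raise ValueError("analyze stage requires the cai stage")
            base = table[table["visit"] == 1]
            res = group_comparison(base, "cai", "group", ("age_at_mri",))
            _write(res.pairwise.assign(omnibus_p=res.omnibus_p), outdir / "group_comparison.csv", manifest)
            ftd = base[base["group"] == "FTD"]
            if ftd["phenotype"].nunique() > 1:
                res_ph = group_comparison(ftd, "cai", "phenotype", ("age_at_mri",))
                _write(
                    res_ph.pairwise.assign(omnibus_p=res_ph.omnibus_p),
                    outdir / "phenotype_comparison.csv",
                    manifest,
                )
            longi_rows = []
            for grp in ("CTR", "AD", "FTD"):
                sub = table[table["group"] == grp]
                if (sub.groupby("subject_id")["visit"].nunique() > 1).any():
                    lres = longitudinal_model(table, grp)
                    longi_rows.append(lres.fixed_effects.assign(group=grp, singular=lres.singular))
            if longi_rows:
                _write(pd.concat(longi_rows, ignore_index=True), outdir / "longitudinal.csv", manifest)
            if biomarkers is not None:
                _write(
                    biomarker_group_comparison(base, BIOMARKER_COLUMNS, "group"),
                    outdir / "biomarker_groups.csv",
                    manifest,
                )
                corr_rows = []
                for grp, markers in (
                    ("FTD", ["csf_nfl", "plasma_nfl", "mmse", "age_at_mri"]),
                    ("AD", ["plasma_gfap", "mmse", "age_at_mri"]),
                    ("CTR", ["age_at_mri"]),
                ):
                    sub = base[base["group"] == grp]
                    for r in spearman_associations(sub, markers, "cai"):
                        corr_rows.append(
                            {"group": grp, "x": r.x, "rho": r.rho, "p": r.p, "n": r.n,
                             "insufficient": r.insufficient}
                        )
                _write(pd.DataFrame(corr_rows), outdir / "correlations.csv", manifest)

        if "cluster" in config.stages:
            stage = "cluster"
            if table is None:
                raise ValueError("cluster stage requires the cai stage")
            base = table[table["visit"] == 1]
            for disease in config.cluster_diseases:
                cres = cluster_by_cai(base, disease)
                _write(
                    cres.labels.reset_index(),
                    outdir / f"cluster_{disease}_labels.csv",
                    manifest,
                )
                sil = pd.DataFrame(
                    sorted(cres.silhouette_by_k.items()), columns=["k", "mean_silhouette"]
                )
                _write(sil, outdir / f"cluster_{disease}_silhouette.csv", manifest)
                pheno = base.set_index("subject_id")["phenotype"]
                _write(
                    cluster_composition(cres, pheno),
                    outdir / f"cluster_{disease}_composition.csv",
                    manifest,
                )
                if biomarkers is not None:
                    contrasts = contrast_biomarkers(base, cres, list(BIOMARKER_COLUMNS) + ["mmse"])
                    rows = [
                        {
                            "biomarker": c.biomarker,
                            "test": c.test,
                            "statistic": c.statistic,
                            "p": c.p,
                            "insufficient": c.insufficient,
                            **{f"mean_z_cluster{k}": v for k, v in c.cluster_mean_z.items()},
                        }
                        for c in contrasts
                    ]
                    _write(pd.DataFrame(rows), outdir / f"cluster_{disease}_contrasts.csv", manifest)
        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
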
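"""Result tables, the volcano plot and the end-to-end pipeline runner.

The pipeline mirrors the published two-library comparison: preprocess both
FASTQ libraries, screen contaminants and annotate against the mature
catalog, drop the low-abundance pool, normalize to RPKM, run the
no-replicate DE stage, and write the three result tables (counts/RPKM;
up-in-library-1; up-in-library-2) plus the M–D volcano plot and a run
manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import MiRNAAnnotator, low_abundance_filter
from .diffexp import DECall, NoiseCloud, NoiseSimDE
from .io_preprocess import FastqPreprocessor
from .quantification import (D_DECIMALS, M_DECIMALS, RPKM_DECIMALS,
                             RpkmNormalizer, expression_table)

logger = logging.getLogger(__name__)

VOLCANO_EPSILON = 1e-2  # floor for the log-scaled D axis


@dataclass(frozen=True)
class VolcanoPoint:
    name: str
    M: float
    D: float
    is_DE: bool


def volcano_plot(points: Sequence[VolcanoPoint], out: str | Path,
                 noise: NoiseCloud | None = None, log_d: bool = True,
                 formats: Sequence[str] = ("png",)) -> list[Path]:
    """Scatter M against D, DE miRNAs highlighted; optional noise cloud.

    D is drawn on a log axis by default (it spans several orders of
    magnitude) with values floored at ``VOLCANO_EPSILON``; the floor is
    noted on the axis label. Returns the files written.
    """
    if not points:
        raise ValueError("no points to plot")
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    def floor_d(d: np.ndarray) -> np.ndarray:
        return np.maximum(d, VOLCANO_EPSILON) if log_d else d

    fig, ax = plt.subplots(figsize=(6, 5))
    if noise is not None and len(noise):
        m_noise = np.concatenate([noise.pairs[:, 0], -noise.pairs[:, 0]])
        d_noise = np.concatenate([noise.pairs[:, 1]] * 2)
        ax.scatter(m_noise, floor_d(d_noise), s=4, c="0.3", alpha=0.3,
                   label="noise", rasterized=True)
    m = np.array([p.M for p in points])
    d = np.array([p.D for p in points])
    de = np.array([p.is_DE for p in points])
    if np.any(~de):
        ax.scatter(m[~de], floor_d(d[~de]), s=14, c="black", label="not DE")
    if np.any(de):
        ax.scatter(m[de], floor_d(d[de]), s=18, c="red",
                   label="DE (P > threshold)")
    if log_d:
        ax.set_yscale("log")
        ax.set_ylabel(f"D-value, |x1 - x2| (RPKM, floored at {VOLCANO_EPSILON:g})")
    else:
        ax.set_ylabel("D-value, |x1 - x2| (RPKM)")
    ax.set_xlabel("M-value, log2(x1 / x2)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    out = Path(out)
    written = []
    for fmt in formats:
        path = out.with_suffix(f".{fmt}")
        fig.savefig(path, dpi=150)
        written.append(path)
    plt.close(fig)
    return written


def _format_expression(expr: pd.DataFrame) -> pd.DataFrame:
    out = expr.copy()
    for col in out.columns:
        if col.startswith("rpkm_"):
            out[col] = out[col].round(RPKM_DECIMALS)
    return out


def write_tables(expr: pd.DataFrame, calls: Sequence[DECall],
                 out_dir: str | Path, lib1: str = "1", lib2: str = "2",
                 ) -> dict[str, Path]:
    """Write the counts/RPKM table and the two direction-wise DE tables.

    DE tables carry columns miRNA, P, M-value, D-value, each direction
    sorted by descending |M|; M is rounded to 3 decimals, D to 2, RPKM
    to 3 (the published precision).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["expression"] = out_dir / "expression.tsv"
    _format_expression(expr).to_csv(paths["expression"], sep="\t")
    for direction, lib in (("up_in_1", lib1), ("up_in_2", lib2)):
        rows = [c for c in calls if c.direction == direction]
        rows.sort(key=lambda c: (-abs(c.M), c.name))
        df = pd.DataFrame(
            {
                "miRNA": [c.name for c in rows],
                "P": [round(c.probability, 4) for c in rows],
                "M-value": [round(c.M, M_DECIMALS) for c in rows],
                "D-value": [round(c.D, D_DECIMALS) for c in rows],
            }
        )
        key = f"de_up_in_{lib}"
        paths[key] = out_dir / f"{key}.tsv"
        df.to_csv(paths[key], sep="\t", index=False)
    return paths


REQUIRED_CONFIG_KEYS = ("libraries", "catalog", "out_dir")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: Mapping | str | Path) -> dict:
    """Run preprocess -> annotate -> quantify -> diffexp -> report.

    ``config`` is a mapping (or YAML path) with keys: ``libraries`` (list
    of two {id, fastq, total_raw_override?}), ``catalog`` (FASTA path),
    ``contaminants`` (list of FASTA paths, optional), ``out_dir``, ``seed``
    and optional stage-parameter blocks ``preprocess``, ``annotate``,
    ``diffexp``. Returns the run manifest (also written to the run
    directory as JSON).
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    for key in REQUIRED_CONFIG_KEYS:
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    libraries = config["libraries"]
    if len(libraries) != 2:
        raise ValueError(f"exactly two libraries required, got {len(libraries)}")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "tool": "mirdiff", "version": __version__,
        "python": platform.python_version(),
        "seed": seed, "stages": [], "parameters": {},
    }

    stage = "preprocess"
    try:
        pre_params = dict(config.get("preprocess", {}))
        pre = FastqPreprocessor(**pre_params)
        manifest["parameters"]["preprocess"] = pre.get_params()
        collapsed = {}
        stats = {}
        for lib in libraries:
            collapsed[lib["id"]] = pre.transform(lib["fastq"])
            stats[lib["id"]] = pre.stats_.to_dict()
            if "total_raw_override" in lib:
                stats[lib["id"]]["n_raw"] = int(lib["total_raw_override"])
        manifest["stages"].append({"stage": stage, "reads": stats})
        logger.info("preprocess: %s", stats)

        stage = "annotate"
        ann_params = dict(config.get("annotate", {}))
        pool_fraction = ann_params.pop("pool_fraction", 0.0001)
        annotator = MiRNAAnnotator(
            catalog=config["catalog"],
            contaminants=config.get("contaminants"),
            **ann_params).fit()
        manifest["parameters"]["annotate"] = {
            "ambiguity": annotator.ambiguity,
            "max_5p_offset": annotator.max_5p_offset,
            "pool_fraction": pool_fraction,
        }
        profiles = {}
        for lib in libraries:
            lid = lib["id"]
            profiles[lid] = annotator.transform(
                collapsed[lid], library_id=lid,
                total_raw_reads=stats[lid]["n_raw"])
        kept, dropped = low_abundance_filter(
            list(profiles.values()), pool_fraction=pool_fraction)
        manifest["stages"].append({
            "stage": stage,
            "n_mirnas_detected": len(set().union(
                *(p.per_mirna for p in profiles.values()))),
            "n_mirnas_kept": len(kept),
            "n_low_abundance_dropped": len(dropped),
        })
        logger.info("annotate: kept %d miRNAs, dropped %d", len(kept), len(dropped))

        stage = "quantify"
        norm = RpkmNormalizer()
        lib1, lib2 = libraries[0]["id"], libraries[1]["id"]
        # mature lengths back a miRNA absent from one library (count 0)
        mature_lengths = {m.name: len(m.seq) for m in annotator.catalog_}
        records = {
            lid: norm.transform(profiles[lid], names=kept,
                                mature_lengths=mature_lengths)
            for lid in (lib1, lib2)
        }
        expr = expression_table(records[lib1], records[lib2])
        manifest["stages"].append({"stage": stage, "n_mirnas": len(expr)})

        stage = "diffexp"
        de_params = dict(config.get("diffexp", {}))
        de = NoiseSimDE(random_state=seed, **de_params).fit(expr)
        manifest["parameters"]["diffexp"] = {
            k: v for k, v in de.get_params().items() if k != "random_state"}
        manifest["stages"].append({
            "stage": stage,
            "n_up_" + lib1: de.n_up_1_,
            "n_up_" + lib2: de.n_up_2_,
        })
        logger.info("diffexp: %d up in %s, %d up in %s",
                    de.n_up_1_, lib1, de.n_up_2_, lib2)

        stage = "report"
        paths = write_tables(expr, de.calls_, out_dir, lib1=lib1, lib2=lib2)
        points = [
            VolcanoPoint(c.name, c.M, c.D, c.direction != "not_DE")
            for c in de.calls_
        ]
        plot_formats = config.get("plot_formats", ["png", "svg"])
        plots = volcano_plot(points, out_dir / "volcano",
                             noise=de.noise_cloud_, formats=plot_formats)
        manifest["stages"].append({
            "stage": stage,
            "tables": {k: str(v) for k, v in paths.items()},
            "plots": [str(p) for p in plots],
        })
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
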
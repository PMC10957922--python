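"""One-command orchestration: segment → 1-NN → fit → metrics → associate.

Every (sample × ordered cell-type pair) is a fitting unit; units are
enumerated up front and each terminates in exactly one recorded state —
``fit``, ``filtered-at-level-L``, ``rejected`` or ``errored`` — so a 2%
rejection rate in a cohort is ordinary bookkeeping, not a failure. A
JSON manifest lists every produced artifact with a checksum, and
per-unit errors never abort the remaining units.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import differential_test
from .data_model import (
    CELL_TYPES,
    CellTable,
    CohortLabels,
    write_metrics,
)
from .nlme import FitControls, sequential_filter_fit
from .nn_stats import (
    EmptyTargetError,
    cross_nn_distances,
    empirical_g_curve,
    g_auc,
)
from .segmentation import (
    assign_compartments,
    compute_compartment_areas,
    split_foci,
    total_areas,
    trim_distal_stroma,
)
from .tme_metrics import attach_sr_metrics, build_metrics_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full cohort analysis."""

    pairs: str | list[tuple[str, str]] = "all"  # "all" = 7×7 ordered pairs
    eps: float = 300.0
    min_pts: int = 50
    pixel_size: float = 10.0
    trim_stroma: float | None = 150.0
    g_auc_thresholds: tuple[float, ...] = (25.0, 50.0, 100.0)
    fdr_threshold: float = 0.10
    fit_controls: FitControls = field(default_factory=FitControls)
    seed: int = 0
    run_segmentation: bool = True
    run_association: bool = True

    def pair_list(self) -> list[tuple[str, str]]:
        if self.pairs == "all":
            return list(itertools.product(CELL_TYPES, CELL_TYPES))
        return list(self.pairs)


def _count_states(units: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for v in units.values():
        key = "errored" if v.startswith("errored") else v
        counts[key] = counts.get(key, 0) + 1
    return counts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(
    cells: CellTable,
    cfg: PipelineConfig,
    out_dir: str | Path,
    labels: CohortLabels | None = None,
) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample_ids = cells.sample_ids
    pairs = cfg.pair_list()
    units: dict[str, str] = {
        f"{sid}|{ft}->{tt}": "pending" for sid in sample_ids for ft, tt in pairs
    }
    logger.info(
        "enumerated %d fitting units (%d samples × %d pairs)",
        len(units), len(sample_ids), len(pairs),
    )

    if cfg.run_segmentation:
        cells = split_foci(cells, eps=cfg.eps, min_pts=cfg.min_pts)
        cells = assign_compartments(cells, pixel_size=cfg.pixel_size)
        areas = total_areas(compute_compartment_areas(cells, pixel_size=cfg.pixel_size))
        if cfg.trim_stroma is not None:
            cells = trim_distal_stroma(cells, max_dist=cfg.trim_stroma)
    else:
        areas = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "tumor_area": np.nan,
                "stroma_area": np.nan,
                "total_area": np.nan,
            }
        )

    fits = {}
    g_aucs: dict[tuple[str, str], dict[str, dict[float, float]]] = {}
    fit_reports = {}
    for ft, tt in pairs:
        sets = {}
        pair_g: dict[str, dict[float, float]] = {}
        for sid in sample_ids:
            key = f"{sid}|{ft}->{tt}"
            try:
                d = cross_nn_distances(cells, ft, tt, sample_id=sid)
                sets[sid] = d
                g = empirical_g_curve(d, r_max=max(cfg.g_auc_thresholds))
                pair_g[sid] = {T: g_auc(g, T) for T in cfg.g_auc_thresholds}
            except EmptyTargetError as exc:
                units[key] = f"errored: empty target (nFROM={exc.n_from}, nTO={exc.n_to})"
            except Exception as exc:  # per-unit isolation
                units[key] = f"errored: {exc}"
        g_aucs[(ft, tt)] = pair_g
        if len(sets) >= 3:
            try:
                fit = sequential_filter_fit(
                    sets, controls=cfg.fit_controls, from_type=ft, to_type=tt
                )
            except Exception as exc:
                for sid in sets:
                    units[f"{sid}|{ft}->{tt}"] = f"errored: {exc}"
                continue
            fits[(ft, tt)] = fit
            for sid in sets:
                key = f"{sid}|{ft}->{tt}"
                if fit.rejected:
                    units[key] = "rejected"
                elif sid in fit.samples_used:
                    units[key] = "fit"
                else:
                    units[key] = f"filtered-at-level-{fit.filter_level}"
        else:
            for sid in sets:
                units[f"{sid}|{ft}->{tt}"] = "rejected"

    # metrics matrix
    metrics = build_metrics_matrix(cells, areas)
    metrics = attach_sr_metrics(metrics, fits, g_aucs)

    artifacts = {}

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)

    _write("cells_processed.tsv", lambda p: cells.df.to_csv(p, sep="\t", index=False))
    _write("areas.tsv", lambda p: areas.to_csv(p, sep="\t", index=False))
    if len(metrics):
        _write("metrics.tsv", lambda p: write_metrics(metrics, p))
    _write(
        "fits.json",
        lambda p: p.write_text(
            json.dumps(
                {f"{ft}->{tt}": f.to_dict() for (ft, tt), f in fits.items()},
                indent=1,
                default=float,
            )
        ),
    )

    if cfg.run_association and labels is not None and len(metrics):
        labels.check_against(cells)
        diff = differential_test(metrics, labels)
        _write("differential.tsv", lambda p: diff.to_csv(p, sep="\t", index=False))

    manifest = {
        "n_samples": len(sample_ids),
        "n_pairs": len(pairs),
        "n_units": len(units),
        "units": units,
        "unit_counts": _count_states(units),
        "artifacts": artifacts,
        "seed": cfg.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
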
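"""Compartment immune-cell densities and exclusion ratios.

Densities are reported in cells/mm² (1 mm² = 10⁶ μm²). The exclusion
ratio — stromal over intratumoral density of an immune type — serves as
a proxy for the excluded/inflamed immune-phenotype axis: values well
above 1 indicate immune cells held in the stroma, values near or below 1
an infiltrated tumor. A 0.5-cell continuity correction keeps the ratio
finite and log-transformable when a compartment holds no cells; raw
densities are reported without correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import CellTable

UM2_PER_MM2 = 1e6

IMMUNE_TYPES = ("cd8_t", "foxp3_t", "t_helper", "b_cell", "macrophage")


def compartment_count(ct: CellTable, sample_id: str, cell_type: str, compartment: str) -> int:
    df = ct.df
    return int(
        (
            (df["sample_id"] == sample_id)
            & (df["cell_type"] == cell_type)
            & (df["compartment"] == compartment)
        ).sum()
    )


def compartment_density(
    ct: CellTable,
    sample_id: str,
    cell_type: str,
    compartment: str,
    areas: pd.DataFrame,
) -> float:
    """Cells of ``cell_type`` in ``compartment`` per mm² of that compartment.

    Returns NaN (missing, flagged by the caller) when the compartment
    area is zero rather than raising.
    """
    row = areas.loc[areas["sample_id"] == sample_id]
    if row.empty:
        return float("nan")
    area_um2 = float(row.iloc[0][f"{compartment}_area"])
    if area_um2 <= 0:
        return float("nan")
    n = compartment_count(ct, sample_id, cell_type, compartment)
    return n / (area_um2 / UM2_PER_MM2)


def exclusion_ratio(
    n_stroma: int,
    n_tumor: int,
    stroma_area_um2: float,
    tumor_area_um2: float,
    correction: float = 0.5,
) -> float:
    """Stromal over intratumoral density with a continuity correction.

    ((n_stroma + c)/stroma area) / ((n_tumor + c)/tumor area) with
    c = 0.5 cells by default; NaN when either area is zero.
    """
    if stroma_area_um2 <= 0 or tumor_area_um2 <= 0:
        return float("nan")
    num = (n_stroma + correction) / stroma_area_um2
    den = (n_tumor + correction) / tumor_area_um2
    return num / den


def build_metrics_matrix(
    ct: CellTable,
    areas: pd.DataFrame,
    immune_types: tuple[str, ...] = IMMUNE_TYPES,
) -> pd.DataFrame:
    """Per-sample density and exclusion-ratio feature table.

    Columns are machine-parsable ``metric.cell_type.compartment`` names:
    ``density.<type>.tumor``, ``density.<type>.stroma`` (cells/mm²) and
    ``exclusion.<type>`` (dimensionless ratio). Missing values (zero
    compartment area) are NaN.
    """
    rows = {}
    for sid in ct.sample_ids:
        rec = {}
        arow = areas.loc[areas["sample_id"] == sid]
        t_area = float(arow.iloc[0]["tumor_area"]) if not arow.empty else 0.0
        s_area = float(arow.iloc[0]["stroma_area"]) if not arow.empty else 0.0
        for imm in immune_types:
            rec[f"density.{imm}.tumor"] = compartment_density(ct, sid, imm, "tumor", areas)
            rec[f"density.{imm}.stroma"] = compartment_density(ct, sid, imm, "stroma", areas)
            rec[f"exclusion.{imm}"] = exclusion_ratio(
                compartment_count(ct, sid, imm, "stroma"),
                compartment_count(ct, sid, imm, "tumor"),
                s_area,
                t_area,
            )
        rows[sid] = rec
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def attach_sr_metrics(
    metrics: pd.DataFrame,
    fits: dict[tuple[str, str], "object"],
    g_aucs: dict[tuple[str, str], dict[str, dict[float, float]]] | None = None,
) -> pd.DataFrame:
    """Extend a metrics matrix with per-sample SR parameters.

    ``fits`` maps (from_type, to_type) to a converged WeibullFit; adds
    ``shape.<from>.<to>``, ``scale.<from>.<to>`` and
    ``median_1nn.<from>.<to>`` columns. ``g_aucs`` optionally maps the
    same keys to per-sample G-AUC-T dictionaries, added as
    ``g_auc_<T>.<from>.<to>``.
    """
    from .weibull import median_1nn

    out = metrics.copy()
    for (ft, tt), fit in fits.items():
        if getattr(fit, "rejected", False):
            continue
        key = f"{ft}.{tt}"
        shapes = {s: p.shape for s, p in fit.per_sample.items()}
        scales = {s: p.scale for s, p in fit.per_sample.items()}
        medians = {s: median_1nn(p) for s, p in fit.per_sample.items()}
        out[f"shape.{key}"] = pd.Series(shapes)
        out[f"scale.{key}"] = pd.Series(scales)
        out[f"median_1nn.{key}"] = pd.Series(medians)
    if g_aucs:
        for (ft, tt), per_sample in g_aucs.items():
            for sid, aucs in per_sample.items():
                for T, v in aucs.items():
                    out.loc[sid, f"g_auc_{int(T)}.{ft}.{tt}"] = v
    return out
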
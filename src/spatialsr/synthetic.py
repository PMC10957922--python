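"""Seed-reproducible synthetic cohorts of tissue cell maps.

Real multiplex-immunofluorescence cohorts carry per-cell coordinates and
phenotypes from clinical trial material that cannot be redistributed, so
every statistical component here is exercised on synthetic point
patterns with known structure:

* homogeneous Poisson (CSR) patterns, whose cross 1-NN distances are
  Weibull with shape 2 and scale (πλ)^(−1/2) — a closed-form oracle;
* Thomas cluster processes (Poisson parents with Gaussian offspring)
  emulating dense cancer-cell nests;
* cohorts of slides with a negative-cell stroma and rarer immune
  populations whose proximity to cancer cells differs between response
  groups (attraction in responders, exclusion in non-responders);
* distance cohorts drawn directly from per-sample Weibull laws with
  Gaussian random effects on the unconstrained link scale — the oracle
  for mixed-effects parameter recovery.

Four scenario presets reproduce the canonical scale/shape regimes of the
parameter space: densely packed targets (low scale, high shape),
co-mingled clusters (low scale, low shape), dispersed targets (high
scale, low shape) and mutually repulsed clusters (high scale, high
shape).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import CELL_TYPES, CellTable, CohortLabels
from .nn_stats import NNDistanceSet
from .weibull import link_transform

Window = tuple[float, float]  # (width, height) in μm, origin at (0, 0)

SCENARIO_PRESETS = ("packed_target", "comingled", "dispersed_target", "repulsion")


@dataclass
class SimConfig:
    """Configuration of a synthetic cohort of tissue slides.

    Defaults emulate a two-arm trial-sized cohort: ~2·10³ cancer cells
    per 1 mm² slide arranged in nests, an equally abundant negative-cell
    stroma, and immune populations one to two orders of magnitude rarer.
    """

    window: Window = (1000.0, 1000.0)
    intensities: dict[str, float] = field(
        default_factory=lambda: {
            "cancer": 2e-3,
            "negative": 2e-3,
            "cd8_t": 2e-4,
            "macrophage": 1.5e-4,
            "b_cell": 1e-4,
            "foxp3_t": 5e-5,
            "t_helper": 1e-4,
        }
    )
    architecture: str = "tumor_nests"  # csr | tumor_nests | excluded | inflamed
    n_nests: int = 8
    nest_radius: float = 60.0  # Gaussian offspring SD of the Thomas nests, μm
    infiltration_depth: float = 30.0  # e-folding length of the proximity kernel, μm
    response_effect: float = 0.9  # 0 = no group difference, 1 = maximal
    n_samples_per_group: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.window[0] <= 0 or self.window[1] <= 0:
            raise ValueError("window area must be positive")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("intensities must be >= 0")
        if self.nest_radius * 2 > min(self.window):
            raise ValueError("nests larger than the window are infeasible")
        if not 0.0 <= self.response_effect <= 1.0:
            raise ValueError("response_effect must lie in [0, 1]")
        unknown = set(self.intensities) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types in intensities: {sorted(unknown)}")


def simulate_poisson_pattern(
    intensity: float, window: Window, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson point pattern: (n, 2) positions in μm."""
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    w, h = window
    n = rng.poisson(intensity * w * h)
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def simulate_thomas_pattern(
    parent_intensity: float,
    mean_offspring: float,
    offspring_sd: float,
    window: Window,
    rng: np.random.Generator,
    parents: np.ndarray | None = None,
) -> np.ndarray:
    """Thomas cluster process: Poisson parents, Gaussian offspring.

    Offspring falling outside the window are reflected back into it
    (edge nests are folded rather than lost, as in real tissue sections
    where a nest continues past the section boundary).
    """
    w, h = window
    if parents is None:
        parents = simulate_poisson_pattern(parent_intensity, window, rng)
    pts = []
    for p in parents:
        k = rng.poisson(mean_offspring)
        if k:
            pts.append(p + rng.normal(0.0, offspring_sd, (k, 2)))
    if not pts:
        return np.empty((0, 2))
    out = np.concatenate(pts)
    # reflect strays back into the window (edge nests are folded rather
    # than piled up on the boundary)
    out[:, 0] = w - np.abs(w - np.abs(out[:, 0]))
    out[:, 1] = h - np.abs(h - np.abs(out[:, 1]))
    return out


def _proximity_thinned(
    n_target: int,
    anchors: np.ndarray,
    window: Window,
    rng: np.random.Generator,
    depth: float,
    effect: float,
    attract: bool,
) -> np.ndarray:
    """Place points with distance-kernel attraction/repulsion to anchors.

    Candidates are drawn uniformly and accepted with probability
    (1 − e) + e·k(d) where d is the distance to the nearest anchor and
    k(d) = exp(−d/depth) for attraction, 1 − exp(−d/depth) for repulsion.
    """
    from scipy.spatial import cKDTree

    if n_target == 0:
        return np.empty((0, 2))
    if len(anchors) == 0 or effect == 0.0:
        w, h = window
        return np.column_stack(
            [rng.uniform(0, w, n_target), rng.uniform(0, h, n_target)]
        )
    tree = cKDTree(anchors)
    w, h = window
    out: list[np.ndarray] = []
    got = 0
    # rejection sampling in batches; acceptance ratio bounded below by 1-e
    while got < n_target:
        m = max(4 * (n_target - got), 256)
        cand = np.column_stack([rng.uniform(0, w, m), rng.uniform(0, h, m)])
        d, _ = tree.query(cand, k=1)
        k = np.exp(-d / depth)
        if not attract:
            k = 1.0 - k
        accept = rng.uniform(size=m) < (1.0 - effect) + effect * k
        kept = cand[accept][: n_target - got]
        out.append(kept)
        got += len(kept)
    return np.concatenate(out)


def simulate_tme_slide(
    cfg: SimConfig, sample_id: str, responder: bool, rng: np.random.Generator
) -> pd.DataFrame:
    """One synthetic slide as a raw cell dataframe."""
    w, h = cfg.window
    area = w * h
    rows = []

    lam_cancer = cfg.intensities.get("cancer", 0.0)
    if cfg.architecture == "csr" or lam_cancer == 0:
        cancer = simulate_poisson_pattern(lam_cancer, cfg.window, rng)
    else:
        n_cancer = lam_cancer * area
        parents = np.column_stack(
            [rng.uniform(0, w, cfg.n_nests), rng.uniform(0, h, cfg.n_nests)]
        )
        cancer = simulate_thomas_pattern(
            0.0, n_cancer / max(cfg.n_nests, 1), cfg.nest_radius, cfg.window, rng,
            parents=parents,
        )
    rows.append(("cancer", cancer))

    # negative cells form the stroma: repelled from the cancer nests
    lam_neg = cfg.intensities.get("negative", 0.0)
    n_neg = rng.poisson(lam_neg * area)
    negative = _proximity_thinned(
        n_neg, cancer, cfg.window, rng,
        depth=max(cfg.nest_radius, 1.0), effect=0.7 if cfg.architecture != "csr" else 0.0,
        attract=False,
    )
    rows.append(("negative", negative))

    # immune populations: proximity to cancer differs by response group
    attract = responder
    for ct in ("cd8_t", "macrophage", "b_cell", "foxp3_t", "t_helper"):
        lam = cfg.intensities.get(ct, 0.0)
        n = rng.poisson(lam * area)
        effect = cfg.response_effect if cfg.architecture != "csr" else 0.0
        pts = _proximity_thinned(
            n, cancer, cfg.window, rng,
            depth=cfg.infiltration_depth, effect=effect, attract=attract,
        )
        rows.append((ct, pts))

    frames = []
    for ct, pts in rows:
        if len(pts):
            frames.append(
                pd.DataFrame(
                    {"sample_id": sample_id, "x": pts[:, 0], "y": pts[:, 1], "cell_type": ct}
                )
            )
    if not frames:
        return pd.DataFrame(columns=["sample_id", "x", "y", "cell_type"])
    return pd.concat(frames, ignore_index=True)


def simulate_tme_cohort(cfg: SimConfig) -> tuple[CellTable, CohortLabels]:
    """A full two-group cohort of synthetic slides with response labels."""
    rng = np.random.default_rng(cfg.seed)
    frames = []
    labels = []
    for g, responder in (("R", True), ("N", False)):
        for i in range(cfg.n_samples_per_group):
            sid = f"{g}{i + 1:02d}"
            frames.append(simulate_tme_slide(cfg, sid, responder, rng))
            labels.append((sid, "responder" if responder else "non_responder"))
    cells = CellTable.from_dataframe(pd.concat(frames, ignore_index=True))
    lab = CohortLabels.from_dataframe(
        pd.DataFrame(labels, columns=["sample_id", "response"])
    )
    return cells, lab


def simulate_weibull_cohort(
    pop_A: float,
    pop_B: float,
    re_sd_A: float,
    re_sd_B: float,
    n_samples: int,
    n_distances: int,
    seed: int,
    from_type: str = "cd8_t",
    to_type: str = "cancer",
) -> tuple[dict[str, NNDistanceSet], dict[str, tuple[float, float]]]:
    """Distance cohort drawn from per-sample Weibull laws.

    Per sample, (A_i, B_i) ~ N((pop_A, pop_B), diag(re_sd²)) on the
    unconstrained scale, mapped through the logistic links to (a_i, b_i),
    then ``n_distances`` draws from Weibull(a_i, b_i). Returns the
    distance sets and the true per-sample (a_i, b_i).
    """
    if re_sd_A < 0 or re_sd_B < 0:
        raise ValueError("random-effect SDs must be >= 0")
    rng = np.random.default_rng(seed)
    sets: dict[str, NNDistanceSet] = {}
    truth: dict[str, tuple[float, float]] = {}
    for i in range(n_samples):
        Ai = pop_A + rng.normal(0.0, re_sd_A)
        Bi = pop_B + rng.normal(0.0, re_sd_B)
        a, b = link_transform(Ai, Bi)
        d = b * rng.weibull(a, size=n_distances)
        sid = f"S{i + 1:02d}"
        sets[sid] = NNDistanceSet(
            sample_id=sid,
            from_type=from_type,
            to_type=to_type,
            distances=d,
            n_from=n_distances,
            n_to=n_distances,
        )
        truth[sid] = (a, b)
    return sets, truth


# ---------------------------------------------------------------------------
# scenario presets for the scale/shape taxonomy


def simulate_scenario(
    name: str, rng: np.random.Generator, window: Window = (800.0, 800.0)
) -> tuple[np.ndarray, np.ndarray]:
    """(reference, target) point patterns for one taxonomy preset.

    packed_target
        Sparse reference cells against a dense CSR target — there is
        always a target nearby (low scale, high shape; the CSR case).
    comingled
        Both types share dense Thomas clusters, plus a uniform minority
        of reference cells between clusters — short modal distances with
        a heavy tail (low scale, low shape).
    dispersed_target
        Targets in tight clusters, references spread widely around the
        same cluster centers — a broad spread of distances (high scale,
        low shape).
    repulsion
        Reference and target clusters mutually displaced — distances
        concentrate around the cluster gap (high scale, high shape).
    """
    w, h = window
    if name == "packed_target":
        ref = simulate_poisson_pattern(8e-4, window, rng)
        tgt = simulate_poisson_pattern(1e-2, window, rng)
    elif name == "comingled":
        parents = simulate_poisson_pattern(3e-5, window, rng)
        tgt = simulate_thomas_pattern(0, 50, 10.0, window, rng, parents=parents)
        ref_in = simulate_thomas_pattern(0, 12, 10.0, window, rng, parents=parents)
        ref_out = simulate_poisson_pattern(6e-5, window, rng)
        ref = np.concatenate([ref_in, ref_out]) if len(ref_in) else ref_out
    elif name == "dispersed_target":
        parents = simulate_poisson_pattern(8e-6, window, rng)
        if len(parents) == 0:
            parents = np.array([[w / 2, h / 2]])
        tgt = simulate_thomas_pattern(0, 80, 15.0, window, rng, parents=parents)
        ref = simulate_thomas_pattern(0, 60, 220.0, window, rng, parents=parents)
    elif name == "repulsion":
        # two mutually displaced cluster groups: distances concentrate
        # around the inter-cluster gap
        jitter = rng.uniform(-40.0, 40.0, size=2)
        tgt_parents = np.array([[w / 4, h / 2]]) + jitter
        ref_parents = tgt_parents + np.array([250.0, 0.0])
        tgt = simulate_thomas_pattern(0, 250, 25.0, window, rng, parents=tgt_parents)
        ref = simulate_thomas_pattern(0, 250, 25.0, window, rng, parents=ref_parents)
    else:
        raise ValueError(f"unknown scenario preset {name!r}; choose from {SCENARIO_PRESETS}")
    if len(ref) == 0 or len(tgt) == 0:
        raise ValueError(f"scenario {name!r} produced an empty pattern; reseed")
    return ref, tgt


def scenario_distance_cohort(
    name: str, n_samples: int, seed: int, window: Window = (800.0, 800.0)
) -> dict[str, NNDistanceSet]:
    """Cohort of cross 1-NN distance sets for one taxonomy preset."""
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    sets = {}
    for i in range(n_samples):
        ref, tgt = simulate_scenario(name, rng, window=window)
        d, _ = cKDTree(tgt).query(ref, k=1)
        sid = f"{name}_{i + 1:02d}"
        sets[sid] = NNDistanceSet(
            sample_id=sid,
            from_type="cd8_t",
            to_type="cancer",
            distances=np.asarray(d, dtype=float),
            n_from=len(ref),
            n_to=len(tgt),
        )
    return sets
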
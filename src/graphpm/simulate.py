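"""Synthetic cohorts with planted, configurable brain-symptom effects.

The generator emulates the statistical structure the GPM assumes, without
any real fMRI data:

* per subject and cognitive state, regional time series from a latent
  factor model (one global factor plus one factor per community block)
  whose within-block coupling varies across subjects, blocks, and nodes —
  so the resulting Fisher-z connectomes have community structure and
  between-subject graph-metric variation;
* three correlated symptom scales at baseline and two follow-ups with
  lost-to-follow-up and scale-level missingness, a medication-load
  covariate, and a two-level diagnostic group label;
* a planted linear dependence of one symptom on one graph metric (global
  or of a named ROI node), calibrated so the brain term explains a
  configured fraction of target variance on the modeling scale (the
  mania-like scale is exponentiated, so ``log(x+1)`` is its natural
  transform).

Planting operates on the *metric*: subject-level coupling modulates the
connectome, metrics are computed from the generated graphs, and the target
is built from the realised (standardised) metric values — connectomes stay
realistic while the signal is learnable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import SYMPTOMS, CohortTable, ModelSpec, assemble_features, symptom_column
from .connectome import Connectome, TimeSeries, build_connectome, to_positive_graph
from .metrics import MetricVector, RoiMap, metric_vector
from .model import LOOCV, GraphPredictiveModel

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "default_roi_map",
    "generate_connectomes",
    "generate_symptoms",
    "generate_cohort",
    "generate_edge_effect_cohort",
    "recovery_experiment",
    "RecoveryResult",
]

#: Scale locations/SDs roughly matching clinical questionnaire totals
#: (anhedonia ~ MASQ-AD, impulsivity ~ BIS); the mania-like scale is
#: exponentiated from its latent so log1p recovers linearity.
SCALE_PARAMS = {
    "anhedonia": ("linear", 79.5, 12.2),
    "impulsivity": ("linear", 67.6, 11.3),
    "mania": ("expm1", 1.45, 0.75),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``planted_feature`` is a metric name (``"global_efficiency"`` or
    ``"<roi>:<metric>"``) or ``"none"``; ``effect_size`` is the target R^2
    of the brain term on the modeling scale of ``target_symptom`` at
    ``target_timepoint``.
    """

    n_subjects: int = 80
    n_nodes: int = 216
    n_blocks: int = 6
    states: tuple[str, ...] = ("task", "rest")
    n_timepoints: int = 150
    within_corr: float = 0.35
    between_corr: float = 0.08
    subject_sd: float = 0.25
    node_sd: float = 0.20
    state_sd: float = 0.10
    planted_feature: str = "L_ACC:betweenness"
    planted_state: str = "rest"
    target_symptom: str = "impulsivity"
    target_timepoint: str = "baseline"
    effect_size: float = 0.2
    covariate_effect_other: float = 0.25
    covariate_effect_medication: float = 0.10
    followup_autocorr: float = 0.6
    baseline_corr: float = 0.4
    noise_sd: float = 0.8
    missing_3m: float = 0.10
    missing_6m: float = 0.16
    scale_missing: float = 0.02
    group_split: float = 0.725
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 8:
            raise ValueError("n_nodes must be >= 8")
        if not (0 <= self.effect_size < 1):
            raise ValueError("effect_size must lie in [0, 1)")
        for name in ("within_corr", "between_corr", "missing_3m", "missing_6m",
                     "scale_missing", "group_split", "followup_autocorr",
                     "baseline_corr"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.between_corr >= self.within_corr:
            raise ValueError("between_corr must be below within_corr")
        if self.n_blocks < 1 or self.n_nodes // self.n_blocks < 2:
            raise ValueError("degenerate block configuration")
        if self.target_symptom not in SYMPTOMS:
            raise ValueError(f"unknown target symptom {self.target_symptom!r}")


def default_roi_map(cfg: SyntheticConfig) -> RoiMap:
    """Six single-node reward-circuit-style ROIs spread across blocks."""
    names = ["L_ACC", "R_ACC", "L_caudate", "R_caudate", "L_NAc", "R_NAc"]
    block_size = cfg.n_nodes // cfg.n_blocks
    entries = {}
    for k, name in enumerate(names):
        b = k % cfg.n_blocks
        offset = 1 + k // cfg.n_blocks
        entries[name] = [min(b * block_size + offset, cfg.n_nodes - 1)]
    if len({tuple(v) for v in entries.values()}) < len(names):
        raise ValueError("degenerate block configuration: ROIs collide")
    return RoiMap(entries)


def _subject_ids(n: int) -> list[str]:
    return [f"sub-{i:03d}" for i in range(n)]


def generate_connectomes(
    cfg: SyntheticConfig, seed: int | None = None
) -> dict[tuple[str, str], Connectome]:
    """Simulate block-structured connectomes for every subject and state.

    Node time series follow ``x_i = a_i f_b + c g + e_i`` with unit noise,
    a global factor g and per-block factors f_b; baseline loadings are set
    so population within/between-block correlations match the configured
    levels, and log-normal subject/block/node/state multipliers on ``a_i``
    drive between-subject metric variation.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, B, T = cfg.n_nodes, cfg.n_blocks, cfg.n_timepoints
    block_of = np.arange(n) * B // n  # contiguous, near-equal blocks
    c_glob = np.sqrt(cfg.between_corr / (1 - cfg.within_corr))
    a0 = np.sqrt((cfg.within_corr - cfg.between_corr) / (1 - cfg.within_corr))
    labels = [f"node{i:03d}" for i in range(n)]
    out: dict[tuple[str, str], Connectome] = {}
    for sid in _subject_ids(cfg.n_subjects):
        u_block = rng.normal(0, cfg.subject_sd, B)
        v_node = rng.normal(0, cfg.node_sd, n)
        for state in cfg.states:
            w_state = rng.normal(0, cfg.state_sd, B)
            load = a0 * np.exp(u_block[block_of] + v_node + w_state[block_of])
            g = rng.normal(size=T)
            f = rng.normal(size=(B, T))
            eps = rng.normal(size=(n, T))
            x = load[:, None] * f[block_of] + c_glob * g[None, :] + eps
            ts = TimeSeries(sid, state, [x], labels)
            out[(sid, state)] = build_connectome(ts)
    return out


def compute_metric_vectors(
    connectomes: Mapping[tuple[str, str], Connectome], roi: RoiMap
) -> list[MetricVector]:
    """Positive-graph metric vectors for every (subject, state) connectome."""
    return [
        metric_vector(to_positive_graph(c), roi, sid, state)
        for (sid, state), c in sorted(connectomes.items())
    ]


def _feature_table(metric_vectors, states) -> pd.DataFrame:
    spec = ModelSpec("anhedonia", candidate_states=tuple(states))
    return assemble_features(metric_vectors, spec)


def generate_symptoms(
    cfg: SyntheticConfig,
    metric_vectors: list[MetricVector],
    seed: int | None = None,
    brain_override: np.ndarray | None = None,
) -> CohortTable:
    """Clinical table with the planted metric-symptom dependence.

    The target (on its modeling scale) is
    ``beta * z(planted metric) + sum(gamma * covariates) + eps`` with beta
    calibrated from the realised non-brain variance so the brain term
    explains ``effect_size`` of target variance.  Follow-up scores are
    autocorrelated with baseline; missingness is applied per time point.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    features = _feature_table(metric_vectors, cfg.states)
    subjects = list(features.index)
    n = len(subjects)

    if brain_override is not None:
        brain = np.asarray(brain_override, dtype=float)
    elif cfg.planted_feature == "none":
        brain = None
    else:
        col = f"{cfg.planted_state}:{cfg.planted_feature}"
        if col not in features.columns:
            raise ValueError(f"planted feature {col!r} absent from metric vectors")
        vals = features[col].to_numpy(dtype=float)
        brain = (vals - vals.mean()) / vals.std()

    # medication load: many unmedicated, right-skewed doses for the rest
    med = np.where(rng.random(n) < 0.45, 0.0, rng.gamma(2.0, 0.5, n))
    med_z = (med - med.mean()) / (med.std() if med.std() > 0 else 1.0)

    # correlated baseline latents for the three scales
    rho = cfg.baseline_corr
    cov = np.full((3, 3), rho)
    np.fill_diagonal(cov, 1.0)
    lat_base = rng.multivariate_normal(np.zeros(3), cov, size=n)
    lat = {s: {"baseline": lat_base[:, i]} for i, s in enumerate(SYMPTOMS)}

    tgt_s, tgt_t = cfg.target_symptom, cfg.target_timepoint
    others = [s for s in SYMPTOMS if s != tgt_s]

    def planted(rest: np.ndarray) -> np.ndarray:
        if brain is None or cfg.effect_size == 0:
            return rest
        v_rest = rest.var()
        beta = np.sqrt(cfg.effect_size * v_rest / (1 - cfg.effect_size))
        return beta * brain + rest

    if tgt_t == "baseline":
        rest = (
            cfg.covariate_effect_other * (lat[others[0]]["baseline"] + lat[others[1]]["baseline"])
            + cfg.covariate_effect_medication * med_z
            + cfg.noise_sd * rng.normal(size=n)
        )
        lat[tgt_s]["baseline"] = planted(rest)

    a = cfg.followup_autocorr
    innov = np.sqrt(max(1 - a**2, 0.05))
    for t in ("3m", "6m"):
        for s in SYMPTOMS:
            base_same = lat[s]["baseline"]
            cross = 0.1 * sum(lat[o]["baseline"] for o in SYMPTOMS if o != s)
            series = a * base_same + cross + innov * rng.normal(size=n)
            if s == tgt_s and t == tgt_t:
                rest = (
                    a * base_same
                    + cross
                    + cfg.covariate_effect_medication * med_z
                    + cfg.noise_sd * rng.normal(size=n)
                )
                series = planted(rest)
            lat[s][t] = series

    data: dict[str, np.ndarray] = {}
    for s in SYMPTOMS:
        kind, loc, scale = SCALE_PARAMS[s]
        for t in ("baseline", "3m", "6m"):
            z = lat[s][t]
            raw = loc + scale * z
            if kind == "expm1":
                raw = np.expm1(np.maximum(raw, 0.0))
            data[symptom_column(s, t)] = raw

    frame = pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"))
    lost3 = rng.random(n) < cfg.missing_3m
    lost6 = rng.random(n) < cfg.missing_6m
    for s in SYMPTOMS:
        frame.loc[lost3, symptom_column(s, "3m")] = np.nan
        frame.loc[lost6, symptom_column(s, "6m")] = np.nan
        for t in ("baseline", "3m", "6m"):
            drop = rng.random(n) < cfg.scale_missing
            frame.loc[drop, symptom_column(s, t)] = np.nan

    frame["medication_load"] = med
    n_uni = int(round(cfg.group_split * n))
    groups = np.array(["unipolar"] * n_uni + ["bipolar"] * (n - n_uni))
    frame["group"] = rng.permutation(groups)
    return CohortTable(frame)


@dataclass
class SyntheticCohort:
    """All artefacts of one generated cohort."""

    config: SyntheticConfig
    connectomes: dict[tuple[str, str], Connectome]
    metric_vectors: list[MetricVector]
    features: pd.DataFrame
    cohort: CohortTable
    roi_map: RoiMap
    edge_signal: dict | None = None

    def model_spec(self, **overrides) -> ModelSpec:
        kw = dict(
            target_symptom=self.config.target_symptom,
            target_timepoint=self.config.target_timepoint,
            candidate_states=tuple(self.config.states),
        )
        kw.update(overrides)
        return ModelSpec(**kw)

    def model(self, spec: ModelSpec | None = None, **kw) -> GraphPredictiveModel:
        return GraphPredictiveModel(
            self.features, self.cohort, spec or self.model_spec(), **kw
        )

    @property
    def planted_column(self) -> str:
        return f"{self.config.planted_state}:{self.config.planted_feature}"


def generate_cohort(cfg: SyntheticConfig, seed: int | None = None) -> SyntheticCohort:
    """Connectomes -> metric vectors -> symptoms, with derived stage seeds."""
    master = cfg.seed if seed is None else seed
    s_conn, s_symp = _spawn_seeds(master, 2)
    connectomes = generate_connectomes(cfg, s_conn)
    roi = default_roi_map(cfg)
    mvs = compute_metric_vectors(connectomes, roi)
    cohort = generate_symptoms(cfg, mvs, s_symp)
    features = _feature_table(mvs, cfg.states)
    return SyntheticCohort(cfg, connectomes, mvs, features, cohort, roi)


def generate_edge_effect_cohort(
    cfg: SyntheticConfig,
    n_signal_edges: int = 20,
    edge_strength: float = 0.3,
    seed: int | None = None,
) -> SyntheticCohort:
    """Cohort whose signal lives in individual edges, not a graph metric.

    A subject-level latent u is added (scaled by ``edge_strength``) to
    ``n_signal_edges`` random edges of the planted state's connectome, and
    the target is built from u itself — the diffuse edge-level signal the
    CPM is designed for, with no single metric carrying it by design.
    """
    master = cfg.seed if seed is None else seed
    s_conn, s_symp, s_edge = _spawn_seeds(master, 3)
    connectomes = generate_connectomes(cfg, s_conn)
    rng = np.random.default_rng(s_edge)
    n = cfg.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    pick = rng.choice(iu.size, size=n_signal_edges, replace=False)
    subjects = _subject_ids(cfg.n_subjects)
    u = rng.normal(size=cfg.n_subjects)
    for s_i, sid in enumerate(subjects):
        c = connectomes[(sid, cfg.planted_state)]
        z = c.z.copy()
        z[iu[pick], ju[pick]] += edge_strength * u[s_i]
        z[ju[pick], iu[pick]] += edge_strength * u[s_i]
        connectomes[(sid, cfg.planted_state)] = Connectome(
            sid, cfg.planted_state, z, c.node_labels
        )
    roi = default_roi_map(cfg)
    mvs = compute_metric_vectors(connectomes, roi)
    cohort = generate_symptoms(cfg, mvs, s_symp, brain_override=u)
    features = _feature_table(mvs, cfg.states)
    return SyntheticCohort(
        cfg, connectomes, mvs, features, cohort, roi,
        edge_signal={"edges": list(zip(iu[pick].tolist(), ju[pick].tolist())),
                     "strength": edge_strength, "u": u},
    )


def _spawn_seeds(master: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]


@dataclass
class RecoveryResult:
    """Per-replicate end-to-end GPM outcomes on planted-effect cohorts."""

    replicates: pd.DataFrame
    config: SyntheticConfig

    def summary(self) -> dict[str, float]:
        rep = self.replicates
        out = {
            "n_replicates": float(len(rep)),
            "selection_accuracy": float(rep["planted_selected"].mean()),
            "mean_r": float(rep["pearson_r"].mean()),
            "mean_mse_diff": float(rep["mse_diff"].mean()),
            "frac_model_beats_null": float((rep["mse_diff"] > 0).mean()),
        }
        if "comparison_p" in rep:
            out["corrected_test_rejection"] = float((rep["comparison_p"] < 0.05).mean())
        if "permutation_p" in rep:
            out["permutation_rejection"] = float((rep["permutation_p"] < 0.05).mean())
        return out


def recovery_experiment(
    cfg: SyntheticConfig,
    n_replicates: int = 100,
    seed: int = 0,
    scheme=LOOCV(),
    do_comparison: bool = False,
    do_permutation: bool = False,
    n_perm: int = 200,
    comparison_repeats: int = 5,
) -> RecoveryResult:
    """End-to-end parameter recovery across replicate cohorts.

    For each replicate: generate a cohort, run the GPM and its null under
    the given CV scheme, and record whether the modal selected feature is
    the planted one, the CV Pearson r, and the relative MSE difference;
    optionally also the corrected-test and permutation p-values.
    """
    seeds = _spawn_seeds(seed, n_replicates)
    rows = []
    for rep, s in enumerate(seeds):
        syn = generate_cohort(cfg, s)
        model = syn.model()
        res = model.fit(scheme)
        null = model.fit_null(scheme)
        counts = res.selected_counts()
        modal = counts.index[0] if len(counts) else ""
        row = {
            "replicate": rep,
            "planted_selected": modal == syn.planted_column,
            "pearson_r": res.pearson_r,
            "mse_gpm": res.mse,
            "mse_null": null.mse,
            "mse_diff": (null.mse - res.mse) / null.mse,
        }
        if do_comparison:
            comp = model.compare_to_null(k=10, repeats=comparison_repeats, seed=s)
            row["comparison_p"] = comp.p
        if do_permutation:
            row["permutation_p"] = res.permutation_test(n_perm=n_perm, seed=s).p
        rows.append(row)
    return RecoveryResult(pd.DataFrame(rows), cfg)
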
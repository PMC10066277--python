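"""Synthetic cohorts with the statistical structure the pipeline assumes.

What is emulated
----------------
* a two-group cohort (19 case / 20 control by default) with a scalar latent
  "language typicality" theta per participant, group-separated by a
  configurable standardized mean difference;
* per-conversation feature tables (81 columns by default) in which a subset
  of informative features load linearly on theta, with a participant-level
  random effect and i.i.d. conversation noise on top — the shape of a
  dictionary-based word-count feature table without any text;
* ordinal severity scores (integer 7..14, the diagnostic floor upward) for
  case participants only, rank-linked to theta with controllable strength;
* parcellated conversation scans built from a factor model: every node
  loads on a global factor (baseline connectivity), case participants get
  an extra global loading on designated "over-connected" regions, and a
  compensation factor couples a seed region with a partner node set whose
  seed-side loading grows with theta for case participants only.

Planting connectivity through factor loadings guarantees a valid joint
covariance and yields whole-brain-connectedness group differences of the
kind the mapping stage tests for.  Ground truth (theta, planted loadings,
planted feature means) is stored alongside every dataset for tests and is
never consumed by pipeline stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import substream
from .core import FeatureTable, ScanTimeSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_features",
    "simulate_severity",
    "simulate_timeseries",
    "simulate_partner_features",
    "simulate_dataset",
    "write_dataset",
    "default_node_layout",
    "default_node_sets",
]

SEVERITY_MIN = 7
SEVERITY_MAX = 14
NOISE_VAR_FLOOR = 0.05


def default_node_layout(n_nodes: int = 80) -> pd.DataFrame:
    """Two parallel chains of nodes, one per hemisphere.

    Within a hemisphere consecutive nodes sit one unit apart (so a radius
    rule of ~1.5 yields a chain adjacency); hemispheres are two units apart
    and never adjacent.
    """
    n_right = n_nodes // 2
    n_left = n_nodes - n_right
    rows = []
    for i in range(n_right):
        rows.append({"node_id": f"R{i:02d}", "hemisphere": "R", "x": 1.0, "y": float(i), "z": 0.0})
    for i in range(n_left):
        rows.append({"node_id": f"L{i:02d}", "hemisphere": "L", "x": -1.0, "y": float(i), "z": 0.0})
    return pd.DataFrame(rows)


def default_node_sets(n_nodes: int = 80) -> dict:
    """Three contiguous right-hemisphere over-connected regions (10 nodes
    each, separated by gaps) plus a 2:1 left:right partner node set."""
    n_right = n_nodes // 2
    n_left = n_nodes - n_right
    if n_right < 40 or n_left < 10:
        raise ValueError(
            "default node sets need >= 80 nodes; supply explicit node sets "
            "for smaller layouts"
        )
    regions = {
        "region_A": tuple(f"R{i:02d}" for i in range(0, 10)),
        "region_B": tuple(f"R{i:02d}" for i in range(12, 22)),
        "region_C": tuple(f"R{i:02d}" for i in range(24, 34)),
    }
    partner = tuple(f"L{i:02d}" for i in range(0, 10)) + tuple(
        f"R{i:02d}" for i in range(35, 40)
    )
    return {
        "overconnected": regions,
        "compensation": regions["region_A"],
        "partner": partner,
    }


@dataclass
class SimulationConfig:
    """Generator settings; defaults mirror the study conditions.

    Cohort: 19 case / 20 control male-cohort-sized groups, 3 conversations
    per participant, 81 features, 180 timepoints (6 min at TR 2 s).
    Parameters without a stated condition (effect sizes, loadings, noise)
    are fixed at values calibrated once so that desk-scale classifier
    accuracy lands in a realistic 70-85% band; see docs/methods.md.
    """

    n_case: int = 19
    n_control: int = 20
    n_conversations_per_participant: int = 3
    n_features: int = 81
    n_informative_features: int = 20
    feature_effect_size: float = 1.3  # group separation of theta, in SD units
    within_participant_sd: float = 0.5
    noise_sd: float = 1.0
    severity_link_strength: float = 0.55
    n_nodes: int = 80
    n_timepoints: int = 180
    baseline_connectivity: float = 0.10
    group_connectivity_delta: float = 0.50
    compensation_slope: float = 0.06
    region_coupling: float = 0.15
    partner_coupling: float = 0.45
    compensation_node_set: Optional[tuple[str, ...]] = None
    partner_node_set: Optional[tuple[str, ...]] = None
    overconnected_node_sets: Optional[dict] = None
    nodes: Optional[pd.DataFrame] = field(default=None, repr=False)
    age_range: tuple[float, float] = (14.7, 32.0)
    motion_log_mean: float = -2.5  # lognormal mean FD ~ 0.08 mm
    motion_log_sd: float = 0.4
    n_audio_failures: int = 2
    case_label: str = "case"
    control_label: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 participants per group")
        if self.n_informative_features > self.n_features:
            raise ValueError("n_informative_features cannot exceed n_features")
        if not 0.0 <= self.severity_link_strength <= 1.0:
            raise ValueError("severity_link_strength must lie in [0, 1]")
        if not 0.0 < self.baseline_connectivity < 1.0:
            raise ValueError("baseline_connectivity must lie in (0, 1)")
        if self.nodes is None:
            self.nodes = default_node_layout(self.n_nodes)
        else:
            self.nodes = self.nodes.reset_index(drop=True)
            self.n_nodes = len(self.nodes)
        if self.compensation_node_set is None or self.partner_node_set is None:
            sets = default_node_sets(self.n_nodes)
            if self.compensation_node_set is None:
                self.compensation_node_set = sets["compensation"]
            if self.partner_node_set is None:
                self.partner_node_set = sets["partner"]
            if self.overconnected_node_sets is None:
                self.overconnected_node_sets = sets["overconnected"]
        if self.overconnected_node_sets is None:
            self.overconnected_node_sets = {"region_A": tuple(self.compensation_node_set)}
        self.compensation_node_set = tuple(self.compensation_node_set)
        self.partner_node_set = tuple(self.partner_node_set)
        self.overconnected_node_sets = {
            k: tuple(v) for k, v in self.overconnected_node_sets.items()
        }
        if set(self.compensation_node_set) & set(self.partner_node_set):
            raise ValueError("compensation and partner node sets must be disjoint")
        known = set(self.nodes["node_id"].astype(str))
        for name, nodes in {
            "compensation": self.compensation_node_set,
            "partner": self.partner_node_set,
            **self.overconnected_node_sets,
        }.items():
            missing = set(nodes) - known
            if missing:
                raise ValueError(f"node set {name!r} references unknown nodes {sorted(missing)}")
        self._validate_covariance()

    def _validate_covariance(self) -> None:
        """All implied node variances must keep a positive noise floor."""
        a2 = self.baseline_connectivity
        c_max = max(
            self.partner_coupling,
            self.region_coupling
            + max(self.group_connectivity_delta, 0.0)
            + 3.0 * abs(self.compensation_slope),
        )
        if a2 + c_max**2 > 1.0 - NOISE_VAR_FLOOR:
            raise ValueError(
                "implied covariance not positive definite: "
                f"baseline_connectivity={self.baseline_connectivity}, "
                f"group_connectivity_delta={self.group_connectivity_delta}, "
                f"region_coupling={self.region_coupling}, "
                f"compensation_slope={self.compensation_slope} exceed the "
                f"unit-variance budget (a^2 + c_max^2 = {a2 + c_max**2:.3f} "
                f"> {1.0 - NOISE_VAR_FLOOR})"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nodes"] = None
        d["compensation_node_set"] = list(self.compensation_node_set)
        d["partner_node_set"] = list(self.partner_node_set)
        d["overconnected_node_sets"] = {
            k: list(v) for k, v in self.overconnected_node_sets.items()
        }
        return d


@dataclass
class GroundTruth:
    """Planted quantities, consumed only by tests, never by the pipeline."""

    participants: pd.DataFrame  # participant_id, group, theta, age, motion, coupling
    feature_loadings: dict[str, float]
    informative_features: tuple[str, ...]
    excluded_conversations: tuple[str, ...]
    node_sets: dict
    config: SimulationConfig

    def theta_of(self, participant_id: str) -> float:
        row = self.participants.set_index("participant_id")["theta"]
        return float(row.loc[participant_id])


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the cohort: group, age, motion and latent typicality theta.

    theta ~ N(-d/2, 1) for case and N(+d/2, 1) for control, where d is
    ``feature_effect_size`` — higher theta means more control-like
    language behavior.
    """
    rng = substream(config.seed, "cohort")
    n = config.n_case + config.n_control
    pids = [f"sub{i + 1:03d}" for i in range(n)]
    groups = [config.case_label] * config.n_case + [config.control_label] * config.n_control
    d = config.feature_effect_size
    shift = np.where(np.array(groups) == config.case_label, -d / 2.0, d / 2.0)
    theta = rng.standard_normal(n) + shift
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    motion = rng.lognormal(config.motion_log_mean, config.motion_log_sd, size=n)
    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "group": groups,
            "theta": theta,
            "age": age,
            "motion": motion,
        }
    )
    # conversation roster and the audio-failure exclusions (from distinct
    # control participants, mirroring the two lost recordings)
    conv_ids = [
        f"{pid}_c{k + 1}"
        for pid in pids
        for k in range(config.n_conversations_per_participant)
    ]
    controls = participants.loc[
        participants["group"] == config.control_label, "participant_id"
    ].to_numpy()
    n_excl = min(config.n_audio_failures, len(controls))
    excl_pids = rng.choice(controls, size=n_excl, replace=False)
    excluded = tuple(
        f"{pid}_c{rng.integers(1, config.n_conversations_per_participant + 1)}"
        for pid in excl_pids
    )
    loadings_rng = substream(config.seed, "feature-loadings")
    informative = tuple(f"feat_{j + 1:03d}" for j in range(config.n_informative_features))
    signs = np.where(loadings_rng.random(config.n_informative_features) < 0.5, -1.0, 1.0)
    mags = loadings_rng.uniform(0.4, 1.0, size=config.n_informative_features)
    feature_loadings = {name: float(s * m) for name, s, m in zip(informative, signs, mags)}
    gt = GroundTruth(
        participants=participants,
        feature_loadings=feature_loadings,
        informative_features=informative,
        excluded_conversations=excluded,
        node_sets={
            "compensation": config.compensation_node_set,
            "partner": config.partner_node_set,
            "overconnected": config.overconnected_node_sets,
        },
        config=config,
    )
    gt.conversation_ids = tuple(conv_ids)  # type: ignore[attr-defined]
    return participants, gt


def _feature_matrix(
    participants: pd.DataFrame,
    gt: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    null_features: bool = False,
) -> pd.DataFrame:
    n_part = len(participants)
    n_conv = config.n_conversations_per_participant
    feat_names = [f"feat_{j + 1:03d}" for j in range(config.n_features)]
    beta = np.zeros(config.n_features)
    if not null_features:
        for j, name in enumerate(feat_names):
            if name in gt.feature_loadings:
                beta[j] = gt.feature_loadings[name]
    informative = np.array([beta[j] != 0.0 for j in range(config.n_features)])
    theta = participants["theta"].to_numpy()
    # participant-level random effect on informative features only, shared
    # across a participant's conversations; non-informative features are
    # pure conversation-level noise
    b = rng.normal(0.0, config.within_participant_sd, size=(n_part, config.n_features))
    b[:, ~informative] = 0.0
    rows = []
    values = []
    for p in range(n_part):
        pid = participants["participant_id"].iloc[p]
        for k in range(n_conv):
            eps = rng.normal(0.0, config.noise_sd, size=config.n_features)
            values.append(beta * theta[p] + b[p] + eps)
            rows.append(
                {
                    "conversation_id": f"{pid}_c{k + 1}",
                    "participant_id": pid,
                    "group": participants["group"].iloc[p],
                }
            )
    frame = pd.DataFrame(rows)
    frame[feat_names] = np.asarray(values)
    return frame


def simulate_features(
    participants: pd.DataFrame,
    gt: GroundTruth,
    config: SimulationConfig,
) -> FeatureTable:
    """One row per conversation; informative features load on theta."""
    rng = substream(config.seed, "features")
    frame = _feature_matrix(participants, gt, config, rng)
    return FeatureTable(
        data=frame, feature_columns=tuple(f"feat_{j + 1:03d}" for j in range(config.n_features))
    )


def simulate_partner_features(
    participants: pd.DataFrame,
    gt: GroundTruth,
    config: SimulationConfig,
) -> FeatureTable:
    """Features of the conversation partner: pure noise, no group signal.

    Same conversation roster as the participant table, so the control
    classifier runs the identical chain on it.
    """
    rng = substream(config.seed, "partner-features")
    frame = _feature_matrix(participants, gt, config, rng, null_features=True)
    return FeatureTable(
        data=frame, feature_columns=tuple(f"feat_{j + 1:03d}" for j in range(config.n_features))
    )


def simulate_severity(
    participants: pd.DataFrame,
    gt: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Ordinal severity (7..14) for case participants, rank-linked to theta.

    The link strength lambda is planted on the Spearman scale through the
    bivariate-normal relation rho_pearson = 2 sin(pi * lambda / 6); the
    severity latent is monotone-decreasing in theta (higher typicality,
    fewer observed signs) before binning into the 8 ordinal levels.
    """
    rng = substream(config.seed, "severity")
    case = participants[participants["group"] == config.case_label]
    n = len(case)
    lam = config.severity_link_strength
    rho = 2.0 * np.sin(np.pi * lam / 6.0)
    theta = case["theta"].to_numpy()
    tstar = (theta - theta.mean()) / (theta.std(ddof=0) or 1.0)
    latent = -(rho * tstar + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n))
    order = np.argsort(np.argsort(latent, kind="stable"), kind="stable")
    n_levels = SEVERITY_MAX - SEVERITY_MIN + 1
    severity = SEVERITY_MIN + np.minimum(
        (order * n_levels) // max(n, 1), n_levels - 1
    ).astype(int)
    return pd.DataFrame(
        {"participant_id": case["participant_id"].to_numpy(), "severity": severity}
    )


def planted_couplings(
    participants: pd.DataFrame, config: SimulationConfig
) -> np.ndarray:
    """Seed-region compensation-factor loading per participant (the plant).

    Case: region_coupling + group_connectivity_delta + slope * theta,
    clipped to keep node variance decomposable; control: region_coupling.
    """
    theta = participants["theta"].to_numpy()
    is_case = (participants["group"] == config.case_label).to_numpy()
    c_cap = np.sqrt(max(1.0 - NOISE_VAR_FLOOR - config.baseline_connectivity, 0.0))
    c = np.where(
        is_case,
        config.region_coupling
        + config.group_connectivity_delta
        + config.compensation_slope * theta,
        config.region_coupling,
    )
    return np.clip(c, 0.0, c_cap)


def simulate_timeseries(
    participants: pd.DataFrame,
    gt: GroundTruth,
    config: SimulationConfig,
) -> list[ScanTimeSeries]:
    """One scan per conversation from the factor model.

    Every node loads sqrt(baseline_connectivity) on a global factor (both
    groups alike).  Each over-connected region has its own factor: control
    participants load ``region_coupling`` on it, case participants
    ``region_coupling + group_connectivity_delta``.  The compensation
    region's factor is shared with the partner node set (which loads
    ``partner_coupling`` in both groups), and the case-group loading on it
    additionally grows with theta at ``compensation_slope`` (clipped to
    keep the covariance positive definite).  Node-wise noise completes
    each series to unit variance.
    """
    rng = substream(config.seed, "timeseries")
    nodes = config.nodes
    node_ids = nodes["node_id"].astype(str).to_numpy()
    n_nodes = len(node_ids)
    in_seed = np.isin(node_ids, list(config.compensation_node_set))
    in_partner = np.isin(node_ids, list(config.partner_node_set))
    seed_set = set(config.compensation_node_set)
    other_regions = [
        np.isin(node_ids, list(members))
        for name, members in config.overconnected_node_sets.items()
        if set(members) != seed_set
    ]
    base_a = np.sqrt(config.baseline_connectivity)
    couplings = planted_couplings(participants, config)
    gt.participants = participants.assign(coupling=couplings)
    scans = []
    T = config.n_timepoints
    for p in range(len(participants)):
        row = participants.iloc[p]
        is_case = row["group"] == config.case_label
        a = np.full(n_nodes, base_a)
        # factor loading matrix: compensation factor first, then one factor
        # per remaining over-connected region
        n_factors = 1 + len(other_regions)
        c = np.zeros((n_nodes, n_factors))
        c[in_seed, 0] = couplings[p]
        c[in_partner, 0] = config.partner_coupling
        c_region = config.region_coupling + (
            config.group_connectivity_delta if is_case else 0.0
        )
        for f, mask in enumerate(other_regions):
            c[mask, f + 1] = c_region
        noise_var = np.maximum(1.0 - a**2 - (c**2).sum(axis=1), NOISE_VAR_FLOOR)
        noise_sd = np.sqrt(noise_var)
        for k in range(config.n_conversations_per_participant):
            g = rng.standard_normal(T)
            fac = rng.standard_normal((n_factors, T))
            eps = rng.standard_normal((n_nodes, T)) * noise_sd[:, None]
            data = a[:, None] * g[None, :] + c @ fac + eps
            scan_motion = float(row["motion"] * np.exp(rng.normal(0.0, 0.2)))
            scans.append(
                ScanTimeSeries(
                    scan_id=f"{row['participant_id']}_c{k + 1}",
                    participant_id=str(row["participant_id"]),
                    data=data,
                    nodes=nodes,
                    age=float(row["age"]),
                    motion=scan_motion,
                    group=str(row["group"]),
                )
            )
    return scans


def simulate_dataset(config: SimulationConfig) -> dict:
    """Generate the full synthetic study: cohort, features, severity, scans."""
    participants, gt = simulate_cohort(config)
    features = simulate_features(participants, gt, config)
    partner = simulate_partner_features(participants, gt, config)
    severity = simulate_severity(participants, gt, config)
    scans = simulate_timeseries(participants, gt, config)
    return {
        "participants": participants,
        "ground_truth": gt,
        "features": features,
        "partner_features": partner,
        "severity": severity,
        "scans": scans,
    }


def write_dataset(dataset: dict, out_dir: str | Path) -> None:
    """Write a simulated dataset in the on-disk layout the CLI consumes."""
    from . import io as cio

    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    cio.write_feature_table(dataset["features"], out / "features.tsv")
    cio.write_feature_table(dataset["partner_features"], out / "partner_features.tsv")
    dataset["severity"].to_csv(out / "severity.tsv", sep="\t", index=False)
    gt: GroundTruth = dataset["ground_truth"]
    cov_rows = []
    for scan in dataset["scans"]:
        cio.write_scan_timeseries(scan, out / "scans" / f"{scan.scan_id}.tsv")
        cov_rows.append(
            {
                "scan_id": scan.scan_id,
                "participant_id": scan.participant_id,
                "group": scan.group,
                "age": scan.age,
                "motion": scan.motion,
            }
        )
    pd.DataFrame(cov_rows).to_csv(out / "covariates.tsv", sep="\t", index=False,
                                  float_format=cio.FLOAT_FORMAT)
    gt.config.nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    truth = {
        "participants": gt.participants.to_dict(orient="list"),
        "feature_loadings": gt.feature_loadings,
        "informative_features": list(gt.informative_features),
        "excluded_conversations": list(gt.excluded_conversations),
        "node_sets": {
            "compensation": list(gt.node_sets["compensation"]),
            "partner": list(gt.node_sets["partner"]),
            "overconnected": {k: list(v) for k, v in gt.node_sets["overconnected"].items()},
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    cio.write_manifest(
        out / "manifest.json",
        config=gt.config.to_dict(),
        extra={"stage": "simulate", "seed": gt.config.seed},
    )
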
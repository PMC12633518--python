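"""Synthetic dynamic-PET cohort generator with known ground truth.

Two levels of simulation are provided:

* **scan level** — full dynamic TACs driven by a tri-exponential bolus
  input function through irreversible one-tissue kinetics (optional
  reversible efflux to stress the K1 estimator), frame-averaged, with
  count-statistics noise (SD proportional to sqrt(C / frame duration)),
  multiplicative batch effects, covariate-driven amplitude effects, and
  localized disease effects on designated regions;
* **edge level** — edge tables with designated group signatures at a
  controlled effect size in noise-SD units, for classifier power and null
  studies where full kinetic simulation is unnecessary.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import FrameSchedule, InputFunction, ScanRecord, TimeActivityCurve
from .registry import RoiRegistry, build_default_registry

__all__ = [
    "InputFunctionParams",
    "GroupSpec",
    "CovariateEffects",
    "CohortDesign",
    "SubjectParams",
    "GroundTruth",
    "simulate_input_function",
    "simulate_scan",
    "simulate_cohort",
    "simulate_edge_cohort",
    "roi_edge_signature",
    "example_design",
    "default_schedule",
    "load_design",
    "save_design",
]

#: Seed for the fixed "anatomical" baseline pattern (shared across cohorts
#: so different simulated sites see the same underlying biology).
_ANATOMY_SEED = 834201


@dataclass(frozen=True)
class InputFunctionParams:
    """Tri-exponential bolus: C_p(t) = (a1*t - a2 - a3)e^{-l1 t} + a2 e^{-l2 t} + a3 e^{-l3 t}."""

    a1: float = 851.1  # kBq/mL/min
    a2: float = 21.88  # kBq/mL
    a3: float = 20.81  # kBq/mL
    l1: float = 4.1339  # 1/min
    l2: float = 0.1191  # 1/min
    l3: float = 0.01043  # 1/min


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group within a batch/tracer cell."""

    name: str  # diagnosis label; "HC" for controls
    n: int
    tracer: str = "TRACER-A"
    batch: str = "BATCH-1"
    affected_rois: tuple[str, ...] = ()
    k1_effect: float = 0.0  # fractional K1 change in affected ROIs
    retest: bool = False
    blockade: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.name!r}: n must be >= 1")


@dataclass(frozen=True)
class CovariateEffects:
    """Multiplicative TAC-amplitude modifiers per covariate unit."""

    sex_m: float = 0.0  # males vs females
    genotype_mab: float = 0.0  # MAB vs HAB
    age_per_year: float = 0.0  # per year above 45
    dw_per_unit: float = 0.0  # per MBq/kg above 4


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[GroupSpec, ...]
    batch_scales: dict[str, float] = field(default_factory=dict)
    covariate_effects: CovariateEffects = CovariateEffects()
    noise_kappa: float = 0.0  # SD = kappa * sqrt(C / frame duration)
    frame_start: tuple[float, ...] = ()
    frame_end: tuple[float, ...] = ()
    if_params: InputFunctionParams = InputFunctionParams()
    k2: float = 0.0  # reversible efflux (stresses the irreversible K1 fit)
    vb_scale: float = 1.0  # blood-like amplitude component; 0 = pure irreversible
    subject_k1_sd: float = 0.03  # fractional per-region subject jitter
    blockade_factor: float = 0.5  # dispersion shrinkage toward the median
    tracers_without_genotype: tuple[str, ...] = ()
    dose_mean_mbq: float = 350.0

    def schedule(self) -> FrameSchedule:
        if self.frame_start:
            return FrameSchedule(np.array(self.frame_start), np.array(self.frame_end))
        return default_schedule()

    def __post_init__(self) -> None:
        if self.noise_kappa < 0:
            raise ValueError("noise_kappa must be >= 0")
        if not self.groups:
            raise ValueError("design needs at least one group")


@dataclass(frozen=True)
class SubjectParams:
    """Everything needed to regenerate one subject's scans deterministically."""

    subject_id: str
    group: GroupSpec
    k1: np.ndarray  # per-region influx, registry order
    vb: np.ndarray  # per-region blood-like amplitude component
    age: float
    sex: str
    genotype: str
    dose_mbq: float
    weight_kg: float


@dataclass
class ScanTruth:
    scan_id: str
    k1: dict[str, float]
    amplitude: float


@dataclass
class GroundTruth:
    scans: dict[str, ScanTruth]
    affected_rois: dict[str, tuple[str, ...]]  # per group
    covariate_effects: CovariateEffects
    design: CohortDesign


def default_schedule() -> FrameSchedule:
    """A 26-frame, 90-minute protocol (8x15s, 3x1, 5x2, 5x5, 5x10 min)."""
    durations = [0.25] * 8 + [1.0] * 3 + [2.0] * 5 + [5.0] * 5 + [10.0] * 5
    end = np.cumsum(durations)
    start = end - np.array(durations)
    return FrameSchedule(start, end)


def simulate_input_function(
    params: InputFunctionParams, grid_minutes
) -> InputFunction:
    """Evaluate the bolus model on ``grid_minutes`` (clipped at 0)."""
    t = np.asarray(grid_minutes, dtype=float)
    c = (
        (params.a1 * t - params.a2 - params.a3) * np.exp(-params.l1 * t)
        + params.a2 * np.exp(-params.l2 * t)
        + params.a3 * np.exp(-params.l3 * t)
    )
    return InputFunction(t, np.clip(c, 0.0, None))


def _anatomy(registry: RoiRegistry) -> tuple[np.ndarray, np.ndarray]:
    """Fixed per-region baseline K1 and blood-amplitude patterns."""
    rng = np.random.default_rng(_ANATOMY_SEED)
    base = {"cortical": 0.12, "subcortical": 0.10, "cerebellar": 0.11, "brainstem": 0.09}
    k1 = np.array([base[e.roi_class] for e in registry])
    k1 = k1 * (1.0 + rng.uniform(-0.25, 0.25, size=len(registry)))
    vb = rng.uniform(0.02, 0.06, size=len(registry))
    return k1, vb


def _fine_grid(schedule: FrameSchedule, dt: float = 0.02) -> np.ndarray:
    t_end = float(schedule.frame_end[-1])
    n = int(round(t_end / dt)) + 1
    return np.linspace(0.0, t_end, n)


def _tissue_curves(
    k1: np.ndarray, vb: np.ndarray, cp: np.ndarray, grid: np.ndarray, k2: float
) -> np.ndarray:
    """True tissue curves (regions x time) on the fine grid."""
    dt = grid[1] - grid[0]
    if k2 > 0:
        kernel = np.exp(-k2 * grid)
        conv = np.convolve(cp, kernel)[: grid.size] * dt
    else:
        conv = np.concatenate([[0.0], np.cumsum(0.5 * (cp[1:] + cp[:-1]) * np.diff(grid))])
    return k1[:, None] * conv[None, :] + vb[:, None] * cp[None, :]


def _frame_average(curves: np.ndarray, grid: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average each region's curve over each frame (regions x frames)."""
    dt = grid[1] - grid[0]
    cum = np.concatenate(
        [np.zeros((curves.shape[0], 1)), np.cumsum(0.5 * (curves[:, 1:] + curves[:, :-1]) * dt, axis=1)],
        axis=1,
    )
    out = np.empty((curves.shape[0], schedule.n_frames))
    for f, (a, b) in enumerate(zip(schedule.frame_start, schedule.frame_end)):
        ca = np.array([np.interp(a, grid, cum[r]) for r in range(curves.shape[0])])
        cb = np.array([np.interp(b, grid, cum[r]) for r in range(curves.shape[0])])
        out[:, f] = (cb - ca) / (b - a)
    return out


def _draw_subject(
    design: CohortDesign,
    group: GroupSpec,
    subject_id: str,
    registry: RoiRegistry,
    rng: np.random.Generator,
) -> SubjectParams:
    k1_base, vb_base = _anatomy(registry)
    k1 = k1_base * (1.0 + rng.normal(0.0, design.subject_k1_sd, size=len(registry)))
    vb = vb_base * (1.0 + rng.normal(0.0, design.subject_k1_sd, size=len(registry)))
    k1 = np.clip(k1, 1e-4, None)
    vb = np.clip(vb, 1e-4, None) * design.vb_scale
    if group.affected_rois and group.k1_effect != 0.0:
        idx = [registry.index(r) for r in group.affected_rois]
        k1[idx] *= 1.0 + group.k1_effect
    age = float(np.clip(rng.normal(45.0, 12.0), 18.0, 85.0))
    sex = "M" if rng.random() < 0.5 else "F"
    if group.tracer in design.tracers_without_genotype:
        genotype = "NA"
    else:
        genotype = "HAB" if rng.random() < 0.6 else "MAB"
    dose = float(np.clip(rng.normal(design.dose_mean_mbq, 0.08 * design.dose_mean_mbq), 50.0, None))
    weight = float(np.clip(rng.normal(75.0, 12.0), 40.0, 130.0))
    return SubjectParams(
        subject_id=subject_id, group=group, k1=k1, vb=vb,
        age=age, sex=sex, genotype=genotype, dose_mbq=dose, weight_kg=weight,
    )


def _amplitude(design: CohortDesign, subject: SubjectParams) -> float:
    eff = design.covariate_effects
    scale = design.batch_scales.get(subject.group.batch, 1.0)
    dw = subject.dose_mbq / subject.weight_kg
    amp = scale * (
        1.0
        + eff.sex_m * (subject.sex == "M")
        + eff.genotype_mab * (subject.genotype == "MAB")
        + eff.age_per_year * (subject.age - 45.0)
        + eff.dw_per_unit * (dw - 4.0)
    )
    if amp <= 0:
        raise ValueError("covariate effects drove the TAC amplitude non-positive")
    return amp


def simulate_scan(
    design: CohortDesign,
    subject: SubjectParams,
    seed: int,
    session: str = "baseline",
    registry: RoiRegistry | None = None,
) -> tuple[ScanRecord, ScanTruth]:
    """One scan for one subject: true kinetics + frame averaging + noise."""
    registry = registry or build_default_registry()
    rng = np.random.default_rng(seed)
    schedule = design.schedule()
    grid = _fine_grid(schedule)
    cp = simulate_input_function(design.if_params, grid).concentrations

    k1, vb = subject.k1.copy(), subject.vb.copy()
    if session == "block":
        f = design.blockade_factor
        k1 = np.median(k1) + f * (k1 - np.median(k1))
        vb = np.median(vb) + f * (vb - np.median(vb))

    amp = _amplitude(design, subject)
    curves = amp * _tissue_curves(k1, vb, cp, grid, design.k2)
    frames = _frame_average(curves, grid, schedule)

    if design.noise_kappa > 0:
        sd = design.noise_kappa * np.sqrt(
            np.clip(frames, 1e-6, None) / schedule.durations[None, :]
        )
        frames = frames + rng.normal(0.0, 1.0, size=frames.shape) * sd

    scan_id = f"{subject.subject_id}_{session}"
    tacs = {
        name: TimeActivityCurve(name, np.clip(frames[i], 0.0, None))
        for i, name in enumerate(registry.names)
    }
    idif_grid = np.unique(np.concatenate([np.linspace(0.0, 3.0, 61), np.linspace(3.0, grid[-1], 120)]))
    idif = simulate_input_function(design.if_params, idif_grid)
    record = ScanRecord(
        scan_id=scan_id,
        subject_id=subject.subject_id,
        tracer=subject.group.tracer,
        batch=subject.group.batch,
        dose_mbq=subject.dose_mbq,
        weight_kg=subject.weight_kg,
        age=subject.age,
        sex=subject.sex,
        genotype=subject.genotype,
        diagnosis=subject.group.name,
        session=session,
        tacs=tacs,
        schedule=schedule,
        idif=idif,
    )
    truth = ScanTruth(
        scan_id=scan_id,
        k1={name: float(amp * k1[i]) for i, name in enumerate(registry.names)},
        amplitude=amp,
    )
    return record, truth


def simulate_cohort(
    design: CohortDesign,
    seed: int,
    out_dir=None,
    registry: RoiRegistry | None = None,
) -> tuple[list[ScanRecord], GroundTruth]:
    """Simulate all groups/sessions; optionally write the cohort to disk."""
    registry = registry or build_default_registry()
    root = np.random.default_rng(seed)
    scans: list[ScanRecord] = []
    truths: dict[str, ScanTruth] = {}
    for gi, group in enumerate(design.groups):
        for si in range(group.n):
            subject_id = f"{group.name}-{group.batch}-s{si:03d}"
            subj_rng = np.random.default_rng(root.integers(0, 2**63))
            subject = _draw_subject(design, group, subject_id, registry, subj_rng)
            sessions = ["baseline"]
            if group.retest:
                sessions.append("retest")
            if group.blockade:
                sessions.append("block")
            for session in sessions:
                scan_seed = int(root.integers(0, 2**63))
                record, truth = simulate_scan(
                    design, subject, scan_seed, session=session, registry=registry
                )
                scans.append(record)
                truths[record.scan_id] = truth
    gt = GroundTruth(
        scans=truths,
        affected_rois={g.name: g.affected_rois for g in design.groups},
        covariate_effects=design.covariate_effects,
        design=design,
    )
    if out_dir is not None:
        from .io import write_cohort

        write_cohort(scans, out_dir)
    return scans, gt


# --------------------------------------------------------------------------
# edge-level generator


def roi_edge_signature(
    n_rois: int,
    affected_rois: Sequence[int],
    edges_per_roi: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Edge indices touching the affected ROIs (``edges_per_roi`` each).

    Partner regions are drawn without replacement among non-affected ROIs,
    so every selected edge touches exactly one affected ROI.
    """
    iu, ju = np.triu_indices(n_rois, k=1)
    edge_lookup = {}
    for e, (i, j) in enumerate(zip(iu, ju)):
        edge_lookup[(int(i), int(j))] = e
    affected = set(int(r) for r in affected_rois)
    others = [r for r in range(n_rois) if r not in affected]
    chosen: list[int] = []
    for roi in sorted(affected):
        partners = rng.choice(others, size=edges_per_roi, replace=False)
        for p in partners:
            a, b = min(roi, int(p)), max(roi, int(p))
            chosen.append(edge_lookup[(a, b)])
    return np.unique(np.array(chosen, dtype=int))


def simulate_edge_cohort(
    group_sizes: Mapping[str, int],
    n_rois: int,
    signatures: Mapping[str, np.ndarray] | None,
    effect_size: float,
    noise_sd: float = 1.0,
    baseline_sd: float = 0.5,
    seed: int = 0,
    roi_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Edge table with group-specific signatures.

    Every scan is ``baseline + group offset + N(0, noise_sd)`` per edge; the
    group offset is ``effect_size * noise_sd`` on that group's signature
    edges and 0 elsewhere.  The common baseline is drawn once per cohort
    (N(0, baseline_sd) across edges).  Returns (edge table, labels).
    """
    from .network import edge_names

    rng = np.random.default_rng(seed)
    n_edges = n_rois * (n_rois - 1) // 2
    names = list(roi_names) if roi_names is not None else [f"r{i:03d}" for i in range(n_rois)]
    cols = edge_names(names)
    baseline = rng.normal(0.0, baseline_sd, size=n_edges)
    signatures = signatures or {}

    rows, labels, ids = [], [], []
    for group in group_sizes:
        offset = np.zeros(n_edges)
        sig = signatures.get(group)
        if sig is not None and effect_size != 0.0:
            offset[np.asarray(sig, dtype=int)] = effect_size * noise_sd
        for s in range(group_sizes[group]):
            rows.append(baseline + offset + rng.normal(0.0, noise_sd, size=n_edges))
            labels.append(group)
            ids.append(f"{group}-s{s:03d}")
    edge_df = pd.DataFrame(np.array(rows), index=ids, columns=cols)
    edge_df.index.name = "scan_id"
    return edge_df, pd.Series(labels, index=ids, name="diagnosis")


def example_design(scale: float = 1.0) -> CohortDesign:
    """A small multi-tracer, multi-batch, five-disease demo layout.

    Group sizes are a scaled-down version of a realistic multi-site cohort
    (three tracers, seven batches, five disease groups plus controls,
    with retest and blockade sub-cohorts).
    """
    registry = build_default_registry()

    def rois(names: Sequence[str]) -> tuple[str, ...]:
        return tuple(names)

    def n(x: int) -> int:
        return max(2, int(round(x * scale)))

    groups = (
        GroupSpec("HC", n(8), "TRACER-A", "SITE1-A"),
        GroupSpec("SCZ", n(4), "TRACER-A", "SITE1-A",
                  affected_rois=rois(["lh_putamen", "rh_pallidum", "lh_frontalpole"]),
                  k1_effect=0.15, blockade=True),
        GroupSpec("TBI", n(4), "TRACER-A", "SITE1-A",
                  affected_rois=rois(["lh_lateralorbitofrontal", "lh_rostralanteriorcingulate",
                                      "lh_medialorbitofrontal"]),
                  k1_effect=0.15),
        GroupSpec("AD", n(3), "TRACER-A", "SITE1-A",
                  affected_rois=rois(["lh_hippocampus", "rh_hippocampus"]),
                  k1_effect=0.12, retest=True),
        GroupSpec("HC", n(6), "TRACER-A", "SITE2-A"),
        GroupSpec("cLBP", n(5), "TRACER-A", "SITE2-A",
                  affected_rois=rois(["lh_accumbens", "rh_caudalanteriorcingulate", "lh_bankssts"]),
                  k1_effect=0.15),
        GroupSpec("HC", n(8), "TRACER-B", "SITE3-B", retest=True),
        GroupSpec("MS", n(6), "TRACER-B", "SITE3-B",
                  affected_rois=rois(["lh_putamen", "rh_putamen", "lh_thalamus"]),
                  k1_effect=0.18),
        GroupSpec("HC", n(8), "TRACER-C", "SITE4-C"),
        GroupSpec("DEP", n(6), "TRACER-C", "SITE4-C",
                  affected_rois=rois(["rh_caudalmiddlefrontal", "lh_rostralanteriorcingulate",
                                      "lh_parsopercularis"]),
                  k1_effect=0.12),
    )
    return CohortDesign(
        groups=groups,
        batch_scales={"SITE1-A": 1.0, "SITE2-A": 1.1, "SITE3-B": 0.95, "SITE4-C": 1.05},
        covariate_effects=CovariateEffects(
            sex_m=0.04, genotype_mab=0.05, age_per_year=-0.002, dw_per_unit=0.01
        ),
        noise_kappa=0.3,
        tracers_without_genotype=("TRACER-C",),
    )


# --------------------------------------------------------------------------
# design (de)serialization


def load_design(path) -> CohortDesign:
    """Load a cohort design from YAML (schema mirrors :class:`CohortDesign`)."""
    import yaml

    raw = yaml.safe_load(open(path))
    if not isinstance(raw, dict) or "groups" not in raw:
        raise ValueError("design file must be a mapping with a 'groups' list")
    groups = tuple(
        GroupSpec(
            name=str(g["name"]),
            n=int(g["n"]),
            tracer=str(g.get("tracer", "TRACER-A")),
            batch=str(g.get("batch", "BATCH-1")),
            affected_rois=tuple(g.get("affected_rois", ())),
            k1_effect=float(g.get("k1_effect", 0.0)),
            retest=bool(g.get("retest", False)),
            blockade=bool(g.get("blockade", False)),
        )
        for g in raw["groups"]
    )
    eff = raw.get("covariate_effects", {})
    kwargs = {
        k: raw[k]
        for k in (
            "batch_scales", "noise_kappa", "k2", "vb_scale", "subject_k1_sd",
            "blockade_factor", "dose_mean_mbq",
        )
        if k in raw
    }
    if "tracers_without_genotype" in raw:
        kwargs["tracers_without_genotype"] = tuple(raw["tracers_without_genotype"])
    if "frame_start" in raw:
        kwargs["frame_start"] = tuple(raw["frame_start"])
        kwargs["frame_end"] = tuple(raw["frame_end"])
    if "if_params" in raw:
        kwargs["if_params"] = InputFunctionParams(**raw["if_params"])
    return CohortDesign(
        groups=groups,
        covariate_effects=CovariateEffects(**eff),
        **kwargs,
    )


def save_design(design: CohortDesign, path) -> None:
    """Serialize a design to YAML (inverse of :func:`load_design`)."""
    import yaml

    doc = {
        "groups": [
            {
                "name": g.name, "n": g.n, "tracer": g.tracer, "batch": g.batch,
                "affected_rois": list(g.affected_rois), "k1_effect": g.k1_effect,
                "retest": g.retest, "blockade": g.blockade,
            }
            for g in design.groups
        ],
        "batch_scales": dict(design.batch_scales),
        "covariate_effects": asdict(design.covariate_effects),
        "noise_kappa": design.noise_kappa,
        "k2": design.k2,
        "vb_scale": design.vb_scale,
        "subject_k1_sd": design.subject_k1_sd,
        "blockade_factor": design.blockade_factor,
        "tracers_without_genotype": list(design.tracers_without_genotype),
        "dose_mean_mbq": design.dose_mean_mbq,
        "if_params": asdict(design.if_params),
    }
    if design.frame_start:
        doc["frame_start"] = list(design.frame_start)
        doc["frame_end"] = list(design.frame_end)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
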
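"""End-to-end orchestration: phantom cohort → degradation → flap extraction
→ metrics → morphometry → reports and meshes.

A run is driven by a :class:`RunConfig` (YAML-serialisable, flat blocks for
the phantom, degradation and contour parameters).  Every seeded quantity is
derived from the single master seed, so two identical configurations yield
byte-identical tabular outputs.  Skipped slices and excluded patients are
logged with machine-parsable reason codes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as sm
from . import morphometry as mm
from .errors import PatientExcluded, ValidationError
from .flap import ContourParams, SliceRegions, extract_flap_volume
from .mesh import stack_to_mesh
from .phantom import DegradationSpec, PhantomResult, PhantomSpec, degrade_prediction, generate_phantom
from .volume_io import FALSE_LUMEN, FLAP, LabelVolume, TRUE_LUMEN, read_label_volume, write_label_volume

logger = logging.getLogger(__name__)

MODES = ("simulate", "evaluate", "quantify", "full")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "full"
    out_dir: str = "runs/out"
    seed: int = 0
    n_patients: int = 4
    hd_units: str = "mm"
    cv_folds: int = 4
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    phantom_jitter: dict = field(default_factory=dict)  # field -> [lo, hi]
    degradation: dict = field(default_factory=dict)  # DegradationSpec overrides
    contour: dict = field(default_factory=dict)  # ContourParams overrides
    slice_ranges: dict = field(default_factory=dict)  # patient -> [lo, hi]
    patients: list = field(default_factory=list)  # [{id, gt, pred}] file mode
    export_meshes: bool = True

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode in ("evaluate", "quantify") and self.patients:
            for p in self.patients:
                for key in ("gt", "pred"):
                    if key in p and not Path(p[key]).exists():
                        raise ValidationError(
                            f"patient {p.get('id')}: missing file {p[key]}"
                        )
        self.contour_params()  # raises on bad contour values

    def contour_params(self) -> ContourParams:
        return ContourParams(**self.contour)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path


#: default per-patient jitter ranges for cohort generation (mm / radians)
DEFAULT_JITTER = {
    "outer_diameter": [40.0, 55.0],
    "flap_thickness": [1.8, 3.0],
    "flap_offset": [4.0, 12.0],
    "flap_angle": [0.0, 3.1],
}


def generate_cohort(
    config: RunConfig,
) -> list[tuple[str, PhantomResult, LabelVolume]]:
    """Seeded cohort of phantom patients with degraded predictions."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients)
    jitter = {**DEFAULT_JITTER, **config.phantom_jitter}
    cohort = []
    for i, child in enumerate(children):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng(child)
        overrides = dict(config.phantom)
        for name, (lo, hi) in jitter.items():
            if name not in overrides:
                overrides[name] = float(rng.uniform(lo, hi))
        pseed = int(child.generate_state(1)[0] % (2**31))
        spec = PhantomSpec(seed=pseed, **overrides)
        result = generate_phantom(spec)
        deg = DegradationSpec(
            seed=pseed,
            **{
                "boundary_shift_mm": 0.9,
                "flip_fraction": 0.03,
                "dropout_slices": 0,
                **config.degradation,
            },
        )
        deg.validate(spec)
        pred = degrade_prediction(result.annotation, deg)
        cohort.append((pid, result, pred))
    return cohort


def _evaluate(
    pairs: list[tuple[str, LabelVolume, LabelVolume]], config: RunConfig, out: Path
) -> dict:
    per_patient = {}
    for pid, gt, pred in pairs:
        per_patient[pid] = sm.patient_metrics(gt, pred, hd_units=config.hd_units)
    frame = sm.metrics_frame(per_patient)
    frame = frame.sort_values(["patient_id", "label"]).reset_index(drop=True)
    metrics_csv = out / "metrics_per_patient.csv"
    frame.to_csv(metrics_csv, index=False)
    summary = sm.summarize_metrics(frame)
    summary_csv = out / "metrics_summary.csv"
    summary.to_csv(summary_csv, index=False)
    headline = {
        f"mean_dsc_{lbl.lower()}": float(
            frame.loc[frame["label"] == lbl, "dsc"].mean()
        )
        for lbl in ("TL", "FL")
    }
    return {
        "metrics_per_patient_csv": str(metrics_csv),
        "metrics_summary_csv": str(summary_csv),
        **headline,
    }


def _quantify_volume(
    volume: LabelVolume, pid: str, config: RunConfig, skip_log: list
) -> tuple[LabelVolume, list[mm.SliceMorphometry]]:
    params = config.contour_params()
    flap_vol = extract_flap_volume(volume, params, skip_log=skip_log)
    results = []
    for z in range(flap_vol.n_slices):
        sl = flap_vol.voxels[z]
        if not ((sl == TRUE_LUMEN).any() and (sl == FALSE_LUMEN).any() and (sl == FLAP).any()):
            continue
        regions = SliceRegions(
            tl_mask=sl == TRUE_LUMEN,
            fl_mask=sl == FALSE_LUMEN,
            flap_mask=sl == FLAP,
            aorta_mask=np.isin(sl, (TRUE_LUMEN, FALSE_LUMEN, FLAP)),
            in_plane_spacing=flap_vol.in_plane_spacing,
        )
        results.append(mm.slice_morphometry(regions, z=z))
    return flap_vol, results


def _quantify(
    pairs: list[tuple[str, LabelVolume, LabelVolume]], config: RunConfig, out: Path
) -> dict:
    slice_rows = []
    gt_patients, pred_patients = [], []
    vol_dir = out / "flap_volumes"
    vol_dir.mkdir(exist_ok=True)
    for pid, gt, pred in pairs:
        srange = config.slice_ranges.get(pid)
        srange = tuple(srange) if srange else None
        for role, volume, bucket in (
            ("gt", gt, gt_patients),
            ("pred", pred, pred_patients),
        ):
            skips: list = []
            flap_vol, slices = _quantify_volume(volume, pid, config, skips)
            write_label_volume(flap_vol, vol_dir / f"{pid}_{role}_flap.nii.gz")
            for s in slices:
                slice_rows.append(
                    {"patient_id": pid, "role": role, **dataclasses.asdict(s)}
                )
            for z, reason in skips:
                logger.warning("SKIP_SLICE patient=%s role=%s z=%d reason=%s", pid, role, z, reason)
            try:
                bucket.append(mm.patient_morphometry(slices, srange, patient_id=pid))
            except PatientExcluded as exc:
                logger.warning("EXCLUDE_PATIENT patient=%s role=%s: %s", pid, role, exc)
    slices_csv = out / "morphometry_per_slice.csv"
    pd.DataFrame(slice_rows).to_csv(slices_csv, index=False)
    patients_csv = out / "morphometry_per_patient.csv"
    both = mm.morphometry_frame(gt_patients).assign(role="gt")
    both = pd.concat(
        [both, mm.morphometry_frame(pred_patients).assign(role="pred")],
        ignore_index=True,
    )
    both.to_csv(patients_csv, index=False)
    # relative errors only over patients present in both roles
    gt_ids = {p.patient_id for p in gt_patients}
    pred_ids = {p.patient_id for p in pred_patients}
    common = gt_ids & pred_ids
    comparisons = mm.compare_morphometry(
        [p for p in gt_patients if p.patient_id in common],
        [p for p in pred_patients if p.patient_id in common],
    )
    comparison_csv = out / "morphometry_comparison.csv"
    mm.comparison_frame(comparisons).to_csv(comparison_csv, index=False)
    headline = {
        f"re_{c.field_name}_pct": 100.0 * c.mean_relative_error for c in comparisons
    }
    return {
        "morphometry_per_slice_csv": str(slices_csv),
        "morphometry_per_patient_csv": str(patients_csv),
        "morphometry_comparison_csv": str(comparison_csv),
        **headline,
    }


def _export_meshes(
    pairs: list[tuple[str, LabelVolume, LabelVolume]], out: Path
) -> list[str]:
    mesh_dir = out / "meshes"
    mesh_dir.mkdir(exist_ok=True)
    paths = []
    for pid, gt, _pred in pairs:
        for label, name in ((TRUE_LUMEN, "tl"), (FALSE_LUMEN, "fl")):
            mesh = stack_to_mesh(gt, label)
            paths.append(str(mesh.export(mesh_dir / f"{pid}_{name}.stl")))
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage chain; returns a machine-readable summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s")
    )
    root = logging.getLogger("aortamorph")
    root.addHandler(handler)
    try:
        config.to_yaml(out / "config_used.yaml")
        summary: dict = {"mode": config.mode, "out_dir": str(out)}
        if config.mode in ("simulate", "full"):
            cohort = generate_cohort(config)
            vol_dir = out / "volumes"
            vol_dir.mkdir(exist_ok=True)
            pairs = []
            for pid, result, pred in cohort:
                write_label_volume(result.annotation, vol_dir / f"{pid}_gt.nii.gz")
                write_label_volume(result.full_truth, vol_dir / f"{pid}_full.nii.gz")
                write_label_volume(pred, vol_dir / f"{pid}_pred.nii.gz")
                pairs.append((pid, result.annotation, pred))
            summary["volumes_dir"] = str(vol_dir)
            summary["n_patients"] = len(pairs)
        else:
            pairs = []
            for p in config.patients:
                gt = read_label_volume(p["gt"])
                pred = read_label_volume(p["pred"])
                if gt.shape != pred.shape:
                    raise ValidationError(
                        f"stage=load patient={p['id']}: gt shape {gt.shape} "
                        f"!= pred shape {pred.shape}"
                    )
                pairs.append((p["id"], gt, pred))
        if config.mode in ("evaluate", "full"):
            summary.update(_evaluate(pairs, config, out))
        if config.mode in ("quantify", "full"):
            summary.update(_quantify(pairs, config, out))
        if config.mode == "full" and config.export_meshes:
            summary["meshes"] = _export_meshes(pairs, out)
        logger.info("run complete: %s", summary)
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
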
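"""Study orchestration: run enumeration, seeding, manifests, pipeline stages.

The full study design is ``n_property_sets x |diameters| x 2 source
positions`` single transport runs (236 x 6 x 2 = 2832 at study defaults),
plus an optional ideal run with unperturbed properties.  Per-run seeds are
derived from a master seed with a counter-based hash and constrained to
(0, 2^31) exclusive, so the whole study is reproducible from one integer.

``run_pipeline`` drives simulate -> process -> calibrate -> evaluate
idempotently: every run directory carries a manifest (config hash, seed)
and a resumed pipeline skips completed runs, refusing to reuse outputs whose
manifest no longer matches the configuration unless forced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montecarlo import DetectedPhotons, MCConfig, SourceSpec, simulate, render_reflectance
from .presets import DIAMETER_GRID_UM, N_PROPERTY_SETS, StudyPreset, get_preset
from .properties import BasePropertySet, sample_property_set
from .signal import compute_knorm, compute_spdri, extract_profile
from .skin_model import build_tissue_volume
from .calibration import fit_knorm_regression, InvalidFitError
from .surrogate import SurrogateConfig, generate_calibration_dataset
from .evaluation import run_evaluation


@dataclass(frozen=True)
class RunSpec:
    run_index: int
    property_set_id: int      # -1 denotes the ideal (unperturbed) set
    diameter_um: float
    source_index: int         # 0 or 1
    seed: int


@dataclass(frozen=True)
class ExperimentPlan:
    """Enumeration parameters of one study."""

    scale_preset: str = "paper"                 # "paper" | "desk"
    n_property_sets: int = N_PROPERTY_SETS
    diameters_um: tuple[float, ...] = DIAMETER_GRID_UM
    n_source_positions: int = 2
    ideal_run: bool = False
    master_seed: int = 1
    n_photons: int | None = None                # None -> preset default

    @property
    def run_count(self) -> int:
        return (self.n_property_sets * len(self.diameters_um)
                * self.n_source_positions)

    def preset(self) -> StudyPreset:
        return get_preset(self.scale_preset)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentPlan":
        data = yaml.safe_load(Path(path).read_text())
        data["diameters_um"] = tuple(data["diameters_um"])
        return cls(**data)


def derive_seed(master_seed: int, run_index: int) -> int:
    """Counter-based per-run seed in (0, 2^31) exclusive."""
    state = np.random.SeedSequence([int(master_seed), int(run_index)])
    return int(state.generate_state(1)[0] % (2**31 - 2)) + 1


def enumerate_runs(plan: ExperimentPlan) -> list[RunSpec]:
    """Deterministic ordered run list (property set, diameter, source).

    The order is property-set-major, then diameter, then source position;
    the ideal run (unperturbed properties), when flagged, is appended for
    every diameter/source combination with ``property_set_id = -1``.
    """
    runs: list[RunSpec] = []
    idx = 0
    set_ids = list(range(plan.n_property_sets))
    if plan.ideal_run:
        set_ids.append(-1)
    for sid in set_ids:
        for d in plan.diameters_um:
            for s in range(plan.n_source_positions):
                runs.append(RunSpec(
                    run_index=idx, property_set_id=sid, diameter_um=float(d),
                    source_index=s, seed=derive_seed(plan.master_seed, idx),
                ))
                idx += 1
    return runs


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

STAGES = ("simulate", "process", "calibrate", "evaluate")


def _plan_hash(plan: ExperimentPlan) -> str:
    payload = json.dumps(asdict(plan), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_dir(out_dir: Path, run: RunSpec) -> Path:
    return out_dir / "runs" / (
        f"set{run.property_set_id:+04d}_d{run.diameter_um:04.1f}"
        f"_src{run.source_index}"
    )


class ManifestError(RuntimeError):
    pass


def _property_set_for(plan: ExperimentPlan, base: BasePropertySet, sid: int):
    if sid < 0:
        return sample_property_set(base, 0.0, 0.0, rng=0)
    return sample_property_set(
        base, rng=np.random.default_rng(
            np.random.SeedSequence([plan.master_seed, 10_000_019 + sid])
        ),
    )


def simulate_diameter_series(preset: StudyPreset | None = None,
                             pset=None,
                             n_photons: int | None = None,
                             seed: int = 1,
                             base: BasePropertySet | None = None,
                             ) -> pd.DataFrame:
    """K_norm versus capillary diameter from one shared photon set per source.

    Builds a volume whose capillary loops are labelled as nested diameter
    shells, runs one transport per source position, and re-renders the same
    detected photons for every diameter of the preset's grid by switching
    the shells inside the diameter to blood absorption (the capillary's
    optical contrast at 424 nm is dominated by the oxyhaemoglobin Soret
    band).  Photon noise is therefore fully correlated across diameters,
    which makes the diameter dependence of K_norm measurable at desk-scale
    photon counts.  Returns a frame with columns ``diameter_um``,
    ``capillary_id`` and ``k_norm``.
    """
    from .skin_model import build_shelled_volume, shell_mu_a_map

    preset = preset or get_preset("desk")
    base = base or BasePropertySet.default()
    if pset is None:
        pset = sample_property_set(base, 0.0, 0.0, rng=0)
    layers = preset.layers()
    layers = [replace(l, props=pset.media[l.name]) for l in layers]
    blood = pset.media["blood"]
    shell_props = pset.media["papillary_dermis"]
    geometries = [(d, preset.geometry(d)) for d in preset.diameters_um]
    volume = build_shelled_volume(geometries, layers, blood, shell_props)
    base_mua = np.array([m.mu_a for m in volume.media])

    detected = []
    for si, src in enumerate(preset.source_positions):
        config = MCConfig(
            n_photons=n_photons or preset.default_photons,
            seed=derive_seed(seed, si), boundary=preset.mc_boundary,
        )
        detected.append(simulate(volume, SourceSpec(center=src), config))

    ana = preset.analysis
    apparent = [y - ana.source_shift[1] / 2.0
                for y in ana.capillary_y_positions]
    rows = []
    for d in preset.diameters_um:
        mua = shell_mu_a_map(volume, d, blood.mu_a, shell_props.mu_a,
                             base_mua)
        img_a = render_reflectance(detected[0], mua)
        img_b = render_reflectance(detected[1], mua)
        spdri = compute_spdri(img_a, img_b, ana.source_shift,
                              smoothing_sigma=ana.smoothing_sigma)
        profile = extract_profile(spdri, ana.cross_section_x,
                                  savgol_order=ana.savgol_order,
                                  savgol_frame=ana.savgol_frame)
        knorm = compute_knorm(profile, apparent,
                              search_window=ana.search_window)
        for entry in knorm.entries:
            rows.append({"diameter_um": d,
                         "capillary_id": entry.capillary_id,
                         "k_norm": np.nan if entry.missing else entry.k_norm})
    return pd.DataFrame(rows)


def _dataset_from_mc(plan: ExperimentPlan, base: BasePropertySet,
                     out_dir: Path):
    """Assemble a CalibrationDataset from the transport-derived K_norm/betas."""
    from .properties import PREDICTOR_NAMES, reduce_predictors
    from .surrogate import CalibrationDataset, SURFACE_PREDICTORS

    betas = pd.read_csv(out_dir / "betas.csv")
    knorm = pd.read_csv(out_dir / "knorm.csv")
    per = (knorm.groupby(["property_set_id", "diameter_um"])["k_norm"]
           .mean().reset_index())
    rows = []
    for _, b in betas.iterrows():
        sid = int(b["property_set_id"])
        if sid < 0:
            continue
        pset = _property_set_for(plan, base, sid)
        row = {"set_id": sid}
        row.update(dict(zip(PREDICTOR_NAMES, reduce_predictors(pset))))
        row["beta0_true"] = b["beta0"]
        row["beta1_true"] = b["beta1"]
        sel = per[per["property_set_id"] == sid]
        for _, r in sel.iterrows():
            row[f"knorm_{r['diameter_um']:g}"] = r["k_norm"]
        row["beta1_nonpos"] = b["beta1"] <= 0
        rows.append(row)
    base_pred = reduce_predictors(sample_property_set(base, 0.0, 0.0, rng=0))
    cfg = SurrogateConfig(n_property_sets=len(rows),
                          diameters_um=plan.diameters_um,
                          seed=plan.master_seed)
    ix1 = PREDICTOR_NAMES.index(SURFACE_PREDICTORS[0])
    ix2 = PREDICTOR_NAMES.index(SURFACE_PREDICTORS[1])
    ideal = None
    ideal_rows = betas[betas["property_set_id"] < 0]
    if len(ideal_rows):
        ideal = (float(ideal_rows["beta0"].iloc[0]),
                 float(ideal_rows["beta1"].iloc[0]))
    return CalibrationDataset(frame=pd.DataFrame(rows),
                              diameters_um=plan.diameters_um,
                              config=cfg, base_x1=float(base_pred[ix1]),
                              base_x2=float(base_pred[ix2]),
                              ideal_beta_override=ideal)


def run_pipeline(plan: ExperimentPlan, out_dir,
                 stages: tuple[str, ...] = STAGES,
                 resume: bool = True, force: bool = False,
                 base: BasePropertySet | None = None,
                 eval_repeats: int = 30,
                 eval_seed: int | None = None) -> dict[str, Path]:
    """Execute the study stages under ``out_dir`` with per-run manifests.

    ``simulate`` runs the transport for every enumerated run and stores the
    detected-photon stream; ``process`` renders the image pairs, forms the
    SP-DRI ratio, and extracts per-capillary K_norm values; ``calibrate``
    fits the K_norm-vs-diameter line per property set; ``evaluate`` runs the
    repeated-split diameter-prediction study.  When fewer than 10 property
    sets carry fitted betas, the evaluation falls back to the surrogate
    calibration dataset generated from the plan's master seed (recorded in
    its manifest).
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base or BasePropertySet.default()
    preset = plan.preset()
    phash = _plan_hash(plan)
    runs = enumerate_runs(plan)
    results: dict[str, Path] = {}

    if "simulate" in stages:
        for run in runs:
            rdir = _run_dir(out_dir, run)
            manifest = rdir / "manifest.json"
            photons = rdir / "detected.h5"
            if manifest.exists():
                meta = json.loads(manifest.read_text())
                if meta.get("plan_hash") != phash and not force:
                    raise ManifestError(
                        f"{manifest} was produced under a different "
                        "configuration; rerun with force=True to overwrite"
                    )
                if resume and meta.get("plan_hash") == phash and photons.exists():
                    continue
            rdir.mkdir(parents=True, exist_ok=True)
            pset = _property_set_for(plan, base, run.property_set_id)
            geometry = preset.geometry(run.diameter_um)
            volume = build_tissue_volume(geometry, preset.layers(),
                                         pset.media["blood"])
            volume.media = tuple(pset.media_list())
            source = SourceSpec(
                center=preset.source_positions[run.source_index])
            config = MCConfig(
                n_photons=plan.n_photons or preset.default_photons,
                seed=run.seed, boundary=preset.mc_boundary,
            )
            detected = simulate(volume, source, config)
            detected.to_hdf5(photons)
            manifest.write_text(json.dumps({
                "plan_hash": phash, "run_index": run.run_index,
                "seed": run.seed, "property_set_id": run.property_set_id,
                "diameter_um": run.diameter_um,
                "source_index": run.source_index,
                "n_detected": len(detected),
            }, indent=1))
        results["runs"] = out_dir / "runs"

    if "process" in stages:
        ana = preset.analysis
        sy = ana.source_shift[1]
        apparent = [y - sy / 2.0 for y in ana.capillary_y_positions]
        rows = []
        pairs = {}
        for run in runs:
            key = (run.property_set_id, run.diameter_um)
            pairs.setdefault(key, {})[run.source_index] = run
        for (sid, diam), by_src in sorted(pairs.items()):
            if set(by_src) != {0, 1}:
                continue
            pset = _property_set_for(plan, base, sid)
            mua = np.array([m.mu_a for m in pset.media_list()])
            imgs = {}
            for s, run in by_src.items():
                det = DetectedPhotons.from_hdf5(
                    _run_dir(out_dir, run) / "detected.h5")
                imgs[s] = render_reflectance(det, mua)
            spdri = compute_spdri(imgs[0], imgs[1], ana.source_shift,
                                  smoothing_sigma=ana.smoothing_sigma)
            profile = extract_profile(spdri, ana.cross_section_x,
                                      savgol_order=ana.savgol_order,
                                      savgol_frame=ana.savgol_frame)
            knorm = compute_knorm(profile, apparent,
                                  search_window=ana.search_window)
            for entry in knorm.entries:
                rows.append({
                    "property_set_id": sid, "diameter_um": diam,
                    "capillary_id": entry.capillary_id,
                    "k_norm": np.nan if entry.missing else entry.k_norm,
                })
        knorm_csv = out_dir / "knorm.csv"
        pd.DataFrame(rows).to_csv(knorm_csv, index=False)
        results["knorm"] = knorm_csv

    if "calibrate" in stages:
        knorm_csv = out_dir / "knorm.csv"
        if not knorm_csv.exists():
            raise FileNotFoundError("run the process stage first")
        df = pd.read_csv(knorm_csv)
        fits = []
        for sid, grp in df.groupby("property_set_id"):
            per_diam = grp.groupby("diameter_um")["k_norm"].mean()
            try:
                fit = fit_knorm_regression(per_diam.items())
            except InvalidFitError:
                continue
            fits.append({"property_set_id": sid, "beta0": fit.beta0,
                         "beta1": fit.beta1, "r_squared": fit.r_squared,
                         "n_used": fit.n_used, "n_missing": fit.n_missing})
        betas_csv = out_dir / "betas.csv"
        pd.DataFrame(fits).to_csv(betas_csv, index=False)
        results["betas"] = betas_csv

    if "evaluate" in stages:
        betas_csv = out_dir / "betas.csv"
        n_beta_rows = 0
        if betas_csv.exists():
            n_beta_rows = len(pd.read_csv(betas_csv))
        if n_beta_rows >= 10:
            dataset = _dataset_from_mc(plan, base, out_dir)
            source = "monte_carlo"
        else:
            dataset = generate_calibration_dataset(
                SurrogateConfig(seed=plan.master_seed), base=base)
            source = "surrogate"
        table = run_evaluation(
            dataset, n_repeats=eval_repeats,
            rng=eval_seed if eval_seed is not None else plan.master_seed,
        )
        summary_csv = out_dir / "summary.csv"
        table.to_csv(summary_csv)
        (out_dir / "evaluation_manifest.json").write_text(json.dumps({
            "plan_hash": phash, "dataset_source": source,
            "n_mc_beta_rows": n_beta_rows, "repeats": eval_repeats,
            "overall_cv_percent": table.overall_cv_percent,
        }, indent=1))
        results["summary"] = summary_csv

    return results
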
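"""Configured, resumable pipeline: generate -> drain -> filter -> subsample
-> solve -> metrics -> fit.

A :class:`PipelineConfig` (typically loaded from YAML) fixes every seed
and size explicitly; rerunning an identical config reproduces identical
numeric outputs.  Stage artifacts are written under the output
directory, keyed by a hash of the configuration, and the expensive
generate/drain stage is reused when its artifacts already match the
config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phase_io import PhaseVolume, filter_noise, read_volume, write_volume
from .pore_metrics import metrics_series
from .rev_sampling import dyadic_series, extract_subsamples, manifest, resample_at_origins
from .stokes_cell import solve_conductivity
from .synthetic_geometry import (
    DrainageSchedule,
    SyntheticSpec,
    drainage_series,
    generate_clay_like,
    generate_sand_like,
)
from .wrc_vg import WRCPoint, convergence_stats, fit_vg

logger = logging.getLogger(__name__)

#: Porosity / crack presets for the bulk-vs-rhizosphere contrast: the
#: rhizosphere variants emulate densification (reduced macroporosity)
#: through a lower porosity target and fewer cracks; they are parameter
#: presets, not an asserted structural model of rhizosphere soil.
CONDITION_PRESETS = {
    "bulk_sand": {"texture": "sand_like", "target_porosity": 0.45},
    "rhizosphere_sand": {"texture": "sand_like", "target_porosity": 0.40},
    "bulk_clay": {"texture": "clay_like", "target_porosity": 0.45, "crack_count": 3},
    "rhizosphere_clay": {
        "texture": "clay_like",
        "target_porosity": 0.40,
        "crack_count": 2,
    },
}


@dataclass
class ConditionConfig:
    """One soil condition (texture preset plus overrides)."""

    name: str
    texture: str
    target_porosity: float
    crack_count: int = 3
    grain_radius_range: tuple[float, float] | None = None
    aggregate_radius_range: tuple[float, float] | None = None


@dataclass
class PipelineConfig:
    """Full pipeline configuration; all seeds explicit."""

    seed: int = 0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_um: float = 1.0
    conditions: list[ConditionConfig] = field(default_factory=list)
    potentials_kpa: tuple[float, ...] = (0.0, -5.0, -10.0, -20.0, -40.0, -60.0, -75.0)
    n_subsamples: int = 2
    subsample_side_voxels: int = 24
    j_max: int = 3
    directions: tuple[int, ...] = (0,)
    solver_tolerance: float = 1e-8
    solver_method: str = "auto"
    outdir: str = "rhizoflow_out"

    def __post_init__(self) -> None:
        if not self.conditions:
            self.conditions = [
                ConditionConfig(name=n, **p) for n, p in CONDITION_PRESETS.items()
            ]
        fixed = []
        for c in self.conditions:
            fixed.append(ConditionConfig(**c) if isinstance(c, dict) else c)
        self.conditions = fixed
        if self.seed is None:
            raise ValueError("seed must be explicit (no wall-clock seeding)")
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape components must be >= 16")
        if self.subsample_side_voxels > min(self.grid_shape):
            raise ValueError("subsample side exceeds grid")
        if not self.solver_tolerance > 0:
            raise ValueError("solver_tolerance must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "potentials_kpa", "directions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def canonical_json(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # where results land must not change them
        return json.dumps(d, sort_keys=True, default=str)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _generate(cond: ConditionConfig, cfg: PipelineConfig, seed: int) -> PhaseVolume:
    kwargs: dict = {
        "texture": cond.texture,
        "grid_shape": tuple(cfg.grid_shape),
        "voxel_size_um": cfg.voxel_size_um,
        "target_porosity": cond.target_porosity,
        "rng_seed": seed,
        "crack_count": cond.crack_count,
    }
    if cond.grain_radius_range:
        kwargs["grain_radius_range"] = tuple(cond.grain_radius_range)
    if cond.aggregate_radius_range:
        kwargs["aggregate_radius_range"] = tuple(cond.aggregate_radius_range)
    spec = SyntheticSpec(**kwargs)
    if cond.texture == "sand_like":
        return generate_sand_like(spec)
    return generate_clay_like(spec)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow and return the aggregated report.

    Per condition: generate a saturated synthetic volume, drain it over
    the potential schedule, apply the noise filter, tabulate pore
    metrics, solve REV conductivities (same subsample coordinates across
    potentials, dyadic levels at saturation for the convergence series),
    and fit the van Genuchten model to the resulting retention and
    conductivity curves.  Artifacts (TIFF volumes, CSV tables, JSON
    report) land in ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(json.loads(config.canonical_json()), sort_keys=True)
    )
    schedule = DrainageSchedule(potentials_kpa=tuple(config.potentials_kpa))
    report: dict = {"config_digest": digest, "conditions": {}}

    for idx, cond in enumerate(config.conditions):
        t0 = time.time()
        cond_dir = outdir / cond.name
        cond_dir.mkdir(exist_ok=True)
        seed = config.seed * 1009 + idx * 101

        volumes = _load_or_make_series(cond, config, schedule, seed, cond_dir, digest)
        volumes = [filter_noise(v) for v in volumes]

        metrics = metrics_series(volumes)
        metrics.to_csv(cond_dir / "pore_metrics.csv", index=False)

        # REV conductivity at fixed coordinates across potentials
        subs0 = extract_subsamples(
            volumes[0],
            config.n_subsamples,
            side_voxels=config.subsample_side_voxels,
            seed=seed + 7,
        )
        manifest(subs0).to_csv(cond_dir / "rev_manifest.csv", index=False)

        kh_series = []
        for vol in volumes:
            subs = resample_at_origins(vol, subs0)
            khs = []
            for s in subs:
                res = solve_conductivity(
                    s,
                    directions=config.directions,
                    tolerance=config.solver_tolerance,
                    method=config.solver_method,
                )
                khs.append(res.K_h_cm_s[config.directions[0]])
            kh_series.append(float(np.mean(khs)))

        # dyadic convergence series at saturation
        conv_results = []
        for s in subs0:
            for rev in dyadic_series(s, j_max=config.j_max):
                conv_results.append(
                    solve_conductivity(
                        rev,
                        directions=config.directions,
                        tolerance=config.solver_tolerance,
                        method=config.solver_method,
                    )
                )
        try:
            conv = convergence_stats(conv_results, axis=config.directions[0])
            conv.table.to_csv(cond_dir / "convergence.csv", index=False)
            conv_records = conv.table.to_dict(orient="records")
        except ValueError as exc:  # e.g. a single subsample: no SD
            conv_records = [{"error": str(exc)}]

        thetas = [v.water_fraction for v in volumes]
        wrc = [
            WRCPoint(p, th)
            for p, th in zip(config.potentials_kpa, thetas)
        ]
        kpts = [
            WRCPoint(p, th, k_cm_s=kh)
            for p, th, kh in zip(config.potentials_kpa, thetas, kh_series)
        ]
        wrc_df = pd.DataFrame(
            {
                "potential_kPa": config.potentials_kpa,
                "head_cm": [w.head_cm for w in wrc],
                "theta": thetas,
                "K_cm_s": kh_series,
            }
        )
        wrc_df.to_csv(cond_dir / "wrc.csv", index=False)

        fit_info: dict
        try:
            fit = fit_vg(wrc, kpts)
            fit_info = {
                "theta_s": fit.params.theta_s,
                "theta_r": fit.params.theta_r,
                "alpha_per_cm": fit.params.alpha_per_cm,
                "n": fit.params.n,
                "m": fit.params.m,
                "Ksat_cm_s": fit.params.ksat_cm_s,
                "cost": fit.cost,
            }
        except ValueError as exc:  # e.g. a barely-draining clay: flat data
            fit_info = {"error": str(exc)}
        with open(cond_dir / "van_genuchten.json", "w") as fh:
            json.dump(fit_info, fh, indent=2, sort_keys=True)
            fh.write("\n")

        report["conditions"][cond.name] = {
            "porosity": volumes[0].porosity,
            "theta": thetas,
            "K_h_cm_s": kh_series,
            "wfp_volume_percent_change": metrics.attrs["wfp_volume_percent_change"],
            "van_genuchten": fit_info,
            "convergence": conv_records,
        }
        logger.info("condition %s done in %.1fs", cond.name, time.time() - t0)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _load_or_make_series(
    cond: ConditionConfig,
    config: PipelineConfig,
    schedule: DrainageSchedule,
    seed: int,
    cond_dir: Path,
    digest: str,
) -> list[PhaseVolume]:
    """Drainage series for a condition, reusing cached volumes when the
    config hash matches."""
    paths = [
        cond_dir / f"phase_{abs(p):g}kPa.tif" for p in schedule.potentials_kpa
    ]
    if all(p.exists() for p in paths):
        try:
            vols = [read_volume(p) for p in paths]
            if all(
                isinstance(v, PhaseVolume) and v.meta.get("config_digest") == digest
                for v in vols
            ):
                logger.info("reusing cached volumes for %s", cond.name)
                return vols
        except (ValueError, OSError):  # stale or foreign cache: regenerate
            pass
    saturated = _generate(cond, config, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vols = drainage_series(saturated, schedule)
    for v, path in zip(vols, paths):
        v.meta["config_digest"] = digest
        write_volume(v, path)
    return vols
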
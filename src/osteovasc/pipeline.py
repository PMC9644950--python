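"""End-to-end orchestration: per-specimen image analysis and cross-specimen
growth/statistics, with deterministic provenance.

``run_specimen`` chains segmentation → morphometry → orientation on one
grayscale volume and returns (and optionally writes) the per-specimen
summary; ``run_cohort`` fits Gompertz growth curves per species/bone and
regresses the proportion outcomes (porosity, orientation indices) on age
and on radial growth rate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import growth as gr
from . import morphometry as mm
from . import orientation as ori
from . import segmentation as seg
from .errors import PipelineStageError
from .volumes import BinaryVolume, GrayscaleVolume, write_tiff

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one per-specimen run."""

    voxel_size: float = 2.0
    closing_radius: float = 8.0          # voxels; >= largest expected canal radius
    lacuna_threshold: float = 1000.0     # μm³ canal/lacuna boundary
    min_segment_length: float = 3.0      # voxels; spur filter for skeleton chords
    center_override: tuple[float, float] | None = None   # (x, y) μm
    midshaft_radius_mm: float | None = None              # calliper r2; enables I
    thickness_step: float | None = None  # voxels; local-thickness radius step
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or self.closing_radius <= 0:
            raise ValueError("voxel_size and closing_radius must be positive")
        if self.lacuna_threshold < 0 or self.min_segment_length < 0:
            raise ValueError("thresholds must be non-negative")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["center_override"] = list(self.center_override) if self.center_override else None
        return d

    def manifest(self) -> dict:
        payload = json.dumps(self.as_dict(), sort_keys=True)
        return {
            "config": self.as_dict(),
            "config_hash": hashlib.sha256(payload.encode()).hexdigest(),
            "package_version": __version__,
            "coordinate_convention": "0-based voxels; world (x,y,z) um from the volume corner; z = stack axis = bone long axis",
        }


@dataclass
class SpecimenResult:
    summary: mm.MorphometrySummary
    indices: ori.OrientationIndices
    segments: list[ori.CanalSegment]
    threshold: float
    frame: ori.BoneFrame
    canal_mask: BinaryVolume
    lacuna_mask: BinaryVolume
    cortex_mask: BinaryVolume
    pore_table: pd.DataFrame

    def segment_table(self) -> pd.DataFrame:
        s = self.segments
        return pd.DataFrame(
            {
                "segment_id": np.arange(len(s)),
                "x0_um": [t.endpoints[0, 0] for t in s],
                "y0_um": [t.endpoints[0, 1] for t in s],
                "z0_um": [t.endpoints[0, 2] for t in s],
                "x1_um": [t.endpoints[1, 0] for t in s],
                "y1_um": [t.endpoints[1, 1] for t in s],
                "z1_um": [t.endpoints[1, 2] for t in s],
                "chord_length_um": [t.chord_length for t in s],
                "path_length_um": [t.path_length for t in s],
                "theta_long_deg": [t.theta_long for t in s],
                "theta_rad_deg": [t.theta_rad for t in s],
                "category": [t.category for t in s],
            }
        )


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_specimen(
    volume: GrayscaleVolume,
    config: RunConfig,
    exclusion: BinaryVolume | None = None,
) -> SpecimenResult:
    """Segment one grayscale cortex volume, measure it, and orient its canal
    network.  Identical inputs and config produce identical outputs; if
    ``config.output_dir`` is set, masks, tables and the manifest are written
    there (partial artefacts are retained on stage failure)."""
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "manifest.json").write_text(json.dumps(config.manifest(), indent=2, sort_keys=True))

    with _stage("segmentation"):
        mineralised = seg.threshold_min_cross_entropy(volume)
        threshold = mineralised.threshold
        cortex = seg.close_cortex(mineralised, config.closing_radius)
        pores = seg.extract_pores(cortex, mineralised, exclusion)
        canals, lacunae, pore_table = seg.partition_pores(pores, config.lacuna_threshold)
    if outdir:
        write_tiff(outdir / "cortex_mask.tif", cortex)
        write_tiff(outdir / "canal_mask.tif", canals)
        write_tiff(outdir / "lacuna_mask.tif", lacunae)
        pore_table.to_csv(outdir / "pore_components.csv", index=False)

    with _stage("morphometry"):
        phi = mm.porosity(canals, cortex)
        canal_th = mm.local_thickness_mean(canals, step_voxels=config.thickness_step) if canals.count() else float("nan")
        cort_th = mm.cortical_thickness(cortex, step_voxels=config.thickness_step)
        r2 = config.midshaft_radius_mm
        I = mm.second_moment_of_area(r2, cort_th / 1000.0) if r2 is not None else None
        summary = mm.MorphometrySummary(
            porosity=phi,
            mean_canal_thickness_um=canal_th,
            mean_cortical_thickness_um=cort_th,
            midshaft_radius_mm=r2,
            second_moment_mm4=I,
        )

    with _stage("orientation"):
        if config.center_override is not None:
            frame = ori.BoneFrame(center=tuple(config.center_override))
        else:
            frame = ori.estimate_center(cortex)
        skel = ori.skeletonize(canals)
        segments = ori.extract_segments(
            skel, frame, min_length=config.min_segment_length * volume.voxel_size)
        indices = ori.orientation_indices(segments)

    result = SpecimenResult(
        summary=summary, indices=indices, segments=segments, threshold=threshold,
        frame=frame, canal_mask=canals, lacuna_mask=lacunae, cortex_mask=cortex,
        pore_table=pore_table,
    )
    if outdir:
        result.segment_table().to_csv(outdir / "segments.csv", index=False)
        row = {**summary.as_dict(), **indices.as_dict(), "threshold": threshold,
               "center_x_um": frame.center[0], "center_y_um": frame.center[1]}
        pd.DataFrame([row]).to_csv(outdir / "summary.csv", index=False)
        run_log = {"threshold": threshold, **config.manifest()}
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return result


# --------------------------------------------------------------------------
# cohort statistics
# --------------------------------------------------------------------------

INDEX_COLUMNS = ("laminar_index", "longitudinal_index", "radial_index", "oblique_index")

AGE_CLASS_BOUNDS_DAYS = {"juvenile": 42.0, "sub_adult": 182.5}


def age_class(age_days: float) -> str:
    """Juvenile (≤ 42 d), sub-adult (≤ 6 months), adult (older)."""
    if age_days <= AGE_CLASS_BOUNDS_DAYS["juvenile"]:
        return "juvenile"
    if age_days <= AGE_CLASS_BOUNDS_DAYS["sub_adult"]:
        return "sub_adult"
    return "adult"


@dataclass
class CohortResult:
    growth: pd.DataFrame         # per species/bone/measure Gompertz parameters
    regressions: pd.DataFrame    # beta regressions of proportions
    correlations: pd.DataFrame   # Pearson r for unbounded responses
    fits: dict = field(default_factory=dict)
    n_tests: int = 0


def run_cohort(table: pd.DataFrame, min_specimens: int = 4) -> CohortResult:
    """Cross-specimen analyses over a tidy per-specimen table.

    Expected columns: ``species, bone, age_days`` plus any of
    ``bone_length_mm, midshaft_diameter_mm, porosity`` and the four
    orientation-index columns.  Per species/bone: Gompertz fits of length
    and diameter against age (skipped with a warning when there are fewer
    than ``min_specimens`` distinct ages); beta regressions of each
    proportion on age and, when a diameter curve exists, on the radial
    growth rate at each specimen's age; Pearson correlations for unbounded
    responses.  Raw p-values are reported; the number of tests run is
    recorded instead of a multiplicity correction.
    """
    growth_rows, reg_rows, cor_rows = [], [], []
    fits: dict = {}
    n_tests = 0
    for (species, bone), g in table.groupby(["species", "bone"], sort=True):
        ages = g["age_days"].to_numpy(dtype=float)
        for measure, col in (("length", "bone_length_mm"), ("diameter", "midshaft_diameter_mm")):
            if col not in g or g[col].isna().all():
                continue
            sel = ~g[col].isna()
            t, y = ages[sel], g.loc[sel, col].to_numpy(dtype=float)
            if len(np.unique(t)) < max(min_specimens, 4):
                warnings.warn(f"{species}/{bone}/{measure}: too few distinct ages, Gompertz fit skipped")
                continue
            # radial growth uses the radius curve: diameter/2
            yy = y / 2.0 if measure == "diameter" else y
            try:
                fit = gr.fit_gompertz(t, yy)
            except Exception as err:
                warnings.warn(f"{species}/{bone}/{measure}: Gompertz fit failed ({err})")
                continue
            fits[(species, bone, measure)] = fit
            growth_rows.append({
                "species": species, "bone": bone, "measure": measure,
                "A": fit.A, "b": fit.b, "k": fit.k,
                "t_infl_days": fit.t_infl, "max_rate_mm_per_day": fit.max_rate,
                "n": fit.n,
            })

        dia_fit = fits.get((species, bone, "diameter"))
        covariates = {"age_days": ages}
        if dia_fit is not None:
            covariates["radial_growth_rate"] = np.asarray(dia_fit.rate(ages))
        for resp in ("porosity", *INDEX_COLUMNS):
            if resp not in g or g[resp].isna().all():
                continue
            sel = ~g[resp].isna()
            y = g.loc[sel, resp].to_numpy(dtype=float)
            if len(y) < min_specimens or np.ptp(y) == 0:
                continue
            for cov_name, cov in covariates.items():
                x = cov[np.asarray(sel)]
                if np.ptp(x) == 0:
                    continue
                X_full = np.column_stack([np.ones_like(x), x])
                X_null = np.ones((len(x), 1))
                try:
                    full = gr.fit_beta_regression(y, X_full)
                    null = gr.fit_beta_regression(y, X_null)
                    lrt = gr.lr_test(full, null)
                except Exception as err:
                    warnings.warn(f"{species}/{bone}/{resp}~{cov_name}: beta regression failed ({err})")
                    continue
                n_tests += 1
                reg_rows.append({
                    "species": species, "bone": bone, "response": resp,
                    "covariate": cov_name, "slope": full.beta[1],
                    "pseudo_r2": full.pseudo_r2, "lr_statistic": lrt.statistic,
                    "p_value": lrt.pvalue, "n": full.nobs,
                })
        for resp in ("mean_canal_thickness_um", "cortical_thickness_um", "midshaft_diameter_mm"):
            if resp not in g or g[resp].isna().all():
                continue
            sel = ~g[resp].isna()
            y = g.loc[sel, resp].to_numpy(dtype=float)
            for cov_name, cov in covariates.items():
                x = cov[np.asarray(sel)]
                if len(y) < 3 or np.std(y) == 0 or np.std(x) == 0:
                    continue
                r, p = gr.pearson_r(x, y)
                n_tests += 1
                cor_rows.append({
                    "species": species, "bone": bone, "response": resp,
                    "covariate": cov_name, "pearson_r": r, "p_value": p, "n": len(y),
                })
    log.info("cohort analysis ran %d hypothesis tests; p-values are reported raw "
             "(no multiple-comparison correction)", n_tests)
    return CohortResult(
        growth=pd.DataFrame(growth_rows),
        regressions=pd.DataFrame(reg_rows),
        correlations=pd.DataFrame(cor_rows),
        fits=fits,
        n_tests=n_tests,
    )
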
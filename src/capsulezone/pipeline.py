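"""End-to-end orchestration: synth → score → zonate → portal → survive.

A run is described by a :class:`RunConfig`; every stage writes plain CSV/JSON
outputs into the run directory and the run ends with a manifest recording the
package version, the seed, a hash of the configuration and the SHA-256 of
every output file, so a run is reproducible and byte-auditable.  Scoring
stages only ever see geometry — treatment and outcome columns are introduced
only in the survival stage, mirroring scoring blinded to clinical outcome.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import capsulezone
from capsulezone.errors import CapsulezoneError, ValidationError
from capsulezone.growth_patterns import aggregate, assign_strata, score_slide
from capsulezone.outcomes import build_survival_report
from capsulezone.portal_tracts import compare_pt_subtypes, measure_pins, pt_density
from capsulezone.synthetic_cohort import (
    GeneratorConfig,
    generate_geometry,
    generate_intensities,
    generate_pins,
)
from capsulezone.zonation import EXPANSION_UM, bin_and_average

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    modality: str = "ihc"  # ihc/if → 1500 µm PLP expansion, ish → 1000 µm
    n_zonation_cases: int = 3
    tumor_radius_um: float = 800.0
    # the portal-tract analysis runs on a large, thick-rimmed fully
    # encapsulated case, mirroring its restriction to >95%-encapsulated lesions
    pt_tumor_radius_um: float = 3000.0
    pt_rim_range_um: tuple[float, float] = (800.0, 1200.0)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if self.modality not in EXPANSION_UM:
            raise ValidationError(f"unknown modality {self.modality!r}")

    @property
    def expansion_um(self) -> float:
        return EXPANSION_UM[self.modality]

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-cohort analysis and write the report bundle.

    Stages: cohort + slide synthesis; growth-pattern scoring with strata;
    zonation profiling on a small case series; portal-tract measurement and
    subtype comparison; survival report.  Returns the manifest (also written
    as ``manifest.json``).  Any stage failure removes partial outputs and
    re-raises with a stage tag.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "init"
    t0 = time.perf_counter()
    try:
        from capsulezone.synthetic_cohort import generate_cohort

        # --- synth: cohort and one slide per patient ------------------------
        stage = "synth"
        gen = dataclasses.replace(
            config.generator, seed=config.seed, tumor_radius_um=config.tumor_radius_um
        )
        cohort, slides = generate_cohort(gen, with_slides=True)
        logger.info("synth: %d patients, %d slides", len(cohort), len(slides))

        # --- score: geometry only (blinded to outcome columns) --------------
        stage = "score"
        rows = []
        per_patient: dict[str, list] = {}
        for slide in slides:
            fractions = score_slide(slide.annotation_set)
            per_patient.setdefault(slide.annotation_set.patient_id, []).append(fractions)
            strata = assign_strata(fractions)
            rows.append({
                "unit_id": fractions.unit_id, "level": "slide",
                "pct_encapsulated": fractions.percent_encapsulated,
                "pct_replacement": fractions.percent_replacement,
                "pct_pushing": fractions.percent_pushing,
                "predominant": fractions.predominant,
                "stratum_enc": strata.encapsulation_stratum,
                "stratum_repl": strata.replacement_stratum,
                "total_length_um": fractions.total_interface_length,
            })
        for patient_id, units in sorted(per_patient.items()):
            pooled = aggregate(units, unit_id=patient_id)
            strata = assign_strata(pooled)
            rows.append({
                "unit_id": patient_id, "level": "patient",
                "pct_encapsulated": pooled.percent_encapsulated,
                "pct_replacement": pooled.percent_replacement,
                "pct_pushing": pooled.percent_pushing,
                "predominant": pooled.predominant,
                "stratum_enc": strata.encapsulation_stratum,
                "stratum_repl": strata.replacement_stratum,
                "total_length_um": pooled.total_interface_length,
            })
        fractions_path = out / "fractions.csv"
        pd.DataFrame(rows).to_csv(fractions_path, index=False)
        written.append(fractions_path)

        # --- zonate: small fully-encapsulated case series -------------------
        stage = "zonate"
        tiles_per_case = {}
        for k in range(config.n_zonation_cases):
            case = generate_geometry(
                seed=config.seed * 1000 + k,
                target_fractions={"encapsulated": 100.0},
                slide_id=f"zonation_{k}",
                tumor_radius_um=config.tumor_radius_um,
            )
            tiles_per_case[f"zonation_{k}"] = generate_intensities(
                case, seed=config.seed * 1000 + k, expansion_um=config.expansion_um
            )
        profiles = bin_and_average(tiles_per_case, markers=["NGFR", "ASMA", "FAP"])
        profile_path = out / "profile.csv"
        pd.concat([p.to_frame() for p in profiles.values()]).to_csv(profile_path, index=False)
        written.append(profile_path)

        # --- portal: pins on the first zonation case -------------------------
        stage = "portal"
        pt_slide = generate_geometry(
            seed=config.seed * 1000, target_fractions={"encapsulated": 100.0},
            slide_id="pt_case", tumor_radius_um=config.pt_tumor_radius_um,
            rim_thickness_range_um=config.pt_rim_range_um,
        )
        pins = generate_pins(
            pt_slide, density_per_mm2=gen.pins_per_mm2,
            subtype_slope=gen.subtype_slope, seed=config.seed * 1000,
        )
        borders = pt_slide.annotation_set.interface_border_polylines
        measurements = measure_pins(
            pins, borders["liver_rim_interface"], borders["rim_tumor_interface"]
        ) if pins else []
        pt_rows = [{
            "slide_id": m.pin.slide_id, "subtype": m.pin.subtype,
            "d_liver_um": m.d_liver, "d_tumor_um": m.d_tumor,
            "relative_distance": m.relative_distance,
        } for m in measurements]
        pt_path = out / "pt_stats.csv"
        pd.DataFrame(pt_rows).to_csv(pt_path, index=False)
        written.append(pt_path)
        pt_summary = {
            "density_per_mm2": pt_density(pins, pt_slide.rim_polygon) if pins else 0.0,
            **(compare_pt_subtypes(measurements) if measurements else {}),
        }
        pt_summary_path = out / "pt_summary.json"
        pt_summary_path.write_text(json.dumps(pt_summary, indent=2, sort_keys=True))
        written.append(pt_summary_path)

        # --- survive ---------------------------------------------------------
        stage = "survive"
        report = build_survival_report(cohort, endpoint="os")
        surv_rows = []
        for label in ("cox_univariate_strata", "cox_continuous", "cox_multivariate"):
            fit = report[label]
            if fit is None:
                continue
            s = fit.summary().reset_index(names="covariate")
            s.insert(0, "model", label)
            surv_rows.append(s)
        cox_path = out / "cox_forest.csv"
        pd.concat(surv_rows).to_csv(cox_path, index=False)
        written.append(cox_path)
        tests_path = out / "survival_tests.json"
        tests_path.write_text(json.dumps({
            "logrank_stratum": report["logrank_stratum"],
            "logrank_sex": report["logrank_sex"],
        }, indent=2, sort_keys=True))
        written.append(tests_path)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        written.append(cohort_path)

        # --- manifest ---------------------------------------------------------
        stage = "manifest"
        manifest = {
            "package_version": capsulezone.__version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "outputs": {p.name: _sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline complete in %.1f s", time.perf_counter() - t0)
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise CapsulezoneError(f"pipeline stage {stage!r} failed: {exc}") from exc
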
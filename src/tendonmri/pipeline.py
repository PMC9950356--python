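"""End-to-end studies on synthetic cohorts.

Four studies mirror the method-comparison questions the package exists
for:

* **standardisation** — which of the four SI formulas tracks histological
  lesion severity (blue-pixel percentage) best, at n = 23 paired samples;
* **roi comparison** — how well the largest inscribed circle and the
  1 mm² central circle reproduce the whole-lesion SI (Eq-3 standardised);
* **csa study** — whether CSA read at a fixed level or at each
  examination's own maximum level better represents lesion volume over a
  follow-up with a drifting maximum level;
* **automation study** — agreement of the locally adaptive automated
  segmentation with ground-truth ("manual") detection, CSA and SI, per
  MRI-sequence noise profile.

"Manual" measurements in all synthetic studies are ground-truth-mask
measurements: the generator stands in for the examiner.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import ImageGeometry, ImageSlice, RoiMask, SEQUENCE_LABELS
from .errors import InputError
from .histology import quantify_histology
from .io import save_results
from .lesion_geometry import records_from_masks, summarise_timepoint
from .roi import (
    FORMULA_IDS,
    central_small_roi,
    largest_inscribed_circle,
    measure_si,
    place_reference_rois,
    pool_background,
    rasterise_circle,
    standardise_si,
)
from .segmentation import AdaptiveSegParams, automated_measurement
from .stats import compare_methods, percent_agreement, spearman
from .synthetic import (
    GroundTruth,
    LesionPhantomParams,
    child_seeds,
    generate_histology,
    generate_stack,
    generate_timecourse,
)

logger = logging.getLogger("tendonmri")


@dataclass
class PipelineConfig:
    """Single source of truth for every study parameter."""

    geometry: ImageGeometry = field(default_factory=ImageGeometry)
    seg_params: AdaptiveSegParams = field(default_factory=AdaptiveSegParams)
    seed: int = 0
    n_levels: int = 12
    noise_sd: float = 8.0
    # standardisation study (paired MRI + histology)
    n_histology_samples: int = 23
    histology_coupling: float = 0.7
    histology_intercept: float = 0.15
    histology_noise: float = 0.05
    # ROI comparison
    n_roi_images: int = 60
    # CSA / volume study
    n_subjects: int = 6
    n_timepoints: int = 10
    shrink_rate: float = 0.85
    max_drift: int = 2
    # automation study
    n_auto_subjects: int = 8
    sequences: tuple = SEQUENCE_LABELS
    min_snr: float = 2.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sequences"] = list(self.sequences)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = ImageGeometry(**d["geometry"])
        if "seg_params" in d and isinstance(d["seg_params"], dict):
            d["seg_params"] = AdaptiveSegParams(**d["seg_params"])
        if "sequences" in d:
            d["sequences"] = tuple(d["sequences"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class StudyResult:
    """Per-sample rows plus the comparison-statistics summary of one study."""

    samples: pd.DataFrame
    summary: pd.DataFrame


def _standardised_si_values(
    slice_: ImageSlice,
    truth: GroundTruth,
    level: int,
    geometry: ImageGeometry,
) -> dict[str, float]:
    """All four standardised-SI values for one lesion-bearing slice.

    The healthy-tendon (SDFT) SI is measured on the SDFT mask with the
    lesion pixels excluded; the background reference pools the three
    background ROIs (mean of means; pooled SD).
    """
    lesion_mask = truth.lesion_masks[level]
    if lesion_mask.is_empty:
        raise InputError(f"no lesion at level {level}")
    healthy = RoiMask(truth.sdft_masks[level].mask & ~lesion_mask.mask, role="sdft")
    refs = place_reference_rois(
        slice_, truth.bone_roi_centre_mm, truth.limb_mask, geometry
    )
    bone = measure_si(slice_, refs[0])
    background = pool_background([measure_si(slice_, r) for r in refs[1:]])
    lesion = measure_si(slice_, lesion_mask)
    sdft = measure_si(slice_, healthy)
    ref_for = {
        "SDNR_background": background, "REL_background": background,
        "SDNR_cortical": bone, "REL_cortical": bone,
    }
    return {
        fid: standardise_si(lesion, sdft, ref_for[fid], fid).value
        for fid in FORMULA_IDS
    }


def run_standardisation_study(config: PipelineConfig) -> StudyResult:
    """Four SI formulas vs histological blue-pixel percentage, n paired samples.

    Each sample is one subject's peak-lesion slice plus a trichrome-like
    section whose blue fraction is coupled to the phantom severity
    (blue_fraction = intercept + coupling·severity + noise, clipped to
    [0, 1]); the coupling direction and strength are configuration, not an
    assumption of the analysis.
    """
    n = config.n_histology_samples
    rng = np.random.default_rng(config.seed)
    seeds = child_seeds(config.seed + 1, 2 * n)
    rows = []
    for i in range(n):
        severity = float(rng.uniform(0.1, 0.95))
        params = LesionPhantomParams(
            severity=severity, noise_sd=config.noise_sd, seed=seeds[2 * i]
        )
        stack, truth = generate_stack(
            params, config.geometry, n_levels=config.n_levels,
            subject_id=f"subject_{i:02d}",
        )
        level = int(np.argmax(truth.true_csa_per_level))
        values = _standardised_si_values(
            stack.slices[level], truth, level, config.geometry
        )
        blue_fraction = float(np.clip(
            config.histology_intercept
            + config.histology_coupling * severity
            + rng.normal(0.0, config.histology_noise),
            0.0, 1.0,
        ))
        image, _ = generate_histology(blue_fraction, seed=seeds[2 * i + 1])
        histo = quantify_histology(image)
        rows.append({
            "subject_id": f"subject_{i:02d}", "severity": severity,
            "blue_percent": histo.blue_percent, **values,
        })
    samples = pd.DataFrame(rows)
    summary_rows = []
    for fid in FORMULA_IDS:
        r, p = spearman(samples[fid], samples["blue_percent"])
        summary_rows.append({"formula_id": fid, "spearman_r": r, "p_value": p, "n": n})
    return StudyResult(samples, pd.DataFrame(summary_rows))


def run_roi_comparison(config: PipelineConfig) -> StudyResult:
    """Circle-ROI vs whole-lesion SI (all Eq-3 standardised)."""
    n = config.n_roi_images
    rng = np.random.default_rng(config.seed + 10)
    seeds = child_seeds(config.seed + 11, n)
    rows = []
    for i in range(n):
        params = LesionPhantomParams(
            severity=float(rng.uniform(0.2, 0.95)),
            max_csa_mm2=float(rng.uniform(12.0, 60.0)),
            max_level_index=1, n_lesion_levels=1,
            noise_sd=config.noise_sd, seed=seeds[i],
        )
        stack, truth = generate_stack(
            params, config.geometry, n_levels=3, subject_id=f"image_{i:03d}"
        )
        slice_ = stack.slices[1]
        lesion_mask = truth.lesion_masks[1]
        refs = place_reference_rois(
            slice_, truth.bone_roi_centre_mm, truth.limb_mask, config.geometry
        )
        background = pool_background([measure_si(slice_, r) for r in refs[1:]])

        big = largest_inscribed_circle(lesion_mask, config.geometry)
        big_mask = rasterise_circle(
            big, config.geometry, role="lesion_circle_max", clip_to=lesion_mask
        )
        small = central_small_roi(lesion_mask, config.geometry)
        small_mask = rasterise_circle(
            small, config.geometry, role="lesion_circle_1mm2", clip_to=lesion_mask
        )
        values = {}
        for name, mask in (
            ("whole", lesion_mask), ("circle_max", big_mask),
            ("circle_1mm2", small_mask),
        ):
            si = measure_si(slice_, mask)
            values[name] = standardise_si(si, None, background, "REL_background").value
        rows.append({"subject_id": f"image_{i:03d}", "severity": params.severity,
                     "csa_mm2": truth.true_csa_per_level[1], **values})
    samples = pd.DataFrame(rows)
    summary_rows = []
    for roi_type in ("circle_max", "circle_1mm2"):
        res = compare_methods(samples[roi_type], samples["whole"])
        summary_rows.append({
            "roi_type": roi_type, "n": res.n,
            "spearman_r": res.spearman_r, "p_value": res.p_value,
            "mean_ratio": res.mean_ratio,
            "loa_lower": res.loa_lower, "loa_upper": res.loa_upper,
        })
    return StudyResult(samples, pd.DataFrame(summary_rows))


def run_csa_study(config: PipelineConfig) -> StudyResult:
    """CSA-fixed and CSA-maximum vs lesion volume over drifting follow-ups."""
    rng = np.random.default_rng(config.seed + 20)
    seeds = child_seeds(config.seed + 21, config.n_subjects)
    rows = []
    for s in range(config.n_subjects):
        drift = [0]
        for _ in range(config.n_timepoints - 1):
            step = int(rng.integers(-1, 2))
            drift.append(int(np.clip(drift[-1] + step, -config.max_drift,
                                     config.max_drift)))
        base = LesionPhantomParams(
            severity=float(rng.uniform(0.4, 0.95)),
            max_csa_mm2=float(rng.uniform(25.0, 50.0)),
            noise_sd=config.noise_sd, seed=seeds[s],
        )
        series = generate_timecourse(
            base, config.n_timepoints, config.shrink_rate, drift,
            config.geometry, n_levels=config.n_levels,
            subject_id=f"subject_{s}",
        )
        fixed_level: int | None = None
        for t, (stack, truth) in enumerate(series):
            records = records_from_masks(
                truth.lesion_masks, stack.level_indices, config.geometry
            )
            summary = summarise_timepoint(
                records, fixed_level, config.geometry, time_point=t + 1
            )
            if fixed_level is None and summary.max_level_index is not None:
                fixed_level = summary.max_level_index
            rows.append({
                "subject_id": f"subject_{s}", "time_point": t + 1,
                "csa_fixed_mm2": summary.csa_fixed_mm2,
                "csa_max_mm2": summary.csa_max_mm2,
                "max_level_index": summary.max_level_index,
                "volume_mm3": summary.volume_mm3,
                "level_shift_mm": summary.level_shift_mm,
            })
    samples = pd.DataFrame(rows)
    present = samples[samples["volume_mm3"] > 0]
    summary_rows = []
    for variant in ("csa_max_mm2", "csa_fixed_mm2"):
        r, p = spearman(present[variant], present["volume_mm3"])
        summary_rows.append({
            "csa_variant": variant, "spearman_r": r, "p_value": p,
            "n": len(present),
        })
    return StudyResult(samples, pd.DataFrame(summary_rows))


def _background_sd_estimate(slice_: ImageSlice, limb_mask: RoiMask) -> float:
    corner = slice_.pixels[:24, :24]
    if limb_mask.mask[:24, :24].any():
        corner = slice_.pixels[~limb_mask.mask]
    return float(corner.std(ddof=0))


def run_automation_study(config: PipelineConfig) -> StudyResult:
    """Automated vs ground-truth detection, CSA and SI per sequence profile.

    Slices whose SDFT-to-background-noise SNR falls below ``min_snr`` are
    excluded from the measurement comparison (and logged), mirroring a
    quality gate an examiner would apply; detection agreement uses every
    slice.
    """
    rng = np.random.default_rng(config.seed + 30)
    samples_rows = []
    for seq_index, seq in enumerate(config.sequences):
        seeds = child_seeds(config.seed + 31 + seq_index, config.n_auto_subjects)
        for s in range(config.n_auto_subjects):
            severity = 0.15 + 0.8 * s / max(config.n_auto_subjects - 1, 1)
            params = LesionPhantomParams(
                severity=severity,
                max_csa_mm2=float(rng.uniform(18.0, 45.0)),
                noise_sd=config.noise_sd, seed=seeds[s],
            )
            stack, truth = generate_stack(
                params, config.geometry, n_levels=config.n_levels,
                sequence_label=seq, subject_id=f"{seq}_{s}",
            )
            for k, slice_ in enumerate(stack.slices):
                truth_mask = truth.lesion_masks[k]
                manual_present = not truth_mask.is_empty
                record = automated_measurement(
                    slice_, truth.sdft_masks[k], config.seg_params, config.geometry
                )
                auto_present = record.csa_mm2 > 0
                noise_est = _background_sd_estimate(slice_, truth.limb_mask)
                snr = (measure_si(slice_, truth.sdft_masks[k]).mean_si
                       / max(noise_est, 1e-9))
                row = {
                    "subject_id": f"{seq}_{s}", "sequence_label": seq,
                    "level_index": slice_.level_index, "severity": severity,
                    "manual_present": manual_present, "auto_present": auto_present,
                    "snr": snr, "quality_ok": snr >= config.min_snr,
                    "manual_csa_mm2": truth_mask.area_mm2(config.geometry),
                    "auto_csa_mm2": record.csa_mm2,
                }
                if manual_present:
                    row["manual_si"] = measure_si(slice_, truth_mask).mean_si
                if record.si is not None:
                    row["auto_si"] = record.si.mean_si
                samples_rows.append(row)
    samples = pd.DataFrame(samples_rows)
    n_excluded = int((~samples["quality_ok"]).sum())
    if n_excluded:
        logger.info("automation study: %d slices excluded by the SNR gate",
                    n_excluded)

    summary_rows = []
    groups = [(seq, samples[samples["sequence_label"] == seq])
              for seq in config.sequences]
    groups.append(("all", samples))
    for label, grp in groups:
        row = {
            "sequence_label": label,
            "n_images": len(grp),
            "detection_agreement_percent": percent_agreement(
                grp["manual_present"], grp["auto_present"]
            ),
        }
        si_cols = {"manual_si", "auto_si"}
        measurable = grp[
            grp["manual_present"] & grp["auto_present"] & grp["quality_ok"]
        ]
        if si_cols <= set(grp.columns):
            measurable = measurable.dropna(subset=list(si_cols))
        else:
            measurable = measurable.iloc[0:0]
        if len(measurable) >= 3:
            csa = compare_methods(measurable["auto_csa_mm2"],
                                  measurable["manual_csa_mm2"])
            si = compare_methods(measurable["auto_si"], measurable["manual_si"])
            row.update({
                "n_measured": len(measurable),
                "csa_spearman_r": csa.spearman_r, "csa_p_value": csa.p_value,
                "csa_mean_ratio": csa.mean_ratio,
                "csa_loa_lower": csa.loa_lower, "csa_loa_upper": csa.loa_upper,
                "si_spearman_r": si.spearman_r, "si_p_value": si.p_value,
                "si_mean_ratio": si.mean_ratio,
                "si_loa_lower": si.loa_lower, "si_loa_upper": si.loa_upper,
            })
        summary_rows.append(row)
    return StudyResult(samples, pd.DataFrame(summary_rows))


STUDIES = {
    "standardisation": run_standardisation_study,
    "roi_comparison": run_roi_comparison,
    "csa_study": run_csa_study,
    "automation_study": run_automation_study,
}


def run_all(config: PipelineConfig, output_dir: str | Path | None = None,
            *, make_plots: bool = False) -> dict[str, StudyResult]:
    """Run the four studies; optionally write CSVs, config and plots."""
    results: dict[str, StudyResult] = {}
    for name, fn in STUDIES.items():
        t0 = time.perf_counter()
        results[name] = fn(config)
        logger.info("%s finished in %.1f s", name, time.perf_counter() - t0)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.save(out / "config.yaml")
        for name, res in results.items():
            save_results(res.samples, out / f"{name}_samples.csv")
            save_results(res.summary, out / f"{name}_summary.csv")
        if make_plots:
            from . import plotting
            plotting.study_plots(results, out)
    return results
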
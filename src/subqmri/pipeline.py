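"""End-to-end orchestration of the phantom aging analysis.

``run_pipeline`` generates (or receives) a phantom cohort and pushes every
subject through the full chain — T2* fitting on the multi-echo magnitudes,
QSM reconstruction from the first-echo phase, conjunction masking, ROI
extraction with CSF thresholding, centers of mass — and then computes the
group summary tables, probabilistic-atlas overlap metrics, location PCA,
and the correlation battery with Bonferroni families. Every stage appends
its parameters to a provenance log, and each emitted table records which
logged operations produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from subqmri import agingstats, io as qio, qsm, segmentation as seg, spatial
from subqmri.phantom import NUCLEI, PhantomSpec, default_spec, generate_cohort
from subqmri.relaxometry import fit_t2star

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "default_families",
           "process_subject"]

#: Structures for which a Dice coefficient is computed (the Bonferroni
#: family for Dice-age correlations): seven gray-matter nuclei plus four
#: ventricular compartments.
DICE_FAMILY_STRUCTURES = (
    "STR", "GPe", "GPi", "RN", "STN", "SN", "PAG",
    "LV", "third_ventricle", "aqueduct", "fourth_ventricle",
)


def default_families() -> dict[str, tuple[str, ...]]:
    """Declared Bonferroni families: analysis block -> member structures."""
    return {
        "dice_age": DICE_FAMILY_STRUCTURES,
        "volume_age": DICE_FAMILY_STRUCTURES,
        "t1_age": NUCLEI,
        "t2star_age": NUCLEI,
        "qsm_age": NUCLEI,
        "location_age": NUCLEI,
    }


@dataclass
class PipelineConfig:
    """All tunable parameters of one pipeline run."""

    spec: PhantomSpec = dc_field(default_factory=default_spec)
    seed: int = 0
    echo_index: int = 0  # echo used for QSM field estimation
    tkd_threshold: float = 0.1
    smv_radius_mm: float = 4.0
    ventricle_erosion_mm: float = 2.0
    unwrap_method: str = "region"
    # CSF upper-threshold rule: structure -> reference compartment
    csf_reference: dict = dc_field(
        default_factory=lambda: {"STR": "LV", "PAG": "aqueduct"}
    )
    csf_threshold_modalities: tuple[str, ...] = ("t1", "t2star")
    families: dict = dc_field(default_factory=default_families)
    dice_covariate: bool = True
    run_qsm: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.tkd_threshold < 2.0 / 3.0:
            raise ValueError("TKD threshold must lie in (0, 2/3)")


@dataclass
class PipelineReport:
    """Bundle of per-subject and group-level results plus provenance."""

    subject_table: pd.DataFrame
    roi_table: pd.DataFrame
    group_tables: dict
    correlations: pd.DataFrame
    atlas_metrics: pd.DataFrame
    pca_scores: pd.DataFrame
    provenance: list
    table_sources: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subject_table.to_csv(out / "subjects.csv", index=False)
        self.roi_table.to_csv(out / "roi_summaries.csv", index=False)
        for name, df in self.group_tables.items():
            df.to_csv(out / f"group_{name}.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.atlas_metrics.to_csv(out / "atlas_overlap.csv", index=False)
        self.pca_scores.to_csv(out / "location_pca.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {"operations": self.provenance, "table_sources": self.table_sources},
                fh,
                indent=2,
                default=str,
            )


class _Provenance:
    def __init__(self) -> None:
        self.entries: list[dict] = []

    def log(self, op: str, **params) -> int:
        self.entries.append({"id": len(self.entries), "op": op, "params": params})
        return len(self.entries) - 1


def _conjunctions(record) -> tuple[dict, dict]:
    """Conjunction masks and Dice per structure/hemisphere."""
    conj, dices = {}, {}
    for key, (r1, r2) in record.rater_masks.items():
        conj[key] = seg.conjunction(r1, r2)
        dices[key] = seg.dice(r1, r2)
    return conj, dices


def _csf_conjunction(conj: dict, name: str) -> np.ndarray | None:
    parts = [m for (n, _h), m in conj.items() if n == name]
    if not parts:
        return None
    out = parts[0]
    for m in parts[1:]:
        out = out | m
    return out if out.any() else None


def process_subject(
    record,
    spec: PhantomSpec,
    config: PipelineConfig,
    prov: _Provenance | None = None,
    smv_valid_mask: np.ndarray | None = None,
) -> list[dict]:
    """Run the per-subject measurement chain; returns tidy ROI rows.

    ``smv_valid_mask`` optionally supplies the precomputed SMV-eroded
    brain mask (all phantom subjects share one brain mask).
    """
    prov = prov or _Provenance()
    conj, dices = _conjunctions(record)
    prov.log("conjunction_and_dice", subject=record.subject_id,
             structures=sorted({k[0] for k in conj}))

    # T2* fit restricted to the voxels any downstream ROI needs
    fit_mask = np.zeros(spec.shape, dtype=bool)
    for m in conj.values():
        fit_mask |= m
    fit = fit_t2star(record.series, mask=fit_mask)
    op_fit = prov.log("fit_t2star", subject=record.subject_id,
                      echo_times_ms=list(spec.echo_times_ms),
                      n_voxels=int(fit_mask.sum()))

    chi = None
    op_qsm = None
    if config.run_qsm:
        fieldmap = qsm.phase_to_field(
            record.series, echo_index=config.echo_index, mask=record.brain_mask,
            f0_mhz=spec.f0_mhz, unwrap_method=config.unwrap_method,
        )
        fieldmap = qsm.remove_background(
            fieldmap, radius_mm=config.smv_radius_mm, valid_mask=smv_valid_mask
        )
        chi_map = qsm.invert_dipole(fieldmap, threshold=config.tkd_threshold)
        lv_conj = _csf_conjunction(conj, "LV")
        if lv_conj is None:
            raise ValueError("no lateral-ventricle mask for QSM normalization")
        chi_map = qsm.normalize_to_ventricles(
            chi_map, lv_conj, erosion_mm=config.ventricle_erosion_mm
        )
        chi = chi_map.chi
        op_qsm = prov.log(
            "qsm_reconstruction", subject=record.subject_id,
            echo_index=config.echo_index, unwrap=config.unwrap_method,
            smv_radius_mm=config.smv_radius_mm,
            tkd_threshold=config.tkd_threshold,
            ventricle_erosion_mm=config.ventricle_erosion_mm,
            reference_offset_ppm=chi_map.reference_offset,
        )

    csf_refs = {
        name: _csf_conjunction(conj, comp)
        for name, comp in config.csf_reference.items()
    }

    voxel = spec.voxel_size
    template_affine = record.to_template @ record.affine
    rows = []
    for (name, hemi), roi in conj.items():
        if not roi.any():
            # the raters genuinely disagreed everywhere; drop this ROI for
            # this subject rather than aborting the cohort
            prov.log("empty_conjunction_skipped", subject=record.subject_id,
                     structure=name, hemisphere=hemi)
            continue
        csf_mask = csf_refs.get(name)
        row = {
            "subject": record.subject_id,
            "age": record.age,
            "group": record.group,
            "structure": name,
            "hemisphere": hemi,
            "dice": dices[(name, hemi)],
            "volume_mm3": seg.mask_volume_mm3(roi, voxel),
            "ventricle_volume_mm3": record.ventricle_volume_mm3,
            "ops": [op_fit] + ([op_qsm] if op_qsm is not None else []),
        }
        for modality, qmap in (("t1", record.t1_map), ("t2star", fit.t2star_ms)):
            ref = csf_mask if modality in config.csf_threshold_modalities else None
            summ = seg.extract_roi_means(qmap, roi, ref, name, hemi)
            row[f"{modality}_mean"] = summ.mean
            row[f"{modality}_mean_unthresholded"] = summ.mean_unthresholded
            row[f"{modality}_csf_threshold"] = summ.csf_threshold
            row[f"{modality}_n_excluded"] = summ.n_excluded
        if chi is not None:
            summ = seg.extract_roi_means(chi, roi, None, name, hemi)
            row["chi_mean"] = summ.mean
        com = spatial.center_of_mass(
            roi, record.affine, record.subject_id, name, hemi
        )
        tpl = (template_affine @ np.linalg.inv(record.affine)
               @ np.append(com.xyz_mm, 1.0))[:3]
        row["com_x"], row["com_y"], row["com_z"] = (float(v) for v in tpl)
        rows.append(row)
    return rows


def _group_tables(roi: pd.DataFrame) -> dict:
    """Mean/SD summary per structure, hemisphere, and age group."""
    tables = {}
    value_cols = {
        "volume": "volume_mm3",
        "dice": "dice",
        "t1": "t1_mean",
        "t2star": "t2star_mean",
    }
    if "chi_mean" in roi.columns:
        value_cols["qsm"] = "chi_mean"
    for name, col in value_cols.items():
        g = (
            roi.groupby(["structure", "hemisphere", "group"], sort=True)[col]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        tables[name] = g
    return tables


def _correlation_battery(roi: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Per-structure correlations with age, Bonferroni-corrected per family.

    Bilateral structures contribute one observation per hemisphere (the
    hemispheres are treated as observations, not nested); the inter-rater
    Dice coefficient enters as a covariate when configured.
    """
    out = []
    families = config.families

    def run_family(family: str, outcome_col: str, members) -> None:
        results, meta = [], []
        for name in members:
            sub = roi[roi["structure"] == name]
            if sub.empty or outcome_col not in sub or sub[outcome_col].isna().any():
                continue
            covs = {}
            if config.dice_covariate and outcome_col != "dice":
                covs["dice"] = sub["dice"].to_numpy()
            try:
                res = agingstats.pearson_age_correlation(
                    sub[outcome_col].to_numpy(),
                    sub["age"].to_numpy(),
                    covariates=covs or None,
                    outcome=f"{name}:{outcome_col}",
                )
            except ValueError:
                continue
            results.append(res)
            meta.append((name, len(sub)))
        if not results:
            return
        agingstats.bonferroni(results, family, family_size=len(members))
        for (name, n), res in zip(meta, results):
            out.append(
                {
                    "family": family,
                    "structure": name,
                    "outcome": res.outcome.split(":")[1],
                    "n_obs": n,
                    "covariates": ",".join(res.covariates),
                    "r": res.r,
                    "df": res.df,
                    "t": res.t,
                    "p_raw": res.p_raw,
                    "p_corrected": res.p_corrected,
                    "family_size": res.family_size,
                    "significant": res.significant,
                }
            )

    run_family("dice_age", "dice", families["dice_age"])
    run_family("volume_age", "volume_mm3", families["volume_age"])
    run_family("t1_age", "t1_mean", families["t1_age"])
    run_family("t2star_age", "t2star_mean", families["t2star_age"])
    if "chi_mean" in roi.columns:
        run_family("qsm_age", "chi_mean", families["qsm_age"])
    return pd.DataFrame(out)


def _location_analysis(
    roi: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mirrored-CoM PCA per nucleus + partial correlation of scores with age."""
    score_rows, corr_results, meta = [], [], []
    members = config.families["location_age"]
    for name in members:
        sub = roi[roi["structure"] == name]
        if len(sub) < 4:
            continue
        records = [
            spatial.CoMRecord(
                subject=r.subject, structure=name, hemisphere=r.hemisphere,
                xyz_mm=(r.com_x, r.com_y, r.com_z),
            )
            for r in sub.itertuples()
        ]
        pca = spatial.location_pca(records, mirror_left=True, structure=name)
        for r, score in zip(sub.itertuples(), pca.scores):
            score_rows.append(
                {
                    "structure": name,
                    "subject": r.subject,
                    "hemisphere": r.hemisphere,
                    "age": r.age,
                    "pc1_score": float(score),
                    "explained_variance_pc1": float(pca.explained_variance_ratio[0]),
                }
            )
        covs = {"ventricle_volume": sub["ventricle_volume_mm3"].to_numpy()}
        if config.dice_covariate:
            covs["dice"] = sub["dice"].to_numpy()
        try:
            res = agingstats.pearson_age_correlation(
                pca.scores, sub["age"].to_numpy(), covariates=covs,
                outcome=f"{name}:pc1_score",
            )
        except ValueError:
            continue  # too few observations or degenerate covariates
        corr_results.append(res)
        meta.append((name, len(sub)))
    if corr_results:
        agingstats.bonferroni(corr_results, "location_age", family_size=len(members))
    corr_rows = [
        {
            "family": "location_age",
            "structure": name,
            "outcome": "pc1_score",
            "n_obs": n,
            "covariates": ",".join(res.covariates),
            "r": res.r,
            "df": res.df,
            "t": res.t,
            "p_raw": res.p_raw,
            "p_corrected": res.p_corrected,
            "family_size": res.family_size,
            "significant": res.significant,
        }
        for (name, n), res in zip(meta, corr_results)
    ]
    return pd.DataFrame(score_rows), pd.DataFrame(corr_rows)


def _atlas_metrics(records, roi: pd.DataFrame) -> pd.DataFrame:
    """Maximum / mean percentage overlap per structure, hemisphere, group."""
    rows = []
    by_key: dict[tuple, dict[str, list]] = {}
    for rec in records:
        for key, (r1, r2) in rec.rater_masks.items():
            by_key.setdefault(key, {}).setdefault(rec.group, []).append(
                seg.conjunction(r1, r2)
            )
    for (name, hemi), groups in sorted(by_key.items()):
        for group, masks in sorted(groups.items()):
            if len(masks) < 2:
                continue
            atlas = spatial.overlap_metrics(masks, structure=name, group=group)
            rows.append(
                {
                    "structure": name,
                    "hemisphere": hemi,
                    "group": group,
                    "n_subjects": atlas.n_subjects,
                    "max_overlap_pct": atlas.max_overlap,
                    "mean_overlap_pct": atlas.mean_overlap,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    records=None,
    out_dir=None,
) -> PipelineReport:
    """Run the full analysis; simulates the cohort unless records are given."""
    prov = _Provenance()
    spec = config.spec
    if records is None:
        prov.log("generate_cohort", seed=config.seed,
                 group_sizes=dict(spec.group_sizes), noise_sd=spec.noise_sd,
                 echo_times_ms=list(spec.echo_times_ms))
        records = generate_cohort(spec, seed=config.seed, simulate=True)

    smv_valid = None
    if config.run_qsm and records:
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(
            records[0].brain_mask, sampling=spec.voxel_size
        )
        smv_valid = dist > config.smv_radius_mm

    rows = []
    for rec in records:
        mask_ok = smv_valid is not None and np.array_equal(
            rec.brain_mask, records[0].brain_mask
        )
        rows.extend(
            process_subject(
                rec, spec, config, prov,
                smv_valid_mask=smv_valid if mask_ok else None,
            )
        )
    roi = pd.DataFrame(rows)
    roi_ops = sorted({op for ops in roi.pop("ops") for op in ops})

    subject_table = pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "group": [r.group for r in records],
            "seed": [r.seed for r in records],
        }
    )

    # the nuclei tables exclude CSF compartments; dice/volume keep them
    group_tables = _group_tables(roi)
    correlations = _correlation_battery(roi, config)
    pca_scores, location_corr = _location_analysis(roi, config)
    if not location_corr.empty:
        correlations = pd.concat([correlations, location_corr], ignore_index=True)
    atlas = _atlas_metrics(records, roi)
    op_tables = prov.log(
        "group_statistics", families={k: list(v) for k, v in config.families.items()},
        dice_covariate=config.dice_covariate, alpha=0.05,
    )

    table_sources = {
        "roi_summaries": roi_ops,
        "subjects": [0],
        "correlations": roi_ops + [op_tables],
        "atlas_overlap": roi_ops + [op_tables],
        "location_pca": roi_ops + [op_tables],
        **{f"group_{k}": roi_ops + [op_tables] for k in group_tables},
    }
    report = PipelineReport(
        subject_table=subject_table,
        roi_table=roi,
        group_tables=group_tables,
        correlations=correlations,
        atlas_metrics=atlas,
        pca_scores=pca_scores,
        provenance=prov.entries,
        table_sources=table_sources,
    )
    if out_dir is not None:
        report.write(out_dir)
        qio.save_subject_table(records, Path(out_dir) / "subjects.csv")
    return report
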
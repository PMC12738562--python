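"""End-to-end orchestration: simulate -> fit -> analyze.

These functions are the library behind the command-line interface; they work
on an on-disk dataset layout (NIfTI volumes + CSV tables + plain-text offset
sidecar) so each stage can be re-run independently.  The acceptance and test
suites drive the same code paths in memory where disk I/O is irrelevant.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import config as cfgmod
from . import roi_pipeline as roi
from . import stats as st
from . import synthetic_data as sd
from . import zspectrum_fitting as zf
from .atlas import CSF_CODE, RIGHT_OFFSET, REGION_CODES
from .t1_mapping import compute_t1_dfa

log = logging.getLogger("guancest")


def run_simulate(cfg: dict, out_dir) -> pd.DataFrame:
    """Generate the synthetic dataset on disk; returns the cohort table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    c = cfg["cohort"]
    cohort = sd.simulate_clinical_cohort(c["n_pwpd"], c["n_hc"], c["seed"])
    acq = cfgmod.make_acquisition(cfg)
    eff = cfgmod.make_effect(cfg)
    sd.write_dataset(out, cohort, eff, acq, c["seed"],
                     regions=tuple(cfg["phantom"]["regions"]),
                     blob_shape=tuple(cfg["phantom"]["blob_shape"]))
    cfgmod.dump_config(cfg, out / "resolved_config.yaml")
    log.info("simulated %d subjects -> %s", len(cohort), out)
    return sd.cohort_to_frame(cohort)


def _fit_mask(labels: np.ndarray) -> np.ndarray:
    return (labels > 0) & (labels != CSF_CODE)


def run_fit(cfg: dict, data_dir) -> None:
    """Voxel-wise PLOF + DFA T1 for every subject in a dataset directory."""
    data = Path(data_dir)
    cohort = pd.read_csv(data / "cohort.csv")
    offsets = np.loadtxt(data / "offsets_ppm.txt")
    labels_img = nib.load(data / "labels.nii.gz")
    labels = np.asarray(labels_img.dataobj).astype(np.int16)
    plof = cfgmod.make_plof(cfg)
    dfa = cfgmod.make_dfa(cfg)

    missing = [sid for sid in cohort.subject_id
               if not (data / sid / "cest.nii.gz").exists()]
    if missing:
        raise FileNotFoundError(f"missing CEST volumes for subjects: {missing}")

    for sid in cohort.subject_id:
        sub = data / sid
        cest = np.asarray(nib.load(sub / "cest.nii.gz").dataobj)
        if cest.shape[3] != offsets.size:
            raise ValueError(
                f"{sub / 'cest.nii.gz'}: 4th axis ({cest.shape[3]}) does not "
                f"match offsets_ppm.txt ({offsets.size})")
        maps = zf.fit_map(cest, offsets, _fit_mask(labels), plof)
        for key in ("guan_pct", "amide_pct", "rmse", "b0_ppm"):
            nib.save(nib.Nifti1Image(maps[key].astype(np.float32), labels_img.affine),
                     sub / f"{key}.nii.gz")
        nib.save(nib.Nifti1Image(maps["converged"], labels_img.affine),
                 sub / "converged.nii.gz")
        s_low = np.asarray(nib.load(sub / "spgr_low.nii.gz").dataobj)
        s_high = np.asarray(nib.load(sub / "spgr_high.nii.gz").dataobj)
        t1 = compute_t1_dfa(s_low, s_high, dfa)
        nib.save(nib.Nifti1Image(t1.t1_ms.astype(np.float32), labels_img.affine),
                 sub / "t1_ms.nii.gz")
        n_fit = int(np.isfinite(maps["guan_pct"]).sum())
        n_conv = int(maps["converged"].sum())
        (sub / "fit_log.json").write_text(json.dumps(
            {"subject": sid, "fitted_voxels": n_fit, "converged_voxels": n_conv,
             "t1_valid_voxels": int(t1.valid.sum())}))
        log.info("fitted %s: %d voxels (%d converged)", sid, n_fit, n_conv)


def build_region_table(cfg: dict, data_dir, metric: str = "guan_pct") -> pd.DataFrame:
    """Combined-hemisphere, outlier-flagged region table for one metric."""
    data = Path(data_dir)
    cohort = pd.read_csv(data / "cohort.csv")
    labels = np.asarray(nib.load(data / "labels.nii.gz").dataobj).astype(np.int16)
    regions = list(cfg["phantom"]["regions"])
    rows = []
    for _, subj in cohort.iterrows():
        sub = data / subj.subject_id
        vol = np.asarray(nib.load(sub / f"{metric}.nii.gz").dataobj)
        conv = np.asarray(nib.load(sub / "converged.nii.gz").dataobj).astype(bool)
        per_hemi = roi.extract_roi_means(vol, labels, regions, qc_mask=conv,
                                         subject_id=subj.subject_id)
        rows.append(roi.hemisphere_select(per_hemi, subj.group, subj.affected_side))
    table = pd.concat(rows, ignore_index=True)
    groups = dict(zip(cohort.subject_id, cohort.group))
    table = roi.filter_region_table(table, groups,
                                    cfg["stats"]["fence_multiplier"])
    return roi.add_composites(table)


def group_stats(table: pd.DataFrame, cohort: pd.DataFrame, alpha: float = 0.05) -> dict:
    """t-tests per region (HC vs PwPD), Kendall tau-b vs motor severity in
    patients, and ANCOVA for regions whose correlation is significant."""
    merged = table.merge(
        cohort[["subject_id", "group", "updrs3", "age_years", "sex"]],
        on="subject_id")
    usable = merged[~merged.excluded & merged.value_pct.notna()]

    ttests, kendalls, ancovas = [], [], []
    for region, sub in usable.groupby("region", sort=False):
        hc = sub[sub.group == "HC"].value_pct.to_numpy()
        pwpd = sub[sub.group == "PwPD"].value_pct.to_numpy()
        if hc.size >= 2 and pwpd.size >= 2:
            r = st.two_sample_ttest(hc, pwpd)
            ttests.append({"region": region, "t": r.t_stat, "df": r.df,
                           "p": r.p_two_sided, "mean_hc": r.mean_a, "sd_hc": r.sd_a,
                           "n_hc": r.n_a, "mean_pwpd": r.mean_b, "sd_pwpd": r.sd_b,
                           "n_pwpd": r.n_b})
        pat = sub[sub.group == "PwPD"]
        if len(pat) >= 3 and pat.value_pct.nunique() > 1 and pat.updrs3.nunique() > 1:
            k = st.kendall_tau_b(pat.value_pct.to_numpy(), pat.updrs3.to_numpy())
            kendalls.append({"region": region, "tau_b": k.tau_b, "p": k.p_value,
                             "n": k.n})
            if k.p_value < alpha and len(pat) > 4 and pat.sex.nunique() > 1:
                a = st.ancova_fit(pat.value_pct.to_numpy(), pat.updrs3.to_numpy(),
                                  pat.age_years.to_numpy(), list(pat.sex))
                ancovas.append({"region": region,
                                "beta_severity": a.params["severity"],
                                "se_severity": a.bse["severity"],
                                "p_severity": a.pvalues["severity"],
                                "beta_age": a.params["age"],
                                "beta_sex": a.params["sex"], "n": a.n})
    return {"ttest": pd.DataFrame(ttests), "kendall": pd.DataFrame(kendalls),
            "ancova": pd.DataFrame(ancovas)}


def run_analyze(cfg: dict, data_dir, out_dir) -> dict:
    """Region tables, statistics, difference map and a run report."""
    data, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(data / "cohort.csv")
    if cohort.group.nunique() < 2:
        log.warning("single-group dataset: group comparisons skipped")

    results = {}
    for metric in ("guan_pct", "amide_pct"):
        table = build_region_table(cfg, data, metric)
        table.to_csv(out / f"region_table_{metric}.csv", index=False)
        if cohort.group.nunique() >= 2:
            stats = group_stats(table, cohort, cfg["stats"]["alpha"])
            for name, df in stats.items():
                df.to_csv(out / f"{name}_{metric}.csv", index=False)
            results[metric] = {"table": table, **stats}
        else:
            results[metric] = {"table": table}

    # normalized group-difference map on the guanidino channel
    if cohort.group.nunique() >= 2:
        labels_img = nib.load(data / "labels.nii.gz")
        hc_maps, pwpd = [], []
        csf = None
        for _, subj in cohort.iterrows():
            sub = data / subj.subject_id
            vol = np.asarray(nib.load(sub / "guan_pct.nii.gz").dataobj)
            if csf is None:
                t1w = np.asarray(nib.load(sub / "t1w.nii.gz").dataobj)
                csf = roi.csf_mask(t1w, cfg["stats"]["csf_threshold_fraction"])
            if subj.group == "HC":
                hc_maps.append(vol)
            else:
                pwpd.append((vol, subj.affected_side))
        dmap = roi.difference_map(hc_maps, pwpd, csf)
        nib.save(nib.Nifti1Image(dmap.astype(np.float32), labels_img.affine),
                 out / "difference_map.nii.gz")
        results["difference_map"] = dmap

    # run report: all exclusions, never silent
    lines = ["analysis report", "================"]
    for metric in ("guan_pct", "amide_pct"):
        excl = results[metric]["table"]
        excl = excl[excl.excluded]
        lines.append(f"{metric}: {len(excl)} excluded region rows")
        for _, r in excl.iterrows():
            lines.append(f"  {r.subject_id} {r.region} [{r.hemisphere}]: {r.reason}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    cfgmod.dump_config(cfg, out / "resolved_config.yaml")
    return results
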